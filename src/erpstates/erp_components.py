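"""P1/N170 component measurement and within-subject ANOVA statistics.

Peaks are marked on the ROI-mean waveform as the first local extremum of
the component's polarity inside a search window; amplitudes are quantified
as per-electrode means over a 40 ms window centred on each condition's
peak, so amplitude comparisons are free of latency confounds.

``rm_anova`` implements the classical fully-crossed repeated-measures
ANOVA for any number of within-subject factors on a balanced table:
F-ratios from the balanced tensor decomposition (each effect tested
against its interaction with subjects), Greenhouse-Geisser epsilon from
the covariance of orthonormal contrast scores, and partial eta squared
per effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ConfigurationError, Evoked, PipelineError, grand_average

__all__ = [
    "ComponentDef",
    "PeakResult",
    "P1_DEF",
    "N1_DEF",
    "find_peak",
    "mean_amplitude",
    "measure_table",
    "rm_anova",
    "planned_contrast",
    "behavior_stats",
    "electrode_factors",
]

#: Analysis electrode sets (defined in the source study by inspection of
#: difference topographies; fixed defaults here).
P1_ELECTRODES = ("O1", "OZ", "O2", "PO3", "POZ", "PO4")
N1_ELECTRODES = ("CB1", "CB2", "P7", "P8", "PO5", "PO6", "PO7", "PO8")

#: electrode -> (location/hemisphere level, site level) for the factorial
#: electrode models: P1 uses Location (occipital vs parieto-occipital) x
#: Site (3); N1 uses Hemisphere (left vs right) x Site (4).
P1_ELECTRODE_FACTORS = {
    "O1": ("occipital", "s1"),
    "OZ": ("occipital", "s2"),
    "O2": ("occipital", "s3"),
    "PO3": ("parieto-occipital", "s1"),
    "POZ": ("parieto-occipital", "s2"),
    "PO4": ("parieto-occipital", "s3"),
}
N1_ELECTRODE_FACTORS = {
    "CB1": ("left", "s1"),
    "P7": ("left", "s2"),
    "PO5": ("left", "s3"),
    "PO7": ("left", "s4"),
    "CB2": ("right", "s1"),
    "P8": ("right", "s2"),
    "PO6": ("right", "s3"),
    "PO8": ("right", "s4"),
}


@dataclass(frozen=True)
class ComponentDef:
    """A component to measure: polarity, search window, electrode ROI."""

    name: str
    polarity: int  # +1 or -1
    search_window_ms: tuple[float, float]
    electrode_set: tuple[str, ...]
    mean_amp_halfwidth_ms: float = 20.0

    def __post_init__(self):
        if self.polarity not in (+1, -1):
            raise ConfigurationError("polarity must be +1 or -1")


#: Search windows enclose the observed latency ranges (P1 114-119 ms,
#: N170 159-170 ms) with margin.
P1_DEF = ComponentDef("P1", +1, (80.0, 160.0), P1_ELECTRODES)
N1_DEF = ComponentDef("N1", -1, (130.0, 210.0), N1_ELECTRODES)


@dataclass(frozen=True)
class PeakResult:
    found: bool
    latency_ms: float = np.nan
    amplitude_uv: float = np.nan


def _roi_waveform(ev: Evoked, comp: ComponentDef) -> np.ndarray:
    idx = ev.montage.indices(comp.electrode_set)
    return ev.data[idx].mean(axis=0)


def find_peak(ev: Evoked, comp: ComponentDef) -> PeakResult:
    """First local extremum of the component's polarity on the ROI mean.

    The waveform is the mean over ``comp.electrode_set``; candidates are
    interior local extrema within the search window whose signed value
    matches the polarity; the earliest qualifies (plateaus and exact ties
    therefore resolve to the earliest latency). No extremum -> a flagged
    missing-peak result, never a window edge.
    """
    t = ev.times_ms
    w = comp.polarity * _roi_waveform(ev, comp)
    lo, hi = comp.search_window_ms
    inside = np.flatnonzero((t >= lo) & (t < hi))
    for i in inside:
        if i == 0 or i == len(w) - 1:
            continue
        if w[i] >= w[i - 1] and w[i] >= w[i + 1] and w[i] > 0:
            if w[i] > w[i - 1] or w[i] > w[i + 1]:
                return PeakResult(True, float(t[i]), float(comp.polarity * w[i]))
    return PeakResult(False)


def mean_amplitude(ev: Evoked, comp: ComponentDef, peak_latency_ms: float) -> pd.Series:
    """Per-electrode mean voltage over [peak-hw, peak+hw) (default 40 ms)."""
    hw = comp.mean_amp_halfwidth_ms
    i0 = ev.time_index(peak_latency_ms - hw)
    i1 = ev.time_index(peak_latency_ms + hw)
    n_time = ev.data.shape[1]
    if i0 < 0 or i1 > n_time or i1 <= i0:
        raise PipelineError(
            f"{comp.name}: mean-amplitude window around {peak_latency_ms} ms "
            "clipped by the epoch edge"
        )
    idx = ev.montage.indices(comp.electrode_set)
    vals = ev.data[idx, i0:i1].mean(axis=1)
    return pd.Series(vals, index=list(comp.electrode_set), name="mean_amplitude_uv")


def measure_table(
    evokeds: list[tuple[int, dict, Evoked]],
    comp: ComponentDef,
    peak_from: str = "condition",
) -> pd.DataFrame:
    """Long measurement table: subject x condition x electrode.

    ``evokeds`` holds (subject, condition-labels, Evoked) triples. The
    40 ms mean-amplitude window is centred on each condition's
    grand-average peak (``peak_from="condition"``, the reported-analysis
    convention) or on each subject's own peak (``"subject"``). Per-subject
    peak latency/amplitude from the subject ROI waveform are included;
    subjects with no detectable peak get NaN latency rows and a warning.
    """
    if peak_from not in ("condition", "subject"):
        raise ConfigurationError("peak_from must be 'condition' or 'subject'")
    by_cond: dict[tuple, list] = {}
    for subject, cond, ev in evokeds:
        key = tuple(sorted(cond.items()))
        by_cond.setdefault(key, []).append((subject, cond, ev))

    rows = []
    for key, items in by_cond.items():
        cond = dict(key)
        ga = grand_average([ev for _, _, ev in items])
        cond_peak = find_peak(ga, comp)
        if not cond_peak.found:
            warnings.warn(f"{comp.name}: no grand-average peak for {cond!r}")
        for subject, _, ev in items:
            sp = find_peak(ev, comp)
            if not sp.found:
                warnings.warn(
                    f"{comp.name}: no peak for subject {subject} in {cond!r}"
                )
            centre = None
            if peak_from == "condition" and cond_peak.found:
                centre = cond_peak.latency_ms
            elif peak_from == "subject" and sp.found:
                centre = sp.latency_ms
            amps = (
                mean_amplitude(ev, comp, centre)
                if centre is not None
                else pd.Series(np.nan, index=list(comp.electrode_set))
            )
            for electrode in comp.electrode_set:
                rows.append(
                    {
                        "subject": subject,
                        **cond,
                        "electrode": electrode,
                        "peak_latency_ms": sp.latency_ms,
                        "peak_amplitude_uv": sp.amplitude_uv,
                        "mean_amplitude_uv": float(amps[electrode]),
                    }
                )
    return pd.DataFrame(rows)


def electrode_factors(table: pd.DataFrame, comp_name: str) -> pd.DataFrame:
    """Add the factorial electrode columns (location/hemisphere, site)."""
    mapping = P1_ELECTRODE_FACTORS if comp_name == "P1" else N1_ELECTRODE_FACTORS
    out = table.copy()
    first = {k: v[0] for k, v in mapping.items()}
    second = {k: v[1] for k, v in mapping.items()}
    col = "location" if comp_name == "P1" else "hemisphere"
    out[col] = out["electrode"].map(first)
    out["site"] = out["electrode"].map(second)
    return out


# ------------------------------------------------------------------ rmANOVA


def _contrast_basis(n_levels: int) -> np.ndarray:
    """Orthonormal basis of the between-level contrast space, (l-1, l)."""
    centering = np.eye(n_levels) - 1.0 / n_levels
    u, s, _ = np.linalg.svd(centering)
    return u[:, s > 1e-9].T


def _tensorize(table: pd.DataFrame, factors: list[str], dependent: str):
    """Pivot a long balanced table into (n_subjects, l1, ..., lk)."""
    subjects = list(pd.unique(table["subject"]))
    levels = [list(pd.unique(table[f])) for f in factors]
    grouped = table.groupby(["subject", *factors], sort=False, observed=True)[
        dependent
    ].mean()
    shape = (len(subjects), *map(len, levels))
    tensor = np.full(shape, np.nan)
    index = {s: i for i, s in enumerate(subjects)}
    level_index = [{lv: i for i, lv in enumerate(lvls)} for lvls in levels]
    for key, val in grouped.items():
        key = (key,) if len(factors) == 0 else key
        subj, *cells = key if isinstance(key, tuple) else (key,)
        pos = (index[subj], *[li[c] for li, c in zip(level_index, cells)])
        tensor[pos] = val
    if np.isnan(tensor).any():
        missing = []
        it = np.argwhere(np.isnan(tensor))
        for pos in it[:20]:
            cell = [subjects[pos[0]]] + [
                levels[d][pos[d + 1]] for d in range(len(factors))
            ]
            missing.append(tuple(cell))
        raise ConfigurationError(
            f"incomplete design: missing subject x condition cells {missing}"
        )
    return tensor, subjects, levels


def rm_anova(
    table: pd.DataFrame, factors: list[str], dependent: str
) -> pd.DataFrame:
    """Repeated-measures ANOVA for a fully-crossed within-subject design.

    Returns one row per main effect and interaction with columns
    ``effect, F, df_num, df_den, gg_epsilon, p_uncorrected, p_gg,
    partial_eta_sq, ss_effect, ss_error``. Replicate rows within a
    subject x cell (e.g. multiple electrodes when electrode is not a
    factor) are averaged before analysis. Greenhouse-Geisser epsilon is 1
    by construction for single-df effects.
    """
    if not factors:
        raise ConfigurationError("rm_anova needs at least one factor")
    tensor, subjects, levels = _tensorize(table, factors, dependent)
    n = len(subjects)
    if n < 2:
        raise ConfigurationError("rm_anova needs at least two subjects")
    k = len(factors)
    n_levels = [len(lv) for lv in levels]

    rows = []
    for subset in chain.from_iterable(
        combinations(range(k), r) for r in range(1, k + 1)
    ):
        other = [d for d in range(k) if d not in subset]
        # collapse factors outside the effect (axis 0 is subjects)
        collapsed = tensor.mean(axis=tuple(d + 1 for d in other), keepdims=False)
        # collapsed has shape (n, levels of subset factors in original order)
        df_num = int(np.prod([n_levels[d] - 1 for d in subset]))
        if df_num == 0:  # a single-level factor (e.g. after subsetting)
            continue
        mult = float(np.prod([n_levels[d] for d in other]))

        cell_means = collapsed.mean(axis=0)
        eff = cell_means.copy()
        for ax in range(eff.ndim):
            eff = eff - eff.mean(axis=ax, keepdims=True)
        ss_eff = n * mult * float((eff**2).sum())

        resid = collapsed.copy()
        for ax in range(resid.ndim):
            resid = resid - resid.mean(axis=ax, keepdims=True)
        ss_err = mult * float((resid**2).sum())
        ss_err = max(ss_err - 0.0, 0.0)

        df_den = (n - 1) * df_num
        ms_eff = ss_eff / df_num
        ms_err = ss_err / df_den
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)

        # Greenhouse-Geisser epsilon from orthonormal contrast scores
        if df_num == 1:
            eps = 1.0
        else:
            C = _contrast_basis(n_levels[subset[0]])
            for d in subset[1:]:
                C = np.kron(C, _contrast_basis(n_levels[d]))
            Y = collapsed.reshape(n, -1)
            scores = Y @ C.T
            sigma = np.cov(scores, rowvar=False, ddof=1)
            tr = np.trace(sigma)
            denom = df_num * float((sigma**2).sum())
            eps = float(tr**2 / denom) if denom > 0 else 1.0
            eps = min(1.0, max(eps, 1.0 / df_num))

        p_unc = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0
        p_gg = (
            float(stats.f.sf(F, eps * df_num, eps * df_den))
            if np.isfinite(F)
            else 0.0
        )
        pes = (
            ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        )
        rows.append(
            {
                "effect": ":".join(factors[d] for d in subset),
                "F": float(F),
                "df_num": df_num,
                "df_den": df_den,
                "gg_epsilon": float(eps),
                "p_uncorrected": p_unc,
                "p_gg": p_gg,
                "partial_eta_sq": float(pes),
                "ss_effect": ss_eff,
                "ss_error": ss_err,
            }
        )
    return pd.DataFrame(rows)


def planned_contrast(
    table: pd.DataFrame,
    subset: dict,
    factors: list[str],
    dependent: str,
) -> pd.DataFrame:
    """rm_anova on the subset of rows matching ``subset`` column filters."""
    mask = pd.Series(True, index=table.index)
    for col, val in subset.items():
        mask &= table[col] == val
    sub = table[mask]
    if sub.empty:
        raise ConfigurationError(f"planned contrast subset {subset!r} is empty")
    return rm_anova(sub, factors, dependent)


def posthoc_pairwise(
    table: pd.DataFrame, factor: str, dependent: str
) -> pd.DataFrame:
    """Paired t-tests between factor levels with Holm correction."""
    cells = (
        table.groupby(["subject", factor], sort=False, observed=True)[dependent]
        .mean()
        .unstack(factor)
    )
    pairs = list(combinations(cells.columns, 2))
    rows = []
    for a, b in pairs:
        t, p = stats.ttest_rel(cells[a], cells[b])
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    order = np.argsort(out["p"].to_numpy())
    m = len(out)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * out["p"].iloc[i])
        adj[i] = min(1.0, running)
    out["p_holm"] = adj
    return out


def behavior_stats(
    beh: pd.DataFrame,
    factors: list[str] = ("role", "category", "colour"),
    rt_floor_ms: float = 100.0,
    deviants_only: bool = True,
) -> dict[str, pd.DataFrame]:
    """Accuracy and reaction-time ANOVAs over the deviant conditions.

    Accuracy is the per-cell proportion correct over all valid trials;
    RT averages correct responses at or above the floor (anticipations
    below 100 ms are excluded). Returns ``{"accuracy": ..., "rt": ...}``.
    """
    factors = list(factors)
    data = beh[beh["role"] != "standard"] if deviants_only else beh
    acc = (
        data.groupby(["subject", *factors], sort=False, observed=True)["correct"]
        .mean()
        .reset_index()
        .rename(columns={"correct": "accuracy"})
    )
    valid_rt = data[(data["rt_ms"] >= rt_floor_ms) & data["correct"]]
    rt_counts = valid_rt.groupby(["subject", *factors], observed=True).size()
    expected = acc.set_index(["subject", *factors]).index
    empty = expected.difference(rt_counts.index)
    if len(empty):
        raise PipelineError(
            f"subjects with zero valid RTs in cells: {list(empty[:10])}"
        )
    rt = (
        valid_rt.groupby(["subject", *factors], sort=False, observed=True)["rt_ms"]
        .mean()
        .reset_index()
    )
    return {
        "accuracy": rm_anova(acc, factors, "accuracy"),
        "rt": rm_anova(rt, factors, "rt_ms"),
    }
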