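"""Functional microstate segmentation of averaged ERPs.

Scalp-map series are segmented with the atomize-and-agglomerate
hierarchical clustering (AAHC): every timepoint map starts as its own
cluster; at each step the cluster contributing least to the global
explained variance is dissolved and its members are reassigned to the
best-correlated surviving cluster. Template maps are the (renormalized)
member mean in polarity-sensitive mode — the convention for ERP data,
where a P1-positive and an N1-negative map are genuinely different states
— or the first principal orientation in polarity-invariant mode.

Model order is chosen with the modified predictive-residual-variance
cross-validation criterion, which multiplies the residual variance by
((N_ch - 1) / (N_ch - 1 - K))^2 to penalize the map count. Chosen
templates are back-fitted to individual condition ERPs by spatial
correlation, yielding per-map explained variance (GFP-weighted squared
correlation over assigned timepoints) and mean-GFP fitting statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ConfigurationError, Evoked, PipelineError

__all__ = [
    "MicrostateModel",
    "BackfitResult",
    "concatenate_maps",
    "segment",
    "cross_validation_criterion",
    "select_k",
    "backfit",
    "fit_statistics",
    "name_maps_by_latency",
]

_FLAT_TOL = 1e-12


@dataclass
class MicrostateModel:
    """K template maps with training-fit diagnostics."""

    k: int
    templates: np.ndarray  # (K, n_channels), zero mean, unit GFP
    channel_names: tuple[str, ...]
    polarity_sensitive: bool
    residual_variance: float  # uV^2, predictive residual on training maps
    cv_score: float  # penalized residual variance, uV^2
    gev_total: float
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.templates.shape[1]


@dataclass
class BackfitResult:
    """Per-timepoint template assignment for one ERP plus map statistics."""

    labels: np.ndarray  # 1..K, 0 = unassigned
    times_ms: np.ndarray
    correlations: np.ndarray  # signed spatial correlation with winning map
    stats: pd.DataFrame  # per map: explained_variance, mean_gfp_uv, coverage_ms
    gev_total: float


def _center(maps: np.ndarray) -> np.ndarray:
    return maps - maps.mean(axis=1, keepdims=True)


def _unit_rows(maps: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(maps, axis=1, keepdims=True)
    norm = np.where(norm < _FLAT_TOL, 1.0, norm)
    return maps / norm


def concatenate_maps(evokeds: list[Evoked], window_ms: tuple[float, float] | None = None):
    """Stack average-referenced scalp maps from evokeds into (T, n_ch).

    Returns (maps, times_ms, channel_names); ``times_ms`` repeats the
    evoked time axis per condition.
    """
    if not evokeds:
        raise ConfigurationError("no evokeds to concatenate")
    names = evokeds[0].montage.scalp_names
    blocks, times = [], []
    for ev in evokeds:
        if ev.montage.scalp_names != names:
            raise ConfigurationError("montage mismatch across evokeds")
        t = ev.times_ms
        data = ev.scalp_data()
        if window_ms is not None:
            keep = (t >= window_ms[0]) & (t < window_ms[1])
            t, data = t[keep], data[:, keep]
        blocks.append(_center(data.T))
        times.append(t)
    return np.vstack(blocks), np.concatenate(times), names


def _assign(maps: np.ndarray, templates: np.ndarray, polarity_sensitive: bool):
    """(labels 0-based, signed corr with winner); flat maps get label -1."""
    m_norm = np.linalg.norm(maps, axis=1)
    t_unit = _unit_rows(templates)
    corr = maps @ t_unit.T
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = corr / np.where(m_norm < _FLAT_TOL, np.nan, m_norm)[:, None]
    score = corr if polarity_sensitive else np.abs(corr)
    labels = np.nanargmax(
        np.where(np.isnan(score), -np.inf, score), axis=1
    )  # argmax ties -> lowest index
    winner = np.take_along_axis(corr, labels[:, None], axis=1)[:, 0]
    labels = np.where(m_norm < _FLAT_TOL, -1, labels)
    winner = np.where(m_norm < _FLAT_TOL, np.nan, winner)
    return labels, winner


def _template_of(members: np.ndarray, polarity_sensitive: bool) -> np.ndarray:
    if polarity_sensitive:
        t = members.mean(axis=0)
    else:
        # first principal orientation of the member maps
        _, _, vt = np.linalg.svd(members, full_matrices=False)
        t = vt[0]
        # orient along the majority polarity for reproducibility
        if (members @ t).sum() < 0:
            t = -t
    norm = np.linalg.norm(t)
    if norm < _FLAT_TOL:
        raise PipelineError("degenerate (flat) template encountered")
    return t / norm


def _model_from_clusters(
    maps, templates_unit, channel_names, polarity_sensitive, meta
) -> MicrostateModel:
    n_ch = maps.shape[1]
    k = templates_unit.shape[0]
    labels, corr = _assign(maps, templates_unit, polarity_sensitive)
    norms2 = (maps**2).sum(axis=1)
    proj2 = np.zeros(len(maps))
    ok = labels >= 0
    proj2[ok] = (corr[ok] ** 2) * norms2[ok]
    gev_total = float(proj2.sum() / norms2.sum()) if norms2.sum() > 0 else 0.0
    sigma2 = float((norms2 - proj2).sum() / (len(maps) * (n_ch - 1)))
    if k >= n_ch - 1:
        cv = np.nan
    else:
        cv = sigma2 * ((n_ch - 1) / (n_ch - 1 - k)) ** 2
    # templates stored at unit GFP (spatial RMS 1)
    templates_gfp = templates_unit * np.sqrt(n_ch)
    return MicrostateModel(
        k=k,
        templates=templates_gfp,
        channel_names=tuple(channel_names),
        polarity_sensitive=polarity_sensitive,
        residual_variance=sigma2,
        cv_score=float(cv) if np.isfinite(sigma2) else np.nan,
        gev_total=gev_total,
        meta=dict(meta),
    )


def segment(
    grand_evokeds: list[Evoked],
    k_range: tuple[int, int] = (2, 8),
    polarity_sensitive: bool = True,
    window_ms: tuple[float, float] | None = (0.0, 500.0),
    gfp_peaks_only: bool = False,
    seed: int | None = None,
) -> list[MicrostateModel]:
    """AAHC segmentation of concatenated grand-average maps.

    Returns one fitted model per K in ``k_range`` (inclusive), smallest K
    first. ``seed`` is accepted for interface symmetry; the agglomeration
    itself is deterministic.
    """
    maps, times, names = concatenate_maps(grand_evokeds, window_ms)
    if gfp_peaks_only:
        g = np.sqrt((maps**2).mean(axis=1))
        interior = (g[1:-1] >= g[:-2]) & (g[1:-1] >= g[2:])
        keep = np.flatnonzero(interior) + 1
        maps = maps[keep]
        times = times[keep]
    # drop flat maps from training
    norms = np.linalg.norm(maps, axis=1)
    maps = maps[norms > _FLAT_TOL]
    k_min, k_max = int(k_range[0]), int(k_range[1])
    if not (1 <= k_min <= k_max <= len(maps)):
        raise ConfigurationError(
            f"k_range {k_range} incompatible with {len(maps)} distinct maps"
        )

    meta = {
        "window_ms": window_ms,
        "n_training_maps": int(len(maps)),
        "gfp_peaks_only": gfp_peaks_only,
        "k_range": (k_min, k_max),
        "seed": seed,
    }

    # --- atomize: one cluster per training map
    members: list[list[int]] = [[i] for i in range(len(maps))]
    templates = _unit_rows(maps.copy())
    norms2 = (maps**2).sum(axis=1)
    # contribution of each cluster to total explained variance
    contrib = [(maps[i] @ templates[j]) ** 2 for j, [i] in enumerate(members)]
    contrib = np.array(contrib)

    models: dict[int, MicrostateModel] = {}

    def record(k):
        if k_min <= k <= k_max:
            models[k] = _model_from_clusters(
                maps, templates, names, polarity_sensitive, meta
            )

    record(len(members))
    while len(members) > k_min:
        worst = int(np.argmin(contrib))
        orphans = members.pop(worst)
        templates = np.delete(templates, worst, axis=0)
        contrib = np.delete(contrib, worst)
        labels, _ = _assign(maps[orphans], templates, polarity_sensitive)
        touched = set()
        for orphan, lab in zip(orphans, labels):
            members[int(lab)].append(orphan)
            touched.add(int(lab))
        for j in touched:
            mem = maps[members[j]]
            templates[j] = _template_of(mem, polarity_sensitive)
            proj = mem @ templates[j]
            contrib[j] = float((proj**2).sum())
        record(len(members))
    return [models[k] for k in sorted(models)]


def cross_validation_criterion(model: MicrostateModel, maps: np.ndarray) -> float:
    """Modified predictive residual variance of ``model`` on map series.

    sigma^2 = sum_t (v_t'v_t - (u_Lt' v_t)^2) / (T (N_ch - 1)), penalized
    by ((N_ch - 1) / (N_ch - 1 - K))^2. Undefined (error) for
    K >= N_ch - 1.
    """
    maps = _center(np.asarray(maps, float))
    n_ch = maps.shape[1]
    if model.k >= n_ch - 1:
        raise ConfigurationError(
            f"cross-validation criterion undefined for K={model.k} >= N_ch-1={n_ch - 1}"
        )
    t_unit = _unit_rows(model.templates)
    labels, corr = _assign(maps, t_unit, model.polarity_sensitive)
    norms2 = (maps**2).sum(axis=1)
    proj2 = np.zeros(len(maps))
    ok = labels >= 0
    proj2[ok] = (corr[ok] ** 2) * norms2[ok]
    sigma2 = float((norms2 - proj2).sum() / (len(maps) * (n_ch - 1)))
    return sigma2 * ((n_ch - 1) / (n_ch - 1 - model.k)) ** 2


def select_k(models: list[MicrostateModel]) -> MicrostateModel:
    """Model with the lowest cross-validation score."""
    scored = [m for m in models if np.isfinite(m.cv_score)]
    if not scored:
        raise PipelineError("no model has a finite cross-validation score")
    return min(scored, key=lambda m: m.cv_score)


def _absorb_short_segments(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Relabel runs shorter than ``min_len`` with the preceding segment's
    label (the following one at the start). Unassigned stretches are
    left alone."""
    out = labels.copy()
    runs = []
    start = 0
    for i in range(1, len(out) + 1):
        if i == len(out) or out[i] != out[start]:
            runs.append((start, i))
            start = i
    for idx, (lo, hi) in enumerate(runs):
        if hi - lo >= min_len or out[lo] == 0:
            continue
        if idx > 0:
            out[lo:hi] = out[runs[idx - 1][0]]
        elif idx + 1 < len(runs):
            out[lo:hi] = out[runs[idx + 1][0]]
    return out


def backfit(
    model: MicrostateModel,
    ev: Evoked,
    window_ms: tuple[float, float] | None = None,
    min_segment_ms: float = 0.0,
) -> BackfitResult:
    """Label each timepoint with the best-correlated template map.

    Assignment maximizes the (polarity-sensitive: signed) spatial
    correlation; exact ties resolve to the lowest template index;
    zero-GFP timepoints stay unassigned (label 0). Per-map explained
    variance is the GFP-weighted squared correlation summed over assigned
    timepoints, normalized by the total squared GFP in the window.
    ``min_segment_ms`` > 0 absorbs shorter label runs into their
    temporal neighbours (off by default).
    """
    if tuple(model.channel_names) != tuple(ev.montage.scalp_names):
        raise ConfigurationError("evoked montage does not match model channels")
    t = ev.times_ms
    data = _center(ev.scalp_data().T)  # (T, ch)
    if window_ms is not None:
        keep = (t >= window_ms[0]) & (t < window_ms[1])
        t, data = t[keep], data[keep]
    if len(t) == 0:
        raise ConfigurationError("backfit window contains no timepoints")
    dt = 1000.0 / ev.sampling_rate

    labels0, corr = _assign(data, _unit_rows(model.templates), model.polarity_sensitive)
    labels1 = np.where(labels0 >= 0, labels0 + 1, 0)
    if min_segment_ms > 0:
        labels1 = _absorb_short_segments(labels1, int(round(min_segment_ms / dt)))
        # recompute the winning correlation for relabeled points
        t_unit = _unit_rows(model.templates)
        reassigned = labels1 != np.where(labels0 >= 0, labels0 + 1, 0)
        for i in np.flatnonzero(reassigned):
            v = data[i]
            nv = np.linalg.norm(v)
            corr[i] = (v @ t_unit[labels1[i] - 1]) / nv if nv > _FLAT_TOL else np.nan
        labels0 = labels1 - 1
    norms2 = (data**2).sum(axis=1)
    gfp_t = np.sqrt((data**2).mean(axis=1))
    total = norms2.sum()
    rows = []
    for k in range(model.k):
        sel = labels0 == k
        ev_frac = float(((corr[sel] ** 2) * norms2[sel]).sum() / total) if total > 0 else 0.0
        rows.append(
            {
                "map": k + 1,
                "explained_variance": ev_frac,
                "mean_gfp_uv": float(gfp_t[sel].mean()) if sel.any() else 0.0,
                "coverage_ms": float(sel.sum() * dt),
            }
        )
    stats = pd.DataFrame(rows)
    labels = np.where(labels0 >= 0, labels0 + 1, 0)
    return BackfitResult(
        labels=labels,
        times_ms=t,
        correlations=corr,
        stats=stats,
        gev_total=float(stats["explained_variance"].sum()),
    )


def fit_statistics(
    model: MicrostateModel,
    evokeds: list[tuple[int, dict, Evoked]],
    window_ms: tuple[float, float] | None = None,
    maps: list[int] | None = None,
) -> pd.DataFrame:
    """Long table of back-fit statistics: subject x condition x map.

    ``evokeds`` holds (subject, condition-labels, Evoked) triples covering
    a complete subject x condition grid; ``maps`` optionally restricts to
    a subset of 1-based map labels. Maps never assigned for a cell
    contribute zero explained variance and coverage.
    """
    if not evokeds:
        raise ConfigurationError("fit_statistics needs at least one evoked")
    keep = list(maps) if maps is not None else list(range(1, model.k + 1))
    rows = []
    seen = set()
    for subject, cond, ev in evokeds:
        key = (subject, tuple(sorted(cond.items())))
        if key in seen:
            raise ConfigurationError(f"duplicate subject x condition cell {key!r}")
        seen.add(key)
        bf = backfit(model, ev, window_ms)
        sub = bf.stats[bf.stats["map"].isin(keep)]
        for _, r in sub.iterrows():
            rows.append(
                {"subject": subject, **cond, "map": int(r["map"]), **{
                    "explained_variance": r["explained_variance"],
                    "mean_gfp_uv": r["mean_gfp_uv"],
                    "coverage_ms": r["coverage_ms"],
                }}
            )
    table = pd.DataFrame(rows)
    counts = table.groupby("subject", observed=True).size()
    if counts.nunique() > 1:
        raise ConfigurationError("incomplete subject x condition x map grid")
    return table


def name_maps_by_latency(
    model: MicrostateModel,
    grand_evokeds: list[Evoked],
    component_windows: dict[str, tuple[float, float]],
    window_ms: tuple[float, float] | None = (0.0, 500.0),
) -> dict[int, str]:
    """Name maps (P1a, P1b, N1a, ...) by median assigned grand latency.

    Each map's median assigned latency across the grand-average backfits
    places it in one of ``component_windows``; maps sharing a window get
    letter suffixes in latency order. Maps outside every window keep a
    generic ``map<k>`` name.
    """
    med = {}
    all_lab, all_t = [], []
    for ev in grand_evokeds:
        bf = backfit(model, ev, window_ms)
        all_lab.append(bf.labels)
        all_t.append(bf.times_ms)
    labels = np.concatenate(all_lab)
    times = np.concatenate(all_t)
    for k in range(1, model.k + 1):
        sel = labels == k
        med[k] = float(np.median(times[sel])) if sel.any() else np.nan
    names = {}
    for comp, (lo, hi) in component_windows.items():
        inside = sorted(
            [k for k, m in med.items() if np.isfinite(m) and lo <= m < hi],
            key=lambda k: med[k],
        )
        for i, k in enumerate(inside):
            suffix = chr(ord("a") + i) if len(inside) > 1 else ""
            names[k] = f"{comp}{suffix}"
    for k in range(1, model.k + 1):
        names.setdefault(k, f"map{k}")
    return names
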