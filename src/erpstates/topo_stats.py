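"""Reference-free topographic statistics: GFP, dissimilarity, TANOVA.

Global field power (GFP) is the spatial root-mean-square of an
average-referenced map — a reference-free index of signal strength.
Global dissimilarity (DISS) compares the *configuration* of two maps
after GFP normalization and satisfies DISS^2 = 2 (1 - r) with r the
spatial Pearson correlation, so it runs from 0 (proportional maps, same
polarity) to 2 (polarity reversal).

The TANOVA is a paired randomization test: at each timepoint the observed
DISS between the two condition group-mean maps is compared with a null
built by randomly swapping each subject's condition assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ConfigurationError, Evoked, PipelineError

__all__ = [
    "gfp",
    "dissimilarity",
    "spatial_correlation",
    "TanovaResult",
    "tanova",
    "significant_windows",
]

_ZERO_GFP_TOL = 1e-12


def _as_centered(values: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Validate average reference (zero channel mean) and return the map."""
    v = np.asarray(values, float)
    scale = np.abs(v).max() if v.size else 0.0
    if scale > 0 and abs(v.mean()) > tol * scale:
        raise ConfigurationError(
            "topographic map is not average-referenced (nonzero channel mean)"
        )
    return v - v.mean()  # remove numerical residue


def gfp(values: np.ndarray) -> float:
    """Global field power: spatial RMS of an average-referenced map (uV)."""
    v = _as_centered(values)
    return float(np.sqrt((v**2).mean()))


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Spatial Pearson correlation between two average-referenced maps."""
    a, b = _as_centered(u), _as_centered(v)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < _ZERO_GFP_TOL or nb < _ZERO_GFP_TOL:
        raise PipelineError("spatial correlation undefined for a flat map")
    return float(a @ b / (na * nb))


def dissimilarity(u: np.ndarray, v: np.ndarray) -> float:
    """Global dissimilarity between two average-referenced maps.

    Both maps are scaled to unit GFP; the value is the RMS of their
    difference, in [0, 2].
    """
    a, b = _as_centered(u), _as_centered(v)
    ga, gb = np.sqrt((a**2).mean()), np.sqrt((b**2).mean())
    if ga < _ZERO_GFP_TOL or gb < _ZERO_GFP_TOL:
        raise PipelineError("dissimilarity undefined for a zero-GFP map")
    return float(np.sqrt(((a / ga - b / gb) ** 2).mean()))


@dataclass
class TanovaResult:
    """Per-timepoint TANOVA output plus extracted significant windows."""

    times_ms: np.ndarray
    observed_diss: np.ndarray
    p_values: np.ndarray
    alpha: float
    n_permutations: int
    seed: int | None
    exact: bool
    windows: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.times_ms,
                "observed_diss": self.observed_diss,
                "p": self.p_values,
            }
        )


def _normalized_mean_maps(stack: np.ndarray, normalize: bool) -> np.ndarray:
    """Group-mean maps per timepoint; optionally GFP-normalized.

    ``stack``: (n_subjects, n_channels, n_times) -> (n_channels, n_times).
    """
    mean = stack.mean(axis=0)
    mean = mean - mean.mean(axis=0, keepdims=True)
    if normalize:
        g = np.sqrt((mean**2).mean(axis=0, keepdims=True))
        g = np.where(g < _ZERO_GFP_TOL, np.nan, g)
        mean = mean / g
    return mean


def _diss_series(mean_a: np.ndarray, mean_b: np.ndarray, normalize: bool) -> np.ndarray:
    a = mean_a - mean_a.mean(axis=0, keepdims=True)
    b = mean_b - mean_b.mean(axis=0, keepdims=True)
    if normalize:
        ga = np.sqrt((a**2).mean(axis=0, keepdims=True))
        gb = np.sqrt((b**2).mean(axis=0, keepdims=True))
        ga = np.where(ga < _ZERO_GFP_TOL, np.nan, ga)
        gb = np.where(gb < _ZERO_GFP_TOL, np.nan, gb)
        a, b = a / ga, b / gb
    return np.sqrt(((a - b) ** 2).mean(axis=0))


def tanova(
    cond_a: list[Evoked],
    cond_b: list[Evoked],
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    min_duration_ms: float = 10.0,
    normalize: bool = True,
    exact: bool | None = None,
) -> TanovaResult:
    """Paired topographic randomization test over each timepoint.

    ``cond_a[i]`` and ``cond_b[i]`` must be the same subject's two
    condition averages on a common time axis. The observed statistic is
    the DISS of the two (GFP-normalized) group-mean maps; the null swaps
    each subject's condition labels. For small samples (2^n <= n_perm, or
    ``exact=True``) all 2^n relabelings are enumerated and p is the exact
    null fraction >= observed; otherwise ``n_perm`` random relabelings are
    drawn and p = (count + 1) / (n_perm + 1).
    """
    if len(cond_a) != len(cond_b) or not cond_a:
        raise ConfigurationError("tanova needs paired, equal-length condition lists")
    n = len(cond_a)
    first = cond_a[0]
    for ev in (*cond_a, *cond_b):
        if ev.window_ms != first.window_ms or ev.sampling_rate != first.sampling_rate:
            raise ConfigurationError("evokeds must share a common time axis")
        if ev.montage.names != first.montage.names:
            raise ConfigurationError("evokeds must share a montage")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse TANOVA p-value resolution")

    a = np.stack([ev.scalp_data() for ev in cond_a])  # (n, ch, t)
    b = np.stack([ev.scalp_data() for ev in cond_b])
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)

    observed = _diss_series(a.mean(0), b.mean(0), normalize)

    if exact is None:
        exact = 2**n <= n_perm
    if exact:
        signs = np.array(
            [[1 if (m >> i) & 1 else -1 for i in range(n)] for m in range(2**n)]
        )
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n))

    # Swapping subject i flips the sign of diff_i, so each relabeling's two
    # group means are mean(total)/2 +/- mean(s * diff)/2 — one matmul per
    # chunk of permutations.
    diff = a - b
    half_total = (a + b).mean(0) / 2.0  # (ch, t)
    flat = diff.reshape(n, -1)
    n_ch, n_t = half_total.shape
    count = np.zeros_like(observed)
    chunk = max(1, int(2e7 // (n_ch * n_t)))
    for lo in range(0, len(signs), chunk):
        s = signs[lo : lo + chunk]
        sdiff = (s @ flat).reshape(len(s), n_ch, n_t) / (2.0 * n)
        perm_a = half_total[None] + sdiff
        perm_b = half_total[None] - sdiff
        pa = perm_a - perm_a.mean(axis=1, keepdims=True)
        pb = perm_b - perm_b.mean(axis=1, keepdims=True)
        if normalize:
            ga = np.sqrt((pa**2).mean(axis=1, keepdims=True))
            gb = np.sqrt((pb**2).mean(axis=1, keepdims=True))
            ga = np.where(ga < _ZERO_GFP_TOL, np.nan, ga)
            gb = np.where(gb < _ZERO_GFP_TOL, np.nan, gb)
            pa, pb = pa / ga, pb / gb
        null = np.sqrt(((pa - pb) ** 2).mean(axis=1))  # (chunk, t)
        count += (null >= observed[None] - 1e-12).sum(axis=0)
    if exact:
        p = count / len(signs)
    else:
        p = (count + 1.0) / (n_perm + 1.0)
    p = np.where(np.isnan(observed), 1.0, np.minimum(p, 1.0))

    times = first.times_ms
    result = TanovaResult(
        times_ms=times,
        observed_diss=observed,
        p_values=p,
        alpha=alpha,
        n_permutations=len(signs),
        seed=seed,
        exact=bool(exact),
        windows=[],
    )
    result.windows = significant_windows(result, alpha, min_duration_ms)
    return result


def significant_windows(
    res: TanovaResult, alpha: float | None = None, min_duration_ms: float = 10.0
) -> list[tuple[float, float]]:
    """Maximal runs of consecutive p < alpha lasting >= min_duration.

    Windows are half-open [start_ms, end_ms): the end is the time of the
    first non-significant sample after the run.
    """
    alpha = res.alpha if alpha is None else alpha
    sig = res.p_values < alpha
    t = res.times_ms
    dt = float(t[1] - t[0]) if len(t) > 1 else 0.0
    windows = []
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            while j + 1 < len(sig) and sig[j + 1]:
                j += 1
            start, end = float(t[i]), float(t[j] + dt)
            if end - start >= min_duration_ms:
                windows.append((start, end))
            i = j + 1
        else:
            i += 1
    return windows
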