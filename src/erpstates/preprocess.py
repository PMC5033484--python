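"""Continuous-recording preprocessing for oddball ERP experiments.

The chain mirrors a classical averaged-ERP workflow: zero-phase low-pass
filtering, regression-based ocular (blink) correction, epoching with
pre-stimulus baseline removal, absolute-threshold artifact rejection,
per-condition averaging of correct trials, and common-average
re-referencing for grand averages.

Conventions: time in milliseconds, voltages in microvolts, sample indices
0-based, windows half-open ``[start, end)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .montage import Montage

__all__ = [
    "Recording",
    "EpochSet",
    "Evoked",
    "PipelineError",
    "ConfigurationError",
    "lowpass_filter",
    "detect_blinks",
    "correct_ocular",
    "make_epochs",
    "reject_artifacts",
    "average_condition",
    "rereference_average",
    "grand_average",
    "write_epochs_h5",
    "read_epochs_h5",
]


class PipelineError(RuntimeError):
    """Raised when a processing stage cannot produce a valid result."""


class ConfigurationError(ValueError):
    """Raised for infeasible or inconsistent run configurations."""


# ---------------------------------------------------------------- containers


@dataclass
class Recording:
    """Continuous multi-channel voltage trace with event annotations.

    ``data`` is channels x samples in microvolts; ``events`` holds one row
    per trial with at least ``onset_sample``, ``role``, ``category``,
    ``colour`` columns (behavioural columns optional).
    """

    montage: Montage
    data: np.ndarray
    sampling_rate: float
    events: pd.DataFrame
    reference: str = "recording-reference"
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.data.shape[0] != self.montage.n_channels:
            raise ConfigurationError("data rows must match montage channels")
        if len(self.events) and "onset_sample" in self.events:
            on = self.events["onset_sample"].to_numpy()
            if on.min() < 0 or on.max() >= self.data.shape[1]:
                raise ConfigurationError("event onsets outside data extent")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def scalp_indices(self) -> np.ndarray:
        return self.montage.indices(self.montage.scalp_names)


@dataclass
class EpochSet:
    """Epoched voltages (channels x time x trials) with a rejection mask."""

    montage: Montage
    data: np.ndarray
    sampling_rate: float
    window_ms: tuple[float, float]
    trials: pd.DataFrame  # one row per kept-or-rejected trial
    rejected: np.ndarray  # bool per trial
    reject_reason: np.ndarray  # str per trial ("" if kept)
    baseline_state: bool = False
    reference: str = "recording-reference"

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        n = self.data.shape[1]
        return self.window_ms[0] + dt * np.arange(n)

    def kept(self) -> np.ndarray:
        return ~self.rejected


@dataclass
class Evoked:
    """A condition average: channels x time in microvolts."""

    montage: Montage
    data: np.ndarray
    sampling_rate: float
    window_ms: tuple[float, float]
    condition: dict
    n_trials: int
    reference: str = "recording-reference"

    @property
    def times_ms(self) -> np.ndarray:
        dt = 1000.0 / self.sampling_rate
        return self.window_ms[0] + dt * np.arange(self.data.shape[1])

    def scalp_data(self) -> np.ndarray:
        return self.data[self.montage.indices(self.montage.scalp_names)]

    def time_index(self, t_ms: float) -> int:
        return int(round((t_ms - self.window_ms[0]) * self.sampling_rate / 1000.0))


# ---------------------------------------------------------------- filtering


def lowpass_filter(rec: Recording, cutoff_hz: float = 30.0, order: int = 8) -> Recording:
    """Zero-phase Butterworth low-pass (applied forward and backward).

    An order-8 Butterworth has a nominal 48 dB/octave single-pass roll-off;
    the forward-backward application squares the magnitude response and
    cancels the group delay, so the passband is delay-free with unit DC
    gain.
    """
    nyq = rec.sampling_rate / 2.0
    if cutoff_hz >= nyq:
        raise ConfigurationError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist {nyq} Hz"
        )
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rec.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    info = dict(rec.info)
    info["lowpass"] = {"cutoff_hz": cutoff_hz, "order": order, "realization": "butter-sosfiltfilt"}
    return replace(rec, data=out, info=info)


def lowpass_gain(freq_hz, cutoff_hz: float = 30.0, order: int = 8, fs: float | None = None):
    """Analytic magnitude response of :func:`lowpass_filter` (two passes).

    With ``fs`` given, the Butterworth ratio uses the bilinear-transform
    prewarped frequencies of the realized digital filter; otherwise the
    analog prototype formula.
    """
    f = np.asarray(freq_hz, float)
    if fs is None:
        ratio = f / cutoff_hz
    else:
        ratio = np.tan(np.pi * f / fs) / np.tan(np.pi * cutoff_hz / fs)
    single = 1.0 / np.sqrt(1.0 + ratio ** (2 * order))
    return single**2


# ---------------------------------------------------------------- ocular


def detect_blinks(rec: Recording, z_threshold: float = 3.5, min_separation_ms: float = 400.0) -> np.ndarray:
    """Detect blink peaks on the EOG channel by a z-score threshold.

    Returns sample indices of local EOG maxima whose z-score (relative to
    the whole-channel mean/sd) exceeds ``z_threshold``, enforcing a minimum
    separation between successive blinks.
    """
    if rec.montage.eog_name is None:
        raise ConfigurationError("recording has no EOG channel")
    eog = rec.data[rec.montage.index(rec.montage.eog_name)]
    z = (eog - eog.mean()) / (eog.std() + 1e-12)
    dist = max(1, int(round(min_separation_ms * rec.sampling_rate / 1000.0)))
    peaks, _ = signal.find_peaks(z, height=z_threshold, distance=dist)
    return peaks


def correct_ocular(
    rec: Recording,
    eog_channel: str | None = None,
    blink_events: np.ndarray | None = None,
    segment_halfwidth_ms: float = 200.0,
) -> Recording:
    """Regression-based blink correction (Gratton/Coles/Donchin style).

    Propagation of ocular activity to each scalp channel is estimated by
    ordinary least squares of the scalp channel on the EOG channel over
    blink segments (a fixed window around each blink peak), after removing
    the per-segment means so that slow drifts and stimulus-locked activity
    do not bias the slope. The whole recording is then corrected as
    ``scalp - b * EOG``.

    With no blink events the recording is returned unchanged; a flat EOG
    over the blink segments triggers a warning and an identity transform.
    """
    eog_name = eog_channel or rec.montage.eog_name
    if eog_name is None:
        raise ConfigurationError("no EOG channel available for ocular correction")
    eog_idx = rec.montage.index(eog_name)
    if blink_events is None:
        blink_events = detect_blinks(rec)
    blink_events = np.asarray(blink_events, dtype=int)
    info = dict(rec.info)
    if blink_events.size == 0:
        info["ocular"] = {"n_blinks": 0, "applied": False}
        return replace(rec, info=info)

    half = int(round(segment_halfwidth_ms * rec.sampling_rate / 1000.0))
    segs = []
    for p in blink_events:
        lo, hi = max(0, p - half), min(rec.n_samples, p + half)
        seg = rec.data[:, lo:hi]
        segs.append(seg - seg.mean(axis=1, keepdims=True))
    stacked = np.concatenate(segs, axis=1)

    eog_seg = stacked[eog_idx]
    denom = float(eog_seg @ eog_seg)
    if denom < 1e-12 * stacked.shape[1]:
        warnings.warn("EOG variance ~0 over blink segments; skipping ocular correction")
        info["ocular"] = {"n_blinks": int(blink_events.size), "applied": False}
        return replace(rec, info=info)

    coeffs = stacked @ eog_seg / denom  # per-channel propagation
    coeffs[eog_idx] = 0.0
    out = rec.data - np.outer(coeffs, rec.data[eog_idx])
    info["ocular"] = {
        "n_blinks": int(blink_events.size),
        "applied": True,
        "coefficients": {n: float(c) for n, c in zip(rec.montage.names, coeffs)},
    }
    return replace(rec, data=out, info=info)


# ---------------------------------------------------------------- epoching


def make_epochs(
    rec: Recording,
    window_ms: tuple[float, float] = (-100.0, 500.0),
    baseline_ms: tuple[float, float] | None = (-100.0, 0.0),
) -> EpochSet:
    """Cut stimulus-locked epochs and subtract the pre-stimulus baseline.

    Windows are half-open in samples: at 1 kHz, [-100, 500) ms yields 600
    samples. Trials whose window would cross a recording edge are dropped
    with reason ``"edge"``.
    """
    fs = rec.sampling_rate
    i0 = int(round(window_ms[0] * fs / 1000.0))
    i1 = int(round(window_ms[1] * fs / 1000.0))
    n_time = i1 - i0
    if n_time <= 0 or not (window_ms[0] <= 0.0 < window_ms[1]):
        raise ConfigurationError("epoch window must cover stimulus onset")

    onsets = rec.events["onset_sample"].to_numpy(dtype=int)
    ok = (onsets + i0 >= 0) & (onsets + i1 <= rec.n_samples)
    data = np.empty((rec.montage.n_channels, n_time, len(onsets)))
    data[:] = np.nan
    for t, (on, good) in enumerate(zip(onsets, ok)):
        if good:
            data[:, :, t] = rec.data[:, on + i0 : on + i1]

    rejected = ~ok
    reasons = np.where(ok, "", "edge").astype(object)

    baseline_state = False
    if baseline_ms is not None:
        b0 = int(round(baseline_ms[0] * fs / 1000.0)) - i0
        b1 = int(round(baseline_ms[1] * fs / 1000.0)) - i0
        if not (0 <= b0 < b1 <= n_time):
            raise ConfigurationError("baseline window outside epoch window")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN dropped trials
            base = np.nanmean(data[:, b0:b1, :], axis=1, keepdims=True)
        data = data - base
        baseline_state = True

    return EpochSet(
        montage=rec.montage,
        data=data,
        sampling_rate=fs,
        window_ms=tuple(window_ms),
        trials=rec.events.reset_index(drop=True).copy(),
        rejected=rejected,
        reject_reason=reasons,
        baseline_state=baseline_state,
        reference=rec.reference,
    )


def reject_artifacts(ep: EpochSet, threshold_uv: float = 75.0, scalp_only: bool = True) -> EpochSet:
    """Mark epochs exceeding ``threshold_uv`` in absolute value on any channel.

    The screen is applied to baseline-corrected data; kept data are
    unchanged. Rejection is strictly ``|v| > threshold`` ("exceeding").
    """
    if not ep.baseline_state:
        raise PipelineError("artifact rejection expects baseline-corrected epochs")
    ch = (
        ep.montage.indices(ep.montage.scalp_names)
        if scalp_only
        else np.arange(ep.montage.n_channels)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak = np.nanmax(np.abs(ep.data[ch]), axis=(0, 1))
    bad = peak > threshold_uv
    rejected = ep.rejected | np.where(np.isnan(peak), False, bad)
    reasons = ep.reject_reason.copy()
    newly = bad & ~ep.rejected & ~np.isnan(peak)
    reasons[newly] = "amplitude"
    return replace(ep, rejected=rejected, reject_reason=reasons)


def rejection_log(ep: EpochSet, subject=None) -> pd.DataFrame:
    """Long-format rejection log (one row per rejected trial)."""
    ch = ep.montage.indices(ep.montage.scalp_names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        peak = np.nanmax(np.abs(ep.data[ch]), axis=(0, 1))
    rows = []
    for t in np.flatnonzero(ep.rejected):
        rows.append(
            {
                "subject": subject,
                "epoch": int(t),
                "max_abs_uv": float(peak[t]) if np.isfinite(peak[t]) else np.nan,
                "reason": str(ep.reject_reason[t]),
            }
        )
    return pd.DataFrame(rows, columns=["subject", "epoch", "max_abs_uv", "reason"])


# ---------------------------------------------------------------- averaging


def average_condition(
    ep: EpochSet, condition: dict | None = None, correct_only: bool = True
) -> Evoked:
    """Average kept trials matching ``condition`` (column -> value) filters.

    By default only correctly answered trials contribute, matching the
    reported-analysis convention.
    """
    mask = ep.kept().copy()
    cond = dict(condition or {})
    for col, val in cond.items():
        mask &= (ep.trials[col] == val).to_numpy()
    if correct_only and "correct" in ep.trials:
        mask &= ep.trials["correct"].to_numpy().astype(bool)
    if not mask.any():
        raise PipelineError(f"no surviving trials for condition {cond!r}")
    data = ep.data[:, :, mask].mean(axis=2)
    return Evoked(
        montage=ep.montage,
        data=data,
        sampling_rate=ep.sampling_rate,
        window_ms=ep.window_ms,
        condition=cond,
        n_trials=int(mask.sum()),
        reference=ep.reference,
    )


def rereference_average(ev: Evoked, scalp_only: bool = True) -> Evoked:
    """Re-reference to the common average of the scalp channels."""
    data = ev.data.copy()
    idx = (
        ev.montage.indices(ev.montage.scalp_names)
        if scalp_only
        else np.arange(ev.montage.n_channels)
    )
    data[idx] -= data[idx].mean(axis=0, keepdims=True)
    return replace(ev, data=data, reference="average")


def grand_average(evokeds: list[Evoked]) -> Evoked:
    """Unweighted mean across subjects' evokeds (same montage and window)."""
    if not evokeds:
        raise PipelineError("grand_average needs at least one evoked")
    first = evokeds[0]
    for ev in evokeds[1:]:
        if ev.montage.names != first.montage.names:
            raise ConfigurationError("montage mismatch across evokeds")
        if ev.window_ms != first.window_ms or ev.sampling_rate != first.sampling_rate:
            raise ConfigurationError("time-axis mismatch across evokeds")
        if ev.reference != first.reference:
            raise ConfigurationError("reference mismatch across evokeds")
    data = np.mean([ev.data for ev in evokeds], axis=0)
    return replace(
        first,
        data=data,
        n_trials=int(sum(ev.n_trials for ev in evokeds)),
        condition=dict(first.condition),
    )


# ---------------------------------------------------------------- import


def read_raw_recording(path, events: pd.DataFrame | None = None, eog_name: str | None = None) -> Recording:
    """Import a continuous EEG file (EDF, BrainVision, ...) as a Recording.

    Reads through MNE's raw readers, converts to microvolts, and builds
    the montage from the file's channel names and digitized positions
    (channels without positions get the origin). Events default to the
    file's annotations (columns ``onset_sample`` and ``description``); a
    user-supplied per-trial table with an ``onset_sample`` column
    replaces them.
    """
    import mne

    raw = mne.io.read_raw(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    names = tuple(str(n).upper() for n in raw.ch_names)
    pos = np.zeros((len(names), 3))
    for i, ch in enumerate(raw.info["chs"]):
        loc = ch["loc"][:3]
        if np.isfinite(loc).all():
            pos[i] = loc
    eog = eog_name.upper() if eog_name else None
    montage = Montage(names, pos, eog if eog in names else None)
    if events is None:
        rows = [
            {
                "onset_sample": int(round(onset * raw.info["sfreq"])),
                "description": desc,
            }
            for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
        ]
        events = pd.DataFrame(rows, columns=["onset_sample", "description"])
    return Recording(
        montage=montage,
        data=data,
        sampling_rate=float(raw.info["sfreq"]),
        events=events,
        reference="recording-reference",
        info={"source": str(path)},
    )


# ---------------------------------------------------------------- storage


def write_epochs_h5(path, ep: EpochSet) -> None:
    """Write an EpochSet as HDF5 (voltages) plus an embedded JSON sidecar."""
    sidecar = {
        "window_ms": list(ep.window_ms),
        "sampling_rate": ep.sampling_rate,
        "channels": list(ep.montage.names),
        "eog": ep.montage.eog_name,
        "baseline_state": ep.baseline_state,
        "reference": ep.reference,
        "trials": ep.trials.to_dict(orient="list"),
        "rejected": ep.rejected.astype(int).tolist(),
        "reject_reason": [str(r) for r in ep.reject_reason],
    }
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=ep.data, compression="gzip", compression_opts=1)
        fh.create_dataset("positions", data=ep.montage.positions)
        fh.attrs["sidecar"] = json.dumps(sidecar)


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        positions = fh["positions"][()]
        sidecar = json.loads(fh.attrs["sidecar"])
    montage = Montage(tuple(sidecar["channels"]), positions, sidecar["eog"])
    return EpochSet(
        montage=montage,
        data=data,
        sampling_rate=float(sidecar["sampling_rate"]),
        window_ms=tuple(sidecar["window_ms"]),
        trials=pd.DataFrame(sidecar["trials"]),
        rejected=np.array(sidecar["rejected"], dtype=bool),
        reject_reason=np.array(sidecar["reject_reason"], dtype=object),
        baseline_state=bool(sidecar["baseline_state"]),
        reference=sidecar["reference"],
    )
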