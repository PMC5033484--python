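"""Electrode montages: standard 10-20 positions, distances, .sfp text I/O.

Positions come from the MNE standard_1005 template (idealized 10-05 head,
metres, head-centred RAS). CB1/CB2 — Quik-Cap names for the inferior
occipital row — are placed at the I1/I2 template positions. VEOG is a
synthetic below-forehead position used only for blink propagation geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "standard_64_montage",
    "compact_montage",
    "write_sfp",
    "read_sfp",
]

#: 64 scalp channels of the extended 10-20 layout used throughout.
STANDARD_64 = (
    "FP1 FPZ FP2 AF7 AF3 AF4 AF8 "
    "F7 F5 F3 F1 FZ F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCZ FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 CZ C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPZ CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 PZ P2 P4 P6 P8 "
    "PO7 PO5 PO3 POZ PO4 PO6 PO8 "
    "CB1 O1 OZ O2 CB2"
).split()

#: Reduced 32-channel layout retaining every analysis electrode
#: (medial-occipital P1 set and lateral occipito-temporal N1 set).
COMPACT_32 = (
    "FP1 FPZ FP2 F7 F3 FZ F4 F8 "
    "FC3 FCZ FC4 T7 C3 CZ C4 T8 "
    "CP3 CPZ CP4 "
    "P7 P3 PZ P4 P8 "
    "PO7 PO5 PO3 POZ PO4 PO6 PO8 "
    "CB1 O1 OZ O2 CB2"
).split()
# 36 names above; trim interior rows to hit 32 while keeping the ROI sets.
COMPACT_32 = [c for c in COMPACT_32 if c not in ("FC3", "FC4", "CP3", "CP4")]

_ALIASES = {"CB1": "I1", "CB2": "I2"}  # inferior occipital row stand-ins

EOG_NAME = "VEOG"


@dataclass(frozen=True)
class Montage:
    """Named electrode set with 3-D positions (metres, head-centred)."""

    names: tuple[str, ...]
    positions: np.ndarray  # (n, 3)
    eog_name: str | None = None
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(self.names) != len(self.positions):
            raise ValueError("names/positions length mismatch")
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.names)}
        )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    @property
    def scalp_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n != self.eog_name)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def distances(self) -> np.ndarray:
        """Pairwise Euclidean distances between electrodes (metres)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(-1))

    def subset(self, names) -> "Montage":
        idx = self.indices(names)
        eog = self.eog_name if self.eog_name in names else None
        return Montage(tuple(names), self.positions[idx].copy(), eog)


def _template_positions() -> dict[str, np.ndarray]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1005")
    pos = std.get_positions()["ch_pos"]
    return {k.upper(): np.asarray(v, float) for k, v in pos.items()}


def _build(names: list[str], with_eog: bool) -> Montage:
    tpl = _template_positions()
    rows, out_names = [], []
    for n in names:
        rows.append(tpl[_ALIASES.get(n, n)])
        out_names.append(n)
    eog = None
    if with_eog:
        below = tpl["FPZ"] + np.array([0.0, 0.01, -0.045])
        rows.append(below)
        out_names.append(EOG_NAME)
        eog = EOG_NAME
    return Montage(tuple(out_names), np.array(rows), eog)


def standard_64_montage(with_eog: bool = True) -> Montage:
    """64 scalp channels (extended 10-20) plus an optional VEOG channel."""
    return _build(list(STANDARD_64), with_eog)


def compact_montage(with_eog: bool = True) -> Montage:
    """32-channel layout for reduced-scale runs; keeps all ROI electrodes."""
    return _build(list(COMPACT_32), with_eog)


def write_sfp(montage: Montage, path) -> None:
    """Write electrode locations in .sfp format (name x y z, metres)."""
    with open(path, "w") as fh:
        for name, (x, y, z) in zip(montage.names, montage.positions):
            fh.write(f"{name}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def read_sfp(path, eog_name: str | None = None) -> Montage:
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    eog = eog_name if eog_name in names else None
    return Montage(tuple(names), np.array(rows), eog)
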