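"""Synthetic visual-oddball EEG/ERP generator.

Emulates a four-block colour/category oddball stream: frequent standards in
runs of 3-5, interleaved one-for-one with rare non-target and target
deviants, with the four (category x colour) stimulus cells rotating through
the standard / non-target / target roles across blocks. Each subject gets a
continuous 64-channel + EOG voltage trace containing planted P1 (medial
occipital, positive, ~115 ms) and N1/N170 (lateral occipito-temporal,
negative, ~165 ms) components, condition-specific amplitude multipliers,
spatially correlated noise, blink artifacts that propagate from the EOG to
the scalp with a front-to-back gradient, and per-trial behavioural
responses (targets slower and less accurate).

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import Montage, standard_64_montage
from .preprocess import ConfigurationError, Recording

__all__ = [
    "DesignConfig",
    "SimConfig",
    "ComponentSpec",
    "BehaviourParams",
    "balanced_run_counts",
    "build_block_sequence",
    "enumerate_stimuli",
    "simulate_subject",
    "simulate_study",
    "default_components",
    "make_effect_matrix",
    "dissociation_effect_matrix",
    "default_sim_config",
    "scaled_design",
    "write_events_tsv",
]

CATEGORIES = ("butterfly", "face")
COLOURS = ("blue", "green")
ROLES = ("standard", "non-target", "target")


# ------------------------------------------------------------------ design


@dataclass(frozen=True)
class DesignConfig:
    """Oddball block structure: counts, run lengths, timing, role rotation."""

    n_blocks: int = 4
    n_standards_per_block: int = 640
    n_nontarget_deviants: int = 80
    n_target_deviants: int = 80
    run_lengths: tuple[int, ...] = (3, 4, 5)
    stim_duration_ms: float = 400.0
    iti_choices_ms: tuple[float, ...] = (450.0, 500.0, 550.0)
    categories: tuple[str, str] = CATEGORIES
    colours: tuple[str, str] = COLOURS
    #: (category, colour) serving as the standard in each block; deviants
    #: follow from it (non-target: same category / other colour, target:
    #: other category / other colour).
    standard_rotation: tuple[tuple[str, str], ...] = (
        ("butterfly", "green"),
        ("face", "blue"),
        ("butterfly", "blue"),
        ("face", "green"),
    )
    standard_button: int = 1
    target_button: int = 5
    n_exemplars_per_cell: int = 80

    def __post_init__(self):
        if not set(self.run_lengths) <= {3, 4, 5}:
            raise ConfigurationError("run_lengths must be drawn from {3, 4, 5}")
        if self.n_nontarget_deviants != self.n_target_deviants:
            raise ConfigurationError("deviant counts must be equal across types")
        if len(self.standard_rotation) < self.n_blocks:
            raise ConfigurationError("standard_rotation shorter than n_blocks")
        roles_seen = set(self.standard_rotation[: self.n_blocks])
        cells = {(c, k) for c in self.categories for k in self.colours}
        if self.n_blocks == 4 and roles_seen != cells:
            raise ConfigurationError(
                "with 4 blocks every (category, colour) cell must serve as standard once"
            )

    @property
    def n_deviants_per_block(self) -> int:
        return self.n_nontarget_deviants + self.n_target_deviants

    def block_roles(self, block: int) -> dict[str, tuple[str, str]]:
        """Map role -> (category, colour) for a block."""
        cat, col = self.standard_rotation[block]
        other_cat = next(c for c in self.categories if c != cat)
        other_col = next(k for k in self.colours if k != col)
        return {
            "standard": (cat, col),
            "non-target": (cat, other_col),
            "target": (other_cat, other_col),
        }


def balanced_run_counts(design: DesignConfig) -> dict[int, int]:
    """Most-balanced multiset of standard-run lengths for one block.

    Finds nonnegative integer counts ``c_l`` over ``design.run_lengths``
    with ``sum c_l = n_deviants`` (one run precedes each deviant) and
    ``sum l * c_l = n_standards_per_block``, minimizing the spread between
    the largest and smallest count (ties: minimize variance, then prefer
    lexicographically-balanced). Raises ``ConfigurationError`` when no such
    multiset exists.
    """
    lengths = sorted(design.run_lengths)
    n_runs = design.n_deviants_per_block
    n_std = design.n_standards_per_block
    best = None
    if len(lengths) == 1:
        counts = [n_runs]
        if lengths[0] * n_runs == n_std:
            best = counts
    elif len(lengths) == 2:
        l0, l1 = lengths
        # c0*l0 + (n_runs-c0)*l1 = n_std
        num = n_runs * l1 - n_std
        den = l1 - l0
        if num % den == 0 and 0 <= num // den <= n_runs:
            best = [num // den, n_runs - num // den]
    else:
        l0, l1, l2 = lengths
        for c0 in range(n_runs + 1):
            rem_runs = n_runs - c0
            rem_std = n_std - c0 * l0
            num = rem_runs * l2 - rem_std
            den = l2 - l1
            if num % den:
                continue
            c1 = num // den
            c2 = rem_runs - c1
            if c1 < 0 or c2 < 0:
                continue
            counts = [c0, c1, c2]
            score = (max(counts) - min(counts), float(np.var(counts)))
            if best is None or score < best[0]:
                best = (score, counts)
        best = best[1] if best else None
    if best is None:
        raise ConfigurationError(
            f"no multiset of run lengths from {lengths} with {n_runs} runs "
            f"sums to {n_std} standards"
        )
    return dict(zip(lengths, best))


def build_block_sequence(design: DesignConfig, block: int, seed: int) -> pd.DataFrame:
    """Generate one block's pseudo-random trial sequence.

    Standards appear in runs whose lengths are a shuffled balanced multiset
    over ``design.run_lengths``; each run is followed by exactly one
    deviant (shuffled mix of non-targets and targets), so deviants are
    never adjacent. Onsets accrue stimulus duration plus a random ITI.
    Deterministic given (design, block, seed).
    """
    if seed is None:
        raise ConfigurationError("a seed is required for reproducible sequences")
    rng = np.random.default_rng([int(seed), int(block), 0x5E0])
    counts = balanced_run_counts(design)
    runs = np.repeat(
        list(counts.keys()), list(counts.values())
    )
    rng.shuffle(runs)
    deviant_roles = np.array(
        ["non-target"] * design.n_nontarget_deviants
        + ["target"] * design.n_target_deviants,
        dtype=object,
    )
    rng.shuffle(deviant_roles)

    roles_map = design.block_roles(block)
    rows = []
    t_ms = 0.0
    for run_len, dev_role in zip(runs, deviant_roles):
        for role in ["standard"] * int(run_len) + [dev_role]:
            cat, col = roles_map[role]
            button = (
                design.target_button if role == "target" else design.standard_button
            )
            rows.append(
                {
                    "block": block,
                    "role": role,
                    "category": cat,
                    "colour": col,
                    "onset_ms": t_ms,
                    "required_response": button,
                }
            )
            t_ms += design.stim_duration_ms + float(rng.choice(design.iti_choices_ms))
    return pd.DataFrame(rows)


def enumerate_stimuli(design: DesignConfig) -> pd.DataFrame:
    """Enumerate the stimulus inventory: exemplars x categories x colours."""
    rows = [
        {"category": cat, "colour": col, "exemplar": e}
        for cat in design.categories
        for col in design.colours
        for e in range(design.n_exemplars_per_cell)
    ]
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ recipe


@dataclass(frozen=True)
class ComponentSpec:
    """One planted ERP component: where, when and how strong.

    ``topography`` is a zero-mean, unit-GFP map over the montage's scalp
    channels; ``base_amplitude_uv`` is therefore the component's GFP at its
    peak before condition multipliers and subject scaling.
    """

    name: str
    latency_mean_ms: float
    latency_sd_ms: float
    width_ms: float  # Gaussian temporal sd
    topography: np.ndarray
    base_amplitude_uv: float
    #: optional per-category topographies (e.g. a laterally shifted face
    #: P1 map); categories not listed fall back to ``topography``
    category_topographies: dict | None = None

    def __post_init__(self):
        variants = [self.topography]
        if self.category_topographies:
            variants += list(self.category_topographies.values())
        for topo in variants:
            topo = np.asarray(topo, float)
            if abs(topo.mean()) > 1e-8:
                raise ConfigurationError(
                    f"{self.name}: topography must have zero channel mean"
                )
            gfp = float(np.sqrt((topo**2).mean()))
            if abs(gfp - 1.0) > 1e-8:
                raise ConfigurationError(f"{self.name}: topography must have unit GFP")

    def topography_for(self, category: str) -> np.ndarray:
        if self.category_topographies and category in self.category_topographies:
            return self.category_topographies[category]
        return self.topography


@dataclass(frozen=True)
class BehaviourParams:
    """Condition-specific behavioural model (Bernoulli accuracy, shifted
    log-normal RT). Defaults centre on the observed deviant means: targets
    are slower (~443 vs ~271 ms) and less accurate (~68% vs ~94%), with a
    small role-dependent category twist on RT (faces faster as targets,
    slower as non-targets)."""

    accuracy: dict = field(
        default_factory=lambda: {"standard": 0.97, "non-target": 0.9371, "target": 0.683}
    )
    rt_mean_ms: dict = field(
        default_factory=lambda: {"standard": 265.0, "non-target": 270.79, "target": 442.86}
    )
    rt_sd_ms: dict = field(
        default_factory=lambda: {"standard": 40.0, "non-target": 39.63, "target": 38.59}
    )
    rt_shift_ms: float = 120.0
    face_rt_shift_ms: float = 8.0  # +8 for non-target faces, -8 for target faces
    anticipation_rate: float = 0.01  # uniform 0-100 ms responses
    rt_floor_ms: float = 100.0


@dataclass(frozen=True)
class SimConfig:
    """Simulation recipe: montage, components, effects, noise and blinks."""

    montage: Montage
    components: tuple[ComponentSpec, ...]
    #: component name -> {(role, category, colour): amplitude multiplier}
    effect_matrix: dict
    n_subjects: int = 19
    sampling_rate: float = 1000.0
    epoch_window_ms: tuple[float, float] = (-100.0, 500.0)
    noise_sd_uv: float = 4.0
    spatial_noise_smoothness: float = 0.5  # kernel length / head radius
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 150.0
    blink_width_ms: float = 40.0
    blink_propagation: np.ndarray | None = None  # scalp coefficients
    subject_sd: float = 0.12  # log-normal sigma of per-subject amplitude scale
    behaviour: BehaviourParams = field(default_factory=BehaviourParams)
    block_gap_ms: float = 2000.0

    def __post_init__(self):
        if self.noise_sd_uv < 0 or self.subject_sd < 0:
            raise ConfigurationError("standard deviations must be nonnegative")
        for comp in self.components:
            for mult in self.effect_matrix.get(comp.name, {}).values():
                if mult <= 0:
                    raise ConfigurationError("effect multipliers must be positive")
            lat = comp.latency_mean_ms
            lo, hi = self.epoch_window_ms
            if not (lo <= lat < hi):
                raise ConfigurationError(
                    f"component {comp.name} latency outside epoch window"
                )


def _gaussian_topography(montage: Montage, centres, sign: float, scale_m: float = 0.05) -> np.ndarray:
    """Zero-mean, unit-GFP scalp map: Gaussian blobs at named electrodes."""
    idx = montage.indices(montage.scalp_names)
    pos = montage.positions[idx]
    topo = np.zeros(len(idx))
    for name in centres:
        c = montage.positions[montage.index(name)]
        d2 = ((pos - c) ** 2).sum(1)
        topo += np.exp(-d2 / (2 * scale_m**2))
    topo *= sign
    topo -= topo.mean()
    topo /= np.sqrt((topo**2).mean())
    return topo


def default_components(
    montage: Montage, p1_category_topographies: bool = True
) -> tuple[ComponentSpec, ComponentSpec]:
    """P1 and N1 with the observed latency ranges and canonical topographies.

    P1: medial-occipital positivity, subject peak latencies ~114-119 ms.
    N1: bilateral occipito-temporal negativity, peak latencies ~159-170 ms.
    Temporal width 10 ms (Gaussian sd) keeps the two components separable.

    With ``p1_category_topographies`` (default) the face P1 map is a
    slightly broader/more lateral medial-occipital distribution than the
    butterfly map, so the category effect is topographic (visible to
    configuration-only tests such as the TANOVA and to the microstate
    Map x Category statistics) as well as an amplitude modulation.
    """
    variants = None
    if p1_category_topographies:
        variants = {
            "butterfly": _gaussian_topography(montage, ["OZ", "POZ"], +1.0),
            "face": _gaussian_topography(montage, ["OZ", "POZ", "PO3", "PO4"], +1.0),
        }
    p1 = ComponentSpec(
        name="P1",
        latency_mean_ms=116.5,
        latency_sd_ms=1.5,
        width_ms=10.0,
        topography=_gaussian_topography(montage, ["OZ", "POZ"], +1.0),
        base_amplitude_uv=3.0,
        category_topographies=variants,
    )
    n1 = ComponentSpec(
        name="N1",
        latency_mean_ms=164.5,
        latency_sd_ms=3.0,
        width_ms=10.0,
        topography=_gaussian_topography(montage, ["P7", "P8", "PO7", "PO8"], -1.0),
        base_amplitude_uv=4.0,
    )
    return p1, n1


def make_effect_matrix(
    design: DesignConfig | None = None,
    p1_face: float = 1.3,
    n1_target: float = 1.4,
    p1_nontarget_blue: float = 1.15,
) -> dict:
    """Condition multipliers emulating the observed effect structure.

    P1 is larger for faces (category effect, all roles) and for blue
    non-target deviants (colour-salience effect); N1 is larger for targets
    (task-driven attention effect), independent of category.
    """
    design = design or DesignConfig()
    p1, n1 = {}, {}
    for role in ROLES:
        for cat in design.categories:
            for col in design.colours:
                key = (role, cat, col)
                m_p1 = p1_face if cat == "face" else 1.0
                if role == "non-target" and col == "blue":
                    m_p1 *= p1_nontarget_blue
                p1[key] = m_p1
                n1[key] = n1_target if role == "target" else 1.0
    return {"P1": p1, "N1": n1}


def dissociation_effect_matrix(
    design: DesignConfig | None = None,
    p1_face: float = 1.3,
    n1_target: float = 1.4,
) -> dict:
    """Effect matrix with a category effect only at P1 and an attention
    (target) effect only at N1 — the pure dissociation condition."""
    return make_effect_matrix(design, p1_face=p1_face, n1_target=n1_target, p1_nontarget_blue=1.0)


def default_blink_propagation(montage: Montage) -> np.ndarray:
    """Front-to-back EOG->scalp propagation gradient (per scalp channel)."""
    idx = montage.indices(montage.scalp_names)
    y = montage.positions[idx, 1]  # anterior axis
    frac = (y - y.min()) / (y.max() - y.min())
    return 0.02 + 0.38 * frac**2


def default_sim_config(montage: Montage | None = None, design: DesignConfig | None = None, **overrides) -> SimConfig:
    montage = montage or standard_64_montage()
    design = design or DesignConfig()
    kwargs = dict(
        montage=montage,
        components=default_components(montage),
        effect_matrix=make_effect_matrix(design),
        blink_propagation=default_blink_propagation(montage),
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def scaled_design(
    n_runs_per_block: int = 32, n_blocks: int = 4, run_lengths=(3, 4, 5)
) -> DesignConfig:
    """Reduced-size design with the same structure (for fast runs/tests).

    ``n_runs_per_block`` deviants (half non-target, half target) with a
    mean run length of 4 keeps the run-length arithmetic feasible.
    """
    if n_runs_per_block % 2:
        raise ConfigurationError("n_runs_per_block must be even")
    return DesignConfig(
        n_blocks=n_blocks,
        n_standards_per_block=4 * n_runs_per_block,
        n_nontarget_deviants=n_runs_per_block // 2,
        n_target_deviants=n_runs_per_block // 2,
        run_lengths=tuple(run_lengths),
    )


# ------------------------------------------------------------------ engine


def _spatial_mixing(montage: Montage, smoothness: float) -> np.ndarray:
    """Mixing matrix L with LL' a unit-diagonal smooth spatial covariance."""
    n = montage.n_channels
    if smoothness <= 0:
        return np.eye(n)
    dist = montage.distances()
    head_radius = float(np.linalg.norm(montage.positions, axis=1).mean())
    K = np.exp(-((dist / (smoothness * head_radius)) ** 2))
    K += 1e-6 * np.eye(n)
    d = np.sqrt(np.diag(K))
    K = K / np.outer(d, d)
    return np.linalg.cholesky(K)


def _shifted_lognormal_params(mean: float, sd: float, shift: float) -> tuple[float, float]:
    m = mean - shift
    if m <= 0:
        raise ConfigurationError("RT mean must exceed the log-normal shift")
    s2 = math.log1p((sd / m) ** 2)
    return math.log(m) - s2 / 2.0, math.sqrt(s2)


def _draw_behaviour(trials: pd.DataFrame, beh: BehaviourParams, rng) -> pd.DataFrame:
    n = len(trials)
    roles = trials["role"].to_numpy()
    cats = trials["category"].to_numpy()
    acc_p = np.array([beh.accuracy[r] for r in roles])
    correct = rng.random(n) < acc_p

    rts = np.empty(n)
    for role in np.unique(roles):
        mask = roles == role
        mu, sig = _shifted_lognormal_params(
            beh.rt_mean_ms[role], beh.rt_sd_ms[role], beh.rt_shift_ms
        )
        rts[mask] = beh.rt_shift_ms + rng.lognormal(mu, sig, mask.sum())
    rts += np.where(
        (cats == "face") & (roles == "non-target"), beh.face_rt_shift_ms, 0.0
    )
    rts -= np.where((cats == "face") & (roles == "target"), beh.face_rt_shift_ms, 0.0)
    anticipate = rng.random(n) < beh.anticipation_rate
    rts[anticipate] = rng.uniform(0.0, beh.rt_floor_ms, anticipate.sum())

    out = trials.copy()
    required = trials["required_response"].to_numpy()
    other = np.where(required == required.max(), required.min(), required.max())
    out["response"] = np.where(correct, required, other)
    out["correct"] = correct
    out["rt_ms"] = np.round(rts, 3)
    out["rt_excluded"] = rts < beh.rt_floor_ms
    return out


def simulate_subject(
    design: DesignConfig, sim: SimConfig, subject: int, seed: int
) -> Recording:
    """Simulate one subject's continuous recording with behaviour attached.

    The returned Recording's ``events`` table carries the full trial
    sequence plus behavioural columns; ``info["ground_truth"]`` records the
    planted subject scale, component latencies, blink onsets and the
    propagation vector, for parameter-recovery checks.
    """
    if seed is None:
        raise ConfigurationError("a seed is required for reproducible simulation")
    rng = np.random.default_rng([int(seed), int(subject), 0x51D])

    blocks = [
        build_block_sequence(design, b, int(rng.integers(2**31)))
        for b in range(design.n_blocks)
    ]
    # absolute onsets across blocks
    offset = 0.0
    for b, blk in enumerate(blocks):
        blk["onset_ms"] = blk["onset_ms"] + offset
        offset = blk["onset_ms"].iloc[-1] + design.stim_duration_ms + sim.block_gap_ms
    events = pd.concat(blocks, ignore_index=True)
    events.insert(0, "subject", subject)

    fs = sim.sampling_rate
    dt_ms = 1000.0 / fs
    tail_ms = sim.epoch_window_ms[1] + 100.0
    n_samples = int(round((offset + tail_ms) / dt_ms))
    events["onset_sample"] = np.round(events["onset_ms"] / dt_ms).astype(int)

    montage = sim.montage
    n_ch = montage.n_channels
    scalp = montage.indices(montage.scalp_names)

    # --- noise (spatially smoothed white noise over all channels)
    data = np.zeros((n_ch, n_samples))
    if sim.noise_sd_uv > 0:
        L = _spatial_mixing(montage, sim.spatial_noise_smoothness)
        white = rng.standard_normal((n_ch, n_samples))
        data += sim.noise_sd_uv * (L @ white)

    # --- subject-level parameters
    subject_scale = float(np.exp(rng.normal(0.0, sim.subject_sd)))
    latencies = {
        c.name: float(rng.normal(c.latency_mean_ms, c.latency_sd_ms))
        for c in sim.components
    }

    # --- planted components, trial by trial
    t_axis_ms = np.arange(n_samples) * dt_ms
    onsets = events["onset_sample"].to_numpy()
    keys = list(zip(events["role"], events["category"], events["colour"]))
    for comp in sim.components:
        topo_by_cat = {}
        for cat in set(events["category"]):
            full = np.zeros(n_ch)
            full[scalp] = comp.topography_for(cat)
            topo_by_cat[cat] = full
        lat = latencies[comp.name]
        half = int(round(4 * comp.width_ms / dt_ms))
        centre = int(round(lat / dt_ms))
        rel = np.arange(-half, half + 1)
        course = np.exp(-0.5 * ((rel * dt_ms - (lat - centre * dt_ms)) / comp.width_ms) ** 2)
        mults = np.array([sim.effect_matrix[comp.name][k] for k in keys])
        for on, mult, (_, cat, _) in zip(onsets, mults, keys):
            sl = slice(on + centre - half, on + centre + half + 1)
            if sl.start < 0 or sl.stop > n_samples:
                continue
            amp = comp.base_amplitude_uv * subject_scale * mult
            data[:, sl] += amp * np.outer(topo_by_cat[cat], course)

    # --- blinks on EOG, propagated to scalp
    blink_onsets = np.array([], dtype=int)
    if montage.eog_name is not None and sim.blink_rate_per_min > 0:
        eog_idx = montage.index(montage.eog_name)
        duration_min = n_samples * dt_ms / 60000.0
        n_blinks = rng.poisson(sim.blink_rate_per_min * duration_min)
        if n_blinks:
            blink_onsets = np.sort(
                rng.integers(int(0.5 * fs), n_samples - int(0.5 * fs), n_blinks)
            )
            width = sim.blink_width_ms / dt_ms
            half = int(round(4 * width))
            course = np.exp(-0.5 * (np.arange(-half, half + 1) / width) ** 2)
            prop = (
                sim.blink_propagation
                if sim.blink_propagation is not None
                else default_blink_propagation(montage)
            )
            wave = np.zeros(n_samples)
            for on in blink_onsets:  # onsets are drawn clear of the edges
                wave[on - half : on + half + 1] += sim.blink_amplitude_uv * course
            data[eog_idx] += wave
            data[scalp] += np.outer(prop, wave)

    events = _draw_behaviour(events, sim.behaviour, rng)

    info = {
        "ground_truth": {
            "subject_scale": subject_scale,
            "latencies_ms": latencies,
            "blink_onsets": blink_onsets,
            "blink_propagation": (
                None
                if sim.blink_propagation is None
                else np.asarray(sim.blink_propagation)
            ),
        },
        "subject": subject,
        "seed": int(seed),
    }
    return Recording(
        montage=montage,
        data=data,
        sampling_rate=fs,
        events=events,
        reference="recording-reference",
        info=info,
    )


def simulate_study(design: DesignConfig, sim: SimConfig, seed: int):
    """Yield (subject, Recording) for each subject in the recipe."""
    for subject in range(sim.n_subjects):
        yield subject, simulate_subject(design, sim, subject, seed)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    cols = [
        c
        for c in [
            "subject",
            "block",
            "onset_ms",
            "role",
            "category",
            "colour",
            "required_response",
            "response",
            "correct",
            "rt_ms",
            "rt_excluded",
        ]
        if c in events.columns
    ]
    events[cols].to_csv(path, sep="\t", index=False)
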