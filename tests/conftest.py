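import dataclasses

import numpy as np
import pandas as pd
import pytest

from erpstates.montage import Montage, compact_montage, standard_64_montage
from erpstates.preprocess import Evoked


@pytest.fixture(scope="session")
def montage64():
    return standard_64_montage()


@pytest.fixture(scope="session")
def montage32():
    return compact_montage()


@pytest.fixture(scope="session")
def montage16():
    """Small generic montage for statistics tests (no EOG)."""
    rng = np.random.default_rng(7)
    pts = rng.standard_normal((16, 3))
    pts /= np.linalg.norm(pts, axis=1, keepdims=True)
    pts *= 0.095
    names = tuple(f"G{i}" for i in range(16))
    return Montage(names, pts)


def make_evoked(montage, data, sampling_rate=1000.0, window_ms=(-100.0, 500.0), **kw):
    """Evoked wrapper for hand-built channel x time arrays."""
    cond = kw.pop("condition", {})
    n_trials = kw.pop("n_trials", 1)
    reference = kw.pop("reference", "average")
    return Evoked(
        montage=montage,
        data=np.asarray(data, float),
        sampling_rate=sampling_rate,
        window_ms=window_ms,
        condition=cond,
        n_trials=n_trials,
        reference=reference,
    )


@pytest.fixture
def make_evoked_fn():
    return make_evoked


def quiet_sim(montage, design, **overrides):
    """Noise- and blink-free simulation recipe with fixed latencies."""
    from erpstates.synthetic_erp import default_components, default_sim_config

    comps = tuple(
        dataclasses.replace(c, latency_sd_ms=0.0) for c in default_components(montage)
    )
    base = dict(
        noise_sd_uv=0.0,
        blink_rate_per_min=0.0,
        subject_sd=0.0,
        sampling_rate=250.0,
    )
    base.update(overrides)
    sim = default_sim_config(montage, design, **base)
    return dataclasses.replace(sim, components=comps)


@pytest.fixture
def quiet_sim_fn():
    return quiet_sim
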