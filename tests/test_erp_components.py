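"""Peak marking, mean amplitudes and the repeated-measures ANOVA family."""

import numpy as np
import pandas as pd
import pytest

from erpstates.erp_components import (
    N1_DEF,
    P1_DEF,
    ComponentDef,
    behavior_stats,
    electrode_factors,
    find_peak,
    mean_amplitude,
    measure_table,
    planned_contrast,
    posthoc_pairwise,
    rm_anova,
)
from erpstates.preprocess import ConfigurationError, PipelineError

from conftest import make_evoked


def roi_evoked(montage16, waveform, electrodes=None):
    """Evoked whose ROI-mean waveform equals ``waveform``."""
    data = np.tile(np.asarray(waveform, float), (16, 1))
    return make_evoked(montage16, data)


ROI16 = ComponentDef("P1ish", +1, (80.0, 160.0), ("G0", "G1", "G2"))
ROI16_NEG = ComponentDef("N1ish", -1, (130.0, 210.0), ("G0", "G1"))


def gaussian_bump(times, centre, width=12.0, amp=5.0):
    return amp * np.exp(-0.5 * ((times - centre) / width) ** 2)


def test_find_peak_unique_extremum(montage16):
    t = np.arange(-100, 500)
    ev = roi_evoked(montage16, gaussian_bump(t, 115.0))
    res = find_peak(ev, ROI16)
    assert res.found and res.latency_ms == 115.0
    assert res.amplitude_uv == pytest.approx(5.0)


def test_find_peak_tie_earliest(montage16):
    t = np.arange(-100, 500)
    wave = gaussian_bump(t, 100.0, 5.0) + gaussian_bump(t, 120.0, 5.0)
    ev = roi_evoked(montage16, wave)
    res = find_peak(ev, ROI16)
    assert res.found and res.latency_ms == 100.0


def test_find_peak_polarity_and_missing(montage16):
    t = np.arange(-100, 500)
    ev = roi_evoked(montage16, -gaussian_bump(t, 115.0))  # negative bump only
    res = find_peak(ev, ROI16)  # searching for a positive peak
    assert not res.found and np.isnan(res.latency_ms)
    neg = ComponentDef("n", -1, (80.0, 160.0), ("G0",))
    res2 = find_peak(ev, neg)
    assert res2.found and res2.latency_ms == 115.0 and res2.amplitude_uv < 0


def test_mean_amplitude_constant(montage16):
    ev = roi_evoked(montage16, np.full(600, 2.0))
    amps = mean_amplitude(ev, ROI16, 120.0)
    assert set(amps.index) == set(ROI16.electrode_set)
    np.testing.assert_allclose(amps.to_numpy(), 2.0)


def test_mean_amplitude_symmetric_ramp(montage16):
    t = np.arange(-100, 500, dtype=float)
    wave = 10.0 - np.abs(t - 120.0) * 0.05  # triangle peaking at 120 ms
    ev = roi_evoked(montage16, wave)
    amps = mean_amplitude(ev, ROI16, 120.0)
    # symmetric about the peak: the window mean equals the value ... of the
    # mean offset; brute-force comparison is the contract
    i0, i1 = ev.time_index(100.0), ev.time_index(140.0)
    expected = wave[i0:i1].mean()
    np.testing.assert_allclose(amps.to_numpy(), expected, atol=1e-12)


def test_mean_amplitude_matches_direct_summation(montage16):
    rng = np.random.default_rng(0)
    data = rng.normal(size=(16, 600))
    ev = make_evoked(montage16, data)
    amps = mean_amplitude(ev, ROI16, 132.0)
    i0, i1 = ev.time_index(112.0), ev.time_index(152.0)
    for k, name in enumerate(ROI16.electrode_set):
        assert amps[name] == pytest.approx(
            data[montage16.index(name), i0:i1].mean(), abs=1e-12
        )


def test_mean_amplitude_window_clipped(montage16):
    ev = roi_evoked(montage16, np.zeros(600))
    with pytest.raises(PipelineError, match="clipped"):
        mean_amplitude(ev, ROI16, 490.0)


def test_measure_table_structure(montage16):
    t = np.arange(-100, 500)
    evokeds = []
    for subject in range(3):
        for cond in ({"role": "target"}, {"role": "non-target"}):
            amp = 4.0 + subject * 0.5 + (0.8 if cond["role"] == "target" else 0.0)
            ev = roi_evoked(montage16, gaussian_bump(t, 115.0, amp=amp))
            evokeds.append((subject, cond, ev))
    table = measure_table(evokeds, ROI16)
    assert len(table) == 3 * 2 * len(ROI16.electrode_set)
    assert table["peak_latency_ms"].eq(115.0).all()
    mean_by_role = table.groupby("role")["mean_amplitude_uv"].mean()
    assert mean_by_role["target"] > mean_by_role["non-target"]


# ------------------------------------------------------------------ rmANOVA


def anova_oracle_2x2(table, dependent):
    """Independent cell-means sums-of-squares oracle for subject x A x B."""
    wide = table.pivot_table(
        index="subject", columns=["A", "B"], values=dependent
    )
    Y = wide.to_numpy()  # (n, 4), columns (a1b1, a1b2, a2b1, a2b2)
    n = Y.shape[0]
    a1 = Y[:, :2].mean(1)
    a2 = Y[:, 2:].mean(1)
    b1 = Y[:, [0, 2]].mean(1)
    b2 = Y[:, [1, 3]].mean(1)
    res = {}
    for name, (u, v) in {"A": (a1, a2), "B": (b1, b2)}.items():
        d = u - v
        ss_eff = n * d.mean() ** 2 / 2 * 2  # = n * 2 * (d.mean()/2)**2 * 2
        ss_eff = 2 * n * (d.mean() / 2) ** 2 * 2
        # classical paired computation: F = t^2 with t the paired t statistic
        t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        res[name] = t**2
    inter = (Y[:, 0] - Y[:, 1]) - (Y[:, 2] - Y[:, 3])
    t = inter.mean() / (inter.std(ddof=1) / np.sqrt(n))
    res["A:B"] = t**2
    return res


def test_rm_anova_matches_paired_t_oracle():
    rng = np.random.default_rng(1)
    rows = []
    for s in range(6):
        for a in ("a1", "a2"):
            for b in ("b1", "b2"):
                rows.append(
                    {"subject": s, "A": a, "B": b, "y": rng.normal(loc=(a == "a2") * 1.0)}
                )
    table = pd.DataFrame(rows)
    res = rm_anova(table, ["A", "B"], "y").set_index("effect")
    oracle = anova_oracle_2x2(table, "y")
    for eff in ("A", "B", "A:B"):
        assert res.loc[eff, "F"] == pytest.approx(oracle[eff], abs=1e-8)
        assert res.loc[eff, "df_den"] == 5
        assert res.loc[eff, "gg_epsilon"] == 1.0


def test_rm_anova_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    rows = []
    for s in range(8):
        for a in ("x", "y", "z"):  # 3 levels: epsilon < 1 possible
            for b in ("p", "q"):
                rows.append(
                    {
                        "subject": s,
                        "A": a,
                        "B": b,
                        "score": rng.normal() + {"x": 0, "y": 0.5, "z": 1.2}[a],
                    }
                )
    table = pd.DataFrame(rows)
    ours = rm_anova(table, ["A", "B"], "score").set_index("effect")
    theirs = pingouin.rm_anova(
        data=table, dv="score", within=["A", "B"], subject="subject", effsize="np2"
    ).set_index("Source")
    mapping = {"A": "A", "B": "B", "A:B": "A * B"}
    for eff, their_name in mapping.items():
        assert ours.loc[eff, "F"] == pytest.approx(theirs.loc[their_name, "F"], abs=1e-8)
        assert ours.loc[eff, "partial_eta_sq"] == pytest.approx(
            theirs.loc[their_name, "np2"], abs=1e-8
        )
        assert ours.loc[eff, "p_uncorrected"] == pytest.approx(
            theirs.loc[their_name, "p_unc"], abs=1e-10
        )
        assert ours.loc[eff, "gg_epsilon"] == pytest.approx(
            theirs.loc[their_name, "eps"], abs=1e-6
        )


def test_rm_anova_epsilon_matches_pingouin_oneway():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(3)
    rows = []
    for s in range(10):
        base = rng.normal()
        for i, a in enumerate(("l1", "l2", "l3", "l4")):
            rows.append({"subject": s, "A": a, "y": base * (i + 1) + rng.normal()})
    table = pd.DataFrame(rows)
    ours = rm_anova(table, ["A"], "y").set_index("effect")
    theirs = pingouin.rm_anova(
        data=table, dv="y", within="A", subject="subject", correction=True
    )
    assert ours.loc["A", "F"] == pytest.approx(float(theirs["F"].iloc[0]), abs=1e-8)
    assert ours.loc["A", "gg_epsilon"] == pytest.approx(
        float(theirs["eps"].iloc[0]), abs=1e-6
    )
    assert ours.loc["A", "p_gg"] == pytest.approx(
        float(theirs["p_GG_corr"].iloc[0]), abs=1e-8
    )


def test_rm_anova_identical_values_f_zero():
    rows = [
        {"subject": s, "A": a, "y": float(s)}  # subject effect only
        for s in range(5)
        for a in ("a1", "a2")
    ]
    res = rm_anova(pd.DataFrame(rows), ["A"], "y").set_index("effect")
    assert res.loc["A", "F"] == 0.0


def test_rm_anova_partial_eta_identity_and_invariances():
    rng = np.random.default_rng(4)
    rows = [
        {"subject": s, "A": a, "B": b, "y": rng.normal()}
        for s in range(7)
        for a in ("a1", "a2", "a3")
        for b in ("b1", "b2")
    ]
    table = pd.DataFrame(rows)
    res = rm_anova(table, ["A", "B"], "y")
    for _, r in res.iterrows():
        implied = (r["F"] * r["df_num"]) / (r["F"] * r["df_num"] + r["df_den"])
        assert r["partial_eta_sq"] == pytest.approx(implied, abs=1e-10)
    # invariance to subject relabeling and constant shifts
    relabeled = table.copy()
    relabeled["subject"] = relabeled["subject"].map(lambda s: f"S{(s * 3) % 7}")
    shifted = table.copy()
    shifted["y"] = shifted["y"] + 100.0
    for variant in (relabeled, shifted):
        other = rm_anova(variant, ["A", "B"], "y")
        np.testing.assert_allclose(other["F"], res["F"], atol=1e-8)
        np.testing.assert_allclose(other["gg_epsilon"], res["gg_epsilon"], atol=1e-8)


def test_rm_anova_incomplete_cells_error():
    rows = [
        {"subject": s, "A": a, "y": 1.0}
        for s in range(4)
        for a in ("a1", "a2")
    ][:-1]  # drop one cell
    with pytest.raises(ConfigurationError, match="incomplete"):
        rm_anova(pd.DataFrame(rows), ["A"], "y")


def test_rm_anova_five_factor_df():
    """Fully-crossed 5-factor model reports the expected error df."""
    rng = np.random.default_rng(5)
    rows = []
    for s in range(19):
        for d in ("nt", "t"):
            for c in ("b", "f"):
                for col in ("blue", "green"):
                    for loc in ("o", "po"):
                        for site in ("s1", "s2", "s3"):
                            rows.append(
                                {
                                    "subject": s,
                                    "deviant": d,
                                    "category": c,
                                    "colour": col,
                                    "location": loc,
                                    "site": site,
                                    "y": rng.normal(),
                                }
                            )
    res = rm_anova(
        pd.DataFrame(rows),
        ["deviant", "category", "colour", "location", "site"],
        "y",
    ).set_index("effect")
    assert len(res) == 31  # all main effects and interactions
    for eff in ("deviant", "category", "colour", "location"):
        assert res.loc[eff, "df_num"] == 1 and res.loc[eff, "df_den"] == 18
    assert res.loc["site", "df_num"] == 2 and res.loc["site", "df_den"] == 36


def test_planned_contrast_subsets():
    rng = np.random.default_rng(6)
    rows = [
        {"subject": s, "A": a, "B": b, "y": rng.normal() + (a == "a2") * 1.0}
        for s in range(6)
        for a in ("a1", "a2")
        for b in ("b1", "b2")
    ]
    table = pd.DataFrame(rows)
    sub = planned_contrast(table, {"B": "b1"}, ["A"], "y").set_index("effect")
    assert "A" in sub.index
    with pytest.raises(ConfigurationError, match="empty"):
        planned_contrast(table, {"B": "nope"}, ["A"], "y")


def test_posthoc_holm_monotone():
    rng = np.random.default_rng(7)
    rows = [
        {"subject": s, "A": a, "y": rng.normal() + {"a1": 0, "a2": 2, "a3": 0.1}[a]}
        for s in range(8)
        for a in ("a1", "a2", "a3")
    ]
    out = posthoc_pairwise(pd.DataFrame(rows), "A", "y")
    assert (out["p_holm"] >= out["p"] - 1e-12).all()
    assert (out["p_holm"] <= 1.0).all()


def test_electrode_factor_annotation():
    table = pd.DataFrame({"electrode": list(P1_DEF.electrode_set)})
    out = electrode_factors(table, "P1")
    assert set(out["location"]) == {"occipital", "parieto-occipital"}
    assert set(out["site"]) == {"s1", "s2", "s3"}
    n1 = electrode_factors(pd.DataFrame({"electrode": list(N1_DEF.electrode_set)}), "N1")
    assert set(n1["hemisphere"]) == {"left", "right"}


# ------------------------------------------------------------------ behaviour


def _behaviour_frame(rng, n_sub=6, rt_gap=150.0):
    rows = []
    for s in range(n_sub):
        for role in ("non-target", "target"):
            for cat in ("butterfly", "face"):
                for col in ("blue", "green"):
                    for _ in range(10):
                        rt = 270.0 + (rt_gap if role == "target" else 0.0) + rng.normal(0, 20)
                        rows.append(
                            {
                                "subject": s,
                                "role": role,
                                "category": cat,
                                "colour": col,
                                "correct": bool(rng.random() < (0.7 if role == "target" else 0.95)),
                                "rt_ms": max(rt, 101.0),
                            }
                        )
    return pd.DataFrame(rows)


def test_behavior_stats_structure_and_effect():
    rng = np.random.default_rng(8)
    beh = _behaviour_frame(rng)
    out = behavior_stats(beh)
    rt = out["rt"].set_index("effect")
    acc = out["accuracy"].set_index("effect")
    assert rt.loc["role", "p_gg"] < 0.01  # planted 150 ms gap
    assert {"role", "category", "colour"} <= set(acc.index)


def test_behavior_stats_all_correct_accuracy_f_zero():
    rng = np.random.default_rng(9)
    beh = _behaviour_frame(rng)
    beh["correct"] = True
    out = behavior_stats(beh)
    assert (out["accuracy"]["F"] == 0.0).all()


def test_behavior_stats_empty_cell_error():
    rng = np.random.default_rng(10)
    beh = _behaviour_frame(rng)
    # subject 0 has no valid target RTs at all
    mask = (beh["subject"] == 0) & (beh["role"] == "target")
    beh.loc[mask, "rt_ms"] = 50.0
    with pytest.raises(PipelineError, match="zero valid RTs"):
        behavior_stats(beh)
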