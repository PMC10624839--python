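import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from neuromux.coding import (
    EFFECTS,
    EffectSizeTrack,
    NeuronPhaseFlags,
    anova_window,
    bin_counts,
    classify_phase,
    cohens_d,
    count_flags,
    effect_track,
    mean_effect_table,
    thresholded_eta,
)
from neuromux.io import AnalysisConfig, PhaseEpochs, SpikeTrainSet, TrialTable


# ---------------------------------------------------------------- fixtures

def _mini_trials(n_per_cell=2):
    """Balanced complex-class mini session: stimuli 1-4, all correct."""
    rows = []
    ti = 1
    for _ in range(n_per_cell):
        for sid, val, cho in [(1, "high", "left"), (2, "high", "right"),
                              (3, "low", "left"), (4, "low", "right")]:
            rows.append(("S1", "b1", ti, sid, "complex", val, cho, "correct", True, True))
            ti += 1
    df = pd.DataFrame(rows, columns=[
        "session_id", "animal_id", "trial_index", "stimulus_id", "stim_class",
        "value", "choice", "outcome", "delay_present", "rewarded"])
    return TrialTable(df)


def _track_with(eta_by_effect: dict, cfg=None) -> EffectSizeTrack:
    """Synthetic track: eta_by_effect maps effect -> {window_start: eta}."""
    cfg = cfg or AnalysisConfig()
    starts = cfg.window_starts
    eta = np.zeros((len(starts), 3))
    for e, vals in eta_by_effect.items():
        col = EFFECTS.index(e)
        for t, v in vals.items():
            eta[np.argmin(np.abs(starts - t)), col] = v
    return EffectSizeTrack(starts, eta, np.ones_like(eta), n_trials=100,
                           valid=np.ones(len(starts), bool))


# ---------------------------------------------------------------- binning

def test_bin_counts_window_conventions():
    trials = _mini_trials()
    trains = {"n1": {ti: np.array([]) for ti in range(1, 9)}}
    trains["n1"][1] = np.array([0.0, 3.9, 4.15])
    spikes = SpikeTrainSet(trains, {"n1": "S1"})
    bc = bin_counts(spikes, "n1", trials)
    starts = bc.window_starts
    assert bc.counts.shape == (8, 45)
    row = bc.counts[0]

    def w(t):
        return int(np.argmin(np.abs(starts - t)))

    # the spike at 0.0 lands in the three overlapping windows starting
    # -0.2, -0.1 and 0.0 (window-start inclusion: [start, start + 0.25))
    assert [row[w(t)] for t in (-0.3, -0.2, -0.1, 0.0, 0.1)] == [0, 1, 1, 1, 0]
    # final window [3.9, 4.15): 3.9 included at the start edge, 4.15 excluded
    assert row[-1] == 1


def test_bin_counts_filters_and_errors():
    trials = _mini_trials()
    spikes = SpikeTrainSet({"n1": {}}, {"n1": "S1"})
    with pytest.raises(ValueError, match="no trials"):
        bin_counts(spikes, "n1", trials, stim_class="simple")


# ---------------------------------------------------------------- anova

def _brute_force_ss(y, v, c):
    """Mean-based sums of squares for a balanced 2x2 design (oracle)."""
    y = np.asarray(y, float)
    v = np.asarray(v)
    c = np.asarray(c)
    grand = y.mean()
    vm = {a: y[v == a].mean() for a in np.unique(v)}
    cm = {a: y[c == a].mean() for a in np.unique(c)}
    cell = {(a, b): y[(v == a) & (c == b)].mean() for a in np.unique(v) for b in np.unique(c)}
    ss_v = sum((vm[v[i]] - grand) ** 2 for i in range(len(y)))
    ss_c = sum((cm[c[i]] - grand) ** 2 for i in range(len(y)))
    ss_i = sum((cell[(v[i], c[i])] - vm[v[i]] - cm[c[i]] + grand) ** 2 for i in range(len(y)))
    ss_e = sum((y[i] - cell[(v[i], c[i])]) ** 2 for i in range(len(y)))
    return {"value": ss_v, "choice": ss_c, "interaction": ss_i, "error": ss_e}


def test_anova_all_counts_identical_gives_zero_eta():
    res = anova_window([5] * 8, ["high"] * 4 + ["low"] * 4,
                       ["left", "right"] * 4)
    assert all(res["eta_p2"][e] == 0.0 for e in EFFECTS)


def test_anova_pure_choice_effect():
    # cell means (HL, LL, HR, LR) = (10, 10, 4, 4), zero within-cell variance
    counts, v, c = [], [], []
    for val in ("high", "low"):
        for cho, mean in (("left", 10), ("right", 4)):
            counts += [mean, mean]
            v += [val, val]
            c += [cho, cho]
    res = anova_window(counts, v, c)
    assert res["eta_p2"]["choice"] == pytest.approx(1.0)
    assert res["eta_p2"]["value"] == pytest.approx(0.0)
    assert res["eta_p2"]["interaction"] == pytest.approx(0.0)


def test_anova_matches_bruteforce_oracle_balanced():
    rng = np.random.default_rng(17)
    v = np.repeat(["high", "low"], 10)
    c = np.tile(np.repeat(["left", "right"], 5), 2)
    y = rng.poisson(6, 20).astype(float)
    res = anova_window(y, v, c)
    oracle = _brute_force_ss(y, v, c)
    for e in EFFECTS:
        assert res["ss"][e] == pytest.approx(oracle[e], abs=1e-12)
        eta_oracle = oracle[e] / (oracle[e] + oracle["error"])
        assert res["eta_p2"][e] == pytest.approx(eta_oracle, abs=1e-12)
    assert res["ss"]["error"] == pytest.approx(oracle["error"], abs=1e-12)


def test_anova_matches_statsmodels_type3_unbalanced():
    """Independent route: Type III SS with sum-to-zero contrasts via OLS."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rng = np.random.default_rng(23)
    v = np.array(["high"] * 9 + ["low"] * 13)
    c = np.array(["left"] * 4 + ["right"] * 5 + ["left"] * 7 + ["right"] * 6)
    y = rng.poisson(5, 22) + (c == "left") * 3.0
    res = anova_window(y, v, c)
    fit = smf.ols("y ~ C(v, Sum)*C(c, Sum)",
                  data=pd.DataFrame({"y": y, "v": v, "c": c})).fit()
    tab = anova_lm(fit, typ=3)
    mapping = {"choice": "C(c, Sum)", "value": "C(v, Sum)",
               "interaction": "C(v, Sum):C(c, Sum)"}
    for e, row in mapping.items():
        assert res["ss"][e] == pytest.approx(tab.loc[row, "sum_sq"], abs=1e-10)
        assert res["p"][e] == pytest.approx(tab.loc[row, "PR(>F)"], abs=1e-10)
    assert res["ss"]["error"] == pytest.approx(tab.loc["Residual", "sum_sq"], abs=1e-10)


def test_anova_empty_cell_marks_invalid_not_raise():
    res = anova_window([1, 2, 3, 4], ["high"] * 4, ["left", "left", "right", "right"])
    assert res["valid"] is False
    assert all(res["eta_p2"][e] == 0.0 for e in EFFECTS)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(0.01, 50), shift=st.floats(-3, 50))
def test_eta_invariant_under_affine_count_transform(scale, shift):
    rng = np.random.default_rng(31)
    v = np.repeat(["high", "low"], 12)
    c = np.tile(np.repeat(["left", "right"], 6), 2)
    y = rng.poisson(8, 24).astype(float)
    base = anova_window(y, v, c)
    trans = anova_window(scale * y + shift, v, c)
    for e in EFFECTS:
        assert trans["eta_p2"][e] == pytest.approx(base["eta_p2"][e], abs=1e-9)


def test_classification_invariant_to_trial_order(small_session):
    _, trials, spikes = small_session
    nid = spikes.neuron_ids[0]
    bc = bin_counts(spikes, nid, trials, stim_class="complex")
    track = effect_track(bc)
    rng = np.random.default_rng(2)
    perm = rng.permutation(bc.n_trials)
    bc_perm = type(bc)(bc.window_starts, bc.window_width, bc.counts[perm],
                       bc.trial_index[perm], bc.value_labels[perm], bc.choice_labels[perm])
    track_perm = effect_track(bc_perm)
    np.testing.assert_allclose(track.eta, track_perm.eta, atol=1e-12)
    f1 = classify_phase(track)
    f2 = classify_phase(track_perm)
    assert f1.flags == f2.flags


def test_effect_track_length(small_session):
    _, trials, spikes = small_session
    bc = bin_counts(spikes, spikes.neuron_ids[0], trials, stim_class="complex")
    track = effect_track(bc)
    assert len(track.window_starts) == 45
    assert track.eta.shape == (45, 3)
    assert np.all((track.eta >= 0) & (track.eta <= 1))


# ---------------------------------------------------------------- rules

def test_two_consecutive_value_windows_flag_sample_only():
    track = _track_with({"value": {0.0: 0.05, 0.1: 0.04}})
    flags = classify_phase(track)
    assert flags["sample"]["value"] is True
    assert flags["sample"]["choice"] is False
    assert flags["sample"]["stimulus"] is False
    for ph in ("delay1", "delay2", "delay3"):
        assert not any(flags[ph].values())


def test_single_isolated_window_no_flag():
    track = _track_with({"choice": {0.5: 0.2}})
    flags = classify_phase(track)
    assert not any(any(flags[ph].values()) for ph in flags.flags)


def test_all_three_effects_together_flag_stimulus():
    track = _track_with({e: {0.3: 0.04, 0.4: 0.04} for e in EFFECTS})
    flags = classify_phase(track)
    assert flags["sample"]["stimulus"] is True
    assert flags["sample"]["choice"] is True
    assert flags["sample"]["value"] is True
    assert flags["sample"]["interaction"] is True


def test_two_of_three_effects_strict_vs_relaxed():
    track = _track_with({e: {2.3: 0.05, 2.4: 0.05} for e in ("choice", "value")})
    strict = classify_phase(track, stimulus_rule="strict")
    relaxed = classify_phase(track, stimulus_rule="relaxed")
    assert strict["delay2"]["stimulus"] is False
    assert relaxed["delay2"]["stimulus"] is True


def test_run_straddling_phase_boundary_counts_for_neither():
    track = _track_with({"choice": {0.9: 0.08, 1.0: 0.08}})
    flags = classify_phase(track)
    assert flags["sample"]["choice"] is False
    assert flags["delay1"]["choice"] is False
    # extending the run inside delay1 flags delay1 only
    track2 = _track_with({"choice": {0.9: 0.08, 1.0: 0.08, 1.1: 0.08}})
    flags2 = classify_phase(track2)
    assert flags2["delay1"]["choice"] is True
    assert flags2["sample"]["choice"] is False


def test_threshold_is_inclusive():
    track = _track_with({"choice": {1.5: 0.03, 1.6: 0.03}})
    assert classify_phase(track)["delay1"]["choice"] is True


# ---------------------------------------------------------------- averaging

def test_mean_effect_zero_without_supra_windows():
    track = _track_with({"choice": {t: 0.02 for t in (0.0, 0.1, 0.2)}})
    table = mean_effect_table({"n1": track})
    assert (table["mean_eta_p2"] == 0.0).all()


def test_mean_effect_full_phase_run():
    vals = {round(0.1 * i, 1): 0.05 for i in range(10)}  # all 10 sample windows
    track = _track_with({"choice": vals})
    table = mean_effect_table({"n1": track})
    row = table[(table["phase"] == "sample") & (table["effect"] == "choice")]
    assert row["mean_eta_p2"].iloc[0] == pytest.approx(0.05)


def test_mean_effect_raw_mode_keeps_subthreshold():
    track = _track_with({"choice": {0.0: 0.02}})
    cfg = AnalysisConfig(mean_effect_mode="raw")
    table = mean_effect_table({"n1": track}, cfg=cfg)
    row = table[(table["phase"] == "sample") & (table["effect"] == "choice")]
    assert row["mean_eta_p2"].iloc[0] == pytest.approx(0.002)


def test_thresholded_eta_keeps_whole_runs():
    track = _track_with({"value": {1.0: 0.05, 1.1: 0.04, 1.3: 0.2}})
    kept = thresholded_eta(track, AnalysisConfig())
    col = EFFECTS.index("value")
    starts = track.window_starts
    assert kept[np.argmin(np.abs(starts - 1.0)), col] == 0.05
    assert kept[np.argmin(np.abs(starts - 1.1)), col] == 0.04
    assert kept[np.argmin(np.abs(starts - 1.3)), col] == 0.0  # isolated


# ---------------------------------------------------------------- stats

def test_cohens_d_identical_groups_zero():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    assert cohens_d(a, a.copy(), paired=False) == 0.0


def test_cohens_d_degenerate_errors():
    a = np.array([1.0, 2, 3, 4, 5, 6])
    with pytest.raises(ZeroDivisionError):
        cohens_d(a + 1.0, a, paired=True)  # constant difference, sd -> 0
    with pytest.raises(ValueError):
        cohens_d(a, a[:3], paired=True)


def test_cohens_d_matches_hand_computation():
    a = np.array([3.1, 4.2, 5.0, 6.3, 2.2, 4.4])
    b = np.array([2.0, 3.9, 4.1, 5.0, 2.5, 3.0])
    d = a - b
    expect_paired = d.mean() / np.sqrt(np.sum((d - d.mean()) ** 2) / (len(d) - 1))
    assert cohens_d(a, b, paired=True) == pytest.approx(expect_paired, abs=1e-12)
    sp = np.sqrt((np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)) / (2 * len(a) - 2))
    assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)


def test_count_flags_and_cell_total():
    f1 = NeuronPhaseFlags({ph: {"choice": ph == "sample", "value": False,
                                "stimulus": False, "interaction": False}
                           for ph in ("sample", "delay1", "delay2", "delay3")})
    f2 = NeuronPhaseFlags({ph: {"choice": True, "value": ph == "sample",
                                "stimulus": False, "interaction": False}
                           for ph in ("sample", "delay1", "delay2", "delay3")})
    out = count_flags({"a": f1, "b": f2})
    assert out.loc["sample", "choice"] == 2
    assert out.loc["sample", "value"] == 1
    assert out.loc["sample", "cell_total"] == 2
    assert out.loc["delay2", "cell_total"] == 1
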