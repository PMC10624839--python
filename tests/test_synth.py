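import numpy as np
import pytest

from neuromux.coding import bin_counts
from neuromux.io import AnalysisConfig
from neuromux.synth import (
    GRAY_LEVELS,
    STIMULUS_CATALOG,
    CodingProfile,
    SessionSpec,
    generate_session,
    generate_stimulus_images,
    rate_segments,
)


def _single_neuron_session(profile, n_trials, seed, error_rate=0.0):
    spec = SessionSpec(
        n_trials_per_stimulus=n_trials,
        neurons=[profile],
        error_rate={"complex": error_rate, "simple": error_rate},
    )
    return generate_session(spec, seed)


def test_null_neuron_poisson_mean():
    """Mean spike count over [-0.5, 4.25] matches rate x duration within 3 SEM."""
    baseline = 10.0
    trials, spikes = _single_neuron_session(
        CodingProfile(kind="null", baseline_rate=baseline), n_trials=13, seed=0
    )
    nid = spikes.neuron_ids[0]
    counts = np.array([len(spikes.trains[nid][ti]) for ti in spikes.trains[nid]])
    expected = baseline * 4.75
    sem = np.sqrt(expected / len(counts))
    assert abs(counts.mean() - expected) < 3 * sem


def test_determinism_same_spec_same_seed():
    spec = SessionSpec(n_trials_per_stimulus=5,
                       neurons=[CodingProfile(kind="early_choice")])
    t1, s1 = generate_session(spec, 7)
    t2, s2 = generate_session(spec, 7)
    assert t1.df.equals(t2.df)
    nid = s1.neuron_ids[0]
    for ti in s1.trains[nid]:
        np.testing.assert_array_equal(s1.trains[nid][ti], s2.trains[nid][ti])


def test_early_choice_rate_difference_and_decay():
    """Empirical condition-mean rates recover the programmed gain and its
    exponential decay across the delay (gain at sample, gain*exp(-2/tau) in
    the third delay second)."""
    gain, tau = 8.0, 1.5
    profile = CodingProfile(kind="early_choice", baseline_rate=10.0,
                            effect_gain=gain, decay_tau=tau, preferred_choice="left")
    # 8 stimuli x 300 trials = 2400 trials, half left / half right
    trials, spikes = _single_neuron_session(profile, n_trials=300, seed=3)
    nid = spikes.neuron_ids[0]
    df = trials.df

    def mean_rate(side, lo, hi):
        idx = df.loc[df["choice"] == side, "trial_index"]
        counts = [np.sum((spikes.trains[nid][ti] >= lo) & (spikes.trains[nid][ti] < hi))
                  for ti in idx]
        return np.mean(counts) / (hi - lo)

    diff_sample = mean_rate("left", 0, 1) - mean_rate("right", 0, 1)
    diff_delay3 = mean_rate("left", 3, 4) - mean_rate("right", 3, 4)
    # SEM of a rate difference at ~1200 trials/side, rate ~18 sp/s: ~0.17
    assert abs(diff_sample - gain) < 0.6
    assert abs(diff_delay3 - gain * np.exp(-2.0 / tau)) < 0.6


def test_stimulus_no_choice_profile_has_no_choice_main_effect():
    """The diagonal value-by-choice gain leaves left/right mean rates equal."""
    profile = CodingProfile(kind="stimulus_no_choice", baseline_rate=10.0, effect_gain=10.0)
    trials, spikes = _single_neuron_session(profile, n_trials=300, seed=4)
    nid = spikes.neuron_ids[0]
    df = trials.df[trials.df["stim_class"] == "complex"]

    def rate(side):
        idx = df.loc[df["choice"] == side, "trial_index"]
        return np.mean([np.sum((spikes.trains[nid][ti] >= 0) & (spikes.trains[nid][ti] < 1))
                        for ti in idx])

    assert abs(rate("left") - rate("right")) < 0.5


def test_profile_validation():
    with pytest.raises(ValueError):
        CodingProfile(kind="early_choice", effect_gain=-1.0)
    with pytest.raises(ValueError):
        CodingProfile(kind="early_choice", baseline_rate=0.0)
    with pytest.raises(ValueError):
        CodingProfile(kind="wiggly")
    with pytest.raises(ValueError):
        SessionSpec(n_trials_per_stimulus=0)
    with pytest.raises(ValueError):
        SessionSpec(error_rate={"complex": 1.4, "simple": 0.1})


def test_rate_segments_structure():
    profile = CodingProfile(kind="late_choice", baseline_rate=10.0, effect_gain=8.0,
                            preferred_choice="left")
    import pandas as pd

    trial = pd.Series({"choice": "left", "value": "high", "stimulus_id": 1})
    breaks, rates = rate_segments(profile, trial)
    assert breaks[0] == -0.5 and breaks[-1] == 4.25
    # baseline before delay, gain through the delay, baseline after
    pre = rates[np.searchsorted(breaks, -0.5, side="right") - 1]
    mid = rates[np.searchsorted(breaks, 2.5, side="right") - 1]
    post = rates[np.searchsorted(breaks, 4.1, side="right") - 1]
    assert pre == 10.0 and mid == 18.0 and post == 10.0


def test_null_counts_in_disjoint_windows_uncorrelated():
    """Poisson increments in non-overlapping windows are independent: the
    pooled correlation over 10,000 window-pair samples stays near 0."""
    trials, spikes = _single_neuron_session(
        CodingProfile(kind="null", baseline_rate=15.0), n_trials=75, seed=9
    )
    cfg = AnalysisConfig(window_step=0.25, t_start=-0.5, last_window_start=4.0)
    nid = spikes.neuron_ids[0]
    bc = bin_counts(spikes, nid, trials, cfg)  # 19 disjoint windows
    rng = np.random.default_rng(0)
    n_tr, n_w = bc.counts.shape
    i = rng.integers(0, n_w, size=10_000)
    j = (i + 1 + rng.integers(0, n_w - 1, size=10_000)) % n_w
    t = rng.integers(0, n_tr, size=10_000)
    r = np.corrcoef(bc.counts[t, i], bc.counts[t, j])[0, 1]
    assert abs(r) < 0.05


def test_error_trials_flip_choice():
    trials, _ = _single_neuron_session(CodingProfile(kind="null"), 50, 11, error_rate=0.3)
    df = trials.df
    for _, row in df.iterrows():
        correct_choice = STIMULUS_CATALOG[row["stimulus_id"]][2]
        if row["outcome"] == "correct":
            assert row["choice"] == correct_choice
        else:
            assert row["choice"] != correct_choice


def test_gray_images_exact_levels_and_zero_variance():
    imgs = generate_stimulus_images(64, 64, seed=1)
    for sid, level in zip((5, 6, 7, 8), GRAY_LEVELS):
        arr = imgs.images[sid]
        assert arr.shape == (64, 64)
        assert np.all(arr == level)
        assert np.ptp(arr) == 0.0  # exactly constant
    # 4th gray image is the 98%-white one
    assert np.all(imgs.images[8] == 0.98)


def test_complex_images_have_structure():
    imgs = generate_stimulus_images(96, 96, seed=2)
    for sid in (1, 2, 3, 4):
        lum = imgs.luminance(sid)
        assert lum.shape == (96, 96)
        assert lum.var() > 1e-3
    with pytest.raises(ValueError):
        generate_stimulus_images(32, 64, seed=0)


def test_image_pngs_written(tmp_path):
    imgs = generate_stimulus_images(64, 64, seed=3)
    paths = imgs.save_pngs(tmp_path)
    assert len(paths) == 8
    from PIL import Image

    arr = np.asarray(Image.open(paths[4]))  # stimulus 5, gray 0.431
    assert arr.std() == 0
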