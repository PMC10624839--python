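"""Synthetic sessions and stimulus images emulating the delayed paired-association task.

A session presents 8 stimuli: four "complex" multicolor textured images whose
value factor is reward probability (high = 90%, low = 30%), and four "simple"
uniform gray images (43.1 / 54.9 / 86.3 / 98 % white, rewarded at 50%) whose
value factor is contrast, i.e. distance from the 70.6%-white category
boundary. Each stimulus is associated with a left or right choice; trials are
1 s sample + 3 s delay, spikes are kept over [-0.5, +4.25] s around sample
onset.

Spiking is an inhomogeneous Poisson process with a piecewise-constant rate:
a baseline plus additive, condition-dependent gain terms determined by each
neuron's :class:`CodingProfile`. This is the simplest generative model with
the factorial mean structure the downstream two-way ANOVA assumes;
refractoriness is irrelevant at 250 ms counting windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from neuromux.io import SpikeTrainSet, TrialTable, logger

PROFILE_KINDS = (
    "null",
    "early_choice",
    "late_choice",
    "stimulus_no_choice",
    "stimulus_choice",
    "value_coder",
)

#: stimulus_id -> (stim_class, value, correct choice, gray level or None)
#: Simple values: high contrast = far from the 70.6% boundary (43.1, 98),
#: low contrast = near it (54.9, 86.3). Darks map to left, brights to right.
STIMULUS_CATALOG: dict[int, tuple[str, str, str, float | None]] = {
    1: ("complex", "high", "left", None),
    2: ("complex", "high", "right", None),
    3: ("complex", "low", "left", None),
    4: ("complex", "low", "right", None),
    5: ("simple", "high", "left", 0.431),
    6: ("simple", "low", "left", 0.549),
    7: ("simple", "low", "right", 0.863),
    8: ("simple", "high", "right", 0.98),
}

GRAY_LEVELS = (0.431, 0.549, 0.863, 0.98)

TRIAL_WINDOW = (-0.5, 4.25)  # seconds around sample onset kept per trial
SAMPLE_ON, DELAY_ON, DELAY_OFF = 0.0, 1.0, 4.0


@dataclass
class CodingProfile:
    """How one synthetic neuron codes the task.

    kind
        ``null`` — baseline only. ``early_choice`` — additive choice gain from
        sample onset through the delay. ``late_choice`` — choice gain from
        delay onset. ``value_coder`` — gain for the preferred value level
        during sample and the first delay second. ``stimulus_no_choice`` —
        an interaction-pattern gain (two diagonal value-by-choice cells)
        during the sample phase, which carries no choice main effect.
        ``stimulus_choice`` — gain for one specific stimulus during the
        sample, handing over to a choice gain at ``switch_time``.
    baseline_rate
        spikes/s, must be positive.
    effect_gain
        additive rate difference (spikes/s) between coded conditions.
    switch_time
        seconds; when the stimulus code hands over to the choice code
        (``stimulus_choice`` only).
    decay_tau
        seconds or None; exponential decay of the choice gain across the
        delay, evaluated per delay second from delay onset.
    preferred_stimulus
        stimulus_id for ``stimulus_choice``; None elsewhere.
    """

    kind: str = "null"
    baseline_rate: float = 10.0
    effect_gain: float = 8.0
    switch_time: float = 1.0
    decay_tau: float | None = None
    preferred_stimulus: int | None = None
    preferred_choice: str = "left"
    preferred_value: str = "high"

    def __post_init__(self):
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.effect_gain < 0:
            raise ValueError("effect_gain must be >= 0")
        if not (0.0 <= self.switch_time <= 4.0):
            raise ValueError("switch_time must lie in [0, 4]")
        if self.kind == "stimulus_choice" and self.preferred_stimulus is None:
            self.preferred_stimulus = 1


@dataclass
class SessionSpec:
    """Design of one synthetic session.

    Defaults reproduce the recorded task: reward probabilities 0.9 / 0.3 for
    high / low complex stimuli and 0.5 for all simple stimuli, a 3 s delay,
    and class-wise error rates matching the measured delayed-condition
    performance (complex 91.7% correct, simple 83.2%).
    """

    session_id: str = "S001"
    animal_id: str = "bird01"
    n_trials_per_stimulus: int = 80
    neurons: list[CodingProfile] = field(default_factory=list)
    reward_probability: dict[str, float] = field(
        default_factory=lambda: {"complex-high": 0.9, "complex-low": 0.3, "simple": 0.5}
    )
    delay_present: bool = True
    error_rate: dict[str, float] = field(
        default_factory=lambda: {"complex": 0.083, "simple": 0.168}
    )

    def __post_init__(self):
        if self.n_trials_per_stimulus < 1:
            raise ValueError("n_trials_per_stimulus must be >= 1")
        for k, p in list(self.reward_probability.items()) + list(self.error_rate.items()):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {k}={p} outside [0, 1]")


def default_population(
    n_neurons: int = 104,
    seed: int = 0,
    effect_gain: float = 8.0,
    decay_tau_early: float | None = 1.5,
) -> list[CodingProfile]:
    """A mixed 104-neuron population with all coding kinds represented.

    Baseline rates are drawn uniformly from 5-20 spikes/s (a conventional
    range for forebrain single units; the coding analysis is rate-scale
    invariant). Early-choice neurons decay across the delay by default,
    mirroring the trace-decay phenomenon; late-choice and stimulus-choice
    neurons hold their code stable.
    """
    rng = np.random.default_rng(seed)
    mix = (
        ["early_choice"] * 10
        + ["late_choice"] * 20
        + ["stimulus_choice"] * 16
        + ["stimulus_no_choice"] * 17
        + ["value_coder"] * 10
    )
    mix += ["null"] * max(0, n_neurons - len(mix))
    mix = mix[:n_neurons]
    complex_ids, simple_ids = (1, 2, 3, 4), (5, 6, 7, 8)
    profiles = []
    for i, kind in enumerate(mix):
        pref_stim = None
        if kind == "stimulus_choice":
            pool = complex_ids if i % 2 == 0 else simple_ids
            pref_stim = int(rng.choice(pool))
        profiles.append(
            CodingProfile(
                kind=kind,
                baseline_rate=float(rng.uniform(5.0, 20.0)),
                effect_gain=effect_gain,
                decay_tau=decay_tau_early if kind == "early_choice" else None,
                preferred_stimulus=pref_stim,
                preferred_choice=str(rng.choice(["left", "right"])),
                preferred_value=str(rng.choice(["high", "low"])),
            )
        )
    return profiles


def _trial_frame(spec: SessionSpec, rng: np.random.Generator) -> pd.DataFrame:
    stim_ids = np.repeat(np.arange(1, 9), spec.n_trials_per_stimulus)
    rng.shuffle(stim_ids)
    rows = []
    for ti, sid in enumerate(stim_ids, start=1):
        stim_class, value, correct_choice, _ = STIMULUS_CATALOG[sid]
        correct = rng.random() >= spec.error_rate[stim_class]
        choice = correct_choice if correct else ("right" if correct_choice == "left" else "left")
        key = f"{stim_class}-{value}" if stim_class == "complex" else "simple"
        rewarded = bool(correct and rng.random() < spec.reward_probability[key])
        rows.append(
            (
                spec.session_id,
                spec.animal_id,
                ti,
                sid,
                stim_class,
                value,
                choice,
                "correct" if correct else "incorrect",
                spec.delay_present,
                rewarded,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "session_id",
            "animal_id",
            "trial_index",
            "stimulus_id",
            "stim_class",
            "value",
            "choice",
            "outcome",
            "delay_present",
            "rewarded",
        ],
    )


def _delay_multiplier(seg_start: float, decay_tau: float | None) -> float:
    """Choice-gain multiplier; decays per delay second from delay onset."""
    if decay_tau is None or seg_start < DELAY_ON:
        return 1.0
    return float(np.exp(-(seg_start - DELAY_ON) / decay_tau))


def rate_segments(profile: CodingProfile, trial: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant firing rate for one trial.

    Returns (breakpoints, rates) with len(rates) = len(breakpoints) - 1.
    Rates are clipped at zero (with a logged warning if clipping occurs).
    """
    breaks = sorted({TRIAL_WINDOW[0], SAMPLE_ON, 1.0, 2.0, 3.0, DELAY_OFF, TRIAL_WINDOW[1],
                     profile.switch_time})
    breaks = np.array([b for b in breaks if TRIAL_WINDOW[0] <= b <= TRIAL_WINDOW[1]])
    rates = np.full(len(breaks) - 1, profile.baseline_rate)
    g, kind = profile.effect_gain, profile.kind

    for i, s in enumerate(breaks[:-1]):
        add = 0.0
        in_task = SAMPLE_ON <= s < DELAY_OFF
        in_delay = DELAY_ON <= s < DELAY_OFF
        if kind == "early_choice" and in_task and trial["choice"] == profile.preferred_choice:
            add = g * _delay_multiplier(s, profile.decay_tau)
        elif kind == "late_choice" and in_delay and trial["choice"] == profile.preferred_choice:
            add = g * _delay_multiplier(s, profile.decay_tau)
        elif kind == "value_coder" and SAMPLE_ON <= s < 2.0 and trial["value"] == profile.preferred_value:
            add = g
        elif kind == "stimulus_no_choice" and SAMPLE_ON <= s < DELAY_ON:
            # diagonal value-by-choice pattern: pure interaction, no choice
            # main effect, so the neuron never earns a choice flag
            on_diagonal = (trial["value"] == "high") == (trial["choice"] == "left")
            if on_diagonal:
                add = g
        elif kind == "stimulus_choice":
            if s < profile.switch_time and in_task and trial["stimulus_id"] == profile.preferred_stimulus:
                add = g
            elif s >= profile.switch_time and in_task and trial["choice"] == profile.preferred_choice:
                add = g * _delay_multiplier(s, profile.decay_tau)
        rates[i] += add

    if np.any(rates < 0):
        logger.warning("negative rate clipped to 0 for profile kind %s", kind)
        rates = np.clip(rates, 0.0, None)
    return breaks, rates


def _poisson_train(
    breaks: np.ndarray, rates: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    times = []
    for lo, hi, r in zip(breaks[:-1], breaks[1:], rates):
        if r <= 0:
            continue
        n = rng.poisson(r * (hi - lo))
        if n:
            times.append(rng.uniform(lo, hi, size=n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def generate_session(spec: SessionSpec, seed: int) -> tuple[TrialTable, SpikeTrainSet]:
    """Simulate one session: trial table plus Poisson spike trains.

    Deterministic in (spec, seed): identical inputs give identical output.
    """
    rng = np.random.default_rng(seed)
    df = _trial_frame(spec, rng)
    trials = TrialTable(df)

    trains: dict[str, dict[int, np.ndarray]] = {}
    sessions: dict[str, str] = {}
    for j, profile in enumerate(spec.neurons):
        nid = f"{spec.session_id}_n{j + 1:03d}"
        per_trial: dict[int, np.ndarray] = {}
        for _, trial in df.iterrows():
            breaks, rates = rate_segments(profile, trial)
            per_trial[int(trial["trial_index"])] = _poisson_train(breaks, rates, rng)
        trains[nid] = per_trial
        sessions[nid] = spec.session_id
    return trials, SpikeTrainSet(trains, sessions)


@dataclass
class StimulusImageSet:
    """The 8 task stimuli: ids 1-4 complex RGB textures, 5-8 uniform grays.

    Arrays are float in [0, 1]; grays are 2-D (H, W), complex images (H, W, 3).
    """

    images: dict[int, np.ndarray]

    def luminance(self, stimulus_id: int) -> np.ndarray:
        """Rec. 601 luminance of a stimulus as a 2-D array."""
        img = self.images[stimulus_id]
        if img.ndim == 2:
            return img
        return img @ np.array([0.299, 0.587, 0.114])

    def save_pngs(self, directory) -> list[str]:
        from pathlib import Path

        from PIL import Image

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for sid, img in sorted(self.images.items()):
            arr = np.clip(np.round(img * 255), 0, 255).astype(np.uint8)
            p = directory / f"stimulus_{sid:02d}.png"
            Image.fromarray(arr).save(p)
            paths.append(str(p))
        return paths


def generate_stimulus_images(
    width: int = 128, height: int = 128, seed: int = 0
) -> StimulusImageSet:
    """Procedurally generate the 8-stimulus set.

    Grays are exactly constant at 43.1 / 54.9 / 86.3 / 98 % white. Complex
    stimuli are synthetic stand-ins for the study's photographs: multicolor
    composites of colored patches overlaid with oriented gratings at several
    scales, so they carry spatial-frequency content at multiple orientations
    (the statistical property the Gabor complexity measure is sensitive to).
    """
    if width < 64 or height < 64:
        raise ValueError("width and height must be >= 64")
    rng = np.random.default_rng(seed)
    images: dict[int, np.ndarray] = {}

    yy, xx = np.mgrid[0:height, 0:width].astype(float)
    for sid in (1, 2, 3, 4):
        img = np.empty((height, width, 3))
        # colored background patches
        base = rng.uniform(0.2, 0.8, size=3)
        img[:] = base
        for _ in range(6):
            cy, cx = rng.uniform(0, height), rng.uniform(0, width)
            ry, rx = rng.uniform(8, height / 3), rng.uniform(8, width / 3)
            mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0
            img[mask] = rng.uniform(0.0, 1.0, size=3)
        # oriented gratings at multiple scales and the four bank orientations
        lum_mod = np.zeros((height, width))
        for theta_deg in (0.0, 45.0, 90.0, 135.0):
            theta = np.deg2rad(theta_deg)
            for period in rng.uniform(3.0, 14.0, size=2):
                phase = rng.uniform(0, 2 * np.pi)
                xr = xx * np.cos(theta) + yy * np.sin(theta)
                lum_mod += rng.uniform(0.05, 0.15) * np.cos(2 * np.pi * xr / period + phase)
        img += lum_mod[..., None]
        images[sid] = np.clip(img, 0.0, 1.0)

    for sid, gray in zip((5, 6, 7, 8), GRAY_LEVELS):
        images[sid] = np.full((height, width), gray)
    return StimulusImageSet(images)
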