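"""Mutually exclusive temporal-multiplexing categories and class contrasts.

From the non-exclusive per-phase flags, each neuron receives exactly one
label describing how its code evolves across the trial:

- ``early_choice``: choice flag already in the sample phase; no stimulus,
  value or interaction flag in any phase.
- ``late_choice``: choice flag first appears in a delay phase; no stimulus,
  value or interaction flag in any phase.
- ``stimulus_no_choice``: some stimulus/value/interaction flag somewhere, but
  no choice flag in any phase.
- ``stimulus_choice``: stimulus/value/interaction activity in an earlier
  phase followed by a choice flag in a strictly later phase (the dynamic
  switch from a stimulus code to a choice code).
- ``uncategorized``: none of the above.

Class contrasts on label counts use Pearson's chi-square without continuity
correction; the trace-decay comparison is a paired t-test across the 10
window positions of the first vs last delay second of the population-mean
choice effect (hence df = 9).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from neuromux.io import PhaseEpochs
from neuromux.coding import EffectSizeTrack, NeuronPhaseFlags, EFFECTS

MULTIPLEX_LABELS = (
    "early_choice",
    "late_choice",
    "stimulus_no_choice",
    "stimulus_choice",
    "uncategorized",
)

STIMULUS_TYPE = ("stimulus", "value", "interaction")


def categorize_multiplex(flags: NeuronPhaseFlags, phases: PhaseEpochs | None = None) -> str:
    """Assign one mutually exclusive multiplexing label from phase flags.

    Phase order is sample < delay1 < delay2 < delay3; a same-phase
    co-occurrence of stimulus-type and choice flags does not count as a
    switch (the choice onset must be strictly later).
    """
    phases = phases or PhaseEpochs()
    order = list(phases.names)
    choice_phases = [order.index(p) for p in flags.phases_with("choice")]
    stim_phases = sorted(
        {order.index(p) for cat in STIMULUS_TYPE for p in flags.phases_with(cat)}
    )
    has_stim = bool(stim_phases)
    has_choice = bool(choice_phases)

    if has_choice and not has_stim:
        return "early_choice" if 0 in choice_phases else "late_choice"
    if has_stim and not has_choice:
        return "stimulus_no_choice"
    if has_stim and has_choice and max(choice_phases) > min(stim_phases):
        return "stimulus_choice"
    return "uncategorized"


def chi2_2x2(a: int, b: int, n_a: int, n_b: int) -> tuple[float, float]:
    """Pearson chi-square (df = 1, no continuity correction) comparing the
    proportion a/n_a against b/n_b. Returns (statistic, p)."""
    if not (0 <= a <= n_a and 0 <= b <= n_b):
        raise ValueError("counts must not exceed group totals")
    table = np.array([[a, n_a - a], [b, n_b - b]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ZeroDivisionError("chi-square undefined: a margin of the table is zero")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    chi2 = float(((table - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def chi2_gof_even(k1: int, k2: int) -> tuple[float, float]:
    """Goodness-of-fit chi-square (df = 1) of two counts against an even split."""
    if k1 + k2 <= 0:
        raise ValueError("k1 + k2 must be positive")
    e = (k1 + k2) / 2.0
    chi2 = float((k1 - e) ** 2 / e + (k2 - e) ** 2 / e)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def trace_decay_test(
    tracks: Mapping[str, EffectSizeTrack] | Sequence[EffectSizeTrack],
    phases: PhaseEpochs | None = None,
    phase_a: str = "delay1",
    phase_b: str = "delay3",
) -> tuple[float, int, float]:
    """Paired t-test for decay of the population choice effect across the delay.

    The population-mean choice eta_p^2 is computed per window position (10
    windows per phase, averaged over the supplied choice-coding neurons); the
    i-th window of ``phase_a`` is paired with the i-th window of ``phase_b``.
    Returns (t, df, p) with df = 9 under default windowing; t > 0 means the
    effect was larger early in the delay (trace decay).
    """
    phases = phases or PhaseEpochs()
    track_list = list(tracks.values()) if isinstance(tracks, Mapping) else list(tracks)
    if len(track_list) < 2:
        raise ValueError("need at least 2 neurons for the trace-decay test")

    choice_col = EFFECTS.index("choice")
    pop = np.mean([t.eta[:, choice_col] for t in track_list], axis=0)
    starts = track_list[0].window_starts

    def phase_values(name: str) -> np.ndarray:
        lo, hi = phases.interval(name)
        return pop[(starts >= lo - 1e-9) & (starts < hi - 1e-9)]

    a, b = phase_values(phase_a), phase_values(phase_b)
    if len(a) != len(b):
        raise ValueError("phases must contain equally many windows")
    t, p = stats.ttest_rel(a, b)
    return float(t), len(a) - 1, float(p)
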