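"""Sliding-window two-way ANOVA on spike counts and neuron classification.

For each neuron, spikes are counted in 250 ms windows stepped by 100 ms from
0.5 s before sample onset through the delay (45 windows; each 1 s task phase
owns exactly 10 window starts). Per window, a crossed two-way ANOVA with
factors value (high/low) and choice (left/right) yields, per effect, the
partial eta squared

    eta_p^2 = SS_effect / (SS_effect + SS_error)

computed from Type III sums of squares with sum-to-zero contrasts (for the
2x2 design with interaction these are the classical unweighted-means contrast
sums of squares, which coincide with Type I on balanced data). A neuron is
flagged per phase and category when eta_p^2 >= 0.03 holds in at least two
consecutive windows whose starts both lie inside the phase:

- choice / value / interaction: the corresponding single effect passes;
- stimulus: value, choice AND interaction all pass in the same two
  consecutive windows (the idiosyncratic single-stimulus signature).

Categories are not mutually exclusive; the mutually exclusive multiplexing
labels are derived in :mod:`neuromux.multiplex`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from neuromux.io import AnalysisConfig, PhaseEpochs, SpikeTrainSet, TrialTable

EFFECTS = ("choice", "value", "interaction")
CATEGORIES = ("choice", "value", "stimulus", "interaction")
#: cell order for the 2x2 design: (value, choice)
CELLS = (("high", "left"), ("high", "right"), ("low", "left"), ("low", "right"))


@dataclass
class BinnedCounts:
    """Spike counts per (trial, sliding window) for one neuron."""

    window_starts: np.ndarray  # (W,) seconds
    window_width: float
    counts: np.ndarray  # (n_trials, W) int
    trial_index: np.ndarray  # (n_trials,)
    value_labels: np.ndarray  # (n_trials,)
    choice_labels: np.ndarray  # (n_trials,)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_windows(self) -> int:
        return self.counts.shape[1]


@dataclass
class EffectSizeTrack:
    """Per-window eta_p^2 and p for choice, value, interaction (in that order)."""

    window_starts: np.ndarray  # (W,)
    eta: np.ndarray  # (W, 3), columns ordered as EFFECTS
    p: np.ndarray  # (W, 3)
    n_trials: int
    valid: np.ndarray  # (W,) bool; False where the design was degenerate

    def effect(self, name: str) -> np.ndarray:
        return self.eta[:, EFFECTS.index(name)]


@dataclass
class NeuronPhaseFlags:
    """Per phase x category classification of one neuron (non-exclusive)."""

    flags: dict[str, dict[str, bool]]

    def __getitem__(self, phase: str) -> dict[str, bool]:
        return self.flags[phase]

    def any_flag(self, phase: str) -> bool:
        return any(self.flags[phase].values())

    def category_anywhere(self, category: str) -> bool:
        return any(self.flags[ph][category] for ph in self.flags)

    def phases_with(self, category: str) -> list[str]:
        return [ph for ph in self.flags if self.flags[ph][category]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.flags).T[list(CATEGORIES)]


def bin_counts(
    spikes: SpikeTrainSet,
    neuron_id: str,
    trials: TrialTable,
    cfg: AnalysisConfig | None = None,
    stim_class: str | None = None,
    correct_only: bool = True,
) -> BinnedCounts:
    """Count spikes per sliding window, [start, start + width) half-open.

    ``trials`` is filtered to the neuron's session, to correct trials
    (default), and optionally to one stimulus class before counting.
    """
    cfg = cfg or AnalysisConfig()
    session = spikes.neuron_sessions[neuron_id]
    sub = trials.session(session)
    if correct_only:
        sub = sub.correct_only()
    if stim_class is not None:
        sub = sub.for_class(stim_class)
    if len(sub) == 0:
        raise ValueError(
            f"no trials left for neuron {neuron_id!r} after filtering "
            f"(stim_class={stim_class!r}, correct_only={correct_only})"
        )
    starts = cfg.window_starts
    width = cfg.window_width
    idx = sub.df["trial_index"].to_numpy()
    counts = np.empty((len(idx), len(starts)), dtype=int)
    for r, ti in enumerate(idx):
        t = spikes.spike_times(neuron_id, int(ti))
        lo = np.searchsorted(t, starts, side="left")
        hi = np.searchsorted(t, starts + width, side="left")
        counts[r] = hi - lo
    return BinnedCounts(
        window_starts=starts,
        window_width=width,
        counts=counts,
        trial_index=idx,
        value_labels=sub.df["value"].to_numpy(),
        choice_labels=sub.df["choice"].to_numpy(),
    )


def cell_index(value_labels, choice_labels) -> np.ndarray:
    """Map (value, choice) labels onto cell indices 0..3 (order of CELLS)."""
    v = (np.asarray(value_labels) == "low").astype(int)
    c = (np.asarray(choice_labels) == "right").astype(int)
    return 2 * v + c


def _anova22(counts: np.ndarray, cells: np.ndarray):
    """Vectorized 2x2 Type III ANOVA over windows.

    counts: (n, W); cells: (n,) in 0..3. Returns (ss_eff (W,3), ss_err (W,),
    eta (W,3), p (W,3), valid bool). Effect columns follow EFFECTS order.
    """
    counts = np.asarray(counts, dtype=float)
    n, W = counts.shape
    n_c = np.bincount(cells, minlength=4).astype(float)
    valid = bool(np.all(n_c >= 1) and n - 4 >= 1)
    if not valid:
        z = np.zeros((W, 3))
        return z, np.zeros(W), z, np.ones((W, 3)), False

    onehot = np.zeros((n, 4))
    onehot[np.arange(n), cells] = 1.0
    sums = onehot.T @ counts  # (4, W)
    means = sums / n_c[:, None]
    ss_err = (counts**2).sum(axis=0) - (sums**2 / n_c[:, None]).sum(axis=0)
    ss_err = np.maximum(ss_err, 0.0)

    # unweighted-means contrasts; q is the common contrast variance factor
    q = 0.25 * (1.0 / n_c).sum()
    m_hl, m_hr, m_ll, m_lr = means
    L_choice = (m_hl - m_hr + m_ll - m_lr) / 2.0
    L_value = (m_hl + m_hr - m_ll - m_lr) / 2.0
    L_inter = (m_hl - m_hr - m_ll + m_lr) / 2.0
    ss_eff = np.stack([L_choice**2, L_value**2, L_inter**2], axis=1) / q

    denom = ss_eff + ss_err[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        eta = np.where(denom > 0, ss_eff / denom, 0.0)
    df_err = n - 4
    with np.errstate(invalid="ignore", divide="ignore"):
        F = ss_eff / (ss_err[:, None] / df_err)
    p = np.where(
        ss_err[:, None] > 0,
        stats.f.sf(np.where(ss_err[:, None] > 0, F, 0.0), 1, df_err),
        np.where(ss_eff > 0, 0.0, 1.0),
    )
    return ss_eff, ss_err, eta, p, True


def anova_window(counts, value_labels, choice_labels) -> dict:
    """Two-way ANOVA of one window's counts; returns SS, eta_p^2 and p per effect.

    A degenerate design (an empty value-by-choice cell) yields
    ``valid=False`` with eta 0 rather than an exception.
    """
    counts = np.asarray(counts, dtype=float).reshape(-1, 1)
    cells = cell_index(value_labels, choice_labels)
    ss_eff, ss_err, eta, p, valid = _anova22(counts, cells)
    return {
        "ss": {e: float(ss_eff[0, i]) for i, e in enumerate(EFFECTS)} | {"error": float(ss_err[0])},
        "eta_p2": {e: float(eta[0, i]) for i, e in enumerate(EFFECTS)},
        "p": {e: float(p[0, i]) for i, e in enumerate(EFFECTS)},
        "valid": valid,
    }


def effect_track(bc: BinnedCounts, cells: np.ndarray | None = None) -> EffectSizeTrack:
    """Apply the windowed ANOVA across all sliding windows of one neuron."""
    if cells is None:
        cells = cell_index(bc.value_labels, bc.choice_labels)
    _, _, eta, p, valid = _anova22(bc.counts, cells)
    return EffectSizeTrack(
        window_starts=bc.window_starts,
        eta=eta,
        p=p,
        n_trials=bc.n_trials,
        valid=np.full(bc.n_windows, valid),
    )


def _run_positions(ok_windows: np.ndarray, L: int) -> np.ndarray:
    """ok at start position i iff windows i..i+L-1 are all ok. Shape (W-L+1,)."""
    W = len(ok_windows)
    if W < L:
        return np.zeros(0, dtype=bool)
    pos = np.ones(W - L + 1, dtype=bool)
    for j in range(L):
        pos &= ok_windows[j : W - L + 1 + j]
    return pos


def _qualifying_positions(track: EffectSizeTrack, cfg: AnalysisConfig) -> np.ndarray:
    """(W-L+1, 3) bool: effect e sustains eta >= threshold over L windows from i."""
    supra = (track.eta >= cfg.eta_threshold) & track.valid[:, None]
    return np.stack([_run_positions(supra[:, i], cfg.run_length) for i in range(3)], axis=1)


def classify_phase(
    track: EffectSizeTrack,
    phases: PhaseEpochs | None = None,
    cfg: AnalysisConfig | None = None,
    stimulus_rule: str = "strict",
) -> NeuronPhaseFlags:
    """Per-phase category flags from one effect-size track.

    ``stimulus_rule='strict'`` requires all three effects above threshold in
    the same two consecutive windows; ``'relaxed'`` (used for the permutation
    chance level) requires any two of the three.
    """
    phases = phases or PhaseEpochs()
    cfg = cfg or AnalysisConfig()
    if stimulus_rule not in ("strict", "relaxed"):
        raise ValueError("stimulus_rule must be 'strict' or 'relaxed'")
    L = cfg.run_length
    qual = _qualifying_positions(track, cfg)  # (W-L+1, 3)
    n_pass = qual.sum(axis=1)
    stim_qual = (n_pass == 3) if stimulus_rule == "strict" else (n_pass >= 2)

    starts = track.window_starts
    flags: dict[str, dict[str, bool]] = {}
    for name in phases.names:
        lo, hi = phases.interval(name)
        member = (starts >= lo - 1e-9) & (starts < hi - 1e-9)
        pos_in = _run_positions(member, L)
        flags[name] = {
            "choice": bool(np.any(qual[:, 0] & pos_in)),
            "value": bool(np.any(qual[:, 1] & pos_in)),
            "stimulus": bool(np.any(stim_qual & pos_in)),
            "interaction": bool(np.any(qual[:, 2] & pos_in)),
        }
    return NeuronPhaseFlags(flags)


def thresholded_eta(track: EffectSizeTrack, cfg: AnalysisConfig) -> np.ndarray:
    """eta_p^2 with windows outside qualifying runs zeroed, (W, 3).

    A window contributes its raw eta_p^2 only when it belongs to a run of at
    least ``cfg.run_length`` consecutive supra-threshold windows (runs are
    detected on the whole track; phase membership is applied afterwards when
    averaging).
    """
    W, L = len(track.window_starts), cfg.run_length
    supra = (track.eta >= cfg.eta_threshold) & track.valid[:, None]
    keep = np.zeros((W, 3), dtype=bool)
    for e in range(3):
        pos = _run_positions(supra[:, e], L)
        for i in np.flatnonzero(pos):
            keep[i : i + L, e] = True
    return np.where(keep, track.eta, 0.0)


def mean_effect_table(
    tracks: Mapping[str, EffectSizeTrack],
    phases: PhaseEpochs | None = None,
    cfg: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per neuron x phase x effect mean eta_p^2 over the phase's 10 windows.

    With ``cfg.mean_effect_mode == 'thresholded'`` (default), sub-threshold
    windows contribute 0; with ``'raw'``, plain eta_p^2 values are averaged.
    """
    phases = phases or PhaseEpochs()
    cfg = cfg or AnalysisConfig()
    rows = []
    for nid, track in tracks.items():
        eta = thresholded_eta(track, cfg) if cfg.mean_effect_mode == "thresholded" else track.eta
        starts = track.window_starts
        for name in phases.names:
            lo, hi = phases.interval(name)
            member = (starts >= lo - 1e-9) & (starts < hi - 1e-9)
            for i, e in enumerate(EFFECTS):
                rows.append((nid, name, e, float(eta[member, i].mean())))
    return pd.DataFrame(rows, columns=["neuron_id", "phase", "effect", "mean_eta_p2"])


def cohens_d(group_a, group_b, paired: bool = False) -> float:
    """Cohen's d: paired = mean(diff)/sd(diff); unpaired uses the pooled sd."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ZeroDivisionError("zero variance of paired differences")
        return float(diff.mean() / sd)
    na, nb = len(a), len(b)
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise ZeroDivisionError("zero pooled variance")
    return float((a.mean() - b.mean()) / pooled)


def count_flags(
    flags_by_neuron: Mapping[str, NeuronPhaseFlags], phases: PhaseEpochs | None = None
) -> pd.DataFrame:
    """Observed neurons per phase x category, plus the 'cell_total' column
    (neurons holding any flag in the phase)."""
    phases = phases or PhaseEpochs()
    out = pd.DataFrame(
        0, index=list(phases.names), columns=list(CATEGORIES) + ["cell_total"], dtype=int
    )
    for flags in flags_by_neuron.values():
        for ph in phases.names:
            for cat in CATEGORIES:
                out.loc[ph, cat] += int(flags[ph][cat])
            out.loc[ph, "cell_total"] += int(flags.any_flag(ph))
    return out


class CodingClassifier(BaseEstimator):
    """Fit-shaped front end for the per-neuron coding analysis.

    Parameters
    ----------
    stim_class : {"complex", "simple"}
        Which stimulus class's trials to analyze (classes are analyzed
        separately).
    config : AnalysisConfig or None
        Windowing, threshold and run-length parameters (defaults used if None).
    correct_only : bool, default True
        Restrict to correct trials.
    stimulus_rule : {"strict", "relaxed"}
        Stimulus-category rule (see :func:`classify_phase`).

    Attributes (after ``fit``)
    --------------------------
    tracks_ : dict neuron_id -> EffectSizeTrack
    flags_ : dict neuron_id -> NeuronPhaseFlags
    labels_ : dict neuron_id -> str, mutually exclusive multiplexing label
    mean_effect_ : DataFrame, per neuron x phase x effect mean eta_p^2
    counts_ : DataFrame, observed neurons per phase x category (+ cell_total)
    """

    def __init__(
        self,
        stim_class: str = "complex",
        config: AnalysisConfig | None = None,
        correct_only: bool = True,
        stimulus_rule: str = "strict",
    ):
        self.stim_class = stim_class
        self.config = config
        self.correct_only = correct_only
        self.stimulus_rule = stimulus_rule

    def fit(self, trials: TrialTable, spikes: SpikeTrainSet, neuron_ids=None):
        from neuromux.multiplex import categorize_multiplex

        cfg = self.config or AnalysisConfig()
        phases = PhaseEpochs()
        neuron_ids = list(neuron_ids) if neuron_ids is not None else spikes.neuron_ids
        self.tracks_ = {}
        self.flags_ = {}
        self.labels_ = {}
        for nid in neuron_ids:
            bc = bin_counts(
                spikes, nid, trials, cfg, stim_class=self.stim_class,
                correct_only=self.correct_only,
            )
            track = effect_track(bc)
            self.tracks_[nid] = track
            flags = classify_phase(track, phases, cfg, stimulus_rule=self.stimulus_rule)
            self.flags_[nid] = flags
            self.labels_[nid] = categorize_multiplex(flags, phases)
        self.mean_effect_ = mean_effect_table(self.tracks_, phases, cfg)
        self.counts_ = count_flags(self.flags_, phases)
        return self

    def label_counts(self) -> pd.Series:
        from neuromux.multiplex import MULTIPLEX_LABELS

        s = pd.Series(self.labels_).value_counts()
        return s.reindex(MULTIPLEX_LABELS, fill_value=0)
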