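"""Domain types and tabular I/O for trial tables and spike trains.

All downstream stages consume :class:`TrialTable` and :class:`SpikeTrainSet`;
no stage re-reads raw files. Trial and spike files are delimiter-separated
text with a header row so that fixtures stay diff-able.

Time convention: seconds, sample onset = 0. Spike trains cover at least
[-0.5, +4.25] s per trial (0.5 s pre-sample baseline, 1 s sample, 3 s delay,
0.25 s margin so the analysis interval stays interior for smoothing).
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("neuromux")

STIM_CLASSES = ("complex", "simple")
VALUES = ("high", "low")
CHOICES = ("left", "right")
OUTCOMES = ("correct", "incorrect")

TRIAL_COLUMNS = [
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
]

SPIKE_COLUMNS = ["neuron_id", "session_id", "trial_index", "spike_time_s"]


class FormatError(ValueError):
    """Malformed file: missing column or unparseable structure."""


class RowError(ValueError):
    """A data row violates a domain invariant; carries the row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"row {row}: {message}")
        self.row = row


class ReferenceError_(KeyError):
    """A spike row references a trial absent from the trial table."""


@dataclass(frozen=True)
class PhaseEpochs:
    """The four 1-s analysis epochs: sample and the three delay seconds.

    Intervals are half-open [start, end) in seconds from sample onset and
    contiguous: sample [0,1), delay1 [1,2), delay2 [2,3), delay3 [3,4).
    """

    sample: tuple[float, float] = (0.0, 1.0)
    delay1: tuple[float, float] = (1.0, 2.0)
    delay2: tuple[float, float] = (2.0, 3.0)
    delay3: tuple[float, float] = (3.0, 4.0)

    @property
    def names(self) -> tuple[str, ...]:
        return ("sample", "delay1", "delay2", "delay3")

    def interval(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def __post_init__(self):
        prev_end = None
        for name in self.names:
            lo, hi = self.interval(name)
            if not np.isclose(hi - lo, 1.0):
                raise ValueError(f"phase {name} must be 1 s long, got {hi - lo}")
            if prev_end is not None and not np.isclose(lo, prev_end):
                raise ValueError("phases must be contiguous and non-overlapping")
            prev_end = hi


@dataclass
class AnalysisConfig:
    """Parameters of the sliding-window ANOVA classification.

    Defaults mirror the analysis conditions: 250 ms windows stepped by
    100 ms starting 500 ms before sample onset, a partial-eta-squared
    threshold of 0.03 that must hold in two consecutive windows, 200
    label permutations for the chance level, and Bonferroni control over
    the 20 phase-by-category tests per stimulus class.
    """

    window_width: float = 0.25
    window_step: float = 0.1
    t_start: float = -0.5
    last_window_start: float = 3.9
    eta_threshold: float = 0.03
    run_length: int = 2
    n_permutations: int = 200
    alpha: float = 0.05
    n_tests_bonferroni: int = 20
    rng_seed: int = 0
    # how sub-threshold windows enter the per-phase mean effect table:
    # "thresholded" zeroes windows outside qualifying runs, "raw" keeps all.
    mean_effect_mode: str = "thresholded"

    def __post_init__(self):
        if self.window_step > self.window_width:
            raise ValueError("window_step must be <= window_width")
        if not (0.0 < self.eta_threshold < 1.0):
            raise ValueError("eta_threshold must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.run_length < 1:
            raise ValueError("run_length must be >= 1")
        if self.mean_effect_mode not in ("thresholded", "raw"):
            raise ValueError("mean_effect_mode must be 'thresholded' or 'raw'")

    @property
    def window_starts(self) -> np.ndarray:
        """Window start times, -0.5 ... 3.9 under defaults (45 windows)."""
        n = int(round((self.last_window_start - self.t_start) / self.window_step)) + 1
        return np.round(self.t_start + self.window_step * np.arange(n), 9)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def with_(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


@dataclass
class TrialTable:
    """One row per trial with the full factorial annotation.

    Wraps a validated :class:`pandas.DataFrame` with columns
    ``session_id, animal_id, trial_index, stimulus_id, stim_class, value,
    choice, outcome, delay_present, rewarded``. Within a session every
    stimulus_id maps consistently onto (stim_class, value) and onto a single
    correct-choice side, and trial_index is unique.
    """

    df: pd.DataFrame

    def __post_init__(self):
        self.df = _validate_trials(self.df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sessions(self) -> list[str]:
        return sorted(self.df["session_id"].unique())

    def session(self, session_id: str) -> "TrialTable":
        sub = self.df[self.df["session_id"] == session_id]
        if sub.empty:
            raise KeyError(f"unknown session {session_id!r}")
        return TrialTable(sub.reset_index(drop=True))

    def correct_only(self) -> "TrialTable":
        """Restrict to correct trials (the default for all neural analyses)."""
        return TrialTable(self.df[self.df["outcome"] == "correct"].reset_index(drop=True))

    def for_class(self, stim_class: str) -> "TrialTable":
        if stim_class not in STIM_CLASSES:
            raise ValueError(f"stim_class must be one of {STIM_CLASSES}")
        return TrialTable(self.df[self.df["stim_class"] == stim_class].reset_index(drop=True))


def _validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {missing}")
    df = df[TRIAL_COLUMNS].copy()
    df["trial_index"] = df["trial_index"].astype(int)
    df["stimulus_id"] = df["stimulus_id"].astype(int)
    for col in ("delay_present", "rewarded"):
        df[col] = _as_bool(df[col], col)

    enums = {"stim_class": STIM_CLASSES, "value": VALUES, "choice": CHOICES, "outcome": OUTCOMES}
    for col, allowed in enums.items():
        bad = ~df[col].isin(allowed)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise RowError(row, f"invalid {col} value {df[col].iloc[row]!r}")

    bad = (df["trial_index"] < 1)
    if bad.any():
        raise RowError(int(np.flatnonzero(bad.to_numpy())[0]), "trial_index must be >= 1")
    bad = ~df["stimulus_id"].between(1, 8)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RowError(row, f"stimulus_id {df['stimulus_id'].iloc[row]} outside 1..8")

    for sid, sub in df.groupby("session_id"):
        if sub["trial_index"].duplicated().any():
            raise RowError(
                int(sub.index[sub["trial_index"].duplicated()][0]),
                f"duplicate trial_index in session {sid!r}",
            )
        # stimulus_id -> (stim_class, value) must be constant within a session
        combos = sub.groupby("stimulus_id")[["stim_class", "value"]].nunique()
        if (combos > 1).any().any():
            raise RowError(
                int(sub.index[0]),
                f"stimulus_id maps to multiple (stim_class, value) combos in session {sid!r}",
            )
        # correct trials define the choice mapping; it must be one-to-one
        corr = sub[sub["outcome"] == "correct"]
        if not corr.empty:
            n_choice = corr.groupby("stimulus_id")["choice"].nunique()
            if (n_choice > 1).any():
                raise RowError(
                    int(sub.index[0]),
                    f"inconsistent stimulus->choice mapping in session {sid!r}",
                )
    return df.reset_index(drop=True)


def _as_bool(col: pd.Series, name: str) -> pd.Series:
    if col.dtype == bool:
        return col
    mapping = {"true": True, "false": False, "1": True, "0": False}
    out = col.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        row = int(np.flatnonzero(out.isna().to_numpy())[0])
        raise RowError(row, f"invalid boolean in column {name}")
    return out.astype(bool)


@dataclass
class SpikeTrainSet:
    """Per-neuron, per-trial spike times aligned to sample onset.

    ``trains[neuron_id][trial_index]`` is a sorted float array of spike times
    in seconds. ``neuron_sessions`` maps each neuron to the session whose
    trials its keys reference. Missing (neuron, trial) entries are empty
    trains; :meth:`spike_times` returns an empty array for them.
    """

    trains: dict[str, dict[int, np.ndarray]]
    neuron_sessions: dict[str, str]

    @property
    def neuron_ids(self) -> list[str]:
        return sorted(self.trains)

    def spike_times(self, neuron_id: str, trial_index: int) -> np.ndarray:
        return self.trains.get(neuron_id, {}).get(trial_index, np.empty(0))

    def n_spikes(self, neuron_id: str | None = None) -> int:
        neurons = [neuron_id] if neuron_id is not None else self.neuron_ids
        return int(sum(len(t) for n in neurons for t in self.trains.get(n, {}).values()))

    def validate_against(self, trials: TrialTable) -> None:
        for nid, session in self.neuron_sessions.items():
            known = set(trials.session(session).df["trial_index"])
            extra = set(self.trains.get(nid, {})) - known
            if extra:
                raise ReferenceError_(
                    f"neuron {nid!r} references unknown trial(s) {sorted(extra)[:5]} "
                    f"in session {session!r}"
                )
        for nid, per_trial in self.trains.items():
            for ti, t in per_trial.items():
                if not np.all(np.isfinite(t)):
                    raise ValueError(f"non-finite spike time for neuron {nid!r} trial {ti}")


def read_trials(path: str | Path, sep: str = ",") -> TrialTable:
    """Read a trial table from delimited text with a header row."""
    df = pd.read_csv(path, sep=sep)
    return TrialTable(df)


def write_trials(trials: TrialTable, path: str | Path, sep: str = ",") -> None:
    trials.df.to_csv(path, sep=sep, index=False)


def read_spikes(path: str | Path, trials: TrialTable, sep: str = ",") -> SpikeTrainSet:
    """Read spike trains (columns neuron_id, session_id, trial_index, spike_time_s).

    Spike times are sorted within each trial; out-of-order input is accepted
    with a logged warning. Rows referencing a trial absent from ``trials``
    raise a reference error.
    """
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"spike file missing column(s): {missing}")
    trains: dict[str, dict[int, np.ndarray]] = {}
    sessions: dict[str, str] = {}
    for (nid, session), sub in df.groupby(["neuron_id", "session_id"]):
        nid = str(nid)
        if nid in sessions and sessions[nid] != session:
            raise RowError(int(sub.index[0]), f"neuron {nid!r} appears in multiple sessions")
        sessions[nid] = str(session)
        per_trial: dict[int, np.ndarray] = {}
        for ti, tsub in sub.groupby("trial_index"):
            t = tsub["spike_time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) < 0):
                logger.warning(
                    "spike times out of order for neuron %s trial %s; sorting", nid, ti
                )
                t = np.sort(t)
            per_trial[int(ti)] = t
        trains[nid] = per_trial
    out = SpikeTrainSet(trains, sessions)
    out.validate_against(trials)
    return out


def write_spikes(spikes: SpikeTrainSet, path: str | Path, sep: str = ",") -> None:
    rows = []
    for nid in spikes.neuron_ids:
        session = spikes.neuron_sessions[nid]
        for ti in sorted(spikes.trains[nid]):
            for t in spikes.trains[nid][ti]:
                rows.append((nid, session, ti, t))
    df = pd.DataFrame(rows, columns=SPIKE_COLUMNS)
    df.to_csv(path, sep=sep, index=False, float_format="%.9f")


@contextmanager
def stage_timer(stage: str) -> Iterator[None]:
    """Log wall-clock duration of a pipeline stage to the package logger."""
    t0 = time.perf_counter()
    logger.info("stage %s: start", stage)
    try:
        yield
    finally:
        logger.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
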