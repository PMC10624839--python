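"""Session-level behavioral summaries.

Percent correct per session broken down by stimulus class and delay
condition, the >= 70%-correct session inclusion filter (sessions below it do
not reflect learned behavior), and the delta-performance statistic: the
percentage-point drop from the non-delayed to the delayed condition per
stimulus class — the behavioral signature that a delay costs more for simple
(single-luminance) than for complex stimuli.

The linear mixed-model fit of these summaries (fixed effects delay x class,
random animal) is standard statistical-package territory; this module emits
the tidy per-session table such a fit consumes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from neuromux.io import TrialTable


def summarize_sessions(trials: TrialTable) -> pd.DataFrame:
    """Per session x stim_class x delay condition: n_trials, n_correct, percent.

    Empty cells are absent from the output (rather than reported as 0%).
    Also includes the per-session overall percent correct in the
    ``percent_correct_overall`` column (repeated across the session's rows).
    """
    df = trials.df
    grp = df.groupby(["session_id", "animal_id", "stim_class", "delay_present"])
    out = grp.agg(
        n_trials=("outcome", "size"),
        n_correct=("outcome", lambda s: int((s == "correct").sum())),
    ).reset_index()
    out["percent_correct"] = 100.0 * out["n_correct"] / out["n_trials"]

    overall = (
        df.groupby("session_id")["outcome"]
        .apply(lambda s: 100.0 * (s == "correct").mean())
        .rename("percent_correct_overall")
    )
    return out.merge(overall, on="session_id")


def filter_sessions(summaries: pd.DataFrame, min_percent: float = 70.0) -> list[str]:
    """Session ids whose overall percent correct is >= min_percent (boundary
    inclusive)."""
    if summaries.empty:
        return []
    overall = summaries.groupby("session_id")["percent_correct_overall"].first()
    return sorted(overall.index[overall >= min_percent])


def delta_performance(summaries: pd.DataFrame) -> pd.Series:
    """Per-class performance drop, in percentage points, non-delayed minus delayed.

    Percentages are aggregated trial-weighted across sessions within each
    (class, delay) condition. Raises if either condition is missing for a
    class present in the data.
    """
    agg = summaries.groupby(["stim_class", "delay_present"])[["n_trials", "n_correct"]].sum()
    pct = 100.0 * agg["n_correct"] / agg["n_trials"]
    out = {}
    for cls in summaries["stim_class"].unique():
        try:
            no_delay = pct.loc[(cls, False)]
            delay = pct.loc[(cls, True)]
        except KeyError as err:
            raise ValueError(f"missing delay condition for class {cls!r}") from err
        out[cls] = float(no_delay - delay)
    return pd.Series(out, name="delta_percent")
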