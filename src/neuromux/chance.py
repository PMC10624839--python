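"""Permutation chance levels and Fisher's-exact enrichment tests.

The chance level for each coding category is estimated by re-running the full
classification pipeline on label-shuffled data: per neuron and permutation,
the (value, choice) label *pair* is permuted jointly across trials (one
shuffle applied to all 45 windows), destroying any rate-label association
while preserving the cell sizes of the 2x2 design. 200 permutations are run
by default. Because shuffled data almost never show the full three-effect
stimulus signature, the stimulus category uses the relaxed rule here (any two
of choice/value/interaction above threshold in the same two consecutive
windows). Mean per-category counts over permutations are rounded up (ceil)
to integers, and observed vs chance counts are compared with a one-sided
Fisher's exact test under Bonferroni control (alpha / 20 = 0.0025 for the
4 phases x 5 columns tested per stimulus class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from neuromux.io import AnalysisConfig, PhaseEpochs, SpikeTrainSet, TrialTable
from neuromux.coding import (
    CATEGORIES,
    NeuronPhaseFlags,
    _anova22,
    bin_counts,
    cell_index,
    classify_phase,
    count_flags,
    EffectSizeTrack,
)

COUNT_COLUMNS = tuple(CATEGORIES) + ("cell_total",)


@dataclass
class ChanceTable:
    """Chance-level classification counts per phase x category.

    ``per_permutation`` has shape (n_permutations, 4 phases, 5 columns);
    ``mean`` is its average over permutations and ``ceiled`` the integer
    chance count fed into Fisher's exact test (means rounded up).
    """

    phases: tuple[str, ...]
    columns: tuple[str, ...]
    per_permutation: np.ndarray
    n_neurons: int

    @property
    def mean(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_permutation.mean(axis=0), index=list(self.phases), columns=list(self.columns)
        )

    @property
    def ceiled(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.ceil(self.per_permutation.mean(axis=0)).astype(int),
            index=list(self.phases),
            columns=list(self.columns),
        )


def permute_labels(trials: TrialTable, rng: np.random.Generator) -> TrialTable:
    """Jointly shuffle the (value, choice) label pair across trials.

    The returned table bypasses the stimulus->condition consistency checks
    (shuffling intentionally breaks that yoking); the multiset of label pairs
    is preserved exactly.
    """
    df = trials.df.copy()
    perm = rng.permutation(len(df))
    df[["value", "choice"]] = df[["value", "choice"]].to_numpy()[perm]
    out = object.__new__(TrialTable)
    out.df = df
    return out


def _permuted_flags(
    counts: np.ndarray,
    cells: np.ndarray,
    window_starts: np.ndarray,
    cfg: AnalysisConfig,
    phases: PhaseEpochs,
    rng: np.random.Generator,
    n_permutations: int,
) -> list[NeuronPhaseFlags]:
    """Classification flags of one neuron under label permutations.

    Spike counts stay fixed; only the trial-to-cell assignment is shuffled
    once per permutation. Uses the relaxed stimulus rule.
    """
    out = []
    for _ in range(n_permutations):
        shuffled = cells[rng.permutation(len(cells))]
        _, _, eta, p, valid = _anova22(counts, shuffled)
        track = EffectSizeTrack(
            window_starts=window_starts,
            eta=eta,
            p=p,
            n_trials=counts.shape[0],
            valid=np.full(counts.shape[1], valid),
        )
        out.append(classify_phase(track, phases, cfg, stimulus_rule="relaxed"))
    return out


def chance_counts(
    trials: TrialTable,
    spikes: SpikeTrainSet,
    stim_class: str,
    cfg: AnalysisConfig | None = None,
    neuron_ids=None,
    seed: int | None = None,
    correct_only: bool = True,
) -> ChanceTable:
    """Chance-level category counts from label permutations of all neurons.

    Permutations are drawn independently per neuron from a single seeded
    generator, so the whole table is deterministic in (data, seed,
    n_permutations).
    """
    cfg = cfg or AnalysisConfig()
    phases = PhaseEpochs()
    rng = np.random.default_rng(cfg.rng_seed if seed is None else seed)
    neuron_ids = list(neuron_ids) if neuron_ids is not None else spikes.neuron_ids

    n_perm = cfg.n_permutations
    tally = np.zeros((n_perm, len(phases.names), len(COUNT_COLUMNS)))
    for nid in neuron_ids:
        bc = bin_counts(spikes, nid, trials, cfg, stim_class=stim_class,
                        correct_only=correct_only)
        cells = cell_index(bc.value_labels, bc.choice_labels)
        flags_per_perm = _permuted_flags(
            bc.counts, cells, bc.window_starts, cfg, phases, rng, n_perm
        )
        for k, flags in enumerate(flags_per_perm):
            for i, ph in enumerate(phases.names):
                for j, cat in enumerate(CATEGORIES):
                    tally[k, i, j] += flags[ph][cat]
                tally[k, i, -1] += flags.any_flag(ph)
    return ChanceTable(
        phases=tuple(phases.names),
        columns=COUNT_COLUMNS,
        per_permutation=tally,
        n_neurons=len(neuron_ids),
    )


def fisher_vs_chance(observed: int, chance: int, n_neurons: int) -> float:
    """One-sided Fisher's exact p for enrichment of observed over chance.

    Tests the 2x2 table [[observed, n - observed], [chance, n - chance]]
    with alternative 'observed proportion greater'.
    """
    if not (0 <= observed <= n_neurons and 0 <= chance <= n_neurons):
        raise ValueError("counts must lie in [0, n_neurons]")
    table = [[observed, n_neurons - observed], [chance, n_neurons - chance]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def enrichment_table(
    observed: pd.DataFrame, chance: ChanceTable, alpha: float = 0.05, m: int = 20
) -> pd.DataFrame:
    """Observed vs chance counts with Fisher p per phase x column.

    ``observed`` is the output of :func:`neuromux.coding.count_flags`.
    Returns a long-format frame with columns phase, category, observed,
    chance, p, significant (p < alpha/m).
    """
    thr = bonferroni_threshold(alpha, m)
    ceiled = chance.ceiled
    rows = []
    for ph in chance.phases:
        for col in chance.columns:
            obs = int(observed.loc[ph, col])
            ch = int(ceiled.loc[ph, col])
            p = fisher_vs_chance(obs, ch, chance.n_neurons)
            rows.append((ph, col, obs, ch, p, p < thr))
    return pd.DataFrame(
        rows, columns=["phase", "category", "observed", "chance", "p", "significant"]
    )
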