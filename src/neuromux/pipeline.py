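"""End-to-end orchestration: simulate -> classify -> chance -> multiplex -> report.

A single config (YAML mapping or dict) drives every stage; one global seed
fans out deterministically to per-stage child seeds via
:class:`numpy.random.SeedSequence`, so each stage is individually
reproducible and the final report is byte-identical across runs with the
same config.

Report sections: config echo, behavioral summary and per-class delta
performance, per-class phase-by-category count matrix (observed vs ceiling
chance counts with one-sided Fisher p under Bonferroni), multiplexing label
counts with complex-vs-simple chi-square contrasts, trace-decay t-tests, and
the Gabor median feature density per stimulus image.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from neuromux.behavior import delta_performance, filter_sessions, summarize_sessions
from neuromux.chance import chance_counts, enrichment_table
from neuromux.coding import CodingClassifier
from neuromux.gabor import GaborFeatureExtractor
from neuromux.io import STIM_CLASSES, AnalysisConfig, stage_timer, write_spikes, write_trials
from neuromux.multiplex import MULTIPLEX_LABELS, chi2_2x2, trace_decay_test
from neuromux.synth import SessionSpec, default_population, generate_session, generate_stimulus_images

#: measured percent-correct rates in the task, expressed as error rates;
#: used as the simulation defaults for the two delay conditions.
ERROR_RATES_DELAYED = {"complex": 0.083, "simple": 0.168}
ERROR_RATES_NON_DELAYED = {"complex": 0.076, "simple": 0.088}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "session": {
        "n_trials_per_stimulus": 80,
        "n_neurons": 104,
        "effect_gain": 8.0,
        "decay_tau_early": 1.5,
    },
    "images": {"width": 128, "height": 128},
    "analysis": {},
    "output_dir": None,
}


def _child_seeds(seed: int, n: int) -> list[int]:
    """n deterministic child seeds (< 2**31) from one root seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def load_config(source) -> dict:
    """Merge a YAML path / mapping over the defaults."""
    if source is None:
        user = {}
    elif isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def run_pipeline(config=None) -> dict:
    """Execute all stages from one config; returns the JSON-able report."""
    cfg = load_config(config)
    seed = int(cfg["seed"])
    s_delay, s_nodelay, s_images, s_chance_cx, s_chance_sp, s_pop = _child_seeds(seed, 6)
    acfg = AnalysisConfig(**cfg["analysis"])
    out_dir = Path(cfg["output_dir"]) if cfg["output_dir"] else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    report: dict = {"config": {**cfg, "output_dir": str(out_dir) if out_dir else None}}

    with stage_timer("simulate"):
        sess = cfg["session"]
        profiles = default_population(
            n_neurons=int(sess["n_neurons"]),
            seed=s_pop,
            effect_gain=float(sess["effect_gain"]),
            decay_tau_early=sess.get("decay_tau_early"),
        )
        spec = SessionSpec(
            session_id="sim_delay",
            n_trials_per_stimulus=int(sess["n_trials_per_stimulus"]),
            neurons=profiles,
            delay_present=True,
            error_rate=dict(ERROR_RATES_DELAYED),
        )
        trials, spikes = generate_session(spec, s_delay)
        # a purely behavioral non-delayed session for the delta statistic
        spec_nd = SessionSpec(
            session_id="sim_nodelay",
            n_trials_per_stimulus=int(sess["n_trials_per_stimulus"]),
            neurons=[],
            delay_present=False,
            error_rate=dict(ERROR_RATES_NON_DELAYED),
        )
        trials_nd, _ = generate_session(spec_nd, s_nodelay)
        if out_dir:
            write_trials(trials, out_dir / "trials_delayed.csv")
            write_trials(trials_nd, out_dir / "trials_non_delayed.csv")
            write_spikes(spikes, out_dir / "spikes.csv")

    with stage_timer("behavior"):
        from neuromux.io import TrialTable

        both = TrialTable(pd.concat([trials.df, trials_nd.df], ignore_index=True))
        summaries = summarize_sessions(both)
        included = filter_sessions(summaries)
        delta = delta_performance(summaries)
        report["behavior"] = {
            "sessions_included": included,
            "percent_correct": {
                f"{r.stim_class}_{'delay' if r.delay_present else 'no_delay'}": round(
                    float(r.percent_correct), 2
                )
                for r in summaries.itertuples()
            },
            "delta_performance": {k: round(float(v), 2) for k, v in delta.items()},
        }
        if out_dir:
            summaries.to_csv(out_dir / "behavior_summary.csv", index=False)

    classifiers: dict[str, CodingClassifier] = {}
    report["classification"] = {}
    for stim_class, chance_seed in zip(STIM_CLASSES, (s_chance_cx, s_chance_sp)):
        with stage_timer(f"classify_{stim_class}"):
            clf = CodingClassifier(stim_class=stim_class, config=acfg).fit(trials, spikes)
            classifiers[stim_class] = clf
        with stage_timer(f"chance_{stim_class}"):
            chance = chance_counts(trials, spikes, stim_class, acfg, seed=chance_seed)
            enrich = enrichment_table(clf.counts_, chance, acfg.alpha, acfg.n_tests_bonferroni)
        report["classification"][stim_class] = {
            "observed": clf.counts_.to_dict(),
            "chance_ceiled": chance.ceiled.to_dict(),
            "fisher": [
                {
                    "phase": r.phase,
                    "category": r.category,
                    "observed": int(r.observed),
                    "chance": int(r.chance),
                    "p": float(r.p),
                    "significant": bool(r.significant),
                }
                for r in enrich.itertuples()
            ],
            "multiplex_labels": {k: int(v) for k, v in clf.label_counts().items()},
        }
        if out_dir:
            enrich.to_csv(out_dir / f"enrichment_{stim_class}.csv", index=False)
            clf.mean_effect_.to_csv(out_dir / f"mean_effect_{stim_class}.csv", index=False)

    with stage_timer("multiplex_contrasts"):
        n = int(cfg["session"]["n_neurons"])
        contrasts = {}
        for label in MULTIPLEX_LABELS[:-1]:
            a = int(classifiers["complex"].label_counts()[label])
            b = int(classifiers["simple"].label_counts()[label])
            try:
                chi2, p = chi2_2x2(a, b, n, n)
                contrasts[label] = {"complex": a, "simple": b, "chi2": round(chi2, 4), "p": p}
            except ZeroDivisionError:
                contrasts[label] = {"complex": a, "simple": b, "chi2": None, "p": None}
        report["multiplex_contrasts"] = contrasts

        decay = {}
        for stim_class, label in (("simple", "early_choice"), ("complex", "stimulus_choice")):
            clf = classifiers[stim_class]
            ids = [nid for nid, lab in clf.labels_.items() if lab == label]
            if len(ids) >= 2:
                t, df, p = trace_decay_test({i: clf.tracks_[i] for i in ids})
                decay[f"{label}_{stim_class}"] = {
                    "t": round(t, 4), "df": df, "p": p, "n_neurons": len(ids)
                }
        report["trace_decay"] = decay

    with stage_timer("complexity"):
        imgs = generate_stimulus_images(
            int(cfg["images"]["width"]), int(cfg["images"]["height"]), s_images
        )
        extractor = GaborFeatureExtractor().fit()
        medians = {
            sid: float(np.median(extractor.transform([imgs.luminance(sid)])[0]))
            for sid in sorted(imgs.images)
        }
        report["complexity"] = {
            "median_feature_density": {str(k): v for k, v in medians.items()},
            "complex_exceed_simple": bool(
                min(medians[i] for i in (1, 2, 3, 4)) > max(medians[i] for i in (5, 6, 7, 8))
            ),
        }
        if out_dir:
            imgs.save_pngs(out_dir / "stimuli")

    if out_dir:
        with open(out_dir / "report.json", "w") as fh:
            fh.write(report_json(report))
    return report


def report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON encoding of a report."""
    return json.dumps(report, sort_keys=True, indent=2)
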