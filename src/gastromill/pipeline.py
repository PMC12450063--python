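"""End-to-end orchestration: simulate/load -> detect -> metrics -> features
-> classify -> phase -> stats, with deterministic seeds and a run manifest.

`run_all` takes either a directory of spike CSV + manifest pairs or a
simulation request, executes every stage, and writes the full set of
result tables (`features.csv`, `classification.csv`, `cycles.csv`,
`gm_cycles.csv`, `summary.csv`, `phase_profile.csv`, `transitions.csv`,
`odds_ratios.csv`) plus `stats.json` and a `manifest.json` recording the
configuration and seed, so a rerun reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .core import AnalysisConfig, Recording, read_recording, segment_windows, write_results
from .cycles import analyze_incubation, summarize_incubation
from .features import (FEATURE_NAMES, featurize_segment, fit_cluster_model,
                       segment_categories, transition_table)
from .phase import profile_condition
from .stats import chi_square_distribution_test, odds_ratio_table
from .synth import RhythmSpec, generate_condition_batch

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    seed: int
    config: dict
    inputs: list[str]
    stages: dict[str, bool] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def load_input_dir(input_dir) -> list[Recording]:
    """Read every ``<name>.csv`` + ``<name>.manifest.yaml`` pair in a directory."""
    input_dir = Path(input_dir)
    recs = []
    for csv_path in sorted(input_dir.glob("*.csv")):
        manifest = csv_path.with_suffix("").with_suffix(".manifest.yaml")
        if not manifest.exists():
            manifest = csv_path.with_name(csv_path.stem + ".manifest.json")
        if manifest.exists():
            recs.append(read_recording(csv_path, manifest))
        else:
            logger.warning("no manifest for %s; skipped", csv_path.name)
    return recs


def run_all(out_dir, recordings: Sequence[Recording] | None = None,
            simulate: Mapping[str, float] | str | None = None,
            n_subjects: int = 12, seed: int = 0,
            cfg: AnalysisConfig | None = None) -> RunManifest:
    """Execute the full analysis and write every interface file.

    Either pass ``recordings`` or a ``simulate`` request (a rhythm state
    name, or a state -> proportion mix) that generates ``n_subjects``
    synthetic incubations.
    """
    cfg = cfg or AnalysisConfig(rng_seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(seed=seed, config=dataclasses.asdict(cfg), inputs=[])

    if recordings is None:
        if simulate is None:
            raise ValueError("provide recordings or a simulation request")
        mix = {simulate: 1.0} if isinstance(simulate, str) else dict(simulate)
        batch = generate_condition_batch(n_subjects, mix, seed=seed)
        recordings = [rec for rec, _ in batch]
        manifest.inputs = [f"simulated:{rec.subject_id}" for rec in recordings]
    else:
        manifest.inputs = [rec.subject_id for rec in recordings]
    manifest.stages["load"] = True

    # --- per-incubation metrics, features, rule-based labels -------------
    feature_rows, class_rows, summaries = [], [], []
    cycle_rows, gm_rows, label_seqs = [], [], {}
    vectors, counts, cvs = [], [], []
    for rec in recordings:
        ana = analyze_incubation(rec, cfg)
        summaries.append(summarize_incubation(rec, cfg, analysis=ana).as_row())
        rules = segment_categories(rec, cfg, analysis=ana)
        label_seqs.setdefault(rec.condition, []).append(rules)
        for c in ana.pyloric_cycles:
            cycle_rows.append({"subject_id": rec.subject_id,
                               "condition": rec.condition, **c.__dict__})
        for c in ana.gastric_cycles:
            gm_rows.append({"subject_id": rec.subject_id,
                            "condition": rec.condition, "onset": c.onset,
                            "period": c.period,
                            "has_prepeak": c.prepeak is not None})
        for w, rule in zip(segment_windows(rec, cfg), rules):
            vec = featurize_segment(rec, w, cfg, analysis=ana)
            vectors.append(vec)
            in_w = [b for b in ana.long_ic_bursts if w.contains(b.onset)]
            counts.append(len(in_w))
            periods = [c.period for c in ana.gastric_cycles if w.contains(c.onset)]
            cvs.append(float(np.std(periods) / np.mean(periods))
                       if len(periods) >= 2 else np.nan)
            feature_rows.append({"subject_id": rec.subject_id,
                                 "condition": rec.condition,
                                 "segment": w.index,
                                 **dict(zip(FEATURE_NAMES, vec))})
            class_rows.append({"subject_id": rec.subject_id,
                               "condition": rec.condition, "segment": w.index,
                               "rule_category": rule})
    manifest.stages["metrics"] = manifest.stages["features"] = True

    # --- clustering -------------------------------------------------------
    X = np.asarray(vectors)
    model = fit_cluster_model(X, cfg, long_burst_counts=counts, period_cvs=cvs)
    clusters = model.predict(X)
    mapped = model.categorize(X)
    for row, cl, cat in zip(class_rows, clusters, mapped):
        row["cluster"] = int(cl)
        row["category"] = cat
    model.to_json(out_dir / "cluster_model.json")
    manifest.stages["classify"] = True

    # --- transitions & condition statistics -------------------------------
    stats_summary: dict = {"n_recordings": len(recordings)}
    trans_rows = []
    condition_counts = {}
    for condition, seqs in label_seqs.items():
        ts = transition_table(seqs)
        for a in ts.counts.index:
            for b in ts.counts.columns:
                trans_rows.append({"condition": condition, "from": a, "to": b,
                                   "count": int(ts.counts.loc[a, b])})
        flat = [lab for seq in seqs for lab in seq]
        condition_counts[condition] = {
            "gmr": sum(1 for x in flat if x == "GMR"),
            "non_gmr": sum(1 for x in flat if x != "GMR"),
            "irregular": sum(1 for x in flat if x == "IRREGULAR"),
            "none": sum(1 for x in flat if x == "NONE"),
        }
        stats_summary[f"persistence_{condition}"] = {
            "n_with_gmr": ts.n_with_gmr,
            "n_persistent_gmr": ts.n_persistent_gmr,
        }
    stats_summary["segment_counts"] = condition_counts

    odds_df = pd.DataFrame()
    if len(condition_counts) >= 2:
        counts_df = pd.DataFrame.from_dict(condition_counts, orient="index")
        try:
            odds_df = odds_ratio_table(counts_df[["gmr", "non_gmr"]])
        except ZeroDivisionError:
            logger.warning("zero cell in odds table; odds ratios omitted")
        dist = counts_df[["gmr", "irregular", "none"]].to_numpy().T
        if (dist.sum(axis=0) > 0).all() and dist.shape[1] >= 2:
            nonzero = dist[dist.sum(axis=1) > 0]
            if nonzero.shape[0] >= 2:
                chi = chi_square_distribution_test(nonzero)
                stats_summary["distribution_test"] = {
                    "chi2": chi.statistic, "p": chi.p_value,
                    "cramers_v": chi.effect.value, "band": chi.effect.band,
                }
    manifest.stages["stats"] = True

    # --- phase profiles ----------------------------------------------------
    phase_rows = []
    by_condition: dict[str, list[Recording]] = {}
    for rec in recordings:
        by_condition.setdefault(rec.condition, []).append(rec)
    for condition, recs in by_condition.items():
        try:
            profiles, _ = profile_condition(recs, cfg, condition=condition)
        except ValueError:
            logger.warning("condition %s has no rhythm segments; "
                           "phase profile skipped", condition)
            continue
        for neuron, prof in profiles.items():
            for b in range(cfg.phase_bins):
                phase_rows.append({"condition": condition, "neuron": neuron,
                                   "bin": b, "mean": prof.bins[b],
                                   "se": prof.se[b],
                                   "n": prof.n_experiments})
    manifest.stages["phase"] = True

    tables = {
        "features": pd.DataFrame(feature_rows),
        "classification": pd.DataFrame(class_rows),
        "summary": pd.DataFrame(summaries),
        "cycles": pd.DataFrame(cycle_rows),
        "gm_cycles": pd.DataFrame(gm_rows),
        "transitions": pd.DataFrame(trans_rows),
        "odds_ratios": odds_df,
        "phase_profile": pd.DataFrame(phase_rows),
    }
    paths = write_results(tables, out_dir, summary=stats_summary)
    manifest.outputs = [str(p.name) for p in paths]
    manifest.write(out_dir / "manifest.json")
    return manifest


REQUIRED_OUTPUTS = ("classification.csv", "summary.csv", "summary.json",
                    "manifest.json")


def report(out_dir) -> str:
    """Human-readable markdown summary of a completed run."""
    out_dir = Path(out_dir)
    missing = [n for n in REQUIRED_OUTPUTS if not (out_dir / n).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run in {out_dir}: missing {missing}")
    with open(out_dir / "summary.json", encoding="utf-8") as fh:
        summary = json.load(fh)
    cls = pd.read_csv(out_dir / "classification.csv")

    lines = ["# Rhythm analysis report", ""]
    lines.append(f"Recordings analysed: {summary.get('n_recordings', '?')}")
    lines.append("")
    lines.append("## Segment category distribution")
    dist = (cls.groupby(["condition", "category"]).size()
            .unstack(fill_value=0)) if "category" in cls else pd.DataFrame()
    lines.append(dist.to_markdown() if not dist.empty else "(no categories)")
    lines.append("")
    odds = _read_csv_or_empty(out_dir / "odds_ratios.csv")
    if not odds.empty:
        lines.append("## Odds ratios of rhythm occurrence")
        lines.append(odds.round(3).to_markdown(index=False))
    else:
        lines.append("## Odds ratios")
        lines.append("(single condition: odds-ratio section omitted)")
    lines.append("")
    trans = _read_csv_or_empty(out_dir / "transitions.csv")
    if not trans.empty:
        lines.append("## Segment transitions")
        lines.append(trans[trans["count"] > 0].to_markdown(index=False))
    return "\n".join(lines) + "\n"


def _read_csv_or_empty(path: Path) -> pd.DataFrame:
    if not path.exists():
        return pd.DataFrame()
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
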