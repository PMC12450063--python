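"""100-bin phase profiles of firing across the gastric mill cycle.

Each gastric mill cycle (consecutive cycle-defining long IC burst onsets,
after prepeak reattachment) is divided into 100 bins; bin 0 starts at the
IC burst onset.  Spike counts per bin are averaged over all cycles starting
in each 200-s segment and normalised by the segment's average bin duration
(mean cycle period / 100), making the profile approximately a firing rate
across the cycle.  Only segments classified as gastric mill rhythms enter
the analysis.  Profiles are then averaged within an experiment over its
rhythm segments, and within a condition over experiments (mean +/- SE).

Cross-condition comparison uses the heuristic family-wise control of the
source analysis instead of a Bonferroni-style correction: a bin is flagged
for a condition only when (1) a bootstrap confidence interval on the
difference of experiment-level group means excludes zero at alpha = 0.01
against *both* other conditions, and (2) the flag persists over at least
two consecutive bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnalysisConfig, Recording, ValidationError, segment_windows
from .cycles import GastricCycle, IncubationAnalysis, analyze_incubation, duty_cycle
from .features import segment_categories

logger = logging.getLogger(__name__)

PROFILE_NEURONS = ("IC", "PD", "LPG", "LG", "DG", "AM")


@dataclass
class PhaseProfile:
    """Mean normalised spikes-per-bin across a condition's experiments."""

    neuron: str
    condition: str
    bins: np.ndarray       # (phase_bins,) mean across experiments
    se: np.ndarray         # (phase_bins,) SE across experiments (NaN if n < 2)
    n_experiments: int


def bin_cycle(spike_times: np.ndarray, cycle: GastricCycle,
              n_bins: int = 100) -> np.ndarray:
    """Integer spike counts per phase bin for one cycle.

    A spike at phase ``phi`` in [0, 1) lands in bin ``floor(n_bins * phi)``;
    the counts sum to the number of in-cycle spikes.
    """
    if cycle.period <= 0:
        raise ValidationError("cycle period must be positive")
    times = np.asarray(spike_times, dtype=float)
    sel = (times >= cycle.onset) & (times < cycle.stop)
    phases = (times[sel] - cycle.onset) / cycle.period
    idx = np.minimum((n_bins * phases).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def _segment_profile(rec: Recording, cycles: list[GastricCycle],
                     n_bins: int) -> dict[str, np.ndarray]:
    """Mean counts/bin over a segment's cycles, divided by avg bin duration."""
    mean_period = float(np.mean([c.period for c in cycles]))
    bin_duration = mean_period / n_bins
    out = {}
    for neuron in PROFILE_NEURONS:
        train = rec.trains.get(neuron)
        if train is None:
            continue
        counts = np.stack([bin_cycle(train.times, c, n_bins) for c in cycles])
        out[neuron] = counts.mean(axis=0) / bin_duration
    return out


def experiment_profiles(rec: Recording, cfg: AnalysisConfig | None = None,
                        labels: Sequence[str] | None = None,
                        analysis: IncubationAnalysis | None = None
                        ) -> dict[str, np.ndarray] | None:
    """One experiment's per-neuron profile, averaged over its GMR segments.

    ``labels`` are the per-segment rhythm categories (rule-based by
    default).  Returns ``None`` when the experiment has no gastric mill
    rhythm segment with at least one cycle.
    """
    cfg = cfg or AnalysisConfig()
    ana = analysis or analyze_incubation(rec, cfg)
    if labels is None:
        labels = segment_categories(rec, cfg, analysis=ana)
    per_segment: list[dict[str, np.ndarray]] = []
    for w, lab in zip(segment_windows(rec, cfg), labels):
        if lab != "GMR":
            continue
        cycles = [c for c in ana.gastric_cycles if w.contains(c.onset)]
        if not cycles:
            continue
        per_segment.append(_segment_profile(rec, cycles, cfg.phase_bins))
    if not per_segment:
        return None
    neurons = set().union(*(p.keys() for p in per_segment))
    return {n: np.mean([p[n] for p in per_segment if n in p], axis=0)
            for n in neurons}


def profile_condition(recordings: Sequence[Recording],
                      cfg: AnalysisConfig | None = None,
                      condition: str | None = None,
                      labels_per_recording: Sequence[Sequence[str]] | None = None,
                      ) -> tuple[dict[str, PhaseProfile], dict[str, np.ndarray]]:
    """Condition-level phase profiles (mean +/- SE over experiments).

    Returns ``(profiles, per_experiment)`` where ``per_experiment`` maps
    neuron -> array of shape (n_experiments, phase_bins), the inputs for
    cross-condition bin comparisons.  Raises when no experiment contributes
    a gastric-mill-rhythm segment.
    """
    cfg = cfg or AnalysisConfig()
    condition = condition or (recordings[0].condition if recordings else "?")
    rows: dict[str, list[np.ndarray]] = {n: [] for n in PROFILE_NEURONS}
    n_exp = 0
    for i, rec in enumerate(recordings):
        labels = None if labels_per_recording is None else labels_per_recording[i]
        prof = experiment_profiles(rec, cfg, labels=labels)
        if prof is None:
            continue
        n_exp += 1
        for neuron, values in prof.items():
            rows[neuron].append(values)
    if n_exp == 0:
        raise ValidationError(
            f"condition {condition!r} has no gastric mill rhythm segments")
    profiles, per_experiment = {}, {}
    for neuron, values in rows.items():
        if not values:
            continue
        arr = np.stack(values)
        per_experiment[neuron] = arr
        se = (arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
              if arr.shape[0] >= 2 else np.full(arr.shape[1], np.nan))
        profiles[neuron] = PhaseProfile(neuron, condition, arr.mean(axis=0),
                                        se, arr.shape[0])
    return profiles, per_experiment


# ---------------------------------------------------------------------------
# Cross-condition comparison

def _basic_ci_bins(a: np.ndarray, b: np.ndarray, level: float,
                   n_iter: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Basic (reverse-percentile) bootstrap CI per bin on mean(a) - mean(b).

    ``a``/``b`` are (n_experiments, bins).  One set of resample indices is
    shared across bins, preserving the across-bin correlation structure.
    """
    est = a.mean(axis=0) - b.mean(axis=0)
    ia = rng.integers(0, a.shape[0], size=(n_iter, a.shape[0]))
    ib = rng.integers(0, b.shape[0], size=(n_iter, b.shape[0]))
    boot = a[ia].mean(axis=1) - b[ib].mean(axis=1)     # (n_iter, bins)
    alpha = 1.0 - level
    q_lo, q_hi = np.quantile(boot, [alpha / 2, 1 - alpha / 2], axis=0)
    return 2 * est - q_hi, 2 * est - q_lo


def _runs_of_true(flags: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    runs, start = [], None
    for i, f in enumerate(flags):
        if f and start is None:
            start = i
        elif not f and start is not None:
            if i - start >= min_len:
                runs.append((start, i))
            start = None
    if start is not None and len(flags) - start >= min_len:
        runs.append((start, len(flags)))
    return runs


def compare_conditions(per_experiment: Mapping[str, Mapping[str, np.ndarray]],
                       cfg: AnalysisConfig | None = None,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Flag phase bins where one condition differs from both others.

    ``per_experiment`` maps condition -> neuron -> (n_experiments, bins)
    array of experiment-level profiles.  For each (neuron, bin, condition),
    a basic bootstrap CI at confidence ``1 - alpha_phase`` is built on the
    difference of group means against each other condition; the bin is
    flagged only if both CIs exclude zero, and flags are filtered to runs
    of at least ``min_consecutive_bins``.  Returns a table with columns
    ``neuron, condition, bin, run_id``.
    """
    cfg = cfg or AnalysisConfig()
    rng = rng or np.random.default_rng(cfg.rng_seed)
    conditions = list(per_experiment)
    if len(conditions) != 3:
        raise ValidationError("the comparison heuristic needs exactly three "
                              f"conditions, got {len(conditions)}")
    for cond, by_neuron in per_experiment.items():
        for neuron, arr in by_neuron.items():
            if arr.shape[0] < 2:
                raise ValidationError(
                    f"condition {cond!r} has fewer than two experiments "
                    f"for neuron {neuron}")
    level = 1.0 - cfg.alpha_phase
    neurons = sorted(set.intersection(
        *(set(by_neuron) for by_neuron in per_experiment.values())))
    records = []
    run_id = 0
    for neuron in neurons:
        for cond in conditions:
            others = [c for c in conditions if c != cond]
            flags = np.ones(cfg.phase_bins, dtype=bool)
            for other in others:
                lo, hi = _basic_ci_bins(per_experiment[cond][neuron],
                                        per_experiment[other][neuron],
                                        level, cfg.bootstrap_iterations, rng)
                flags &= (lo > 0) | (hi < 0)
            for start, stop in _runs_of_true(flags, cfg.min_consecutive_bins):
                for b in range(start, stop):
                    records.append((neuron, cond, b, run_id))
                run_id += 1
    return pd.DataFrame(records, columns=["neuron", "condition", "bin", "run_id"])


def duty_cycle_summary(recordings: Sequence[Recording],
                       cfg: AnalysisConfig | None = None,
                       labels_per_recording: Sequence[Sequence[str]] | None = None,
                       ) -> tuple[float, float, int]:
    """Condition-level IC duty cycle: mean +/- SE (%) over experiments.

    Per experiment, the mean over gastric cycles in its rhythm segments of
    (long IC burst duration / cycle period); then mean and SE across
    experiments.
    """
    cfg = cfg or AnalysisConfig()
    per_exp = []
    for i, rec in enumerate(recordings):
        ana = analyze_incubation(rec, cfg)
        labels = (labels_per_recording[i] if labels_per_recording is not None
                  else segment_categories(rec, cfg, analysis=ana))
        duties = []
        for w, lab in zip(segment_windows(rec, cfg), labels):
            if lab != "GMR":
                continue
            duties += [duty_cycle(c.long_ic_burst.duration, c.period)
                       for c in ana.gastric_cycles if w.contains(c.onset)]
        if duties:
            per_exp.append(float(np.mean(duties)))
    if not per_exp:
        raise ValidationError("no gastric mill rhythm segments in condition")
    arr = np.asarray(per_exp)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size >= 2 else float("nan")
    return float(arr.mean()), se, arr.size
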