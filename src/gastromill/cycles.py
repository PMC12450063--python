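"""Pyloric and gastric mill cycle construction and per-incubation metrics.

The pyloric cycle is the interval between consecutive PD burst onsets
(~1 s); the gastric mill cycle is the interval between consecutive long
(>= 1 s) IC burst onsets (~13-20 s).  An IC-associated *interruption* is a
pyloric cycle whose period reaches at least 150% of the control period,
where the control period is the mean over all pyloric cycles carrying fewer
than 10 IC spikes.

A brief gastric-mill-timed IC burst (1-2 s) that is followed within 5 s by
a longer (> 2 s) burst is a *prepeak*: it belongs to the preceding cycle
and does not start a new one, but still counts toward burst-count, duration
and rate statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bursts import Burst, bursts_in_window, ceiling_for, detect_bursts
from .core import AnalysisConfig, Recording, SETTLE_EXCLUSION_S, SpikeTrain

logger = logging.getLogger(__name__)

PREPEAK_MIN_S = 1.0
PREPEAK_MAX_S = 2.0
PREPEAK_SUCCESSOR_MIN_S = 2.0
PREPEAK_MAX_GAP_S = 5.0


@dataclass
class PyloricCycle:
    """One pyloric cycle: consecutive PD burst onsets and the IC load inside."""

    index: int
    onset: float
    period: float
    ic_spike_count: int
    is_control: bool
    pct_of_control: float = math.nan
    is_interrupted: bool = False

    @property
    def frequency(self) -> float:
        return 1.0 / self.period


@dataclass
class GastricCycle:
    """One gastric mill cycle: consecutive cycle-defining long IC bursts."""

    onset: float
    period: float
    long_ic_burst: Burst
    prepeak: Burst | None = None
    member_bursts: dict[str, list[Burst]] = field(default_factory=dict)

    @property
    def stop(self) -> float:
        return self.onset + self.period


@dataclass
class NeuronBurstStats:
    mean_spikes_per_burst: float = math.nan
    mean_rate_hz: float = math.nan
    mean_duration_s: float = math.nan


@dataclass
class IncubationSummary:
    """Whole-incubation burst/cycle metrics (means are NaN when undefined)."""

    subject_id: str
    condition: str
    n_long_ic_bursts: int = 0
    n_interruptions: int = 0
    mean_ic_spikes_per_long_burst: float = math.nan
    mean_ic_rate_hz: float = math.nan
    mean_ic_duty_cycle_pct: float = math.nan
    mean_gm_period_s: float = math.nan
    mean_ic_burst_duration_s: float = math.nan
    mean_control_period_s: float = math.nan
    mean_delay_duration_s: float = math.nan
    mean_delay_pct_control: float = math.nan
    per_neuron: dict[str, NeuronBurstStats] = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {k: v for k, v in self.__dict__.items() if k != "per_neuron"}
        for neuron, stats in self.per_neuron.items():
            for key, val in stats.__dict__.items():
                row[f"{neuron}_{key}"] = val
        return row


def extract_long_ic_bursts(ic_bursts: list[Burst],
                           cfg: AnalysisConfig | None = None) -> list[Burst]:
    """Bursts with duration >= ``cfg.long_ic_burst_min_s`` (inclusive, 1 s)."""
    cfg = cfg or AnalysisConfig()
    return [b for b in ic_bursts if b.duration >= cfg.long_ic_burst_min_s]


def classify_prepeaks(long_bursts: list[Burst]
                      ) -> tuple[list[Burst], list[Burst]]:
    """Split long IC bursts into cycle-defining bursts and prepeaks.

    Returns ``(cycle_defining, prepeaks)``.  A burst is a prepeak when its
    duration is in [1, 2] s and the next burst lasts > 2 s and starts within
    5 s of the brief burst's offset.
    """
    cycle_defining: list[Burst] = []
    prepeaks: list[Burst] = []
    for i, b in enumerate(long_bursts):
        nxt = long_bursts[i + 1] if i + 1 < len(long_bursts) else None
        if (nxt is not None
                and PREPEAK_MIN_S <= b.duration <= PREPEAK_MAX_S
                and nxt.duration > PREPEAK_SUCCESSOR_MIN_S
                and nxt.onset - b.offset <= PREPEAK_MAX_GAP_S):
            prepeaks.append(b)
        else:
            cycle_defining.append(b)
    return cycle_defining, prepeaks


def build_pyloric_cycles(pd_bursts: list[Burst], ic_train: SpikeTrain | None,
                         cfg: AnalysisConfig | None = None
                         ) -> list[PyloricCycle]:
    """Cycles from consecutive PD burst onsets, with IC load and flags.

    IC spikes are assigned to the half-open interval between consecutive PD
    onsets.  The control period is the mean over cycles with fewer than
    ``cfg.control_ic_spike_max`` IC spikes; interruption flags compare each
    period against ``cfg.interruption_threshold`` times that mean.
    """
    cfg = cfg or AnalysisConfig()
    if len(pd_bursts) < 2:
        logger.warning("fewer than two PD bursts; no pyloric cycles")
        return []
    onsets = np.array([b.onset for b in pd_bursts])
    ic_times = ic_train.times if ic_train is not None else np.empty(0)
    counts = np.diff(np.searchsorted(ic_times, onsets, side="left"))
    periods = np.diff(onsets)
    cycles = [
        PyloricCycle(index=i, onset=float(onsets[i]), period=float(periods[i]),
                     ic_spike_count=int(counts[i]),
                     is_control=int(counts[i]) < cfg.control_ic_spike_max)
        for i in range(len(periods))
    ]
    control = [c.period for c in cycles if c.is_control]
    if not control:
        logger.warning("no control pyloric cycles (<%d IC spikes); "
                       "interruption flags left unset", cfg.control_ic_spike_max)
        return cycles
    control_mean = float(np.mean(control))
    for c in cycles:
        c.pct_of_control = 100.0 * c.period / control_mean
        c.is_interrupted = c.pct_of_control >= cfg.interruption_threshold * 100.0
    return cycles


def build_gastric_cycles(cycle_bursts: list[Burst],
                         all_neuron_bursts: dict[str, list[Burst]] | None = None,
                         prepeaks: list[Burst] | None = None
                         ) -> list[GastricCycle]:
    """Cycles from consecutive cycle-defining long IC burst onsets.

    Member bursts (and prepeaks) are assigned to the cycle containing their
    onset; a burst spanning a cycle boundary belongs to the cycle in which
    it starts.
    """
    if len(cycle_bursts) < 2:
        logger.warning("fewer than two cycle-defining long IC bursts; "
                       "no gastric cycles")
        return []
    cycles = []
    for i in range(len(cycle_bursts) - 1):
        b, nxt = cycle_bursts[i], cycle_bursts[i + 1]
        cyc = GastricCycle(onset=b.onset, period=nxt.onset - b.onset,
                           long_ic_burst=b)
        if all_neuron_bursts:
            for neuron, bursts in all_neuron_bursts.items():
                cyc.member_bursts[neuron] = [
                    m for m in bursts if cyc.onset <= m.onset < cyc.stop]
        cycles.append(cyc)
    for pp in prepeaks or []:
        for cyc in cycles:
            if cyc.onset <= pp.onset < cyc.stop:
                cyc.prepeak = pp
                break
    return cycles


def duty_cycle(burst_duration: float, cycle_period: float) -> float:
    """Burst duration over cycle period, as a percentage (capped at 100)."""
    if cycle_period <= 0:
        raise ValueError("cycle_period must be positive")
    if burst_duration > cycle_period:
        logger.warning("burst duration %.3f s exceeds cycle period %.3f s; "
                       "duty cycle capped at 100%%", burst_duration, cycle_period)
        return 100.0
    return 100.0 * burst_duration / cycle_period


def cycles_with_ic_load(cycles: list[PyloricCycle],
                        min_ic_spikes: int = 20) -> list[PyloricCycle]:
    """Pyloric cycles with strictly more than ``min_ic_spikes`` IC spikes."""
    return [c for c in cycles if c.ic_spike_count > min_ic_spikes]


# ---------------------------------------------------------------------------
# Whole-incubation analysis

@dataclass
class IncubationAnalysis:
    """Intermediate products shared by the summary, features and phase stages."""

    pyloric_cycles: list[PyloricCycle]
    gastric_cycles: list[GastricCycle]
    long_ic_bursts: list[Burst]      # cycle-defining + prepeaks
    cycle_bursts: list[Burst]
    prepeaks: list[Burst]
    bursts_by_neuron: dict[str, list[Burst]]


class _AnalysisWindow:
    def __init__(self, start: float, stop: float) -> None:
        self.start, self.stop = start, stop


def analyze_incubation(rec: Recording, cfg: AnalysisConfig | None = None
                       ) -> IncubationAnalysis:
    """Run burst detection and cycle construction over an incubation.

    Analysis spans ``[incubation_start + 60 s, incubation end)``; bursts are
    detected on the full trains and then kept if their onset falls inside
    the analysis window (onset-owns rule).
    """
    cfg = cfg or AnalysisConfig()
    window = _AnalysisWindow(rec.incubation_start + SETTLE_EXCLUSION_S,
                             rec.incubation_stop)

    bursts_by_neuron: dict[str, list[Burst]] = {}
    for neuron, train in rec.trains.items():
        ceiling = ceiling_for(neuron, gastric_context=False, cfg=cfg)
        bursts_by_neuron[neuron] = bursts_in_window(
            detect_bursts(train, ceiling), window)

    ic_train = rec.trains.get("IC")
    if ic_train is not None:
        slow = detect_bursts(ic_train, ceiling_for("IC", True, cfg))
        long_bursts = bursts_in_window(extract_long_ic_bursts(slow, cfg), window)
    else:
        long_bursts = []
    cycle_bursts, prepeaks = classify_prepeaks(long_bursts)

    pyl = build_pyloric_cycles(bursts_by_neuron.get("PD", []), ic_train, cfg)
    gas = build_gastric_cycles(cycle_bursts, bursts_by_neuron, prepeaks)
    return IncubationAnalysis(pyl, gas, long_bursts, cycle_bursts, prepeaks,
                              bursts_by_neuron)


def _mean(values) -> float:
    values = list(values)
    return float(np.mean(values)) if values else math.nan


def summarize_incubation(rec: Recording, cfg: AnalysisConfig | None = None,
                         analysis: IncubationAnalysis | None = None
                         ) -> IncubationSummary:
    """Per-incubation counts and means over the post-60-s analysis window.

    Prepeak bursts count toward burst-count/duration/rate statistics but are
    excluded from the cycle-period determination.
    """
    cfg = cfg or AnalysisConfig()
    ana = analysis or analyze_incubation(rec, cfg)
    s = IncubationSummary(rec.subject_id, rec.condition)

    s.n_long_ic_bursts = len(ana.long_ic_bursts)
    s.mean_ic_spikes_per_long_burst = _mean(b.n_spikes for b in ana.long_ic_bursts)
    s.mean_ic_rate_hz = _mean(b.rate_hz for b in ana.long_ic_bursts)
    s.mean_ic_burst_duration_s = _mean(b.duration for b in ana.long_ic_bursts)
    s.mean_gm_period_s = _mean(c.period for c in ana.gastric_cycles)
    s.mean_ic_duty_cycle_pct = _mean(
        duty_cycle(c.long_ic_burst.duration, c.period) for c in ana.gastric_cycles)

    interrupted = [c for c in ana.pyloric_cycles if c.is_interrupted]
    s.n_interruptions = len(interrupted)
    s.mean_delay_duration_s = _mean(c.period for c in interrupted)
    s.mean_delay_pct_control = _mean(c.pct_of_control for c in interrupted)
    s.mean_control_period_s = _mean(
        c.period for c in ana.pyloric_cycles if c.is_control)

    for neuron in ("LG", "DG", "AM"):
        bs = ana.bursts_by_neuron.get(neuron, [])
        s.per_neuron[neuron] = NeuronBurstStats(
            mean_spikes_per_burst=_mean(b.n_spikes for b in bs),
            mean_rate_hz=_mean(b.rate_hz for b in bs),
            mean_duration_s=_mean(b.duration for b in bs),
        )
    return s
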