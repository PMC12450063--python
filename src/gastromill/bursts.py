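"""Burst detection by neuron-class-specific interspike-interval ceilings.

A burst is a maximal run of consecutive spikes in which no interspike
interval exceeds the class ceiling: 2 s for the slow gastric-mill class
(LG, DG, and long IC bursts), 0.25 s for the fast pyloric/gastropyloric
class.  The comparison is strict — a gap equal to the ceiling keeps the run
together ("no interval *longer* than" the ceiling).

Runs of fewer than two spikes are not bursts (the intraburst rate
(n − 1)/duration is undefined for a singleton); they are reported as tonic
spikes so that bursts plus tonic spikes always partition the train.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnalysisConfig, NEURONS, SLOW_BURST_NEURONS, SpikeTrain, ValidationError

MIN_BURST_SPIKES = 2


@dataclass(frozen=True)
class Burst:
    """A contiguous group of spikes under an ISI ceiling."""

    neuron: str
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.size < MIN_BURST_SPIKES:
            raise ValidationError("a burst needs at least two spikes")
        if times[-1] <= times[0]:
            raise ValidationError("burst spikes must span positive duration")

    @property
    def onset(self) -> float:
        return float(self.spike_times[0])

    @property
    def offset(self) -> float:
        return float(self.spike_times[-1])

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    @property
    def duration(self) -> float:
        """Onset of first to onset of last spike, seconds."""
        return self.offset - self.onset

    @property
    def rate_hz(self) -> float:
        """Intraburst firing rate: (n_spikes − 1) / duration."""
        return burst_rate(self)


def burst_rate(b: Burst) -> float:
    """Spikes-per-second within a burst, ``(n − 1) / duration``."""
    return (b.n_spikes - 1) / b.duration


def split_bursts(train: SpikeTrain, isi_ceiling_s: float
                 ) -> tuple[list[Burst], np.ndarray]:
    """Partition a train into bursts and tonic (isolated) spikes.

    Greedy single pass: a gap strictly greater than the ceiling closes the
    current group; groups of >= 2 spikes become bursts, singletons go to the
    tonic set.  Bursts are disjoint and time-ordered, and every spike lands
    in exactly one of the two outputs.
    """
    if isi_ceiling_s <= 0:
        raise ValidationError("isi_ceiling_s must be positive")
    times = train.times
    if times.size == 0:
        return [], times.copy()
    breaks = np.flatnonzero(np.diff(times) > isi_ceiling_s) + 1
    groups = np.split(times, breaks)
    bursts = [Burst(train.neuron, g) for g in groups if g.size >= MIN_BURST_SPIKES]
    tonic = np.concatenate(
        [g for g in groups if g.size < MIN_BURST_SPIKES] or [np.empty(0)])
    return bursts, tonic


def detect_bursts(train: SpikeTrain, isi_ceiling_s: float) -> list[Burst]:
    """Bursts of a train under an ISI ceiling (tonic spikes discarded)."""
    return split_bursts(train, isi_ceiling_s)[0]


def ceiling_for(neuron: str, gastric_context: bool = False,
                cfg: AnalysisConfig | None = None) -> float:
    """The ISI ceiling for a neuron.

    LG and DG always use the slow (2 s) ceiling, as does IC when extracting
    its gastric-mill-timed long bursts (``gastric_context=True``).  All other
    neurons — and IC's pyloric-timed bursts — use the fast (0.25 s) ceiling.
    """
    cfg = cfg or AnalysisConfig()
    if neuron not in NEURONS:
        raise ValidationError(f"unknown neuron label {neuron!r}")
    if neuron in SLOW_BURST_NEURONS or (neuron == "IC" and gastric_context):
        return cfg.slow_isi_ceiling_s
    return cfg.fast_isi_ceiling_s


def bursts_in_window(bursts: list[Burst], window) -> list[Burst]:
    """Bursts whose onset lies in ``[window.start, window.stop)``.

    Onset-owns rule: a burst truncated by a window boundary is counted in
    the window containing its onset, so each burst belongs to exactly one
    window.
    """
    return [b for b in bursts if window.start <= b.onset < window.stop]
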