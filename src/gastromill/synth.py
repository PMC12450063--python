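"""Synthetic spike trains for gastric mill / pyloric rhythm analysis.

Emulates the recorded motor pattern of six stomatogastric neurons under
three rhythm states:

``FULL``
    A regular gastric mill rhythm: cycles of ~14 s (CV 0.18) defined by
    long (>= 1 s) IC bursts firing at ~21-28 Hz, with an LG burst at cycle
    onset, an AM burst co-extensive with the IC burst, a DG burst from the
    IC burst end to the cycle midpoint, LPG duty-cycle expansion
    mid-cycle, and IC-burst-timed interruptions (period x interruption
    factor) of the ~1.1-s pyloric (PD) rhythm.  A fraction of cycles carry
    a brief (1-2 s) "prepeak" IC burst shortly before the main burst.
``IRREGULAR``
    Long IC bursts persist but with cycle periods >= 40 s, elevated period
    CV, and per-neuron burst dropout.
``NONE``
    Only pyloric-timed activity; all IC bursts are brief (< 0.5 s).

Intraburst spikes sit on a jittered regular grid rather than a Poisson
process: the downstream burst definitions are ISI ceilings (0.25 s / 2 s),
and regular spiking at gastric rates keeps every emitted burst unambiguous
under those ceilings, so the generator's ground truth is recoverable
exactly from its own output.  Event layout enforces a > 2 s gap between
any two gastric-mill-timed IC events and suppresses pyloric-timed IC
bursts within 2.5 s of them, for the same reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import Recording, SpikeTrain, ValidationError, segment_windows

STATES = ("FULL", "IRREGULAR", "NONE")

_PD_INTRA_RATE_HZ = 23.0
_LG_RATE_HZ = 5.0
_AM_RATE_HZ = 8.0
_DG_RATE_HZ = 14.0
_LPG_RATE_HZ = 25.0
_IC_PYLORIC_RATE_HZ = 27.0
_IC_PYLORIC_DUR_S = 0.15
#: minimum silence around gastric IC events so the 2-s ISI ceiling never
#: merges or splits them against the ground truth
_IC_GUARD_S = 2.5


@dataclass(frozen=True)
class RhythmSpec:
    """Parameters of one simulated incubation.

    ``gm_period_s``/``gm_period_cv``/``dropout`` default per state when left
    ``None`` (FULL: 14 s / 0.18 / 0; IRREGULAR: 48 s / 0.37 / 0.25).
    Irregular periods are truncated below at 40 s, the defining bound for an
    irregular rhythm.
    """

    state: str = "FULL"
    gm_period_s: float | None = None
    gm_period_cv: float | None = None
    ic_long_burst_duration_s: float = 2.5
    ic_burst_rate_hz: float = 24.0
    pyloric_period_s: float = 1.1
    pd_duty_cycle: float = 0.20
    interruption_factor: float = 1.8
    prepeak_probability: float = 0.2
    dropout: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"unknown rhythm state {self.state!r}")
        for name in ("ic_long_burst_duration_s", "ic_burst_rate_hz",
                     "pyloric_period_s", "pd_duty_cycle", "interruption_factor"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.gm_period_s is not None:
            if self.state == "FULL" and not (13.0 <= self.gm_period_s <= 20.0):
                raise ValidationError(
                    "FULL gastric period must lie in [13, 20] s")
            if self.state == "IRREGULAR" and self.gm_period_s < 40.0:
                raise ValidationError(
                    "IRREGULAR gastric period must be at least 40 s")

    @property
    def period_mean(self) -> float:
        if self.gm_period_s is not None:
            return self.gm_period_s
        return 14.0 if self.state == "FULL" else 48.0

    @property
    def period_cv(self) -> float:
        if self.gm_period_cv is not None:
            return self.gm_period_cv
        return 0.18 if self.state == "FULL" else 0.37

    @property
    def dropout_p(self) -> float:
        if self.dropout is not None:
            return self.dropout
        return 0.25 if self.state == "IRREGULAR" else 0.0


@dataclass
class GroundTruth:
    """Generator-side labels used as the oracle in recovery tests."""

    state: str
    segment_categories: list[str] = field(default_factory=list)
    gastric_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    long_ic_intervals: list[tuple[float, float]] = field(default_factory=list)
    prepeak_intervals: list[tuple[float, float]] = field(default_factory=list)
    pyloric_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    interrupted_pyloric_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    burst_intervals: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    tonic_times: dict[str, np.ndarray] = field(default_factory=dict)


def _burst_spikes(rng: np.random.Generator, onset: float, duration: float,
                  rate_hz: float) -> np.ndarray:
    """A jittered regular spike grid spanning exactly [onset, onset+duration]."""
    n = max(2, int(round(duration * rate_hz)) + 1)
    times = onset + np.linspace(0.0, duration, n)
    if n > 2:
        step = duration / (n - 1)
        times[1:-1] += rng.uniform(-0.15, 0.15, n - 2) * step
    return times


class _Emitter:
    """Accumulates spikes and ground-truth intervals per neuron."""

    def __init__(self) -> None:
        self.spikes: dict[str, list[np.ndarray]] = {}
        self.intervals: dict[str, list[tuple[float, float]]] = {}
        self.tonic: dict[str, list[float]] = {}

    def burst(self, neuron: str, times: np.ndarray) -> tuple[float, float]:
        self.spikes.setdefault(neuron, []).append(times)
        iv = (float(times[0]), float(times[-1]))
        self.intervals.setdefault(neuron, []).append(iv)
        return iv

    def tonic_spike(self, neuron: str, t: float) -> None:
        self.spikes.setdefault(neuron, []).append(np.array([t]))
        self.tonic.setdefault(neuron, []).append(t)

    def train(self, neuron: str, t_stop: float) -> SpikeTrain:
        parts = self.spikes.get(neuron, [])
        times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        return SpikeTrain(neuron, times, 0.0, t_stop)


def _draw_period(rng: np.random.Generator, spec: RhythmSpec) -> float:
    mean, sd = spec.period_mean, spec.period_cv * spec.period_mean
    lo = 40.0 if spec.state == "IRREGULAR" else 0.6 * mean
    hi = math.inf if spec.state == "IRREGULAR" else 1.5 * mean
    for _ in range(1000):
        p = rng.normal(mean, sd)
        if lo <= p <= hi:
            return p
    return mean  # pragma: no cover - astronomically unlikely


def _min_distance(interval: tuple[float, float],
                  others: list[tuple[float, float]]) -> float:
    a, b = interval
    dist = math.inf
    for lo, hi in others:
        if hi > a and lo < b:
            return 0.0
        dist = min(dist, lo - b if lo >= b else a - hi)
    return dist


def generate_recording(spec: RhythmSpec, duration_s: float = 900.0,
                       subject_id: str = "synthetic",
                       condition: str = "synthetic",
                       ) -> tuple[Recording, GroundTruth]:
    """Simulate one incubation and return it with its ground truth.

    The incubation spans ``[0, duration_s)``; the same spec and seed always
    yield identical output.
    """
    if spec.state != "NONE" and duration_s < 3 * spec.period_mean:
        raise ValidationError(
            f"duration {duration_s} s too short for {spec.state} rhythm "
            f"with {spec.period_mean} s cycles")
    rng = np.random.default_rng(spec.seed)
    em = _Emitter()
    truth = GroundTruth(state=spec.state)

    gastric_ic: list[tuple[float, float]] = []  # mains + prepeaks, for layout
    if spec.state in ("FULL", "IRREGULAR"):
        # candidate cycle onsets
        onsets = []
        t = rng.uniform(4.0, 9.0)
        while t < duration_s - 0.6 * spec.period_mean:
            onsets.append(t)
            t += _draw_period(rng, spec)
        onsets = np.asarray(onsets)
        keep = rng.random(onsets.size) >= (spec.dropout_p if spec.state == "IRREGULAR" else 0.0)
        member_keep = {
            n: rng.random(onsets.size) >= spec.dropout_p for n in ("LG", "DG", "AM")
        }

        emitted_mains: list[float] = []
        durations: dict[int, float] = {}
        for i, g in enumerate(onsets):
            if not keep[i]:
                continue
            nxt = onsets[i + 1] if i + 1 < onsets.size else g + spec.period_mean
            p_i = nxt - g
            d = float(np.clip(rng.normal(spec.ic_long_burst_duration_s, 0.4),
                              1.3, min(4.0, 0.32 * p_i)))
            if g + d > duration_s - 0.1:
                continue
            iv = em.burst("IC", _burst_spikes(rng, g, d, spec.ic_burst_rate_hz))
            gastric_ic.append(iv)
            truth.long_ic_intervals.append(iv)
            emitted_mains.append(g)
            durations[i] = d

            # coordinated member bursts
            if member_keep["LG"][i]:
                lg_d = float(np.clip(rng.normal(3.0, 0.4), 1.5, 0.35 * p_i))
                if g + 0.05 + lg_d < duration_s:
                    em.burst("LG", _burst_spikes(rng, g + 0.05, lg_d, _LG_RATE_HZ))
            if member_keep["AM"][i]:
                if g + d < duration_s:
                    em.burst("AM", _burst_spikes(rng, g + 0.02, d - 0.04, _AM_RATE_HZ))
            if member_keep["DG"][i]:
                dg_on = g + d + 0.15
                dg_d = float(np.clip(0.45 * p_i - d - 0.15, 1.0, 8.0))
                if dg_on + dg_d < duration_s:
                    em.burst("DG", _burst_spikes(rng, dg_on, dg_d, _DG_RATE_HZ))

        # prepeaks (FULL only): brief burst 2.5-4.5 s before the main burst
        if spec.state == "FULL":
            for i, g in enumerate(onsets):
                if i not in durations or durations[i] <= 2.2:
                    continue
                if rng.random() >= spec.prepeak_probability:
                    continue
                pp_dur = rng.uniform(1.1, 1.9)
                gap = rng.uniform(2.5, 4.5)
                pp_on = g - gap - pp_dur
                iv = (pp_on, g - gap)
                if pp_on <= 0.5 or _min_distance(iv, gastric_ic) <= 2.2:
                    continue
                iv = em.burst("IC", _burst_spikes(rng, pp_on, pp_dur,
                                                  spec.ic_burst_rate_hz))
                gastric_ic.append(iv)
                truth.long_ic_intervals.append(iv)
                truth.prepeak_intervals.append(iv)

        truth.gastric_onsets = np.asarray(emitted_mains)
        truth.long_ic_intervals.sort()
        gastric_ic.sort()

    # --- pyloric rhythm (PD, LPG, pyloric-timed IC) -----------------------
    p_base = spec.pyloric_period_s
    pd_dur = spec.pd_duty_cycle * p_base
    pyl_onsets: list[float] = []
    interrupted: list[float] = []
    t = rng.uniform(0.2, 1.0)
    k = 0
    gm_onsets_arr = truth.gastric_onsets
    while t + pd_dur < duration_s:
        tentative = p_base * (1.0 + rng.uniform(-0.03, 0.03))
        if _min_distance((t, t + tentative), gastric_ic) <= 0.0:
            period = p_base * spec.interruption_factor
            interrupted.append(t)
        else:
            period = tentative
        pyl_onsets.append(t)
        em.burst("PD", _burst_spikes(rng, t, pd_dur, _PD_INTRA_RATE_HZ))

        is_interrupted = bool(interrupted) and interrupted[-1] == t
        if not is_interrupted:
            # LPG in antiphase with PD; duty doubles mid-gastric-cycle
            lpg_dur = spec.pd_duty_cycle * p_base
            if gm_onsets_arr.size:
                j = int(np.searchsorted(gm_onsets_arr, t, side="right")) - 1
                if 0 <= j < gm_onsets_arr.size - 1:
                    phase = (t - gm_onsets_arr[j]) / (
                        gm_onsets_arr[j + 1] - gm_onsets_arr[j])
                    if 0.25 <= phase <= 0.55:
                        lpg_dur *= 2.0
            lpg_on = t + 0.45 * p_base
            if lpg_on + lpg_dur < duration_s:
                em.burst("LPG", _burst_spikes(rng, lpg_on, lpg_dur, _LPG_RATE_HZ))
            # sparse pyloric-timed IC bursts, kept clear of gastric IC events
            if k % 3 == 0:
                ic_iv = (t + 0.3, t + 0.3 + _IC_PYLORIC_DUR_S)
                if (ic_iv[1] < duration_s
                        and _min_distance(ic_iv, gastric_ic) > _IC_GUARD_S):
                    em.burst("IC", _burst_spikes(rng, ic_iv[0],
                                                 _IC_PYLORIC_DUR_S,
                                                 _IC_PYLORIC_RATE_HZ))
        t += period
        k += 1

    truth.pyloric_onsets = np.asarray(pyl_onsets)
    truth.interrupted_pyloric_onsets = np.asarray(interrupted)

    # --- sparse tonic activity for gastric neurons silent of bursts ------
    if spec.state == "NONE":
        for neuron in ("LG", "DG", "AM"):
            t = rng.uniform(1.0, 6.0)
            while t < duration_s - 0.5:
                em.tonic_spike(neuron, t)
                t += rng.uniform(3.0, 12.0)

    trains = {n: em.train(n, duration_s)
              for n in ("IC", "PD", "LPG", "LG", "DG", "AM")
              if n in em.spikes}
    rec = Recording(subject_id=subject_id, condition=condition,
                    incubation_start=0.0, incubation_duration=duration_s,
                    trains=trains)
    truth.burst_intervals = {n: sorted(iv) for n, iv in em.intervals.items()}
    truth.tonic_times = {n: np.asarray(v) for n, v in em.tonic.items()}
    truth.segment_categories = _segment_truth(rec, truth)
    return rec, truth


def _segment_truth(rec: Recording, truth: GroundTruth) -> list[str]:
    cats = []
    for w in segment_windows(rec):
        if truth.state == "FULL":
            cats.append("GMR")
        elif truth.state == "NONE":
            cats.append("NONE")
        else:
            n = int(np.sum((truth.gastric_onsets >= w.start)
                           & (truth.gastric_onsets < w.stop)))
            cats.append("IRREGULAR" if n >= 1 else "NONE")
    return cats


def generate_condition_batch(n_subjects: int, mix: Mapping[str, float],
                             seed: int, duration_s: float = 900.0,
                             condition: str = "synthetic",
                             spec_template: RhythmSpec | None = None,
                             ) -> list[tuple[Recording, GroundTruth]]:
    """A reproducible batch of recordings with states drawn from ``mix``.

    States are allocated deterministically (largest-remainder rounding of
    the proportions, interleaved round-robin across subjects); each subject
    gets an independent child RNG stream of ``seed``.
    """
    if n_subjects < 0:
        raise ValidationError("n_subjects must be non-negative")
    if any(p < 0 for p in mix.values()):
        raise ValidationError("mix proportions must be non-negative")
    total = sum(mix.values())
    if n_subjects and not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValidationError(f"mix proportions must sum to 1, got {total}")

    states = [s for s in STATES if mix.get(s, 0) > 0]
    counts = {s: int(math.floor(mix[s] * n_subjects)) for s in states}
    remainders = sorted(states, key=lambda s: (-(mix[s] * n_subjects - counts[s]),
                                               STATES.index(s)))
    for s in remainders[: n_subjects - sum(counts.values())]:
        counts[s] += 1
    pools = {s: counts[s] for s in states}
    assignment = []
    while len(assignment) < n_subjects:
        for s in states:
            if pools[s] > 0:
                assignment.append(s)
                pools[s] -= 1

    template = spec_template or RhythmSpec()
    children = np.random.SeedSequence(seed).spawn(n_subjects)
    batch = []
    for i, state in enumerate(assignment):
        sub_seed = int(children[i].generate_state(1)[0] & 0x7FFFFFFF)
        spec = replace(template, state=state, seed=sub_seed,
                       gm_period_s=None, gm_period_cv=None, dropout=None)
        batch.append(generate_recording(spec, duration_s,
                                        subject_id=f"{condition}-{i:02d}",
                                        condition=condition))
    return batch


def contingency_fixture() -> pd.DataFrame:
    """Printed per-condition 200-s segment classification counts.

    Rows: condition; columns ``gmr`` (segments with a gastric mill rhythm)
    and ``non_gmr`` (irregular + no rhythm combined).  These are the study's
    published segment counts, provided as a worked-example input for the
    odds/odds-ratio statistics.
    """
    data = {
        "1uM-S": (9, 87),
        "1uM-UH": (21, 19),
        "1uM-FH": (38, 6),
        "10uM-S": (42, 22),
    }
    return pd.DataFrame.from_dict(data, orient="index",
                                  columns=["gmr", "non_gmr"])
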