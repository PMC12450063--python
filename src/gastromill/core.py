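"""Core domain types, spike-time I/O and incubation windowing.

Spike-time data enter the package as per-experiment tables of
``(neuron, time_s)`` rows plus a small manifest describing the incubation
(subject, condition, incubation start/duration).  All times are seconds as
floats; input files must already be in seconds — no millisecond dialect is
accepted, to avoid silent unit errors.

Windows and cycle intervals are half-open ``[start, stop)`` throughout so a
spike on a boundary is counted exactly once.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The identified stomatogastric (STG) motor neurons this package knows about.
#: Unknown labels are rejected rather than passed through, because burst
#: detection thresholds are neuron-class specific.
NEURONS = ("IC", "PD", "LPG", "LG", "DG", "AM", "VD", "MG", "GM")

#: Neurons whose gastric-mill-timed bursts are delimited with the slow (2 s)
#: interspike-interval ceiling.  IC is special-cased: its long gastric bursts
#: use the slow ceiling while its pyloric-timed bursts use the fast one.
SLOW_BURST_NEURONS = frozenset({"LG", "DG"})

CONDITIONS = (
    "saline", "UH", "FH", "1uM-S", "1uM-UH", "1uM-FH", "10uM-S", "1uM-UH-D",
)


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class ValidationError(ValueError):
    """Raised when parsed data violate a domain invariant."""


@dataclass(frozen=True)
class SpikeTrain:
    """One neuron's sorted spike times over a recording window.

    Parameters
    ----------
    neuron : str
        One of :data:`NEURONS`.
    times : numpy.ndarray
        Strictly increasing spike times, seconds.
    t_start, t_stop : float
        Recording window bounds; every spike lies in ``[t_start, t_stop]``.
    """

    neuron: str
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        if self.neuron not in NEURONS:
            raise ValidationError(
                f"unknown neuron label {self.neuron!r}; expected one of {NEURONS}"
            )
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.t_stop <= self.t_start:
            raise ValidationError(
                f"{self.neuron}: t_stop ({self.t_stop}) must exceed t_start ({self.t_start})"
            )
        if times.size:
            bad = np.flatnonzero(np.diff(times) <= 0)
            if bad.size:
                raise ValidationError(
                    f"{self.neuron}: spike times not strictly increasing at "
                    f"t={times[bad[0] + 1]:.6f} s"
                )
            if times[0] < self.t_start or times[-1] > self.t_stop:
                raise ValidationError(
                    f"{self.neuron}: spikes outside recording window "
                    f"[{self.t_start}, {self.t_stop}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def isis(self) -> np.ndarray:
        """Interspike intervals, seconds."""
        return np.diff(self.times)

    def shifted(self, delta: float) -> "SpikeTrain":
        return SpikeTrain(self.neuron, self.times + delta,
                          self.t_start + delta, self.t_stop + delta)


@dataclass
class Recording:
    """A single incubation: per-neuron spike trains plus experiment metadata.

    ``incubation_start``/``incubation_duration`` delimit the bath-application
    window (default 900 s, i.e. a 15-min incubation) that all downstream
    windowing is anchored to.
    """

    subject_id: str
    condition: str
    incubation_start: float
    incubation_duration: float = 900.0
    trains: dict[str, SpikeTrain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.incubation_duration <= 0:
            raise ValidationError("incubation_duration must be positive")
        for name, train in self.trains.items():
            if name != train.neuron:
                raise ValidationError(
                    f"trains key {name!r} does not match train neuron {train.neuron!r}"
                )
            if (train.t_start > self.incubation_start
                    or train.t_stop < self.incubation_start + self.incubation_duration):
                raise ValidationError(
                    f"{name}: incubation window not inside recording window"
                )

    @property
    def incubation_stop(self) -> float:
        return self.incubation_start + self.incubation_duration

    def shifted(self, delta: float) -> "Recording":
        return replace(
            self,
            incubation_start=self.incubation_start + delta,
            trains={k: v.shifted(delta) for k, v in self.trains.items()},
        )


@dataclass(frozen=True)
class SegmentWindow:
    """A 200-s half-open analysis window ``[start, stop)``."""

    index: int
    start: float
    stop: float

    SEGMENT_LENGTH_S = 200.0

    def __post_init__(self) -> None:
        if not math.isclose(self.stop - self.start, self.SEGMENT_LENGTH_S):
            raise ValidationError(
                f"segment window must span {self.SEGMENT_LENGTH_S} s, "
                f"got {self.stop - self.start}"
            )

    def contains(self, t: float) -> bool:
        return self.start <= t < self.stop


@dataclass
class AnalysisConfig:
    """All tunable thresholds of the analysis, with the study's defaults.

    Attributes
    ----------
    long_ic_burst_min_s : float
        Minimum duration for an IC burst to count as gastric-mill-timed
        ("long"); inclusive threshold.
    slow_isi_ceiling_s, fast_isi_ceiling_s : float
        ISI ceilings delimiting bursts for the slow (LG, DG, long IC) and
        fast (pyloric/gastropyloric) neuron classes.
    interruption_threshold : float
        A pyloric cycle whose period is at least this fraction of the mean
        control period counts as an IC-associated interruption.
    control_ic_spike_max : int
        Pyloric cycles with fewer than this many IC spikes define the
        control (baseline) period; exclusive bound.
    phase_bins : int
        Bins per gastric mill cycle for phase profiles.
    """

    long_ic_burst_min_s: float = 1.0
    slow_isi_ceiling_s: float = 2.0
    fast_isi_ceiling_s: float = 0.25
    interruption_threshold: float = 1.5
    control_ic_spike_max: int = 10
    phase_bins: int = 100
    n_pca_components: int = 10
    k_clusters: int = 3
    bootstrap_iterations: int = 10_000
    alpha_phase: float = 0.01
    min_consecutive_bins: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("long_ic_burst_min_s", "slow_isi_ceiling_s",
                     "fast_isi_ceiling_s", "interruption_threshold"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.phase_bins < 2:
            raise ValidationError("phase_bins must be at least 2")
        if self.control_ic_spike_max <= 0 or self.k_clusters < 1:
            raise ValidationError("control_ic_spike_max and k_clusters must be positive")


# ---------------------------------------------------------------------------
# Windowing

#: Settle-in period excluded at the start of every incubation, seconds.
SETTLE_EXCLUSION_S = 60.0
MAX_SEGMENTS = 4


def segment_windows(rec: Recording, cfg: AnalysisConfig | None = None
                    ) -> list[SegmentWindow]:
    """Four successive nonoverlapping 200-s windows of an incubation.

    Segment ``k`` spans ``[incubation_start + 60 + 200k, ... + 200)``; with
    the default 900-s incubation the four windows cover 800 of the 840 s
    remaining after the 60-s settle-in exclusion (95%).

    Shorter incubations yield fewer windows (with a warning); an incubation
    too short for even one window is an error.
    """
    base = rec.incubation_start + SETTLE_EXCLUSION_S
    available = rec.incubation_duration - SETTLE_EXCLUSION_S
    n = min(MAX_SEGMENTS, int(available // SegmentWindow.SEGMENT_LENGTH_S))
    if n < 1:
        raise ValidationError(
            f"incubation of {rec.incubation_duration} s is too short for one "
            f"200-s segment after the {SETTLE_EXCLUSION_S:.0f}-s exclusion"
        )
    if n < MAX_SEGMENTS:
        logger.warning(
            "incubation of %.0f s yields only %d of %d segments",
            rec.incubation_duration, n, MAX_SEGMENTS,
        )
    length = SegmentWindow.SEGMENT_LENGTH_S
    return [SegmentWindow(k, base + k * length, base + (k + 1) * length)
            for k in range(n)]


def slice_train(train: SpikeTrain, window) -> SpikeTrain:
    """Restrict a train to spikes with ``start <= t < stop`` (half-open)."""
    start, stop = window.start, window.stop
    lo, hi = np.searchsorted(train.times, [start, stop], side="left")
    return SpikeTrain(train.neuron, train.times[lo:hi],
                      t_start=start, t_stop=stop)


# ---------------------------------------------------------------------------
# File I/O

SPIKE_COLUMNS = ("neuron", "time_s")
MANIFEST_KEYS = ("subject_id", "condition", "incubation_start_s",
                 "incubation_duration_s")


def read_recording(spike_csv_path, manifest_path) -> Recording:
    """Load a recording from a spike CSV and a YAML/JSON manifest.

    The CSV has header ``neuron,time_s`` with one spike per row; the manifest
    supplies ``subject_id, condition, incubation_start_s,
    incubation_duration_s``.
    """
    with open(manifest_path, "r", encoding="utf-8") as fh:
        manifest = yaml.safe_load(fh)
    missing = [k for k in MANIFEST_KEYS if k not in manifest]
    if missing:
        raise FormatError(f"manifest {manifest_path} missing keys: {missing}")

    df = pd.read_csv(spike_csv_path, float_precision="round_trip")
    if not set(SPIKE_COLUMNS).issubset(df.columns):
        raise FormatError(
            f"spike CSV {spike_csv_path} must have columns {SPIKE_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    unknown = set(df["neuron"].unique()) - set(NEURONS)
    if unknown:
        raise ValidationError(f"unknown neuron labels in spike CSV: {sorted(unknown)}")
    if df.empty:
        logger.warning("spike CSV %s contains no spikes", spike_csv_path)

    t0 = float(manifest["incubation_start_s"])
    dur = float(manifest["incubation_duration_s"])
    trains: dict[str, SpikeTrain] = {}
    for neuron, grp in df.groupby("neuron", sort=True):
        times = np.sort(grp["time_s"].to_numpy(dtype=float))
        dup = np.flatnonzero(np.diff(times) <= 0)
        if dup.size:
            raise ValidationError(
                f"duplicate spike time for neuron {neuron} at t={times[dup[0]]:.6f} s"
            )
        t_start = min(times[0], t0)
        t_stop = max(times[-1], t0 + dur)
        trains[str(neuron)] = SpikeTrain(str(neuron), times, t_start, t_stop)
    return Recording(
        subject_id=str(manifest["subject_id"]),
        condition=str(manifest["condition"]),
        incubation_start=t0,
        incubation_duration=dur,
        trains=trains,
    )


def write_recording(rec: Recording, spike_csv_path, manifest_path) -> None:
    """Inverse of :func:`read_recording` (round-trips on valid inputs)."""
    rows = [(name, t)
            for name in sorted(rec.trains)
            for t in rec.trains[name].times]
    # full precision so read_recording(write_recording(rec)) is identity
    pd.DataFrame(rows, columns=list(SPIKE_COLUMNS)).to_csv(
        spike_csv_path, index=False, float_format="%.17g")
    manifest = {
        "subject_id": rec.subject_id,
        "condition": rec.condition,
        "incubation_start_s": rec.incubation_start,
        "incubation_duration_s": rec.incubation_duration,
    }
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir,
                  summary: Mapping | None = None) -> list[Path]:
    """Write one CSV per result table plus a JSON summary.

    Column order is preserved deterministically; reals are written with 12
    significant digits so a round-trip read reproduces them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for name, table in tables.items():
        path = out_dir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.12g")
        paths.append(path)
    summary_path = out_dir / "summary.json"
    with open(summary_path, "w", encoding="utf-8") as fh:
        json.dump({} if summary is None else dict(summary), fh, indent=2,
                  sort_keys=True, default=_json_default)
    paths.append(summary_path)
    return paths


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
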