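"""Per-segment feature vectors, clustering into rhythm states, and labels.

Each 200-s segment of an incubation is summarised by a fixed-length
120-feature vector: for each of the five analysed neurons (IC, PD, LG, DG,
AM), ten ISI deciles, ten deciles of spike phase within the gastric mill
cycle, the mean intraburst firing rate, the ratio of second- to first-order
ISI variability, the ratio of the largest to second-largest ISI, and a
burstiness index in [0, 1].

Vectors are z-scored across the dataset, projected onto the top ten
principal components, and clustered with k-means (k = 3).  Clusters are
mapped onto the three rhythm categories — GMR (gastric mill rhythm),
IRREGULAR, NONE — by an explicit rule on per-segment long-IC-burst counts;
an interpretable rule-based classifier over the cycle metrics provides an
independent check of that mapping.  A 2-D t-SNE embedding is provided for
visualisation only and plays no role in classification.

Features that are undefined for a segment (too few spikes, no gastric
cycles) carry a NaN sentinel and are imputed at the dataset mean (z-score
0) during model fitting, so inactive segments remain featurizable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bursts import Burst, detect_bursts
from .core import AnalysisConfig, Recording, SegmentWindow, ValidationError, slice_train
from .cycles import GastricCycle, IncubationAnalysis, analyze_incubation

logger = logging.getLogger(__name__)

FEATURE_NEURONS = ("IC", "PD", "LG", "DG", "AM")
CATEGORIES = ("GMR", "IRREGULAR", "NONE")
N_DECILES = 10
FEATURES_PER_NEURON = 2 * N_DECILES + 4
N_FEATURES = FEATURES_PER_NEURON * len(FEATURE_NEURONS)

DECILE_PROBS = np.arange(1, N_DECILES + 1) / N_DECILES

#: ISI ceiling context used for the intraburst-rate feature: IC, LG and DG
#: are read with the slow gastric ceiling, PD and AM with the fast one.
_FEATURE_GASTRIC_CONTEXT = {"IC": True, "PD": False, "LG": True,
                            "DG": True, "AM": False}


def feature_names() -> list[str]:
    names = []
    for neuron in FEATURE_NEURONS:
        names += [f"{neuron}_isi_decile_{i}" for i in range(1, N_DECILES + 1)]
        names += [f"{neuron}_phase_decile_{i}" for i in range(1, N_DECILES + 1)]
        names += [f"{neuron}_intraburst_rate_hz", f"{neuron}_isi2_over_isi1",
                  f"{neuron}_max_isi_ratio", f"{neuron}_burstiness"]
    return names


FEATURE_NAMES = feature_names()


# ---------------------------------------------------------------------------
# Scalar features

def burstiness(isis) -> float:
    """Largest jump between sorted ISIs over the ISI at the jump, in [0, 1].

    Sort the ISIs ascending, find the consecutive pair with the maximum
    difference, and divide that difference by the larger member of the
    pair.  Values near 1 indicate a clear separation between short
    within-burst and long between-burst intervals; 0 means perfectly
    regular spiking.  NaN when fewer than two ISIs are available.
    """
    s = np.sort(np.asarray(isis, dtype=float))
    if s.size < 2:
        return np.nan
    diffs = np.diff(s)
    i = int(np.argmax(diffs))
    return float(diffs[i] / s[i + 1]) if s[i + 1] > 0 else np.nan


def isi_order_ratio(isis) -> float:
    """Second-order over first-order ISI variability.

    Mean absolute difference of consecutive ISIs divided by the mean ISI;
    0 for perfectly regular spiking.  NaN for fewer than two ISIs
    (three spikes).
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return np.nan
    mean_isi = float(np.mean(isis))
    if mean_isi <= 0:
        return np.nan
    return float(np.mean(np.abs(np.diff(isis)))) / mean_isi


def max_ratio(isis) -> float:
    """Largest over second-largest ISI (>= 1); NaN for fewer than two ISIs."""
    isis = np.asarray(isis, dtype=float)
    if isis.size < 2:
        return np.nan
    top = np.partition(isis, -2)[-2:]
    second, largest = float(top[0]), float(top[1])
    return largest / second if second > 0 else np.nan


def deciles(values) -> np.ndarray:
    """Ten linear-interpolation quantiles at p = 0.1, 0.2, ..., 1.0.

    Turns a variable-length sample into a fixed-length non-decreasing
    summary; an empty sample yields ten NaN sentinels.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return np.full(N_DECILES, np.nan)
    return np.quantile(values, DECILE_PROBS)


def phase_of_spikes(train, gastric_cycles: list[GastricCycle]) -> np.ndarray:
    """Phase in [0, 1) of each spike inside a gastric cycle.

    Phase 0 is the cycle-defining IC burst onset; spikes outside every
    cycle are dropped.
    """
    if not gastric_cycles:
        logger.warning("no gastric cycles; phase features undefined")
        return np.empty(0)
    phases = []
    for cyc in gastric_cycles:
        lo, hi = np.searchsorted(train.times, [cyc.onset, cyc.stop], side="left")
        phases.append((train.times[lo:hi] - cyc.onset) / cyc.period)
    return np.concatenate(phases) if phases else np.empty(0)


# ---------------------------------------------------------------------------
# Per-segment featurization

def featurize_segment(rec: Recording, window: SegmentWindow,
                      cfg: AnalysisConfig | None = None,
                      analysis: IncubationAnalysis | None = None) -> np.ndarray:
    """The 120-length feature vector of one 200-s segment.

    ISI features come from the spikes inside the window; phase features are
    computed against the gastric cycles whose onset lies in the window
    (cycle-defining long IC bursts after prepeak removal, detected over the
    whole incubation).  Deterministic: the same input yields an identical
    vector, and shifting all spike times together leaves it unchanged.
    """
    from .bursts import ceiling_for  # local to avoid cycle at import time

    cfg = cfg or AnalysisConfig()
    ana = analysis or analyze_incubation(rec, cfg)
    cycles = [c for c in ana.gastric_cycles if window.contains(c.onset)]

    out = np.full(N_FEATURES, np.nan)
    for j, neuron in enumerate(FEATURE_NEURONS):
        train = rec.trains.get(neuron)
        if train is None:
            logger.warning("neuron %s absent; its feature block is sentinel",
                           neuron)
            continue
        seg = slice_train(train, window)
        isis = seg.isis
        base = j * FEATURES_PER_NEURON
        out[base:base + N_DECILES] = deciles(isis)
        out[base + N_DECILES:base + 2 * N_DECILES] = deciles(
            phase_of_spikes(seg, cycles) if cycles else np.empty(0))
        ceiling = ceiling_for(neuron, _FEATURE_GASTRIC_CONTEXT[neuron], cfg)
        bursts = detect_bursts(seg, ceiling)
        out[base + 2 * N_DECILES] = (
            float(np.mean([b.rate_hz for b in bursts])) if bursts else np.nan)
        out[base + 2 * N_DECILES + 1] = isi_order_ratio(isis)
        out[base + 2 * N_DECILES + 2] = max_ratio(isis)
        out[base + 2 * N_DECILES + 3] = burstiness(isis)
    return out


# ---------------------------------------------------------------------------
# Clustering

@dataclass
class ClusterModel:
    """z-score -> PCA -> k-means model with a cluster-to-category mapping."""

    center: np.ndarray
    scale: np.ndarray
    components: np.ndarray            # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    centroids: np.ndarray             # (k, n_components)
    mapping: dict[int, str]
    seed: int

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        X = (np.asarray(vectors, dtype=float) - self.center) / self.scale
        X = np.nan_to_num(X, nan=0.0, posinf=0.0, neginf=0.0)
        return X @ self.components.T

    def predict(self, vectors: np.ndarray) -> np.ndarray:
        Z = self.transform(vectors)
        d = ((Z[:, None, :] - self.centroids[None, :, :]) ** 2).sum(axis=2)
        return np.argmin(d, axis=1)

    def categorize(self, vectors: np.ndarray) -> list[str]:
        return [self.mapping[int(c)] for c in self.predict(vectors)]

    def to_json(self, path) -> None:
        payload = {
            "center": self.center.tolist(), "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "centroids": self.centroids.tolist(),
            "mapping": {str(k): v for k, v in self.mapping.items()},
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClusterModel":
        with open(path, "r", encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(np.array(p["center"]), np.array(p["scale"]),
                   np.array(p["components"]),
                   np.array(p["explained_variance_ratio"]),
                   np.array(p["centroids"]),
                   {int(k): v for k, v in p["mapping"].items()}, p["seed"])


def fit_cluster_model(vectors: np.ndarray, cfg: AnalysisConfig | None = None,
                      long_burst_counts=None, period_cvs=None) -> ClusterModel:
    """Fit z-score -> top-10 PCA -> k-means (k = 3) on segment vectors.

    z-scoring uses the dataset mean and sample SD per feature (NaN-aware);
    zero-variance features are neutralised (z = 0) with a warning.  k-means
    runs 50 restarts from the fixed seed and keeps the best inertia.

    ``long_burst_counts`` (per-segment long IC burst counts, aligned with
    ``vectors``) drives the cluster-to-category mapping: the cluster with
    the lowest mean count is NONE, the highest is GMR (ties broken toward
    the lower ``period_cvs``), the remainder IRREGULAR.  Without counts the
    mapping is left as identity cluster labels.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    cfg = cfg or AnalysisConfig()
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2:
        raise ValidationError("vectors must be a 2-D array")
    if X.shape[0] < cfg.k_clusters:
        raise ValidationError(
            f"need at least {cfg.k_clusters} vectors, got {X.shape[0]}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = np.nanmean(X, axis=0)
        scale = np.nanstd(X, axis=0, ddof=1)
    center = np.nan_to_num(center, nan=0.0)
    zero_var = ~(scale > 0)
    if zero_var.any():
        logger.warning("%d zero-variance features neutralised in z-scoring",
                       int(zero_var.sum()))
        scale = np.where(zero_var, 1.0, scale)
    scale = np.nan_to_num(scale, nan=1.0)
    Z = np.nan_to_num((X - center) / scale, nan=0.0)
    if not np.any(np.std(Z, axis=0) > 0):
        raise ValidationError("all feature vectors identical; cannot cluster")

    n_comp = min(cfg.n_pca_components, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, random_state=cfg.rng_seed)
    P = pca.fit_transform(Z)
    ev = float(pca.explained_variance_ratio_.sum())
    if ev <= 0.95:
        # the original dataset's top-10 components explained >95% of total
        # variance; datasets with flatter spectra are fitted anyway
        logger.warning("retained components explain %.1f%% of variance "
                       "(< 95%%)", 100 * ev)
    km = KMeans(n_clusters=cfg.k_clusters, n_init=50,
                random_state=cfg.rng_seed)
    labels = km.fit_predict(P)

    mapping = {c: str(c) for c in range(cfg.k_clusters)}
    if long_burst_counts is not None:
        mapping = map_clusters(labels, np.asarray(long_burst_counts, float),
                               None if period_cvs is None
                               else np.asarray(period_cvs, float),
                               cfg.k_clusters)
    return ClusterModel(center=center, scale=scale,
                        components=pca.components_,
                        explained_variance_ratio=pca.explained_variance_ratio_,
                        centroids=km.cluster_centers_, mapping=mapping,
                        seed=cfg.rng_seed)


def map_clusters(labels: np.ndarray, long_burst_counts: np.ndarray,
                 period_cvs: np.ndarray | None, k: int) -> dict[int, str]:
    """Assign rhythm categories to clusters from per-segment burst counts.

    The cluster whose members have the highest mean long-IC-burst count
    (ties broken by the lowest mean cycle-period CV) is the gastric mill
    rhythm; the lowest-count cluster is NONE; any remainder is IRREGULAR.
    """
    means, cvs = {}, {}
    for c in range(k):
        sel = labels == c
        means[c] = float(np.mean(long_burst_counts[sel])) if sel.any() else -1.0
        if period_cvs is not None and sel.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cvs[c] = float(np.nanmean(period_cvs[sel]))
        else:
            cvs[c] = np.nan
    order = sorted(range(k), key=lambda c: (means[c],
                                            -cvs[c] if np.isfinite(cvs[c]) else 0.0))
    mapping = {order[0]: "NONE", order[-1]: "GMR"}
    for c in order[1:-1]:
        mapping[c] = "IRREGULAR"
    return mapping


def embed_2d(vectors: np.ndarray, model: ClusterModel,
             cfg: AnalysisConfig | None = None) -> np.ndarray:
    """2-D t-SNE layout of the PCA scores, for plotting only."""
    from sklearn.manifold import TSNE

    cfg = cfg or AnalysisConfig()
    Z = model.transform(vectors)
    perplexity = min(30.0, max(2.0, (Z.shape[0] - 1) / 3))
    tsne = TSNE(n_components=2, perplexity=perplexity,
                random_state=cfg.rng_seed, init="pca")
    return tsne.fit_transform(Z)


# ---------------------------------------------------------------------------
# Rule-based categories and transitions

def segment_categories(rec: Recording, cfg: AnalysisConfig | None = None,
                       analysis: IncubationAnalysis | None = None
                       ) -> list[str]:
    """Rule-based rhythm category of every segment of an incubation.

    GMR requires at least three gastric cycles starting in the segment with
    mean period below 40 s, an LG and an AM burst in every cycle, a DG
    burst in at least half the cycles (1:2 IC:DG patterns allowed), and on
    average at least one interrupted pyloric cycle per gastric cycle.
    NONE means no long IC burst started in the segment; anything else is
    IRREGULAR.
    """
    from .core import segment_windows

    cfg = cfg or AnalysisConfig()
    ana = analysis or analyze_incubation(rec, cfg)
    cats = []
    for w in segment_windows(rec, cfg):
        cats.append(_rule_category(ana, w))
    return cats


def _rule_category(ana: IncubationAnalysis, window) -> str:
    long_in_window = [b for b in ana.long_ic_bursts
                      if window.start <= b.onset < window.stop]
    if not long_in_window:
        return "NONE"
    cycles = [c for c in ana.gastric_cycles
              if window.start <= c.onset < window.stop]
    if len(cycles) >= 3 and float(np.mean([c.period for c in cycles])) < 40.0:
        lg_ok = all(c.member_bursts.get("LG") for c in cycles)
        am_ok = all(c.member_bursts.get("AM") for c in cycles)
        dg_ok = (sum(1 for c in cycles if c.member_bursts.get("DG"))
                 >= 0.5 * len(cycles))
        n_interrupted = sum(1 for c in ana.pyloric_cycles
                            if c.is_interrupted
                            and window.start <= c.onset < window.stop)
        if lg_ok and am_ok and dg_ok and n_interrupted >= len(cycles):
            return "GMR"
    return "IRREGULAR"


def rule_based_category(rec: Recording, window: SegmentWindow,
                        cfg: AnalysisConfig | None = None,
                        analysis: IncubationAnalysis | None = None) -> str:
    """Rule-based category of a single segment (see :func:`segment_categories`)."""
    cfg = cfg or AnalysisConfig()
    ana = analysis or analyze_incubation(rec, cfg)
    return _rule_category(ana, window)


@dataclass
class TransitionSummary:
    """Segment-to-segment category transition counts and persistence."""

    counts: pd.DataFrame
    n_incubations: int
    n_persistent_gmr: int             # all segments GMR
    n_with_gmr: int                   # at least one GMR segment
    nonadjacent_transitions: list[tuple[str, str]] = field(default_factory=list)


def transition_table(label_sequences) -> TransitionSummary:
    """Transition counts over consecutive-segment category labels.

    ``label_sequences`` is one label list per incubation.  Direct
    GMR <-> NONE transitions skip the intermediate IRREGULAR state; they are
    recorded and flagged as non-adjacent but are not errors.
    """
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    summary = TransitionSummary(counts=counts,
                                n_incubations=0, n_persistent_gmr=0,
                                n_with_gmr=0)
    for labels in label_sequences:
        labels = list(labels)
        summary.n_incubations += 1
        if labels and all(lab == "GMR" for lab in labels):
            summary.n_persistent_gmr += 1
        if any(lab == "GMR" for lab in labels):
            summary.n_with_gmr += 1
        for a, b in zip(labels, labels[1:]):
            counts.loc[a, b] += 1
            if {a, b} == {"GMR", "NONE"}:
                summary.nonadjacent_transitions.append((a, b))
    return summary
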