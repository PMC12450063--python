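# Methods

This note documents the analysis conventions, the synthetic-data model, the
numerical choices, and the limitations of `gastromill`.

## Analysis conventions

**Time and intervals.** All times are seconds (float64).  Every window and
cycle interval is half-open `[start, stop)`, so a spike or burst onset on a
boundary is counted exactly once.  Bursts are assigned to windows by the
*onset-owns* rule: a burst truncated by a segment boundary belongs to the
segment containing its onset.

**Burst definition.** A burst is a maximal run of spikes in which no
interspike interval exceeds the class ceiling (strict comparison: a gap
equal to the ceiling keeps the run together).  Ceilings: 2 s for LG, DG and
gastric-mill-timed IC bursts; 0.25 s for all other neurons and for
pyloric-timed IC activity.  Runs of fewer than two spikes are tonic, not
bursts — the intraburst rate (n − 1)/duration is undefined for singletons.
A consequence worth knowing: the *number of bursts* is not monotone in the
ceiling (two isolated spikes merge into a new burst when the ceiling rises
past their gap); the number of spike groups is.

**Long IC bursts and prepeaks.** The long-burst threshold is ≥ 1 s
*inclusive* (`long_ic_burst_min_s`, configurable; usage in the literature
wavers between "≥ 1 s" and "> 1 s").  A burst of 1–2 s followed within 5 s
by a > 2 s burst is a prepeak: it is excluded from cycle-period onsets but
retained in burst-count, duration and rate statistics, and its spikes are
binned into the cycle that contains it.

**Interruptions.** The control pyloric period is the arithmetic mean over
all cycles of the incubation with < 10 IC spikes (a global baseline, not a
running one).  A cycle at ≥ 150% of that mean is an interruption.  IC
spikes are assigned to pyloric cycles by the half-open interval between
consecutive PD onsets.

**Windowing.** Analysis starts 60 s after incubation onset (settle-in
exclusion).  Four 200-s segments cover 800 of the remaining 840 s of a
900-s incubation.  Whole-incubation summaries use everything from +60 s to
the incubation end.

## Segment features and clustering

Each segment yields 24 features per neuron (IC, PD, LG, DG, AM; 120
total): 10 ISI deciles, 10 phase deciles, mean intraburst rate, the
second-/first-order ISI ratio, the max/second-max ISI ratio, and
burstiness.

Numerical definitions where the field's usage is loose:

- **Deciles** are the 10 linear-interpolation quantiles at p = 0.1 … 1.0
  (10 summary values, not 9 cut points), keeping the per-neuron block at
  24 and the vector at 120.
- **Burstiness** sorts the ISIs, finds the consecutive pair with the
  largest difference, and returns that difference divided by the larger
  member — in [0, 1), 0 for regular spiking.
- **Second-/first-order ISI ratio** is defined here as the mean absolute
  difference of consecutive ISIs divided by the mean ISI (0 for regular
  spiking).  This is an explicit stand-in: the originating literature names
  the ratio without defining it, and this contract is the one implemented
  and tested.
- **Intraburst rate** reads IC, LG and DG with the slow ceiling and PD and
  AM with the fast one.

Features undefined for a segment (too few spikes, no gastric cycles) carry
NaN and are imputed at the dataset mean — z-score 0 — during fitting, so
quiescent segments remain featurizable.  z-scoring uses the sample SD
(ddof = 1); zero-variance features are neutralised with a warning.

Clustering is PCA (top 10 components) then k-means (k = 3, 50 restarts,
fixed seed, best inertia).  On the original dataset the 10 components
explained > 95% of total variance; on the default synthetic batch they
explain ~90–92% (the generator's independent within-burst jitter spreads
variance across many features more evenly than correlated real
recordings), so the model records and warns on, rather than asserts, that
figure.  Clusters are mapped to categories by an explicit rule — lowest
mean long-IC-burst count → NONE, highest (ties broken by lower period CV)
→ GMR, remainder → IRREGULAR — because a reproducible pipeline cannot rely
on the original "conceptual" assignment.  The 2-D t-SNE embedding
(perplexity ≤ 30, fixed seed) is for plotting only and never classifies.

An interpretable rule-based classifier validates the mapping: GMR needs
≥ 3 gastric cycles in the segment with mean period < 40 s, an LG and AM
burst in every cycle, DG in at least half (1:2 IC:DG patterns occur), and
≥ 1 interruption per gastric cycle on average; NONE means no long IC burst
in the segment; the rest is IRREGULAR.

## Phase analysis

Cycles are divided into 100 bins from one cycle-defining IC burst onset to
the next.  Per segment, mean spike counts per bin are divided by the
*average* bin duration (mean cycle period within the segment / 100) —
per-cycle bin durations are not used, matching the normalisation's purpose
of removing cycle-period differences across incubations.  Averaging runs
segment → experiment → condition, restricted to rhythm-classified
segments.

The cross-condition heuristic (α = 0.01, different from both other
conditions, ≥ 2 consecutive bins) is deliberately not a formal FWER
correction; a regression test bounds its null flag rate.  The bootstrap
unit is the experiment-level profile; one resample index set is shared
across bins within a comparison, which preserves across-bin correlation.

## Statistics

- **Odds ratios** use the Woolf log-normal CI by default.  The odds ratios
  recomputed from published segment counts do not all match the published
  roundings (e.g. 10.7 recomputed vs 11.5 printed for unfed hemolymph vs
  saline; 52.5% vs "55%" of segments); the package always reports the
  recomputed value.  The published CI construction is not reproducible
  from the printed counts by any standard method, so the CI engine is a
  reporting convenience, not a reproduction.
- **Bootstrap CIs** use the basic (reverse-percentile) method, 10,000
  iterations by default, cascading 95 → 99 → 99.9 → 99.99 → 99.999% while
  the interval excludes zero.  The basic method does not guarantee
  `low ≤ point ≤ high` for skewed resampling distributions and slightly
  undercovers at small n (measured ~93–94% at n = 20 for a nominal 95%).
- **Unbiased Cohen's d** is Hedges-corrected, J = 1 − 3/(4·df − 1) with
  df = nₐ + n_b − 2.
- **Friedman/Kendall's W** is implemented directly (tie-corrected
  midranks, χ² = n(k − 1)W) because the scipy implementation refuses the
  paired k = 2 design, which is used here; at k = 2 the statistic reduces
  to a sign-test-like quantity.  Agreement with scipy is exact at k ≥ 3.
- **Repeated-measures correlation** subject-demeans both variables;
  r_rm carries the common slope's sign, dof = N − k − 1, CI by Fisher z.
  It matches the rmcorr/pingouin implementation exactly where the latter
  applies, and additionally supports two-subject designs.
- **Equal-slopes ANCOVA** tests the group × covariate interaction first;
  when homogeneous, it reports covariate-adjusted means at the grand-mean
  covariate with Holm–Šidák-corrected pairwise contrasts.  The per-group
  "identity line" check — predicting responses from the common-slope model
  and comparing them against the baseline values with an independent-samples
  t test — follows the source procedure literally; it is *not* a standard
  lack-of-fit test and should be read as the original study's construction.

## Synthetic-data model

The generator emulates the six analysed neurons under three states.  It is
a descriptive event-layout model, not a biophysical one: no conductances,
no temperature effects, and no GM/MG/VD spikes (those neurons do not
participate in this rhythm variant).

- **FULL**: gastric cycle periods from a normal distribution (mean 14 s,
  CV 0.18) truncated to [0.6, 1.5]× the mean; each cycle has a long IC
  burst (mean 2.5 s, ≥ 1.3 s, spikes on a jittered regular grid at 24 Hz),
  an LG burst at cycle onset (~3 s, 5 Hz), an AM burst co-extensive with
  IC (8 Hz), a DG burst from IC burst end to ~45% of the cycle (14 Hz),
  and with probability 0.2 a prepeak (1.1–1.9 s) ending 2.5–4.5 s before
  the main burst.  The pyloric rhythm runs at 1.1 s ± 3% jitter; any
  pyloric cycle overlapping a long IC burst has its period multiplied by
  the interruption factor (default 1.8).  LPG bursts in antiphase with PD
  and doubles its duty cycle mid-gastric-cycle; PD and LPG pyloric-timed
  activity pauses appropriately during interruptions.  IC also fires brief
  (0.15 s) pyloric-timed bursts every third pyloric cycle.
- **IRREGULAR**: periods from mean 48 s, CV 0.37, truncated below at 40 s —
  the defining bound for an irregular rhythm — with per-neuron burst
  dropout (default 0.25) producing intermittency; no prepeaks.
- **NONE**: pyloric activity only; all IC bursts < 0.5 s; LG/DG/AM fire
  sparse tonic spikes (gaps ≥ 3 s).

Two layout guards make the ground truth exactly recoverable from the
emitted spikes, which is the generator's purpose: every gastric-mill-timed
IC event keeps > 2.2 s of silence from any other IC event (so the 2-s
ceiling neither merges nor splits events against the truth), and
pyloric-timed IC bursts are suppressed within 2.5 s of gastric events.
Intraburst spikes sit on a jittered regular grid rather than a Poisson
process for the same reason: the downstream definitions are ISI ceilings,
and grid spiking keeps every burst unambiguous under them.  Truncating the
FULL period at 0.6× the mean keeps the prepeak rule unambiguous (a short
main burst can never fall within 5 s of the next cycle's burst).

Choices where the emulated conditions state no value: IC intraburst rate
24 Hz (reported range 21–28 Hz), interruption factor 1.8 (criterion is
≥ 1.5; 1.8 gives the detection margin a real interruption shows), LG/DG/AM
rates and durations in the ranges of the reported per-neuron burst tables,
pyloric jitter ±3%.  Batch generation allocates states by deterministic
largest-remainder rounding interleaved across subjects, and each subject
draws from an independent child stream of the batch seed.

**What passing tests do and do not show.**  The generator produces
noise-free, well-separated states: burst boundaries are unambiguous, every
FULL segment satisfies the rhythm definition, and category recovery is
essentially perfect.  Real recordings have spike-sorting errors, drifting
periods, partially coordinated cycles and borderline segments; exact
ground-truth recovery and 100% classification agreement on synthetic data
therefore validate the *bookkeeping* (definitions, thresholds, windowing,
feature arithmetic, model plumbing), not the discriminability of real
rhythm states.  Quantities that depend on the raw study recordings (the
per-neuron burst parameter tables, real phase profile shapes, published
r_rm values) are out of reach by construction and are not claimed.

## Problem sizes

Default tests and the acceptance script use 900-s incubations, 12–20
subject batches, 500–800 bootstrap-coverage replicates, and 800–10,000
bootstrap iterations depending on the analysis — sizes chosen so the whole
suite runs in well under a minute of compute per property while keeping
Monte-Carlo noise far below the tested tolerances.

## Known limitations

- Single-condition runs skip odds ratios (nothing to compare) and the
  three-condition phase heuristic requires exactly three conditions.
- The interruption rule needs at least one control cycle; an incubation
  whose every pyloric cycle carries ≥ 10 IC spikes leaves interruption
  flags unset (warned).
- χ² distribution tests error on tables with zero expected counts rather
  than silently correcting; use the odds machinery's continuity option for
  zero cells.
- Input spike times must be in seconds; no millisecond dialect or
  proprietary acquisition formats are read, and spike sorting is assumed
  done.
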