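# Methods

This note documents the models, conventions and numerical choices behind
each module, the design decisions taken where the underlying protocols are
open to interpretation, and the known limitations. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Up–down (Dixon) thresholds (`vonfrey`)

**Model.** The staircase presents log-spaced von Frey filaments, stepping
down after a withdrawal (X) and up after a non-withdrawal (O), and ends a
fixed number of presentations after the first response change (default 4;
configurable, since conventions vary between 4 and 5). The 50% withdrawal
threshold is `10^(log10(last filament, g) + 0.3·k)`, where 0.3 is the
nominal log10 spacing of the series and `k` depends on the terminal
response pattern.

**The k table.** The classical pattern→k tables are derived from a normal
tolerance model: `P(withdraw at dose x) = Φ(x − μ)` with doses in units of
one step and σ equal to one step. We regenerate the constants by that same
construction: for each pattern (the response string from just before the
first change to the end), the dose walk is reconstructed, μ is estimated by
maximum likelihood (bounded scalar minimization of the exact probit
negative log-likelihood, tolerance 1e-10), and `k = μ̂ − x_last` in step
units. The packaged table (`data/updown_k_table.json`, patterns of 2–9
responses) is therefore *derived, not transcribed*; it can be rebuilt with
`build_k_table()` and overridden by the user. Mirror symmetry (swapping
X↔O flips the sign of k) holds by construction and is asserted in tests.

**Censoring.** A staircase with no response change is censored: all-O
sequences that reach the strongest filament get a ceiling estimate at the
maximum force; all-X sequences that reach the weakest get a floor estimate
at the minimum force. Censored estimates stay inside the physical filament
range rather than extrapolating beyond it — a deliberately conservative
choice.

**Estimator behavior.** Estimates take discrete values
(filament × 10^(0.3k)), so for a fixed true threshold the sampling
distribution of the estimate is atomic. Simulation studies therefore place
the true threshold on the filament grid and use a uniformly 0.3-log-spaced
series, the condition under which the formula's fixed 0.3 step matches the
actual spacing. Off-grid truths incur a quantization bias of up to half a
filament step, and non-uniform commercial filament sets (the default series
here averages ~0.25 log10 spacing) add a spacing-mismatch bias of similar
size; both are properties of the classical method, not of this
implementation. At a steep psychometric slope (15 logit units per log10
gram — >98% response accuracy one filament step from threshold) the median
estimate over 10,000 simulated staircases recovers an on-grid truth within
0.05 log10 units; the estimator-recovery metric in the acceptance script
uses exactly these conditions (n = 10,000, slope 15, truth at the 4th of 8
filaments).

**Weighted averages.** Longitudinal summaries use a time-weighted mean with
trapezoidal weights (interior points weigh half the sum of adjacent gaps;
boundary points half their single gap), which reduces to the arithmetic
mean on equally spaced days. This was chosen because assessment days in
long studies are irregular; a plain mean is available by passing equal
days. Threshold statistics are taken on log10 grams throughout.

## Behavioral scores (`behavior`)

WB% and SPT% are the printed formulas; SPT pools fluid volumes across the
two side-swapped nights (a single ratio of sums, not a mean of nightly
ratios), tolerating a single night with a warning. Gait metrics are
ipsi/contra ratios with per-metric missing values on zero denominators.

**Guarding index.** The source protocol references an external definition
without reproducing it, so the composite here is explicit and configurable:
the ipsi/contra ratio of the *weighted geometric mean* of stance time and
paw contact area, subtracted from 1. The geometric mean makes the index
scale correctly — proportionally halving ipsilateral loading gives exactly
0.5 — and it is 0 for symmetric gait, negative when the injured limb is
loaded more (permitted and meaningful). Monotonicity in ipsilateral loading
is property-tested.

## Actigraphy (`actigraphy`)

**Conventions.** 10-s epochs (any divisor of 3600 s is accepted); ZT0 =
lights on, dark phase ZT12–24; epochs are 0-based half-open intervals.
PIR count semantics vary by hardware, so binarization is configurable; the
default marks an epoch inactive iff its count is 0.

**Immobility-defined sleep.** Maximal runs of inactive epochs lasting
≥ 40 s (4 epochs) are immobility bouts — a rule validated against EEG in
prior literature. Everything else forms maximal *activity* segments, so
pauses shorter than the rule do not break an activity bout; this is the
complement interpretation that makes "long (>10 min) activity bouts"
well defined. The partition is exact (immobility + activity = stream) and
is tested against an independent run-length-encoding oracle.

**Profiles and phase summaries.** Hour-of-day profiles, IS and IV are
computed on whole ZT days only (partial days at stream ends are trimmed) so
hour-of-day means are unbiased. Long-bout fractions use a strict >10 min
duration cutoff intersected with the phase.

**IS / IV.** On the hourly immobility-fraction series (a flag switches to
activity):

    IS = n·Σ_h (x̄_h − x̄)² / (p·Σ_i (x_i − x̄)²),  p = 24 bins/day
    IV = n·Σ_{i≥2} (x_i − x_{i−1})² / ((n−1)·Σ_i (x_i − x̄)²)

IS is 1 for a perfectly repeated daily profile and ≈ 1/d for structureless
noise over d days; IV is ≈ 2 for white noise, 4 for strict alternation
(attained, n even), and small for smooth profiles (24/1150 ≈ 0.0209 for an
hourly ramp). Constant series raise an explicit "undefined (zero
variance)" error rather than returning a value.

**Lomb–Scargle.** The classical periodogram (scipy.signal.lombscargle on
the mean-centered series, divided by the series variance) over a period
grid of 16–32 h in 0.1-h steps. Both the grid peak and the power at the
point nearest 24 h are reported, since "rhythm power" is used in both
senses in the field. The peak's significance is the classical level
`1 − (1 − e^(−P))^M` with M the grid size; because the grid oversamples
the independent frequencies of a 2-week recording, this is conservative,
and it is labeled approximate. Constant series return power 0 with a
warning.

## Profiling and prediction (`profiling`)

The 1-SD rule uses the control group's sample SD (n−1) and an *inclusive*
boundary ("one SD or more"), in the direction of impairment declared per
assay. Classification is affine-invariant (property-tested). Cutoffs can be
computed within sex (the pipeline default) or pooled. Note the rule's
intrinsic operating point: an animal drawn from the control distribution
itself is flagged ~16% of the time, so estimated affected fractions sit
slightly above the planted fraction in calibration cohorts; recovery is
therefore assessed against the 95% binomial interval of the planted labels.

Correlation matrices report raw Pearson p-values (multiplicity correction
is applied only in the DEG correlation filter, where the protocol states
it); constant inputs yield an explicit undefined flag. Prediction uses the
time-weighted average of an early assay inside days 0–14 as the predictor
of a late outcome, on log10 scale for thresholds.

## DEG cascade (`deg`)

Normalization is plain CPM by column sum with a prior of 0.5 before log2 —
no TMM-style composition correction, a documented limitation (the
synthetic generator is composition-balanced, see below; real data with
large asymmetric regulation would need TMM). Low-expression filtering keeps
genes with CPM ≥ 1 in ≥ 50% of samples (inclusive).

- *Overall treatment model*: per-gene OLS `log2CPM ~ treatment + timing`
  (no interaction — the minimal identified model), two-sided t on the
  treatment coefficient, DEGs at nominal p < 0.05 plus the fold cutoff.
- *Nested late contrast*: Welch t between the late-timing groups, BH FDR
  across tested genes, q < 0.05 plus the fold cutoff.
- *Fold cutoff*: "1.2-fold change" is read on the linear scale,
  |log2FC| > log2 1.2 ≈ 0.263; a `fc_scale="log2"` flag selects the
  alternative reading (|log2FC| > 1.2) where that convention is wanted.
- *Phenotype filter*: keep genes whose Pearson p against the log10
  mechanical threshold beats Bonferroni over the tested set, and whose p
  against the guarding index is ≥ 0.05 (the exclusion arm is nominal —
  a Bonferroni-corrected exclusion would be nearly vacuous).
- *Set algebra* is exact, with a small expression language (`|`, `&`, `-`,
  parentheses); *delta ranking* selects genes with |Δ_early| > |Δ_late|
  (cell-mean differences on log2CPM), ranked by the excess, ties broken
  deterministically by gene id.
- Test statistics are ordinary (unmoderated) t statistics; an
  empirical-Bayes moderation hook is a natural extension point but not
  implemented.

The pipeline is invariant to gene-row and sample-column order, and the
log2FC sign convention (treated minus vehicle) is uniform across contrasts.

## Synthetic cohorts (`synth`)

The generator's purpose is calibration: it plants known structure and the
downstream stages must recover it.

**Behavioral trajectories.** Injury burden rises as
`b0(t) = drop·(1 − e^(−r·t))` (default drop 0.8, r 0.5/day: plateau within
a week, as joint-injury hypersensitivity develops). Treatment multiplies
burden by (1 − rescue) inside its windows; an early window (starting by
day 7) leaves a persistent residual rescue afterwards, while a late window
does not — reproducing the qualitative difference between early and late
intervention. A per-animal frailty factor `m = exp(σ_f·z)`, z ~ N(0,1),
enters as a survival-scale exponent, `B = 1 − (1 − b0)^m`, which is
monotone, never saturates, and makes log10(1 − B) — hence the log
threshold — exactly linear in m. Thresholds are
`baseline·(1 − B)` with log-normal noise; WB, affective durations scale
linearly in B. Emotional comorbidity `C = B·logistic((t − 90)/15)` emerges
around day 90 and drives sucrose preference and open-field center time.
Resilient animals (fraction configurable) never drop their sucrose
preference; resilience is thresholded on a susceptibility score
`(z + ε)/√2` so that it shares the frailty axis (correlation ≈ 0.7) while
keeping the marginal resilient fraction exact — this is what couples early
sensory burden to late anhedonia. With `frailty_sd = 0` the score has no
phenotypic consequence and the early→late null is exact, which the
type-I-rate calibration exploits.

**Activity streams.** A two-state (active/inactive) Markov chain per 10-s
epoch. Defaults: dark-phase stay-active 0.98 and become-active 0.02 (mean
activity bouts ~8 min, immobility ~8 min), light-phase 0.90/0.005 (short
activity, long immobility); become-active probabilities are modulated by
`1 + amplitude·cos(2π(ZT − 18)/24)` (clipped into (0,1) with a warning if
violated). Injury divides the dark-phase stay-active *odds* by
(1 + fragmentation), shortening dark activity bouts without touching the
light phase — fragmenting rhythms exactly along the axes the summary
statistics measure. Counts in active epochs are 1 + Poisson(3); PIR count
distributions are hardware-specific and this choice is a stand-in, which
is why the scoring default binarizes at zero.

**Counts.** Negative-binomial with dispersion (NB size) 10 — moderate
biological variability for bulk tissue; baseline log2CPM ~ N(4, 2);
library sizes log-normal around 2×10⁷ (deep bulk coverage). Planted
treatment DEGs shift the log2 mean by ±log2FC (default 1.5) in treated
samples; phenotype-linked genes have log2 mean linear in the sample's
log10 threshold (slope ±4 log2CPM per log10 g). Effect signs are assigned
by greedy mass balancing — fixed-fold balancing for treatment DEGs, equal
mass of +slope and −slope genes for covariate-linked genes — and expected
per-sample fractions are renormalized, so the planted effects are
composition-neutral and plain-CPM normalization leaves null genes
unbiased. The default sample sheet (8 per treatment×timing cell) gives
treated samples rescued thresholds (~0.4 g vs ~0.07 g) and a guarding
index that varies independently of treatment, so the correlation filter's
two arms are decoupled.

**What the generator does not emulate.** Real effect sizes, sex-specific
effect magnitudes, TMM-requiring composition shifts, batch effects,
overdispersion heterogeneity across genes, PIR sensor count distributions,
and within-animal assay correlations beyond the single frailty factor.
Passing calibration here shows the *pipeline's statistics* behave as
designed under their assumptions; it does not validate those assumptions
on real recordings.

**Reproducibility.** One root seed; per-animal and per-matrix child
generators are derived via `SeedSequence(seed, spawn_key=...)` counters,
so any subset regenerates without replaying the whole cohort. Identical
inputs give byte-identical outputs (asserted).

## Orchestration (`pipeline`, `cli`, `io`)

Stages run in dependency order, each consuming the previous stage's files;
the manifest records the config hash, seeds, per-stage row/gene counts,
package version and wall clock, and is written even on failure (partial
completion). Because the manifest carries wall-clock metadata it is
excluded from byte-level determinism comparisons; all data outputs are
bit-identical across reruns of the same config and seed. Defaults filling
protocol gaps are logged with an `ASSUMPTION` tag. Behavioral values may
be missing (NA propagates into pairwise-complete correlations); counts may
not. Problem sizes in the packaged demo and the acceptance script (cohorts
of 40 injured animals, 14-day streams, 2,000 genes × 32 samples, 100-seed
calibration loops) were chosen as the smallest sizes at which the planted
effects and calibration rates are statistically resolvable.
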