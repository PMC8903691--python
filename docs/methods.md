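# Methods

`megconn` re-implements, as a tested pipeline with synthetic ground truth, a
multi-frequency MEG effective-connectivity analysis of a two-group
(migraine patients vs healthy controls) emotional-stimuli experiment: sensor
recordings are band-pass filtered into the five canonical bands, projected
to source space with a beamformer, converted into a signed, directed,
thresholded connectivity graph per subject and band, summarized by four
graph metrics, and compared across groups with exact and rank-based
statistics.  This note documents the model, the estimation choices, and what
the synthetic validation does and does not establish.

## The analysis model

**Edge definition (correlation + t-threshold).**  For every pair of
virtual sensors the Pearson correlation

    R(X_a, X_b) = C(X_a, X_b) / (S_a S_b)

is computed on the trial-averaged evoked response inside the analysis window
(default 90–180 ms after the stimulus trigger).  Each correlation is
converted to a t value

    Tp = R * sqrt((K - 2) / (1 - R^2))

with `K` the number of data points entering the correlation, and the pair is
retained as an edge when the two-sided p-value of `Tp` under a Student t
distribution with `K - 2` degrees of freedom is below `alpha_edge`
(default 0.01).  Retained edges are signed by the correlation: positive =
excitatory, negative = inhibitory.

*Degrees-of-freedom honesty.*  The t-threshold assumes the `K` samples are
independent.  A band-limited signal of bandwidth `B` observed for `T`
seconds carries only about `2BT` independent samples; feeding the raw
sample count of an oversampled narrow-band window into the formula makes the
threshold wildly anticonservative (for the gamma band at 1000 Hz the window
holds 90 samples but only ~11 effective ones, and the nominal 1% threshold
then retains ~35% of null pairs).  The pipeline therefore decimates the
averaged evoked window to roughly `decimate_bw_factor` (default 2.5) times
the band width before the correlation stage, so `K` approximates the
effective sample count.  A floor of K ≥ 8 is kept; for the lowest bands a
90 ms window simply does not support a meaningful correlation estimate and
results there should be treated as exploratory regardless of the threshold
convention.

**Direction (multivariate Granger causality).**  For every retained pair,
direction is assigned by conditional Granger causality: an MVAR model is fit
by least squares over per-trial segments (lags never cross trial
boundaries), with the model order selected by BIC up to
`gc_max_lag_ms` worth of lags (default 20 ms at the working rate).  The GC
statistic for a→b is `ln(RSS_reduced / RSS_full)` for predicting b with and
without a's lags, F-tested at `gc_alpha` (default 0.05); one significant
direction gives a directed edge, both give a bidirectional edge, neither
leaves the edge undirected.  When the retained-source count exceeds
`gc_max_system` (default 20) the conditional model is downgraded to
pairwise GC, since a conditional fit over thousands of sources is neither
feasible nor identifiable.

Three deliberate asymmetries between the correlation and GC stages:

1. *GC runs on single trials, not the average.*  The trial-averaged evoked
   response is a deterministic repeated waveform; inside an autoregressive
   fit it acts as a common confound and manufactures spurious "causality".
   The per-trial ensemble mean is therefore subtracted before the GC fit.
2. *GC runs on notch-filtered broadband data, not the band-passed data.*
   Zero-phase (forward–backward) filtering mixes future samples into the
   past and provably corrupts directed inference; a causal filter distorts
   it less but still colors the residuals beyond what a low-order VAR can
   whiten.  Band selectivity already lives in the edge-definition stage, so
   directivity is estimated on the unbanded (DC-removed, notch-filtered)
   virtual sensors.
3. *Correlation runs on the zero-phase filtered average*, where zero phase
   is exactly what is wanted: no group delay relative to the trigger.

**Node roles and the pattern contrast.**  Nodes are labelled driver /
driven / mixed / isolated from their directed degrees.  The headline
group contrast is the presence of at least one directed edge from a
prefrontal (PFC) source to a temporal-lobe (TL) source; a bidirectional
edge contains that direction and counts.

**Graph metrics.**  Degree D, strength S (sum of |R| over incident edges),
characteristic path length L, and clustering coefficient C, all on the
undirected skeleton of the thresholded graph (S weighted, the rest
binarized).  L averages shortest-path hop counts over connected ordered
pairs; disconnected pairs are excluded (`L_mode="harmonic"` is available),
and a graph with no edges yields NaN rather than 0.  Nodes of degree < 2
contribute clustering 0 and are not dropped, so group means always compare
identical node sets.

**Group statistics.**  Pattern prevalence is compared with a two-sided
Fisher exact test (probability-summation convention; on the published
19/24 vs 8/24 table it reproduces p ≈ 0.003).  Metrics are compared with
pooled-variance Student t-tests.  Both Bonferroni families are reported —
alpha/5 = 0.01 for the five bands and alpha/20 = 0.0025 for bands ×
metrics — alongside Benjamini–Hochberg FDR rejection flags; the two
corrections are never merged.  Clinical covariates (headache history,
attack frequency, duration, VAS, HAM-A, HAM-D) are related to metrics
within the patient group by Spearman rank correlation (t approximation;
exact permutation p behind a flag for n ≤ 10).

## Source reconstruction

Virtual sensors come from a unit-gain scalar LCMV beamformer with diagonal
loading (`reg`, default 0.05 of the mean covariance diagonal).  Two
estimation choices matter enormously for connectivity and are therefore
configurable with safe defaults:

* **Covariance window** (`cov_window`, default `"baseline"`).  The classical
  LCMV filter built from task-window covariance actively cancels sources
  that are correlated with the target — precisely the sources a
  connectivity analysis cares about.  With strongly coupled sources the
  reconstructed correlation can even flip sign.  Estimating the covariance
  from the pre-stimulus baseline (noise) removes the cancellation at the
  cost of adaptivity.
* **Null constraints** (`null_constraints`, default on).  For a small grid
  the weights can place an explicit zero at every other modeled voxel,
  `W = C⁻¹G (GᵀC⁻¹G)⁻¹`, eliminating inter-source leakage — the dominant
  confound for both correlation and GC — at the price of some noise
  amplification.  This is only practical for small grids; large grids fall
  back to independent single-constraint filters.

Voxels closer than 10 mm are merged greedily in descending output power
(ties by lowest index); separation of exactly 10 mm keeps both.  Merging is
idempotent.

## The synthetic cohort generator

No subject-level recordings are publicly deposited, so validation rests on
a generator with exact ground truth.

**Sources.**  Eight sources at fixed head-like positions (2 PFC, 2 TL,
2 occipital, 2 parietal "other").  Each source is an AR(2) resonator
centred on the analysis band's centre frequency (pole radius 0.8, i.e. a
spectral bandwidth of roughly `(1-r)·sfreq/π` ≈ 60 Hz at the default
1000 Hz) driven by white Gaussian innovations.  Band-limiting through the
AR dynamics rather than by filtering the innovations keeps the joint
process an exact finite-order VAR: the Granger-causal ground truth is then
literal (the coupling coefficients), BIC recovers the true order, and the
GC F-test is calibrated on null pairs.  Band-shaping by filtering the
innovations instead is still available (`filter_innovations=True`) but
makes any finite-order VAR fit misspecified.

**Planted structure.**
* *Pattern edge (PFC→TL):* innovation correlation 0.95 between sources 0
  (PFC) and 2 (TL) plus a lag-1 coefficient of 0.15 from 0 to 2.  The split
  matters: narrow-band sources have an envelope memory of only ~5 samples,
  so a large *lagged* coefficient would decorrelate the pair (the coupled
  component arrives phase-shifted) and destroy the correlation edge the
  thresholding stage must find.  The zero-lag correlation carries the edge;
  the small lagged term carries the direction, and at the GC stage's sample
  sizes a coefficient of 0.15 is overwhelming evidence.
* *Background cluster:* PFC-1 and the posterior sources share a common
  innovation factor (pairwise correlation 0.85) plus weak directed
  occipital→frontal couplings — the excitatory anterior–posterior
  background both groups show.  A per-subject latent statistic u ~ U(0,1)
  sets how many optional cluster members are active, so the subject's true
  background degree and strength are monotone in u.
* *Clinical covariates:* drawn from the published group means/SDs, clipped
  at zero.  Within patients the named covariate (default HAM-D) is tied to
  u by a Gaussian copula with `r = 2 sin(π ρ_S / 6)`, planting a target
  Spearman correlation (default −0.5) without fixing marginals.  Spearman
  being invariant to monotone transforms, the planted value survives the
  marginal mapping exactly (up to the small zero-clipping tie mass).

**Measurement.**  Trials are stimulus-locked: sources are silent before the
trigger (so the pre-trigger interval is pure sensor noise — the baseline
covariance window used by the beamformer), and each trial carries a shared
"evoked" realization plus an independent "induced" realization of the same
VAR.  Sensors see a dipole-like distance-kernel gain (inverse-square
magnitude envelope, signed by a random source orientation projected on the
channel direction, log-normal gain jitter, unit-norm columns) on a
hemispherical cap, plus white sensor noise at `snr_db` (default 25 dB,
variance-ratio definition over the post-trigger interval; the realized SNR
is auditable from the silent baseline and is within 1 dB of the request).
The default is a deliberately clean, strong-source regime: at realistic
single-trial SNRs the shared projected sensor noise is instantaneously
correlated across virtual sensors, and with thousands of GC samples that
correlated measurement noise manufactures spurious bidirectional
"causality" (an errors-in-variables effect).  The generator's purpose is
verifiable ground truth, not noise realism; the limitation is stated below.

**Determinism.**  All randomness flows from the cohort seed through a
`SeedSequence` spawn tree; the same spec reproduces bit-identical cohorts,
and the pipeline's metrics tables are byte-identical across fresh runs.

## Problem sizes

Full study conditions are 24 patients + 24 controls, prevalences 19/24 and
8/24, 60 trials (the paradigm's per-category trial count) of 300 ms at
1000 Hz on 64 channels.  The repeated end-to-end validation (200 cohort
replicates in the test suite and acceptance script) runs the same
conditions at a smoke problem size — 48 channels, 40 trials of 240 ms —
chosen so one replicate completes in a few seconds on one CPU; single-run
examples use the full defaults.  The default sampling rate is 1000 Hz
rather than the hardware's 6000 Hz; 6000 is honored when configured.

## What the validation shows — and does not

The planted-recovery results establish that every stage does what it claims
on data whose ground truth is known exactly: the t-threshold retains planted
correlation edges and rejects null pairs at its nominal rate (once K is the
effective sample count), conditional GC recovers planted directions with a
calibrated null, the beamformer reconstructs well-separated sources, the
prevalence contrast survives to a significant Fisher decision in the
majority of replicates, and the planted clinical correlation is recovered
with the correct sign in essentially all of them.

They do not establish performance on real MEG: real data have non-white,
spatially structured noise, artifacts (ocular, cardiac, muscle), imperfect
forward models, thousands of candidate voxels rather than eight known
sources, source dynamics that are not finite-order VARs, and within-subject
condition structure (the three emotion conditions are modeled as
independent runs).  In particular the leakage-free reconstruction relies on
a known, small source model; with a realistic scanning grid the
null-constrained variant is unavailable and leakage corrections would be
needed.  The low-band (delta/theta) analyses inherit the fundamental
short-window limitation noted above.

## Known limitations and open choices

* "L represented the number of edges" in the source description conflicts
  with the standard characteristic-path-length definition; the standard
  definition is implemented and the discrepancy simply flagged.
* The correlation normalizer is read as the covariance (Pearson R) — the
  only reading consistent with a correlation coefficient in [-1, 1].
* Whether the published prevalence p-value is pre- or post-correction is
  ambiguous; the raw two-sided Fisher p is reported and the comparison
  threshold is configurable.
* The artifact-rejection rule (peak amplitude over 5× the median robust
  channel SD) is a stated operationalization of "without noise and other
  artifacts"; real pipelines would add ICA/SSP.
* Head-movement exclusion treats "beyond 5 mm" strictly: exactly 5 mm is
  kept.
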