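# Methods

This note documents the models implemented in `mmpscreen`, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical choices that matter.

## Barcode calling

**Model.** An amplicon read is `flank_up + barcode + flank_down` (possibly
padded). Flanks are located by a sliding-window Hamming scan; a placement
is accepted with at most `max_mismatch` (default 2) mismatches *per
flank*, not jointly. Among in-budget windows the minimal-mismatch,
leftmost one wins; the downstream flank is searched strictly to the right
of the upstream one. `N` bases never match, so they count as mismatches.
Indels in flanks are not modelled — a read whose flank carries an indel
is rescued, if at all, by the cosine step downstream.

The antisense mate is reverse-complemented (qualities reversed) before
the scan so both mates are processed in sense orientation. Reconciliation
of the two extractions: identical sequences or a single recovered
direction pass through; equal-length disagreements are resolved per
position by the higher Phred score (ties take the sense base —
deterministic and documented); unequal-length disagreements have no
per-base merge, so the mate with fewer total flank mismatches wins
(ties: higher mean barcode quality, then sense).

**Cosine assignment.** The feature space is overlapping k-mer counts with
k = 3 by default, exposed as a parameter. Rationale: one substitution in
a 20-mer changes at most three 3-mers, so a read one error away from its
catalog entry scores at least 15/18 ≈ 0.833 when the entry's 3-mers are
distinct — above the 0.8 confidence threshold, which is therefore
conservative for single errors. With k = 4 the same read would score
≈ 0.77 and be rejected. Scores within 1e−12 of 1 are reported as exactly
1.0 (cosine of non-negative count vectors cannot exceed 1; this removes
float round-off from the exact-match case). Two or more catalog entries
tied for the maximum within 1e−12 make the call *ambiguous*; ambiguous
calls never pass the threshold and never enter count matrices, avoiding
arbitrary inflation of one strain.

Coordinates are 0-based half-open; qualities are Phred+33 throughout.

## Enrichment

Replicates are pooled by summation (technical sequencing replicates of
the same sorted population). Per strain,

    log2fc = log2((c_h + a)/(N_h + S·a)) − log2((c_l + a)/(N_l + S·a))

with pseudocount a = 0.5 per strain per bin (finite for zero counts,
standard half-integer correction), library sizes N and S strains. The
test conditions on n = c_h + c_l and evaluates c_h ~ Binomial(n, p0)
with p0 = N_h/(N_h + N_l), two-sided by the minimal-likelihood rule
(scipy's `binomtest` default); n = 0 gives p = 1 by convention. This is
a deliberate, self-contained substitute for a negative-binomial
shrinkage fit (DESeq2-style): it ignores biological overdispersion
between sorted populations and is exactly calibrated only against read
sampling. BH (`statsmodels`) provides q-values; ranking is by
(q ascending, log2fc descending, strain id) — a total order, so the
top-n selection is permutation-invariant.

**Deming regression.** Closed form for the errors-in-variables slope
with variance ratio λ (default 1 = orthogonal regression). Degenerate
cases fail loudly: fewer than two distinct points; s_xy = 0 with
s_yy = λ·s_xx (orientation undefined) or s_yy > λ·s_xx (vertical line).

## Trajectories

The filter keeps trajectories that (a) start at time 0, (b) stop before
sampling index 300 — an index bound on the fluorescence grid, exposed as
a parameter because the grid interval is configuration-dependent (2 h
here) — and (c) keep both reporter signals strictly above 50 arbitrary
units at every sample. "0–5 divisions" is inclusive. The early-life mean
uses raw (uncentered) ratios: centering by the lifetime mean would leak
lifespan information into the predictor. The lifespan correlation uses
only cells observed to die; censored cells are retained everywhere else.
Windowed group summaries (default 21.5–26.5 h) bootstrap over cells (the
independent units), 1,000 seeded resamples — a nonparametric stand-in
for mixed-effects genotype contrasts, which are out of scope.

## Flow corrections

Decay correction is log-linear least squares of log(signal) on pass time
— closed-form and deterministic, matching an exponential decay rate
constant; the corrected value is the intercept exponentiated (signal at
t = 0). Pooled mode fits one slope per group (strain × experiment, the
"set of samples" measured together) with per-sample intercepts. The
plate ratio subtracts the per-wavelength averaged background before
forming the 572/546 ratio per timepoint, then averages; timepoints with
non-positive denominators are excluded and counted. The mass adjustment
multiplies MMP_s by (1 + d) with d = MMP_i,mut/MMP_i,WT − 1. A negative
multiplier would flip the sign of a positive fluorescence quantity, so
only the magnitude convention is implemented; because "normalized to
mass" can also be read as division, `direction="divide"` is available
and the choice is always explicit in the API and CLI.

## Potassium deconvolution

Young cultures: concentration = (total − blank) / (n_cells × V̄), with
V̄ the spherical volume of the mean Coulter diameter (π/6·d³; 1 µm³ =
1 fL). A blank exceeding the measurement reports 0 mM with a warning.

Aged cultures: the diameter distribution is fit as a three-component
univariate Gaussian mixture by EM — k-means++-style seeded
initialization, 10 restarts (best log-likelihood kept), tolerance 1e−8
on the log-likelihood, variance floor 1e−4 µm² (floored components are
flagged, not silently accepted), at most 500 iterations; all exposed as
parameters. Components are relabeled by ascending mean so results are
invariant to initialization order; the smallest-mean component is the
daughter class and the two larger ones are pooled as old mothers, their
mean volume weight-averaged. Per-class counts are apportioned by fitted
weights, since class-resolved counts are not observed. Component volume
uses the sphere of the mean diameter by default, faithful to the
young-cell convention; this under-estimates E[volume] by the Jensen gap
3µσ² (≈ 1% at µ = 5 µm, σ = 0.3 µm), and a moment-correct mode
(E[d³] = µ³ + 3µσ²) is available. The fit operates on diameters, not
volumes, matching what a Coulter counter reports.

Old-cell potassium is bounded two ways: a point estimate assuming
daughters hold the young-culture concentration, and an upper bound
assuming they hold none. A negative point estimate (daughter correction
exceeding the measurement) is reported with a warning, never clipped —
the sign is diagnostic.

## Synthetic generators

Every generator is a pure function of its config including the seed, and
emits truth tables so recovery tests compare against generating
parameters, never re-derived values.

* **Catalog** — uniform random barcodes accepted at pairwise Hamming
  ≥ 5 (default), rejection-sampled with a bounded attempt budget.
* **Screen** — strain abundances are log-normal (sd 0.5) to emulate pool
  skew; cell-level log MMP ratios are Normal(µ_strain, 1) with hit
  strains shifted by `hit_effect` sd; a finite pool (300k cells by
  default) is sorted at its empirical tertiles and each bin sequenced as
  a read multinomial. Because the sorted pool is finite, counts are
  overdispersed relative to pure read sampling — as in a real FACS
  screen. `n_pool_cells=None` selects the infinite-pool limit (analytic
  tertile masses), the regime in which the exact binomial test is
  calibrated; the calibration checks use it deliberately. Reads carry
  per-base substitutions, whole-flank corruption (1–3 extra
  substitutions per corrupted flank), and uniform-random junk reads;
  substituted bases get low Phred scores so quality merging is
  informative. The antisense mate is the reverse complement of the clean
  construct with its own independent errors. Read depth and the
  abundance distribution are not experimentally constrained; the
  defaults are stand-ins.
* **Trajectories** — a latent standard bivariate normal with correlation
  `target_correlation` (default 0.55) drives the initial ratio
  (log-normal, sd 0.15) and lifespan (Normal(25, 8) divisions, rounded,
  floored at 6 so the early-life window always exists). MMP_s declines
  by 5% per division; MMP_i is flat; both carry 5% multiplicative noise.
  Divisions accrue on a uniform grid (one per 1.5 h, sampled every 2 h):
  trajectory statistics in scope depend on counts, not timing realism.
  The measured correlation is mildly attenuated (≈ 0.53–0.55 at the
  defaults) by lifespan rounding/flooring and measurement noise.
* **Decay** — signal(t) = initial·e^(−rate·t)·(1 + ε), ε ~ N(0, cv²),
  passes 5 min apart.
* **Sizes** — three-Gaussian diameters (defaults 3/5/6.5 µm, sd 0.3,
  weights 0.5/0.3/0.2 — heavy daughter contamination of a 48-h aged
  culture); each cell's potassium is its spherical volume times its
  class concentration (daughters 200 mM, old 150 mM); negative draws
  are rejected, resampled and counted.

**What the generators do not emulate:** platform-specific quality
profiles, indel sequencing errors and PCR chimeras (the flank matcher is
substitution-only by design); sorter impurity and gating; biological
replicate dispersion between sorted populations; stochastic division
timing; non-Gaussian size components. Passing tests therefore certify
the algorithms against their stated models, not against every artifact
of real instruments.

## Problem sizes

The test suite and acceptance script scale the simulations to desk
scale: 50k read pairs for end-to-end calling, 10,000 strain-draws for
null calibration, 4,700 strains with 35 planted hits for recall, 10,000
cells for correlation recovery, 100 seeded series for decay recovery,
and 50,000 diameters for mixture recovery. These sizes give Monte-Carlo
error comfortably inside the asserted tolerances.
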