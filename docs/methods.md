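# Methods

## The analysis in brief

A T-RFLP campaign yields, per sampling date, a table of electrophoresis peaks
(fragment length in bp, fluorescence area).  The package turns these into
compositional profiles over integer T-RF bins, quantifies between-date change
with a Pearson-based moving window, relates community variation to
operational covariates by canonical correspondence analysis (CCA) and Mantel
tests, and maps clone sequences onto observed T-RFs by in-silico restriction
digestion.  A synthetic-data generator with planted structure provides ground
truth for every stage.

## Preprocessing

1. **Size window** — fragments shorter than 50 bp or longer than 500 bp are
   discarded (primer peaks, sizing uncertainty); the boundaries themselves
   are kept, because only strict violations are excluded.
2. **Binning** — fragment lengths are clustered across samples by
   single-linkage in one dimension: sorted lengths split wherever the gap
   between neighbours exceeds the tolerance (default 1.0 bp, a typical
   capillary sizing precision).  Chains of closely spaced peaks therefore
   merge.  Each cluster is labelled with the rounded area-weighted mean
   length; within a sample, areas falling in one cluster are summed.
3. **Relative abundance** — peak area divided by the sample's total area.
4. **Noise floor** — bins with relative abundance strictly below 2 % are
   background noise ("below 2 %" is a strict inequality, so a bin at exactly
   2 % survives).  By default the survivors are renormalized to sum to 1,
   because the downstream Pearson and chi-square machinery assumes
   compositions; renormalization can be disabled to keep raw ratios for
   reporting.  The removed mass is recorded either way, so kept + removed
   mass always equals 1.

Times are integer days since the first sample.  Whether profiles should be
renormalized after the noise filter is genuinely open in practice; both
behaviours are supported and the default is documented here.

## Moving-window change rate

Similarity between two profiles is the Pearson product-moment correlation of
their abundance vectors over the union of their bins (absent bins are
explicit zeros), expressed as a percentage.  The change value of a
consecutive pair is 100 − similarity; Δt(interval) is the arithmetic mean ±
sample (n−1) standard deviation of the change values.  Design points:

- A negative correlation makes the change exceed 100 %.  Values are not
  clamped — the subtraction formula is applied literally — but a warning is
  issued, since the change-percentage framing presumes r ≥ 0.
- "Consecutive" means adjacent in the time-sorted series even when the gap
  differs from the nominal interval; the actual gap is recorded per pair.
- An optional `exclude_before_day` drops an initial non-stationary phase
  (e.g. reactor start-up) from the summary statistics only; all pairs are
  still reported.
- Pairwise Pearson is computed on the union of the two samples' bins; on an
  assembled profile matrix this coincides with using every bin, since absent
  bins are explicit zeros.

The fixed-similarity generator is the analytic oracle for this statistic:
profiles are uniform compositions displaced along a circle in the zero-sum
subspace of bin space, so consecutive Pearson correlations equal the cosine
of the step angle exactly, and target_r = 0.90 forces every change value to
10 %.

## Canonical correspondence analysis

With P = Y/Y₊₊, row sums r, column sums c, the chi-square standardized matrix
is Q = (P − rcᵀ)/√(rcᵀ); total inertia is ‖Q‖².  Covariates are
weighted-standardized (weights r) and weighted by √r; Q is projected onto
their column space and the fitted matrix singular-value-decomposed.  Squared
singular values are the canonical eigenvalues; constrained + residual
inertia equals total inertia by construction (asserted to 10⁻⁹ in tests).
When the constraints span the whole centered sample space, the canonical
axes coincide with unconstrained correspondence analysis — the oracle used
in the tests.

- **Scaling** — "species-focused" (default): species scores in principal
  coordinates (weighted averages scaled by the singular values), site scores
  in standard coordinates; a site-focused flag swaps the roles.  Each axis is
  oriented so its largest-magnitude species score is positive.
- **Collinearity** — constant columns are dropped, exact collinearity is
  removed by rank-revealing QR, and remaining columns are screened by
  variance inflation factor with threshold 20.  The screen is a data-hygiene
  step, not part of the mathematics, so it is exposed as `vif_threshold`
  (disable with `None`).
- **Permutation tests** — rows of X are permuted as whole cases ("full
  model"); the statistic is the first canonical eigenvalue or the trace.
  P = (1 + b)/(1 + n_perm), so P is never 0 and its floor with 499
  permutations is 0.002.  Permutations are evaluated in one batched QR over
  the whole permutation stack.
- **Forward selection** — greedy: each round scores every excluded variable
  by the extra constrained inertia given the included set, tests the best by
  permutation, includes it if P < alpha (0.05).  The test statistic is the
  pseudo-F ratio (extra inertia over residual inertia per residual degree of
  freedom); raw extra inertia is available via a flag — the two order
  candidates identically.  Conditioning on the included set permutes the
  candidate's residuals after projecting out the included variables, then
  re-orthogonalizes each permuted vector.  The greedy best-of-k choice means
  the familywise inclusion probability of some decoy exceeds alpha; per-decoy
  rates stay near alpha/k.

## Mantel tests

r_M is the Pearson correlation of the upper-triangle entries of two distance
matrices.  The community matrix defaults to Bray–Curtis on relative
abundances (ecological convention; one-minus-Pearson is available for
consistency with the moving window).  Environmental matrices are |zᵢ − zⱼ|
per variable, z-scored by default (r_M is invariant to linear rescaling of
one matrix, so standardization only aids interpretability).  Missing values
are handled complete-case per variable, with dropped sample ids logged.  The
null permutes rows/columns of one matrix jointly; the default tail is
one-sided greater (positive association), 999 permutations, and an
exhaustive mode enumerates all n! relabelings for n ≤ 7, reporting the exact
proportion with the identity included so P > 0.

## In-silico digestion

The labeled terminal fragment runs from the 5′ labeled base (the first base
of the forward primer — primer bases count toward the length) through the
base preceding the cut.  TaqI recognizes TCGA and cleaves T^CGA, so
predicted_trf = (0-based index of the first TCGA) + 1; a site-free amplicon
reports its full length as uncut.  This convention reproduces the canonical
219/354/491 bp geometry of *amoA* T-RFs.  Orientation searches for the
forward primer on both strands with IUPAC-aware matching and one allowed
mismatch (cloned inserts can carry PCR errors); finding it on both strands is
an ambiguity error.  Degenerate bases in a candidate site are treated
conservatively: the site counts only when every IUPAC expansion of the
window matches, and merely-possible sites trigger a warning.  Predicted
fragments are assigned to the nearest observed bin within ±3 bp — the
midpoint of the 1–7 bp discrepancy commonly reported between in-silico and
capillary-observed sizes — with ties broken toward the smaller bin.

## Synthetic data generator

The generator emulates a year-long activated-sludge campaign: 24 samples at
15-day intervals, three dominant T-RFs (219, 354, 491 bp), spurious peaks
strictly below the 2 % floor, and 12 operational covariates as stationary
AR(1) processes with magnitudes typical of a municipal plant running
near-complete nitrification (effluent ammonia ~1.5 mg/L, effluent nitrate
~26 mg/L, DO ~2.5 mg/L, seasonal temperature 20 ± 6 °C with lag-1
autocorrelation 0.9).  Concentration variables are clipped at zero and
removal efficiency at 100 %, which slightly shrinks the realized sd of
variables with mass near the bound.

Taxon abundances respond to a named driver through Gaussian (unimodal)
response curves a_kt = h_k·exp(−(x_t − u_k)²/(2t_k²)) — the standard
ecological response model that motivates correspondence-analysis ordination —
and are normalized to compositions.  Rendering to peak tables multiplies by a
total fluorescence (50 000 units), adds Gaussian length jitter, and places
noise peaks at least 2 bp away from true bins so the noise filter removes
exactly them.  By default abundances are deterministic given the covariates;
a Dirichlet resampling option adds compositional counting noise.  All draws
flow from one integer seed through named SeedSequence streams, so outputs
are bit-identical across runs.

Presets: `noise_free_scenario` (no jitter, no noise peaks; the preprocessing
round trip is exact by construction because every true taxon stays above the
floor over the plausible temperature range), `default_scenario` (3 noise
peaks/sample at < 1.5 %, 0.15 bp jitter), `dirty_scenario` (noise close to
the floor, for negative tests), and `planted_driver_scenario` (temperature
plus five decoy covariates).  Decoys are iid white noise by design: the
permutation tests assume exchangeable rows, and an autocorrelated decoy
tested against the autocorrelated residual of a seasonal driver inflates
type-I error — a genuine caveat for real monitoring series, where
conclusions about autocorrelated covariates should be treated cautiously.

What the generator does *not* emulate: electropherogram traces and peak
calling, pull-up/stutter artifacts, PCR and primer bias, partial digestion
pseudo-T-RFs, and multinomial counting noise (unless the Dirichlet option is
enabled).  Passing tests therefore validate the statistical machinery and
the filtering rules, not robustness to instrument-level artifacts.

## Numerical choices and degenerate inputs

- Eigenvalues below 10⁻¹² are treated as zero; axes are capped at
  min(rank of constraints, species − 1, samples − 1).
- Constant abundance vectors make Pearson similarity an explicit error, not
  a silent NaN; zero row/column sums abort chi-square standardization with
  the offending label.
- Fewer than two retained change pairs give an undefined (NaN) Δt sd,
  reported as such.
- The permutation estimator (1 + b)/(1 + n) is used everywhere a sampled
  null is built; ties count as extreme (with a 10⁻¹² tolerance), keeping the
  tests exact under exchangeability.
- Pipeline outputs contain no timestamps, so identical configurations yield
  byte-identical output trees (verified by checksum comparison).

## Problem sizes in the validation suite

Calibration checks use 1000 null replicates at n = 24 (499 permutations for
the global CCA test, 999 for Mantel); driver recovery uses 100 scenario
seeds; the CCA/CA equivalence oracle uses 200 random 6×4 tables; exhaustive
Mantel enumeration covers n = 4–6 against a 4999-permutation sample.  These
sizes give binomial confidence intervals tight enough to detect a
miscalibrated test while keeping the whole suite to about a minute.

## Known limitations

- Pearson similarity on profiles with very few bins (three dominant T-RFs)
  is coarse: single-pair changes can exceed 100 % when profiles anti-correlate.
- Forward selection inherits greedy selection bias; its P-values are
  per-candidate, not familywise.
- Permutation inference assumes exchangeable samples; strong temporal
  autocorrelation in both community and covariate violates this
  (see the decoy discussion above).
- Binning by single-linkage can chain arbitrarily far in pathological peak
  layouts; the 1 bp default is tuned to capillary precision, not to dense
  peak ladders.
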