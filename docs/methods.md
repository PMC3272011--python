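# Methods

## The evaluation model

A validated assembly is modelled as a set of contigs plus a set of
diagnostic feature records, each placed on a contig interval (0-based,
half-open; points stored as width-1 intervals — unambiguous overlap
arithmetic, BED-compatible). Twelve feature types are distinguished; two
(`BREAKPOINT`, `HIGH_SNP`) are point-like, the rest describe extended
regions. For analysis, `HIGH_LINKING_CVG` (mates in another scaffold) and
`HIGH_SPANNING_CVG` (mates in another contig) are collapsed into one
column, named `HIGH_SPANNING_CVG`, since both flag the same kind of
inter-sequence inconsistency; collapsing merges columns and never drops
counts.

### Counting rules

A point feature counts once regardless of any span recorded for it. An
extent feature of length L counts `max(1, ceil(L / T))` with window
T = `extent_window` (default 10 000 bp, configurable): long anomalies
should weigh proportionally to their footprint, and any feature counts at
least once. Doubling T never increases a count (monotone), and the
per-assembly total is invariant under reordering of the input file.

### N50 / NG50

N50 is the smallest contig length L such that contigs ≥ L sum to at least
half the denominator. The default denominator is the assembly total (the
universal convention); passing a genome size gives NG50. When the contigs
sum to less than half the genome, NG50 is undefined and an error is
raised rather than returning the shortest contig.

### Feature-Response Curve

Contigs are sorted by length descending, ties broken by contig id
ascending so the curve is deterministic. For each integer threshold φ
from 0 to the total feature count, the longest prefix of that order whose
*cumulative* feature count is ≤ φ contributes its summed length;
coverage(φ) is that length divided by the genome size (explicit argument,
falling back to the assembly's genome-size estimate and then to the total
assembly length). Cumulative prefix semantics are the published FRC
construction; a per-contig-threshold variant (each contig enters as soon
as its own count fits the budget) is exposed behind `per_contig=True` for
comparison. Coverage is non-decreasing in φ, and restricting the feature
subset never lowers coverage at any φ.

Curves are ranked by the trapezoidal area under coverage over [0, φmax],
normalized by φmax, with the curve extended at its final value; a
saturated flat curve at coverage c has AUC exactly c.

## PCA and Marčenko–Pastur retention

Feature counts and bp-scale metrics (N50) live on wildly different
scales, so PCA is performed on the sample correlation matrix (columns
z-scored with sample SD, ddof = 1; zero-variance columns dropped with a
warning). Eigenvalue-based retention rules — Kaiser's λ > 1 in particular
— are only meaningful on this scale. Loadings are sign-fixed so each
component's largest-magnitude coefficient is positive, making loading
tables reproducible.

Three retention rules are reported:

* **cumulative variance**: smallest k reaching the threshold (default 80 %);
* **Marčenko–Pastur**: eigenvalues strictly above the fitted bulk edge
  λ₊ = σ²(1+√γ)², γ = p/n taken from the matrix shape (never fitted);
* **Kaiser**: eigenvalues strictly above 1, as a secondary reference.

The MP noise scale σ² is fitted by grid search over 0.05…3.0 in steps of
0.01, minimizing the Cramér–von Mises distance between the MP CDF
(numerically integrated density, plus the point mass at zero when γ > 1)
and the empirical eigenvalue CDF at plotting positions (i − ½)/N. The
grid resolution bounds the fit precision at ±0.005; on null Gaussian
matrices with n = 500, p = 50 the fitted σ² is within 1 % of truth and at
most two eigenvalues exceed λ₊. A degenerate all-equal spectrum is
rejected.

## ICA feature selection

ICA is run on the standardized feature columns only; the N50 and
NUM_CONTIG metric columns are excluded. Estimation uses FastICA
(scikit-learn): PCA whitening to unit variance, symmetric fixed-point
iteration with the logcosh contrast, tolerance 1e-6, up to 1000
iterations. Up to five restarts with seeds derived from the user seed are
run and the solution with the largest total |excess kurtosis| of its
sources is kept — mixtures of independent sources are less kurtotic than
the sources themselves, so this projection-pursuit criterion favours the
best-separated solution. Non-convergence in every restart degrades to the
best effort with a warning. Source signs are fixed to positive skewness,
falling back to a positive largest-magnitude mixing coefficient for
near-symmetric sources, so repeated runs with one seed are bit-identical.

Components are ranked by |excess kurtosis| (population-moment Fisher
form, m₄/m₂² − 3, computed on the estimated sources): sub-Gaussian
sources are just as non-Gaussian as super-Gaussian ones, so the magnitude
is the right ranking key even though strongly peaked sources are the
common case. Retention keeps the shortest prefix holding ≥ 80 % of the
total |kurtosis| mass (ties by component index); a percentile reading
("top 80 %" as a quantile cut) is exposed as `method="percentile"`. From
each retained component the feature with the largest |mixing coefficient|
is selected; duplicates are dropped preserving first occurrence.

The default number of components is `min(n_var, n_obs − 1)`. When the
goal is to recover a known or MP-indicated latent dimensionality k, pass
`n_components=k` explicitly and select over all k components, as
`examples/04` does: with few, similarly kurtotic sources the
cumulative-mass rule is dominated by the sampling noise of the kurtosis
estimator (for a Laplace source at n = 80 the sample excess kurtosis has
a standard error comparable to its mean), so the number of components,
not the retention fraction, should carry the dimensionality decision.

## Validation scoring

True mis-assembly intervals (BED-like: contig, start, end, kind) are
filtered before scoring: SNP and indel intervals shorter than
`min_indel_length` (default 10 bp) are dropped, as are breakpoint
intervals starting within `edge_margin` (default 1000 bp) of either
contig end, where alignment boundaries are noisy. A feature is *correct*
iff its interval intersects a filtered true interval on the same contig
by at least 1 bp (half-open semantics: touching intervals do not
overlap). Totals use the counting rules, so an extent feature spanning c
windows contributes c to both the feature total and, if it overlaps, the
correct total. Overlap queries use an interval tree; the test suite
checks the result against brute-force all-pairs intersection. A
best-effort converter from `show-coords`-style alignment rows to
breakpoint intervals at internal alignment boundaries is provided;
running the alignment itself is out of scope.

## Synthetic generators

### Cohort matrices

`simulate_matrix` produces X = A·S + ε at the scale of a realistic
evaluation cohort: 80 observations, the 11 analysis feature columns, 3
latent error factors. The loading design plants recoverable ground truth
for both retention and selection:

* features are partitioned into disjoint per-factor groups; each group
  has one **dominant** feature (loading 1.0, idiosyncratic noise
  SD 0.05) and members at loading 0.5 with noise SD 0.5. On the
  correlation scale the dominant column correlates ≈ 0.995 with its
  factor and members ≈ 0.71, so the per-component argmax of the mixing
  matrix has a wide margin, while each group still forms a strong spike
  (λ ≈ 2–3.5) well above the MP edge (≈ 0.9 at the fitted noise scale).
* sources are drawn by stratified inverse-CDF sampling (permuted stratum
  midpoints) and exactly decorrelated empirically. Stratification is a
  variance-reduction device: each realized source then genuinely carries
  its family's non-Gaussian signature (a plain Laplace sample of size 80
  looks Gaussian disturbingly often, with sample excess kurtosis near 0),
  and exact decorrelation matches the independence premise of ICA.
  Families: laplace (default; excess kurtosis 3), exponential, uniform.
* the latent field maps to counts through `round(softplus(300 + 60·x))`
  (positive, approximately linear at this operating point so the planted
  correlation structure survives rounding), or through a Poisson link for
  over-dispersion experiments.

Measured under these defaults: the MP rule recovers rank 3 in ≈ 99 % of
cohorts, and 3-component ICA selection returns exactly the three planted
dominant features in ≈ 92 % (residual failures are finite-sample ICA
rotations that let a member column edge past a dominant one).

### Toy assemblies

`simulate_assembly` draws contig lengths from a log-normal law (default
30 contigs, median 30 kb — a small bacterial draft), plants a
mis-assembly per contig with probability `error_rate`, and for each error
emits one truth interval plus a burst of 1 + Poisson(2) co-located
feature records of mixed types — mimicking how multiple layout violations
co-occur at a real error locus — plus uniform background features at
0.02/kb. Contig structure and error placement use separate seed-derived
streams, so varying the error rate alone leaves the contigs fixed; the
genome size defaults to 1.25× the total contig length. All outputs
round-trip through the package's parsers.

What the generators deliberately do **not** emulate: real read layouts,
assembler-specific feature biases (e.g. one feature type saturating every
contig of one assembler), correlations between feature types beyond the
planted factors, and sequence content. Passing tests therefore
demonstrate the correctness and calibration of the *methods*, not claims
about any particular assembler.

## Numerical choices and edge cases

* FRC ties in contig length break by id; φ grids are integer.
* `standardize` requires ≥ 2 rows; PCA rejects non-finite input.
* MP fitting requires ≥ 3 eigenvalues and a non-degenerate spectrum.
* `excess_kurtosis` requires ≥ 4 samples and positive variance.
* All derived seeds stay below 2³¹; every simulation is bit-reproducible
  per seed.
* Problem sizes in the test and acceptance suites (200 random FRC/scoring
  instances, 50 null and 20 spiked/planted cohorts) keep full runs in the
  tens of seconds while leaving the Monte Carlo rates' confidence margins
  comfortably inside the asserted bounds.

## Known limitations

* The extent-window constant and the validation edge margin are
  field-plausible defaults, not values anchored to a published pipeline;
  both are configurable.
* The MP fit assumes the noise bulk dominates the spectrum; with very few
  variables (p ≲ 5) the empirical CDF is too coarse for a stable fit.
* ICA selection inherits FastICA's finite-sample behaviour: with few
  observations, components may converge to rotations of the true sources
  and selection can miss a dominant feature; the restart criterion
  mitigates but does not eliminate this.
* Validation scoring treats any ≥ 1 bp overlap as a hit; containment or
  reciprocal-overlap notions are not implemented.
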