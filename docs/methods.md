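# Methods

## Model and procedure

`permdeg` tests for differential expression between two small groups of
RNA-seq libraries without distributional assumptions on the per-gene
statistic. The observed statistic is the classical pooled-variance Student
t of treated vs control CPM values; its reference distribution is built by
recomputing the statistic under every possible relabelling of the samples
that preserves the group sizes (C(n, n₁) assignments; 20 for 3-vs-3), and
pooling the non-identity results across genes. This pooling is what gives
p-values finer than 1/20: the null holds (C(n, n₁) − 1) · G values, so the
smallest attainable p is 1/(1 + 19·G) for a 3-vs-3 design with G tested
genes. The trade-off is the standard one for pooled permutation nulls
(familiar from SAM-style methods): genes share a common null, so
gene-specific variance structure is only captured through the
t-statistic's own studentization.

Fold changes are `log2((mean_trt + c)/(mean_ctl + c))` on TMM-scaled CPM
group means with pseudocount `c = 0.5`; the pseudocount keeps every value
finite and shrinks ratios of near-zero means toward 0. The |log2FC| call
cutoff is not user-chosen but derived from the same permutation null: the
mean of the absolute 0.5th and 99.5th percentiles of the pooled null
log2FC values (linear "type 7" interpolation between order statistics).
The *absolute* percentile pair is used because a near-symmetric null has a
signed-percentile mean of ≈ 0, which could not serve as a threshold. On a
tight real dataset this construction can yield cutoffs like 0.428
(1.35-fold); under the simulator's default dispersion it sits near 1.4.

### Decision rule

A gene is called `up` iff it passes the expression filter, `p_adj ≤ α`
(default 0.05) and `log2FC > cutoff`; `down` symmetric; otherwise `none`.

### Zero-variance genes

If the pooled standard error is 0 and the group means agree, t = 0; if
they differ, t = ±∞, a sentinel ranked above every finite value in the
empirical p computation (infinite null values count as exceeding
everything; an observed infinity is tied only by null infinities). This
avoids NaN propagation while preserving ordering; no SAM-style variance
offset is added.

### Empirical p-values

Two-tailed, gene-pooled, add-one smoothed:
`p_g = (1 + #{v ∈ null : |v| ≥ |t_g|})/(1 + N)`, guaranteeing p ∈ (0, 1]
and exact super-uniformity under exchangeability. The identity assignment
is excluded from the null (it is the observed statistic). "Adjusted" here
means adjusted by the empirical null, not a named multiple-testing
correction; an optional Benjamini–Hochberg pass over the pooled p-values
is available (`bh=True` / `--bh`, default off) for users who want FDR
control in the classical sense.

## TMM normalization

The trimmed-mean-of-M-values recipe is fixed for bit-reproducibility:
reference sample = the one whose 75th-percentile count fraction is closest
to the across-sample mean; M and A computed over genes with nonzero counts
in both sample and reference; two-sided trims of 30% (M) and 5% (A) on
average ranks; inverse-delta-method-variance weights
`(1/y_s − 1/N_s + 1/y_r − 1/N_r)⁻¹`; factors rescaled to geometric mean 1.
Fewer than 10 surviving genes triggers a factor-1 fallback with a warning.
This matches edgeR's `calcNormFactors(method="TMM")` to ≤ 3e-5 on the test
fixtures.

A note on depth invariance: scaling one sample's counts by a constant is
absorbed *exactly* by its library size, but the TMM factor itself shifts
slightly (≲ 1%) because the precision weights see raw counts — a property
shared by the reference implementation. The tests therefore assert exact
absorption modulo the factor shift, and bound the shift.

## Low-expression filter

Default: keep genes with CPM ≥ 1 in at least min(group sizes) samples
(configurable, can be disabled). Filtered genes are excluded from the null
and never called, but their statistics are still reported with
`filtered = True`.

## The simulator

`simulate_counts` emulates the features the analysis is sensitive to:

* per-gene baselines μ_g ~ LogNormal(log 50, 1.5) interpreted as mean
  counts at unit (10⁶-scale) depth — realized library sizes are
  proportional to the drawn per-sample depth rates L_s ~ U(0.7, 1.3)·10⁶,
  with the proportionality set by total expression;
* NB counts via a gamma–Poisson mixture with `variance = μ + φμ²`
  (default φ = 0.1, i.e. BCV ≈ 0.32, typical of biological replicates;
  `"trended"` sets φ_g = 0.05 + 5/μ_g);
* a 3 + 3 design by default; a seeded random 5% of genes carry
  |log2FC| = 2 effects, balanced up/down, applied to the treated-group
  mean;
* an optional composition-bias mode inflating 5% of genes in one sample to
  exercise TMM.

What it does **not** emulate: batch effects, gene–gene correlation,
GC/length bias, alignment artifacts, or outlier samples. Calibration and
recovery results on simulated data therefore bound what the pipeline can
do under its own assumptions, not its behavior on arbitrary real data.

## Performance under the default conditions

Benchmarks run by the test suite and `scripts/acceptance.py` at 2000
genes, 3-vs-3, five seeds:

* type-I error at α = 0.05 on effect-free data is within Monte-Carlo noise
  of nominal (the pooled empirical p is exact under exchangeability);
* with 5% DE at |log2FC| = 2 and φ = 0.1, empirical FDR among calls is
  well under 0.25, while sensitivity plateaus near 0.70–0.75: the
  noncentral-t power ceiling of a 3-vs-3 pooled-variance test at the
  null's 5% point is ~0.75 at this effect/dispersion, and the derived
  |log2FC| cutoff (~1.4 under these conditions) removes a further slice of
  true effects whose observed fold-change (sd ≈ 0.4 at n = 3)
  falls short. Larger effects, more replicates, or tighter dispersion
  raise sensitivity; this is a property of the design, not of the
  implementation.

## Numerical and design choices

* Percentiles: numpy default linear interpolation, so the cutoff is
  implementation-independent.
* "Student's t-test" is read as the equal-variance pooled t (Welch
  available via `welch=True`).
* Assignment enumeration is lexicographic and deterministic; designs whose
  C(n, n₁) exceeds the cap (default 10 000) fall back to seeded sampling
  without replacement, observed assignment always first.
* Counts must be integral on read; `allow_noninteger` rounds half-to-even
  for estimated counts.
* Panel screening: "highly expressed" defaults to mean CPM ≥ 10 across all
  samples; a top-k-within-panel rank rule is available since published
  "highly expressed" subsets are often rank-based. Responsiveness is
  copied from the DEG call. Panel genes absent from the matrix are
  reported as absent, never dropped.
* All randomness flows through explicit integer seeds; identical config +
  seed reproduces byte-identical outputs.

## Limitations

Pairing, covariates, count-model GLMs and moderated variance estimators
are out of scope. The pooled null assumes genes are exchangeable enough
for a shared reference distribution; strongly heteroskedastic statistics
would argue for per-gene nulls (and many more permutations than a 3-vs-3
design can offer). With only 20 assignments, the permutation null's
extreme tail is driven by cross-gene pooling, so a handful of wild genes
(e.g. near the expression filter boundary) can widen the derived
fold-change cutoff noticeably.
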