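# Methods

## The model

Single-cell RNA-seq count data are sparse and bimodal: a gene is either
"Off" (zero count) or "On" (a positive count) in each cell, and two cell
populations can differ in *how often* a gene is on, in the *level* of its
positive expression, or in the *spread* of that positive expression. The
package tests all three at once. For gene *j* with counts `y_jgi` in groups
*g = 1, 2* of sizes `n1`, `n2`, let `m_jg` be the number of positive cells
and `x_jg` the vector of positive counts.

1. **On-proportion** — pooled two-proportion z-test of
   `H0: p_j1 = p_j2` with `p̂_jg = m_jg / n_g`,
   `z = (p̂_j1 − p̂_j2) / sqrt(p̂*(1 − p̂*)(1/n1 + 1/n2))`,
   `p̂* = (m_j1 + m_j2)/(n1 + n2)`; `L1 = 2 P(Z > |z|)`.
2. **Location of the positive part** — Welch t-test of `H0: μ_j1 = μ_j2`
   on `x_j1` vs `x_j2`, `t = (x̄_j1 − x̄_j2)/sqrt(s²_j1/m_j1 + s²_j2/m_j2)`
   with Welch–Satterthwaite degrees of freedom (the statistic's
   denominator already implies unequal variances; Welch df is the only
   consistent reference distribution); `L2 = 2 P(T > |t|)`.
3. **Scale of the positive part** — Brown–Forsythe test of
   `H0: σ²_j1 = σ²_j2`: one-way ANOVA F on the absolute deviations
   `z_jgi = |x_jgi − median(x_jg)|`, referred to `F(1, m_j1 + m_j2 − 2)`,
   one-sided upper tail: `L3 = P(F > W)`.

The evidence is pooled by Fisher's method, `Q = −2 Σ ln L_i`. If the three
p-values were independent and uniform, `Q ~ χ²(6)`; they are not (the
location and scale tests share the positive part), so the reference
degrees of freedom are *calibrated on the data*: the χ² df is fitted by
maximum likelihood to the genome-wide distribution of Q, searched on
[2, 6], using only genes where all three components were computable.
The fit uses the central 90% of the Q values with the trim points entering
the likelihood as truncation bounds (a truncated MLE), so a minority of
genuinely DE genes in the upper tail cannot inflate the estimate while the
estimator stays consistent — it recovers a generating df within ±0.05 at
10000 draws in the test suite. `Q` is then converted to a p-value by the
upper tail of `χ²(df̂)`, adjusted across genes by Benjamini–Hochberg, and a
gene is called DE when `q < α` (default 0.05).

### Degenerate components

Absence of evidence must not create evidence, so any component that cannot
be computed contributes `L_i = 1` (zero to Q) and is recorded in a validity
mask:

* components 2–3 require at least `min_cells_on` (default 3, the smallest
  size at which a variance or a median-deviation spread means anything)
  positive cells in *each* group;
* the proportion test is degenerate when the pooled proportion is 0 or 1;
* zero pooled variance with equal means gives `L = 1`; with different
  means the p-value is clamped to the floor (1e-300, also applied before
  every logarithm so Q stays finite).

Genes with fewer than three valid components are referred to a chi-square
with `df̂ · n_valid / 3`; genes with none (all-zero genes) get `p = q = 1`
by construction. A warning is logged when `n1 + n2 < 60`, where the test
is known to lose power.

### Calibration: what the chi-square approximation can and cannot do

Two caveats, both quantified by the test suite rather than assumed away:

* On heavily sparse data (≈90% zeros, no gene filtering) a noticeable
  fraction of genes is degenerate or near-degenerate: their combined
  p-value sits exactly at 1 (conservative), and for genes with a handful
  of positive cells the component p-values are discrete. The combined
  p-value distribution under a true null is therefore *not* uniform — it
  is conservative near 1 and mildly inflated in the far tail.
* Because `corr(log L2, log L3) > 0`, Q has mean 6 but variance above 12
  under the null, and no single-df chi-square matches both the bulk and
  the tail. The fitted df (typically 4.5–5.7) matches the bulk; raw
  p-values below 0.05 are then roughly 1.5–2× their nominal frequency.
  FDR control at the BH level is much more robust: the BH-significant
  fraction on null datasets stays below 0.01 at α = 0.05 in all
  replicates, which is the operationally relevant guarantee.

The practical consequence: treat the q-values, not the raw p-values, as
the calibrated quantity, and expect the realized FDR on strongly powered
datasets to exceed the nominal level somewhat (0.1–0.3 in the bundled
benchmarks).

## Synthetic benchmarks

### Gene-swap semi-simulation

Given any source count matrix, cells are split uniformly at random into
two pseudo-groups — an exact global null by exchangeability. Ground-truth
DE genes are created by ranking genes on their group-2 mean count, taking
the first `k` genes (default 200) with mean strictly above an anchor `s1`
and the first `k` non-overlapping genes with mean strictly above
`s2 = FC · s1`, pairing them in rank order, and exchanging each pair's
group-2 rows cell-by-cell. Group 1 stays bit-identical to the source and
each pair's total count mass within group 2 is conserved. `FC` (> 1)
controls the DE strength; 1.5 / 2 / 2.5 are the weak / moderate / strong
settings used in the benchmark grids. `s1 = "auto"` resolves to the median
of the positive group-2 gene means — a value in the well-populated middle
of the mean distribution so both selection windows can be filled; the
anchor is recorded in the dataset's provenance because absolute F1 values
depend on it (swaps around a higher anchor are easier to detect).
Pairing is by rank order, deterministic given the seed.

### Splat-style artificial simulation

A generative re-implementation of the standard gamma-Poisson hierarchy for
droplet data: gene base means `~ Gamma(0.6, rate 0.3)`; a DE subset
(default 1000 of 11000) receives a multiplier `f` or `1/f` with equal
probability, `f = exp(N(de_factor, 0.4))`; library sizes
`~ LogNormal(ln 2000, 0.3)`; the expected count of gene *j* in cell *i* is
its group's normalised gene mean times the cell's library size; counts are
negative binomial via a gamma-Poisson mixture with dispersion `bcv² = 0.04`
(constant across genes); optional logistic-in-log-mean dropout. The
defaults produce ~85% zeros at 2000 reads/cell, UMI-like. The truth set is
exactly the genes with multiplier ≠ 1.

Note one subtlety of the hierarchy itself: per-cell normalisation divides
by the group's gene-mean sum, so when the DE multipliers do not average to
one the *non-DE* genes shift by a common small factor (~2% at the default
settings) between groups. At tens of thousands of cells that shift is
detectable, which deflates measured precision against the multiplier-based
truth — a property of splat-style benchmarks at scale, not of the test.

### UMI-like source generator

For semi-simulations without external data: gene means from a heavy-tailed
`Gamma(0.4)`, rescaled by a common factor solved (Brent root-finding on
the exact NB zero-probability) so the expected zero fraction hits a target
(default 0.9); counts NB with gamma shape 2, i.i.d. across cells, so cells
are exchangeable.

**What these generators do not emulate:** cell-to-cell correlation,
batch effects, cell subpopulation structure inside a group, gene–gene
correlation, ambient RNA, and (for the source generator) library-size
variation. Passing benchmarks here demonstrates the statistical machinery
under the stated count models, not performance on any particular tissue.

## Evaluation

Calls are scored against the planted truth over the full gene universe:
TPR (recall), precision, F1, specificity, realized FDR. Ratios with empty
denominators are reported as 0 and flagged by name rather than propagated
as NaN. Benchmark grids average the *per-replicate metrics* (mean and sd
over seeded replicates); pooling confusion counts first is available
behind a flag. Replicate seeds are spawned from a single seed via
`numpy.random.SeedSequence`, so every table is reproducible.

Default problem sizes in the shipped benchmarks: 10000 genes × 4000 cells
(5 replicates) for the headline gene-swap accuracy; 11000 genes × 20000
and 5000 cells (3 replicates) for the splat-style benchmark; 5000 genes ×
2000 cells (10 replicates) for null calibration. These sizes put every
gene-level statistic in its asymptotic regime while keeping a full run in
minutes on one CPU.

## Numerical choices

* p-value floor 1e-300 before logarithms (no −inf in Q).
* df search bounded to [2, 6]: 6 is the independence ceiling, 2 the
  single-component floor; trim fraction 5% per tail; at least 50 usable Q
  values or the fit falls back to df = 6 with a warning.
* BH step-up implemented directly (sort, cumulative minimum from the top);
  verified against statsmodels in the test suite.
* Ties in gene ranking (semi-simulation selection) broken by gene index
  via a stable sort; means ranked over all group-2 cells including zeros.
* Sparse matrices are CSR genes × cells throughout; the Brown–Forsythe
  pass iterates per gene over stored positive values only (medians do not
  vectorise over ragged rows), everything else is vectorised.
* Raw counts are tested by default; an optional counts-per-million rescale
  affects only the positive-part tests (proportions are scale-invariant).

## Limitations

* Two groups only; no covariates, no pseudobulk.
* Raw p-values are approximate (see the calibration section); rely on
  q-values.
* Power is poor below ~60 cells total (a warning is emitted).
* The splat-style generator is faithful in spirit, not a numerical port of
  any existing simulator; its constant-BCV dispersion understates the
  mean–dispersion trend of real droplet data, which makes moderately
  expressed genes somewhat easier to test than in real data.
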