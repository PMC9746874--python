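# heartde

Differential expression testing for sparse single-cell RNA-seq counts,
plus the simulation benchmarks to validate it — for anyone comparing two
predefined groups of cells (conditions, clusters, cell types) on a raw
gene × cell UMI or read count matrix.

## The test

Sparse single-cell counts are two-part data: a gene is "Off" (zero) or
"On" (positive) in each cell. Two cell groups can differ in the
on-proportion, in the level of positive expression, or in its spread, and
a method that looks at only one of these misses the others. For each gene
the package runs three component tests —

* a pooled two-proportion z-test on the expressing-cell fractions
  (`L1 = 2P(Z > |z|)`),
* a Welch t-test on the positive counts (`L2 = 2P(T > |t|)`),
* a Brown–Forsythe dispersion test on the positive counts
  (`L3 = P(F(1, m1+m2−2) > W)`),

— and combines them with Fisher's method, `Q = −2 Σ ln L_i`. Because the
components are correlated, Q is not χ²(6); its degrees of freedom are
calibrated genome-wide by a trimmed maximum-likelihood fit on [2, 6].
P-values from `χ²(df̂)` are BH-adjusted and genes are called DE at
`q < α`. The whole pipeline is vectorised and tests ~10⁴ genes ×
2×10⁴ cells in seconds.

Two benchmark generators with exact ground truth ship alongside: a
splat-style gamma-Poisson simulator (known DE multipliers) and a gene-swap
semi-simulation that plants DE genes into any real count matrix by
exchanging mean-matched gene pairs (anchors `s1` and `s2 = FC·s1`) in one
of two random cell halves.

## Worked example

```python
from heartde import HeartDE, SemiSimConfig, make_semisim, simulate_pbmc_like_source
from heartde.evaluation import confusion_metrics

source = simulate_pbmc_like_source(n_genes=2000, n_cells=600, sparsity_target=0.9, seed=7)
sim = make_semisim(source, SemiSimConfig(fc=2.5, k=50, s1="auto", seed=7))

res = HeartDE(sim.counts, sim.groups).fit()
print(res.summary())
```

```
HEART combination test
==========================================================
genes tested:        2000
cells (group 1/2):   300 / 300
fitted df of Q:      4.694
DE genes (q < 0.05): 86
----------------------------------------------------------
top genes by q:
 gene_id  m1  m2         Q            p        q
 gene337   8  45 48.324750 2.059483e-09 0.000002
 gene494  75  21 49.619966 1.115224e-09 0.000002
gene1309  12  53 42.936840 2.615352e-08 0.000017
...
```

86 genes are called DE at FDR 5%; the fitted df (4.69 < 6) reflects the
correlation between the location and dispersion components. The top genes
show the signature the test is built for — e.g. gene337 is on in 8 cells
of group 1 but 45 of group 2. Scoring the calls against the 100 planted
swap genes:

```python
m = confusion_metrics(set(res.de_genes), sim.truth_de, set(sim.counts.gene_ids))
print(f"F1={m.f1:.3f}  TPR={m.tpr:.3f}  realized FDR={m.fdr:.3f}")
```

```
F1=0.806  TPR=0.750  realized FDR=0.128
```

On real data, build the model from files instead:

```bash
heart test --counts pbmc/ --format mtx --groups groups.tsv --alpha 0.05 --out results.tsv
```

which accepts 10x Matrix Market directories (v2 and v3 layouts) or
delimited tables, writes a lossless TSV of per-gene results and a JSON run
manifest. `heart semisim`, `heart splatsim` and `heart bench` generate
benchmark datasets and replicate-averaged metric tables from the command
line; all randomness flows from `--seed`.

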