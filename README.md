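# permdeg

Permutation-null differential expression for small replicated bulk RNA-seq
designs, with TMM normalization, a null-derived fold-change threshold, and
gene-panel screening.

## The problem

With three biological replicates per condition, parametric RNA-seq tests
lean heavily on distributional assumptions, and a per-gene permutation test
is stuck at a resolution of 1/C(6,3) = 1/20 — no gene can reach p ≤ 0.05 on
its own. `permdeg` implements the pragmatic alternative used in small-design
transcriptome studies (for example, screens for transporter and
protein-degradation signatures in treated melanocytes):

1. **TMM normalization.** Library scaling factors by the trimmed mean of
   M-values: per sample vs a reference, gene-wise log-ratios
   `M = log2((y_gs/N_s)/(y_gr/N_r))` are trimmed (30% by M, 5% by
   abundance A) and averaged with inverse-variance weights; expression is
   reported as CPM against the effective library size `N_s · f_s`.
2. **Exhaustive permutation null.** For every one of the C(n, n₁) group
   label assignments, per-gene Student t-statistics (pooled variance) and
   pseudocounted log2 fold-changes are recomputed on the CPM matrix. The
   19 non-identity assignments of a 3-vs-3 design, pooled across all G
   genes, give an empirical null of 19·G values.
3. **Empirical adjusted p-values.** Two-tailed, gene-pooled, add-one:
   `p_g = (1 + #{|v| ≥ |t_g|}) / (1 + 19·G)`.
4. **Null-derived fold-change cutoff.** The mean of the absolute 0.5th and
   99.5th percentiles of the pooled null log2FC distribution; a cutoff of
   0.428 corresponds to a 1.35-fold change.
5. **Calls.** A gene is `up` (`down`) iff it passes the low-expression
   filter, `p_adj ≤ α` and `log2FC > cutoff` (`< −cutoff`).

A seeded negative-binomial simulator (`variance = μ + φμ²`, log-normal
baselines, unequal depths, spiked-in effects with ground truth) provides
inputs for calibration and recovery benchmarks, and panel screens flag
highly expressed / treatment-responsive genes (e.g. the shipped SLC
transporter and melanogenesis panels).

## Worked example

```python
from permdeg import SimConfig, evaluate_run, run_from_matrix, simulate_counts

cm, truth = simulate_counts(SimConfig(n_genes=2000, de_fraction=0.05, seed=42))
table, summary, norm = run_from_matrix(cm)
print(summary.to_text())
metrics = evaluate_run(table, truth)
for key in ("sensitivity", "fdr", "type_i_error"):
    print(f"{key:14s}: {metrics[key]:.3f}")
```

prints (abridged):

```
genes in input          : 2000
genes failing filter    : 4
label assignments       : 20
|log2FC| cutoff (null)  : 1.599 (3.03-fold)
alpha                   : 0.05
upregulated genes       : 37
downregulated genes     : 30
...
sensitivity   : 0.650
fdr           : 0.030
type_i_error  : 0.001
```

All 20 label assignments of the 3-vs-3 design were enumerated; the null
log2FC tails put the fold-change cutoff at 1.60 (3.03-fold) under the
simulator's moderate dispersion (φ = 0.1); 65 of the 100 spiked-in genes
are recovered with the correct direction, and ~3% of the 67 calls are
false. The same run from
the shell:

```bash
permdeg simulate --n-genes 2000 --seed 42 --out-prefix sim_
permdeg run --counts sim_counts.tsv --groups sim_groups.tsv \
    --control-label CTL --out results.tsv
permdeg evaluate --results results.tsv --truth sim_truth.tsv
permdeg panels --counts sim_counts.tsv --groups sim_groups.tsv \
    --results results.tsv --panel slc_named
```

The `examples/` directory contains one narrative script per capability:
simulation + calling, TMM under composition bias, the null threshold, and
panel screening.

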