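# mirex

Predicting per-gene mRNA expression levels from DNA sequence and miRNA
target knowledge.

Steady-state mRNA levels are shaped both by transcription — encoded in the
promoter region around the transcription start site (TSS) — and by
post-transcriptional repression, notably by microRNAs (miRNAs) that bind
target mRNAs and lower their abundance. `mirex` implements a CNN regressor
that predicts a gene's log-scale expression from

* a **TSS-centered one-hot DNA window** (default 10,500 bases: 3,000
  upstream + 7,500 downstream of the TSS),
* **eight mRNA half-life features** (5'UTR/ORF/3'UTR lengths and CG
  content, intron length, exon-junction density), and
* a **per-gene miRNA feature vector** x, where x_i is miRNA i's
  log-normalised expression if miRNA i targets the gene and 0 otherwise.

Its core contribution is a **residual-correlation selection** of the most
informative miRNAs: a sequence+half-life *baseline* model (no miRNA
inputs) is trained first; since it cannot see repression, genes repressed
by an active miRNA fall below its predictions.  With residuals
r = y − ŷ and TargetScan's Cumulative Weighted Context++ Score (CWCS;
more negative = stronger predicted binding), each miRNA is scored by the
Spearman correlation ρ(r, CWCS) over its target genes, and the top 10
enter the final model.  Four variants are compared on test-set
R² = 1 − RSS/TSS over the 10 best of 12 seeded runs each, with Welch
t-tests: **baseline**, **all_mirna** (every miRNA), **mirex** (top-10 by
signed correlation) and **abs_corr** (top-10 by |r|-correlation).

A fully specified synthetic-data generator (planted promoter motifs,
linear half-life effects, planted miRNA repressors whose effect tracks
|CWCS|, decoy miRNAs, Gaussian noise) makes every stage testable without
downloading genomics data; see `docs/methods.md` for the model, the
generator, and all numerical choices.

## Worked example

Generate a synthetic dataset (1,200 genes, 1,000-base windows, 20 miRNAs
of which 5 are planted repressors), train the baseline, and select miRNAs
from its residuals:

```python
from mirex import (SimConfig, generate, ExpressionCNN, ModelConfig,
                   TrainConfig, rank_mirnas, truth_eval)
from mirex.pipeline import prepare_model_data
from mirex.selection import residuals_from_baseline

sim = generate(SimConfig(seed=0))
data = prepare_model_data(sim.records, sim.features,
                          sim.mirna_expr, sim.targets, sim.split)
baseline = ExpressionCNN(data.subset_mirnas([]), ModelConfig.toy(window=1000))
result = baseline.fit(TrainConfig.toy(seed=0))
print(result.summary())

selection = rank_mirnas(residuals_from_baseline(result), sim.targets,
                        mode="signed", k=10)
recovered, precision, recall = truth_eval(selection, sim.truth)
print(f"planted miRNAs recovered: {recovered}/5")
```

Output:

```
Expression CNN regression results
=========================================
window (bases)                       1000
conv blocks                             1
miRNA features (K)                      0
parameters                          10569
seed                                    0
epochs run                             35
best epoch                             27
best val MSE                      0.33278
validation R2                      0.6827
test R2                            0.7147
=========================================
planted miRNAs recovered: 5/5
```

The baseline explains ~71% of test-set expression variance (the half-life
and motif signal); the unexplained residuals carry the planted repression,
and the signed residual–CWCS ranking places all 5 planted miRNAs in its
top 10.  The full four-variant comparison is one call
(`mirex.run_pipeline`) or one command:

```bash
mirex simulate --out data/ --seed 1
mirex run-all --data data/ --out results/ --seed 1
```

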