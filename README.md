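# cytosynergy

Factorial cytokine-stimulation RNA-seq analysis: from a four-condition count
matrix (control, cytokine A, cytokine B, and the A+B combination — the
IL-17 / TNF-α design on porcine aortic endothelial cells), call differential
expression with an exact Poisson test and classify every regulated gene as
**synergistic**, **additive**, or **antagonistic-excluded**.

## Who this is for

Anyone analysing a 2×2 cytokine (or drug) stimulation experiment measured by
bulk RNA-seq who wants the classical log2-fold-change synergy bookkeeping
rather than a GLM interaction term: which genes respond to the combination
more than the sum of the single treatments, which respond additively, and
which are suppressed by the combination.

## The model

Let *x* and *y* be the log2 fold changes (log2-FCH) of the two single
treatments versus control and *xy* the log2-FCH of the combination, each with
a delta-method standard error from Poisson counting noise:

```
log2_fch = log2((mean_t + c) / (mean_c + c)),
se^2     = (1/ln 2)^2 * (1/(n_t * mu_t) + 1/(n_c * mu_c)),
```

with size-factor-normalized group means and pseudocount *c* = 0.5. Two Wald
tests drive the classification:

* **sum test** — H0: *xy* = *x* + *y* (departure from log-scale additivity);
* **dominance test** — H0: *xy* = *x* and H0: *xy* = *y*.

A gene is *synergistic* when the sum test rejects and |*xy*| > |*x* + *y*|
(positive if the combined effect is up, negative if down); its *synergy
increase* is |*xy*| − |*x* + *y*|. A gene whose combined response is
significantly smaller in magnitude than a single response is *antagonistic*
and excluded. A non-synergistic gene whose combined response significantly
exceeds both single responses is *additive*. Genes enter the cascade only if
differentially expressed in the combination-vs-control contrast — an exact
conditional Poisson test (pooled counts; binomial given the two-group total)
with Benjamini–Hochberg adjustment, flagging fold change > 1.5 and adjusted
p < 0.05.

Downstream utilities cover hypergeometric gene-set over-representation (GMT
input), ligand–receptor co-regulation reports, and the validation-assay
formulas (2^−ΔΔCt relative qPCR quantification, % complement-dependent
cytotoxicity from OD450, geometric mean fluorescence intensity, Student's
t with mean ± SEM). A simulator generates factorial count matrices with known
per-gene interaction structure so the whole pipeline is testable end to end.

## Worked example

```python
import cytosynergy as cs

config = cs.SimConfig.strong_effect(n_genes=1000, seed=7)
matrix, truth = cs.simulate_factorial_counts(config)

factors = cs.size_factors(matrix)                      # median-of-ratios
de = cs.de_all_contrasts(matrix, factors)              # exact Poisson + BH
triplets = cs.build_triplets(cs.estimate_effects(matrix, factors))
calls, summary = cs.classify_all(triplets, de)
print(summary)
```

prints

```
                        up  down  total
category
synergistic_positive   100     0    100
synergistic_negative     0    99     99
additive                62    89    151
antagonistic_excluded   52    49    101
not_classified          76    73    149
```

Of 600 eligible genes, 199 are called synergistic (100 induced, 99
repressed) and 151 additive; the 101 antagonistic genes — combination response
significantly weaker than a single-cytokine response — are excluded from the
additive-or-synergistic list, and the rest show no significant interaction
pattern. Against the simulator's ground truth this run recovers the three
target categories with macro precision 0.99 and recall 0.99
(`cs.recovery_scores(truth, calls)`).

The same analysis is available from the shell:

```sh
cytosynergy simulate --out-dir simdata --n-genes 1000 --seed 7
cytosynergy classify --counts simdata/counts.tsv --metadata simdata/metadata.tsv --out-dir results
cytosynergy assay ddct --ct-target-treated 24 --ct-ref-treated 18 \
    --ct-target-control 25 --ct-ref-control 18   # -> 2
```

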