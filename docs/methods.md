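# Methods

## Design and model

The pipeline targets a 2×2 factorial stimulation experiment: bulk RNA-seq
counts for an untreated control, each of two cytokines alone (labelled A and
B; in the motivating system, human IL-17 at 100 ng/ml and human TNF-α at
2 ng/ml on porcine aortic endothelial cells), and their combination, with
replicate libraries per condition (default 3, i.e. 12 samples).

All effects live on the log2 scale. For gene *g* and contrast *t* vs control,

    log2_fch = log2((mu_t + c) / (mu_c + c))

where `mu` are size-factor-normalized group means and `c` is a pseudocount
(default 0.5) that keeps estimates finite at zero counts. The standard error
comes from the delta method under Poisson sampling of each replicate:

    se^2 = (1/ln 2)^2 * (1 / (n_t * mu_t) + 1 / (n_c * mu_c))

with the pseudocounted means plugged in. A parametric-bootstrap check in the
test suite confirms the formula to within 10% at typical counts.

## Differential expression

Replicate counts are pooled within condition (Poisson sums are Poisson), and
the two pooled counts are compared with the exact conditional test: given the
total k_t + k_c, k_t is binomial with success probability
E_t / (E_t + E_c), where E is the summed size factors of each group. The
two-sided p-value doubles the smaller tail, capped at 1; an empty total gives
p = 1. P-values are Benjamini–Hochberg adjusted across genes within each
contrast. A gene is differentially expressed when fold change exceeds 1.5 in
either direction *and* adjusted p < 0.05. Both thresholds are configurable.

The doubling construction is deliberately transparent: the test suite checks
it against exhaustive rational enumeration (exact fractions) to 1e-12 for
group totals up to 100. Discreteness makes the test mildly conservative,
which shows up as super-uniform null p-values.

Size factors use either total-count scaling or the median-of-ratios
estimator (median across always-expressed genes of each sample's ratio to
the per-gene geometric-mean reference); both are rescaled to geometric mean
1, and the effect/DE routines renormalize whatever factors they receive the
same way, so results are invariant to a global rescaling of the factors.

## Synergy classification

Per gene, the effect triplet (x, y, xy) = (A vs control, B vs control, AB vs
control) enters a decision cascade driven by two Wald z-tests on the log2
scale (the simplest test consistent with hypothesis testing on fold changes;
the machinery is otherwise unconstrained by the study design):

1. **Sum test** — z = (xy − x − y) / sqrt(se_xy² + se_x² + se_y²). If it
   rejects at alpha (default 0.05) and |xy| > |x + y| the gene is
   *synergistic*; the synergy increase is |xy| − |x + y|, and the call is
   positive or negative according to the sign of xy. Reading the
   positive/negative split as the direction of the combined effect (rather
   than the sign of the synergy increase, which is positive by construction
   for every synergistic gene) is the only interpretation that allows both
   synergistically induced and synergistically repressed genes.
2. **Antagonism exclusion** — otherwise, if xy is significantly different
   from a single effect *and* smaller in magnitude (|xy| < |x| or |xy| < |y|),
   the combination blunts a single-cytokine response: the gene is
   antagonistic and excluded from the additive-or-synergistic list.
3. **Dominance test** — otherwise, if both z = (xy − x)/sqrt(se_xy² + se_x²)
   and the analogous test against y reject and |xy| exceeds both |x| and
   |y|, the gene is *additive*.
4. Anything else is *not classified*.

The cascade is a partition: every eligible gene receives exactly one
category, and within the additive-or-synergistic list the up/down directions
partition the genes — the structural identity behind reporting
"synergistic + additive = total" and "up + down = total" side by side.

Eligibility (which genes enter the cascade) defaults to differential
expression in the combination-vs-control contrast; union-of-any-contrast and
no-filter modes are available because the original screening order is not
fully determined by the published definitions. Test 1/Test 2 p-values are
used raw by default — the false-discovery control sits at the DE stage — with
an optional BH adjustment of each test family across genes.

## Simulator

`simulate_factorial_counts` draws per-gene baselines b ~ N(mean, sd) on the
log2 scale and sets the expected count of gene g in sample s of condition c
to

    sizefactor_s * 2^(b + x·[c in {A, AB}] + y·[c in {B, AB}] + i·[c = AB]),

with counts Poisson (dispersion 0) or gamma-Poisson (negative binomial with
size 1/dispersion; variance mu + dispersion·mu²). Genes are assigned to six
truth categories by deterministic largest-remainder quotas so category
counts are exact, not Bernoulli draws:

| category        | x, y                  | interaction i                      |
|-----------------|-----------------------|------------------------------------|
| null            | 0, 0                  | 0                                  |
| single_only     | one of ±U(1, 2), 0    | 0                                  |
| additive        | same sign, ±U(1, 2)   | 0                                  |
| synergistic_pos | +U(1, 2), +U(1, 2)    | +U(1.5, 2.5)                       |
| synergistic_neg | −U(1, 2), −U(1, 2)    | −U(1.5, 2.5)                       |
| antagonistic    | same sign, ±U(1, 2)   | set so combined = 0.6·max(|x|,|y|) |

Default fractions are 0.40 / 0.15 / 0.15 / 0.10 / 0.10 / 0.10 — a mostly
unresponsive transcriptome with a substantial regulated minority, the shape
a strong dual-cytokine stimulus produces in endothelial cells. The
antagonistic combined effect is pulled back to 60% of the larger single
effect: far enough below it to be a genuine magnitude reversal, large enough
that most such genes still clear the fold-change eligibility gate and
exercise the exclusion branch.

The base configuration uses baseline log2 mean 6, sd 2 (control means from
tens to thousands of counts, bulk RNA-seq magnitude). `SimConfig.strong_effect()`
is the well-powered scenario used for recovery benchmarking: baseline
N(8, 1) truncated below at log2 = 6 (control mean ≥ 64 counts) with the same
effect ranges, at which point three Poisson replicates per condition give the
Wald cascade essentially full power.

What the simulator does *not* emulate: gene-length and GC biases, batch
effects, correlated genes, library-preparation artifacts, or read-level
noise. Passing recovery tests therefore demonstrates correctness of the
estimators and the cascade logic under the stated sampling model, not
robustness to the full messiness of real libraries; real data are also
overdispersed, which the Poisson-based exact test does not model (the
simulator's `dispersion` knob exists precisely to probe that mismatch).

## Downstream reports

Over-representation of the additive-or-synergistic gene list in user-supplied
GMT gene sets uses the one-sided hypergeometric upper tail
P(X ≥ k) with the tested genes as the universe, BH-adjusted across sets;
sets are intersected with the universe first and empty sets dropped. Gene
identifiers match case-insensitively as opaque strings — no ortholog mapping
is attempted, so cross-species symbol harmonisation is the caller's job.
Ligand–receptor pairs are reported as both_up / both_down / discordant when
both members are in the classified list, incomplete otherwise.

## Assay formulas

* Relative qPCR quantification: ΔCt = Ct_target − Ct_reference per group,
  ΔΔCt = ΔCt_treated − ΔCt_control, fold change = 2^−ΔΔCt (reference gene
  rpl13a in the motivating experiments). Replicate Ct values are averaged
  per group before differencing by default; positional per-replicate pairing
  is available. No amplification-efficiency correction is applied.
* Complement-dependent cytotoxicity: 100 × (OD_control − OD_experimental) /
  OD_control from OD450 viability readings; negative values are preserved
  unless clamping is requested.
* Geometric mean fluorescence intensity: exp(mean(log values)).
* Group comparisons: two-tailed equal-variance Student's t with
  df = n₁ + n₂ − 2 and per-group mean ± SEM (sd/√n).

## Numerical choices and edge cases

* Pseudocount 0.5 applies to fold-change estimation only; the exact test uses
  raw pooled counts and needs none.
* Wald p-values come from the standard normal survival function; a zero
  combined variance is an error rather than a silent p = 0.
* An all-zero sample is rejected by name during normalization; a zero total
  for a gene yields p = 1 and no DE call.
* Writers emit TSV with genes sorted lexicographically and a fixed float
  format, and the run manifest excludes timestamps, so repeated runs are
  byte-identical.
* Benchmark problem sizes — 1,000 genes for recovery, 5,000 for null-rate
  checks, totals ≤ 100 for the enumeration oracle — are large enough for
  stable rates (binomial sampling error on a 5% rate at n = 5,000 is ±0.6%)
  while keeping the whole suite in seconds.

## Known limitations

* The Poisson sampling model understates biological replicate variance;
  per-replicate overdispersion handling (negative-binomial GLMs, shrinkage)
  is deliberately out of scope.
* Replicate pooling in the exact test treats library-size-normalized pooled
  counts as the unit of evidence; with very unequal size factors the
  conditional binomial is an approximation to the per-replicate likelihood.
* No dose–response or Bliss/Loewe synergy modelling: the classification is
  a fixed-dose, single-timepoint scheme.
* KEGG (or any) gene-set content is user-supplied; no database snapshot is
  bundled, so enrichment results depend on the collection version provided.
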