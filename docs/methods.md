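# Methods

`dptcell` implements a pipeline for discovering and characterizing
double-positive (DP) αβγδ T cells — cells coexpressing both a rearranged αβ
and a rearranged γδ T-cell receptor — in single-cell RNA-seq data, together
with the downstream analyses such a discovery calls for: conserved-marker
differential expression, receptor–ligand interaction inference, and CDR3
repertoire-overlap analysis. Everything is exercised on synthetic data with
planted ground truth, so each stage's recovery behavior is measurable.

## Normalization

Counts are normalized per cell to transcripts per million (TPM; each cell
sums to 10⁶) and log-transformed as `ln(1 + TPM)`. The natural-log-with-
pseudocount convention keeps zeros at zero and matches the common single-cell
toolchain default. Optional gene standardization uses the sample standard
deviation (n − 1) and clips z-scores at ±10 (configurable); zero-variance
genes map to all-zero. Cells with zero total counts are rejected with an
explicit error rather than dropped silently. All derived layers are computed
from the immutable counts layer, so re-running a step can never compound a
transformation.

## Constant-chain gating

Initial subset labels come from fixed log-TPM thresholds on the TCR constant
chains: αβ (AB) requires TRAC > 2.5 with TRDC, TRGC1 and TRGC2 all < 0.5;
γδ (GD) requires TRAC < 0.5 with any γ/δ chain > 2.5; DP requires TRAC > 2.5
with any γ/δ chain > 2.5. TRBC1/TRBC2 are expressed across all T cells and
take no part in the rules. Comparisons are strict, so a cell sitting exactly
on a threshold is UNASSIGNED, as is any cell matching no rule (e.g. TRAC
between the thresholds while a γ/δ chain is high); such cells are resolved by
the classifier. The labels always partition the cells.

## Lineage classifier

A logistic regression with an elastic-net penalty is trained per donor on
that donor's gated AB (class 0) and GD (class 1) cells, using log-TPM of all
genes *except* the six TCR constant chains — the model must not simply read
the gating rule back off the features. Cells are weighted by
`n_total / (2 · n_class)` so each class carries equal total weight.

Numerical choices:

- mixing parameter α = 0.5 by default (configurable; α = 1 gives the lasso);
- the penalty path is glmnet-style: 15 values geometrically spaced from the
  smallest λ that zeroes every coefficient down to 1/100 of it;
- λ is chosen by a 10-fold stratified inner loop minimizing weighted binomial
  deviance; features are standardized inside each training fold (fitted
  coefficients are mapped back to the log-TPM scale, so stored models act on
  raw log-TPM);
- fits use scikit-learn's saga solver with warm starts along the path and a
  fixed internal shuffling seed, making training deterministic;
- a 5-fold stratified outer loop estimates generalization AUC; each cell is
  scored exactly once by a model whose λ selection never saw it.

Validation mirrors three controls: nested-CV AUC on one donor, cross-donor
AUC (train on one donor, test on another), and a shuffled-label control whose
AUC should collapse to chance. Probabilities from the per-donor models
(trained on the first two donors by default, since additional donors may lack
enough γδ cells) are averaged unweighted; for three or more donors the mean
extends naturally. UNASSIGNED cells with averaged P(γδ) ≥ 0.75 become GD,
≤ 0.25 become AB, and strictly in between become DP. The printed inequalities
leave the boundary points unspecified; this package sends boundary values to
the adjacent single-positive class, so DP calls require strictly intermediate
probabilities.

## Conserved markers

Differential expression between two subsets is tested per donor and per gene
with a negative-binomial likelihood-ratio test: group means are estimated on
the size-factor-normalized scale (size factor = total counts / 10⁶, so means
are TPM-scale), a shared dispersion θ comes from method-of-moments on the
pooled normalized counts (falling back to the Poisson likelihood when the
variance does not exceed the mean), and twice the deviance between the
separate-means and pooled-mean fits is referred to χ²(1). Log fold-change is
the natural log of the ratio of normalized group means with a 10⁻⁹
pseudocount. This is a deliberately simple, calibrated NB test — it does not
reproduce any particular packaged implementation's statistic. P-values are
BH-adjusted within each donor; a gene is a conserved marker when it is
significant (adjusted p < 0.05) with |log FC| ≥ 0.1 and a consistent sign in
every required donor.

## Receptor–ligand interactions

For each annotated pair, the score is
`log2((mean_TPM(gene_a | T subset) + mean_TPM(gene_b | other type)) / 2 + 1)`.
The description "averaging the expression of the two genes" is ambiguous when
the two genes live in different cell sets of unequal size; the type-mean
reading used here is the only one that needs no pairing rule. Genes detected
in fewer than 20% of cells of every cell type are excluded (boundary
inclusive).

Specificity is assessed with two background distributions of 1,000 re-scored
draws (reducible for speed): one replaces the T subset with random same-size
sets of *other* T cells (the subset's own cells are excluded from the pool),
the other replaces the non-T type with random sets of other non-T cells.
Draws are without replacement within a draw and independent across draws.
When a pool is smaller than the replaced group, the draw size is capped at
the pool size — the background becomes noisier, which only makes the p-value
more conservative — rather than dropping the row, so the largest T subset
remains testable.

The p-value is the upper-tail probability of the observed score under a
Student-t location/scale fit of the background scores
(`z = (obs − mean(bg)) / sd(bg)`, df = n_draws − 1). Because each background
draw is a same-size random set, the background's spread estimates the
observed score's own sampling variability, and this tail probability is
approximately uniform under a label-permuted null — a property verified by
simulation. (A one-sample t-test of the background against the observed
value, read literally, divides by sd/√n_draws and rejects ~45% of true nulls;
it is not usable as a specificity test.) If the background is degenerate
(zero variance), the p-value is 1 when the observed score does not exceed it
and 1/n_draws otherwise. The two background p-values are combined by their
maximum — conservative for dependent tests — and BH-adjusted across all rows
of the run (all pairs × all type combinations). The test is one-sided for
enrichment; the direction is switchable in principle by negating scores.

## Repertoire overlap

Clone identity is the exact CDR3 string; the Vβ family matters only for the
usage distributions (amino-acid vs nucleotide matching is a question of what
the input tables contain, not of this code). Duplicate (CDR3, Vβ) rows are
aggregated by summing counts on read. Overlap reports the shared and
sample-exclusive clone sets and each sample's shared-read fraction (reads in
shared clones / total reads). Vβ usage is reported both as fraction of
distinct clones and as fraction of reads per family; each vector sums to 1.

## Synthetic data

The generator emulates a multi-donor fetal-skin-like experiment: eight cell
classes (αβ, γδ and DP T cells; fibroblasts, endothelial cells, myeloid
cells, NK cells, keratinocytes) in configurable proportions, per-donor
multinomial sampling, log-normal library sizes (σ = 0.3 on the log scale,
mean 10,000 counts), and per-gene negative-binomial counts with shared
dispersion θ = 10 around class-specific expected TPM profiles. Each class
overexpresses a disjoint block of 20 marker genes by a 4-fold effect; DP
cells additionally carry *both* the αβ and the γδ marker programs plus their
own block — the coexpression structure that makes intermediates sit mid-way
on the classifier's probability axis. TCR constant genes follow the planted
lineage: TRAC high in AB/DP, γ/δ constants high in GD/DP, TRBC1/2 high in all
T cells, and everything low (0.5 TPM) elsewhere.

The default "on" level is 1,000 TPM. At 10,000 counts per cell the high gate
(log TPM > 2.5) is equivalent to observing at least one transcript of the
gene, so gate fidelity is governed by P(count ≥ 1) on the on-side and
P(count = 0)³ on the off-side; the defaults put both above 97%, and planted
AB/GD cells recover their gate label ≥ 90% of the time, with on/off
separation far beyond the 100-fold minimum the recoverability property
assumes. Markedly lower on-expression (e.g. 300 TPM at 5,000 counts, i.e. an
expected count of 1.5) caps the AB gate's recall below 80% for any
Poisson-mixture count model — a depth limitation of threshold gating worth
keeping in mind with real data.

Clone tables plant `round(shared_fraction × n_clones_a)` CDR3 sequences in
both samples; counts are geometric (p = 0.2) as a simple heavy-tailed clone
size model, and Vβ families are uniform over a configurable list.

What the generator does *not* model: ambient RNA, doublets, UMI collisions,
batch/chemistry effects, donor-specific biology, or correlated gene modules
beyond the marker blocks. Passing tests therefore demonstrate that the
algorithms recover structure they are designed for under clean droplet-like
noise — not that real fetal-skin data are this easy.

## Problem sizes and defaults

Default runs use 2 donors × 750 cells × 400 genes; classifier checks use a
T-cell-only composition (48% αβ, 32% γδ, 20% DP) at 300 genes, and
interaction calibration uses 1,000 cells with ≥ 2,000 pair-tests at 200
background draws. These sizes give stable estimates (binomial SE on a 5%
rejection rate with 2,000 tests is ~0.5%) while keeping a full run in the
low minutes on one CPU.

## Known limitations

- The NB test's moment-based dispersion is per-gene and shared across groups;
  at very small group sizes (≲20 cells) its type-I error can drift from
  nominal.
- The interaction analysis collapses multi-subunit complexes to gene pairs
  and ignores secreted-vs-membrane directionality.
- DP calls inherit the gating thresholds' depth sensitivity: at low library
  sizes the constant-chain gate loses cells to the UNASSIGNED pool and the
  classifier's band does the work.
- With more than two training donors the unweighted model average is an
  extrapolation of the two-donor design, not a validated ensemble.
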