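# dptcell

Tools for discovering and characterizing **double-positive (DP) αβγδ T
cells** — T cells coexpressing both a rearranged αβ and a rearranged γδ
T-cell receptor — in single-cell RNA-seq data, with companion analyses for
marker discovery, receptor–ligand interaction inference, and TCR repertoire
overlap. The package targets computational immunologists who want a tested,
reusable implementation of this analysis style, exercised end-to-end on
synthetic data with planted ground truth.

## What it computes

1. **Constant-chain gating.** Each T cell is labeled from log-TPM of the TCR
   constant genes: AB if `TRAC > 2.5` and all of TRDC/TRGC1/TRGC2 `< 0.5`;
   GD if `TRAC < 0.5` and any γ/δ constant `> 2.5`; DP if both are high;
   otherwise UNASSIGNED. β constants (TRBC1/2) are expressed in all T cells
   and excluded from the rules.
2. **Elastic-net lineage classifier.** Per donor, a weighted logistic
   regression with elastic-net penalty (α = 0.5) is trained on gated AB vs GD
   cells over all genes except the TCR constants. The penalty strength is
   selected by a 10-fold inner loop (weighted binomial deviance) and
   generalization AUC is estimated by a 5-fold stratified outer loop; models
   transfer across donors and a shuffled-label control collapses to chance.
   Averaged per-donor probabilities place each ungated cell on the αβ (p→0)
   to γδ (p→1) axis; cells with `0.25 < p < 0.75` are called DP.
3. **Conserved markers.** Per-donor negative-binomial likelihood-ratio tests
   (moment-estimated shared dispersion, TPM-scale means) with BH adjustment;
   a marker must be significant with `|log FC| ≥ 0.1` and a consistent sign
   in every required donor.
4. **Receptor–ligand interactions.** For each annotated gene pair and each
   (T subset, non-T type) combination, the score
   `log2((mean TPM_a + mean TPM_b)/2 + 1)` is tested against two swap-based
   background distributions (random other T cells / random other non-T
   cells), p-values are combined by maximum and BH-adjusted. Genes must be
   detected in ≥ 20% of cells of some type.
5. **Repertoire overlap.** Exact-CDR3 shared/exclusive clone sets between
   paired samples, shared-read fractions, and Vβ family usage by clones and
   by reads.
6. **Synthetic data.** A negative-binomial simulator of multi-donor
   mixed-population experiments with planted lineages (DP cells coexpress
   both single-positive marker programs) and paired clone tables with a
   controllable shared-clone fraction.

## Worked example

```python
import pandas as pd
import dptcell as dp

cfg = dp.SynthConfig(seed=7, n_genes=300,
                     fractions={"AB_T": 0.48, "GD_T": 0.32, "DP_T": 0.20})
adata, truth = dp.generate_expression(cfg)       # 1,500 T cells, 2 donors
dp.preprocess(adata)                             # TPM + log layers

gates = dp.assign_by_constant_chains(adata)
print(dp.gating_summary(gates, adata.obs["donor"]))

ccfg = dp.ClassifierConfig(seed=0)
models = [dp.train_donor_model(adata, gates, d, ccfg)
          for d in ("donor1", "donor2")]
probs = dp.predict_probability(models, dp.strip_tcr_genes(adata))
final = dp.assign_final_subsets(gates, probs, ccfg)
report = dp.recover_planted_lineages(final, truth)
print(report["confusion"])
print(pd.concat({"recall": report["recall"],
                 "precision": report["precision"]}, axis=1).round(3))
```

Output:

```
gate_label   AB   GD   DP  UNASSIGNED
donor
donor1      378  224  148           0
donor2      368  228  154           0
subset         AB   GD   DP
true_lineage
AB            746    0    8
GD              0  451    2
DP              0    1  292
    recall  precision
AB   0.989      1.000
GD   0.996      0.998
DP   0.997      0.967
```

The gating table counts initial labels per donor; the confusion matrix
compares final subset calls against the planted lineages, here recovering the
20% DP population with 99.7% recall and 96.7% precision.

The same stages are available from the shell:

```bash
dptcell simulate expression --seed 7 --out data/
dptcell preprocess --in data/ --out data/matrix.h5ad
dptcell gate --matrix data/matrix.h5ad --out gates.csv
dptcell classify --matrix data/matrix.h5ad --gates gates.csv \
        --donors donor1,donor2 --out subsets.csv
dptcell pipeline run --seed 7 --out run/      # full orchestrated run
```

`dptcell pipeline run` writes a `manifest.json` recording every artifact with
its SHA-256 hash and the per-stage seeds; reruns with the same global seed
are byte-identical.

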