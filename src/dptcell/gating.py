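"""Rule-based T-cell subset gating on TCR constant-chain expression.

A cell is called alpha-beta (AB) when TRAC is high and every gamma/delta
constant chain is low, gamma-delta (GD) when TRAC is low and any gamma/delta
chain is high, and double-positive (DP) when TRAC and at least one
gamma/delta chain are both high.  Beta-chain constants (TRBC1/TRBC2) are on
in all T cells and take no part in the rules.  Comparisons are strict
(log TPM > 2.5 high, < 0.5 low); everything else is UNASSIGNED and left for
the lineage classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

GATE_LABELS = ("AB", "GD", "DP", "UNASSIGNED")


@dataclass(frozen=True)
class GatingConfig:
    alpha_gene: str = "TRAC"
    gd_genes: tuple[str, ...] = ("TRDC", "TRGC1", "TRGC2")
    beta_genes: tuple[str, ...] = ("TRBC1", "TRBC2")  # excluded from rules
    hi_threshold: float = 2.5
    lo_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not self.lo_threshold < self.hi_threshold:
            raise ValueError("lo_threshold must be < hi_threshold")
        if self.alpha_gene in self.gd_genes:
            raise ValueError("alpha_gene must not be among gd_genes")


def assign_by_constant_chains(
    adata: ad.AnnData, config: GatingConfig | None = None
) -> pd.Series:
    """Per-cell gate label (AB/GD/DP/UNASSIGNED) from log-TPM thresholds."""
    config = config or GatingConfig()
    if "log_tpm" not in adata.layers:
        raise ValueError("log_tpm layer missing; run preprocessing first")
    needed = (config.alpha_gene, *config.gd_genes)
    missing = [g for g in needed if g not in adata.var_names]
    if missing:
        raise ValueError(f"configured gating genes absent from matrix: {missing}")

    x = np.asarray(adata.layers["log_tpm"])
    gi = {g: adata.var_names.get_loc(g) for g in needed}
    alpha = x[:, gi[config.alpha_gene]]
    gd = x[:, [gi[g] for g in config.gd_genes]]

    hi, lo = config.hi_threshold, config.lo_threshold
    alpha_hi, alpha_lo = alpha > hi, alpha < lo
    any_gd_hi = (gd > hi).any(axis=1)
    all_gd_lo = (gd < lo).all(axis=1)

    labels = np.full(adata.n_obs, "UNASSIGNED", dtype=object)
    labels[alpha_hi & all_gd_lo] = "AB"
    labels[alpha_lo & any_gd_hi] = "GD"
    labels[alpha_hi & any_gd_hi] = "DP"
    return pd.Series(labels, index=adata.obs_names, name="gate_label")


def gating_summary(labels: pd.Series, donors: pd.Series) -> pd.DataFrame:
    """Per-donor counts of each gate label (rows: donors, columns: labels)."""
    labels = pd.Series(labels)
    donors = pd.Series(donors).reindex(labels.index)
    if donors.isna().any():
        raise ValueError("every labeled cell needs a donor")
    tab = pd.crosstab(donors, labels)
    return tab.reindex(columns=list(GATE_LABELS), fill_value=0)
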