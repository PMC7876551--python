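"""Count normalization and derived per-cell-type expression summaries.

Raw counts are normalized to transcripts per million (TPM), log-transformed
as ``ln(1 + TPM)`` and optionally gene-standardized.  All layers are derived
from the immutable ``counts`` layer, so re-running a step recomputes rather
than compounds the transformation.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd

TPM_TOTAL = 1e6


def _counts(adata: ad.AnnData) -> np.ndarray:
    if "counts" in adata.layers:
        return np.asarray(adata.layers["counts"], dtype=np.float64)
    return np.asarray(adata.X, dtype=np.float64)


def tpm_normalize(adata: ad.AnnData) -> ad.AnnData:
    """Add a ``tpm`` layer: counts scaled so each cell sums to 1e6.

    Raises ``ValueError`` naming the offending cells if any cell has zero
    total counts.
    """
    counts = _counts(adata)
    totals = counts.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = list(adata.obs_names[zero][:20])
        raise ValueError(f"cells with zero total counts cannot be TPM-normalized: {bad}")
    adata.layers["tpm"] = counts / totals[:, None] * TPM_TOTAL
    return adata


def log_transform(adata: ad.AnnData) -> ad.AnnData:
    """Add a ``log_tpm`` layer, ``ln(1 + TPM)``."""
    if "tpm" not in adata.layers:
        raise ValueError("tpm layer missing; run tpm_normalize first")
    adata.layers["log_tpm"] = np.log1p(np.asarray(adata.layers["tpm"]))
    return adata


def scale_genes(adata: ad.AnnData, cap: float = 10.0) -> ad.AnnData:
    """Add a ``scaled`` layer: per-gene z-scores of log-TPM, clipped at ±cap.

    Uses the sample standard deviation (n−1 denominator); zero-variance genes
    map to all zeros.
    """
    if "log_tpm" not in adata.layers:
        raise ValueError("log_tpm layer missing; run log_transform first")
    x = np.asarray(adata.layers["log_tpm"], dtype=np.float64)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (x - mean) / safe_sd
    z[:, sd <= 0] = 0.0
    adata.layers["scaled"] = np.clip(z, -cap, cap)
    return adata


def preprocess(adata: ad.AnnData, scale: bool = False, cap: float = 10.0) -> ad.AnnData:
    """TPM-normalize and log-transform (and optionally scale) in one call."""
    tpm_normalize(adata)
    log_transform(adata)
    if scale:
        scale_genes(adata, cap=cap)
    return adata


def expression_fraction(adata: ad.AnnData, cell_type_labels: pd.Series) -> pd.DataFrame:
    """Fraction of cells of each type with nonzero counts, gene x cell-type.

    Every cell must carry a label; used by the receptor–ligand gene filter.
    """
    labels = pd.Series(cell_type_labels).reindex(adata.obs_names)
    if labels.isna().any():
        bad = list(labels.index[labels.isna()][:20])
        raise ValueError(f"unlabeled cells: {bad}")
    counts = _counts(adata)
    nonzero = counts > 0
    out = {}
    for ct in sorted(labels.unique()):
        mask = (labels == ct).to_numpy()
        out[ct] = nonzero[mask].mean(axis=0)
    return pd.DataFrame(out, index=adata.var_names)
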