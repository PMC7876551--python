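"""Conserved-marker discovery between T-cell subsets.

Differential expression is tested per donor with a negative-binomial
likelihood-ratio test: per gene, group means are fitted on the size-factor
normalized scale under a shared method-of-moments dispersion, and the
one-degree-of-freedom deviance between the pooled-mean and separate-mean fits
is referred to a chi-squared distribution.  Genes are "conserved" markers
when they are significant (BH-adjusted p below alpha) with a sufficiently
large, sign-consistent log fold-change in every required donor.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

LOGFC_EPS = 1e-9


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def _nb_loglik(counts: np.ndarray, mu: np.ndarray, theta: float) -> float:
    mu = np.maximum(mu, 1e-12)
    if not np.isfinite(theta):  # Poisson limit
        return float(np.sum(counts * np.log(mu) - mu - special.gammaln(counts + 1)))
    return float(
        np.sum(
            special.gammaln(counts + theta)
            - special.gammaln(theta)
            - special.gammaln(counts + 1)
            + theta * np.log(theta / (theta + mu))
            + counts * np.log(mu / (theta + mu))
        )
    )


def _moment_dispersion(normalized: np.ndarray) -> float:
    """Shared NB dispersion theta from pooled normalized counts (per gene)."""
    m = normalized.mean()
    v = normalized.var(ddof=1) if len(normalized) > 1 else 0.0
    if v <= m or m <= 0:
        return np.inf  # at or below Poisson: fall back to Poisson likelihood
    return m * m / (v - m)


def nb_test(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    size_factors_a: np.ndarray | None = None,
    size_factors_b: np.ndarray | None = None,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test between two cell groups.

    ``counts_*`` are cells x genes integer arrays; size factors default to 1.
    Returns a DataFrame with ``log_fc`` (natural log of normalized group-mean
    ratio, A over B) and ``pvalue``.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, dtype=np.float64))
    counts_b = np.atleast_2d(np.asarray(counts_b, dtype=np.float64))
    if counts_a.shape[0] == 0 or counts_b.shape[0] == 0:
        raise ValueError("both groups must be nonempty")
    if counts_a.shape[1] != counts_b.shape[1]:
        raise ValueError("gene dimensions differ between groups")
    sa = np.ones(counts_a.shape[0]) if size_factors_a is None else np.asarray(size_factors_a, float)
    sb = np.ones(counts_b.shape[0]) if size_factors_b is None else np.asarray(size_factors_b, float)

    n_genes = counts_a.shape[1]
    log_fc = np.zeros(n_genes)
    pvals = np.ones(n_genes)
    s_all = np.concatenate([sa, sb])
    for g in range(n_genes):
        ca, cb = counts_a[:, g], counts_b[:, g]
        c_all = np.concatenate([ca, cb])
        qa, qb = ca.sum() / sa.sum(), cb.sum() / sb.sum()
        q0 = c_all.sum() / s_all.sum()
        log_fc[g] = np.log(qa + LOGFC_EPS) - np.log(qb + LOGFC_EPS)
        if c_all.sum() == 0:
            continue
        theta = _moment_dispersion(c_all / s_all)
        ll_sep = _nb_loglik(ca, sa * qa, theta) + _nb_loglik(cb, sb * qb, theta)
        ll_pool = _nb_loglik(c_all, s_all * q0, theta)
        stat = max(0.0, 2.0 * (ll_sep - ll_pool))
        pvals[g] = float(stats.chi2.sf(stat, df=1))
    index = pd.Index(genes, name="gene") if genes is not None else pd.RangeIndex(n_genes)
    return pd.DataFrame({"log_fc": log_fc, "pvalue": pvals}, index=index)


def conserved_markers(
    per_donor_results: dict[str, pd.DataFrame],
    donors_required: list[str],
    alpha: float = 0.05,
    min_logfc: float = 0.1,
) -> pd.DataFrame:
    """Combine per-donor DE tables into a conserved-marker table.

    BH adjustment is applied within each donor; a gene is conserved when in
    every required donor its adjusted p < alpha, |log FC| >= min_logfc and the
    fold-change signs agree.
    """
    missing = [d for d in donors_required if d not in per_donor_results]
    if missing:
        raise ValueError(f"missing DE results for donors: {missing}")
    pieces = {}
    for donor in donors_required:
        res = per_donor_results[donor].copy()
        res["p_adjusted"] = bh_adjust(res["pvalue"])
        pieces[donor] = res
    genes = pieces[donors_required[0]].index
    out = pd.DataFrame(index=genes)
    for donor, res in pieces.items():
        res = res.reindex(genes)
        out[f"{donor}_log_fc"] = res["log_fc"]
        out[f"{donor}_pvalue"] = res["pvalue"]
        out[f"{donor}_p_adjusted"] = res["p_adjusted"]
    sig = np.ones(len(genes), dtype=bool)
    signs = []
    for donor in donors_required:
        lfc = out[f"{donor}_log_fc"].to_numpy()
        sig &= (out[f"{donor}_p_adjusted"].to_numpy() < alpha) & (np.abs(lfc) >= min_logfc)
        signs.append(np.sign(lfc))
    signs = np.vstack(signs)
    consistent = (signs == signs[0]).all(axis=0) & (signs[0] != 0)
    out["conserved"] = sig & consistent
    return out


def find_conserved_markers(
    adata: ad.AnnData,
    subset_labels: pd.Series,
    group_a: str = "AB",
    group_b: str = "GD",
    donors: list[str] | None = None,
    alpha: float = 0.05,
    min_logfc: float = 0.1,
) -> pd.DataFrame:
    """Run the per-donor NB test for group_a vs group_b and combine.

    Size factors are total counts / 1e6, so group means (and log FC) are on
    the TPM scale.
    """
    labels = pd.Series(subset_labels).reindex(adata.obs_names)
    counts = np.asarray(adata.layers.get("counts", adata.X), dtype=np.float64)
    size = counts.sum(axis=1) / 1e6
    donor_col = adata.obs["donor"]
    donors = donors or sorted(donor_col.unique())
    results = {}
    for donor in donors:
        in_d = (donor_col == donor).to_numpy()
        ma = in_d & (labels == group_a).to_numpy()
        mb = in_d & (labels == group_b).to_numpy()
        if ma.sum() == 0 or mb.sum() == 0:
            raise ValueError(f"donor {donor} lacks cells in {group_a} or {group_b}")
        results[donor] = nb_test(
            counts[ma], counts[mb], size[ma], size[mb], genes=list(adata.var_names)
        )
    return conserved_markers(results, donors, alpha=alpha, min_logfc=min_logfc)
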