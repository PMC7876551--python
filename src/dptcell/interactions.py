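"""Receptor–ligand interaction inference between T subsets and other cells.

For each annotated gene pair, the score combines the mean TPM of the
receptor-side gene over one T-cell subset with the mean TPM of the
ligand-side gene over one non-T cell type:
``log2((mean_a + mean_b) / 2 + pseudocount)``.  Specificity is assessed
against two background distributions of re-scored draws — one replacing the
T cells with random same-size sets of other T cells, one replacing the non-T
cells likewise — and the observed score is referred to the upper tail of a
Student-t location/scale fit of each background.  The two p-values are
combined by their maximum and BH-adjusted across all rows of the run.
Only genes detected in at least ``min_fraction`` of cells of some cell type
enter the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .markers import bh_adjust
from .preprocess import expression_fraction

logger = logging.getLogger(__name__)

T_SUBSETS = ("AB", "GD", "DP")


@dataclass(frozen=True)
class InteractionConfig:
    min_fraction: float = 0.20
    n_draws: int = 1000
    seed: int = 0
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")


def load_pairs(path: str | Path) -> pd.DataFrame:
    """Read a two-gene-per-row annotation CSV (gene_a, gene_b[, source])."""
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if not {"gene_a", "gene_b"} <= set(cols):
        raise ValueError(f"pair table {path} must have gene_a and gene_b columns")
    if "source" not in df.columns:
        df["source"] = "unknown"
    bad = df.index[df["gene_a"].isna() | df["gene_b"].isna() | (df["gene_a"] == "") | (df["gene_b"] == "")]
    if len(bad):
        # +2: header line plus 1-based indexing
        raise ValueError(f"malformed pair rows (missing gene) at lines: {[i + 2 for i in bad[:10]]}")
    out = df[["gene_a", "gene_b", "source"]].drop_duplicates().reset_index(drop=True)
    if out.empty:
        logger.warning("pair table %s is empty", path)
    return out


def filter_pairs(
    pairs: pd.DataFrame,
    fraction_table: pd.DataFrame,
    config: InteractionConfig | None = None,
) -> pd.DataFrame:
    """Keep pairs whose two genes are each detected in >= min_fraction of
    cells in at least one cell type (and are present in the matrix)."""
    config = config or InteractionConfig()
    eligible = set(fraction_table.index[fraction_table.max(axis=1) >= config.min_fraction])
    keep = pairs["gene_a"].isin(eligible) & pairs["gene_b"].isin(eligible)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_pairs: dropped %d of %d pairs", dropped, len(pairs))
    return pairs[keep].reset_index(drop=True)


def _tpm(adata: ad.AnnData) -> np.ndarray:
    if "tpm" not in adata.layers:
        raise ValueError("tpm layer missing; run preprocessing first")
    return np.asarray(adata.layers["tpm"], dtype=np.float64)


def interaction_score(
    adata: ad.AnnData,
    pair: tuple[str, str],
    cells_a: np.ndarray,
    cells_b: np.ndarray,
    config: InteractionConfig | None = None,
) -> float:
    """log2 of the average of the two cell-type-mean TPMs, plus pseudocount."""
    config = config or InteractionConfig()
    if len(cells_a) == 0 or len(cells_b) == 0:
        raise ValueError("both cell sets must be nonempty")
    tpm = _tpm(adata)
    ia = adata.var_names.get_loc(pair[0])
    ib = adata.var_names.get_loc(pair[1])
    mean_a = tpm[cells_a, ia].mean()
    mean_b = tpm[cells_b, ib].mean()
    return float(np.log2((mean_a + mean_b) / 2 + config.pseudocount))


def _score_from_means(mean_a, mean_b, pseudocount: float):
    return np.log2((np.asarray(mean_a) + np.asarray(mean_b)) / 2 + pseudocount)


def background_distribution(
    adata: ad.AnnData,
    pair: tuple[str, str],
    fixed_side: str,
    fixed_cells: np.ndarray,
    swap_pool: np.ndarray,
    swap_size: int,
    config: InteractionConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Scores of ``n_draws`` re-computations with one side swapped out.

    ``fixed_side`` is "a" or "b": the partner whose original cells are kept.
    The other partner's cells are replaced, per draw, by ``swap_size`` cells
    drawn without replacement from ``swap_pool``.
    """
    config = config or InteractionConfig()
    if fixed_side not in ("a", "b"):
        raise ValueError("fixed_side must be 'a' or 'b'")
    if swap_size < 1 or len(swap_pool) < swap_size:
        raise ValueError(
            f"swap pool of {len(swap_pool)} cells cannot supply draws of {swap_size}"
        )
    rng = rng or np.random.default_rng(config.seed)
    tpm = _tpm(adata)
    ia = adata.var_names.get_loc(pair[0])
    ib = adata.var_names.get_loc(pair[1])
    fixed_gene, swap_gene = (ia, ib) if fixed_side == "a" else (ib, ia)
    fixed_mean = tpm[fixed_cells, fixed_gene].mean()
    pool_expr = tpm[swap_pool, swap_gene]
    draw_means = np.empty(config.n_draws)
    for i in range(config.n_draws):
        idx = rng.choice(len(pool_expr), size=swap_size, replace=False)
        draw_means[i] = pool_expr[idx].mean()
    if fixed_side == "a":
        return _score_from_means(fixed_mean, draw_means, config.pseudocount)
    return _score_from_means(draw_means, fixed_mean, config.pseudocount)


def interaction_pvalue(observed_score: float, background_scores: np.ndarray) -> float:
    """Upper-tail probability of the observed score under a Student-t
    location/scale fit of the background; small p means the observed score
    exceeds what random same-size cell sets produce."""
    bg = np.asarray(background_scores, dtype=float)
    if len(bg) < 2:
        raise ValueError("need at least 2 background scores")
    mean, sd = bg.mean(), bg.std(ddof=1)
    if sd == 0:
        return 1.0 if observed_score <= mean else 1.0 / len(bg)
    z = (observed_score - mean) / sd
    return float(stats.t.sf(z, df=len(bg) - 1))


def combine_and_adjust(results: pd.DataFrame) -> pd.DataFrame:
    """Add max-combined and BH-adjusted p-values across all rows of a run."""
    if results.empty:
        return results.assign(p_combined=[], p_adjusted=[])
    if results[["p_bg_tcell", "p_bg_other"]].isna().any().any():
        raise ValueError("both background p-values must be present for every row")
    out = results.copy()
    out["p_combined"] = out[["p_bg_tcell", "p_bg_other"]].max(axis=1)
    out["p_adjusted"] = bh_adjust(out["p_combined"])
    return out


def run_interaction_analysis(
    adata: ad.AnnData,
    subset_labels: pd.Series,
    pairs: pd.DataFrame,
    config: InteractionConfig | None = None,
) -> pd.DataFrame:
    """Score every eligible (pair, T-subset, non-T type) combination.

    ``subset_labels`` holds final AB/GD/DP calls for T cells and cell-type
    names for everything else.  gene_a is the partner expressed on the T-cell
    side.  Backgrounds swap the T subset against the other T cells and the
    non-T type against the other non-T cells.
    """
    config = config or InteractionConfig()
    labels = pd.Series(subset_labels).reindex(adata.obs_names)
    if labels.isna().any():
        raise ValueError("every cell needs a subset/cell-type label")
    lab = labels.to_numpy()
    t_types = [t for t in T_SUBSETS if (lab == t).any()]
    other_types = sorted(set(lab) - set(T_SUBSETS))
    if not t_types or not other_types:
        raise ValueError("need both T-cell subsets and non-T cell types")
    frac = expression_fraction(adata, labels)
    eligible = filter_pairs(pairs, frac, config)
    if eligible.empty:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "source", "type_a", "type_b", "score",
                     "p_bg_tcell", "p_bg_other", "p_combined", "p_adjusted"]
        )

    all_idx = np.arange(adata.n_obs)
    is_t = np.isin(lab, T_SUBSETS)
    rng = np.random.default_rng(config.seed)
    rows = []
    for t_type in t_types:
        cells_t = all_idx[lab == t_type]
        pool_t = all_idx[is_t & (lab != t_type)]
        for o_type in other_types:
            cells_o = all_idx[lab == o_type]
            pool_o = all_idx[~is_t & (lab != o_type)]
            for _, pr in eligible.iterrows():
                pair = (pr["gene_a"], pr["gene_b"])
                if pair[0] not in adata.var_names or pair[1] not in adata.var_names:
                    logger.info("skipping pair %s: gene absent from matrix", pair)
                    continue
                # swap sets match the replaced group's size where the pool
                # allows; a smaller pool caps the draw (noisier background,
                # hence conservative p-values) rather than dropping the row
                size_t = min(len(cells_t), len(pool_t))
                size_o = min(len(cells_o), len(pool_o))
                if size_t < 1 or size_o < 1:
                    logger.info("skipping (%s, %s, %s/%s): empty swap pool",
                                *pair, t_type, o_type)
                    continue
                score = interaction_score(adata, pair, cells_t, cells_o, config)
                bg_t = background_distribution(
                    adata, pair, "b", cells_o, pool_t, size_t, config, rng
                )
                bg_o = background_distribution(
                    adata, pair, "a", cells_t, pool_o, size_o, config, rng
                )
                rows.append(
                    {
                        "gene_a": pair[0],
                        "gene_b": pair[1],
                        "source": pr["source"],
                        "type_a": t_type,
                        "type_b": o_type,
                        "score": score,
                        "p_bg_tcell": interaction_pvalue(score, bg_t),
                        "p_bg_other": interaction_pvalue(score, bg_o),
                    }
                )
    return combine_and_adjust(pd.DataFrame(rows))
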