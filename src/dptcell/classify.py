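"""Elastic-net lineage classifier with nested and cross-donor validation.

A weighted logistic regression with an elastic-net penalty is trained per
donor on the gated alpha-beta (class 0) and gamma-delta (class 1) cells,
using log-TPM expression of all genes except the TCR constant chains, so the
model cannot simply read the gating rule back off the features.  The penalty
strength λ is chosen by an inner K-fold loop minimizing weighted binomial
deviance along a glmnet-style λ path; an outer stratified loop estimates
generalization AUC without leaking the test fold into λ selection.  Averaged
probabilities from the per-donor models place each ungated cell on an
alpha-beta (p→0) to gamma-delta (p→1) axis; cells in the intermediate band
are called double-positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .simulate import TCR_CONSTANT_GENES

logger = logging.getLogger(__name__)

CLASS_ENCODING = {"AB": 0, "GD": 1}


@dataclass(frozen=True)
class ClassifierConfig:
    outer_folds: int = 5
    inner_folds: int = 10
    band_lo: float = 0.25
    band_hi: float = 0.75
    mixing_alpha: float = 0.5
    n_lambda: int = 15
    lambda_min_ratio: float = 0.01
    training_donors: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.band_lo < self.band_hi < 1:
            raise ValueError("require 0 < band_lo < band_hi < 1")
        if not 0 <= self.mixing_alpha <= 1:
            raise ValueError("mixing_alpha must be in [0, 1]")


@dataclass
class LineageModel:
    """Fitted per-donor model; ``predict`` returns P(gamma-delta)."""

    donor: str
    genes: list[str]
    coefficients: np.ndarray  # on the original log-TPM scale
    intercept: float
    mixing_alpha: float
    penalty_lambda: float

    def coefficient_map(self) -> dict[str, float]:
        return dict(zip(self.genes, self.coefficients.tolist()))

    def predict(self, adata: ad.AnnData) -> pd.Series:
        x = _features(adata)
        coef = pd.Series(self.coefficients, index=self.genes)
        aligned = coef.reindex(adata.var_names, fill_value=0.0).to_numpy()
        missing = [g for g in self.genes if g not in adata.var_names]
        if missing:
            logger.warning("model genes absent from matrix (treated as zero): %d", len(missing))
        score = x @ aligned + self.intercept
        prob = 1.0 / (1.0 + np.exp(-score))
        return pd.Series(prob, index=adata.obs_names, name="p_gd")

    def to_dict(self) -> dict:
        return {
            "donor": self.donor,
            "intercept": self.intercept,
            "mixing_alpha": self.mixing_alpha,
            "penalty_lambda": self.penalty_lambda,
            "class_encoding": CLASS_ENCODING,
            "coefficients": self.coefficient_map(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageModel":
        genes = list(d["coefficients"])
        return cls(
            donor=d["donor"],
            genes=genes,
            coefficients=np.array([d["coefficients"][g] for g in genes]),
            intercept=float(d["intercept"]),
            mixing_alpha=float(d["mixing_alpha"]),
            penalty_lambda=float(d["penalty_lambda"]),
        )


def _features(adata: ad.AnnData) -> np.ndarray:
    if "log_tpm" not in adata.layers:
        raise ValueError("log_tpm layer missing; run preprocessing first")
    return np.asarray(adata.layers["log_tpm"], dtype=np.float64)


def strip_tcr_genes(
    adata: ad.AnnData, tcr_genes: tuple[str, ...] = TCR_CONSTANT_GENES
) -> ad.AnnData:
    """Drop the TCR constant-chain genes from the feature space."""
    present = [g for g in tcr_genes if g in adata.var_names]
    if len(present) < len(tcr_genes):
        logger.warning(
            "some TCR genes absent from matrix: %s", sorted(set(tcr_genes) - set(present))
        )
    keep = [g for g in adata.var_names if g not in set(tcr_genes)]
    return adata[:, keep].copy()


def class_weights(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Balanced weights n_total / (2 * n_class); each class sums to n/2."""
    labels = np.asarray(labels)
    n = len(labels)
    weights = np.empty(n, dtype=np.float64)
    for cls in CLASS_ENCODING:
        mask = labels == cls
        if not mask.any():
            raise ValueError(f"class {cls} has zero members; cannot weight")
        weights[mask] = n / (2 * mask.sum())
    if set(np.unique(labels)) - set(CLASS_ENCODING):
        raise ValueError("labels must be AB or GD only")
    return weights


def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
    safe = np.where(sd > 0, sd, 1.0)
    return (x - mean) / safe, mean, safe


def _lambda_path(
    xs: np.ndarray, y: np.ndarray, w: np.ndarray, config: ClassifierConfig
) -> np.ndarray:
    """glmnet-style geometric λ path from the smallest all-zero-coefficient λ."""
    n = len(y)
    ybar = np.average(y, weights=w)
    grad = xs.T @ (w * (y - ybar)) / n
    alpha = max(config.mixing_alpha, 1e-3)  # ridge limit still needs a finite path
    lam_max = np.abs(grad).max() / alpha
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * config.lambda_min_ratio, config.n_lambda)


def _enet_estimator(alpha: float) -> LogisticRegression:
    return LogisticRegression(
        solver="saga",
        l1_ratio=alpha,
        max_iter=2000,
        tol=1e-3,
        warm_start=True,
        random_state=0,  # saga's internal shuffling; fold seeds live in the CV
    )


def _fit_enet(
    xs: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    lam: float,
    alpha: float,
    model: LogisticRegression | None = None,
) -> tuple[np.ndarray, float]:
    # glmnet objective (1/n)·Σ wᵢℓᵢ + λ·(α‖β‖₁ + (1−α)/2·‖β‖²) maps to
    # sklearn's C·Σ wᵢℓᵢ + penalty with C = 1/(n·λ); a warm-started model
    # reused along a decreasing-λ path converges much faster
    model = model if model is not None else _enet_estimator(alpha)
    model.C = 1.0 / (len(y) * lam)
    model.fit(xs, y, sample_weight=w)
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def _deviance(p: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2 * np.sum(w * (y * np.log(p) + (1 - y) * np.log(1 - p))) / w.sum())


def _select_lambda(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, config: ClassifierConfig, seed: int
) -> float:
    xs_all, _, _ = _standardize(x)
    path = _lambda_path(xs_all, y, w, config)
    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True, random_state=seed)
    dev = np.zeros(len(path))
    for tr, va in skf.split(x, y):
        xs, mean, sd = _standardize(x[tr])
        xv = (x[va] - mean) / sd
        model = _enet_estimator(config.mixing_alpha)
        for i, lam in enumerate(path):  # path runs from strong to weak penalty
            coef, b0 = _fit_enet(xs, y[tr], w[tr], lam, config.mixing_alpha, model)
            p = 1.0 / (1.0 + np.exp(-(xv @ coef + b0)))
            dev[i] += _deviance(p, y[va], w[va])
    return float(path[int(np.argmin(dev))])


def _fit_final(
    x: np.ndarray, y: np.ndarray, w: np.ndarray, lam: float, alpha: float
) -> tuple[np.ndarray, float]:
    xs, mean, sd = _standardize(x)
    coef_s, b0_s = _fit_enet(xs, y, w, lam, alpha)
    coef = coef_s / sd
    return coef, b0_s - float(coef @ mean)


def _donor_training_data(
    adata: ad.AnnData, gate_labels: pd.Series, donor: str, config: ClassifierConfig
) -> tuple[ad.AnnData, np.ndarray, np.ndarray]:
    gate_labels = pd.Series(gate_labels).reindex(adata.obs_names)
    mask = (adata.obs["donor"] == donor).to_numpy() & gate_labels.isin(CLASS_ENCODING).to_numpy()
    sub = adata[mask]
    labels = gate_labels[mask]
    for cls in CLASS_ENCODING:
        n_cls = int((labels == cls).sum())
        if n_cls < config.inner_folds:
            raise ValueError(
                f"donor {donor} has {n_cls} {cls} cells; need >= inner_folds="
                f"{config.inner_folds} (use fewer folds or more cells)"
            )
    sub = strip_tcr_genes(sub)
    y = labels.map(CLASS_ENCODING).to_numpy(dtype=np.int64)
    return sub, y, class_weights(labels)


def train_donor_model(
    adata: ad.AnnData,
    gate_labels: pd.Series,
    donor: str,
    config: ClassifierConfig | None = None,
) -> LineageModel:
    """Train one donor's elastic-net model on its gated AB/GD cells."""
    config = config or ClassifierConfig()
    sub, y, w = _donor_training_data(adata, gate_labels, donor, config)
    x = _features(sub)
    lam = _select_lambda(x, y, w, config, config.seed)
    coef, intercept = _fit_final(x, y, w, lam, config.mixing_alpha)
    return LineageModel(
        donor=donor,
        genes=list(sub.var_names),
        coefficients=coef,
        intercept=intercept,
        mixing_alpha=config.mixing_alpha,
        penalty_lambda=lam,
    )


def nested_cv_evaluate(
    adata: ad.AnnData,
    gate_labels: pd.Series,
    donor: str,
    config: ClassifierConfig | None = None,
) -> dict:
    """Nested cross-validation on one donor's gated cells.

    Outer folds are stratified by class; λ is re-selected inside each outer
    training set, so the held-out fold never influences model selection.
    Returns per-fold AUCs, the pooled AUC, pooled ROC points and the
    out-of-fold probabilities.
    """
    config = config or ClassifierConfig()
    sub, y, w = _donor_training_data(adata, gate_labels, donor, config)
    x = _features(sub)
    skf = StratifiedKFold(
        n_splits=config.outer_folds, shuffle=True, random_state=config.seed
    )
    oof = np.full(len(y), np.nan)
    fold_aucs = []
    for k, (tr, te) in enumerate(skf.split(x, y)):
        lam = _select_lambda(x[tr], y[tr], w[tr], config, config.seed + 1 + k)
        coef, b0 = _fit_final(x[tr], y[tr], w[tr], lam, config.mixing_alpha)
        p = 1.0 / (1.0 + np.exp(-(x[te] @ coef + b0)))
        oof[te] = p
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], p)))
    assert not np.isnan(oof).any(), "every cell must be scored exactly once"
    fpr, tpr, _ = roc_curve(y, oof)
    return {
        "fold_aucs": fold_aucs,
        "auc": float(roc_auc_score(y, oof)),
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        "probabilities": pd.Series(oof, index=sub.obs_names, name="p_gd"),
    }


def cross_donor_evaluate(
    model: LineageModel,
    adata: ad.AnnData,
    gate_labels: pd.Series,
    target_donor: str,
) -> float:
    """AUC of one donor's model on another donor's gated cells."""
    gate_labels = pd.Series(gate_labels).reindex(adata.obs_names)
    mask = (adata.obs["donor"] == target_donor).to_numpy() & gate_labels.isin(
        CLASS_ENCODING
    ).to_numpy()
    sub = adata[mask]
    y = gate_labels[mask].map(CLASS_ENCODING).to_numpy(dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError(f"target donor {target_donor} lacks one of the two classes")
    p = model.predict(sub).to_numpy()
    return float(roc_auc_score(y, p))


def predict_probability(models: list[LineageModel], adata: ad.AnnData) -> pd.Series:
    """Unweighted mean of the per-donor model probabilities P(gamma-delta)."""
    if not models:
        raise ValueError("need at least one trained model")
    probs = [m.predict(adata) for m in models]
    return pd.concat(probs, axis=1).mean(axis=1).rename("p_gd")


def assign_final_subsets(
    gate_labels: pd.Series,
    probabilities: pd.Series,
    config: ClassifierConfig | None = None,
) -> pd.Series:
    """Resolve UNASSIGNED cells by probability band; gated cells keep labels.

    p ≤ band_lo → AB, p ≥ band_hi → GD, strictly in between → DP.
    """
    config = config or ClassifierConfig()
    gate_labels = pd.Series(gate_labels)
    final = gate_labels.copy().astype(object)
    un = gate_labels == "UNASSIGNED"
    p = pd.Series(probabilities).reindex(gate_labels.index)
    if un.any() and p[un].isna().any():
        bad = list(gate_labels.index[un & p.isna()][:20])
        raise ValueError(f"missing probability for UNASSIGNED cells: {bad}")
    final[un & (p <= config.band_lo)] = "AB"
    final[un & (p >= config.band_hi)] = "GD"
    final[un & (p > config.band_lo) & (p < config.band_hi)] = "DP"
    return final.rename("subset")


def recover_planted_lineages(
    final_labels: pd.Series, truth: pd.DataFrame
) -> dict:
    """Confusion matrix and per-class recall/precision over planted T cells."""
    t = truth.set_index("cell_id") if "cell_id" in truth.columns else truth
    t = t.loc[t["true_lineage"].isin(["AB", "GD", "DP"])]
    pred = pd.Series(final_labels).reindex(t.index)
    order = ["AB", "GD", "DP"]
    conf = pd.crosstab(t["true_lineage"], pred).reindex(
        index=order, columns=order, fill_value=0
    )
    diag = pd.Series(np.diag(conf), index=order, dtype=float)
    recall = diag / conf.sum(axis=1).replace(0, np.nan)
    precision = diag / conf.sum(axis=0).replace(0, np.nan)
    return {"confusion": conf, "recall": recall, "precision": precision}
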