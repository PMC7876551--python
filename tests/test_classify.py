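import numpy as np
import pandas as pd
import pytest

from dptcell import (
    ClassifierConfig,
    LineageModel,
    TCR_CONSTANT_GENES,
    assign_final_subsets,
    class_weights,
    cross_donor_evaluate,
    nested_cv_evaluate,
    predict_probability,
    recover_planted_lineages,
    strip_tcr_genes,
    train_donor_model,
)
from conftest import make_adata

SMALL_CFG = ClassifierConfig(outer_folds=3, inner_folds=5, n_lambda=8, seed=0)


def separable_donor(n_per_class=30, n_genes=10, noise=0.05, seed=0, donor="d1"):
    """Tiny donor where gene 0 perfectly separates AB from GD."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    log_tpm = rng.uniform(0, noise, size=(n, n_genes))
    y = np.array(["AB"] * n_per_class + ["GD"] * n_per_class)
    log_tpm[y == "GD", 0] += 5.0
    adata = make_adata(np.ones((n, n_genes), dtype=int), donor=donor)
    adata.layers["log_tpm"] = log_tpm
    labels = pd.Series(y, index=adata.obs_names)
    return adata, labels


def test_strip_tcr_genes_drops_exactly_the_constants():
    genes = list(TCR_CONSTANT_GENES) + [f"G{i}" for i in range(94)]
    adata = make_adata(np.ones((3, 100), dtype=int), genes=genes)
    out = strip_tcr_genes(adata)
    assert out.n_vars == 94
    assert not set(TCR_CONSTANT_GENES) & set(out.var_names)
    assert list(out.obs_names) == list(adata.obs_names)
    # absent genes tolerated
    plain = make_adata(np.ones((3, 4), dtype=int), genes=list("WXYZ"))
    assert list(strip_tcr_genes(plain).var_names) == list("WXYZ")


def test_class_weights_closed_form_and_balance():
    labels = np.array(["AB"] * 90 + ["GD"] * 10)
    w = class_weights(labels)
    assert w[0] == pytest.approx(100 / 180)
    assert w[-1] == pytest.approx(5.0)
    assert w[labels == "AB"].sum() == pytest.approx(w[labels == "GD"].sum())
    assert (class_weights(np.array(["AB", "GD"] * 25)) == 1).all()
    with pytest.raises(ValueError):
        class_weights(np.array(["AB"] * 10))


def _dummy_model(p_target, genes=("G0",), donor="dX"):
    """Model emitting a constant probability p_target."""
    logit = np.log(p_target / (1 - p_target))
    return LineageModel(
        donor=donor, genes=list(genes), coefficients=np.zeros(len(genes)),
        intercept=logit, mixing_alpha=0.5, penalty_lambda=0.1,
    )


def test_predict_probability_is_symmetric_mean():
    adata = make_adata(np.ones((4, 1), dtype=int), genes=["G0"])
    adata.layers["log_tpm"] = np.zeros((4, 1))
    m1, m2 = _dummy_model(0.2), _dummy_model(0.6)
    avg = predict_probability([m1, m2], adata)
    assert np.allclose(avg, 0.4)
    assert predict_probability([m2, m1], adata).equals(avg.rename("p_gd"))
    assert np.allclose(predict_probability([m1, m1], adata), 0.2)
    with pytest.raises(ValueError):
        predict_probability([], adata)


def test_predictions_blind_to_tcr_gene_values():
    adata, labels = separable_donor(n_per_class=10, n_genes=8)
    adata.var_names = ["TRAC", "G1", "G2", "G3", "G4", "G5", "G6", "G7"]
    # the informative gene is TRAC: stripping it must leave a null model,
    # and arbitrary TRAC values must not move predictions
    model = train_donor_model(adata, labels, "d1", SMALL_CFG)
    assert "TRAC" not in model.genes
    p1 = model.predict(adata)
    adata2 = adata.copy()
    adata2.layers["log_tpm"] = adata.layers["log_tpm"].copy()
    adata2.layers["log_tpm"][:, 0] = 99.0
    assert np.allclose(model.predict(adata2), p1)


def test_training_separates_planted_classes():
    from sklearn.metrics import roc_auc_score

    adata, labels = separable_donor()
    model = train_donor_model(adata, labels, "d1", SMALL_CFG)
    p = model.predict(adata)
    y = (labels == "GD").astype(int)
    assert roc_auc_score(y, p) == 1.0
    assert model.penalty_lambda > 0


def test_training_requires_both_classes_and_enough_cells():
    adata, labels = separable_donor(n_per_class=10)
    with pytest.raises(ValueError, match="GD"):
        train_donor_model(adata, labels.where(labels == "AB", "AB"), "d1", SMALL_CFG)
    few = ClassifierConfig(inner_folds=50)
    with pytest.raises(ValueError, match="inner_folds"):
        train_donor_model(adata, labels, "d1", few)


def test_nested_cv_perfectly_separable_gene_gives_auc_one():
    adata, labels = separable_donor()
    res = nested_cv_evaluate(adata, labels, "d1", SMALL_CFG)
    assert res["auc"] == 1.0
    assert len(res["fold_aucs"]) == SMALL_CFG.outer_folds
    assert res["probabilities"].between(0, 1).all()
    assert not res["probabilities"].isna().any()


def test_nested_cv_shuffled_labels_near_chance():
    rng = np.random.default_rng(7)
    adata, labels = separable_donor(n_per_class=100, seed=7)
    shuffled = pd.Series(rng.permutation(labels.values), index=labels.index)
    res = nested_cv_evaluate(adata, shuffled, "d1", SMALL_CFG)
    assert 0.35 <= res["auc"] <= 0.65


def test_cross_donor_transfer_and_null_model():
    import anndata as ad

    adata1, labels1 = separable_donor(seed=1, donor="d1")
    adata2, labels2 = separable_donor(seed=2, donor="d2")
    adata2.obs_names = [f"d2_{c}" for c in adata2.obs_names]
    labels2.index = adata2.obs_names
    both = ad.concat([adata1, adata2])
    labels = pd.concat([labels1, labels2])
    model = train_donor_model(both, labels, "d1", SMALL_CFG)
    assert cross_donor_evaluate(model, both, labels, "d2") >= 0.99
    null = _dummy_model(0.5, genes=list(both.var_names))
    assert cross_donor_evaluate(null, both, labels, "d2") == pytest.approx(0.5, abs=0.1)
    single = labels.where(labels == "AB", "AB")
    with pytest.raises(ValueError):
        cross_donor_evaluate(model, both, single, "d2")


@pytest.mark.parametrize(
    "p,expected",
    [(0.9, "GD"), (0.1, "AB"), (0.5, "DP"), (0.25, "AB"), (0.75, "GD"), (0.0, "AB")],
)
def test_probability_band_assignment(p, expected):
    gates = pd.Series(["UNASSIGNED"], index=["c0"])
    probs = pd.Series([p], index=["c0"])
    assert assign_final_subsets(gates, probs).iloc[0] == expected


def test_final_assignment_keeps_gated_labels_and_checks_probs():
    gates = pd.Series(["AB", "DP", "UNASSIGNED"], index=["c0", "c1", "c2"])
    probs = pd.Series([0.99, 0.99, 0.99], index=gates.index)
    final = assign_final_subsets(gates, probs)
    assert final.tolist() == ["AB", "DP", "GD"]
    assert not (final == "UNASSIGNED").any()
    with pytest.raises(ValueError, match="c2"):
        assign_final_subsets(gates, probs.drop("c2"))


def test_recover_planted_lineages_identity_on_perfect_labels():
    truth = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(6)],
            "true_lineage": ["AB", "AB", "GD", "GD", "DP", "NONT"],
        }
    )
    labels = pd.Series(["AB", "AB", "GD", "GD", "DP", "AB"], index=truth["cell_id"])
    rec = recover_planted_lineages(labels, truth)
    assert np.array_equal(np.diag(rec["confusion"]), [2, 2, 1])
    assert rec["confusion"].to_numpy().sum() == 5  # NONT excluded
    assert (rec["recall"] == 1.0).all() and (rec["precision"] == 1.0).all()
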