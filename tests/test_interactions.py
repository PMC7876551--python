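import numpy as np
import pandas as pd
import pytest

from dptcell import (
    InteractionConfig,
    background_distribution,
    combine_and_adjust,
    expression_fraction,
    filter_pairs,
    interaction_pvalue,
    interaction_score,
    load_pairs,
    run_interaction_analysis,
)
from conftest import make_adata


def tpm_adata(tpm, genes=None, **obs_cols):
    tpm = np.asarray(tpm, float)
    adata = make_adata(np.ones_like(tpm, dtype=int), genes=genes, **obs_cols)
    adata.layers["tpm"] = tpm
    return adata


def test_load_pairs_dedup_and_errors(tmp_path):
    f = tmp_path / "pairs.csv"
    f.write_text("gene_a,gene_b,source\nR1,L1,db\nR1,L1,db\nR2,L2,db\n")
    pairs = load_pairs(f)
    assert len(pairs) == 2
    f.write_text("gene_a,gene_b,source\nR1,,db\n")
    with pytest.raises(ValueError, match="line"):
        load_pairs(f)
    f.write_text("gene_a,gene_b,source\n")
    assert load_pairs(f).empty


def test_filter_pairs_boundary_inclusive_and_brute_force():
    frac = pd.DataFrame(
        {"T": [0.19, 0.20, 0.9, 0.0], "FIBRO": [0.1, 0.0, 0.9, 0.0]},
        index=["gA", "gB", "gC", "gD"],
    )
    pairs = pd.DataFrame(
        {"gene_a": ["gA", "gB", "gC"], "gene_b": ["gC", "gC", "gD"], "source": "x"}
    )
    kept = filter_pairs(pairs, frac, InteractionConfig())
    # gA at 0.19 max fraction is ineligible; gB at exactly 0.20 is eligible
    assert kept[["gene_a", "gene_b"]].values.tolist() == [["gB", "gC"]]
    eligible = {g for g in frac.index if frac.loc[g].max() >= 0.20}
    brute = pairs[[a in eligible and b in eligible for a, b in zip(pairs.gene_a, pairs.gene_b)]]
    assert kept[["gene_a", "gene_b"]].values.tolist() == brute[["gene_a", "gene_b"]].values.tolist()


def test_interaction_score_closed_form_and_symmetry():
    adata = tpm_adata([[10, 0], [10, 0], [0, 6], [0, 6]], genes=["R", "L"])
    cells_a, cells_b = np.array([0, 1]), np.array([2, 3])
    s = interaction_score(adata, ("R", "L"), cells_a, cells_b)
    assert s == pytest.approx(np.log2(9))
    # swapping gene roles together with their cell sets leaves the score unchanged
    assert interaction_score(adata, ("L", "R"), cells_b, cells_a) == pytest.approx(s)
    zero = interaction_score(adata, ("L", "R"), cells_a, cells_b)
    assert zero == pytest.approx(0.0)  # both means zero -> log2(1)
    with pytest.raises(ValueError):
        interaction_score(adata, ("R", "L"), np.array([], dtype=int), cells_b)


def test_background_contract_and_determinism():
    rng = np.random.default_rng(17)
    adata = tpm_adata(rng.uniform(0, 100, size=(60, 2)), genes=["R", "L"])
    fixed = np.arange(10)
    pool = np.arange(20, 60)
    cfg = InteractionConfig(n_draws=2, seed=17)
    assert len(background_distribution(adata, ("R", "L"), "a", fixed, pool, 10, cfg)) == 2
    cfg = InteractionConfig(n_draws=50, seed=17)
    b1 = background_distribution(adata, ("R", "L"), "a", fixed, pool, 10, cfg)
    b2 = background_distribution(adata, ("R", "L"), "a", fixed, pool, 10, cfg)
    assert np.array_equal(b1, b2)
    with pytest.raises(ValueError):
        background_distribution(adata, ("R", "L"), "a", fixed, pool, 41, cfg)


def test_background_null_recenters_on_observed():
    # swap pool drawn from the same distribution as the original cells
    rng = np.random.default_rng(17)
    adata = tpm_adata(rng.uniform(0, 100, size=(500, 2)), genes=["R", "L"])
    cells_a, cells_b = np.arange(0, 100), np.arange(100, 200)
    pool = np.arange(200, 500)
    cfg = InteractionConfig(n_draws=500, seed=17)
    obs = interaction_score(adata, ("R", "L"), cells_a, cells_b)
    bg = background_distribution(adata, ("R", "L"), "a", cells_a, pool, 100, cfg)
    # the observed score is itself one draw from the same law: the difference
    # from the background mean is on the scale of a single draw's SD
    assert abs(bg.mean() - obs) <= 3 * bg.std(ddof=1)


def test_interaction_pvalue_cases():
    rng = np.random.default_rng(17)
    bg = rng.normal(1.0, 0.1, size=1000)
    assert interaction_pvalue(5.0, bg) < 1e-10
    assert interaction_pvalue(bg.mean(), bg) == pytest.approx(0.5, abs=0.01)
    flat = np.full(100, 2.0)
    assert interaction_pvalue(1.0, flat) == 1.0
    assert interaction_pvalue(3.0, flat) == pytest.approx(0.01)
    with pytest.raises(ValueError):
        interaction_pvalue(1.0, np.array([1.0]))


def test_interaction_pvalue_uniform_under_null():
    rng = np.random.default_rng(17)
    pvals = [
        interaction_pvalue(rng.normal(), rng.normal(size=200)) for _ in range(2000)
    ]
    rate = np.mean(np.asarray(pvals) < 0.05)
    assert 0.035 <= rate <= 0.065


def test_combine_and_adjust_closed_forms():
    df = pd.DataFrame(
        {"p_bg_tcell": [0.01, 0.02, 0.03], "p_bg_other": [0.2, 0.01, 0.01]}
    )
    out = combine_and_adjust(df)
    assert out["p_combined"].tolist() == [0.2, 0.02, 0.03]
    solo = combine_and_adjust(pd.DataFrame({"p_bg_tcell": [0.01, 0.02, 0.03],
                                            "p_bg_other": [0.01, 0.02, 0.03]}))
    assert np.allclose(solo["p_adjusted"], [0.03, 0.03, 0.03])
    with pytest.raises(ValueError):
        combine_and_adjust(pd.DataFrame({"p_bg_tcell": [0.1], "p_bg_other": [np.nan]}))


def _labeled_dataset(seed=17):
    rng = np.random.default_rng(seed)
    n = 300
    labels = np.array(
        ["AB"] * 60 + ["GD"] * 60 + ["DP"] * 60 + ["FIBRO"] * 60 + ["ENDO"] * 60
    )
    tpm = rng.uniform(20, 60, size=(n, 4))
    genes = ["RCPT", "LGND", "N1", "N2"]
    # planted specificity: receptor only in DP cells, ligand only in fibroblasts
    tpm[:, 0] = np.where(labels == "DP", 500.0, 1.0)
    tpm[:, 1] = np.where(labels == "FIBRO", 500.0, 1.0)
    adata = make_adata((tpm > 0).astype(int), genes=genes)
    adata.layers["counts"] = np.ceil(tpm).astype(np.int64)
    adata.layers["tpm"] = tpm
    return adata, pd.Series(labels, index=adata.obs_names)


def test_planted_specific_pair_tops_the_run():
    adata, labels = _labeled_dataset()
    pairs = pd.DataFrame(
        {"gene_a": ["RCPT", "N1"], "gene_b": ["LGND", "N2"], "source": "x"}
    )
    res = run_interaction_analysis(adata, labels, pairs, InteractionConfig(n_draws=200, seed=17))
    assert len(res) == 2 * 3 * 2  # pairs x T subsets x other types
    top = res.loc[res["p_adjusted"].idxmin()]
    assert (top["gene_a"], top["gene_b"], top["type_a"], top["type_b"]) == (
        "RCPT", "LGND", "DP", "FIBRO",
    )


def test_run_requires_both_compartments_and_handles_empty_pairs():
    adata, labels = _labeled_dataset()
    empty = run_interaction_analysis(
        adata, labels, pd.DataFrame(columns=["gene_a", "gene_b", "source"]),
        InteractionConfig(n_draws=10, seed=1),
    )
    assert empty.empty
    t_only = labels[labels.isin(["AB", "GD", "DP"])]
    with pytest.raises(ValueError):
        run_interaction_analysis(adata[t_only.index.to_numpy()].copy(), t_only,
                                 pd.DataFrame({"gene_a": ["N1"], "gene_b": ["N2"],
                                               "source": ["x"]}),
                                 InteractionConfig(n_draws=10, seed=1))


def test_full_run_is_reproducible():
    adata, labels = _labeled_dataset()
    pairs = pd.DataFrame({"gene_a": ["RCPT"], "gene_b": ["LGND"], "source": "x"})
    cfg = InteractionConfig(n_draws=50, seed=3)
    r1 = run_interaction_analysis(adata, labels, pairs, cfg)
    r2 = run_interaction_analysis(adata, labels, pairs, cfg)
    pd.testing.assert_frame_equal(r1, r2)
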