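"""End-to-end orchestration: simulate → preprocess → gate → classify →
markers → interactions → repertoire, with a provenance manifest.

Every stage draws its seed deterministically from the global seed, so a rerun
with the same configuration reproduces byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, gating, interactions, io, markers, repertoire, simulate
from .preprocess import preprocess as _preprocess

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "gate", "classify", "markers", "interactions", "repertoire")


def derive_seed(global_seed: int, module: str) -> int:
    """Stable 31-bit per-module seed from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{module}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class CloneConfig:
    n_clones_a: int = 60
    n_clones_b: int = 50
    shared_fraction: float = 0.1


@dataclass(frozen=True)
class MarkerConfig:
    alpha: float = 0.05
    min_logfc: float = 0.1
    group_a: str = "AB"
    group_b: str = "GD"


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    log_level: str = "INFO"
    n_interaction_pairs: int = 10
    simulate: simulate.SynthConfig = field(default_factory=simulate.SynthConfig)
    gating: gating.GatingConfig = field(default_factory=gating.GatingConfig)
    classifier: classify.ClassifierConfig = field(default_factory=classify.ClassifierConfig)
    interactions: interactions.InteractionConfig = field(
        default_factory=interactions.InteractionConfig
    )
    markers: MarkerConfig = field(default_factory=MarkerConfig)
    clones: CloneConfig = field(default_factory=CloneConfig)


_BLOCKS = {
    "simulate": simulate.SynthConfig,
    "gating": gating.GatingConfig,
    "classifier": classify.ClassifierConfig,
    "interactions": interactions.InteractionConfig,
    "markers": MarkerConfig,
    "clones": CloneConfig,
}
_TOP_KEYS = {"seed", "log_level", "n_interaction_pairs", *_BLOCKS}


def _build_block(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    coerced = {}
    for k, v in data.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config block at {path}: {exc}") from exc


def normalize_config(data: dict | None) -> RunConfig:
    """Fill defaults and validate a raw config mapping; rejects unknown keys."""
    data = dict(data or {})
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys at /: {sorted(unknown)}")
    kwargs = {}
    for key in ("seed", "log_level", "n_interaction_pairs"):
        if key in data:
            kwargs[key] = data[key]
    for name, cls in _BLOCKS.items():
        block = data.get(name, {})
        if not isinstance(block, dict):
            raise ValueError(f"config block /{name} must be a mapping")
        kwargs[name] = _build_block(cls, block, f"/{name}")
    return RunConfig(**kwargs)


def validate_config(path: str | Path) -> RunConfig:
    """Load and normalize a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    return normalize_config(raw)


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    return _clean(d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _default_pair_table(var_names, n_pairs: int, seed: int) -> pd.DataFrame:
    """Synthetic receptor–ligand annotation over the simulated gene space:
    pairs a T-lineage marker gene (T-cell side) with a stromal/immune marker
    gene (other side)."""
    rng = np.random.default_rng(seed)
    t_genes = [g for g in var_names if g.startswith(("AB_T-", "GD_T-", "DP_T-"))]
    o_genes = [g for g in var_names if g.startswith(("FIBRO-", "ENDO-", "MYELOID-", "NK-", "KERAT-"))]
    if not t_genes or not o_genes:
        raise ValueError("matrix lacks marker genes to build a default pair table")
    ga = rng.choice(t_genes, size=n_pairs, replace=len(t_genes) < n_pairs)
    gb = rng.choice(o_genes, size=n_pairs, replace=len(o_genes) < n_pairs)
    return pd.DataFrame({"gene_a": ga, "gene_b": gb, "source": "synthetic"}).drop_duplicates()


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and return (and write) the artifact manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    manifest: dict = {"global_seed": config.seed, "stages": {}}

    def record(stage: str, seed: int | None, files: list[Path]) -> None:
        manifest["stages"][stage] = {
            "seed": seed,
            "files": {str(p.relative_to(out)): _sha256(p) for p in files},
        }

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("simulate")
        sim_seed = derive_seed(config.seed, "simulate")
        adata, truth = simulate.generate_expression(config.simulate.with_(seed=sim_seed))
        files = io.write_mtx_dir(adata, out / "expression")
        truth_path = out / "expression" / "truth.csv"
        truth.to_csv(truth_path, index=False)
        record("simulate", sim_seed, [*files, truth_path])

        stage("preprocess")
        _preprocess(adata)
        qc = pd.DataFrame(
            {
                "total_counts": np.asarray(adata.layers["counts"]).sum(axis=1),
                "n_genes_detected": (np.asarray(adata.layers["counts"]) > 0).sum(axis=1),
            },
            index=adata.obs_names.rename("cell_id"),
        )
        qc_path = out / "qc_summary.csv"
        qc.to_csv(qc_path)
        record("preprocess", None, [qc_path])

        stage("gate")
        # subset assignment concerns T cells only; non-T types keep their
        # coarse label for the interaction analysis
        adata_t = adata[(adata.obs["cell_type"] == "T").to_numpy()].copy()
        gate_labels = gating.assign_by_constant_chains(adata_t, config.gating)
        gate_path = io.write_labels(gate_labels, out / "gate_labels.csv", "gate_label")
        summary_path = out / "gating_summary.csv"
        gating.gating_summary(gate_labels, adata_t.obs["donor"]).to_csv(summary_path)
        record("gate", None, [gate_path, summary_path])

        stage("classify")
        cls_seed = derive_seed(config.seed, "classify")
        cls_config = dataclasses.replace(config.classifier, seed=cls_seed)
        donors = list(cls_config.training_donors or sorted(adata_t.obs["donor"].unique())[:2])
        models = [
            classify.train_donor_model(adata_t, gate_labels, d, cls_config) for d in donors
        ]
        stripped = classify.strip_tcr_genes(adata_t)
        probs = classify.predict_probability(models, stripped)
        final = classify.assign_final_subsets(gate_labels, probs, cls_config)
        final_path = io.write_labels(final, out / "final_labels.csv", "subset")
        models_path = out / "models.json"
        models_path.write_text(json.dumps([m.to_dict() for m in models], indent=1, sort_keys=True))
        recovery = classify.recover_planted_lineages(final, truth)
        rec_path = out / "recovery.csv"
        pd.concat(
            {"recall": recovery["recall"], "precision": recovery["precision"]}, axis=1
        ).to_csv(rec_path)
        record("classify", cls_seed, [final_path, models_path, rec_path])

        stage("markers")
        mk = markers.find_conserved_markers(
            adata,
            final,
            group_a=config.markers.group_a,
            group_b=config.markers.group_b,
            donors=donors,
            alpha=config.markers.alpha,
            min_logfc=config.markers.min_logfc,
        )
        mk_path = out / "markers.csv"
        mk.to_csv(mk_path)
        record("markers", None, [mk_path])

        stage("interactions")
        int_seed = derive_seed(config.seed, "interactions")
        int_config = dataclasses.replace(config.interactions, seed=int_seed)
        pair_table = _default_pair_table(
            adata.var_names, config.n_interaction_pairs, derive_seed(config.seed, "pairs")
        )
        pairs_path = out / "pairs.csv"
        pair_table.to_csv(pairs_path, index=False)
        cell_labels = adata.obs["cell_type"].astype(str).copy()
        cell_labels.loc[final.index] = final
        result = interactions.run_interaction_analysis(adata, cell_labels, pair_table, int_config)
        int_path = out / "interactions.csv"
        result.to_csv(int_path, index=False)
        record("interactions", int_seed, [pairs_path, int_path])

        stage("repertoire")
        rep_seed = derive_seed(config.seed, "repertoire")
        ta, tb = simulate.generate_clone_tables(
            config.clones.n_clones_a,
            config.clones.n_clones_b,
            config.clones.shared_fraction,
            seed=rep_seed,
        )
        pa = io.write_clone_table(ta, out / "clones_a.csv")
        pb = io.write_clone_table(tb, out / "clones_b.csv")
        ov = repertoire.overlap_analysis(ta, tb)
        report = pd.DataFrame(
            {
                "n_shared": [ov.n_shared],
                "n_exclusive_a": [len(ov.exclusive_a)],
                "n_exclusive_b": [len(ov.exclusive_b)],
                "shared_read_fraction_a": [ov.shared_read_fraction_a],
                "shared_read_fraction_b": [ov.shared_read_fraction_b],
            }
        )
        rep_path = out / "overlap_report.csv"
        report.to_csv(rep_path, index=False)
        vb_path = out / "vbeta_a.csv"
        repertoire.vbeta_distribution(ta).to_csv(vb_path)
        record("repertoire", rep_seed, [pa, pb, rep_path, vb_path])
    except Exception as exc:
        done = set(manifest["stages"])
        current = next((s for s in STAGES if s not in done), "unknown")
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
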