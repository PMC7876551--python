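"""Synthetic multi-donor single-cell data with planted T-cell lineages.

The generator emulates a droplet scRNA-seq experiment on fetal skin: a mix of
alpha-beta (AB_T), gamma-delta (GD_T) and double-positive (DP_T) T cells plus
several non-T cell types, with TCR constant-chain genes expressed according to
the planted lineage, disjoint lineage-specific marker programs, log-normal
library sizes and negative-binomial count noise.  DP_T cells coexpress both
the AB and the GD marker program in addition to a small DP-specific block,
which is what makes them separable as intermediates downstream.

It also produces paired TCR-beta clone tables with a controllable fraction of
shared CDR3 sequences, for repertoire-overlap analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import anndata as ad
import numpy as np
import pandas as pd

TCR_CONSTANT_GENES = ("TRAC", "TRBC1", "TRBC2", "TRDC", "TRGC1", "TRGC2")
GD_CONSTANT_GENES = ("TRDC", "TRGC1", "TRGC2")
BETA_CONSTANT_GENES = ("TRBC1", "TRBC2")

CELL_CLASSES = ("AB_T", "GD_T", "DP_T", "FIBRO", "ENDO", "MYELOID", "NK", "KERAT")
T_CLASS_LINEAGE = {"AB_T": "AB", "GD_T": "GD", "DP_T": "DP"}

_DEFAULT_FRACTIONS = {
    "AB_T": 0.30,
    "GD_T": 0.10,
    "DP_T": 0.10,
    "FIBRO": 0.15,
    "ENDO": 0.10,
    "MYELOID": 0.10,
    "NK": 0.075,
    "KERAT": 0.075,
}

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_DEFAULT_VBETA_FAMILIES = tuple(f"V{i:02d}" for i in range(1, 25))


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic expression experiment.

    Expression means are on the TPM scale (expected transcripts per million of
    the cell's library); ``dispersion`` is the negative-binomial shape
    parameter theta, with per-gene variance ``mu + mu^2 / theta``.
    """

    n_donors: int = 2
    cells_per_donor: int = 750
    n_genes: int = 400
    fractions: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    tcr_high_mean: float = 1000.0
    tcr_low_mean: float = 0.5
    n_marker_genes_per_class: int = 20
    marker_effect: float = 4.0
    dispersion: float = 10.0
    library_size_mean: float = 10_000.0
    library_size_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(CELL_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown cell classes in fractions: {sorted(unknown)}")
        vals = np.array([self.fractions.get(c, 0.0) for c in CELL_CLASSES], float)
        if (vals < 0).any():
            raise ConfigurationError("fractions must be nonnegative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ConfigurationError(f"fractions must sum to 1, got {vals.sum()!r}")
        n_marker_total = len(CELL_CLASSES) * self.n_marker_genes_per_class
        if self.n_genes < len(TCR_CONSTANT_GENES) + n_marker_total:
            raise ConfigurationError(
                f"n_genes={self.n_genes} too small for {n_marker_total} marker genes "
                f"plus {len(TCR_CONSTANT_GENES)} TCR constant genes"
            )
        if self.n_donors < 1 or self.cells_per_donor < 1:
            raise ConfigurationError("n_donors and cells_per_donor must be >= 1")
        if self.marker_effect <= 1:
            raise ConfigurationError("marker_effect must be > 1")
        if self.dispersion <= 0:
            raise ConfigurationError("dispersion must be > 0")
        if min(self.tcr_high_mean, self.tcr_low_mean) < 0:
            raise ConfigurationError("TCR means must be nonnegative")

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


def _gene_names(config: SynthConfig) -> list[str]:
    names = list(TCR_CONSTANT_GENES)
    for cls in CELL_CLASSES:
        names += [f"{cls}-MK{i:02d}" for i in range(config.n_marker_genes_per_class)]
    n_bg = config.n_genes - len(names)
    names += [f"GENE{i:04d}" for i in range(n_bg)]
    return names


def _class_rate_profiles(config: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Expected relative expression (TPM-scale) per class, genes x classes."""
    genes = _gene_names(config)
    n = len(genes)
    base = rng.lognormal(mean=3.0, sigma=1.0, size=n)
    base[: len(TCR_CONSTANT_GENES)] = 0.0  # TCR genes set per lineage below

    hi, lo = config.tcr_high_mean, config.tcr_low_mean
    profiles = {}
    marker_start = {
        cls: len(TCR_CONSTANT_GENES) + i * config.n_marker_genes_per_class
        for i, cls in enumerate(CELL_CLASSES)
    }
    for cls in CELL_CLASSES:
        prof = base.copy()
        s = marker_start[cls]
        prof[s : s + config.n_marker_genes_per_class] *= config.marker_effect
        if cls == "DP_T":
            # intermediates carry both single-positive marker programs
            for parent in ("AB_T", "GD_T"):
                ps = marker_start[parent]
                prof[ps : ps + config.n_marker_genes_per_class] *= config.marker_effect
        tcr = dict.fromkeys(TCR_CONSTANT_GENES, lo)
        if cls in T_CLASS_LINEAGE:
            tcr["TRBC1"] = tcr["TRBC2"] = hi  # beta chain on in every T cell
            if cls in ("AB_T", "DP_T"):
                tcr["TRAC"] = hi
            if cls in ("GD_T", "DP_T"):
                for g in GD_CONSTANT_GENES:
                    tcr[g] = hi
        # tcr_high_mean / tcr_low_mean are on the TPM scale: rescale the
        # non-TCR genes to fill the remaining TPM budget, then normalize
        n_tcr = len(TCR_CONSTANT_GENES)
        tcr_total = sum(tcr.values())
        prof[n_tcr:] *= (1e6 - tcr_total) / prof[n_tcr:].sum()
        for i, g in enumerate(TCR_CONSTANT_GENES):
            prof[i] = tcr[g]
        profiles[cls] = prof / prof.sum()
    return pd.DataFrame(profiles, index=genes)


def generate_expression(config: SynthConfig) -> tuple[ad.AnnData, pd.DataFrame]:
    """Simulate a multi-donor count matrix with planted lineages.

    Returns the matrix as an :class:`anndata.AnnData` whose ``layers["counts"]``
    (and ``X``) hold integer counts, with per-cell metadata in ``obs`` (donor,
    coarse ``cell_type``, planted ``true_class``/``true_lineage``), and a truth
    table DataFrame with one row per cell.
    """
    rng = np.random.default_rng(config.seed)
    profiles = _class_rate_profiles(config, rng)
    genes = list(profiles.index)
    classes = list(profiles.columns)
    frac = np.array([config.fractions.get(c, 0.0) for c in classes])

    n_cells = config.n_donors * config.cells_per_donor
    donor_ids, cell_ids, class_idx = [], [], []
    for d in range(config.n_donors):
        donor = f"donor{d + 1}"
        idx = rng.choice(len(classes), size=config.cells_per_donor, p=frac)
        class_idx.append(idx)
        donor_ids += [donor] * config.cells_per_donor
        cell_ids += [f"{donor}_CELL{i:05d}" for i in range(config.cells_per_donor)]
    class_idx = np.concatenate(class_idx)

    sigma = config.library_size_sigma
    mu_log = np.log(config.library_size_mean) - sigma**2 / 2
    lib = rng.lognormal(mean=mu_log, sigma=sigma, size=n_cells)

    rates = profiles.to_numpy().T[class_idx]  # cells x genes, rows sum to 1
    mu = rates * lib[:, None]
    theta = config.dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p).astype(np.int64)

    cell_class = np.array(classes)[class_idx]
    obs = pd.DataFrame(
        {
            "donor": donor_ids,
            "true_class": cell_class,
            "true_lineage": [T_CLASS_LINEAGE.get(c, "NONT") for c in cell_class],
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    obs["cell_type"] = np.where(obs["true_lineage"].ne("NONT"), "T", obs["true_class"])

    adata = ad.AnnData(
        X=counts.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = counts

    truth = obs.reset_index()[["cell_id", "donor", "true_class", "true_lineage"]]
    return adata, truth


def _random_cdr3(rng: np.random.Generator, existing: set[str]) -> str:
    while True:
        middle = "".join(rng.choice(_AMINO_ACIDS, size=rng.integers(4, 10)))
        seq = f"CASS{middle}EQFF"
        if seq not in existing:
            existing.add(seq)
            return seq


def generate_clone_tables(
    n_clones_a: int,
    n_clones_b: int,
    shared_fraction: float,
    seed: int = 0,
    families: tuple[str, ...] = _DEFAULT_VBETA_FAMILIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired CDR3 clone tables with a planted shared-clone fraction.

    ``round(shared_fraction * n_clones_a)`` CDR3 sequences appear in both
    tables; the rest are sample-exclusive.  Clone counts are geometric, the
    V-beta family is drawn uniformly from ``families``.
    """
    if n_clones_a < 1 or n_clones_b < 1:
        raise ConfigurationError("clone counts must be >= 1")
    upper = min(1.0, n_clones_b / n_clones_a)
    if not 0.0 <= shared_fraction <= upper + 1e-12:
        raise ConfigurationError(
            f"shared_fraction must be in [0, {upper:.4g}], got {shared_fraction}"
        )
    rng = np.random.default_rng(seed)
    n_shared = int(round(shared_fraction * n_clones_a))

    existing: set[str] = set()
    shared = [_random_cdr3(rng, existing) for _ in range(n_shared)]
    only_a = [_random_cdr3(rng, existing) for _ in range(n_clones_a - n_shared)]
    only_b = [_random_cdr3(rng, existing) for _ in range(n_clones_b - n_shared)]

    def _table(cdr3s: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cdr3": cdr3s,
                "count": rng.geometric(0.2, size=len(cdr3s)),
                "vbeta": rng.choice(families, size=len(cdr3s)),
            }
        )

    return _table(shared + only_a), _table(shared + only_b)
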