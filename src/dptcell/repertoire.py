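"""CDR3 clone overlap and V-beta family usage between paired samples.

Clone identity is the exact CDR3 string (the V-beta family matters only for
the usage distributions).  Overlap reports the shared and sample-exclusive
clone sets and, per sample, the fraction of sequencing reads carried by
shared clones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

REQUIRED_COLUMNS = ("cdr3", "count", "vbeta")


def aggregate_clones(table: pd.DataFrame) -> pd.DataFrame:
    """Sum counts over duplicate (cdr3, vbeta) rows."""
    return (
        table.groupby(["cdr3", "vbeta"], as_index=False, sort=True)["count"]
        .sum()[["cdr3", "count", "vbeta"]]
    )


def read_clone_table(path: str | Path) -> pd.DataFrame:
    """Read a clone CSV (cdr3,count,vbeta) and aggregate duplicate rows."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clone table {path} missing columns: {missing}")
    if df.empty:
        return df[list(REQUIRED_COLUMNS)]
    df["count"] = pd.to_numeric(df["count"], errors="raise")
    bad = df.index[(df["count"] < 1) | df["cdr3"].isna() | (df["cdr3"] == "")]
    if len(bad):
        raise ValueError(f"invalid clone rows (empty cdr3 or count < 1) at rows: {list(bad[:10])}")
    return aggregate_clones(df[list(REQUIRED_COLUMNS)])


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset[str]
    exclusive_a: frozenset[str]
    exclusive_b: frozenset[str]
    shared_read_fraction_a: float
    shared_read_fraction_b: float

    @property
    def n_shared(self) -> int:
        return len(self.shared)


def overlap_analysis(table_a: pd.DataFrame, table_b: pd.DataFrame) -> OverlapResult:
    """Shared/exclusive clone sets and per-sample shared-read fractions."""
    a = aggregate_clones(table_a) if len(table_a) else table_a
    b = aggregate_clones(table_b) if len(table_b) else table_b
    set_a = set(a["cdr3"]) if len(a) else set()
    set_b = set(b["cdr3"]) if len(b) else set()
    shared = set_a & set_b

    def _fraction(t: pd.DataFrame) -> float:
        total = t["count"].sum() if len(t) else 0
        if total == 0:
            return 0.0
        return float(t.loc[t["cdr3"].isin(shared), "count"].sum() / total)

    return OverlapResult(
        shared=frozenset(shared),
        exclusive_a=frozenset(set_a - set_b),
        exclusive_b=frozenset(set_b - set_a),
        shared_read_fraction_a=_fraction(a),
        shared_read_fraction_b=_fraction(b),
    )


def vbeta_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Per-family fraction of distinct clones and of reads; each sums to 1."""
    if table.empty:
        raise ValueError("clone table is empty")
    agg = aggregate_clones(table)
    by_family = agg.groupby("vbeta")
    clones = by_family["cdr3"].nunique()
    reads = by_family["count"].sum()
    return pd.DataFrame(
        {
            "clone_fraction": clones / clones.sum(),
            "read_fraction": reads / reads.sum(),
        }
    )
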