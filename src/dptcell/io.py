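"""Reading and writing the pipeline's on-disk formats.

Expression matrices travel as 10x-style MTX triplets (``matrix.mtx`` with
genes as rows and cells as columns, ``features.tsv``, ``barcodes.tsv``)
alongside an optional cell-metadata CSV; clone tables and label tables are
plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


def write_mtx_dir(adata: ad.AnnData, out_dir: str | Path) -> list[Path]:
    """Write counts as a 10x-style MTX triplet plus a cell-metadata CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sp.csc_matrix(np.asarray(counts).T)  # genes x cells, 10x orientation
    paths = [out / "matrix.mtx", out / "features.tsv", out / "barcodes.tsv", out / "cell_meta.csv"]
    scipy.io.mmwrite(paths[0], mat, field="integer")
    pd.Series(adata.var_names).to_csv(paths[1], sep="\t", header=False, index=False)
    pd.Series(adata.obs_names).to_csv(paths[2], sep="\t", header=False, index=False)
    adata.obs.rename_axis("cell_id").to_csv(paths[3])
    return paths


def read_mtx_dir(in_dir: str | Path) -> ad.AnnData:
    """Read a 10x-style MTX triplet (and cell_meta.csv if present)."""
    d = Path(in_dir)
    mat = scipy.io.mmread(d / "matrix.mtx")
    counts = np.asarray(sp.csr_matrix(mat).T.todense(), dtype=np.int64)
    genes = pd.read_csv(d / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(d / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    if not genes.is_unique:
        raise ValueError("gene symbols are not unique")
    if not cells.is_unique:
        raise ValueError("cell barcodes are not unique")
    obs = pd.DataFrame(index=pd.Index(cells, name="cell_id"))
    meta_path = d / "cell_meta.csv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, index_col=0)
        obs = meta.reindex(cells)
    adata = ad.AnnData(
        X=counts.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    adata.layers["counts"] = counts
    return adata


def write_labels(labels: pd.Series, path: str | Path, value_name: str = "label") -> Path:
    path = Path(path)
    labels.rename(value_name).rename_axis("cell_id").to_csv(path)
    return path


def read_labels(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, index_col=0)
    return df.iloc[:, 0].astype(str)


def write_clone_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table[["cdr3", "count", "vbeta"]].to_csv(path, index=False)
    return path
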