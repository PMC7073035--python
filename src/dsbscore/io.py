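"""Readers and writers for the standard on-disk formats.

Single-cell matrices use the 10x-style triplet (``matrix.mtx`` genes × cells,
``barcodes.tsv``, and either v2 ``genes.tsv`` or v3 ``features.tsv``); bulk
tables are a genes × samples TSV with a sample-metadata sidecar TSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as spio
from scipy import sparse

from .bulk import BulkTable

__all__ = ["read_10x_mtx", "write_10x_mtx", "read_bulk_tsv", "write_bulk_tsv"]


def _find(directory: Path, stem_options: tuple[str, ...]) -> Path:
    for stem in stem_options:
        p = directory / stem
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {stem_options} in {directory}")


def read_10x_mtx(directory: str | Path, batch: str | None = None) -> AnnData:
    """Read a 10x-style MTX directory into an AnnData (cells × genes).

    Accepts both the v2 dialect (``genes.tsv``: id, symbol) and the v3
    dialect (``features.tsv``: id, symbol, type). Gene symbols become
    ``var_names`` (made unique), gene ids are kept in ``var["gene_id"]``.
    """
    directory = Path(directory)
    mtx = _find(directory, ("matrix.mtx", "matrix.mtx.gz"))
    bc = _find(directory, ("barcodes.tsv", "barcodes.tsv.gz"))
    feat = _find(directory, ("features.tsv", "genes.tsv", "features.tsv.gz", "genes.tsv.gz"))
    x = spio.mmread(str(mtx)).T.tocsr()  # stored genes × cells
    barcodes = pd.read_csv(bc, header=None, sep="\t")[0].astype(str)
    ftab = pd.read_csv(feat, header=None, sep="\t")
    symbols = ftab[1] if ftab.shape[1] >= 2 else ftab[0]
    adata = AnnData(X=x.astype(np.int64),
                    obs=pd.DataFrame(index=barcodes.to_list()),
                    var=pd.DataFrame({"gene_id": ftab[0].to_list()},
                                     index=symbols.astype(str).to_list()))
    adata.var_names_make_unique()
    if batch is not None:
        adata.obs["batch"] = batch
    return adata


def write_10x_mtx(adata: AnnData, directory: str | Path, dialect: str = "v3") -> None:
    """Write an AnnData as an uncompressed 10x-style MTX directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    x = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    spio.mmwrite(str(directory / "matrix.mtx"), x.T.tocoo(), field="integer")
    (directory / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n")
    ids = adata.var["gene_id"] if "gene_id" in adata.var else adata.var_names
    lines = []
    for gid, sym in zip(ids, adata.var_names):
        if dialect == "v3":
            lines.append(f"{gid}\t{sym}\tGene Expression")
        else:
            lines.append(f"{gid}\t{sym}")
    name = "features.tsv" if dialect == "v3" else "genes.tsv"
    (directory / name).write_text("\n".join(lines) + "\n")


def read_bulk_tsv(expr_path: str | Path, meta_path: str | Path,
                  scale: str = "tpm") -> BulkTable:
    """Read a genes × samples TSV plus its sample-metadata sidecar.

    The sidecar needs a ``sample`` column matching the expression columns;
    ``species``, ``condition``, ``day`` and ``replicate`` are carried through.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t").set_index("sample")
    missing = set(expr.columns) - set(meta.index)
    if missing:
        raise ValueError(f"samples without metadata: {sorted(missing)}")
    return BulkTable(expr, meta.loc[expr.columns], scale=scale)


def write_bulk_tsv(table: BulkTable, expr_path: str | Path, meta_path: str | Path) -> None:
    table.expr.to_csv(expr_path, sep="\t")
    table.meta.rename_axis("sample").to_csv(meta_path, sep="\t")
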