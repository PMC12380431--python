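"""Reading and writing the standard on-disk layouts.

Two layouts are supported and round-trip exactly:

* the 10x-style triplet directory — ``matrix.mtx`` (MatrixMarket
  coordinate, stored genes × spots per the 10x convention),
  ``features.tsv`` (gene id, symbol, role), ``barcodes.tsv``, and a
  per-spot ``spots.csv`` (barcode, x, y, sample, group, section,
  soma_flag, plus any extra columns);
* a dense CSV with spots as rows and gene symbols as the header.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy import io as scipy_io
from scipy import sparse

from .containers import SpotMatrix

logger = logging.getLogger(__name__)

_META_DEFAULTS = {
    "x": 0.0,
    "y": 0.0,
    "sample": "sample1",
    "group": "unknown",
    "section": "section1",
    "soma_flag": False,
}


def write_matrix(matrix: SpotMatrix, path: Union[str, Path]) -> None:
    """Write the triplet layout (matrix.mtx + TSVs + spots.csv) to a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    # genes × spots, 10x orientation
    mat = sparse.csr_matrix(np.asarray(matrix.counts).T)
    scipy_io.mmwrite(str(path / "matrix.mtx"), mat)
    matrix.gene_meta[["gene_id", "symbol", "role"]].to_csv(
        path / "features.tsv", sep="\t", header=False, index=False
    )
    matrix.spot_meta[["barcode"]].to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    matrix.spot_meta.to_csv(path / "spots.csv", index=False)


def read_matrix(path: Union[str, Path], strict: bool = False) -> SpotMatrix:
    """Read a triplet directory or a dense CSV into a :class:`SpotMatrix`.

    In strict mode a MatrixMarket file with non-integer entries is an
    error; otherwise values are kept as floats with a warning (already
    normalized data are legitimate input downstream).
    """
    path = Path(path)
    if path.is_dir():
        return _read_triplet(path, strict=strict)
    if path.suffix.lower() in (".csv", ".tsv"):
        return _read_dense(path)
    raise ValueError(f"cannot infer layout of {path}")


def _read_triplet(path: Path, strict: bool) -> SpotMatrix:
    mtx_path = path / "matrix.mtx"
    mat = scipy_io.mmread(str(mtx_path))
    counts = np.asarray(mat.todense() if sparse.issparse(mat) else mat).T
    if not np.issubdtype(counts.dtype, np.integer):
        if np.allclose(counts, np.round(counts)):
            counts = counts.astype(np.int64)
        elif strict:
            raise ValueError(
                f"{mtx_path} contains non-integer entries in strict mode"
            )
        else:
            warnings.warn(
                f"{mtx_path} contains non-integer entries; keeping floats",
                stacklevel=2,
            )
    features = pd.read_csv(
        path / "features.tsv",
        sep="\t",
        header=None,
        names=["gene_id", "symbol", "role"],
    )
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None, names=["barcode"])
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix is {counts.shape[1]} genes × {counts.shape[0]} spots but "
            f"features.tsv has {len(features)} rows and barcodes.tsv {len(barcodes)}"
        )
    spots_csv = path / "spots.csv"
    if spots_csv.exists():
        spot_meta = pd.read_csv(spots_csv)
        if len(spot_meta) != len(barcodes):
            raise ValueError(
                f"spots.csv has {len(spot_meta)} rows, expected {len(barcodes)}"
            )
    else:
        spot_meta = barcodes.copy()
    for col, default in _META_DEFAULTS.items():
        if col not in spot_meta.columns:
            spot_meta[col] = default
    if "soma_flag" in spot_meta.columns:
        spot_meta["soma_flag"] = spot_meta["soma_flag"].astype(bool)
    return SpotMatrix(counts=counts, spot_meta=spot_meta, gene_meta=features)


def _read_dense(path: Path) -> SpotMatrix:
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    counts = df.to_numpy()
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    spot_meta = pd.DataFrame({"barcode": df.index.astype(str)})
    for col, default in _META_DEFAULTS.items():
        spot_meta[col] = default
    gene_meta = pd.DataFrame(
        {
            "gene_id": df.columns.astype(str),
            "symbol": df.columns.astype(str),
            "role": "other",
        }
    )
    return SpotMatrix(counts=counts, spot_meta=spot_meta, gene_meta=gene_meta)


def write_dense_csv(matrix: SpotMatrix, path: Union[str, Path]) -> None:
    """Write spots × genes values as a dense CSV, header = gene symbols."""
    df = pd.DataFrame(
        matrix.counts,
        index=matrix.spot_meta["barcode"].to_numpy(),
        columns=matrix.gene_meta["symbol"].to_numpy(),
    )
    df.to_csv(Path(path), index_label="barcode")
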