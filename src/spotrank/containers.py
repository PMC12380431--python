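"""Core in-memory containers shared across the pipeline.

The central object is :class:`SpotMatrix`: a spots-by-genes count (or
normalized expression) matrix with per-spot and per-gene metadata, the
in-memory form of the 10x-style triplet layout (``matrix.mtx`` +
``barcodes.tsv`` + ``features.tsv`` + ``spots.csv``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: Recognised per-gene roles.  Region markers use the compound form
#: ``region_marker:<region>``.
GENE_ROLES = ("da_marker", "glia_marker", "neg_probe", "other")

#: Region labels used throughout: midbrain (SN, VTA, thalamus) and
#: striatal (CP, LSX, white_matter) regions, plus the null label.
REGION_LABELS = ("SN", "VTA", "thalamus", "CP", "LSX", "white_matter", "unassigned")

SPOT_META_COLUMNS = ("barcode", "x", "y", "sample", "group", "section", "soma_flag")


class SpotMatrixError(ValueError):
    """Raised when a SpotMatrix fails its structural invariants."""


@dataclass
class SpotMatrix:
    """Spots × genes expression matrix with aligned metadata.

    Parameters
    ----------
    counts
        2-D array, one row per spot, one column per gene.  Nonnegative
        integers for raw data; real-valued after normalization.
    spot_meta
        One row per spot with columns ``barcode, x, y, sample, group,
        section, soma_flag`` (extra columns such as ``region_truth`` are
        carried along untouched).
    gene_meta
        One row per gene with columns ``gene_id, symbol, role``.
    """

    counts: np.ndarray
    spot_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SpotMatrixError(f"counts must be 2-D, got shape {self.counts.shape}")
        n_spots, n_genes = self.counts.shape
        if len(self.spot_meta) != n_spots:
            raise SpotMatrixError(
                f"spot_meta has {len(self.spot_meta)} rows but counts has "
                f"{n_spots} spots"
            )
        if len(self.gene_meta) != n_genes:
            raise SpotMatrixError(
                f"gene_meta has {len(self.gene_meta)} rows but counts has "
                f"{n_genes} genes"
            )
        for col in SPOT_META_COLUMNS:
            if col not in self.spot_meta.columns:
                raise SpotMatrixError(f"spot_meta missing required column {col!r}")
        for col in ("gene_id", "symbol", "role"):
            if col not in self.gene_meta.columns:
                raise SpotMatrixError(f"gene_meta missing required column {col!r}")
        if np.issubdtype(self.counts.dtype, np.number):
            if np.nanmin(self.counts, initial=0) < 0:
                raise SpotMatrixError("counts must be nonnegative")
        # barcodes unique within each sample
        dup = self.spot_meta.duplicated(subset=["sample", "barcode"])
        if dup.any():
            raise SpotMatrixError(
                f"{int(dup.sum())} duplicated barcodes within a sample"
            )
        self.spot_meta = self.spot_meta.reset_index(drop=True)
        self.gene_meta = self.gene_meta.reset_index(drop=True)

    # -- basic geometry ----------------------------------------------------
    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def symbols(self) -> pd.Index:
        return pd.Index(self.gene_meta["symbol"])

    def gene_index(self, symbol: str) -> int:
        idx = np.flatnonzero(self.gene_meta["symbol"].to_numpy() == symbol)
        if idx.size == 0:
            raise KeyError(f"gene symbol {symbol!r} not present")
        return int(idx[0])

    def genes_with_role(self, role: str) -> np.ndarray:
        """Column indices of genes whose role equals ``role``."""
        return np.flatnonzero(self.gene_meta["role"].to_numpy() == role)

    def region_marker_map(self) -> dict[str, list[int]]:
        """Mapping region → column indices, from ``region_marker:<region>`` roles."""
        out: dict[str, list[int]] = {}
        for j, role in enumerate(self.gene_meta["role"]):
            if isinstance(role, str) and role.startswith("region_marker:"):
                out.setdefault(role.split(":", 1)[1], []).append(j)
        return out

    # -- subsetting --------------------------------------------------------
    def subset_spots(self, mask: np.ndarray) -> "SpotMatrix":
        mask = np.asarray(mask)
        return SpotMatrix(
            counts=self.counts[mask],
            spot_meta=self.spot_meta.loc[np.asarray(mask)].reset_index(drop=True)
            if mask.dtype == bool
            else self.spot_meta.iloc[mask].reset_index(drop=True),
            gene_meta=self.gene_meta.copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "SpotMatrix":
        mask = np.asarray(mask)
        gm = (
            self.gene_meta.loc[mask]
            if mask.dtype == bool
            else self.gene_meta.iloc[mask]
        )
        return SpotMatrix(
            counts=self.counts[:, mask],
            spot_meta=self.spot_meta.copy(),
            gene_meta=gm.reset_index(drop=True),
        )

    def copy(self) -> "SpotMatrix":
        return SpotMatrix(
            counts=self.counts.copy(),
            spot_meta=self.spot_meta.copy(),
            gene_meta=self.gene_meta.copy(),
        )

    def to_anndata(self):
        """Convert to an :class:`anndata.AnnData` (obs=spots, var=genes)."""
        import anndata as ad

        obs = self.spot_meta.copy()
        obs.index = obs.index.astype(str)
        var = self.gene_meta.copy()
        var.index = var["symbol"].astype(str)
        return ad.AnnData(X=self.counts.astype(float), obs=obs, var=var)


@dataclass
class GroupSummary:
    """(mean, dispersion, n) summary of one measurement in one group.

    ``dispersion`` is interpreted per ``kind``: a standard deviation
    (``"SD"``) or a standard error of the mean (``"SEM"``, converted via
    SD = SEM·√n).  These are the µ, σ, n of the FCS/SNS score equations.
    """

    mean: float
    dispersion: float
    n: int
    kind: str = "SD"
    label: str = ""

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be ≥ 2, got {self.n}")
        if not np.isfinite(self.mean):
            raise ValueError(f"group {self.label!r}: mean must be finite")
        if self.dispersion < 0 or not np.isfinite(self.dispersion):
            raise ValueError(
                f"group {self.label!r}: dispersion must be nonnegative and finite"
            )
        if self.kind not in ("SD", "SEM"):
            raise ValueError(f"kind must be 'SD' or 'SEM', got {self.kind!r}")

    @property
    def sd(self) -> float:
        if self.kind == "SEM":
            return self.dispersion * np.sqrt(self.n)
        return self.dispersion

    @property
    def sem(self) -> float:
        if self.kind == "SEM":
            return self.dispersion
        return self.dispersion / np.sqrt(self.n)

    @classmethod
    def from_values(cls, values, label: str = "") -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        if values.size < 2:
            raise ValueError(f"group {label!r}: need ≥ 2 values, got {values.size}")
        return cls(
            mean=float(values.mean()),
            dispersion=float(values.std(ddof=1)),
            n=int(values.size),
            kind="SD",
            label=label,
        )


@dataclass
class TestResult:
    """Outcome of a two-group hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: Optional[float] = None
    n_a: Optional[int] = None
    n_b: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class GroupValues:
    """Two groups of raw measurements, e.g. membrane-potential responses."""

    values_a: np.ndarray
    values_b: np.ndarray
    label_a: str = "a"
    label_b: str = "b"

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.size == 0 or self.values_b.size == 0:
            raise ValueError("both groups must be non-empty")
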