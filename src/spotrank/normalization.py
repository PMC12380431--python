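"""Normalization methods, their evaluation, and score normalization.

Five candidate normalizations are provided — quantile, upper-quartile
(Q3), negative-probe background, total library size, and median — and
ranked by two criteria: the mean absolute MA-plot correlation between
sample pairs (an intensity-dependent bias measure; lower is better) and
the fraction of sample pairs whose normalized value distributions still
differ by a two-sample KS test (lower is better).  SCTransform is a
recognised method name but is not provided; requesting it raises and
the evaluation report records it as unavailable rather than silently
skipping it.

Each observation row of the matrix is treated as one sample/library:
for segment-level data (one row per ROI) this is the usual bulk
convention, and for spot-level data per-spot scaling is the standard
practice.  Use :func:`pseudobulk_by_sample` first to normalize at the
sample level.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SpotMatrix

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("quantile", "q3", "background", "libsize", "median")
#: Methods the report knows about but this package does not implement.
UNAVAILABLE_METHODS = ("sctransform",)

#: Pseudocount added to counts when forming MA log-ratios.
DEFAULT_MA_PSEUDOCOUNT = 0.5


class UnavailableMethodError(ValueError):
    """A compared-but-not-implemented normalization method was requested."""


@dataclass
class NormalizationReport:
    """Evaluation of candidate normalizations.

    ``scores`` has one row per method: mean |MA correlation| over sample
    pairs, fraction of pairs with KS p < alpha, and availability.
    ``chosen_method`` minimizes (MA score, then KS fraction) among the
    available methods.
    """

    scores: pd.DataFrame
    chosen_method: str
    alpha: float
    ks_mode: str = "pairwise"

    def to_dict(self) -> dict:
        return {
            "chosen_method": self.chosen_method,
            "alpha": self.alpha,
            "ks_mode": self.ks_mode,
            "methods": self.scores.to_dict(orient="records"),
        }


@dataclass
class Embedding:
    """PCA result: observation scores, explained variance, gene loadings."""

    scores: np.ndarray
    explained_variance: np.ndarray
    gene_loadings: np.ndarray
    genes: pd.Index
    labels: Optional[np.ndarray] = None


def pseudobulk_by_sample(matrix: SpotMatrix, by: str = "sample") -> SpotMatrix:
    """Sum spot counts within each level of a metadata column.

    Returns a matrix with one row per sample, suitable for sample-level
    normalization and evaluation.
    """
    groups = matrix.spot_meta.groupby(by, sort=True)
    rows, meta = [], []
    for label, idx in groups.groups.items():
        idx = np.asarray(idx)
        rows.append(matrix.counts[idx].sum(axis=0))
        first = matrix.spot_meta.iloc[idx[0]]
        meta.append(
            {
                "barcode": str(label),
                "x": 0.0,
                "y": 0.0,
                "sample": str(label),
                "group": first["group"],
                "section": first["section"],
                "soma_flag": False,
            }
        )
    return SpotMatrix(
        counts=np.vstack(rows),
        spot_meta=pd.DataFrame(meta),
        gene_meta=matrix.gene_meta.copy(),
    )


# ---------------------------------------------------------------------------
# normalization methods (row = sample/library)
# ---------------------------------------------------------------------------

def _quantile_normalize(values: np.ndarray) -> np.ndarray:
    """Classic quantile normalization across rows, ties averaged."""
    order = np.argsort(values, axis=1, kind="stable")
    sorted_vals = np.take_along_axis(values, order, axis=1)
    target = sorted_vals.mean(axis=0)
    out = np.empty_like(values, dtype=float)
    np.put_along_axis(out, order, np.broadcast_to(target, values.shape), axis=1)
    # average target values over ties within each row
    for i in range(values.shape[0]):
        row = values[i]
        uniq, inv = np.unique(row, return_inverse=True)
        if uniq.size < row.size:
            sums = np.bincount(inv, weights=out[i])
            counts = np.bincount(inv)
            out[i] = (sums / counts)[inv]
    return out


def normalize_counts(
    matrix: SpotMatrix,
    method: str,
    pseudocount: float = 0.0,
    background_mode: str = "divide",
) -> SpotMatrix:
    """Return a real-valued matrix normalized by ``method``.

    quantile
        All rows share the identical sorted value vector (rank means,
        ties averaged).
    q3
        Each row scaled so its 75th percentile equals the cross-row mean
        of raw 75th percentiles.
    background
        Each row divided by its mean negative-probe count (GeoMx
        convention); ``background_mode="subtract"`` subtracts it
        instead, clipping at zero.
    libsize
        Each row scaled to the cross-row mean total count.
    median
        Each row scaled so its median over detected (>0) genes equals
        the cross-row mean of such medians.
    """
    if method in UNAVAILABLE_METHODS:
        raise UnavailableMethodError(
            f"normalization method {method!r} is recognised but not provided"
        )
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown method {method!r}; choose from {NORMALIZATION_METHODS}"
        )
    values = matrix.counts.astype(float)
    if values.size == 0:
        raise ValueError("matrix is empty")

    if method == "quantile":
        out = _quantile_normalize(values)
    elif method == "q3":
        q3 = np.percentile(values, 75, axis=1)
        if np.any(q3 <= 0):
            raise ValueError("q3 normalization: some rows have 75th percentile ≤ 0")
        out = values * (q3.mean() / q3)[:, None]
    elif method == "background":
        neg = matrix.genes_with_role("neg_probe")
        if neg.size == 0:
            raise ValueError("background normalization requires ≥ 1 neg_probe gene")
        bg = values[:, neg].mean(axis=1)
        if np.any(bg <= 0):
            raise ValueError("background normalization: zero mean negative-probe count")
        if background_mode == "subtract":
            out = np.clip(values - bg[:, None], 0.0, None)
        else:
            out = values / bg[:, None]
    elif method == "libsize":
        totals = values.sum(axis=1)
        if np.any(totals <= 0):
            raise ValueError("libsize normalization: some rows have zero total count")
        out = values * (totals.mean() / totals)[:, None]
    else:  # median
        med = np.array(
            [np.median(row[row > 0]) if (row > 0).any() else np.nan for row in values]
        )
        if np.any(~np.isfinite(med)):
            raise ValueError("median normalization: some rows have no detected genes")
        out = values * (med.mean() / med)[:, None]

    return SpotMatrix(
        counts=out, spot_meta=matrix.spot_meta.copy(), gene_meta=matrix.gene_meta.copy()
    )


def ma_correlation(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    pseudocount: float = DEFAULT_MA_PSEUDOCOUNT,
) -> float:
    """|Pearson r| between M = log2 ratio and A = mean log2 intensity.

    A normalization without intensity-dependent bias leaves M
    uncorrelated with A.  Returns 0 when either M or A is constant
    (identical or proportional samples).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError(f"need ≥ 3 genes, got {a.size}")
    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    m = la - lb
    avg = 0.5 * (la + lb)
    # zero-variance rule, with a guard against pure float noise in
    # rows that are identical up to rounding (identical/proportional samples)
    if np.ptp(m) < 1e-10 or np.ptp(avg) < 1e-10:
        return 0.0
    r = np.corrcoef(m, avg)[0, 1]
    return float(abs(r))


def _ks_pvalue(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> float:
    method = "exact" if max(a.size, b.size) <= exact_max_n else "asymp"
    return float(stats.ks_2samp(a, b, method=method).pvalue)


def evaluate_normalizations(
    matrix: SpotMatrix,
    methods: Sequence[str] = NORMALIZATION_METHODS + UNAVAILABLE_METHODS,
    alpha: float = 0.05,
    pseudocount: float = DEFAULT_MA_PSEUDOCOUNT,
    ks_mode: str = "pairwise",
) -> NormalizationReport:
    """Score candidate normalizations and pick the best.

    For each available method the matrix is normalized, then every pair
    of rows contributes one |MA correlation| and one two-sample KS test
    on the rows' value distributions (``ks_mode="pooled"`` instead
    compares each row against the pooled values of the others).  Methods
    are ranked by mean |MA correlation|, ties broken by the fraction of
    KS-significant pairs; the winner is recorded as ``chosen_method``.
    """
    n = matrix.n_spots
    if n < 2:
        raise ValueError(f"need ≥ 2 samples to evaluate, got {n}")
    if ks_mode not in ("pairwise", "pooled"):
        raise ValueError(f"ks_mode must be 'pairwise' or 'pooled', got {ks_mode!r}")

    rows = []
    for method in methods:
        if method in UNAVAILABLE_METHODS:
            rows.append(
                {
                    "method": method,
                    "ma_score": np.nan,
                    "ks_significant_fraction": np.nan,
                    "available": False,
                }
            )
            logger.warning("method %r unavailable; recorded, not evaluated", method)
            continue
        normalized = normalize_counts(matrix, method)
        vals = normalized.counts
        ma_scores, ks_flags = [], []
        if ks_mode == "pairwise":
            for i in range(n):
                for j in range(i + 1, n):
                    ma_scores.append(ma_correlation(vals[i], vals[j], pseudocount))
                    ks_flags.append(_ks_pvalue(vals[i], vals[j]) < alpha)
        else:
            for i in range(n):
                others = np.delete(vals, i, axis=0).ravel()
                ma_scores.append(
                    ma_correlation(vals[i], np.delete(vals, i, axis=0).mean(axis=0),
                                   pseudocount)
                )
                ks_flags.append(_ks_pvalue(vals[i], others) < alpha)
        rows.append(
            {
                "method": method,
                "ma_score": float(np.mean(ma_scores)),
                "ks_significant_fraction": float(np.mean(ks_flags)),
                "available": True,
            }
        )

    scores = pd.DataFrame(rows)
    scores["order"] = np.arange(len(scores))  # requested order breaks exact ties
    avail = scores[scores["available"]].sort_values(
        ["ma_score", "ks_significant_fraction", "order"]
    )
    scores = scores.drop(columns=["order"])
    if avail.empty:
        raise ValueError("no available methods were evaluated")
    chosen = str(avail.iloc[0]["method"])
    return NormalizationReport(
        scores=scores, chosen_method=chosen, alpha=alpha, ks_mode=ks_mode
    )


def median_normalize_rows(values: np.ndarray) -> np.ndarray:
    """Scale each row so its median of detected genes hits the cross-row mean."""
    med = np.array(
        [np.median(row[row > 0]) if (row > 0).any() else np.nan for row in values]
    )
    if np.any(~np.isfinite(med)):
        raise ValueError("some rows have no detected genes")
    return values * (med.mean() / med)[:, None]


def pca_on_median_normalized(
    matrix: SpotMatrix,
    region_groups: Sequence,
    n_components: Optional[int] = None,
    aggregate_by: Optional[str] = None,
    per_gene_median_center: bool = False,
) -> Embedding:
    """Centered PCA on median-normalized expression.

    Genes are first restricted to those with total expression > 0 in
    every level of ``region_groups`` (per-spot labels); rows are then
    median-normalized and decomposed.  ``aggregate_by`` optionally
    averages spots within each (region_group, metadata column) cell
    before the PCA.  ``per_gene_median_center`` subtracts each gene's
    median instead of scaling rows (alternative reading of
    median-normalized input).
    """
    from sklearn.decomposition import PCA

    labels = np.asarray(region_groups, dtype=object)
    if labels.size != matrix.n_spots:
        raise ValueError("region_groups length must equal the number of spots")

    keep = np.ones(matrix.n_genes, dtype=bool)
    for lvl in pd.unique(labels):
        keep &= matrix.counts[labels == lvl].sum(axis=0) > 0
    if not keep.any():
        raise ValueError("no genes expressed in every region group")
    values = matrix.counts[:, keep].astype(float)
    genes = pd.Index(matrix.gene_meta["symbol"].to_numpy()[keep])

    if aggregate_by is not None:
        meta = matrix.spot_meta[aggregate_by].to_numpy()
        cells = pd.DataFrame({"g": labels, "m": meta})
        agg_rows, agg_labels = [], []
        for (g, _), idx in cells.groupby(["g", "m"], sort=True).groups.items():
            agg_rows.append(values[np.asarray(idx)].mean(axis=0))
            agg_labels.append(g)
        values = np.vstack(agg_rows)
        labels = np.asarray(agg_labels, dtype=object)

    if values.shape[0] < 2:
        raise ValueError("need ≥ 2 observations after aggregation")

    if per_gene_median_center:
        values = values - np.median(values, axis=0)
    else:
        values = median_normalize_rows(values)

    centered = values - values.mean(axis=0)
    if np.allclose(centered, 0.0):
        warnings.warn(
            "observations are identical; returning zero embedding", stacklevel=2
        )
        k = n_components or 1
        return Embedding(
            scores=np.zeros((values.shape[0], k)),
            explained_variance=np.zeros(k),
            gene_loadings=np.zeros((values.shape[1], k)),
            genes=genes,
            labels=labels,
        )

    max_rank = min(values.shape[0] - 1, values.shape[1])
    k = min(n_components or max_rank, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(values)
    return Embedding(
        scores=scores,
        explained_variance=pca.explained_variance_ratio_,
        gene_loadings=pca.components_.T,
        genes=genes,
        labels=labels,
    )


def normalize_activity_scores(
    scores: Sequence[float], section_ids: Sequence
) -> np.ndarray:
    """Divide each spot's activity score by its tissue section's mean.

    After normalization every section has mean exactly 1, making
    predicted-activity distributions comparable across sections.
    """
    scores = np.asarray(scores, dtype=float)
    sections = np.asarray(section_ids)
    if scores.size != sections.size:
        raise ValueError("scores and section_ids lengths differ")
    out = np.empty_like(scores)
    for section in pd.unique(sections):
        mask = sections == section
        mean = scores[mask].mean()
        if mean == 0:
            raise ValueError(f"section {section!r} has zero mean activity score")
        out[mask] = scores[mask] / mean
    return out
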