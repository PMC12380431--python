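"""Capture-area selection and region assignment.

Implements the inclusion/exclusion rules for dopamine-neuron (DA)
capture areas: a disc is kept only if it expresses at least
``min_da_markers`` of the DA marker genes (Th, Slc6a3, Slc18a2), carries
at least one complete DA soma (an image-derived per-spot boolean,
supplied as metadata), does not express any astrocyte/microglia marker
above a per-gene quantile cutoff, and lies in a candidate region.
Region assignment uses region-specific marker genes with a conservative
tie rule: ambiguous spots stay unassigned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .containers import REGION_LABELS, SpotMatrix

logger = logging.getLogger(__name__)


@dataclass
class SelectionRules:
    """Tunable thresholds of the disc-selection rules.

    da_marker_threshold
        Minimum count for a DA marker to be called "expressed"
        (default 1: detection).
    min_da_markers
        How many of the DA markers must be expressed (default 2 of 3).
    require_soma
        Whether a selected DA disc must carry the soma flag.
    glia_exclusion_quantile
        Per glia gene, the quantile of its counts over all tissue spots
        above which a spot is excluded (default 0.90).
    region_marker_threshold
        Minimum count for a region marker to vote for its region.
    glia_quantile_scope
        ``"dataset"`` (default) computes glia cutoffs over all spots;
        ``"section"`` computes them within each section.
    """

    da_marker_threshold: float = 1.0
    min_da_markers: int = 2
    require_soma: bool = True
    glia_exclusion_quantile: float = 0.90
    region_marker_threshold: float = 10.0
    glia_quantile_scope: str = "dataset"

    def __post_init__(self) -> None:
        if self.min_da_markers not in (1, 2, 3):
            raise ValueError(
                f"min_da_markers must be 1, 2 or 3, got {self.min_da_markers}"
            )
        if not (0.0 < self.glia_exclusion_quantile <= 1.0):
            raise ValueError(
                "glia_exclusion_quantile must be in (0, 1], got "
                f"{self.glia_exclusion_quantile}"
            )
        if self.da_marker_threshold < 0 or self.region_marker_threshold < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.glia_quantile_scope not in ("dataset", "section"):
            raise ValueError(
                f"glia_quantile_scope must be 'dataset' or 'section', got "
                f"{self.glia_quantile_scope!r}"
            )


@dataclass
class RegionSelection:
    """Per-spot region labels, selection mask and rule trace."""

    region: pd.Series  # label per spot, one of REGION_LABELS
    selected: np.ndarray  # boolean per spot
    rule_trace: list[list[str]]  # per spot, e.g. ["marker:pass", "soma:fail"]

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if len(self.region) != len(self.selected) or len(self.rule_trace) != len(
            self.selected
        ):
            raise ValueError("region, selected and rule_trace lengths differ")
        bad = self.selected & (self.region.to_numpy() == "unassigned")
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} selected spots are unassigned (invariant violation)"
            )

    def to_frame(self, matrix: Optional[SpotMatrix] = None) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "region": self.region.to_numpy(),
                "selected": self.selected,
                "rule_trace": [";".join(t) for t in self.rule_trace],
            }
        )
        if matrix is not None:
            out.insert(0, "barcode", matrix.spot_meta["barcode"].to_numpy())
            out.insert(1, "sample", matrix.spot_meta["sample"].to_numpy())
        return out


def glia_cutoffs(
    matrix: SpotMatrix, quantile: float, scope: str = "dataset"
) -> pd.DataFrame:
    """Per glia gene (and per section, if scoped) count cutoffs."""
    glia = matrix.genes_with_role("glia_marker")
    if glia.size == 0:
        raise ValueError("no glia_marker genes present in gene_meta")
    if scope == "dataset":
        cut = np.quantile(matrix.counts[:, glia], quantile, axis=0)
        return pd.DataFrame(
            {"gene": matrix.gene_meta["symbol"].to_numpy()[glia], "cutoff": cut}
        )
    rows = []
    for section, idx in matrix.spot_meta.groupby("section").groups.items():
        cut = np.quantile(matrix.counts[np.asarray(idx)][:, glia], quantile, axis=0)
        for g, c in zip(matrix.gene_meta["symbol"].to_numpy()[glia], cut):
            rows.append({"section": section, "gene": g, "cutoff": c})
    return pd.DataFrame(rows)


def _resolve_regions(
    matrix: SpotMatrix,
    candidate_region_mask: Union[np.ndarray, pd.Series, Sequence],
    region_labels: Optional[Sequence],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize the candidate argument into (mask, per-spot labels)."""
    arr = np.asarray(candidate_region_mask)
    if arr.dtype == bool:
        mask = arr
        if region_labels is not None:
            labels = np.asarray(region_labels, dtype=object)
        elif "region_truth" in matrix.spot_meta.columns:
            labels = matrix.spot_meta["region_truth"].to_numpy(dtype=object)
        else:
            # no label source: candidates default to SN, the canonical DA ROI
            labels = np.where(mask, "SN", "unassigned").astype(object)
    else:
        # labels were passed directly: candidates are the DA regions
        labels = arr.astype(object)
        mask = np.isin(labels, ("SN", "VTA"))
    labels = np.where(np.isin(labels, REGION_LABELS), labels, "unassigned")
    return mask, labels


def select_da_discs(
    matrix: SpotMatrix,
    rules: SelectionRules,
    candidate_region_mask: Union[np.ndarray, pd.Series, Sequence],
    region_labels: Optional[Sequence] = None,
) -> RegionSelection:
    """Apply the DA-disc inclusion/exclusion rules.

    A spot is selected iff all of: it lies in the candidate mask; at
    least ``min_da_markers`` DA markers reach ``da_marker_threshold``;
    its soma flag is set (when required); and no glia marker exceeds its
    exclusion-quantile cutoff.  The rule trace records each test per
    spot.

    ``candidate_region_mask`` may be a boolean mask (region labels then
    come from ``region_labels`` or a ``region_truth`` metadata column)
    or a per-spot label vector, in which case SN and VTA spots are the
    candidates.
    """
    da = matrix.genes_with_role("da_marker")
    if da.size == 0:
        raise ValueError("no da_marker genes present in gene_meta")
    glia = matrix.genes_with_role("glia_marker")
    if glia.size == 0:
        raise ValueError("no glia_marker genes present in gene_meta")

    mask, labels = _resolve_regions(matrix, candidate_region_mask, region_labels)

    n_expressed = (matrix.counts[:, da] >= rules.da_marker_threshold).sum(axis=1)
    marker_pass = n_expressed >= rules.min_da_markers

    if rules.require_soma:
        soma_pass = matrix.spot_meta["soma_flag"].to_numpy(dtype=bool)
    else:
        soma_pass = np.ones(matrix.n_spots, dtype=bool)

    if rules.glia_quantile_scope == "section":
        glia_pass = np.ones(matrix.n_spots, dtype=bool)
        for _, idx in matrix.spot_meta.groupby("section").groups.items():
            idx = np.asarray(idx)
            cut = np.quantile(
                matrix.counts[idx][:, glia], rules.glia_exclusion_quantile, axis=0
            )
            glia_pass[idx] = (matrix.counts[idx][:, glia] <= cut).all(axis=1)
    else:
        cut = np.quantile(
            matrix.counts[:, glia], rules.glia_exclusion_quantile, axis=0
        )
        glia_pass = (matrix.counts[:, glia] <= cut).all(axis=1)

    selected = mask & marker_pass & soma_pass & glia_pass
    trace = [
        [
            f"candidate:{'pass' if m else 'fail'}",
            f"marker:{'pass' if mp else 'fail'}",
            f"soma:{'pass' if sp else 'fail'}",
            f"glia:{'pass' if gp else 'fail'}",
        ]
        for m, mp, sp, gp in zip(mask, marker_pass, soma_pass, glia_pass)
    ]
    region = pd.Series(np.where(selected, labels, labels), dtype=object)
    # spots never selected keep their label; unlabeled ones stay unassigned
    return RegionSelection(region=region, selected=selected, rule_trace=trace)


def assign_marker_regions(
    matrix: SpotMatrix,
    region_marker_map: Optional[Mapping[str, Sequence[str]]] = None,
    rules: Optional[SelectionRules] = None,
) -> RegionSelection:
    """Assign each spot the region whose markers it expresses.

    Each region votes with the number of its marker genes at or above
    ``region_marker_threshold``; the spot takes the region with strictly
    the most votes.  Ties — including no votes at all — leave the spot
    unassigned (conservative: ambiguity is never resolved arbitrarily).

    ``region_marker_map`` maps region label → marker gene symbols; by
    default it is derived from ``region_marker:<region>`` gene roles.
    """
    rules = rules or SelectionRules()
    if region_marker_map is None:
        by_role = matrix.region_marker_map()
        if not by_role:
            raise ValueError("no region_marker:<region> genes present in gene_meta")
        region_cols = by_role
    else:
        region_cols = {}
        symbols = matrix.gene_meta["symbol"].to_numpy()
        for region, markers in region_marker_map.items():
            cols = [int(np.flatnonzero(symbols == m)[0]) for m in markers if m in symbols]
            if not cols:
                raise ValueError(
                    f"region {region!r}: none of its markers {list(markers)} present"
                )
            region_cols[region] = cols

    regions = list(region_cols)
    votes = np.zeros((matrix.n_spots, len(regions)), dtype=int)
    for k, region in enumerate(regions):
        votes[:, k] = (
            matrix.counts[:, region_cols[region]] >= rules.region_marker_threshold
        ).sum(axis=1)

    best = votes.max(axis=1)
    n_best = (votes == best[:, None]).sum(axis=1)
    winner = np.asarray(regions, dtype=object)[votes.argmax(axis=1)]
    labels = np.where((best > 0) & (n_best == 1), winner, "unassigned")

    trace = [
        [f"{r}:{v}" for r, v in zip(regions, row)]
        + [f"assigned:{lab}"]
        for row, lab in zip(votes, labels)
    ]
    return RegionSelection(
        region=pd.Series(labels, dtype=object),
        selected=np.zeros(matrix.n_spots, dtype=bool),
        rule_trace=trace,
    )


def filter_genes_by_detection(matrix: SpotMatrix, min_rate: float) -> SpotMatrix:
    """Drop genes detected (count > 0) in fewer than ``min_rate`` of spots.

    The boundary is inclusive: a gene detected in exactly ``min_rate``
    of spots is retained.  The spot set is unchanged.
    """
    if not (0.0 <= min_rate <= 1.0):
        raise ValueError(f"min_rate must be in [0, 1], got {min_rate}")
    rate = (matrix.counts > 0).mean(axis=0)
    keep = rate >= min_rate
    if not keep.any():
        logger.warning("detection filter at rate %.3g removed every gene", min_rate)
        warnings.warn("detection filter removed every gene", stacklevel=2)
    return matrix.subset_genes(keep)
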