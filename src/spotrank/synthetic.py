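"""Synthetic Visium-like data with known ground truth.

Emulates the three-group chemogenetic design (a DREADD-activated group,
its vehicle control, and an agonist-only control) on midbrain and
striatal sections: region-specific marker genes, dopamine-neuron (DA)
markers shared by SN and VTA, planted differentially expressed genes in
the treated group, glial contamination of a fraction of DA-region
spots, negative probes for background normalization, and a per-spot
soma flag.  Counts are negative-binomial (optionally Poisson); every
draw flows from one seed, with per-(sample, region) sub-streams so
block structure is stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import GroupValues, SpotMatrix

# Canonical marker symbols; extra markers beyond these get synthetic names.
DA_MARKER_SYMBOLS = ["Th", "Slc6a3", "Slc18a2"]
GLIA_MARKER_SYMBOLS = ["Gfap", "Aldh1l1", "Aif1", "P2ry12"]
REGION_MARKER_SYMBOLS = {
    "SN": ["Sox6", "Aldh1a7", "Ndnf"],
    "VTA": ["Calb1", "Otx2", "Cck"],
    "thalamus": ["Prkcd", "Ptpn3", "Synpo2"],
    "CP": ["Ppp1r1b", "Pde10a", "Adora2a"],
    "LSX": ["Trpc4", "Nts", "Crhr2"],
    "white_matter": ["Mbp", "Plp1", "Mog"],
}
MIDBRAIN_REGIONS = ("SN", "VTA", "thalamus")
STRIATAL_REGIONS = ("CP", "LSX", "white_matter")


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration is invalid; names the field."""


def _default_regions() -> dict[str, int]:
    # spots per region per sample; SN/VTA sized so the treated-vs-control
    # contrasts see tens of discs per group, the regime the analysis targets
    return {
        "SN": 10,
        "VTA": 15,
        "thalamus": 12,
        "CP": 40,
        "LSX": 10,
        "white_matter": 10,
    }


def _default_groups() -> list[tuple[str, int]]:
    return [("GqCNO", 3), ("GqVeh", 3), ("CNO", 2)]


def _default_genes_per_role() -> dict[str, int]:
    return {
        "da_markers": 3,
        "glia_markers": 4,
        "region_markers_per_region": 3,
        "negative_probes": 20,
        "planted_degs": 20,
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic dataset.

    Defaults describe the study conditions the analysis assumes: 2000
    genes, 20 planted DEGs at ≥2-fold in the treated group, negative-
    binomial counts with baseline mean 5 and size 10, 8-fold marker
    elevation in home regions, 10% glial contamination of DA-region
    spots, and soma probability 0.8 for DA-region spots.
    """

    n_genes: int = 2000
    genes_per_role: dict[str, int] = field(default_factory=_default_genes_per_role)
    regions: dict[str, int] = field(default_factory=_default_regions)
    groups: list[tuple[str, int]] = field(default_factory=_default_groups)
    treated_group: str = "GqCNO"
    nb_mean: float = 5.0
    nb_dispersion: float = 10.0
    count_model: str = "nb"
    marker_elevation: float = 8.0
    deg_effects: Optional[dict[str, float]] = None
    glial_contamination_rate: float = 0.1
    glia_contamination_fold: float = 10.0
    soma_rate: float = 0.8
    neg_probe_mean: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        roles = dict(_default_genes_per_role())
        roles.update(self.genes_per_role)
        self.genes_per_role = roles
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimulationConfigError(f"n_genes must be ≥ 1, got {self.n_genes}")
        for key, val in self.genes_per_role.items():
            if val < 0:
                raise SimulationConfigError(f"genes_per_role[{key!r}] must be ≥ 0")
        n_region_markers = self.genes_per_role["region_markers_per_region"] * len(
            self.regions
        )
        reserved = (
            self.genes_per_role["da_markers"]
            + self.genes_per_role["glia_markers"]
            + n_region_markers
            + self.genes_per_role["negative_probes"]
            + self.genes_per_role["planted_degs"]
        )
        if reserved > self.n_genes:
            raise SimulationConfigError(
                f"genes_per_role sums to {reserved} > n_genes={self.n_genes}"
            )
        if not self.regions:
            raise SimulationConfigError("regions must be non-empty")
        for region, n in self.regions.items():
            if n < 0:
                raise SimulationConfigError(f"regions[{region!r}] must be ≥ 0")
        if not self.groups:
            raise SimulationConfigError("groups must be non-empty")
        for label, n in self.groups:
            if n < 1:
                raise SimulationConfigError(f"groups[{label!r}] must have ≥ 1 sample")
        if self.treated_group not in {g for g, _ in self.groups}:
            raise SimulationConfigError(
                f"treated_group {self.treated_group!r} not among group labels"
            )
        if self.nb_mean <= 0:
            raise SimulationConfigError(f"nb_mean must be > 0, got {self.nb_mean}")
        if self.nb_dispersion <= 0:
            raise SimulationConfigError(
                f"nb_dispersion must be > 0, got {self.nb_dispersion}"
            )
        if self.count_model not in ("nb", "poisson"):
            raise SimulationConfigError(
                f"count_model must be 'nb' or 'poisson', got {self.count_model!r}"
            )
        if self.marker_elevation < 1:
            raise SimulationConfigError(
                f"marker_elevation must be ≥ 1, got {self.marker_elevation}"
            )
        for rate_name in ("glial_contamination_rate", "soma_rate"):
            rate = getattr(self, rate_name)
            if not (0.0 <= rate <= 1.0):
                raise SimulationConfigError(f"{rate_name} must be in [0, 1], got {rate}")
        if self.neg_probe_mean <= 0:
            raise SimulationConfigError(
                f"neg_probe_mean must be > 0, got {self.neg_probe_mean}"
            )
        if self.deg_effects is not None:
            planted = set(self._planted_symbols())
            extra = set(self.deg_effects) - planted
            if extra:
                raise SimulationConfigError(
                    f"deg_effects defined for non-planted genes: {sorted(extra)[:5]}"
                )
            for g, fold in self.deg_effects.items():
                if fold <= 0:
                    raise SimulationConfigError(
                        f"deg_effects[{g!r}] must be > 0, got {fold}"
                    )

    # -- gene bookkeeping --------------------------------------------------
    def _planted_symbols(self) -> list[str]:
        k = self.genes_per_role["planted_degs"]
        return [f"Deg{i + 1:04d}" for i in range(k)]

    def default_deg_effects(self) -> dict[str, float]:
        """2-, 3- and 4-fold effects, alternating up and down."""
        folds = [2.0, 3.0, 4.0]
        out = {}
        for i, sym in enumerate(self._planted_symbols()):
            f = folds[(i // 2) % 3]
            out[sym] = f if i % 2 == 0 else 1.0 / f
        return out

    def build_gene_meta(self) -> pd.DataFrame:
        symbols: list[str] = []
        roles: list[str] = []

        def add(sym: str, role: str) -> None:
            symbols.append(sym)
            roles.append(role)

        n_da = self.genes_per_role["da_markers"]
        for i in range(n_da):
            sym = DA_MARKER_SYMBOLS[i] if i < len(DA_MARKER_SYMBOLS) else f"DaMk{i + 1}"
            add(sym, "da_marker")
        n_glia = self.genes_per_role["glia_markers"]
        for i in range(n_glia):
            sym = (
                GLIA_MARKER_SYMBOLS[i]
                if i < len(GLIA_MARKER_SYMBOLS)
                else f"GliaMk{i + 1}"
            )
            add(sym, "glia_marker")
        n_per = self.genes_per_role["region_markers_per_region"]
        for region in self.regions:
            canon = REGION_MARKER_SYMBOLS.get(region, [])
            for i in range(n_per):
                sym = canon[i] if i < len(canon) else f"{region}_mk{i + 1}"
                add(sym, f"region_marker:{region}")
        for i in range(self.genes_per_role["negative_probes"]):
            add(f"NegPrb{i + 1:02d}", "neg_probe")
        for sym in self._planted_symbols():
            add(sym, "other")
        n_background = self.n_genes - len(symbols)
        for i in range(n_background):
            add(f"Gene{i + 1:04d}", "other")
        return pd.DataFrame(
            {
                "gene_id": [f"ENSMUSG{i:08d}" for i in range(len(symbols))],
                "symbol": symbols,
                "role": roles,
            }
        )


@dataclass
class SyntheticDataset:
    """A simulated dataset plus the truth needed to score recovery."""

    matrix: SpotMatrix
    truth: pd.DataFrame  # gene, true_fold, home_region — planted DEGs only
    selection_truth: np.ndarray  # per-spot: should be selected under defaults
    config: SimulationConfig


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, size: float, model: str
) -> np.ndarray:
    if model == "poisson":
        return rng.poisson(mean)
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_visium_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a spots × genes dataset with planted structure.

    Marker genes are elevated ``marker_elevation``-fold in their home
    region (DA markers in both SN and VTA); planted DEGs are scaled by
    their fold in every spot of the treated group; negative probes keep
    the baseline background mean everywhere.  The same config and seed
    always yield bit-identical output.
    """
    config.validate()
    gene_meta = config.build_gene_meta()
    n_genes = len(gene_meta)
    roles = gene_meta["role"].to_numpy()
    symbols = gene_meta["symbol"].to_numpy()

    deg_effects = (
        config.deg_effects
        if config.deg_effects is not None
        else config.default_deg_effects()
    )

    # per-gene baseline means
    base_mean = np.full(n_genes, config.nb_mean)
    base_mean[roles == "neg_probe"] = config.neg_probe_mean

    da_cols = np.flatnonzero(roles == "da_marker")
    glia_cols = np.flatnonzero(roles == "glia_marker")
    deg_cols = {sym: j for j, sym in enumerate(symbols) if sym in deg_effects}

    region_marker_cols: dict[str, np.ndarray] = {}
    for region in config.regions:
        region_marker_cols[region] = np.flatnonzero(roles == f"region_marker:{region}")

    # deterministic sub-streams per (sample, region) block
    ss = np.random.SeedSequence(config.seed)
    samples = [
        (f"{label}_{i + 1}", label)
        for label, n in config.groups
        for i in range(n)
    ]
    n_blocks = len(samples) * len(config.regions)
    children = ss.spawn(n_blocks)

    blocks_counts: list[np.ndarray] = []
    meta_rows: list[pd.DataFrame] = []
    sel_truth: list[np.ndarray] = []
    block_i = 0
    for sample, group in samples:
        for region_i, (region, n_spots) in enumerate(config.regions.items()):
            rng = np.random.default_rng(children[block_i])
            block_i += 1
            if n_spots == 0:
                continue
            mean = np.tile(base_mean, (n_spots, 1))
            # home-region marker elevation
            if region in ("SN", "VTA"):
                mean[:, da_cols] *= config.marker_elevation
            mean[:, region_marker_cols[region]] *= config.marker_elevation
            # treated-group effects on planted DEGs
            if group == config.treated_group:
                for sym, j in deg_cols.items():
                    mean[:, j] *= deg_effects[sym]
            # glial contamination of DA-region spots
            contaminated = np.zeros(n_spots, dtype=bool)
            if region in ("SN", "VTA") and config.glial_contamination_rate > 0:
                contaminated = (
                    rng.random(n_spots) < config.glial_contamination_rate
                )
                mean[np.ix_(contaminated, glia_cols)] *= config.glia_contamination_fold
            counts = _draw_counts(rng, mean, config.nb_dispersion, config.count_model)

            if region in ("SN", "VTA"):
                soma = rng.random(n_spots) < config.soma_rate
            else:
                soma = np.zeros(n_spots, dtype=bool)
            section = (
                f"{sample}-mid" if region in MIDBRAIN_REGIONS else f"{sample}-str"
            )
            # region block layout: regions occupy disjoint x bands
            x = region_i * 1000.0 + rng.uniform(0, 800, n_spots)
            y = rng.uniform(0, 800, n_spots)
            meta_rows.append(
                pd.DataFrame(
                    {
                        "barcode": [
                            f"{sample}-{region}-{k + 1:04d}" for k in range(n_spots)
                        ],
                        "x": x,
                        "y": y,
                        "sample": sample,
                        "group": group,
                        "section": section,
                        "soma_flag": soma,
                        "region_truth": region,
                        "contaminated": contaminated,
                    }
                )
            )
            blocks_counts.append(counts)
            sel_truth.append(
                np.full(n_spots, region in ("SN", "VTA")) & soma & ~contaminated
            )

    matrix = SpotMatrix(
        counts=np.vstack(blocks_counts),
        spot_meta=pd.concat(meta_rows, ignore_index=True),
        gene_meta=gene_meta,
    )
    truth = pd.DataFrame(
        {
            "gene": list(deg_effects),
            "true_fold": [deg_effects[g] for g in deg_effects],
            "home_region": "all",
        }
    )
    return SyntheticDataset(
        matrix=matrix,
        truth=truth,
        selection_truth=np.concatenate(sel_truth),
        config=config,
    )


def simulate_human_deg_table(
    mouse_truth: pd.DataFrame,
    concordance_prob: float,
    found_prob: float,
    seed: int,
) -> pd.DataFrame:
    """Synthetic human DEG table matched by symbol to a mouse truth table.

    Each mouse gene appears in the human table with probability
    ``found_prob``; a found gene's direction agrees with the mouse
    direction with probability ``concordance_prob``.  Output columns:
    ``symbol`` (upper-cased, human convention), ``logFC``, ``direction``,
    ``adj_p``.
    """
    if len(mouse_truth) == 0:
        raise ValueError("mouse_truth is empty")
    for name, p in (("concordance_prob", concordance_prob), ("found_prob", found_prob)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    rows = []
    for _, row in mouse_truth.iterrows():
        if rng.random() >= found_prob:
            continue
        mouse_dir = 1 if float(row["true_fold"]) > 1.0 else -1
        direction = mouse_dir if rng.random() < concordance_prob else -mouse_dir
        magnitude = abs(rng.normal(1.0, 0.4)) + 0.05
        rows.append(
            {
                "symbol": str(row["gene"]).upper(),
                "logFC": direction * magnitude,
                "direction": direction,
                "adj_p": float(rng.uniform(1e-4, 0.019)),
            }
        )
    return pd.DataFrame(rows, columns=["symbol", "logFC", "direction", "adj_p"])


def simulate_two_group_values(
    mean_a: float,
    sd_a: float,
    n_a: int,
    mean_b: float,
    sd_b: float,
    n_b: int,
    seed: int,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupValues:
    """Two seeded Gaussian samples, for exercising the two-group tests."""
    if n_a < 2 or n_b < 2:
        raise ValueError(f"each group needs n ≥ 2, got n_a={n_a}, n_b={n_b}")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be > 0")
    rng = np.random.default_rng(seed)
    return GroupValues(
        values_a=rng.normal(mean_a, sd_a, n_a),
        values_b=rng.normal(mean_b, sd_b, n_b),
        label_a=label_a,
        label_b=label_b,
    )


def simulate_depth_series(
    n_samples: int = 6,
    n_genes: int = 2000,
    depth_span: float = 4.0,
    n_neg_probes: int = 20,
    nb_mean: float = 20.0,
    nb_dispersion: float = 10.0,
    noise: bool = True,
    seed: int = 0,
) -> SpotMatrix:
    """Sample-level matrix with pure library-depth differences, no biology.

    One row per sample; all samples share the same per-gene expected
    expression, scaled by depth factors spanning ``depth_span``-fold.
    Used to evaluate normalization methods: a depth-correcting method
    should make the rows indistinguishable.  With ``noise=False`` the
    expected values are returned directly (rows exactly proportional),
    the regime where a correct normalization recovers identical rows.
    """
    if n_samples < 2:
        raise ValueError(f"n_samples must be ≥ 2, got {n_samples}")
    rng = np.random.default_rng(seed)
    # heterogeneous per-gene baseline so distributions have structure
    gene_mean = rng.lognormal(mean=np.log(nb_mean), sigma=1.0, size=n_genes)
    gene_mean[:n_neg_probes] = 1.0  # negative probes: background level
    depths = np.geomspace(1.0, depth_span, n_samples)
    mean = depths[:, None] * gene_mean[None, :]
    if noise:
        p = nb_dispersion / (nb_dispersion + mean)
        counts = rng.negative_binomial(nb_dispersion, p)
    else:
        counts = mean
    roles = ["neg_probe"] * n_neg_probes + ["other"] * (n_genes - n_neg_probes)
    gene_meta = pd.DataFrame(
        {
            "gene_id": [f"G{i:06d}" for i in range(n_genes)],
            "symbol": [f"NegPrb{i + 1:02d}" for i in range(n_neg_probes)]
            + [f"Gene{i + 1:04d}" for i in range(n_genes - n_neg_probes)],
            "role": roles,
        }
    )
    spot_meta = pd.DataFrame(
        {
            "barcode": [f"S{i + 1}" for i in range(n_samples)],
            "x": np.zeros(n_samples),
            "y": np.zeros(n_samples),
            "sample": [f"S{i + 1}" for i in range(n_samples)],
            "group": "null",
            "section": [f"S{i + 1}" for i in range(n_samples)],
            "soma_flag": False,
        }
    )
    return SpotMatrix(counts=counts, spot_meta=spot_meta, gene_meta=gene_meta)
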