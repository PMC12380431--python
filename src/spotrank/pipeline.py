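"""End-to-end orchestration: simulate/read → select → score → hits → congruence.

Every stage consumes and produces files, records its row counts in a
run manifest, and derives all randomness from the single config seed,
so a rerun with the same config and seed reproduces every numeric
artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import __version__
from .congruence import congruence_report
from .containers import SpotMatrix
from .degstats import call_hits, score_genes
from .io import read_matrix, write_matrix
from .normalization import evaluate_normalizations, normalize_counts
from .selection import (
    SelectionRules,
    assign_marker_regions,
    filter_genes_by_detection,
    select_da_discs,
)
from .synthetic import SimulationConfig, simulate_human_deg_table, simulate_visium_dataset

logger = logging.getLogger(__name__)


class PipelineConfigError(ValueError):
    """Invalid pipeline configuration (exit code 2 at the CLI)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3 at the CLI); names the stage."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Exactly one input source: an ``input_path`` (triplet directory or
    dense CSV) or a ``simulation`` config.  Contrasts are (treated,
    control) group-label pairs; scoring runs per region of interest.
    """

    out_dir: Union[str, Path]
    input_path: Optional[Union[str, Path]] = None
    simulation: Optional[SimulationConfig] = None
    rules: SelectionRules = field(default_factory=SelectionRules)
    min_detection_rate: float = 0.0
    normalization_method: Optional[str] = None
    evaluate_normalization: bool = False
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("GqCNO", "GqVeh"), ("GqCNO", "CNO")]
    )
    score_regions: list[str] = field(default_factory=lambda: ["SN", "VTA"])
    alpha: float = 0.05
    top_k: Union[int, str] = "all"
    human_degs_path: Optional[Union[str, Path]] = None
    simulate_human: bool = False
    human_concordance_prob: float = 0.9
    human_found_prob: float = 51 / 59
    seed: int = 0

    def validate(self, matrix: Optional[SpotMatrix] = None) -> None:
        if (self.input_path is None) == (self.simulation is None):
            raise PipelineConfigError(
                "exactly one of input_path or simulation must be set"
            )
        if not (0.0 < self.alpha <= 1.0):
            raise PipelineConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        known_groups = None
        if self.simulation is not None:
            known_groups = {g for g, _ in self.simulation.groups}
        elif matrix is not None:
            known_groups = set(matrix.spot_meta["group"].unique())
        if known_groups is not None:
            for treated, control in self.contrasts:
                for grp in (treated, control):
                    if grp not in known_groups:
                        raise PipelineConfigError(
                            f"contrast group {grp!r} not among groups "
                            f"{sorted(known_groups)}"
                        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            return obj

        return {
            k: enc(v) for k, v in dataclasses.asdict(self).items()
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if data.get("simulation") is not None:
            sim = dict(data["simulation"])
            if "groups" in sim:
                sim["groups"] = [tuple(g) for g in sim["groups"]]
            data["simulation"] = SimulationConfig(**sim)
        if data.get("rules") is not None and not isinstance(
            data["rules"], SelectionRules
        ):
            data["rules"] = SelectionRules(**data["rules"])
        if "contrasts" in data:
            data["contrasts"] = [tuple(c) for c in data["contrasts"]]
        return cls(**data)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run."""

    config_hash: str
    version: str
    seed: int
    stage_counts: dict
    warnings: list[str]
    started: float
    finished: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_atomic(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".partial")
    tmp.write_text(text)
    tmp.replace(path)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the manifest (also written to disk).

    Stages: load/simulate, region assignment, DA-disc selection,
    detection filter, optional normalization (+ evaluation), per-region
    per-contrast gene scoring, dual-contrast hit calling, and — when a
    human DEG table is supplied or simulated — the cross-species
    congruence report.
    """
    started = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    warn_log: list[str] = []
    stage = "validate"
    try:
        config.validate()

        stage = "input"
        truth = None
        if config.simulation is not None:
            dataset = simulate_visium_dataset(config.simulation)
            matrix = dataset.matrix
            truth = dataset.truth
            write_matrix(matrix, out / "simulated")
            truth.to_csv(out / "simulated" / "truth.csv", index=False)
        else:
            matrix = read_matrix(config.input_path)
        config.validate(matrix)
        counts["input"] = {"spots": matrix.n_spots, "genes": matrix.n_genes}

        stage = "regions"
        try:
            regions = assign_marker_regions(matrix, rules=config.rules)
            region_labels = regions.region.to_numpy()
        except ValueError:
            if "region_truth" in matrix.spot_meta.columns:
                region_labels = matrix.spot_meta["region_truth"].to_numpy()
                warn_log.append("no region markers; used region_truth metadata")
            else:
                raise
        counts["regions"] = {
            str(r): int(n)
            for r, n in pd.Series(region_labels).value_counts().items()
        }

        stage = "selection"
        selection = select_da_discs(
            matrix,
            config.rules,
            candidate_region_mask=np.isin(region_labels, ("SN", "VTA")),
            region_labels=region_labels,
        )
        sel_frame = selection.to_frame(matrix)
        _write_atomic(out / "selection.csv", sel_frame.to_csv(index=False))
        per_region = (
            sel_frame[sel_frame["selected"]]
            .groupby(["sample", "region"])
            .size()
            .rename("n_discs")
            .reset_index()
        )
        _write_atomic(
            out / "selection_summary.json",
            json.dumps(
                {
                    "selected_total": int(selection.selected.sum()),
                    "per_sample_region": per_region.to_dict(orient="records"),
                },
                indent=2,
            ),
        )
        counts["selection"] = {"selected": int(selection.selected.sum())}

        stage = "detection_filter"
        filtered = filter_genes_by_detection(matrix, config.min_detection_rate)
        counts["detection_filter"] = {"genes": filtered.n_genes}

        stage = "normalization"
        working = filtered
        if config.evaluate_normalization:
            report = evaluate_normalizations(filtered, alpha=config.alpha)
            _write_atomic(
                out / "normalization_report.json",
                json.dumps(report.to_dict(), indent=2, default=float),
            )
            counts["normalization"] = {"chosen_method": report.chosen_method}
        if config.normalization_method is not None:
            working = normalize_counts(filtered, config.normalization_method)
            counts.setdefault("normalization", {})["applied"] = (
                config.normalization_method
            )

        stage = "scoring"
        score_tables = {}
        for region in config.score_regions:
            mask = selection.selected & (region_labels == region)
            for treated, control in config.contrasts:
                table = score_genes(
                    working, treated, control, region_mask=mask
                )
                key = (region, table.contrast)
                score_tables[key] = table
                _write_atomic(
                    out / f"scores_{region}_{table.contrast}.csv",
                    table.table.to_csv(index=False),
                )
        counts["scoring"] = {"tables": len(score_tables)}

        stage = "hits"
        n_hits = {}
        for region in config.score_regions:
            tables = [
                score_tables[(region, f"{t}_vs_{c}")] for t, c in config.contrasts
            ]
            if len(tables) < 2:
                continue
            hits = call_hits(
                tables[0], tables[1], alpha=config.alpha, top_k=config.top_k
            )
            _write_atomic(
                out / f"hits_{region}.csv", hits.table.to_csv(index=False)
            )
            _write_atomic(
                out / f"hits_{region}_genes.txt", "\n".join(hits.genes) + "\n"
            )
            n_hits[region] = len(hits.genes)
        counts["hits"] = n_hits

        stage = "congruence"
        human = None
        if config.human_degs_path is not None:
            human = pd.read_csv(config.human_degs_path)
        elif config.simulate_human and truth is not None:
            human = simulate_human_deg_table(
                truth,
                concordance_prob=config.human_concordance_prob,
                found_prob=config.human_found_prob,
                seed=config.seed + 1,
            )
        if human is not None and truth is not None:
            report = congruence_report(truth, human, alpha=config.alpha)
            per_gene = report.pop("per_gene")
            _write_atomic(
                out / "congruence_report.json",
                json.dumps(report, indent=2, default=float),
            )
            _write_atomic(
                out / "concordance_per_gene.csv", per_gene.to_csv(index=False)
            )
            counts["congruence"] = {
                "n_found": report["n_found"],
                "p_value": report["p_value"],
            }
    except PipelineConfigError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage attribution is the contract
        raise StageError(f"stage {stage!r} failed: {exc}") from exc

    manifest = RunManifest(
        config_hash=config.config_hash(),
        version=__version__,
        seed=config.seed,
        stage_counts=counts,
        warnings=warn_log,
        started=started,
        finished=time.time(),
    )
    _write_atomic(out / "manifest.json", json.dumps(manifest.to_dict(), indent=2))
    return manifest
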