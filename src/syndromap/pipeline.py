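"""End-to-end pipeline: simulate/load -> distance -> lens -> map -> color ->
enrich -> GLM -> manifest.

Every analysis stage is deterministic; the configured seed governs only the
synthetic-cohort stage, so identical configuration and seed give
byte-identical artifacts (verified by the per-stage checksums recorded in
the manifest).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cde_io import load_cohort, summarize_variables
from .glm_hypothesis import build_glm_dataset, repeated_measures_suite
from .mapper_core import CoverConfig, build_graph, color_graph
from .mds_lens import optimize_lens
from .subgroup_enrichment import (
    EmptySelectionError,
    enrichment_screen,
    select_subgroup,
)
from .synthetic_cohort import PlantedSubgroup, SimulationConfig, generate_cohort
from .syndromic_distance import pairwise_distances, standardize_columns

logger = logging.getLogger("syndromap")

#: poor-and-declining 6-month outcome among CT-negative patients — the
#: node-level analogue of the circled low-recovery mild-TBI region
DEFAULT_PREDICATE = (
    "(gose_6m - gose_3m) < -1.25 and gose_6m < 5.5 and ct_brain_pathology < 0.5"
)
DEFAULT_COLOR_VARIABLES = (
    "ct_brain_pathology",
    "ptsd_dx_6m",
    "gose_3m",
    "gose_6m",
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 0
    # either a cohort file (+ metadata) or a simulation
    cohort_path: str | None = None
    metadata_path: str | None = None
    simulation: SimulationConfig | None = None
    cover: CoverConfig = field(default_factory=CoverConfig)
    lens_max_iter: int = 300
    lens_tol: float = 1e-6
    histogram_bins: int = 10
    impute: str = "mean"
    selection_predicate: str = DEFAULT_PREDICATE
    color_variables: tuple[str, ...] = DEFAULT_COLOR_VARIABLES
    glm_snps: tuple[str, ...] = ("PARP1_rs3219119",)

    def __post_init__(self) -> None:
        if self.cohort_path is None and self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    # -- serialization (round-trips unchanged) --------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cover"] = dataclasses.asdict(self.cover)
        if self.simulation is not None:
            d["simulation"] = dataclasses.asdict(self.simulation)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("cover"):
            d["cover"] = CoverConfig(**d["cover"])
        if d.get("simulation"):
            sim = dict(d["simulation"])
            if sim.get("planted"):
                sim["planted"] = PlantedSubgroup(**sim["planted"])
            for key in ("outcome_means_sds", "genotype_freqs"):
                if sim.get(key):
                    sim[key] = {k: tuple(v) for k, v in sim[key].items()}
            d["simulation"] = SimulationConfig(**sim)
        for key in ("color_variables", "glm_snps"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; return the artifact manifest (also written to
    ``manifest.json``).  A failing stage aborts with the stage name."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stages: list[dict] = []

    def record(stage: str, path: Path, n_in: int, n_out: int) -> None:
        artifacts[stage] = path
        stages.append(
            {"stage": stage, "artifact": path.name, "rows_in": n_in,
             "rows_out": n_out, "status": "ok"}
        )
        logger.info("stage=%s artifact=%s rows_in=%d rows_out=%d",
                    stage, path.name, n_in, n_out)

    # cohort -------------------------------------------------------------
    try:
        if cfg.cohort_path:
            cohort = load_cohort(cfg.cohort_path, cfg.metadata_path)
        else:
            cohort = generate_cohort(cfg.simulation)
        cohort_csv = outdir / "cohort.csv"
        cohort.write_csv(cohort_csv)
        if cohort.truth is not None:
            cohort.truth.to_csv(outdir / "truth.csv", encoding="utf-8")
        summarize_variables(cohort).to_csv(outdir / "cohort_summary.csv",
                                           encoding="utf-8")
        record("cohort", cohort_csv, cohort.n_patients, cohort.n_patients)
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError("cohort", exc) from exc

    # distance -----------------------------------------------------------
    try:
        std = standardize_columns(cohort, impute=cfg.impute)
        dist = pairwise_distances(std)
        dist_csv = outdir / "distance.csv"
        dist.to_csv(dist_csv)
        record("distance", dist_csv, cohort.n_patients, dist.n)
    except Exception as exc:
        raise StageError("distance", exc) from exc

    # lens -----------------------------------------------------------------
    try:
        lens = optimize_lens(dist, max_iter=cfg.lens_max_iter, tol=cfg.lens_tol)
        lens_csv = outdir / "lens.csv"
        lens.to_csv(lens_csv)
        record("lens", lens_csv, dist.n, lens.coords.shape[0])
    except Exception as exc:
        raise StageError("lens", exc) from exc

    # map ------------------------------------------------------------------
    try:
        graph = build_graph(lens, dist, cfg.cover, cfg.histogram_bins, cohort)
        graph_json = outdir / "graph.json"
        graph.to_json(graph_json)
        graph.to_graphml(outdir / "graph.graphml")
        record("map", graph_json, lens.coords.shape[0], len(graph.nodes))
    except Exception as exc:
        raise StageError("map", exc) from exc

    # color ----------------------------------------------------------------
    try:
        import pandas as pd

        colors = {}
        for var in cfg.color_variables:
            colors[var] = color_graph(graph, cohort, var)["value"]
        color_csv = outdir / "node_colors.csv"
        pd.DataFrame(colors).to_csv(color_csv, encoding="utf-8")
        record("color", color_csv, len(graph.nodes), len(graph.nodes))
    except Exception as exc:
        raise StageError("color", exc) from exc

    # enrich ---------------------------------------------------------------
    try:
        sel = select_subgroup(graph, cfg.selection_predicate)
        screen = enrichment_screen(sel, cohort)
        enrich_csv = outdir / "enrichment.csv"
        screen.to_csv(enrich_csv, index=False, encoding="utf-8")
        record("enrich", enrich_csv, len(sel.member_ids), len(screen))
        subgroup_n = len(sel.member_ids)
    except EmptySelectionError as exc:
        # an empty selection is a legitimate outcome on a null cohort
        screen = None
        subgroup_n = 0
        enrich_csv = outdir / "enrichment.csv"
        enrich_csv.write_text("variable,test,statistic,p_value,q_value\n",
                              encoding="utf-8")
        record("enrich", enrich_csv, 0, 0)
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # glm --------------------------------------------------------------------
    try:
        glm_dir = outdir / "glm"
        n_rows = 0
        for snp in cfg.glm_snps:
            dataset = build_glm_dataset(cohort, snp)
            report = repeated_measures_suite(dataset)
            report.write_csv(glm_dir)
            dataset.exclusions.to_csv(
                glm_dir / f"exclusions_{snp}.csv", index=False, encoding="utf-8"
            )
            n_rows += dataset.n
        record("glm", glm_dir, cohort.n_patients, n_rows)
    except Exception as exc:
        raise StageError("glm", exc) from exc

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": stages,
        "checksums": {
            stage: (_sha256(p) if p.is_file() else
                    {f.name: _sha256(f) for f in sorted(p.glob("*.csv"))})
            for stage, p in artifacts.items()
        },
        "subgroup_n": subgroup_n,
        "n_nodes": len(graph.nodes),
        "n_edges": len(graph.edges),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
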