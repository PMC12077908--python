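"""Pipeline orchestration: simulate -> score-csf -> monitor -> tppas.

Each stage is a thin function over the library modules; :func:`run_pipeline`
chains the configured stages, writes their tabular outputs under one output
directory and finishes with a run manifest (inputs, rule values, seed,
package version, stage status). A stage failure halts the run with the
failing stage named and the manifest marked incomplete.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as pio
from . import proteomics as prot
from .monitoring import MonitoringRules, check_eligibility, evaluate_arm, evaluate_patient
from .simulate import (
    SimulationConfig,
    generate_expression_summaries,
    generate_proteomics,
    generate_trajectories,
)
from .transcriptomics import score_cell_types

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate_to_dir"]

OUTCOME_COLUMNS = list(prot.OUTCOME_COLUMNS)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; names the stage."""


@dataclass
class PipelineConfig:
    """Paths and rule overrides for a full run; JSON round-trippable."""

    outdir: str
    seed: int = 0
    matrix: str | None = None
    metadata: str | None = None
    protein_map: str | None = None  # TSV protein -> gene; identity when absent
    pathway: str | None = None
    expression_pathway: str | None = None  # tppas pathway; falls back to `pathway`
    weights: str | None = None
    visits: str | None = None
    therapy: str | None = None
    summary: str | None = None
    alpha: float = 0.05
    simulate: bool = False
    simulation: dict = field(default_factory=dict)
    monitoring_rules: dict = field(default_factory=dict)

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")

    def validate_inputs(self) -> None:
        if self.simulate:
            return
        for name in (
            "matrix", "metadata", "protein_map", "pathway", "expression_pathway",
            "visits", "therapy", "summary", "weights",
        ):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise PipelineError(f"input file for {name!r} does not exist: {value}")


def simulate_to_dir(cfg: SimulationConfig, outdir) -> dict[str, str]:
    """Write one synthetic dataset bundle (matrices, visits, pathway, truth)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = generate_proteomics(cfg)
    trajs = generate_trajectories(cfg)
    expr = generate_expression_summaries(cfg)

    paths = {k: str(outdir / v) for k, v in {
        "matrix": "abundance.tsv",
        "metadata": "samples.tsv",
        "protein_map": "proteins.tsv",
        "pathway": "pathway_directions.tsv",
        "pathway_gmt": "pathway.gmt",
        "expression_pathway": "expression_pathway_directions.tsv",
        "visits": "visits.tsv",
        "therapy": "therapy.tsv",
        "summary": "expression_summary.tsv",
        "truth": "truth.json",
    }.items()}

    pio.write_matrix(sim.dataset.abundance, paths["matrix"])
    meta = sim.dataset.samples.copy()
    meta["collection_date"] = pd.to_datetime(meta["collection_date"]).dt.date
    meta = meta.join(sim.outcomes, on="patient_id")
    meta.to_csv(paths["metadata"], sep="\t", float_format="%.10g")
    sim.dataset.proteins.to_csv(paths["protein_map"], sep="\t")
    pio.write_direction_tsv(sim.pathway, paths["pathway"])
    pio.write_gmt(sim.pathway, paths["pathway_gmt"], description="synthetic pyroptosis panel")
    pio.write_direction_tsv(expr.pathway, paths["expression_pathway"])
    pio.write_visits(trajs.trajectories, paths["visits"], paths["therapy"])
    pio.write_summary(expr.summary, paths["summary"])
    pio.write_json(
        {
            "proteomics": {k: v for k, v in sim.truth.items() if k != "latent_severity"},
            "trajectories": trajs.truth.to_dict(orient="records"),
            "expression": expr.truth,
            "seed": cfg.seed,
        },
        paths["truth"],
    )
    return paths


def _stage_score_csf(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    matrix = pio.read_matrix(config.matrix)
    meta = pd.read_csv(config.metadata, sep="\t", index_col=0, parse_dates=["collection_date"])
    pathway = pio.read_pathway(config.pathway)

    hd_ids = list(meta.index[meta["diagnosis"] == "HD"])
    scaled = prot.hd_scale(matrix, hd_ids)

    baseline = meta[meta["visit_role"] == "baseline"]
    ms_baseline = baseline[baseline["diagnosis"].isin(["RRMS", "progMS"])]
    outcomes = (
        ms_baseline.reset_index()[["patient_id", *OUTCOME_COLUMNS]]
        .drop_duplicates("patient_id")
        .set_index("patient_id")
    )
    severity_by_patient = prot.global_severity(outcomes)
    severity = pd.Series(
        severity_by_patient.loc[ms_baseline["patient_id"]].to_numpy(),
        index=ms_baseline.index,
        name="global_severity",
    )

    if config.weights:
        weights = pio.read_weights(config.weights)
        manifest["score_csf"] = {"weights": "frozen", "n_proteins": len(weights.proteins)}
    else:
        gene_map = None  # columns already identify analytes by gene symbol
        if config.protein_map:
            gene_map = pd.read_csv(config.protein_map, sep="\t", index_col=0)["gene"]
        weights = prot.select_score_proteins(
            scaled, severity, pathway, gene_map=gene_map, alpha=config.alpha
        )
        manifest["score_csf"] = {"weights": "selected", "n_proteins": len(weights.proteins)}
    pio.write_weights(weights, outdir / "weights.json")

    scores = prot.score_samples(scaled, weights)
    scores = scores.join(meta[["patient_id", "diagnosis", "visit_role"]])
    pio.write_matrix(scores, outdir / "scores.tsv")

    comparisons = prot.group_compare(
        scores.loc[baseline.index, "score"],
        meta["diagnosis"],
        severity_outcomes=outcomes,
        patient_of_sample=meta["patient_id"],
    )
    pio.write_json(comparisons, outdir / "group_comparisons.json")

    therapy_meta = meta[meta["visit_role"] == "therapy"]
    if len(therapy_meta) >= 3:
        paired_patients = therapy_meta["patient_id"]
        base_ids = (
            baseline.reset_index().set_index("patient_id").loc[paired_patients].iloc[:, 0]
        )
        base_scaled = scaled.loc[base_ids.to_numpy()]
        base_scaled.index = pd.Index(paired_patients.to_numpy(), name="patient_id")
        ther_scaled = scaled.loc[therapy_meta.index]
        ther_scaled.index = pd.Index(paired_patients.to_numpy(), name="patient_id")
        change = prot.change_analysis(base_scaled, ther_scaled)
        pio.write_matrix(change, outdir / "change_table.tsv")
        pio.write_lines(prot.extreme_gene_list(change), outdir / "extreme_genes.txt")
        manifest["score_csf"]["n_pairs"] = int(len(therapy_meta))


def _stage_monitor(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    rules = MonitoringRules(**config.monitoring_rules)
    trajectories = pio.read_visits(config.visits, config.therapy)
    slope_rows, decisions = [], []
    for traj in trajectories:
        elig = check_eligibility(traj, rules)
        # only eligible (measurably progressing) patients enter monitoring
        decision = (
            evaluate_patient(traj, rules)
            if elig.eligible and traj.therapy_start is not None
            else None
        )
        slope_rows.append(
            {
                "patient_id": traj.patient_id,
                "eligible": elig.eligible,
                "reasons": "; ".join(elig.reasons),
                "baseline_slope": elig.baseline.slope if elig.baseline else float("nan"),
                "therapy_slope": decision.therapy_slope if decision else float("nan"),
                "slope_ratio": decision.slope_ratio if decision else float("nan"),
                "lesion_ratio": decision.lesion_ratio if decision else float("nan"),
                "triggered": decision.triggered if decision else False,
            }
        )
        if decision is not None:
            decisions.append(decision)
    pd.DataFrame(slope_rows).to_csv(outdir / "trigger_report.tsv", sep="\t", index=False, float_format="%.10g")
    if decisions:
        arm = evaluate_arm(decisions, rules)
        pio.write_json(
            {
                "stopped": arm.stopped,
                "n_triggered": arm.n_triggered,
                "n_total": arm.n_total,
                "fraction_triggered": arm.fraction_triggered,
                "rules": dataclasses.asdict(rules),
            },
            outdir / "arm_summary.json",
        )
        manifest["monitor"] = {
            "n_patients": len(trajectories),
            "n_triggered": arm.n_triggered,
            "stopped": arm.stopped,
        }
    else:
        manifest["monitor"] = {"n_patients": len(trajectories), "n_triggered": 0}


def _stage_tppas(config: PipelineConfig, outdir: Path, manifest: dict) -> None:
    summary = pio.read_summary(config.summary)
    pathway = pio.read_pathway(config.expression_pathway or config.pathway)
    scores, exclusions = score_cell_types(summary, pathway)
    pio.write_summary(scores, outdir / "tppas.tsv")
    pio.write_summary(exclusions, outdir / "tppas_exclusions.tsv")
    manifest["tppas"] = {
        "n_cell_types": int(scores["cell_type"].nunique()),
        "n_excluded_genes": int(len(exclusions)),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate_inputs()

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "complete": False,
    }

    def _run(name: str, fn) -> None:
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            manifest["failed_stage"] = name
            pio.write_json(manifest, outdir / "manifest.json")
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append(name)

    if config.simulate:
        sim_cfg = SimulationConfig(seed=config.seed, **config.simulation)
        paths = simulate_to_dir(sim_cfg, outdir / "inputs")
        config.matrix = config.matrix or paths["matrix"]
        config.metadata = config.metadata or paths["metadata"]
        config.protein_map = config.protein_map or paths["protein_map"]
        config.pathway = config.pathway or paths["pathway"]
        config.expression_pathway = config.expression_pathway or paths["expression_pathway"]
        config.visits = config.visits or paths["visits"]
        config.therapy = config.therapy or paths["therapy"]
        config.summary = config.summary or paths["summary"]
        manifest["stages"].append("simulate")

    if config.matrix:
        _run("score-csf", lambda: _stage_score_csf(config, outdir, manifest))
    if config.visits:
        _run("monitor", lambda: _stage_monitor(config, outdir, manifest))
    if config.summary:
        _run("tppas", lambda: _stage_tppas(config, outdir, manifest))

    manifest["complete"] = True
    manifest["inputs"] = {
        k: getattr(config, k)
        for k in (
            "matrix", "metadata", "protein_map", "pathway", "expression_pathway",
            "weights", "visits", "therapy", "summary",
        )
    }
    manifest["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    pio.write_json(manifest, outdir / "manifest.json")
    return manifest
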