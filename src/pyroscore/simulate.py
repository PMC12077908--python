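"""Seeded synthetic data with the statistical structure the analyses assume.

Three generators stand in for the study's patient data:

* :func:`generate_proteomics` — an RFU-like samples x proteins matrix for
  healthy donors (HD), relapsing-remitting (RRMS) and progressive MS
  patients. MS samples carry a latent severity scalar; three observed
  severity outcomes are noisy monotone views of it, and a configurable number
  of "informative" pathway proteins track it on the log scale with a sign
  matching their directionality. Optional paired on-therapy samples support
  the change analysis.
* :func:`generate_trajectories` — piecewise-linear disability trajectories
  on a 0-100 scale: pre-therapy visits follow a patient-specific slope with
  Gaussian visit noise, on-therapy visits continue with that slope times a
  therapy multiplier; new/enlarging lesion counts are Poisson.
* :func:`generate_expression_summaries` — per (group, cell type, gene)
  average expression and fraction expressing, with log2(1 + AGE) linear in
  the detection fraction, planted activation offsets in configured MS cell
  types, and planted residual outlier genes.

All draws derive from one global seed through independent named substreams,
so a fixed seed and config give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .monitoring import PatientTrajectory
from .pathway import PathwaySpec
from .proteomics import ProteomicsDataset

__all__ = [
    "SimulationConfig",
    "SimulatedProteomics",
    "SimulatedTrajectories",
    "SimulatedExpression",
    "generate_proteomics",
    "generate_trajectories",
    "generate_expression_summaries",
    "generate_cell_matrix",
]

DAYS_PER_YEAR = 365.25

CELL_TYPES = (
    "microglia_macrophage",
    "oligodendrocyte",
    "astrocyte",
    "opc",
    "excitatory_neuron",
    "inhibitory_neuron",
    "epithelial_stromal",
)
LESION_TYPES = (
    "active",
    "chronic_active",
    "chronic_inactive",
    "periplaque",
    "nawm",
    "control",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, in one place.

    Defaults mirror the study setting: 49 healthy donors and 168 MS patients
    (100 RRMS / 68 progressive) on a ~7,000-protein panel with a
    severity-linked pyroptosis panel of 60 proteins, 10 of them informative;
    9 treated patients with paired CSF; progressive patients worsening by
    ~1 CombiWISE unit/year seen every ~6 months with ~1 unit of visit noise
    and essentially no new lesion formation.
    """

    seed: int = 0

    # --- proteomics ---
    n_hd: int = 49
    n_rrms: int = 100
    n_prog: int = 68
    n_proteins: int = 7000
    n_pathway: int = 60
    n_informative: int = 10
    effect_size: float = 1.0          # latent severity shift per group step
    protein_severity_beta: float = 0.4  # log-abundance units per severity unit
    protein_noise_sd: float = 1.0       # log-abundance residual SD
    outcome_noise_sd: float = 0.3
    n_treated: int = 9
    treatment_effect: float = 0.0     # log-scale on-therapy shift, signed by direction
    positive_direction_fraction: float = 0.7

    # --- disability trajectories ---
    n_patients: int = 9
    n_visits: int = 4                 # pre-therapy visits
    n_therapy_visits: int = 3
    visit_interval_days: float = 183.0
    baseline_slope_mean: float = 1.0  # disability units / year
    baseline_slope_sd: float = 0.3
    visit_noise_sd: float = 1.0       # disability units
    therapy_slope_multiplier: float | Sequence[float] = 1.0
    lesion_rate_per_year: float = 0.0
    lesion_therapy_multiplier: float = 1.0
    disability_start_mean: float = 50.0
    disability_start_sd: float = 10.0
    start_date: str = "2018-01-15"

    # --- expression summaries ---
    cell_types: tuple[str, ...] = CELL_TYPES
    lesion_types: tuple[str, ...] = LESION_TYPES
    n_pathway_genes: int = 30
    activation_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"microglia_macrophage": 0.5, "oligodendrocyte": 0.5}
    )
    n_outlier_genes: int = 1
    outlier_sd_multiplier: float = 10.0
    expression_noise_sd: float = 0.15
    expression_slope: float = 3.0
    expression_intercept: float = 0.3

    def __post_init__(self) -> None:
        if not (0 <= self.n_informative <= self.n_pathway <= self.n_proteins):
            raise ValueError("need n_informative <= n_pathway <= n_proteins")
        for name in (
            "protein_noise_sd", "outcome_noise_sd", "baseline_slope_sd",
            "visit_noise_sd", "disability_start_sd", "expression_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_hd", "n_rrms", "n_prog", "n_patients", "n_treated"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.lesion_rate_per_year < 0:
            raise ValueError("lesion_rate_per_year must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream of the global seed."""
        return np.random.default_rng([int(self.seed), int(stream)])


_PROTEOMICS_STREAM = 11
_TRAJECTORY_STREAM = 23
_EXPRESSION_STREAM = 37
_CELLS_STREAM = 53


@dataclass
class SimulatedProteomics:
    dataset: ProteomicsDataset
    outcomes: pd.DataFrame          # per MS patient: the three severity outcomes
    pathway: PathwaySpec
    truth: dict


@dataclass
class SimulatedTrajectories:
    trajectories: list[PatientTrajectory]
    truth: pd.DataFrame             # patient_id, baseline slope, therapy multiplier


@dataclass
class SimulatedExpression:
    summary: pd.DataFrame           # group, cell_type, gene, avg_expression, fraction_expressing
    pathway: PathwaySpec
    truth: dict


def _directions(rng: np.random.Generator, n: int, pos_fraction: float) -> np.ndarray:
    return np.where(rng.random(n) < pos_fraction, 1, -1).astype(int)


def generate_proteomics(cfg: SimulationConfig) -> SimulatedProteomics:
    """Simulate the measured CSF panel with planted severity structure."""
    if cfg.n_hd == 0:
        raise ValueError(
            "at least one healthy-donor sample is required: downstream HD "
            "scaling standardizes every protein against the HD distribution"
        )
    rng = cfg.rng(_PROTEOMICS_STREAM)

    width = len(str(cfg.n_proteins))
    protein_ids = [f"SOMA{i + 1:0{width}d}" for i in range(cfg.n_proteins)]
    genes = [f"GENE{i + 1:0{width}d}" for i in range(cfg.n_proteins)]
    pathway_idx = np.sort(rng.choice(cfg.n_proteins, size=cfg.n_pathway, replace=False))
    informative_idx = pathway_idx[:cfg.n_informative]
    directions = _directions(rng, cfg.n_pathway, cfg.positive_direction_fraction)

    beta = np.zeros(cfg.n_proteins)
    info_dirs = directions[:cfg.n_informative]
    beta[informative_idx] = info_dirs * cfg.protein_severity_beta

    # latent severity: 0 for HD by construction; group-shifted for MS
    n_ms = cfg.n_rrms + cfg.n_prog
    severity = np.concatenate(
        [
            rng.normal(cfg.effect_size, 1.0, cfg.n_rrms),
            rng.normal(2.0 * cfg.effect_size, 1.0, cfg.n_prog),
        ]
    )
    diagnoses = ["HD"] * cfg.n_hd + ["RRMS"] * cfg.n_rrms + ["progMS"] * cfg.n_prog
    patient_ids = [f"{d}{i + 1:04d}" for i, d in enumerate(diagnoses)]
    sev_by_patient = dict(zip(patient_ids[cfg.n_hd:], severity))

    mu = rng.normal(7.0, 1.0, cfg.n_proteins)  # baseline log-abundance per protein

    n_samples = cfg.n_hd + n_ms
    sev_all = np.concatenate([np.zeros(cfg.n_hd), severity])
    log_abund = (
        mu[None, :]
        + np.outer(sev_all, np.ones(cfg.n_proteins)) * beta[None, :]
        + rng.normal(0.0, cfg.protein_noise_sd, (n_samples, cfg.n_proteins))
    )

    base_date = pd.Timestamp(cfg.start_date)
    dates = [base_date + pd.Timedelta(days=int(d)) for d in rng.integers(0, 365, n_samples)]
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "diagnosis": diagnoses,
            "collection_date": dates,
            "visit_role": "baseline",
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # paired on-therapy samples for the first n_treated progressive patients
    treated = [p for p, d in zip(patient_ids, diagnoses) if d == "progMS"][: cfg.n_treated]
    if cfg.n_treated > 0 and len(treated) < cfg.n_treated:
        treated += [p for p, d in zip(patient_ids, diagnoses) if d == "RRMS"][
            : cfg.n_treated - len(treated)
        ]
    shift = np.zeros(cfg.n_proteins)
    shift[pathway_idx] = directions * cfg.treatment_effect
    therapy_rows, therapy_meta = [], []
    for p in treated:
        i = patient_ids.index(p)
        row = (
            mu
            + sev_all[i] * beta
            + shift
            + rng.normal(0.0, cfg.protein_noise_sd, cfg.n_proteins)
        )
        therapy_rows.append(row)
        therapy_meta.append(
            {
                "patient_id": p,
                "diagnosis": diagnoses[i],
                "collection_date": dates[i] + pd.Timedelta(days=183),
                "visit_role": "therapy",
            }
        )
    if therapy_rows:
        t_ids = [f"T{i + 1:04d}" for i in range(len(therapy_rows))]
        log_abund = np.vstack([log_abund, np.array(therapy_rows)])
        samples = pd.concat(
            [samples, pd.DataFrame(therapy_meta, index=pd.Index(t_ids, name="sample_id"))]
        )

    abundance = pd.DataFrame(
        np.exp(log_abund), index=samples.index, columns=pd.Index(protein_ids, name="protein")
    )
    proteins = pd.DataFrame(
        {"gene": genes}, index=pd.Index(protein_ids, name="protein")
    )
    dataset = ProteomicsDataset(abundance=abundance, samples=samples, proteins=proteins)

    outcomes = pd.DataFrame(
        {
            "brain_damage_severity": 0.8 * severity + rng.normal(0, cfg.outcome_noise_sd, n_ms),
            "combiwise_severity": 1.2 * severity + rng.normal(0, cfg.outcome_noise_sd, n_ms),
            "msdss": 0.5 * severity + rng.normal(0, cfg.outcome_noise_sd, n_ms),
        },
        index=pd.Index(patient_ids[cfg.n_hd:], name="patient_id"),
    )

    pathway_genes = [genes[i] for i in pathway_idx]
    pathway = PathwaySpec.from_directions(
        dict(zip(pathway_genes, directions)), name="pyroptosis", source="knowledge-base"
    )
    truth = {
        "informative_proteins": [protein_ids[i] for i in informative_idx],
        "informative_genes": [genes[i] for i in informative_idx],
        "informative_directions": dict(
            zip((protein_ids[i] for i in informative_idx), info_dirs.tolist())
        ),
        "pathway_proteins": [protein_ids[i] for i in pathway_idx],
        "latent_severity": pd.Series(sev_by_patient, name="latent_severity"),
        "treated_patients": treated,
    }
    return SimulatedProteomics(dataset=dataset, outcomes=outcomes, pathway=pathway, truth=truth)


def generate_trajectories(cfg: SimulationConfig) -> SimulatedTrajectories:
    """Simulate piecewise-linear disability trajectories with visit noise."""
    if cfg.n_visits < 2:
        raise ValueError("trajectory generation needs n_visits >= 2")
    rng = cfg.rng(_TRAJECTORY_STREAM)

    mult = np.asarray(cfg.therapy_slope_multiplier, dtype=float)
    if mult.ndim == 0:
        mult = np.full(cfg.n_patients, float(mult))
    elif mult.shape != (cfg.n_patients,):
        raise ValueError(
            f"therapy_slope_multiplier must be scalar or length {cfg.n_patients}"
        )

    base_date = pd.Timestamp(cfg.start_date)
    interval = float(cfg.visit_interval_days)
    trajectories: list[PatientTrajectory] = []
    truth_rows = []
    for i in range(cfg.n_patients):
        pid = f"PT{i + 1:04d}"
        slope = rng.normal(cfg.baseline_slope_mean, cfg.baseline_slope_sd)
        d0 = rng.normal(cfg.disability_start_mean, cfg.disability_start_sd)
        start = base_date + pd.Timedelta(days=int(rng.integers(0, 120)))

        pre_days = np.arange(cfg.n_visits) * interval
        therapy_start = start + pd.Timedelta(days=float(pre_days[-1] + 30.0))
        post_days = (
            (therapy_start - start).days + np.arange(cfg.n_therapy_visits) * interval
        )
        ts_years = (therapy_start - start).days / DAYS_PER_YEAR

        rows = []
        for day in pre_days:
            t = day / DAYS_PER_YEAR
            value = d0 + slope * t + rng.normal(0, cfg.visit_noise_sd)
            rows.append((start + pd.Timedelta(days=float(day)), value, False))
        for day in post_days:
            t = day / DAYS_PER_YEAR
            value = (
                d0
                + slope * ts_years
                + mult[i] * slope * (t - ts_years)
                + rng.normal(0, cfg.visit_noise_sd)
            )
            rows.append((start + pd.Timedelta(days=float(day)), value, True))

        dates = [r[0] for r in rows]
        lesions = [0]
        for (d_prev, _, _), (d_cur, _, on) in zip(rows, rows[1:]):
            dt_years = (d_cur - d_prev).days / DAYS_PER_YEAR
            rate = cfg.lesion_rate_per_year * (cfg.lesion_therapy_multiplier if on else 1.0)
            lesions.append(int(rng.poisson(rate * dt_years)))

        visits = pd.DataFrame(
            {
                "date": dates,
                "disability": np.clip([r[1] for r in rows], 0.0, 100.0),
                "lesions": lesions,
            }
        )
        trajectories.append(
            PatientTrajectory(patient_id=pid, visits=visits, therapy_start=therapy_start)
        )
        truth_rows.append((pid, float(slope), float(mult[i]), float(d0)))

    truth = pd.DataFrame(
        truth_rows, columns=["patient_id", "baseline_slope", "therapy_multiplier", "intercept"]
    )
    return SimulatedTrajectories(trajectories=trajectories, truth=truth)


def generate_expression_summaries(cfg: SimulationConfig) -> SimulatedExpression:
    """Simulate per-cell-type expression summaries with planted activation."""
    if len(cfg.cell_types) == 0:
        raise ValueError("cell-type list must be non-empty")
    rng = cfg.rng(_EXPRESSION_STREAM)

    n_genes = cfg.n_pathway_genes
    genes = [f"PYG{i + 1:03d}" for i in range(n_genes)]
    directions = _directions(rng, n_genes, cfg.positive_direction_fraction)
    n_out = min(cfg.n_outlier_genes, n_genes)
    outlier_idx = rng.choice(n_genes, size=n_out, replace=False) if n_out else np.array([], int)
    outlier_signs = np.where(np.arange(n_out) % 2 == 0, 1.0, -1.0)

    rows = []
    for group in ("MS", "control"):
        for ct in cfg.cell_types:
            x = rng.uniform(0.05, 0.95, n_genes)
            ly = (
                cfg.expression_intercept
                + cfg.expression_slope * x
                + rng.normal(0, cfg.expression_noise_sd, n_genes)
            )
            if group == "MS":
                offset = float(dict(cfg.activation_offsets).get(ct, 0.0))
                ly = ly + offset * directions
            disp = cfg.outlier_sd_multiplier * cfg.expression_noise_sd
            for j, s in zip(outlier_idx, outlier_signs):
                ly[j] += s * disp
            y = np.maximum(2.0**ly - 1.0, 0.0)
            for g, yy, xx in zip(genes, y, x):
                rows.append((group, ct, g, float(yy), float(xx)))

    summary = pd.DataFrame(
        rows, columns=["group", "cell_type", "gene", "avg_expression", "fraction_expressing"]
    )
    pathway = PathwaySpec.from_directions(
        dict(zip(genes, directions)), name="pyroptosis", source="knowledge-base"
    )
    truth = {
        "outlier_genes": [genes[i] for i in outlier_idx],
        "directions": dict(zip(genes, directions.tolist())),
        "activation_offsets": dict(cfg.activation_offsets),
    }
    return SimulatedExpression(summary=summary, pathway=pathway, truth=truth)


def generate_cell_matrix(
    cfg: SimulationConfig, n_cells: int = 300, mean_count: float = 2.0
):
    """A small cells x genes count matrix with labels and per-nucleus QC stats.

    Exists only to exercise the summarization and QC paths; it is not a
    realistic single-nucleus simulation. Returns
    ``(counts, genes, cell_types, lesion_types, qc_stats)``.
    """
    rng = cfg.rng(_CELLS_STREAM)
    n_genes = cfg.n_pathway_genes
    genes = [f"PYG{i + 1:03d}" for i in range(n_genes)]
    cell_types = rng.choice(list(cfg.cell_types), size=n_cells)
    lesion_types = rng.choice(list(cfg.lesion_types), size=n_cells)
    gene_rate = rng.uniform(0.2, 2.0, n_genes) * mean_count
    counts = rng.poisson(gene_rate[None, :], size=(n_cells, n_genes)).astype(float)
    qc_stats = pd.DataFrame(
        {
            "mito_fraction": rng.uniform(0.0, 0.15, n_cells),
            "umi": rng.integers(1_000, 12_000, n_cells).astype(float),
        },
        index=pd.Index([f"N{i + 1:05d}" for i in range(n_cells)], name="nucleus_id"),
    )
    return counts, genes, list(cell_types), list(lesion_types), qc_stats
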