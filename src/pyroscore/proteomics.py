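"""CSF proteomic pyroptosis activation scoring.

The pipeline works on relative-abundance matrices from multiplexed aptamer
assays (samples x proteins, RFU-like positive values) and proceeds in four
steps:

1. **HD scaling** — every protein is z-scored against the healthy-donor (HD)
   sample distribution, putting all analytes on a common scale.
2. **Global severity** — three per-patient severity outcomes (brain-damage
   severity, CombiWISE-based severity, MS-DSS) are each z-scored across the
   MS cohort and summed into one composite severity scalar.
3. **Protein selection** — pathway proteins whose HD-scaled levels correlate
   (Spearman) with the composite severity at p < alpha are retained, each
   weighted by its correlation coefficient.
4. **Scoring** — a sample's pyroptosis activation score is the weighted sum
   of its HD-scaled levels over the selected proteins.

A companion change analysis contrasts paired baseline/on-therapy samples:
per-protein mean change, a z-score of that change against the all-protein
change distribution (|z| > 2 flags the ~5% extreme tail), an exact one-sample
Wilcoxon signed-rank test of zero change, and Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pathway import PathwaySpec
from .stats import signed_rank_exact_pvalues

__all__ = [
    "ProteomicsDataset",
    "ScoreWeights",
    "ScoreResult",
    "hd_scale",
    "global_severity",
    "select_score_proteins",
    "pyroptosis_score",
    "score_samples",
    "yearly_score_change",
    "change_analysis",
    "group_compare",
]

logger = logging.getLogger(__name__)

DIAGNOSES = ("HD", "RRMS", "progMS")
OUTCOME_COLUMNS = ("brain_damage_severity", "combiwise_severity", "msdss")
DAYS_PER_YEAR = 365.25


@dataclass
class ProteomicsDataset:
    """Samples x proteins abundance matrix with sample and protein metadata.

    ``abundance``: DataFrame, samples in rows (index = sample id), proteins in
    columns (index = protein id). ``samples``: DataFrame indexed by sample id
    with columns patient_id, diagnosis, collection_date, visit_role.
    ``proteins``: DataFrame indexed by protein id with a ``gene`` column.
    """

    abundance: pd.DataFrame
    samples: pd.DataFrame
    proteins: pd.DataFrame

    def __post_init__(self) -> None:
        if self.abundance.columns.duplicated().any():
            dups = self.abundance.columns[self.abundance.columns.duplicated()].unique()
            raise ValueError(f"duplicate protein identifiers: {list(dups)}")
        if self.abundance.index.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("abundances must be non-negative")
        missing = self.abundance.index.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing)[:5]}")
        bad = set(self.samples["diagnosis"]) - set(DIAGNOSES)
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.abundance.index

    def ids_for(self, diagnosis: str) -> list[str]:
        meta = self.samples.loc[self.sample_ids]
        return list(meta.index[meta["diagnosis"] == diagnosis])


@dataclass
class ScoreWeights:
    """Selected score proteins with their severity-correlation weights."""

    table: pd.DataFrame  # index: protein id; columns: gene, rho, pvalue

    def __post_init__(self) -> None:
        if len(self.table) == 0:
            raise ValueError("no proteins selected; cannot build a score")
        if (self.table["rho"].abs() > 1).any():
            raise ValueError("|rho| must not exceed 1")
        self.table = self.table.sort_index()

    @property
    def proteins(self) -> pd.Index:
        return self.table.index

    @property
    def rho(self) -> pd.Series:
        return self.table["rho"]


@dataclass
class ScoreResult:
    """A scalar activation score with the per-protein contributions."""

    sample_id: str
    score: float
    contributions: pd.Series = field(repr=False)


def hd_scale(
    data: ProteomicsDataset | pd.DataFrame,
    hd_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Z-score every protein against its healthy-donor distribution.

    ``scaled = (x - mean_HD) / sd_HD`` per protein, sample SD (ddof=1).
    Proteins whose HD values are constant are excluded with a warning, since
    no HD-referenced scale exists for them.
    """
    if isinstance(data, ProteomicsDataset):
        matrix = data.abundance
        if hd_ids is None:
            hd_ids = data.ids_for("HD")
    else:
        matrix = data
        if hd_ids is None:
            raise ValueError("hd_ids is required when passing a bare matrix")
    hd_ids = list(hd_ids)
    if len(hd_ids) < 2:
        raise ValueError(f"HD scaling needs >=2 healthy-donor samples, got {len(hd_ids)}")
    absent = set(hd_ids) - set(matrix.index)
    if absent:
        raise ValueError(f"HD sample ids not in matrix: {sorted(absent)}")

    hd = matrix.loc[hd_ids]
    mean = hd.mean(axis=0)
    sd = hd.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        flagged = list(sd.index[degenerate])
        logger.warning(
            "excluding %d protein(s) with zero HD variance: %s",
            len(flagged), flagged[:10],
        )
        mean, sd = mean[~degenerate], sd[~degenerate]
    return (matrix.loc[:, sd.index] - mean) / sd


def global_severity(
    outcomes: pd.DataFrame,
    cohort: list[str] | None = None,
) -> pd.Series:
    """Composite severity: sum of the three z-scored severity outcomes.

    ``outcomes`` is indexed by patient id with the columns
    ``brain_damage_severity``, ``combiwise_severity`` and ``msdss``. Each is
    z-scored across the cohort (ddof=1) and summed, so the composite has mean
    zero over the cohort. An outcome that is constant across the cohort makes
    the scaling undefined and raises.
    """
    if cohort is not None:
        outcomes = outcomes.loc[list(cohort)]
    missing_cols = [c for c in OUTCOME_COLUMNS if c not in outcomes.columns]
    if missing_cols:
        raise ValueError(f"missing severity outcome columns: {missing_cols}")
    sub = outcomes[list(OUTCOME_COLUMNS)]
    if sub.isna().any().any():
        bad = list(sub.index[sub.isna().any(axis=1)])
        raise ValueError(f"patients with missing severity outcomes: {bad[:5]}")
    sd = sub.std(axis=0, ddof=1)
    constant = [c for c in OUTCOME_COLUMNS if sd[c] == 0]
    if constant:
        raise ValueError(f"severity outcome(s) constant across cohort: {constant}")
    z = (sub - sub.mean(axis=0)) / sd
    return z.sum(axis=1).rename("global_severity")


def select_score_proteins(
    scaled: pd.DataFrame,
    severity: pd.Series,
    pathway: PathwaySpec,
    gene_map: pd.Series | None = None,
    alpha: float = 0.05,
    adjust: bool = False,
) -> ScoreWeights:
    """Select pathway proteins whose scaled level tracks disease severity.

    Spearman correlation of each pathway protein's HD-scaled level with the
    composite severity, across the MS samples in ``severity``'s index.
    Proteins with (optionally BH-adjusted) p < alpha are retained with their
    correlation coefficient as score weight.

    ``gene_map`` maps protein id -> gene symbol (defaults to the identity,
    i.e. protein columns already named by gene symbol).
    """
    if gene_map is None:
        gene_map = pd.Series(scaled.columns, index=scaled.columns)
    pathway_genes = {g.upper() for g in pathway.genes}
    candidates = [p for p in scaled.columns if str(gene_map.get(p, "")).upper() in pathway_genes]
    if not candidates:
        raise ValueError("pathway not represented on panel")
    if len(severity) < 10:
        raise ValueError(f"protein selection needs >=10 MS samples, got {len(severity)}")

    sub = scaled.loc[severity.index, candidates]
    sev = severity.to_numpy(dtype=float)
    rows = []
    for pid in candidates:
        rho, p = sps.spearmanr(sub[pid].to_numpy(dtype=float), sev)
        rows.append((pid, str(gene_map.get(pid, pid)), rho, p))
    table = pd.DataFrame(rows, columns=["protein", "gene", "rho", "pvalue"]).set_index("protein")
    if adjust:
        table["pvalue_adj"] = multipletests(table["pvalue"], method="fdr_bh")[1]
        keep = table["pvalue_adj"] < alpha
    else:
        keep = table["pvalue"] < alpha
    selected = table.loc[keep].sort_index()
    if len(selected) == 0:
        raise ValueError(f"no pathway protein correlated with severity at alpha={alpha}")
    return ScoreWeights(selected)


def pyroptosis_score(scaled_sample: pd.Series, weights: ScoreWeights) -> ScoreResult:
    """Score one sample: sum of HD-scaled levels x correlation weights."""
    missing = weights.proteins.difference(scaled_sample.index)
    if len(missing):
        raise ValueError(f"sample is missing score proteins: {list(missing)}")
    levels = scaled_sample.loc[weights.proteins].astype(float)
    if levels.isna().any():
        raise ValueError(
            f"sample has missing values for score proteins: "
            f"{list(levels.index[levels.isna()])}"
        )
    contributions = levels * weights.rho
    return ScoreResult(
        sample_id=str(scaled_sample.name),
        score=float(contributions.sum()),
        contributions=contributions,
    )


def score_samples(scaled: pd.DataFrame, weights: ScoreWeights) -> pd.DataFrame:
    """Score every row of a scaled matrix; returns score + contributions."""
    results = [pyroptosis_score(scaled.loc[sid], weights) for sid in scaled.index]
    out = pd.DataFrame(
        {"score": [r.score for r in results]},
        index=pd.Index(scaled.index, name="sample_id"),
    )
    contrib = pd.DataFrame([r.contributions for r in results], index=out.index)
    return pd.concat([out, contrib.add_prefix("contrib_")], axis=1)


def yearly_score_change(
    baseline_score: float,
    baseline_date,
    followup_score: float,
    followup_date,
) -> float:
    """Annualized change in activation score between two dated samples."""
    t0, t1 = pd.Timestamp(baseline_date), pd.Timestamp(followup_date)
    years = (t1 - t0).days / DAYS_PER_YEAR
    if years <= 0:
        raise ValueError(f"follow-up must postdate baseline (interval {years:.3f} yr)")
    return (followup_score - baseline_score) / years


def change_analysis(
    baseline: pd.DataFrame,
    therapy: pd.DataFrame,
) -> pd.DataFrame:
    """Paired baseline/on-therapy change table over all measured proteins.

    Both inputs are HD-scaled matrices indexed by patient id with identical
    columns. Per protein the table reports the mean change, a z-score of that
    mean change against the distribution of mean changes over *all* proteins
    (|z| > 2 marks the extreme ~5% tail used for enrichment export), the
    two-sided exact one-sample Wilcoxon signed-rank p for zero change, and
    its Benjamini-Hochberg adjustment. Proteins whose change is identically
    zero get p = 1 and ``wilcoxon_defined = False``.
    """
    if not baseline.index.equals(therapy.index):
        therapy = therapy.loc[baseline.index]
    if list(baseline.columns) != list(therapy.columns):
        raise ValueError("baseline and therapy matrices must share protein columns")
    n_pairs = len(baseline)
    if n_pairs < 3:
        raise ValueError(f"change analysis needs >=3 patient pairs, got {n_pairs}")

    changes = therapy.to_numpy(dtype=float) - baseline.to_numpy(dtype=float)  # pairs x proteins
    mean_change = changes.mean(axis=0)
    mu, sd = mean_change.mean(), mean_change.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(mean_change)
    else:
        z = (mean_change - mu) / sd

    pvals = signed_rank_exact_pvalues(changes.T)
    defined = ~(changes == 0).all(axis=0)
    pvals[~defined] = 1.0
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mean_change": mean_change,
            "z": z,
            "extreme": np.abs(z) > 2,
            "wilcoxon_p": pvals,
            "wilcoxon_p_adj": p_adj,
            "wilcoxon_defined": defined,
        },
        index=pd.Index(baseline.columns, name="protein"),
    )


def extreme_gene_list(change_table: pd.DataFrame, gene_map: pd.Series | None = None) -> list[str]:
    """Genes behind the |z| > 2 extreme changes, for external enrichment."""
    ids = change_table.index[change_table["extreme"]]
    if gene_map is None:
        return sorted(set(map(str, ids)))
    return sorted({str(gene_map.get(i, i)) for i in ids})


def group_compare(
    scores: pd.Series,
    diagnosis: pd.Series,
    severity_outcomes: pd.DataFrame | None = None,
    patient_of_sample: pd.Series | None = None,
) -> dict:
    """Group contrasts and severity correlations for computed scores.

    Two-sided Wilcoxon rank-sum (Mann-Whitney) p-values for MS vs HD and
    progressive vs relapsing-remitting MS, plus Spearman correlations of the
    score with brain-damage severity and MS-DSS when outcomes are supplied.
    """
    diagnosis = diagnosis.loc[scores.index]
    groups = {d: scores[diagnosis == d] for d in DIAGNOSES}
    out: dict[str, dict] = {}

    def _ranksum(a: pd.Series, b: pd.Series, label: str) -> None:
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"group comparison {label} needs >=2 samples per group")
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        out[label] = {
            "statistic": float(stat),
            "pvalue": float(p),
            "median_a": float(a.median()),
            "median_b": float(b.median()),
        }

    ms = pd.concat([groups["RRMS"], groups["progMS"]])
    _ranksum(ms, groups["HD"], "ms_vs_hd")
    _ranksum(groups["progMS"], groups["RRMS"], "prog_vs_rrms")

    if severity_outcomes is not None:
        if patient_of_sample is None:
            raise ValueError("patient_of_sample is required for severity correlations")
        ms_ids = ms.index
        patients = patient_of_sample.loc[ms_ids]
        for col, label in (
            ("brain_damage_severity", "score_vs_brain_damage"),
            ("msdss", "score_vs_msdss"),
        ):
            sev = severity_outcomes.loc[patients, col].to_numpy(dtype=float)
            rho, p = sps.spearmanr(ms.loc[ms_ids].to_numpy(dtype=float), sev)
            out[label] = {"rho": float(rho), "pvalue": float(p)}
    return out
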