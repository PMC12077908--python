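"""Transcriptional pyroptosis pathway activation scoring (tPPAS).

Works from single-nucleus expression data summarized per cell type. For each
(group, cell type, gene) the inputs are x = fraction of cells expressing the
gene and y = AGE, the average gene expression. A linear model
``log2(1 + y) ~ x`` fitted over the pathway genes of one cell type identifies
genes whose expression is out of keeping with their detection rate; genes
with residuals beyond +/-2 residual SD are excluded (single pass, no refit).
The score for a cell type is then the directionality-weighted sum

    tPPAS = sum over retained pathway genes g of d(g) * AGE(g)

with d(g) in {+1, -1} from :mod:`pyroscore.pathway`. Nucleus-level QC
(mitochondrial fraction and UMI thresholds) is applied upstream of
summarization.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .pathway import PathwaySpec

__all__ = [
    "NucleusQCRules",
    "QCResult",
    "OutlierResult",
    "filter_nuclei",
    "summarize_expression",
    "exclude_outliers",
    "tppas",
    "score_cell_types",
    "percent_increase",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = ("cell_type", "gene", "avg_expression", "fraction_expressing")


@dataclass(frozen=True)
class NucleusQCRules:
    """Exclusion thresholds for single-nucleus quality control (strict >)."""

    max_mito_fraction: float = 0.10
    max_umi: float = 10_000

    def __post_init__(self) -> None:
        if self.max_mito_fraction <= 0 or self.max_umi <= 0:
            raise ValueError("QC thresholds must be positive")


@dataclass
class QCResult:
    kept: pd.Index
    excluded: pd.DataFrame  # index: nucleus id; column: reason
    unevaluable: pd.Index

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def filter_nuclei(
    stats: pd.DataFrame,
    rules: NucleusQCRules = NucleusQCRules(),
) -> QCResult:
    """Partition nuclei into kept / excluded / unevaluable.

    ``stats`` is indexed by nucleus id with columns ``mito_fraction`` and
    ``umi``. A nucleus is excluded iff mito_fraction > threshold (strict) or
    umi > threshold (strict); a nucleus missing either statistic is reported
    unevaluable, never silently kept.
    """
    for col in ("mito_fraction", "umi"):
        if col not in stats.columns:
            raise ValueError(f"QC stats must contain a {col!r} column")
    missing = stats[["mito_fraction", "umi"]].isna().any(axis=1)
    unevaluable = stats.index[missing]
    evaluable = stats.loc[~missing]

    mito_bad = evaluable["mito_fraction"] > rules.max_mito_fraction
    umi_bad = evaluable["umi"] > rules.max_umi
    reason = pd.Series("", index=evaluable.index, dtype=object)
    reason[mito_bad] = "mito_fraction > " + format(rules.max_mito_fraction, "g")
    reason[umi_bad & ~mito_bad] = "umi > " + format(rules.max_umi, "g")
    reason[umi_bad & mito_bad] += "; umi > " + format(rules.max_umi, "g")
    bad = mito_bad | umi_bad
    excluded = pd.DataFrame({"reason": reason[bad]})
    kept = evaluable.index[~bad]
    logger.info(
        "nucleus QC: %d kept, %d excluded, %d unevaluable",
        len(kept), len(excluded), len(unevaluable),
    )
    return QCResult(kept=kept, excluded=excluded, unevaluable=unevaluable)


def summarize_expression(
    matrix,
    genes: list[str],
    cell_types: pd.Series | list[str],
) -> pd.DataFrame:
    """Per (cell type, gene) average expression and fraction expressing.

    ``matrix`` is cells x genes (dense array or scipy sparse), non-negative.
    AGE is the arithmetic mean of expression over the cells of a type; the
    fraction expressing is the share of those cells with expression > 0.
    Cell types with zero cells are omitted with a warning.
    """
    X = matrix.tocsr() if sp.issparse(matrix) else np.asarray(matrix, dtype=float)
    n_cells = X.shape[0]
    labels = pd.Series(list(cell_types))
    if len(labels) != n_cells:
        raise ValueError(
            f"{n_cells} cells in matrix but {len(labels)} cell-type labels"
        )
    if len(genes) != X.shape[1]:
        raise ValueError(f"{X.shape[1]} gene columns but {len(genes)} gene labels")
    if (X.data if sp.issparse(X) else X).min(initial=0) < 0:
        raise ValueError("expression values must be non-negative")

    rows = []
    for ct in pd.unique(labels):
        idx = np.flatnonzero((labels == ct).to_numpy())
        if idx.size == 0:  # only reachable with categorical labels
            warnings.warn(f"cell type {ct!r} has no cells; omitted", stacklevel=2)
            continue
        block = X[idx]
        if sp.issparse(block):
            age = np.asarray(block.mean(axis=0)).ravel()
            frac = np.asarray((block > 0).sum(axis=0)).ravel() / idx.size
        else:
            age = block.mean(axis=0)
            frac = (block > 0).mean(axis=0)
        for g, a, f in zip(genes, age, frac):
            rows.append((ct, g, float(a), float(f)))
    return pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))


@dataclass
class OutlierResult:
    retained: pd.DataFrame
    excluded_genes: list[str]
    residuals: pd.Series = field(repr=False)
    residual_sd: float = float("nan")
    slope: float = float("nan")
    intercept: float = float("nan")
    degenerate: bool = False


def exclude_outliers(summary: pd.DataFrame) -> OutlierResult:
    """Residual-based outlier exclusion for one (group, cell type) block.

    Fits ``log2(1 + avg_expression) ~ fraction_expressing`` by OLS over the
    pathway genes of the block and excludes genes whose residual exceeds
    +/-2 residual SD (strict; sample SD, ddof=1). The fit is a single pass —
    it is not re-run after exclusion. If every gene has the same detection
    fraction the regression is degenerate; the exclusion then falls back to
    outliers of log2(1 + y) alone and the result is flagged.
    """
    if len(summary) < 3:
        raise ValueError(f"outlier exclusion needs >=3 genes, got {len(summary)}")
    x = summary["fraction_expressing"].to_numpy(dtype=float)
    y = np.log2(1.0 + summary["avg_expression"].to_numpy(dtype=float))
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("summary rows with undefined (x, y) cannot be screened")

    degenerate = np.ptp(x) == 0
    if degenerate:
        slope, intercept = 0.0, float(y.mean())
        logger.warning(
            "all detection fractions identical; falling back to outliers of "
            "log2(1+y) alone"
        )
    else:
        slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    sd = float(resid.std(ddof=1))
    # an essentially perfect fit has no outliers (guards float round-off)
    effectively_zero = sd <= 1e-12 * max(1.0, float(np.abs(y).max()))
    out_mask = (
        np.abs(resid) > 2 * sd
        if not effectively_zero
        else np.zeros(len(resid), dtype=bool)
    )
    residuals = pd.Series(resid, index=summary["gene"].to_numpy(), name="residual")
    return OutlierResult(
        retained=summary.loc[~out_mask].reset_index(drop=True),
        excluded_genes=list(summary.loc[out_mask, "gene"]),
        residuals=residuals,
        residual_sd=sd,
        slope=float(slope),
        intercept=float(intercept),
        degenerate=bool(degenerate),
    )


def tppas(
    summary: pd.DataFrame,
    pathway: PathwaySpec,
    weight_by_fraction: bool = False,
) -> tuple[float, pd.Series]:
    """Signed pathway activation score for one (group, cell type) block.

    ``score = sum over genes g of d(g) * AGE(g)`` over the pathway genes in
    ``summary`` (outlier exclusion is assumed to have been applied already).
    ``weight_by_fraction`` optionally multiplies each term by the fraction of
    cells expressing the gene; the unweighted signed sum is the default.
    Returns (score, per-gene contributions). Gene matching is
    case-insensitive; zero retained pathway genes is an error.
    """
    directions = {g.upper(): pathway.direction_of(g) for g in pathway.genes}
    sub = summary[summary["gene"].str.upper().isin(directions)]
    if len(sub) == 0:
        raise ValueError("no retained pathway genes to score")
    d = sub["gene"].str.upper().map(directions).to_numpy(dtype=float)
    contrib = d * sub["avg_expression"].to_numpy(dtype=float)
    if weight_by_fraction:
        contrib = contrib * sub["fraction_expressing"].to_numpy(dtype=float)
    contributions = pd.Series(contrib, index=sub["gene"].to_numpy(), name="contribution")
    return float(contributions.sum()), contributions


def score_cell_types(
    summary: pd.DataFrame,
    pathway: PathwaySpec,
    apply_exclusion: bool = True,
    weight_by_fraction: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize -> exclude -> score over every (group, cell type) block.

    ``summary`` is a long table with columns group, cell_type, gene,
    avg_expression, fraction_expressing (the ``group`` column is optional;
    a single unnamed group is assumed when absent). Outlier exclusion is run
    independently per block. Returns (scores, exclusion log).
    """
    df = summary.copy()
    if "group" not in df.columns:
        df["group"] = "all"
    score_rows, excl_rows = [], []
    for (group, ct), block in df.groupby(["group", "cell_type"], sort=True):
        block = block[block["gene"].str.upper().isin({g.upper() for g in pathway.genes})]
        if len(block) == 0:
            continue
        if apply_exclusion and len(block) >= 3:
            res = exclude_outliers(block)
            retained = res.retained
            for g in res.excluded_genes:
                excl_rows.append((group, ct, g, float(res.residuals[g]), res.residual_sd))
        else:
            retained = block
        score, contributions = tppas(retained, pathway, weight_by_fraction)
        score_rows.append((group, ct, score, len(contributions)))
    if not score_rows:
        raise ValueError(
            f"no (group, cell type) block shares genes with pathway {pathway.name!r}"
        )
    scores = pd.DataFrame(
        score_rows, columns=["group", "cell_type", "tppas", "n_genes"]
    )
    exclusions = pd.DataFrame(
        excl_rows, columns=["group", "cell_type", "gene", "residual", "residual_sd"]
    )
    return scores, exclusions


def percent_increase(score_ms: float, score_ctrl: float) -> float:
    """Percent increase of the MS score over the control score.

    ``100 * (score_ms - score_ctrl) / score_ctrl``; reports round this to the
    nearest percent. Undefined for a zero control score.
    """
    if score_ctrl == 0:
        raise ValueError("percent increase undefined for a zero control score")
    return 100.0 * (score_ms - score_ctrl) / score_ctrl
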