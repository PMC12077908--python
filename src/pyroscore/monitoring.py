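"""Slope-based clinical safety monitoring of disability progression.

Patients in a platform trial of progressive MS are followed on a continuous
0-100 disability scale (CombiWISE). Eligibility requires measurable
progression at baseline: at least ``min_visits`` pre-therapy visits, each
at least ``min_gap_months`` calendar months apart, spanning at least
``min_span_months``, with a fitted baseline progression slope of at least
``eligibility_min_slope`` units/year.

Individual safety stopping: the study drug is stopped when the on-treatment
yearly progression slope *exceeds* ``slope_multiplier_threshold`` (5x) times
the baseline slope, or when the annualized accumulation of new/enlarging
lesions *exceeds* ``lesion_multiplier_threshold`` (3x) times the baseline
average. Both inequalities are strict. A treatment arm is stopped for
toxicity when ``arm_stop_count`` (3) treated patients trigger individual
criteria; arms are compared with a Yates-corrected chi-square on the 2x2
trigger table and a two-sided rank-sum test on therapy-induced slope changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import yates_chi2_2x2

__all__ = [
    "MonitoringRules",
    "PatientTrajectory",
    "SlopeEstimate",
    "TriggerDecision",
    "EligibilityDecision",
    "ArmStatus",
    "fit_visit_slope",
    "lesion_rate",
    "check_eligibility",
    "evaluate_individual_trigger",
    "evaluate_patient",
    "evaluate_arm",
    "compare_arms_chi2",
    "compare_slope_changes",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class MonitoringRules:
    slope_multiplier_threshold: float = 5.0
    lesion_multiplier_threshold: float = 3.0
    eligibility_min_slope: float = 0.5  # disability units / year
    min_visits: int = 4
    min_gap_months: int = 6
    min_span_months: int = 18
    arm_stop_count: int = 3
    gap_tolerance_days: int = 7  # scheduling jitter allowed on calendar gaps
    min_therapy_visits: int = 2

    def __post_init__(self) -> None:
        for name in (
            "slope_multiplier_threshold", "lesion_multiplier_threshold",
            "eligibility_min_slope", "min_visits", "min_gap_months",
            "min_span_months", "arm_stop_count",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PatientTrajectory:
    """Dated disability/lesion visit records with an optional therapy anchor.

    ``visits``: DataFrame with columns date (datetime-like), disability
    (0-100), lesions (non-negative int), sorted strictly by date.
    """

    patient_id: str
    visits: pd.DataFrame
    therapy_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        v = self.visits.copy()
        v["date"] = pd.to_datetime(v["date"])
        if not v["date"].is_monotonic_increasing or v["date"].duplicated().any():
            raise ValueError(f"{self.patient_id}: visit dates must be strictly increasing")
        dis = v["disability"].to_numpy(dtype=float)
        if ((dis < 0) | (dis > 100)).any():
            raise ValueError(f"{self.patient_id}: disability must lie in [0, 100]")
        if (v["lesions"].to_numpy() < 0).any():
            raise ValueError(f"{self.patient_id}: lesion counts must be >= 0")
        self.visits = v.reset_index(drop=True)
        if self.therapy_start is not None:
            self.therapy_start = pd.Timestamp(self.therapy_start)

    @property
    def pre_therapy(self) -> pd.DataFrame:
        if self.therapy_start is None:
            return self.visits
        return self.visits[self.visits["date"] < self.therapy_start]

    @property
    def on_therapy(self) -> pd.DataFrame:
        if self.therapy_start is None:
            return self.visits.iloc[0:0]
        return self.visits[self.visits["date"] >= self.therapy_start]


@dataclass
class SlopeEstimate:
    slope: float  # disability units / year
    intercept: float
    n_visits: int
    span_years: float
    residual_sd: float


@dataclass
class EligibilityDecision:
    eligible: bool
    reasons: list[str] = field(default_factory=list)
    baseline: SlopeEstimate | None = None


@dataclass
class TriggerDecision:
    patient_id: str
    triggered: bool
    slope_criterion: bool
    lesion_criterion: bool
    slope_ratio: float
    lesion_ratio: float
    baseline_slope: float
    therapy_slope: float
    baseline_lesion_rate: float
    therapy_lesion_rate: float


@dataclass
class ArmStatus:
    stopped: bool
    n_triggered: int
    n_total: int

    @property
    def fraction_triggered(self) -> float:
        return self.n_triggered / self.n_total


def fit_visit_slope(visits: pd.DataFrame) -> SlopeEstimate:
    """OLS slope of disability on time (years from the first visit)."""
    if len(visits) < 2:
        raise ValueError(f"slope fit needs >=2 visits, got {len(visits)}")
    dates = pd.to_datetime(visits["date"])
    t = ((dates - dates.iloc[0]) / pd.Timedelta(days=1)).to_numpy(dtype=float) / DAYS_PER_YEAR
    y = visits["disability"].to_numpy(dtype=float)
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("zero time span between first and last visit")
    res = sps.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    ddof = min(2, len(y) - 1)
    residual_sd = float(np.sqrt((resid**2).sum() / max(len(y) - ddof, 1)))
    return SlopeEstimate(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n_visits=len(visits),
        span_years=span,
        residual_sd=residual_sd,
    )


def lesion_rate(visits: pd.DataFrame) -> float:
    """Annualized new/enlarging lesion accumulation over a visit window.

    Lesion counts recorded at each visit after the first (each covering the
    interval since the previous visit) are summed and divided by the window
    span in years. The count at the window's first visit belongs to the
    preceding interval and is not attributed to this window.
    """
    if len(visits) < 2:
        raise ValueError("lesion rate needs >=2 visits to define a window")
    dates = pd.to_datetime(visits["date"])
    span_years = (dates.iloc[-1] - dates.iloc[0]) / pd.Timedelta(days=1) / DAYS_PER_YEAR
    if span_years <= 0:
        raise ValueError("zero time span between first and last visit")
    total = float(visits["lesions"].iloc[1:].sum())
    return total / span_years


def _months_gap_ok(d0: pd.Timestamp, d1: pd.Timestamp, months: int, tol_days: int) -> bool:
    return d1 >= d0 + pd.DateOffset(months=months) - pd.Timedelta(days=tol_days)


def check_eligibility(
    traj: PatientTrajectory,
    rules: MonitoringRules = MonitoringRules(),
) -> EligibilityDecision:
    """Apply the pre-therapy eligibility screen; always returns a decision.

    Calendar-month gap and span checks allow ``gap_tolerance_days`` of
    scheduling jitter.
    """
    pre = traj.pre_therapy
    reasons: list[str] = []
    if len(pre) < rules.min_visits:
        reasons.append(
            f"fewer than {rules.min_visits} pre-therapy visits ({len(pre)})"
        )
    dates = pd.to_datetime(pre["date"]).tolist()
    for d0, d1 in zip(dates, dates[1:]):
        if not _months_gap_ok(d0, d1, rules.min_gap_months, rules.gap_tolerance_days):
            reasons.append(f"visit gap < {rules.min_gap_months} months")
            break
    if len(dates) >= 2 and not _months_gap_ok(
        dates[0], dates[-1], rules.min_span_months, rules.gap_tolerance_days
    ):
        reasons.append(f"visit span < {rules.min_span_months} months")

    baseline = None
    if len(pre) >= 2:
        baseline = fit_visit_slope(pre)
        if baseline.slope < rules.eligibility_min_slope:
            reasons.append(
                f"baseline slope below {rules.eligibility_min_slope} "
                f"({baseline.slope:.3g} units/yr)"
            )
    else:
        reasons.append("too few visits to fit a baseline slope")
    return EligibilityDecision(eligible=not reasons, reasons=reasons, baseline=baseline)


def evaluate_individual_trigger(
    baseline: SlopeEstimate,
    therapy: SlopeEstimate,
    baseline_lesion_rate: float,
    therapy_lesion_rate: float,
    rules: MonitoringRules = MonitoringRules(),
    patient_id: str = "",
) -> TriggerDecision:
    """Individual safety stop: therapy slope > 5x baseline, strict, or
    annualized therapy lesion rate > 3x baseline average, strict."""
    if baseline.slope <= 0:
        raise ValueError(
            "trigger criterion undefined for non-positive baseline slope; "
            "eligibility should have excluded this patient"
        )
    if baseline_lesion_rate < 0 or therapy_lesion_rate < 0:
        raise ValueError("lesion rates must be non-negative")
    slope_ratio = therapy.slope / baseline.slope
    slope_hit = therapy.slope > rules.slope_multiplier_threshold * baseline.slope
    lesion_ratio = (
        therapy_lesion_rate / baseline_lesion_rate
        if baseline_lesion_rate > 0
        else (np.inf if therapy_lesion_rate > 0 else 0.0)
    )
    lesion_hit = therapy_lesion_rate > rules.lesion_multiplier_threshold * baseline_lesion_rate
    return TriggerDecision(
        patient_id=patient_id,
        triggered=bool(slope_hit or lesion_hit),
        slope_criterion=bool(slope_hit),
        lesion_criterion=bool(lesion_hit),
        slope_ratio=float(slope_ratio),
        lesion_ratio=float(lesion_ratio),
        baseline_slope=baseline.slope,
        therapy_slope=therapy.slope,
        baseline_lesion_rate=float(baseline_lesion_rate),
        therapy_lesion_rate=float(therapy_lesion_rate),
    )


def evaluate_patient(
    traj: PatientTrajectory,
    rules: MonitoringRules = MonitoringRules(),
) -> TriggerDecision | None:
    """Full per-patient path: split at therapy start, fit both slopes and
    lesion rates, and apply the individual stopping criteria.

    Returns ``None`` when there are too few on-therapy visits to estimate a
    therapy slope.
    """
    if traj.therapy_start is None:
        raise ValueError(f"{traj.patient_id}: no therapy start recorded")
    pre, post = traj.pre_therapy, traj.on_therapy
    if len(post) < max(rules.min_therapy_visits, 2):
        return None
    baseline = fit_visit_slope(pre)
    therapy = fit_visit_slope(post)
    return evaluate_individual_trigger(
        baseline,
        therapy,
        baseline_lesion_rate=lesion_rate(pre),
        therapy_lesion_rate=lesion_rate(post),
        rules=rules,
        patient_id=traj.patient_id,
    )


def evaluate_arm(
    decisions: list[TriggerDecision],
    rules: MonitoringRules = MonitoringRules(),
) -> ArmStatus:
    """Arm-level stop: >= ``arm_stop_count`` individual triggers."""
    if not decisions:
        raise ValueError("arm evaluation needs >=1 individual decision")
    n_trig = sum(d.triggered for d in decisions)
    return ArmStatus(
        stopped=n_trig >= rules.arm_stop_count,
        n_triggered=n_trig,
        n_total=len(decisions),
    )


@dataclass
class Chi2Result:
    statistic: float
    pvalue: float
    statistic_uncorrected: float
    pvalue_uncorrected: float
    table: np.ndarray


def compare_arms_chi2(
    a_triggered: int,
    a_total: int,
    b_triggered: int,
    b_total: int,
) -> Chi2Result:
    """Yates-corrected Pearson chi-square (df=1, two-sided) comparing trigger
    incidence between two arms. The uncorrected statistic is reported too."""
    if not (0 <= a_triggered <= a_total and 0 <= b_triggered <= b_total):
        raise ValueError("need totals >= counts >= 0")
    if a_total == 0 or b_total == 0:
        raise ValueError("both arms must contain patients")
    table = np.array(
        [
            [a_triggered, a_total - a_triggered],
            [b_triggered, b_total - b_triggered],
        ],
        dtype=float,
    )
    chi2_y, p_y, chi2_r, p_r = yates_chi2_2x2(table)
    return Chi2Result(chi2_y, p_y, chi2_r, p_r, table)


def compare_slope_changes(
    deltas_arm_a: np.ndarray,
    deltas_arm_b: np.ndarray,
) -> tuple[float, float]:
    """Two-sided rank-sum test on therapy-induced slope changes per arm.

    ``deltas`` are per-patient (therapy slope - baseline slope). Exact null
    distribution when the combined sample size is <= 20 and untied, the
    tie-corrected normal approximation otherwise. Returns (statistic, p).
    """
    a = np.asarray(deltas_arm_a, dtype=float)
    b = np.asarray(deltas_arm_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both arms must be non-empty")
    combined = np.concatenate([a, b])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    stat, p = sps.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(stat), float(p)
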