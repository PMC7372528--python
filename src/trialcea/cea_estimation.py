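"""Incremental cost-effectiveness estimation.

Point estimates follow the within-trial convention: mean per-patient costs by
arm (unadjusted), per-patient QALYs adjusted for baseline utility by ordinary
least squares with arm indicators (TAU as reference), and the incremental
cost-effectiveness ratio ICER = delta_C / delta_E per intervention arm.  Net
monetary benefit NMB(lambda) = lambda*delta_E - delta_C evaluates the ICER
against a willingness-to-pay threshold.  Crude relative risks of
benzodiazepine discontinuation at 12 months are provided with log-normal
confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costing import UnitCostTable, WorkshopAllocation, cost_patient
from .trial_data import ARMS, TrialDataset
from .utility_qaly import MappingCoefficients, qaly_table

__all__ = [
    "AdjustmentModel",
    "CEResult",
    "IcerResult",
    "RelativeRisk",
    "SingularDesignError",
    "build_analysis_table",
    "fit_adjustment",
    "icer",
    "net_monetary_benefit",
    "discontinuation_relative_risk",
    "discontinuation_proportions",
    "estimate_ce",
]

INTERVENTION_ARMS = ("SIW", "SIF")


class SingularDesignError(ValueError):
    """The regression design matrix is rank-deficient."""


@dataclass
class AdjustmentModel:
    """OLS of QALY on baseline utility plus arm indicators (TAU reference).

    The arm coefficients are the baseline-adjusted incremental QALYs of SIW
    and SIF versus TAU.
    """

    params: dict[str, float]
    bse: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    pvalues: dict[str, float]
    r_squared: float
    n: int
    cluster_robust: bool = False
    sm_result: object = field(default=None, repr=False)

    @property
    def incremental_qalys(self) -> dict[str, float]:
        return {arm: self.params[arm] for arm in INTERVENTION_ARMS if arm in self.params}

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for term in self.params:
            lo, hi = self.conf_int[term]
            rows.append(
                {
                    "term": term,
                    "coefficient": self.params[term],
                    "std_err": self.bse[term],
                    "p_value": self.pvalues[term],
                    "ci_low": lo,
                    "ci_high": hi,
                }
            )
        return pd.DataFrame(rows)


def _design_matrix(baseline_utility, arm) -> tuple[np.ndarray, list[str]]:
    baseline = np.asarray(baseline_utility, dtype=float)
    arm = np.asarray(arm, dtype=object)
    cols = [np.ones_like(baseline), baseline]
    names = ["Constant", "Baseline utility"]
    for a in INTERVENTION_ARMS:
        cols.append((arm == a).astype(float))
        names.append(a)
    return np.column_stack(cols), names


def fit_adjustment(
    qalys,
    baseline_utility,
    arm,
    cluster=None,
    cluster_robust: bool = False,
) -> AdjustmentModel:
    """Fit the baseline-adjusted QALY regression on complete cases.

    Parameters
    ----------
    qalys, baseline_utility, arm:
        Per-patient arrays; rows with a missing QALY or baseline utility are
        dropped (complete-case analysis).
    cluster, cluster_robust:
        Optionally compute GP-cluster-robust standard errors.  Plain OLS
        standard errors are the default.

    Raises
    ------
    SingularDesignError
        When the design is rank-deficient, naming the collinear column(s).
    """
    df = pd.DataFrame(
        {
            "qaly": np.asarray(qalys, dtype=float),
            "baseline": np.asarray(baseline_utility, dtype=float),
            "arm": np.asarray(arm, dtype=object),
        }
    )
    if cluster is not None:
        df["cluster"] = np.asarray(cluster, dtype=object)
    df = df.dropna(subset=["qaly", "baseline"])
    arms_present = set(df["arm"])
    if not arms_present.issuperset(ARMS):
        raise ValueError(
            f"fit_adjustment requires all three arms; present: {sorted(arms_present)}"
        )
    X, names = _design_matrix(df["baseline"], df["arm"])
    if len(df) <= X.shape[1]:
        raise ValueError(f"n={len(df)} too small for {X.shape[1]} coefficients")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank beyond the ones before them
        collinear = []
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) == np.linalg.matrix_rank(X[:, :j]):
                collinear.append(names[j])
        raise SingularDesignError(
            f"design matrix is rank-deficient; collinear column(s): {collinear}"
        )
    model = sm.OLS(df["qaly"].to_numpy(), X)
    if cluster_robust:
        if cluster is None:
            raise ValueError("cluster ids required for cluster-robust errors")
        result = model.fit(cov_type="cluster", cov_kwds={"groups": df["cluster"]})
    else:
        result = model.fit()
    ci = result.conf_int()
    return AdjustmentModel(
        params={n: float(v) for n, v in zip(names, result.params)},
        bse={n: float(v) for n, v in zip(names, result.bse)},
        conf_int={n: (float(lo), float(hi)) for n, (lo, hi) in zip(names, ci)},
        pvalues={n: float(v) for n, v in zip(names, result.pvalues)},
        r_squared=float(result.rsquared),
        n=int(result.nobs),
        cluster_robust=cluster_robust,
        sm_result=result,
    )


@dataclass
class IcerResult:
    """ICER with the cost-effectiveness-plane quadrant it lives in.

    ``value`` is ``None`` when delta_E = 0 (the ratio is undefined, not an
    error).  Quadrants: "NE" (costlier, more effective — trade-off),
    "dominant" (cheaper, more effective), "dominated" (costlier, less
    effective), "SW" (cheaper, less effective — trade-off).
    """

    delta_cost: float
    delta_effect: float
    value: float | None
    quadrant: str


def icer(delta_cost: float, delta_effect: float) -> IcerResult:
    if delta_effect > 0:
        quadrant = "NE" if delta_cost > 0 else "dominant"
    elif delta_effect < 0:
        quadrant = "dominated" if delta_cost > 0 else "SW"
    else:
        quadrant = "undefined (delta_effect = 0)"
        return IcerResult(delta_cost, delta_effect, None, quadrant)
    return IcerResult(delta_cost, delta_effect, delta_cost / delta_effect, quadrant)


def net_monetary_benefit(lambda_: float, delta_cost: float, delta_effect: float) -> float:
    """NMB = lambda*delta_E - delta_C; zero exactly at lambda = ICER (delta_E > 0)."""
    if lambda_ < 0:
        raise ValueError(f"willingness-to-pay lambda must be >= 0, got {lambda_}")
    return lambda_ * delta_effect - delta_cost


@dataclass
class RelativeRisk:
    rr: float
    ci_low: float | None = None
    ci_high: float | None = None


def discontinuation_relative_risk(
    p_arm: float | None = None,
    p_tau: float | None = None,
    events_arm: int | None = None,
    n_arm: int | None = None,
    events_tau: int | None = None,
    n_tau: int | None = None,
    alpha: float = 0.05,
) -> RelativeRisk:
    """Crude relative risk of 12-month discontinuation versus TAU.

    Supply either proportions (point estimate only) or event counts (point
    estimate plus a log-normal confidence interval).  A zero TAU proportion
    yields an infinite RR rather than an exception.
    """
    from scipy.stats import norm

    counts = all(v is not None for v in (events_arm, n_arm, events_tau, n_tau))
    if counts:
        p_arm = events_arm / n_arm
        p_tau = events_tau / n_tau
    if p_arm is None or p_tau is None:
        raise ValueError("supply proportions or full event counts")
    if p_tau == 0:
        return RelativeRisk(rr=math.inf)
    rr = p_arm / p_tau
    if not counts or events_arm == 0:
        return RelativeRisk(rr=rr)
    se = math.sqrt(1 / events_arm - 1 / n_arm + 1 / events_tau - 1 / n_tau)
    z = norm.ppf(1 - alpha / 2)
    return RelativeRisk(
        rr=rr,
        ci_low=rr * math.exp(-z * se),
        ci_high=rr * math.exp(z * se),
    )


def discontinuation_proportions(dataset: TrialDataset) -> dict[str, tuple[int, int]]:
    """(events, n) of 12-month benzodiazepine discontinuation per arm."""
    out: dict[str, tuple[int, int]] = {}
    for arm in ARMS:
        group = dataset.patients_in_arm(arm)
        if not group:
            continue
        events = sum(p.assessments[2].benzo_product == "None" for p in group)
        out[arm] = (events, len(group))
    return out


# ---------------------------------------------------------------------------
# pipeline assembly

def build_analysis_table(
    dataset: TrialDataset,
    costs: UnitCostTable,
    coeffs: MappingCoefficients,
    attribution: str = "trapezoid",
    allocation: WorkshopAllocation | None = None,
) -> pd.DataFrame:
    """One row per patient with cost components, utilities, and the QALY.

    This is the frame every downstream stage (point estimates, bootstrap)
    consumes; per-patient costs and QALYs are fixed quantities, so resampling
    schemes can operate on the rows directly.
    """
    if allocation is None:
        allocation = WorkshopAllocation.from_dataset(dataset)
    qt = qaly_table(dataset, coeffs)
    qframe = qt.frame.set_index("patient_id")
    rows = []
    for p in dataset.patients:
        bd = cost_patient(p, costs, allocation, attribution)
        q = qframe.loc[p.patient_id]
        rows.append(
            {
                "patient_id": p.patient_id,
                "gp_id": p.gp_id,
                "region": p.region,
                "arm": p.arm,
                "workshop_share": bd.workshop_share,
                "initial_visit": bd.initial_visit,
                "contact_visits": bd.contact_visits,
                "drug_cost": bd.drug_cost,
                "total_cost": bd.total,
                "baseline_utility": q["utility_bl"],
                "utility_m6": q["utility_m6"],
                "utility_m12": q["utility_m12"],
                "qaly": q["qaly"],
                "complete": bool(q["complete"]),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CEResult:
    """Incremental cost, incremental effect, ICER and NMB for one contrast."""

    arm: str
    mean_cost_arm: float
    mean_cost_tau: float
    mean_qaly_arm: float
    mean_qaly_tau: float
    delta_cost: float
    delta_effect: float
    adjusted: bool
    icer: IcerResult
    threshold: float
    nmb_at_threshold: float


def estimate_ce(
    table: pd.DataFrame,
    adjust_qalys: bool = True,
    adjust_costs: bool = False,
    threshold: float = 45_000.0,
) -> tuple[dict[str, CEResult], AdjustmentModel]:
    """Point-estimate cost-effectiveness of each intervention arm versus TAU.

    Costs enter as unadjusted arm means by default; QALYs are adjusted for
    baseline utility via :func:`fit_adjustment` (the adjusted arm coefficients
    are the incremental effects).  Setting ``adjust_costs`` additionally
    regression-adjusts costs on baseline utility as a sensitivity analysis.
    """
    model = fit_adjustment(table["qaly"], table["baseline_utility"], table["arm"])
    mean_cost = table.groupby("arm")["total_cost"].mean()
    mean_qaly = table.groupby("arm")["qaly"].mean()
    cost_model = None
    if adjust_costs:
        cost_model = fit_adjustment(
            table["total_cost"], table["baseline_utility"], table["arm"]
        )
    results: dict[str, CEResult] = {}
    for arm in INTERVENTION_ARMS:
        if arm not in mean_cost.index:
            continue
        if adjust_costs:
            delta_cost = cost_model.params[arm]
        else:
            delta_cost = float(mean_cost[arm] - mean_cost["TAU"])
        if adjust_qalys:
            delta_effect = model.params[arm]
        else:
            delta_effect = float(mean_qaly[arm] - mean_qaly["TAU"])
        ratio = icer(delta_cost, delta_effect)
        results[arm] = CEResult(
            arm=arm,
            mean_cost_arm=float(mean_cost[arm]),
            mean_cost_tau=float(mean_cost["TAU"]),
            mean_qaly_arm=float(mean_qaly[arm]),
            mean_qaly_tau=float(mean_qaly["TAU"]),
            delta_cost=delta_cost,
            delta_effect=delta_effect,
            adjusted=adjust_qalys,
            icer=ratio,
            threshold=threshold,
            nmb_at_threshold=net_monetary_benefit(threshold, delta_cost, delta_effect),
        )
    return results, model
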