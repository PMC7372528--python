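"""Decision uncertainty: bootstrap, confidence ellipses, acceptability curves.

The joint distribution of (incremental cost, incremental QALY) is estimated
by non-parametric bootstrap on the observed patient-level data: units are
resampled with replacement within arm (preserving arm sizes), per-patient
costs and QALYs are carried with each unit, and the baseline-adjusted QALY
regression is refit in every replicate.  Resampling GP clusters instead of
patients is offered because the trial randomised clusters.

Summaries: bivariate-normal confidence ellipses on the cost-effectiveness
plane scaled by chi-square(2 df) quantiles, and the cost-effectiveness
acceptability curve CEAC(lambda) = fraction of replicates with positive net
monetary benefit at willingness-to-pay lambda (strict inequality: a replicate
with exactly zero NMB counts as not cost-effective).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .cea_estimation import INTERVENTION_ARMS, build_analysis_table
from .costing import UnitCostTable, WorkshopAllocation
from .trial_data import ARMS, TrialDataset
from .utility_qaly import MappingCoefficients

__all__ = [
    "BootstrapReplicates",
    "EllipseSpec",
    "CeacCurve",
    "bootstrap_ce",
    "bootstrap_from_table",
    "confidence_ellipse",
    "ceac",
    "probability_cost_effective",
]

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = (0.50, 0.75, 0.95)
DEFAULT_LAMBDA_GRID = np.arange(0.0, 100_000.0 + 1, 500.0)


@dataclass
class BootstrapReplicates:
    """B bootstrap draws of (delta_cost, delta_qaly) per intervention arm."""

    B: int
    draws: dict[str, np.ndarray]  # arm -> array of shape (B, 2): [delta_cost, delta_qaly]
    seed: int | None
    resample_unit: str
    adjusted: bool
    n_redrawn: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for arm, d in self.draws.items():
            rows.append(
                pd.DataFrame(
                    {
                        "b": np.arange(self.B),
                        "arm": arm,
                        "delta_cost": d[:, 0],
                        "delta_qaly": d[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _fast_adjusted_deltas(cost, qaly, baseline, arm_code, idx) -> tuple | None:
    """Refit the adjustment OLS on resampled rows; None if degenerate.

    ``arm_code``: 0 = TAU, 1 = SIW, 2 = SIF.  Returns per-arm
    (delta_cost, delta_qaly) with costs as unadjusted mean differences.
    """
    code = arm_code[idx]
    c = cost[idx]
    mean_cost = []
    for a in (0, 1, 2):
        mask = code == a
        if not mask.any():
            return None
        mean_cost.append(c[mask].mean())
    q = qaly[idx]
    b = baseline[idx]
    ok = ~(np.isnan(q) | np.isnan(b))
    q, b, code_ok = q[ok], b[ok], code[ok]
    if len(q) < 5:
        return None
    X = np.column_stack(
        [np.ones_like(b), b, (code_ok == 1).astype(float), (code_ok == 2).astype(float)]
    )
    coef, _, rank, _ = np.linalg.lstsq(X, q, rcond=None)
    if rank < 4:
        return None
    return (
        (mean_cost[1] - mean_cost[0], coef[2]),
        (mean_cost[2] - mean_cost[0], coef[3]),
    )


def _unadjusted_deltas(cost, qaly, arm_code, idx) -> tuple | None:
    code = arm_code[idx]
    c = cost[idx]
    q = qaly[idx]
    out = []
    means = {}
    for a in (0, 1, 2):
        mask = code == a
        qa = q[mask]
        qa = qa[~np.isnan(qa)]
        if not mask.any() or len(qa) == 0:
            return None
        means[a] = (c[mask].mean(), qa.mean())
    for a in (1, 2):
        out.append((means[a][0] - means[0][0], means[a][1] - means[0][1]))
    return tuple(out)


def bootstrap_from_table(
    table: pd.DataFrame,
    B: int = 5000,
    seed: int | None = None,
    resample_unit: str = "patient",
    adjusted: bool = True,
    max_redraws: int = 1000,
) -> BootstrapReplicates:
    """Bootstrap the per-patient analysis table (see ``build_analysis_table``).

    Replicates whose resample leaves an arm empty of complete cases or a
    rank-deficient design are redrawn; the count of redraws is logged and
    recorded.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if resample_unit not in ("patient", "gp_cluster"):
        raise ValueError(f"unknown resample_unit {resample_unit!r}")
    rng = np.random.default_rng(seed)
    arm_code = table["arm"].map({"TAU": 0, "SIW": 1, "SIF": 2}).to_numpy()
    cost = table["total_cost"].to_numpy(dtype=float)
    qaly = table["qaly"].to_numpy(dtype=float)
    baseline = table["baseline_utility"].to_numpy(dtype=float)

    # index pools per arm: patients, or clusters with their member rows
    pools: list[list[np.ndarray]] = []
    for a in (0, 1, 2):
        rows = np.flatnonzero(arm_code == a)
        if len(rows) == 0:
            raise ValueError("bootstrap requires all three arms present")
        if resample_unit == "patient":
            pools.append([rows[i : i + 1] for i in range(len(rows))])
        else:
            gps = table["gp_id"].to_numpy()
            ids = np.unique(gps[rows])
            pools.append([rows[gps[rows] == g] for g in ids])

    draws = {arm: np.empty((B, 2)) for arm in INTERVENTION_ARMS}
    n_redrawn = 0
    b = 0
    while b < B:
        idx_parts = []
        for pool in pools:
            pick = rng.integers(0, len(pool), size=len(pool))
            idx_parts.extend(pool[i] for i in pick)
        idx = np.concatenate(idx_parts)
        if adjusted:
            deltas = _fast_adjusted_deltas(cost, qaly, baseline, arm_code, idx)
        else:
            deltas = _unadjusted_deltas(cost, qaly, arm_code, idx)
        if deltas is None:
            n_redrawn += 1
            if n_redrawn > max_redraws:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        draws["SIW"][b] = deltas[0]
        draws["SIF"][b] = deltas[1]
        b += 1
    if n_redrawn:
        logger.info("bootstrap: redrew %d degenerate replicate(s)", n_redrawn)
    return BootstrapReplicates(
        B=B,
        draws=draws,
        seed=seed,
        resample_unit=resample_unit,
        adjusted=adjusted,
        n_redrawn=n_redrawn,
    )


def bootstrap_ce(
    dataset: TrialDataset,
    costs: UnitCostTable,
    coeffs: MappingCoefficients,
    B: int = 5000,
    seed: int | None = None,
    resample_unit: str = "patient",
    adjusted: bool = True,
    attribution: str = "trapezoid",
    allocation: WorkshopAllocation | None = None,
) -> BootstrapReplicates:
    """End-to-end bootstrap: cost and map the dataset, then resample."""
    table = build_analysis_table(dataset, costs, coeffs, attribution, allocation)
    return bootstrap_from_table(
        table, B=B, seed=seed, resample_unit=resample_unit, adjusted=adjusted
    )


# ---------------------------------------------------------------------------
# confidence ellipse

@dataclass
class EllipseSpec:
    """Normal-approximation confidence ellipse of bootstrap (dC, dE) draws.

    The level-p contour is {x : (x-mu)' Sigma^-1 (x-mu) = chi2_2(p)}; its
    semi-axes are sqrt(eigenvalue * chi2_2(p)).  ``marginal_interval`` gives
    the univariate normal interval (chi-square with 1 df, i.e. mu +/- z*sd)
    for one coordinate.
    """

    center: tuple[float, float]
    covariance: np.ndarray
    levels: tuple[float, ...]
    semi_axes: dict[float, tuple[float, float]]
    angle_rad: float
    degenerate: bool = False
    _eigvecs: np.ndarray = field(default=None, repr=False)
    _eigvals: np.ndarray = field(default=None, repr=False)

    def contour(self, level: float, n_points: int = 200) -> np.ndarray:
        """Points (n, 2) on the level-p contour, ordered around the ellipse."""
        radius = math.sqrt(chi2.ppf(level, df=2))
        theta = np.linspace(0.0, 2 * math.pi, n_points)
        circle = np.column_stack([np.cos(theta), np.sin(theta)])
        scaled = circle * np.sqrt(np.maximum(self._eigvals, 0.0)) * radius
        return scaled @ self._eigvecs.T + np.asarray(self.center)

    def area(self, level: float) -> float:
        a, b = self.semi_axes[level]
        return math.pi * a * b

    def marginal_interval(self, level: float, coord: int) -> tuple[float, float]:
        z = math.sqrt(chi2.ppf(level, df=1))
        sd = math.sqrt(max(self.covariance[coord, coord], 0.0))
        c = self.center[coord]
        return (c - z * sd, c + z * sd)

    def mahalanobis_sq(self, points: np.ndarray) -> np.ndarray:
        diff = np.atleast_2d(points) - np.asarray(self.center)
        inv = np.linalg.pinv(self.covariance)
        return np.einsum("ij,jk,ik->i", diff, inv, diff)


def confidence_ellipse(
    replicates: BootstrapReplicates, levels: tuple[float, ...] = DEFAULT_LEVELS
) -> dict[str, EllipseSpec]:
    """Per-arm ellipse specs from the bootstrap draws.

    A singular sample covariance (all draws identical, or B < 3) yields a
    spec flagged ``degenerate`` whose axes collapse along the deficient
    direction.
    """
    if replicates.B < 3:
        raise ValueError("need at least 3 replicates for a covariance")
    out: dict[str, EllipseSpec] = {}
    for arm, d in replicates.draws.items():
        center = (float(d[:, 0].mean()), float(d[:, 1].mean()))
        cov = np.cov(d, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        degenerate = bool(np.min(eigvals) <= 1e-15 * max(np.max(eigvals), 1.0))
        # orientation of the major axis
        major = eigvecs[:, int(np.argmax(eigvals))]
        angle = math.atan2(major[1], major[0])
        semi = {
            lv: tuple(
                float(math.sqrt(max(ev, 0.0) * chi2.ppf(lv, df=2)))
                for ev in sorted(eigvals, reverse=True)
            )
            for lv in levels
        }
        if degenerate:
            logger.warning(
                "confidence_ellipse: singular covariance for arm %s; "
                "axis-aligned degenerate ellipse returned", arm
            )
        out[arm] = EllipseSpec(
            center=center,
            covariance=cov,
            levels=tuple(levels),
            semi_axes=semi,
            angle_rad=angle,
            degenerate=degenerate,
            _eigvecs=eigvecs,
            _eigvals=eigvals,
        )
    return out


# ---------------------------------------------------------------------------
# acceptability curve

@dataclass
class CeacCurve:
    """CEAC(lambda) = P(lambda * dE - dC > 0) over the bootstrap draws."""

    arm: str
    lambda_grid: np.ndarray
    probability: np.ndarray
    B: int
    draws: np.ndarray = field(repr=False)

    def probability_at(self, lambda_: float) -> float:
        """Exact recomputation at any lambda (no interpolation of indicators)."""
        if lambda_ < 0:
            raise ValueError("lambda must be >= 0")
        nmb = lambda_ * self.draws[:, 1] - self.draws[:, 0]
        return float(np.mean(nmb > 0))


def ceac(
    replicates: BootstrapReplicates, lambda_grid=None
) -> dict[str, CeacCurve]:
    grid = np.asarray(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0) or np.any(grid < 0):
        raise ValueError("lambda grid must be 1-D, non-negative, strictly increasing")
    out = {}
    for arm, d in replicates.draws.items():
        nmb = grid[:, None] * d[None, :, 1] - d[None, :, 0]
        prob = np.mean(nmb > 0, axis=1)
        out[arm] = CeacCurve(
            arm=arm, lambda_grid=grid, probability=prob, B=replicates.B, draws=d
        )
    return out


def probability_cost_effective(curve: CeacCurve, lambda_: float) -> float:
    """Probability the arm is cost-effective at willingness-to-pay ``lambda_``."""
    return curve.probability_at(lambda_)
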