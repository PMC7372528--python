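"""Synthetic three-arm cluster-randomised trial generator.

Emulates the statistical structure the downstream analysis assumes: patients
nested in GP clusters across three regions; a benzodiazepine product at
baseline with a two-state continue/discontinue process at 6 and 12 months
whose marginal discontinuation proportions match the configured per-arm
probabilities; Poisson contact-visit counts with a log-normal GP-level
multiplier; and latent utility trajectories with a GP-level additive effect,
within-patient autocorrelation, and additive arm effects.

Utilities are primary in generation: each wave's latent utility is converted
to an integer (HADS-A, HADS-D) pair by inverting the configured linear
mapping (the target utility deficit is split evenly between the subscales and
rounded), so the downstream mapping stage recovers the intended utilities up
to quantisation.  Because quantisation and the utility cap at 1.0 shift
means, the latent additive arm effect is *calibrated* by deterministic
numerical integration so that the population coefficient of the
baseline-adjusted QALY regression equals the configured target incremental
QALY exactly; ``true_parameters`` therefore returns the configured targets as
ground truth.  Expected incremental costs follow in closed form from the
configured rates, mixes and unit costs.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import brentq

from .costing import UnitCostTable, _DEFAULT_GPS_PER_WORKSHOP
from .trial_data import (
    ARMS,
    NOMINAL_TIMES,
    REGIONS,
    AssessmentWave,
    PatientRecord,
    TrialDataset,
)
from .utility_qaly import MappingCoefficients

__all__ = [
    "SimulationConfig",
    "TrueParameters",
    "generate_trial",
    "true_parameters",
    "write_ground_truth",
]

_CONSUMED_PRODUCTS = ("Alprazolam", "Diazepam", "Lorazepam", "Lormetazepam", "Zolpidem", "Other")

# Baseline product-mix proportions by arm (normalised to sum to 1).
_RAW_PRODUCT_MIX = {
    "SIW": {"Alprazolam": 0.179, "Diazepam": 0.089, "Lorazepam": 0.304,
            "Lormetazepam": 0.149, "Zolpidem": 0.119, "Other": 0.250},
    "SIF": {"Alprazolam": 0.199, "Diazepam": 0.115, "Lorazepam": 0.346,
            "Lormetazepam": 0.099, "Zolpidem": 0.147, "Other": 0.168},
    "TAU": {"Alprazolam": 0.150, "Diazepam": 0.052, "Lorazepam": 0.312,
            "Lormetazepam": 0.214, "Zolpidem": 0.150, "Other": 0.208},
}


def _normalised_mix() -> dict[str, dict[str, float]]:
    out = {}
    for arm, mix in _RAW_PRODUCT_MIX.items():
        total = sum(mix.values())
        out[arm] = {p: v / total for p, v in mix.items()}
    return out


def _default_region_weights() -> dict[str, float]:
    counts = {"Balearic": 187, "Catalunya": 192, "Valencia": 153}
    total = sum(counts.values())
    return {r: c / total for r, c in counts.items()}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic trial; defaults emulate the source cohort.

    ``arm_utility_effect`` is the *target baseline-adjusted incremental QALY*
    per intervention arm; the generator calibrates its latent additive effect
    so that this target is the exact population value recovered by the
    adjustment regression.  ``utility_autocorrelation`` (within-patient
    correlation between baseline and follow-up latent utility) is a free
    modelling choice with no empirical anchor; it is surfaced here rather
    than hidden.
    """

    n_patients_per_arm: dict[str, int] = field(
        default_factory=lambda: {"SIW": 168, "SIF": 191, "TAU": 173}
    )
    n_gps_per_arm: int = 25
    region_weights: dict[str, float] = field(default_factory=_default_region_weights)
    discontinuation_prob_6m: dict[str, float] = field(
        default_factory=lambda: {"SIW": 0.459, "SIF": 0.382, "TAU": 0.146}
    )
    discontinuation_prob_12m: dict[str, float] = field(
        default_factory=lambda: {"SIW": 0.452, "SIF": 0.450, "TAU": 0.150}
    )
    product_mix: dict[str, dict[str, float]] = field(default_factory=_normalised_mix)
    contact_visit_rate: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "SIW": {"Balearic": 3.298, "Catalunya": 2.424, "Valencia": 4.022},
            "SIF": {"Balearic": 6.651, "Catalunya": 4.727, "Valencia": 8.103},
            "TAU": {"Balearic": 3.576, "Catalunya": 2.135, "Valencia": 2.471},
        }
    )
    baseline_utility_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "SIW": (0.749, 0.165),
            "SIF": (0.731, 0.154),
            "TAU": (0.758, 0.158),
        }
    )
    arm_utility_effect: dict[str, float] = field(
        default_factory=lambda: {"SIW": 0.0144, "SIF": 0.0340}
    )
    secular_drift: tuple[float, float] = (0.026, 0.046)
    utility_autocorrelation: float = 0.6
    noise_sd: float = 0.12
    cluster_sd: float = 0.03
    missing_rate: float = 0.05
    seed: int = 0
    mapping: MappingCoefficients = field(
        default_factory=MappingCoefficients.illustrative_default
    )

    def __post_init__(self) -> None:
        for arm, n in self.n_patients_per_arm.items():
            if n < 1:
                raise ValueError(f"n_patients_per_arm[{arm}] must be >= 1")
        if self.n_gps_per_arm < 1:
            raise ValueError("n_gps_per_arm must be >= 1")
        for name, probs in (
            ("region_weights", self.region_weights),
            ("discontinuation_prob_6m", self.discontinuation_prob_6m),
            ("discontinuation_prob_12m", self.discontinuation_prob_12m),
        ):
            for key, p in probs.items():
                if not (0.0 <= p <= 1.0):
                    raise ValueError(f"{name}[{key}] = {p} outside [0, 1]")
        if abs(sum(self.region_weights.values()) - 1.0) > 1e-6:
            raise ValueError("region_weights must sum to 1")
        for arm, mix in self.product_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError(f"product_mix[{arm}] must sum to 1")
            if any(v < 0 for v in mix.values()):
                raise ValueError(f"product_mix[{arm}] has negative entries")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate outside [0, 1]")
        if not self.mapping.is_linear:
            raise ValueError("generator requires a linear mapping to invert")
        if self.mapping.coef_hads_a >= 0 or self.mapping.coef_hads_d >= 0:
            raise ValueError("mapping slopes must be negative for inversion")

    # --- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["baseline_utility_mean_sd"] = {
            a: list(v) for a, v in self.baseline_utility_mean_sd.items()
        }
        payload["secular_drift"] = list(self.secular_drift)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        if "mapping" in payload:
            payload["mapping"] = MappingCoefficients(**payload["mapping"])
        if "baseline_utility_mean_sd" in payload:
            payload["baseline_utility_mean_sd"] = {
                a: tuple(v) for a, v in payload["baseline_utility_mean_sd"].items()
            }
        if "secular_drift" in payload:
            payload["secular_drift"] = tuple(payload["secular_drift"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# HADS inversion (the quantiser the calibration integrates over)

def hads_pair_from_utility(u, coeffs: MappingCoefficients):
    """Invert the linear mapping: split the utility deficit evenly.

    Each subscale absorbs half of ``intercept - u`` and is rounded to the
    nearest integer score in [0, 21].
    """
    u = np.asarray(u, dtype=float)
    half = (coeffs.intercept - u) / 2.0
    a = np.clip(np.rint(half / (-coeffs.coef_hads_a)), 0, 21).astype(int)
    d = np.clip(np.rint(half / (-coeffs.coef_hads_d)), 0, 21).astype(int)
    return a, d


def quantised_utility(u, coeffs: MappingCoefficients):
    """Utility actually recovered after HADS inversion and re-mapping."""
    a, d = hads_pair_from_utility(u, coeffs)
    value = coeffs.intercept + coeffs.coef_hads_a * a + coeffs.coef_hads_d * d
    return np.clip(value, coeffs.floor, coeffs.cap)


# ---------------------------------------------------------------------------
# effect calibration: population moments of the quantised utilities

_T_GRID = np.linspace(-8.0, 8.0, 2001)
_T_PDF = np.exp(-0.5 * _T_GRID**2)
_T_NORM = np.trapezoid(_T_PDF, _T_GRID)


def _mean_q(means, sd, coeffs, power: int = 1):
    """E[q(X)^power] for X ~ N(mean, sd), vectorised over an array of means."""
    means = np.atleast_1d(np.asarray(means, dtype=float))
    x = means[:, None] + sd * _T_GRID[None, :]
    q = quantised_utility(x, coeffs)
    if power == 2:
        q = q * q
    out = np.trapezoid(q * _T_PDF[None, :], _T_GRID, axis=1) / _T_NORM
    return out if out.size > 1 else float(out[0])


def _cross_mean(mb, var_b, mf, var_f, cov_bf, coeffs):
    """E[q(U_b) q(U_f)] for a bivariate normal latent pair."""
    sb = math.sqrt(var_b)
    ub = mb + sb * _T_GRID
    cond_mean = mf + (cov_bf / var_b) * (ub - mb)
    cond_sd = math.sqrt(max(var_f - cov_bf**2 / var_b, 1e-12))
    inner = _mean_q(cond_mean, cond_sd, coeffs)
    qb = quantised_utility(ub, coeffs)
    return float(np.trapezoid(qb * inner * _T_PDF, _T_GRID) / _T_NORM)


def _calibration_key(config: SimulationConfig) -> tuple:
    m = config.mapping
    return (
        tuple(sorted(config.n_patients_per_arm.items())),
        tuple(sorted((a, v[0], v[1]) for a, v in config.baseline_utility_mean_sd.items())),
        tuple(sorted(config.arm_utility_effect.items())),
        config.secular_drift,
        config.utility_autocorrelation,
        config.noise_sd,
        config.cluster_sd,
        (m.intercept, m.coef_hads_a, m.coef_hads_d, m.floor, m.cap),
    )


_EFFECT_CACHE: dict[tuple, dict[str, float]] = {}

# AUC weights of the three waves for nominal times (0, 0.5, 1).
_W_BL, _W_M6, _W_M12 = 0.25, 0.5, 0.25


def latent_arm_effects(config: SimulationConfig) -> dict[str, float]:
    """Latent additive follow-up effect per arm solving the calibration.

    Solves, by 1-D root finding on deterministic quadrature moments, for the
    additive latent shift ``e`` at both follow-up waves such that the
    population coefficient of arm in OLS(QALY ~ baseline utility + arm)
    equals ``config.arm_utility_effect[arm]``.  TAU's effect is 0 by
    definition.
    """
    key = _calibration_key(config)
    if key in _EFFECT_CACHE:
        return dict(_EFFECT_CACHE[key])

    coeffs = config.mapping
    rho = config.utility_autocorrelation
    d6, d12 = config.secular_drift
    var_c = config.cluster_sd**2
    var_n = config.noise_sd**2

    arms = [a for a in ARMS if a in config.n_patients_per_arm]
    stats: dict[str, dict[str, float]] = {}
    for arm in arms:
        m, s = config.baseline_utility_mean_sd[arm]
        var_b = var_c + s**2
        var_f = var_c + (rho * s) ** 2 + var_n
        cov_bf = var_c + rho * s**2
        mu_qb = _mean_q(m, math.sqrt(var_b), coeffs)
        e_qb2 = _mean_q(m, math.sqrt(var_b), coeffs, power=2)
        stats[arm] = {
            "m": m,
            "var_b": var_b,
            "var_f": var_f,
            "cov_bf": cov_bf,
            "mu_qb": mu_qb,
            "var_qb": e_qb2 - mu_qb**2,
        }

    def follow_means(arm: str, e: float) -> tuple[float, float]:
        st = stats[arm]
        sd_f = math.sqrt(st["var_f"])
        mu6 = _mean_q(st["m"] + d6 + e, sd_f, coeffs)
        mu12 = _mean_q(st["m"] + d12 + e, sd_f, coeffs)
        return mu6, mu12

    def mean_Q(arm: str, e: float) -> float:
        mu6, mu12 = follow_means(arm, e)
        return _W_BL * stats[arm]["mu_qb"] + _W_M6 * mu6 + _W_M12 * mu12

    def cov_Q_qb(arm: str, e: float) -> float:
        st = stats[arm]
        mu6, mu12 = follow_means(arm, e)
        c6 = _cross_mean(st["m"], st["var_b"], st["m"] + d6 + e,
                         st["var_f"], st["cov_bf"], coeffs) - mu6 * st["mu_qb"]
        c12 = _cross_mean(st["m"], st["var_b"], st["m"] + d12 + e,
                          st["var_f"], st["cov_bf"], coeffs) - mu12 * st["mu_qb"]
        return _W_BL * st["var_qb"] + _W_M6 * c6 + _W_M12 * c12

    targets = {a: config.arm_utility_effect.get(a, 0.0) for a in arms}
    effects = {a: (0.0 if a == "TAU" else targets[a] / (_W_M6 + _W_M12)) for a in arms}
    weights = {a: config.n_patients_per_arm[a] for a in arms}

    for _ in range(3):
        num = sum(weights[a] * cov_Q_qb(a, effects[a]) for a in arms)
        den = sum(weights[a] * stats[a]["var_qb"] for a in arms)
        slope = num / den
        mq_tau = mean_Q("TAU", 0.0)
        for arm in arms:
            if arm == "TAU":
                continue

            def g(e: float, arm=arm) -> float:
                return (
                    mean_Q(arm, e)
                    - mq_tau
                    - slope * (stats[arm]["mu_qb"] - stats["TAU"]["mu_qb"])
                    - targets[arm]
                )

            lo, hi = effects[arm] - 0.2, effects[arm] + 0.2
            while g(lo) > 0:
                lo -= 0.2
            while g(hi) < 0:
                hi += 0.2
            effects[arm] = brentq(g, lo, hi, xtol=1e-7)

    effects = {a: float(e) for a, e in effects.items()}
    _EFFECT_CACHE[key] = dict(effects)
    return effects


# ---------------------------------------------------------------------------
# generation

def generate_trial(config: SimulationConfig, seed: int | None = None) -> TrialDataset:
    """Draw one synthetic trial; deterministic given the seed.

    ``seed`` overrides ``config.seed`` when given, so replicate studies can
    reuse one config.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    effects = latent_arm_effects(config)
    rho = config.utility_autocorrelation
    d6, d12 = config.secular_drift
    coeffs = config.mapping
    regions = list(REGIONS)
    weights = np.array([config.region_weights[r] for r in regions])

    patients: list[PatientRecord] = []
    for arm in ARMS:
        if arm not in config.n_patients_per_arm:
            continue
        n = config.n_patients_per_arm[arm]
        n_gps = config.n_gps_per_arm
        gp_region_idx = rng.choice(len(regions), size=n_gps, p=weights)
        cluster_u = rng.normal(0.0, config.cluster_sd, size=n_gps)
        # log-normal contact multiplier with unit mean
        cluster_v = rng.normal(-config.cluster_sd**2 / 2, config.cluster_sd, size=n_gps)
        gp_of = rng.integers(0, n_gps, size=n)

        rates = np.array(
            [config.contact_visit_rate[arm][regions[gp_region_idx[g]]] for g in range(n_gps)]
        )
        contacts = rng.poisson(rates[gp_of] * np.exp(cluster_v[gp_of]))

        mix = config.product_mix[arm]
        products = rng.choice(
            _CONSUMED_PRODUCTS, size=n, p=[mix[p] for p in _CONSUMED_PRODUCTS]
        )
        p6 = config.discontinuation_prob_6m[arm]
        p12 = config.discontinuation_prob_12m[arm]
        off6 = rng.random(n) < p6
        u = rng.random(n)
        if p12 >= p6:
            extra = (p12 - p6) / (1.0 - p6) if p6 < 1.0 else 0.0
            off12 = off6 | (~off6 & (u < extra))
        else:
            off12 = off6 & (u < p12 / p6)

        m, s = config.baseline_utility_mean_sd[arm]
        z = rng.normal(0.0, s, size=n)
        eps6 = rng.normal(0.0, config.noise_sd, size=n)
        eps12 = rng.normal(0.0, config.noise_sd, size=n)
        e_arm = effects[arm]
        lat_b = m + cluster_u[gp_of] + z
        lat_6 = m + d6 + e_arm + cluster_u[gp_of] + rho * z + eps6
        lat_12 = m + d12 + e_arm + cluster_u[gp_of] + rho * z + eps12

        hads = [hads_pair_from_utility(lat, coeffs) for lat in (lat_b, lat_6, lat_12)]
        missing = rng.random((n, 3)) < config.missing_rate

        for i in range(n):
            waves = []
            wave_products = (str(products[i]),
                             "None" if off6[i] else str(products[i]),
                             "None" if off12[i] else str(products[i]))
            for w, t in enumerate(NOMINAL_TIMES):
                a_score, d_score = hads[w]
                waves.append(
                    AssessmentWave(
                        time_years=t,
                        hads_a=None if missing[i, w] else int(a_score[i]),
                        hads_d=None if missing[i, w] else int(d_score[i]),
                        benzo_product=wave_products[w],
                    )
                )
            patients.append(
                PatientRecord(
                    patient_id=f"{arm}-P{i:04d}",
                    gp_id=f"{arm}-G{gp_of[i]:02d}",
                    region=regions[gp_region_idx[gp_of[i]]],
                    arm=arm,
                    assessments=waves,
                    n_contact_visits=float(contacts[i]),
                    had_initial_visit=arm != "TAU",
                )
            )
    dataset = TrialDataset.from_patients(patients)
    dataset.validate()
    return dataset


# ---------------------------------------------------------------------------
# ground truth

@dataclass
class TrueParameters:
    """Generative incremental costs and QALYs implied by a config."""

    delta_qaly: dict[str, float]
    delta_cost: dict[str, float]
    expected_total_cost: dict[str, float]


def _expected_monthly_drug_cost(mix: dict[str, float], costs: UnitCostTable) -> float:
    return sum(share * costs.drug_monthly_cost[p] for p, share in mix.items())


def true_parameters(
    config: SimulationConfig,
    costs: UnitCostTable | None = None,
    gps_per_workshop: dict[tuple[str, str], float] | None = None,
) -> TrueParameters:
    """Closed-form expected costs and the configured QALY targets.

    Expected per-patient cost per arm (trapezoid drug attribution over
    nominal times 0/6/12 months):

    - workshop share: ``(G/N) * sum_r w_r * workshop_cost(r, arm) / gps_per_workshop(r, arm)``
      (each of the G clusters contributes one GP's share, spread over N patients);
    - initial visit: region-weighted tariff for intervention arms, 0 for TAU;
    - contacts: region-weighted ``rate * follow-up tariff``;
    - drugs: ``mean_monthly * (3 + 6*(1 - p_6m) + 3*(1 - p_12m))`` months,
      since discontinuation is independent of product so the consuming mix
      stays at baseline composition.
    """
    costs = costs or UnitCostTable.defaults()
    gpw = gps_per_workshop or _DEFAULT_GPS_PER_WORKSHOP
    expected: dict[str, float] = {}
    for arm in ARMS:
        if arm not in config.n_patients_per_arm:
            continue
        n = config.n_patients_per_arm[arm]
        w = config.region_weights
        if arm == "TAU":
            workshop = 0.0
            initial = 0.0
        else:
            workshop = (config.n_gps_per_arm / n) * sum(
                w[r] * costs.workshop_cost[(r, arm)] / gpw[(r, arm)] for r in REGIONS
            )
            initial = sum(w[r] * costs.initial_visit_cost[r] for r in REGIONS)
        contact = sum(
            w[r] * config.contact_visit_rate[arm][r] * costs.followup_visit_cost[r]
            for r in REGIONS
        )
        monthly = _expected_monthly_drug_cost(config.product_mix[arm], costs)
        months = (
            3.0
            + 6.0 * (1.0 - config.discontinuation_prob_6m[arm])
            + 3.0 * (1.0 - config.discontinuation_prob_12m[arm])
        )
        expected[arm] = workshop + initial + contact + monthly * months
    delta_cost = {
        arm: expected[arm] - expected["TAU"] for arm in expected if arm != "TAU"
    }
    return TrueParameters(
        delta_qaly=dict(config.arm_utility_effect),
        delta_cost=delta_cost,
        expected_total_cost=expected,
    )


def write_ground_truth(config: SimulationConfig, path) -> None:
    """JSON sidecar with the generative targets, written next to a dataset."""
    truth = true_parameters(config)
    payload = {
        "delta_qaly": truth.delta_qaly,
        "delta_cost": truth.delta_cost,
        "expected_total_cost": truth.expected_total_cost,
        "seed": config.seed,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
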