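"""Result bundles, figures, and the published-style worked example.

``run_full_analysis`` drives the whole pipeline — read or simulate a trial,
cost it, map utilities, estimate adjusted incremental QALYs, bootstrap — and
writes machine-readable CSVs, a JSON manifest of the headline numbers, and
the cost-effectiveness-plane and CEAC figures.  Every figure has a companion
CSV of its plotted values, so no number exists only in a picture.

``demo_worked_example`` reproduces the source study's headline arithmetic
from the bundled published summary values: incremental costs from the arm
cost means, ICERs from the adjusted QALY gains, crude relative risks from
the 12-month discontinuation proportions, and the completeness percentage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference_values
from .cea_estimation import (
    INTERVENTION_ARMS,
    build_analysis_table,
    discontinuation_proportions,
    discontinuation_relative_risk,
    estimate_ce,
    icer,
)
from .costing import UnitCostTable, WorkshopAllocation, arm_cost_summary
from .synthetic_data import SimulationConfig, generate_trial
from .trial_data import completeness_percentage, completeness_summary, read_trial_csv
from .uncertainty import (
    DEFAULT_LEVELS,
    bootstrap_from_table,
    ceac,
    confidence_ellipse,
)
from .utility_qaly import MappingCoefficients, qaly_table

__all__ = ["RunConfig", "run_full_analysis", "demo_worked_example"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs; YAML-loadable."""

    trial_csv: str | None = None  # when None, a synthetic trial is generated
    simulation: SimulationConfig | None = None
    unit_costs_yaml: str | None = None
    mapping_yaml: str | None = None
    attribution: str = "trapezoid"
    resample_unit: str = "patient"
    bootstrap_B: int = 5000
    seed: int | None = None
    lambda_max: float = 100_000.0
    lambda_step: float = 500.0
    threshold: float = 45_000.0
    adjust_costs: bool = False
    output_dir: str = "trialcea_output"
    verbosity: str = "INFO"

    def resolve_costs(self) -> UnitCostTable:
        if self.unit_costs_yaml:
            return UnitCostTable.from_yaml(self.unit_costs_yaml)
        return UnitCostTable.defaults()

    def resolve_mapping(self) -> MappingCoefficients:
        if self.mapping_yaml:
            return MappingCoefficients.from_yaml(self.mapping_yaml)
        return MappingCoefficients.illustrative_default()

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if payload.get("simulation") and payload["simulation"].get("mapping"):
            pass  # asdict already flattened nested dataclasses
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _library_versions() -> dict[str, str]:
    import matplotlib
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
        "matplotlib": matplotlib.__version__,
    }


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _ce_plane_figure(replicates, ellipses, path):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    colors = {"SIW": "tab:blue", "SIF": "tab:orange"}
    for arm, draws in replicates.draws.items():
        ax.scatter(
            draws[:, 1], draws[:, 0], s=4, alpha=0.25, color=colors.get(arm), label=arm
        )
        spec = ellipses[arm]
        for level in spec.levels:
            pts = spec.contour(level)
            ax.plot(pts[:, 1], pts[:, 0], color=colors.get(arm), lw=1.0, alpha=0.8)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs vs TAU")
    ax.set_ylabel("Incremental cost vs TAU (EUR)")
    ax.set_title("Cost-effectiveness plane with 50/75/95% confidence ellipses")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _ceac_figure(curves, threshold, path):
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for arm, curve in curves.items():
        ax.plot(curve.lambda_grid, curve.probability, label=arm)
    ax.axvline(threshold, color="grey", ls="--", lw=0.8, label=f"threshold {threshold:g}")
    ax.set_xlabel("Willingness-to-pay (EUR per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_full_analysis(config: RunConfig) -> dict:
    """Run the pipeline per ``config`` and write the result bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    With ``bootstrap_B = 0`` only point estimates are produced and the
    uncertainty sections are marked absent.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    costs = config.resolve_costs()
    coeffs = config.resolve_mapping()

    if config.trial_csv:
        dataset = read_trial_csv(config.trial_csv)
        logger.info("loaded %d patients from %s", len(dataset), config.trial_csv)
    else:
        sim = config.simulation or SimulationConfig()
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        dataset = generate_trial(sim)
        logger.info("generated synthetic trial with %d patients (seed %s)", len(dataset), sim.seed)

    allocation = WorkshopAllocation.from_dataset(dataset)
    table = build_analysis_table(dataset, costs, coeffs, config.attribution, allocation)
    table.to_csv(out / "patient_table.csv", index=False)

    costs_summary = arm_cost_summary(dataset, costs, allocation, config.attribution)
    costs_summary.means.to_csv(out / "arm_costs.csv")

    qt = qaly_table(dataset, coeffs)
    qt.utility_summary.to_csv(out / "utility_summary.csv", index=False)
    qt.qaly_summary.to_csv(out / "qaly_summary.csv", index=False)

    completeness = completeness_summary(dataset)
    ce_results, model = estimate_ce(
        table,
        adjust_costs=config.adjust_costs,
        threshold=config.threshold,
    )
    model.summary_frame().to_csv(out / "regression.csv", index=False)
    with open(out / "regression.txt", "w", encoding="utf-8") as fh:
        fh.write(model.summary_frame().to_string(index=False))
        fh.write(f"\n\nn = {model.n}   R^2 = {model.r_squared:.4f}\n")

    rr = {}
    props = discontinuation_proportions(dataset)
    for arm in INTERVENTION_ARMS:
        if arm in props and "TAU" in props:
            e_a, n_a = props[arm]
            e_t, n_t = props["TAU"]
            res = discontinuation_relative_risk(
                events_arm=e_a, n_arm=n_a, events_tau=e_t, n_tau=n_t
            )
            rr[arm] = {"rr": res.rr, "ci_low": res.ci_low, "ci_high": res.ci_high}

    ce_rows = []
    for arm, res in ce_results.items():
        ce_rows.append(
            {
                "arm": arm,
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_effect,
                "icer": res.icer.value,
                "quadrant": res.icer.quadrant,
                "nmb_at_threshold": res.nmb_at_threshold,
                "adjusted": res.adjusted,
            }
        )
    pd.DataFrame(ce_rows).to_csv(out / "ce_results.csv", index=False)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "library_versions": _library_versions(),
        "n_patients": len(dataset),
        "completeness_pct": completeness.percentage,
        "attribution": config.attribution,
        "point_estimates": {
            arm: {
                "delta_cost": res.delta_cost,
                "delta_qaly": res.delta_effect,
                "icer": res.icer.value,
                "quadrant": res.icer.quadrant,
                "nmb_at_threshold": res.nmb_at_threshold,
            }
            for arm, res in ce_results.items()
        },
        "regression": {
            "params": model.params,
            "r_squared": model.r_squared,
            "n": model.n,
        },
        "relative_risk_12m": rr,
        "threshold": config.threshold,
    }

    if config.bootstrap_B > 0:
        if config.seed is None:
            raise ValueError("a seed is required when bootstrapping")
        replicates = bootstrap_from_table(
            table,
            B=config.bootstrap_B,
            seed=config.seed,
            resample_unit=config.resample_unit,
            adjusted=True,
        )
        replicates.to_frame().to_csv(out / "replicates.csv", index=False)
        ellipses = confidence_ellipse(replicates, DEFAULT_LEVELS)
        ellipse_rows = []
        for arm, spec in ellipses.items():
            for level in spec.levels:
                a, b = spec.semi_axes[level]
                ellipse_rows.append(
                    {
                        "arm": arm,
                        "level": level,
                        "center_delta_cost": spec.center[0],
                        "center_delta_qaly": spec.center[1],
                        "semi_axis_major": a,
                        "semi_axis_minor": b,
                        "angle_rad": spec.angle_rad,
                        "degenerate": spec.degenerate,
                    }
                )
        pd.DataFrame(ellipse_rows).to_csv(out / "ellipses.csv", index=False)

        grid = np.arange(0.0, config.lambda_max + config.lambda_step / 2, config.lambda_step)
        curves = ceac(replicates, grid)
        ceac_frame = pd.DataFrame({"lambda": grid})
        for arm, curve in curves.items():
            ceac_frame[f"prob_{arm}"] = curve.probability
        ceac_frame.to_csv(out / "ceac.csv", index=False)

        _ce_plane_figure(replicates, ellipses, out / "ce_plane.png")
        _ceac_figure(curves, config.threshold, out / "ceac.png")

        manifest["uncertainty"] = {
            "B": config.bootstrap_B,
            "resample_unit": config.resample_unit,
            "n_redrawn": replicates.n_redrawn,
            "ceac_at_threshold": {
                arm: curves[arm].probability_at(config.threshold) for arm in curves
            },
            "ellipse_95_marginals": {
                arm: {
                    "delta_cost": list(ellipses[arm].marginal_interval(0.95, 0)),
                    "delta_qaly": list(ellipses[arm].marginal_interval(0.95, 1)),
                }
                for arm in ellipses
            },
        }
    else:
        manifest["uncertainty"] = None
        logger.info("bootstrap_B = 0: uncertainty sections absent")

    manifest = _round_floats(manifest, 10)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def demo_worked_example(stream=None) -> dict:
    """Reproduce the source study's headline arithmetic from bundled values.

    Computes (never just echoes) incremental costs from the published arm
    cost means, ICERs from the published adjusted QALY gains, crude relative
    risks from the published 12-month discontinuation proportions and arm
    sizes, and the data-completeness percentage.  Prints a small report and
    returns the numbers.
    """
    stream = stream or sys.stdout
    pub = reference_values.PUBLISHED

    delta_cost = {
        arm: pub["mean_total_cost"][arm] - pub["mean_total_cost"]["TAU"]
        for arm in INTERVENTION_ARMS
    }
    delta_qaly = {arm: pub["adjustment"][arm]["coef"] for arm in INTERVENTION_ARMS}
    icers = {arm: icer(delta_cost[arm], delta_qaly[arm]) for arm in INTERVENTION_ARMS}

    rr = {}
    for arm in INTERVENTION_ARMS:
        n_arm = pub["n_per_arm"][arm]
        n_tau = pub["n_per_arm"]["TAU"]
        events_arm = round(pub["discontinuation_12m"][arm] * n_arm)
        events_tau = round(pub["discontinuation_12m"]["TAU"] * n_tau)
        rr[arm] = discontinuation_relative_risk(
            events_arm=events_arm, n_arm=n_arm, events_tau=events_tau, n_tau=n_tau
        )

    completeness = completeness_percentage(pub["n_complete_12m"], pub["n_randomised"])

    print("Worked example: headline within-trial cost-effectiveness arithmetic", file=stream)
    print("-" * 68, file=stream)
    print(
        f"Data available at 12 months: {pub['n_complete_12m']}/{pub['n_randomised']}"
        f" ({completeness}%)",
        file=stream,
    )
    for arm in INTERVENTION_ARMS:
        print(
            f"{arm}: delta cost = {delta_cost[arm]:8.2f} EUR, "
            f"adjusted delta QALY = {delta_qaly[arm]:.4f}, "
            f"ICER = {icers[arm].value:8.2f} EUR/QALY ({icers[arm].quadrant}), "
            f"RR(discontinuation) = {rr[arm].rr:.2f} "
            f"(95% CI {rr[arm].ci_low:.2f} to {rr[arm].ci_high:.2f})",
            file=stream,
        )
    threshold = pub["threshold_eur_per_qaly"]
    for arm in INTERVENTION_ARMS:
        nmb = threshold * delta_qaly[arm] - delta_cost[arm]
        print(
            f"{arm}: NMB at {threshold:,.0f} EUR/QALY = {nmb:8.2f} EUR", file=stream
        )

    return {
        "delta_cost": {a: round(v, 2) for a, v in delta_cost.items()},
        "delta_qaly": delta_qaly,
        "icer": {a: round(icers[a].value, 2) for a in icers},
        "relative_risk": {a: round(rr[a].rr, 2) for a in rr},
        "relative_risk_ci": {
            a: (round(rr[a].ci_low, 2), round(rr[a].ci_high, 2)) for a in rr
        },
        "completeness_pct": completeness,
    }
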