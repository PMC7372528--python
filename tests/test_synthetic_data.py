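import dataclasses
import json
import math

import numpy as np
import pandas as pd
import pytest

from trialcea.cea_estimation import build_analysis_table, fit_adjustment
from trialcea.costing import UnitCostTable
from trialcea.synthetic_data import (
    SimulationConfig,
    generate_trial,
    hads_pair_from_utility,
    quantised_utility,
    true_parameters,
    write_ground_truth,
)
from trialcea.trial_data import REGIONS, completeness_summary, to_long_frame
from trialcea.utility_qaly import MappingCoefficients, map_hads_to_utility


def test_same_seed_reproduces_dataset_exactly():
    cfg = SimulationConfig()
    a = to_long_frame(generate_trial(cfg, seed=7))
    b = to_long_frame(generate_trial(cfg, seed=7))
    pd.testing.assert_frame_equal(a, b)


def test_different_seeds_differ():
    cfg = SimulationConfig()
    a = to_long_frame(generate_trial(cfg, seed=1))
    b = to_long_frame(generate_trial(cfg, seed=2))
    assert not a.equals(b)


def test_arm_sizes_cluster_structure_and_hads_range(sim_dataset):
    by_arm = {arm: sim_dataset.patients_in_arm(arm) for arm in ("SIW", "SIF", "TAU")}
    assert {a: len(p) for a, p in by_arm.items()} == {"SIW": 168, "SIF": 191, "TAU": 173}
    for p in sim_dataset.patients:
        info = sim_dataset.gp_registry[p.gp_id]
        assert (info.region, info.arm) == (p.region, p.arm)
        assert p.had_initial_visit == (p.arm != "TAU")
        for w in p.assessments:
            if w.hads_a is not None:
                assert 0 <= w.hads_a <= 21 and isinstance(w.hads_a, int)
                assert 0 <= w.hads_d <= 21


def test_zero_missing_rate_gives_full_completeness():
    cfg = dataclasses.replace(SimulationConfig(), missing_rate=0.0, seed=3)
    assert completeness_summary(generate_trial(cfg)).percentage == 100.0


def test_marginal_discontinuation_proportions_match_config():
    n = 4000
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_patients_per_arm={"SIW": n, "SIF": n, "TAU": n},
        n_gps_per_arm=50,
        seed=9,
    )
    ds = generate_trial(cfg)
    for arm in ("SIW", "SIF", "TAU"):
        group = ds.patients_in_arm(arm)
        for wave_idx, probs in ((1, cfg.discontinuation_prob_6m), (2, cfg.discontinuation_prob_12m)):
            p = probs[arm]
            observed = np.mean(
                [pt.assessments[wave_idx].benzo_product == "None" for pt in group]
            )
            tol = 3 * math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) < tol, (arm, wave_idx, observed, p)


def test_continuers_retain_their_baseline_product(sim_dataset):
    for p in sim_dataset.patients:
        base = p.assessments[0].benzo_product
        assert base != "None"  # everyone is a long-term user at entry
        for w in p.assessments[1:]:
            assert w.benzo_product in (base, "None")


def test_contact_visit_means_converge_to_configured_rates():
    n = 6000
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_patients_per_arm={"SIW": n, "SIF": n, "TAU": n},
        n_gps_per_arm=200,
        seed=13,
    )
    ds = generate_trial(cfg)
    for arm in ("SIW", "SIF", "TAU"):
        rates = cfg.contact_visit_rate[arm]
        w = cfg.region_weights
        expected = sum(w[r] * rates[r] for r in REGIONS)
        # variance: region assignment at cluster level + Poisson within
        var_region = sum(w[r] * (rates[r] - expected) ** 2 for r in REGIONS)
        tol = 3 * math.sqrt(var_region / cfg.n_gps_per_arm + expected / n)
        observed = np.mean([p.n_contact_visits for p in ds.patients_in_arm(arm)])
        assert abs(observed - expected) < tol, (arm, observed, expected)


def test_mean_baseline_utility_recovered_through_mapping(sim_dataset, coeffs):
    cfg = SimulationConfig()
    for arm in ("SIW", "SIF", "TAU"):
        target, sd = cfg.baseline_utility_mean_sd[arm]
        group = sim_dataset.patients_in_arm(arm)
        utilities = [
            map_hads_to_utility(p.assessments[0].hads_a, p.assessments[0].hads_d, coeffs)
            for p in group
            if p.assessments[0].has_hads
        ]
        tol = 3 * sd / math.sqrt(len(utilities))
        assert abs(np.mean(utilities) - target) < tol, (arm, np.mean(utilities), target)


def test_hads_inversion_round_trips_through_the_mapping(coeffs):
    # above the even-split saturation point (HADS-A hits 21 near u = -0.05)
    # the quantisation error is at most half a step per subscale
    u = np.linspace(-0.04, 1.1, 41)
    a, d = hads_pair_from_utility(u, coeffs)
    recovered = np.array(
        [map_hads_to_utility(int(ai), int(di), coeffs) for ai, di in zip(a, d)]
    )
    clipped = np.clip(u, None, 1.0)
    assert np.all(np.abs(recovered - clipped) <= 0.031)
    # the generator-side quantiser agrees with the mapping round trip everywhere
    full = np.linspace(-0.4, 1.2, 81)
    a2, d2 = hads_pair_from_utility(full, coeffs)
    via_mapping = np.array(
        [map_hads_to_utility(int(ai), int(di), coeffs) for ai, di in zip(a2, d2)]
    )
    assert np.allclose(via_mapping, quantised_utility(full, coeffs))


def test_adjusted_coefficient_calibration_at_large_n(default_costs, coeffs):
    """The latent-effect calibration makes the population value of the
    adjusted arm coefficient equal the configured target."""
    cfg = dataclasses.replace(
        SimulationConfig(),
        n_patients_per_arm={"SIW": 12000, "SIF": 12000, "TAU": 12000},
        n_gps_per_arm=300,
        missing_rate=0.0,
        seed=21,
    )
    table = build_analysis_table(generate_trial(cfg), default_costs, coeffs)
    model = fit_adjustment(table["qaly"], table["baseline_utility"], table["arm"])
    for arm in ("SIW", "SIF"):
        target = cfg.arm_utility_effect[arm]
        assert abs(model.params[arm] - target) < 3 * model.bse[arm], (
            arm, model.params[arm], target,
        )


class TestTrueParameters:
    def test_default_targets_are_the_configured_gains(self):
        truth = true_parameters(SimulationConfig())
        assert truth.delta_qaly == {"SIW": 0.0144, "SIF": 0.0340}

    def test_zero_effects_give_zero_delta_qaly(self):
        cfg = dataclasses.replace(
            SimulationConfig(), arm_utility_effect={"SIW": 0.0, "SIF": 0.0}
        )
        assert true_parameters(cfg).delta_qaly == {"SIW": 0.0, "SIF": 0.0}

    def test_delta_cost_reduces_to_initial_visit_expectation(self):
        """With identical contact rates, product mixes and discontinuation
        across arms and zero workshop costs, the only cost difference is the
        per-protocol initial visit."""
        cfg = SimulationConfig()
        tau_rates = cfg.contact_visit_rate["TAU"]
        cfg = dataclasses.replace(
            cfg,
            contact_visit_rate={a: dict(tau_rates) for a in ("SIW", "SIF", "TAU")},
            product_mix={a: dict(cfg.product_mix["TAU"]) for a in ("SIW", "SIF", "TAU")},
            discontinuation_prob_6m={a: 0.2 for a in ("SIW", "SIF", "TAU")},
            discontinuation_prob_12m={a: 0.3 for a in ("SIW", "SIF", "TAU")},
        )
        costs = UnitCostTable.defaults()
        costs = dataclasses.replace(
            costs, workshop_cost={k: 0.0 for k in costs.workshop_cost}
        )
        truth = true_parameters(cfg, costs=costs)
        w = cfg.region_weights
        expected_initial = (
            w["Balearic"] * 62.0 + w["Catalunya"] * 40.0 + w["Valencia"] * 56.39
        )
        for arm in ("SIW", "SIF"):
            assert truth.delta_cost[arm] == pytest.approx(expected_initial, abs=1e-9)

    def test_monte_carlo_costs_match_closed_form(self, default_costs, coeffs):
        cfg = dataclasses.replace(
            SimulationConfig(),
            n_patients_per_arm={"SIW": 5000, "SIF": 5000, "TAU": 5000},
            n_gps_per_arm=150,
            seed=17,
        )
        truth = true_parameters(cfg)
        table = build_analysis_table(generate_trial(cfg), default_costs, coeffs)
        means = table.groupby("arm")["total_cost"].mean()
        for arm in ("SIW", "SIF", "TAU"):
            sd = table.loc[table["arm"] == arm, "total_cost"].std()
            # cluster-level region assignment dominates the MC error
            tol = 4 * sd / math.sqrt(cfg.n_gps_per_arm)
            assert abs(means[arm] - truth.expected_total_cost[arm]) < tol


def test_ground_truth_sidecar(tmp_path):
    cfg = SimulationConfig()
    path = tmp_path / "truth.json"
    write_ground_truth(cfg, path)
    payload = json.loads(path.read_text())
    assert payload["delta_qaly"] == {"SIW": 0.0144, "SIF": 0.0340}
    assert set(payload["delta_cost"]) == {"SIW", "SIF"}


def test_config_yaml_round_trip(tmp_path):
    cfg = dataclasses.replace(SimulationConfig(), seed=99, missing_rate=0.1)
    path = tmp_path / "sim.yaml"
    cfg.to_yaml(path)
    back = SimulationConfig.from_yaml(path)
    assert back == cfg


def test_invalid_probabilities_rejected():
    with pytest.raises(ValueError):
        dataclasses.replace(
            SimulationConfig(), discontinuation_prob_12m={"SIW": 1.2, "SIF": 0.4, "TAU": 0.1}
        )
    with pytest.raises(ValueError):
        dataclasses.replace(SimulationConfig(), missing_rate=-0.1)
    bad_mapping = MappingCoefficients(intercept=1.0, coef_hads_a=0.02, coef_hads_d=-0.03)
    with pytest.raises(ValueError, match="slopes"):
        dataclasses.replace(SimulationConfig(), mapping=bad_mapping)
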