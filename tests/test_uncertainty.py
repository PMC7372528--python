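import math

import numpy as np
import pytest

from trialcea.cea_estimation import build_analysis_table, fit_adjustment
from trialcea.trial_data import TrialDataset
from trialcea.uncertainty import (
    BootstrapReplicates,
    _fast_adjusted_deltas,
    bootstrap_from_table,
    ceac,
    confidence_ellipse,
    probability_cost_effective,
)

from conftest import make_patient


@pytest.fixture(scope="module")
def sim_table(sim_dataset, default_costs, coeffs):
    return build_analysis_table(sim_dataset, default_costs, coeffs)


def _degenerate_replicates(dc=117.94, de=0.0144, B=200):
    draws = np.tile([dc, de], (B, 1))
    return BootstrapReplicates(
        B=B,
        draws={"SIW": draws.copy(), "SIF": draws.copy()},
        seed=0,
        resample_unit="patient",
        adjusted=True,
    )


class TestBootstrap:
    def test_seeded_determinism(self, sim_table):
        a = bootstrap_from_table(sim_table, B=10, seed=5)
        b = bootstrap_from_table(sim_table, B=10, seed=5)
        for arm in a.draws:
            np.testing.assert_array_equal(a.draws[arm], b.draws[arm])

    def test_cluster_resampling_differs_and_is_deterministic(self, sim_table):
        a = bootstrap_from_table(sim_table, B=10, seed=5, resample_unit="gp_cluster")
        b = bootstrap_from_table(sim_table, B=10, seed=5, resample_unit="gp_cluster")
        c = bootstrap_from_table(sim_table, B=10, seed=5, resample_unit="patient")
        np.testing.assert_array_equal(a.draws["SIF"], b.draws["SIF"])
        assert not np.array_equal(a.draws["SIF"], c.draws["SIF"])

    def test_identical_patients_give_point_mass(self, default_costs, coeffs):
        patients = []
        for arm, contacts in (("SIW", 3.0), ("SIF", 6.0), ("TAU", 2.0)):
            hads = ((4, 4), (3, 3), (2, 2)) if arm != "TAU" else ((5, 5), (5, 5), (5, 5))
            for i in range(8):
                patients.append(
                    make_patient(f"{arm}{i}", arm=arm, contacts=contacts, hads=hads)
                )
        table = build_analysis_table(
            TrialDataset.from_patients(patients), default_costs, coeffs
        )
        reps = bootstrap_from_table(table, B=25, seed=3, adjusted=False)
        for arm in ("SIW", "SIF"):
            assert np.ptp(reps.draws[arm], axis=0) == pytest.approx((0.0, 0.0))

    def test_bootstrap_mean_matches_point_estimate(self, sim_table):
        B = 400
        reps = bootstrap_from_table(sim_table, B=B, seed=11)
        model = fit_adjustment(
            sim_table["qaly"], sim_table["baseline_utility"], sim_table["arm"]
        )
        for arm in ("SIW", "SIF"):
            de = reps.draws[arm][:, 1]
            mc_se = de.std(ddof=1) / math.sqrt(B)
            assert abs(de.mean() - model.params[arm]) < 3 * mc_se

    def test_fast_refit_matches_statsmodels_on_full_data(self, sim_table):
        idx = np.arange(len(sim_table))
        arm_code = sim_table["arm"].map({"TAU": 0, "SIW": 1, "SIF": 2}).to_numpy()
        deltas = _fast_adjusted_deltas(
            sim_table["total_cost"].to_numpy(float),
            sim_table["qaly"].to_numpy(float),
            sim_table["baseline_utility"].to_numpy(float),
            arm_code,
            idx,
        )
        model = fit_adjustment(
            sim_table["qaly"], sim_table["baseline_utility"], sim_table["arm"]
        )
        mean_cost = sim_table.groupby("arm")["total_cost"].mean()
        assert deltas[0][1] == pytest.approx(model.params["SIW"], abs=1e-10)
        assert deltas[1][1] == pytest.approx(model.params["SIF"], abs=1e-10)
        assert deltas[0][0] == pytest.approx(mean_cost["SIW"] - mean_cost["TAU"])

    def test_invalid_arguments(self, sim_table):
        with pytest.raises(ValueError):
            bootstrap_from_table(sim_table, B=0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_from_table(sim_table, B=5, seed=1, resample_unit="region")


class TestEllipse:
    def test_chi_square_scaling_on_whitened_draws(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(500, 2))
        x = x - x.mean(axis=0)
        # whiten so the sample covariance is exactly the identity
        cov = np.cov(x, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        x = x @ evecs / np.sqrt(evals)
        reps = BootstrapReplicates(
            B=500, draws={"SIW": x, "SIF": x.copy()}, seed=0,
            resample_unit="patient", adjusted=True,
        )
        spec = confidence_ellipse(reps)["SIW"]
        expected = math.sqrt(-2.0 * math.log(0.05))
        for axis in spec.semi_axes[0.95]:
            assert abs(axis - expected) < 1e-6

    def test_nested_levels_have_nested_areas(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=300, seed=2)
        spec = confidence_ellipse(reps)["SIF"]
        assert spec.area(0.50) < spec.area(0.75) < spec.area(0.95)

    def test_monte_carlo_coverage_of_95_contour(self):
        rng = np.random.default_rng(42)
        n = 100_000
        cov = np.array([[4.0, 1.2], [1.2, 1.0]])
        chol = np.linalg.cholesky(cov)
        draws = rng.normal(size=(n, 2)) @ chol.T + np.array([100.0, 0.02])
        reps = BootstrapReplicates(
            B=n, draws={"SIW": draws, "SIF": draws}, seed=0,
            resample_unit="patient", adjusted=True,
        )
        spec = confidence_ellipse(reps)["SIW"]
        from scipy.stats import chi2

        inside = np.mean(spec.mahalanobis_sq(draws) <= chi2.ppf(0.95, 2))
        assert abs(inside - 0.95) < 3 * math.sqrt(0.95 * 0.05 / n)

    def test_affine_cost_rescaling_equivariance(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=200, seed=8)
        spec = confidence_ellipse(reps)["SIW"]
        scaled_draws = {a: d * np.array([10.0, 1.0]) for a, d in reps.draws.items()}
        reps2 = BootstrapReplicates(
            B=200, draws=scaled_draws, seed=8, resample_unit="patient", adjusted=True
        )
        spec2 = confidence_ellipse(reps2)["SIW"]
        lo1, hi1 = spec.marginal_interval(0.95, 0)
        lo2, hi2 = spec2.marginal_interval(0.95, 0)
        assert (lo2, hi2) == pytest.approx((10 * lo1, 10 * hi1))

    def test_degenerate_covariance_flagged(self):
        reps = _degenerate_replicates()
        spec = confidence_ellipse(reps)["SIW"]
        assert spec.degenerate
        assert spec.semi_axes[0.95][1] == pytest.approx(0.0, abs=1e-8)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(ValueError):
            confidence_ellipse(_degenerate_replicates(B=2))


class TestCeac:
    def test_degenerate_draws_step_exactly_at_the_icer(self):
        reps = _degenerate_replicates(117.94, 0.0144)
        curve = ceac(reps)["SIW"]
        # the ICER is 8190.277...; strictly above it NMB > 0
        assert probability_cost_effective(curve, 8190.27) == 0.0
        assert probability_cost_effective(curve, 8190.28) == 1.0
        assert np.all((curve.probability == 0.0) | (curve.probability == 1.0))

    def test_probabilities_bounded_and_limits(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=300, seed=4)
        curve = ceac(reps)["SIF"]
        assert np.all((curve.probability >= 0) & (curve.probability <= 1))
        d = reps.draws["SIF"]
        assert curve.probability[0] == pytest.approx(np.mean(d[:, 0] < 0))
        assert probability_cost_effective(curve, 1e12) == pytest.approx(
            np.mean(d[:, 1] > 0)
        )

    def test_all_dominant_draws_give_unit_curve(self):
        reps = _degenerate_replicates(-5.0, 0.01)
        curve = ceac(reps)["SIW"]
        assert np.all(curve.probability == 1.0)

    def test_exact_off_grid_recomputation(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=100, seed=6)
        curve = ceac(reps, np.array([0.0, 50_000.0]))["SIW"]
        lam = 12_345.6
        d = reps.draws["SIW"]
        assert curve.probability_at(lam) == pytest.approx(
            np.mean(lam * d[:, 1] - d[:, 0] > 0)
        )

    def test_invalid_grid_rejected(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=10, seed=1)
        with pytest.raises(ValueError):
            ceac(reps, np.array([100.0, 50.0]))
        with pytest.raises(ValueError):
            ceac(reps, np.array([-5.0, 10.0]))

    def test_tidy_export(self, sim_table):
        reps = bootstrap_from_table(sim_table, B=10, seed=1)
        frame = reps.to_frame()
        assert set(frame.columns) == {"b", "arm", "delta_cost", "delta_qaly"}
        assert len(frame) == 20
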