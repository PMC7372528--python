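import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea.costing import (
    UnitCostTable,
    WorkshopAllocation,
    arm_cost_summary,
    cost_patient,
    drug_cost,
    visit_costs,
    workshop_share,
)
from trialcea.trial_data import TrialDataset

from conftest import make_patient


class TestWorkshopShare:
    def test_hand_arithmetic(self):
        # one Balearic workshop trained 3 GPs, each treating 1 patient
        assert workshop_share(468.0, 3.0, 1.0) == pytest.approx(156.0)

    def test_zero_cost_is_zero_regardless_of_denominators(self):
        assert workshop_share(0.0, 0.0, 0.0) == 0.0

    def test_nonpositive_denominator_raises(self):
        with pytest.raises(ValueError):
            workshop_share(100.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            workshop_share(100.0, 3.0, -1.0)

    def test_tau_share_is_zero(self, default_costs):
        tau = make_patient("T", arm="TAU")
        alloc = WorkshopAllocation.from_dataset(TrialDataset.from_patients([tau]))
        assert alloc.share_for(tau, default_costs) == 0.0


class TestVisitCosts:
    def test_published_contact_cost_means(self, default_costs):
        # mean contact counts x the 32 EUR Balearic follow-up tariff
        siw = make_patient("S", arm="SIW", region="Balearic", contacts=3.298)
        sif = make_patient("F", arm="SIF", region="Balearic", contacts=6.651)
        assert visit_costs(siw, default_costs)[1] == pytest.approx(105.54, abs=0.01)
        assert visit_costs(sif, default_costs)[1] == pytest.approx(212.83, abs=0.01)

    def test_initial_visit_only_when_protocol_visit_happened(self, default_costs):
        tau = make_patient("T", arm="TAU", region="Balearic", contacts=0.0)
        assert visit_costs(tau, default_costs) == (0.0, 0.0)
        siw = make_patient("S", arm="SIW", region="Valencia", contacts=0.0)
        assert visit_costs(siw, default_costs)[0] == pytest.approx(56.39)

    def test_unknown_region_raises_lookup_error(self, default_costs):
        p = make_patient("S", arm="SIW")
        p.region = "Andalusia"
        with pytest.raises(LookupError):
            visit_costs(p, default_costs)


class TestDrugCost:
    def test_no_consumption_is_zero(self, default_costs):
        p = make_patient("P", products=("None", "None", "None"))
        assert drug_cost(p, default_costs) == 0.0

    def test_constant_consumption_trapezoid(self, default_costs):
        p = make_patient("P")  # Lorazepam at 1.7/month throughout
        assert drug_cost(p, default_costs, "trapezoid") == pytest.approx(20.40)

    def test_baseline_only_trapezoid(self, default_costs):
        p = make_patient("P", products=("Lorazepam", "None", "None"))
        assert drug_cost(p, default_costs, "trapezoid") == pytest.approx(5.10)

    def test_carry_forward_holds_cost_until_next_assessment(self, default_costs):
        p = make_patient("P", products=("Lorazepam", "None", "Lorazepam"))
        # 6 months at 1.7, then 6 months at 0; the final wave adds nothing
        assert drug_cost(p, default_costs, "carry_forward") == pytest.approx(10.20)

    def test_snapshot_sum_charges_one_month_per_wave(self, default_costs):
        p = make_patient("P", products=("Lorazepam", "None", "Zolpidem"))
        assert drug_cost(p, default_costs, "snapshot_sum") == pytest.approx(1.7 + 2.8)

    def test_constant_limit_equivalence(self, default_costs):
        p = make_patient("P", products=("Diazepam", "Diazepam", "Diazepam"))
        assert drug_cost(p, default_costs, "trapezoid") == pytest.approx(
            drug_cost(p, default_costs, "carry_forward")
        )

    def test_override_wins_over_table(self, default_costs):
        p = make_patient("P")
        for w in p.assessments:
            w.benzo_monthly_cost_override = 5.0
        assert drug_cost(p, default_costs) == pytest.approx(60.0)

    def test_unknown_product_without_override_raises(self, default_costs):
        costs = dataclasses.replace(default_costs, drug_monthly_cost={"None": 0.0})
        p = make_patient("P")
        with pytest.raises(LookupError):
            drug_cost(p, costs)

    def test_unknown_rule_rejected(self, default_costs):
        with pytest.raises(ValueError):
            drug_cost(make_patient("P"), default_costs, "midpoint")


class TestCostPatient:
    def test_published_tau_contact_cost(self, default_costs):
        tau = make_patient("T", arm="TAU", region="Balearic", contacts=3.576,
                           products=("None", "None", "None"))
        bd = cost_patient(tau, default_costs)
        assert bd.contact_visits == pytest.approx(114.43, abs=0.01)

    def test_all_zero_resource_use(self, default_costs):
        p = make_patient("T", arm="TAU", contacts=0.0, products=("None",) * 3)
        assert cost_patient(p, default_costs).total == 0.0

    def test_total_is_exact_sum_of_components(self, default_costs):
        p = make_patient("S", arm="SIW", contacts=4.0)
        ds = TrialDataset.from_patients([p])
        bd = cost_patient(p, default_costs, WorkshopAllocation.from_dataset(ds))
        assert bd.total == pytest.approx(
            bd.workshop_share + bd.initial_visit + bd.contact_visits + bd.drug_cost,
            abs=1e-9,
        )
        assert min(bd.workshop_share, bd.initial_visit, bd.contact_visits, bd.drug_cost) >= 0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(k=st.floats(min_value=0.1, max_value=10.0, allow_nan=False))
    def test_homogeneity_in_unit_costs(self, default_costs, k):
        """Scaling every unit cost by k scales every patient total by k."""
        p = make_patient("S", arm="SIW", contacts=3.5)
        ds = TrialDataset.from_patients([p])
        alloc = WorkshopAllocation.from_dataset(ds)
        base = cost_patient(p, default_costs, alloc).total
        scaled = cost_patient(p, default_costs.scaled(k), alloc).total
        assert scaled == pytest.approx(k * base, rel=1e-12)


class TestArmCostSummary:
    def _dataset(self):
        patients = [
            make_patient("S1", arm="SIW", contacts=3.0),
            make_patient("S2", arm="SIW", contacts=5.0),
            make_patient("F1", arm="SIF", contacts=6.0),
            make_patient("T1", arm="TAU", contacts=2.0),
            make_patient("T2", arm="TAU", contacts=4.0),
        ]
        return TrialDataset.from_patients(patients)

    def test_incremental_is_mean_difference_vs_tau(self, default_costs):
        summary = arm_cost_summary(self._dataset(), default_costs)
        means = summary.means
        for arm in ("SIW", "SIF"):
            assert summary.incremental_vs_tau[arm] == pytest.approx(
                means.loc[arm, "total"] - means.loc["TAU", "total"]
            )

    def test_constant_shift_cancels_in_incrementals(self, default_costs):
        """One extra contact for everyone (single region) shifts all arm means
        equally, leaving incrementals unchanged."""
        base = arm_cost_summary(self._dataset(), default_costs)
        shifted_patients = []
        for p in self._dataset().patients:
            q = make_patient(p.patient_id, arm=p.arm, contacts=p.n_contact_visits + 1.0)
            shifted_patients.append(q)
        shifted = arm_cost_summary(
            TrialDataset.from_patients(shifted_patients), default_costs
        )
        for arm in ("SIW", "SIF"):
            assert shifted.incremental_vs_tau[arm] == pytest.approx(
                base.incremental_vs_tau[arm], abs=1e-9
            )

    def test_identical_arms_give_zero_incremental(self, default_costs):
        patients = [
            make_patient("S", arm="SIW", contacts=3.0, initial=False),
            make_patient("F", arm="SIF", contacts=3.0, initial=False),
            make_patient("T", arm="TAU", contacts=3.0),
        ]
        ds = TrialDataset.from_patients(patients)
        costs = dataclasses.replace(
            default_costs,
            workshop_cost={k: 0.0 for k in default_costs.workshop_cost},
        )
        summary = arm_cost_summary(ds, costs)
        for arm in ("SIW", "SIF"):
            assert summary.incremental_vs_tau[arm] == pytest.approx(0.0, abs=1e-9)

    def test_missing_tau_arm_raises(self, default_costs):
        ds = TrialDataset.from_patients([make_patient("S", arm="SIW")])
        with pytest.raises(ValueError):
            arm_cost_summary(ds, default_costs)
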