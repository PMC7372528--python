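"""Per-patient 12-month costing from the health-system perspective.

Four components make up a patient's cost: a share of the GP training-workshop
cost (spread over the patients the GP treated during the trial), the
per-protocol initial cessation visit, follow-up contact visits, and the cost
of benzodiazepine consumed over the year.  Visit tariffs differ by region and
visit type; drug costs are per-product monthly reference prices.  Monetary
arithmetic is kept unrounded internally; rounding to cents happens only at
reporting time.  All costs are euro at 2013 prices.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .trial_data import ARMS, REGIONS, PatientRecord, TrialDataset

__all__ = [
    "UnitCostTable",
    "WorkshopAllocation",
    "PatientCostBreakdown",
    "ArmCostSummary",
    "ATTRIBUTION_RULES",
    "workshop_share",
    "visit_costs",
    "drug_cost",
    "cost_patient",
    "arm_cost_summary",
]

ATTRIBUTION_RULES = ("trapezoid", "carry_forward", "snapshot_sum")

MONTHS_PER_YEAR = 12.0

# Region-specific visit tariffs and monthly reference prices for the commonly
# prescribed products, published by the regional bulletins / AEMPS for the
# 2013 price year.
_DEFAULT_INITIAL_VISIT = {"Balearic": 62.0, "Catalunya": 40.0, "Valencia": 56.39}
_DEFAULT_FOLLOWUP_VISIT = {"Balearic": 32.0, "Catalunya": 40.0, "Valencia": 28.76}
_DEFAULT_DRUG_MONTHLY = {
    "Alprazolam": 2.1,
    "Diazepam": 1.9,
    "Lormetazepam": 2.0,
    "Lorazepam": 1.7,
    "Zolpidem": 2.8,
    "Other": 1.81,
    "None": 0.0,
}
# Cost of one GP training workshop by region and arm (TAU has no workshop).
_DEFAULT_WORKSHOP = {
    ("Balearic", "SIW"): 468.0,
    ("Catalunya", "SIW"): 466.0,
    ("Valencia", "SIW"): 462.0,
    ("Balearic", "SIF"): 543.0,
    ("Catalunya", "SIF"): 541.0,
    ("Valencia", "SIF"): 543.0,
    ("Balearic", "TAU"): 0.0,
    ("Catalunya", "TAU"): 0.0,
    ("Valencia", "TAU"): 0.0,
}
# Mean number of GPs attending one workshop, by region and arm.
_DEFAULT_GPS_PER_WORKSHOP = {
    ("Balearic", "SIW"): 3.0,
    ("Catalunya", "SIW"): 4.5,
    ("Valencia", "SIW"): 2.0,
    ("Balearic", "SIF"): 3.0,
    ("Catalunya", "SIF"): 4.0,
    ("Valencia", "SIF"): 3.0,
    ("Balearic", "TAU"): 3.0,
    ("Catalunya", "TAU"): 5.5,
    ("Valencia", "TAU"): 1.7,
}


@dataclass
class UnitCostTable:
    """Unit costs: visit tariffs by region, monthly drug prices, workshop costs.

    ``currency_multipliers`` are exposed verbatim for reporting-time
    conversion; they are never applied inside the analysis.
    """

    initial_visit_cost: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INITIAL_VISIT)
    )
    followup_visit_cost: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FOLLOWUP_VISIT)
    )
    drug_monthly_cost: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DRUG_MONTHLY)
    )
    workshop_cost: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_WORKSHOP)
    )
    trainer_hourly_rate: float = 75.0
    price_year: int = 2013
    currency_multipliers: dict[str, float] = field(
        default_factory=lambda: {"GBP_per_EUR": 0.8141, "GBP_per_USD": 0.6325}
    )

    def __post_init__(self) -> None:
        for name, table in (
            ("initial_visit_cost", self.initial_visit_cost),
            ("followup_visit_cost", self.followup_visit_cost),
            ("drug_monthly_cost", self.drug_monthly_cost),
            ("workshop_cost", self.workshop_cost),
        ):
            for key, value in table.items():
                if value < 0:
                    raise ValueError(f"{name}[{key!r}] = {value} must be >= 0")

    @classmethod
    def defaults(cls) -> "UnitCostTable":
        return cls()

    def with_followup_override(self, region: str, tariff: float) -> "UnitCostTable":
        """Return a copy with one region's follow-up tariff replaced.

        The published per-arm follow-up cost means for Valencia are consistent
        with a ~€40 tariff rather than the €28.76 one in the unit-cost table;
        this hook lets either reading be configured explicitly instead of the
        package silently choosing one.
        """
        new = dict(self.followup_visit_cost)
        new[region] = float(tariff)
        return replace(self, followup_visit_cost=new)

    def scaled(self, k: float) -> "UnitCostTable":
        """Every unit cost multiplied by ``k`` (used by homogeneity checks)."""
        return replace(
            self,
            initial_visit_cost={r: c * k for r, c in self.initial_visit_cost.items()},
            followup_visit_cost={r: c * k for r, c in self.followup_visit_cost.items()},
            drug_monthly_cost={p: c * k for p, c in self.drug_monthly_cost.items()},
            workshop_cost={key: c * k for key, c in self.workshop_cost.items()},
        )

    # --- serialisation -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "initial_visit_cost": self.initial_visit_cost,
            "followup_visit_cost": self.followup_visit_cost,
            "drug_monthly_cost": self.drug_monthly_cost,
            "workshop_cost": {f"{r}/{a}": c for (r, a), c in self.workshop_cost.items()},
            "trainer_hourly_rate": self.trainer_hourly_rate,
            "price_year": self.price_year,
            "currency_multipliers": self.currency_multipliers,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "UnitCostTable":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        workshop = {
            tuple(key.split("/")): float(c)
            for key, c in payload.get("workshop_cost", {}).items()
        }
        defaults = cls()
        return cls(
            initial_visit_cost=payload.get("initial_visit_cost", defaults.initial_visit_cost),
            followup_visit_cost=payload.get("followup_visit_cost", defaults.followup_visit_cost),
            drug_monthly_cost=payload.get("drug_monthly_cost", defaults.drug_monthly_cost),
            workshop_cost=workshop or defaults.workshop_cost,
            trainer_hourly_rate=payload.get("trainer_hourly_rate", 75.0),
            price_year=payload.get("price_year", 2013),
            currency_multipliers=payload.get(
                "currency_multipliers", defaults.currency_multipliers
            ),
        )


@dataclass
class WorkshopAllocation:
    """Context for spreading workshop costs over patients.

    The share charged to a patient is
    ``workshop_cost(region, arm) / (gps_per_workshop(region, arm) * patients_per_gp)``
    with ``patients_per_gp`` taken from the GP registry when available and
    falling back to the arm-level average otherwise.
    """

    gps_per_workshop: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_GPS_PER_WORKSHOP)
    )
    patients_per_gp: dict[str, float] = field(default_factory=dict)
    arm_mean_patients_per_gp: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_dataset(
        cls,
        dataset: TrialDataset,
        gps_per_workshop: dict[tuple[str, str], float] | None = None,
    ) -> "WorkshopAllocation":
        per_gp = {
            gp_id: float(info.n_patients_treated)
            for gp_id, info in dataset.gp_registry.items()
        }
        arm_means: dict[str, float] = {}
        for arm in ARMS:
            gps = [i for i in dataset.gp_registry.values() if i.arm == arm]
            if gps:
                arm_means[arm] = sum(i.n_patients_treated for i in gps) / len(gps)
        return cls(
            gps_per_workshop=dict(gps_per_workshop or _DEFAULT_GPS_PER_WORKSHOP),
            patients_per_gp=per_gp,
            arm_mean_patients_per_gp=arm_means,
        )

    def share_for(self, record: PatientRecord, costs: UnitCostTable) -> float:
        if record.arm == "TAU":
            return 0.0
        cost = costs.workshop_cost.get((record.region, record.arm))
        if cost is None:
            raise LookupError(
                f"no workshop cost for region={record.region!r}, arm={record.arm!r}"
            )
        gpw = self.gps_per_workshop.get((record.region, record.arm))
        if gpw is None:
            raise LookupError(
                f"no GPs-per-workshop entry for ({record.region!r}, {record.arm!r})"
            )
        ppg = self.patients_per_gp.get(record.gp_id)
        if ppg is None:
            ppg = self.arm_mean_patients_per_gp.get(record.arm)
        if ppg is None:
            raise LookupError(
                f"cannot resolve patients-per-GP for patient {record.patient_id!r}"
            )
        return workshop_share(cost, gpw, ppg)


@dataclass
class PatientCostBreakdown:
    """Euro cost components for one patient over the 12-month horizon."""

    workshop_share: float
    initial_visit: float
    contact_visits: float
    drug_cost: float
    total: float

    @classmethod
    def from_components(
        cls, workshop_share: float, initial_visit: float, contact_visits: float, drug_cost: float
    ) -> "PatientCostBreakdown":
        return cls(
            workshop_share=workshop_share,
            initial_visit=initial_visit,
            contact_visits=contact_visits,
            drug_cost=drug_cost,
            total=workshop_share + initial_visit + contact_visits + drug_cost,
        )


def workshop_share(
    workshop_cost: float, gps_per_workshop: float, patients_per_gp: float
) -> float:
    """Per-patient share of one workshop's cost.

    The training cost of a workshop is divided by the GPs it trained and then
    by the patients each GP treated during the trial.  A zero workshop cost
    yields zero regardless of the denominators.
    """
    if workshop_cost == 0:
        return 0.0
    if workshop_cost < 0:
        raise ValueError(f"workshop_cost={workshop_cost} must be >= 0")
    if gps_per_workshop <= 0 or patients_per_gp <= 0:
        raise ValueError(
            "gps_per_workshop and patients_per_gp must be > 0 "
            f"(got {gps_per_workshop}, {patients_per_gp})"
        )
    return workshop_cost / (gps_per_workshop * patients_per_gp)


def visit_costs(record: PatientRecord, costs: UnitCostTable) -> tuple[float, float]:
    """(initial-visit cost, contact-visit cost) for one patient."""
    try:
        initial_tariff = costs.initial_visit_cost[record.region]
        followup_tariff = costs.followup_visit_cost[record.region]
    except KeyError as exc:
        raise LookupError(f"no visit tariff for region {record.region!r}") from exc
    initial = initial_tariff if record.had_initial_visit else 0.0
    contacts = record.n_contact_visits * followup_tariff
    return initial, contacts


def _monthly_cost(wave, costs: UnitCostTable) -> float:
    if wave.benzo_product == "None":
        return 0.0
    if wave.benzo_monthly_cost_override is not None:
        return wave.benzo_monthly_cost_override
    try:
        return costs.drug_monthly_cost[wave.benzo_product]
    except KeyError as exc:
        raise LookupError(
            f"no monthly cost for product {wave.benzo_product!r} and no override"
        ) from exc


def drug_cost(
    record: PatientRecord, costs: UnitCostTable, attribution: str = "trapezoid"
) -> float:
    """Benzodiazepine cost over the follow-up year for one patient.

    Consumption is only observed at the three assessment waves, so the cost in
    between must be attributed by rule:

    - ``trapezoid`` (default): linear interpolation of the monthly cost
      between consecutive waves,
      ``sum(months_between * (c_k + c_{k+1}) / 2)``.
    - ``carry_forward``: each wave's monthly cost applies until the next
      assessment (the final wave carries no further months).
    - ``snapshot_sum``: one month charged per assessment wave.
    """
    if attribution not in ATTRIBUTION_RULES:
        raise ValueError(
            f"unknown attribution {attribution!r}; expected one of {ATTRIBUTION_RULES}"
        )
    waves = record.assessments
    monthly = [_monthly_cost(w, costs) for w in waves]
    if attribution == "snapshot_sum":
        return float(sum(monthly))
    total = 0.0
    for k in range(len(waves) - 1):
        months = (waves[k + 1].time_years - waves[k].time_years) * MONTHS_PER_YEAR
        if months <= 0:
            raise ValueError(f"wave times not strictly increasing for {record.patient_id}")
        if attribution == "trapezoid":
            total += months * (monthly[k] + monthly[k + 1]) / 2.0
        else:  # carry_forward
            total += months * monthly[k]
    return total


def cost_patient(
    record: PatientRecord,
    costs: UnitCostTable,
    allocation: WorkshopAllocation | None = None,
    attribution: str = "trapezoid",
) -> PatientCostBreakdown:
    """Full cost breakdown for one patient; ``total`` is the exact sum."""
    share = allocation.share_for(record, costs) if allocation is not None else 0.0
    initial, contacts = visit_costs(record, costs)
    drugs = drug_cost(record, costs, attribution)
    return PatientCostBreakdown.from_components(share, initial, contacts, drugs)


@dataclass
class ArmCostSummary:
    """Per-arm mean cost components and incremental mean totals vs TAU."""

    means: "object"  # pandas DataFrame indexed by arm
    incremental_vs_tau: dict[str, float]


def arm_cost_summary(
    dataset: TrialDataset,
    costs: UnitCostTable,
    allocation: WorkshopAllocation | None = None,
    attribution: str = "trapezoid",
) -> ArmCostSummary:
    import pandas as pd

    if allocation is None:
        allocation = WorkshopAllocation.from_dataset(dataset)
    rows = []
    for p in dataset.patients:
        bd = cost_patient(p, costs, allocation, attribution)
        rows.append(
            {
                "arm": p.arm,
                "workshop_share": bd.workshop_share,
                "initial_visit": bd.initial_visit,
                "contact_visits": bd.contact_visits,
                "drug_cost": bd.drug_cost,
                "total": bd.total,
            }
        )
    frame = pd.DataFrame(rows)
    present = [a for a in ARMS if a in set(frame["arm"])] if len(frame) else []
    if "TAU" not in present or len(present) < 2:
        raise ValueError("arm_cost_summary requires TAU plus at least one intervention arm")
    means = frame.groupby("arm").mean(numeric_only=True).reindex(present)
    means["n"] = frame.groupby("arm").size().reindex(present)
    tau_total = means.loc["TAU", "total"]
    incremental = {
        arm: float(means.loc[arm, "total"] - tau_total) for arm in present if arm != "TAU"
    }
    return ArmCostSummary(means=means, incremental_vs_tau=incremental)
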