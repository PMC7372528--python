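"""Patient-level data model for a three-arm benzodiazepine-discontinuation trial.

The trial randomised general practitioners (GPs, the clusters) in three Spanish
regions to one of three arms: treatment as usual (TAU), a structured tapering
interview with written instructions (SIW), or the same interview with scheduled
follow-up visits (SIF).  Each patient carries three assessment waves (baseline,
6 months, 12 months) with Hospital Anxiety and Depression Scale (HADS) subscale
scores and the benzodiazepine product consumed at that wave, plus the count of
follow-up GP contacts over the year and a per-protocol initial-visit flag.

Datasets round-trip losslessly through delimited text (UTF-8 CSV, "." decimal
separator), in either a long (one row per patient-wave) or wide (one row per
patient) layout.  Missing values are empty cells on disk and ``None`` in
memory — never sentinel numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ARMS",
    "REGIONS",
    "PRODUCTS",
    "WAVE_LABELS",
    "NOMINAL_TIMES",
    "AssessmentWave",
    "PatientRecord",
    "GPInfo",
    "TrialDataset",
    "SchemaError",
    "ValidationError",
    "CompletenessSummary",
    "canonical_arm",
    "canonical_region",
    "canonical_product",
    "completeness_percentage",
    "completeness_summary",
    "read_trial_csv",
    "write_trial_csv",
]

logger = logging.getLogger(__name__)

ARMS = ("TAU", "SIW", "SIF")
REGIONS = ("Balearic", "Catalunya", "Valencia")
PRODUCTS = (
    "Alprazolam",
    "Diazepam",
    "Lorazepam",
    "Lormetazepam",
    "Zolpidem",
    "Other",
    "None",
)
WAVE_LABELS = ("bl", "m6", "m12")
NOMINAL_TIMES = (0.0, 0.5, 1.0)
HADS_MIN, HADS_MAX = 0, 21

_REGION_ALIASES = {
    "balearic": "Balearic",
    "balearic islands": "Balearic",
    "baleares": "Balearic",
    "illes balears": "Balearic",
    "catalunya": "Catalunya",
    "catalonia": "Catalunya",
    "valencia": "Valencia",
    "valència": "Valencia",
}
_ARM_ALIASES = {a.lower(): a for a in ARMS}
_PRODUCT_ALIASES = {p.lower(): p for p in PRODUCTS}
_PRODUCT_ALIASES.update({"": "None", "no benzodiazepine": "None", "nan": "None"})


class SchemaError(ValueError):
    """A mandatory column is absent or the file layout cannot be recognised."""


class ValidationError(ValueError):
    """One or more rows violate the data-model invariants.

    ``diagnostics`` is a list of ``(row_index, patient_id, message)`` tuples,
    where ``row_index`` is the 0-based data-row index in the source table.
    """

    def __init__(self, diagnostics: Sequence[tuple[object, object, str]]):
        self.diagnostics = list(diagnostics)
        lines = [f"row {r} (patient {p}): {m}" for r, p, m in self.diagnostics]
        super().__init__(
            f"{len(self.diagnostics)} validation failure(s):\n" + "\n".join(lines)
        )


def canonical_region(token: object) -> str:
    key = str(token).strip().lower()
    if key not in _REGION_ALIASES:
        raise ValueError(f"unknown region token: {token!r}")
    return _REGION_ALIASES[key]


def canonical_arm(token: object) -> str:
    key = str(token).strip().lower()
    if key not in _ARM_ALIASES:
        raise ValueError(f"unknown arm token: {token!r}")
    return _ARM_ALIASES[key]


def canonical_product(token: object) -> str:
    if token is None or (isinstance(token, float) and math.isnan(token)):
        return "None"
    key = str(token).strip().lower()
    if key not in _PRODUCT_ALIASES:
        raise ValueError(f"unknown benzodiazepine product token: {token!r}")
    return _PRODUCT_ALIASES[key]


@dataclass
class AssessmentWave:
    """One assessment: time since baseline (years), HADS scores, product used.

    ``benzo_monthly_cost_override`` carries a formulation-specific monthly cost
    in euro when known; it takes precedence over the product-level unit cost.
    """

    time_years: float
    hads_a: int | None = None
    hads_d: int | None = None
    benzo_product: str = "None"
    benzo_monthly_cost_override: float | None = None

    @property
    def has_hads(self) -> bool:
        return self.hads_a is not None and self.hads_d is not None

    def validate(self) -> list[str]:
        problems = []
        for name, score in (("hads_a", self.hads_a), ("hads_d", self.hads_d)):
            if score is not None and not (HADS_MIN <= score <= HADS_MAX):
                problems.append(f"{name}={score} outside [{HADS_MIN}, {HADS_MAX}]")
        if self.time_years < 0 or not math.isfinite(self.time_years):
            problems.append(f"time_years={self.time_years} must be finite and >= 0")
        if self.benzo_product not in PRODUCTS:
            problems.append(f"unknown benzo_product {self.benzo_product!r}")
        if self.benzo_monthly_cost_override is not None and (
            self.benzo_monthly_cost_override < 0
        ):
            problems.append("benzo_monthly_cost_override must be >= 0")
        return problems


@dataclass
class PatientRecord:
    """One trial participant with exactly three time-ordered assessment waves."""

    patient_id: str
    gp_id: str
    region: str
    arm: str
    assessments: list[AssessmentWave]
    n_contact_visits: float = 0.0
    had_initial_visit: bool = False

    def validate(self) -> list[str]:
        problems = []
        if self.region not in REGIONS:
            problems.append(f"unknown region {self.region!r}")
        if self.arm not in ARMS:
            problems.append(f"unknown arm {self.arm!r}")
        if len(self.assessments) != 3:
            problems.append(f"expected 3 assessment waves, got {len(self.assessments)}")
        else:
            times = [w.time_years for w in self.assessments]
            if times[0] != 0.0:
                problems.append(f"baseline wave time_years={times[0]} must be 0")
            if not (times[0] < times[1] < times[2]):
                problems.append(f"wave times {times} not strictly increasing")
        for i, wave in enumerate(self.assessments):
            problems.extend(f"wave {i}: {p}" for p in wave.validate())
        if not (self.n_contact_visits >= 0 and math.isfinite(self.n_contact_visits)):
            problems.append(f"n_contact_visits={self.n_contact_visits} must be >= 0")
        if self.arm == "TAU" and self.had_initial_visit:
            problems.append("TAU patients cannot have a per-protocol initial visit")
        return problems

    @property
    def complete_12m(self) -> bool:
        """True when the 12-month wave has both HADS subscale scores."""
        return len(self.assessments) == 3 and self.assessments[2].has_hads

    @property
    def complete_trajectory(self) -> bool:
        return len(self.assessments) == 3 and all(w.has_hads for w in self.assessments)


@dataclass
class GPInfo:
    gp_id: str
    region: str
    arm: str
    n_patients_treated: int
    workshop_attended: bool


@dataclass
class TrialDataset:
    """Validated collection of patients plus the GP (cluster) registry."""

    patients: list[PatientRecord]
    gp_registry: dict[str, GPInfo] = field(default_factory=dict)

    @classmethod
    def from_patients(cls, patients: Iterable[PatientRecord]) -> "TrialDataset":
        patients = list(patients)
        registry: dict[str, GPInfo] = {}
        for p in patients:
            info = registry.get(p.gp_id)
            if info is None:
                registry[p.gp_id] = GPInfo(
                    gp_id=p.gp_id,
                    region=p.region,
                    arm=p.arm,
                    n_patients_treated=1,
                    workshop_attended=p.arm != "TAU",
                )
            else:
                info.n_patients_treated += 1
        return cls(patients=patients, gp_registry=registry)

    def validate(self) -> None:
        diagnostics = []
        for i, p in enumerate(self.patients):
            for msg in p.validate():
                diagnostics.append((i, p.patient_id, msg))
            info = self.gp_registry.get(p.gp_id)
            if info is None:
                diagnostics.append((i, p.patient_id, f"gp_id {p.gp_id!r} not in registry"))
            elif (info.region, info.arm) != (p.region, p.arm):
                diagnostics.append(
                    (i, p.patient_id,
                     f"gp_id {p.gp_id!r} registered as {(info.region, info.arm)} "
                     f"but patient has {(p.region, p.arm)}")
                )
        if diagnostics:
            raise ValidationError(diagnostics)

    @property
    def arms(self) -> tuple[str, ...]:
        return tuple(sorted({p.arm for p in self.patients}, key=ARMS.index))

    def patients_in_arm(self, arm: str) -> list[PatientRecord]:
        return [p for p in self.patients if p.arm == arm]

    def __len__(self) -> int:
        return len(self.patients)


# ---------------------------------------------------------------------------
# serialisation

LONG_COLUMNS = (
    "patient_id",
    "gp_id",
    "region",
    "arm",
    "had_initial_visit",
    "n_contact_visits",
    "wave",
    "time_years",
    "hads_a",
    "hads_d",
    "benzo_product",
    "benzo_cost_override",
)
_WIDE_WAVE_FIELDS = ("time_years", "hads_a", "hads_d", "benzo_product", "benzo_cost_override")
WIDE_COLUMNS = (
    "patient_id",
    "gp_id",
    "region",
    "arm",
    "had_initial_visit",
    "n_contact_visits",
) + tuple(f"{f}_{w}" for w in WAVE_LABELS for f in _WIDE_WAVE_FIELDS)


def _fmt_opt(value: object) -> object:
    return "" if value is None else value


def to_long_frame(dataset: TrialDataset) -> pd.DataFrame:
    rows = []
    for p in dataset.patients:
        for label, wave in zip(WAVE_LABELS, p.assessments):
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "gp_id": p.gp_id,
                    "region": p.region,
                    "arm": p.arm,
                    "had_initial_visit": p.had_initial_visit,
                    "n_contact_visits": p.n_contact_visits,
                    "wave": label,
                    "time_years": wave.time_years,
                    "hads_a": _fmt_opt(wave.hads_a),
                    "hads_d": _fmt_opt(wave.hads_d),
                    "benzo_product": wave.benzo_product,
                    "benzo_cost_override": _fmt_opt(wave.benzo_monthly_cost_override),
                }
            )
    return pd.DataFrame(rows, columns=list(LONG_COLUMNS))


def to_wide_frame(dataset: TrialDataset) -> pd.DataFrame:
    rows = []
    for p in dataset.patients:
        row = {
            "patient_id": p.patient_id,
            "gp_id": p.gp_id,
            "region": p.region,
            "arm": p.arm,
            "had_initial_visit": p.had_initial_visit,
            "n_contact_visits": p.n_contact_visits,
        }
        for label, wave in zip(WAVE_LABELS, p.assessments):
            row[f"time_years_{label}"] = wave.time_years
            row[f"hads_a_{label}"] = _fmt_opt(wave.hads_a)
            row[f"hads_d_{label}"] = _fmt_opt(wave.hads_d)
            row[f"benzo_product_{label}"] = wave.benzo_product
            row[f"benzo_cost_override_{label}"] = _fmt_opt(wave.benzo_monthly_cost_override)
        rows.append(row)
    return pd.DataFrame(rows, columns=list(WIDE_COLUMNS))


def _parse_opt_int(value: object, what: str) -> int | None:
    if value is None or value == "":
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    x = float(value)
    if abs(x - round(x)) > 1e-9:
        raise ValueError(f"{what}={value!r} is not an integer")
    return int(round(x))


def _parse_opt_float(value: object) -> float | None:
    if value is None or value == "":
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    key = str(value).strip().lower()
    if key in ("true", "1", "yes"):
        return True
    if key in ("false", "0", "no", ""):
        return False
    raise ValueError(f"cannot interpret {value!r} as boolean")


def _wave_from_fields(time_years, hads_a, hads_d, product, override) -> AssessmentWave:
    return AssessmentWave(
        time_years=float(time_years),
        hads_a=_parse_opt_int(hads_a, "hads_a"),
        hads_d=_parse_opt_int(hads_d, "hads_d"),
        benzo_product=canonical_product(product),
        benzo_monthly_cost_override=_parse_opt_float(override),
    )


def from_long_frame(df: pd.DataFrame) -> TrialDataset:
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    diagnostics: list[tuple[object, object, str]] = []
    patients: list[PatientRecord] = []
    wave_order = {w: i for i, w in enumerate(WAVE_LABELS)}
    for pid, group in df.groupby("patient_id", sort=False):
        first = group.iloc[0]
        row_index = group.index[0]
        try:
            waves_raw = sorted(
                group.itertuples(), key=lambda r: wave_order.get(str(r.wave), 99)
            )
            waves = [
                _wave_from_fields(
                    r.time_years, r.hads_a, r.hads_d, r.benzo_product, r.benzo_cost_override
                )
                for r in waves_raw
            ]
            record = PatientRecord(
                patient_id=str(pid),
                gp_id=str(first["gp_id"]),
                region=canonical_region(first["region"]),
                arm=canonical_arm(first["arm"]),
                assessments=waves,
                n_contact_visits=float(first["n_contact_visits"]),
                had_initial_visit=_parse_bool(first["had_initial_visit"]),
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append((row_index, pid, str(exc)))
            continue
        for msg in record.validate():
            diagnostics.append((row_index, pid, msg))
        patients.append(record)
    if diagnostics:
        raise ValidationError(diagnostics)
    return TrialDataset.from_patients(patients)


def from_wide_frame(df: pd.DataFrame) -> TrialDataset:
    missing = [c for c in WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    diagnostics: list[tuple[object, object, str]] = []
    patients: list[PatientRecord] = []
    for row_index, row in df.iterrows():
        pid = row["patient_id"]
        try:
            waves = [
                _wave_from_fields(
                    row[f"time_years_{w}"],
                    row[f"hads_a_{w}"],
                    row[f"hads_d_{w}"],
                    row[f"benzo_product_{w}"],
                    row[f"benzo_cost_override_{w}"],
                )
                for w in WAVE_LABELS
            ]
            record = PatientRecord(
                patient_id=str(pid),
                gp_id=str(row["gp_id"]),
                region=canonical_region(row["region"]),
                arm=canonical_arm(row["arm"]),
                assessments=waves,
                n_contact_visits=float(row["n_contact_visits"]),
                had_initial_visit=_parse_bool(row["had_initial_visit"]),
            )
        except (ValueError, TypeError) as exc:
            diagnostics.append((row_index, pid, str(exc)))
            continue
        for msg in record.validate():
            diagnostics.append((row_index, pid, msg))
        patients.append(record)
    if diagnostics:
        raise ValidationError(diagnostics)
    return TrialDataset.from_patients(patients)


def read_trial_csv(
    path,
    schema: Mapping[str, str] | None = None,
    layout: str = "auto",
) -> TrialDataset:
    """Read a patient-level trial CSV and return a validated :class:`TrialDataset`.

    Parameters
    ----------
    path:
        CSV file path.
    schema:
        Optional mapping from canonical column names (see ``LONG_COLUMNS`` /
        ``WIDE_COLUMNS``) to the names used in the file.
    layout:
        ``"long"`` (one row per patient-wave), ``"wide"`` (one row per
        patient), or ``"auto"`` to detect by the presence of a ``wave`` column.

    Raises
    ------
    SchemaError
        When mandatory columns are absent.
    ValidationError
        With row-indexed diagnostics when any row violates the data model.
    """
    df = pd.read_csv(path, keep_default_na=True)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    if layout == "auto":
        layout = "long" if "wave" in df.columns else "wide"
    if layout == "long":
        expected = LONG_COLUMNS
        builder = from_long_frame
    elif layout == "wide":
        expected = WIDE_COLUMNS
        builder = from_wide_frame
    else:
        raise ValueError(f"unknown layout {layout!r}")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    if df.empty:
        logger.warning("read_trial_csv: %s contains a header but no rows", path)
        return TrialDataset(patients=[], gp_registry={})
    return builder(df)


def write_trial_csv(dataset: TrialDataset, path, layout: str = "long") -> None:
    """Write a dataset as UTF-8 CSV; missing values become empty cells.

    ``read_trial_csv(write_trial_csv(d))`` reproduces ``d`` field-for-field,
    and a second write of the re-read dataset is byte-identical.
    """
    if layout == "long":
        frame = to_long_frame(dataset)
    elif layout == "wide":
        frame = to_wide_frame(dataset)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    frame.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# completeness

@dataclass
class CompletenessSummary:
    per_arm: dict[str, tuple[int, int]]  # arm -> (n_complete, n_total)
    n_complete: int
    n_total: int
    percentage: float


def completeness_percentage(n_complete: int, n_total: int, decimals: int = 1) -> float:
    if n_total == 0:
        return 0.0
    return round(100.0 * n_complete / n_total, decimals)


def completeness_summary(dataset: TrialDataset, decimals: int = 1) -> CompletenessSummary:
    """Per-arm counts of patients with 12-month data and the overall percentage.

    A patient counts as complete when the 12-month wave carries both HADS
    subscale scores (i.e. outcome data were available at the end of follow-up).
    """
    per_arm: dict[str, tuple[int, int]] = {}
    for arm in ARMS:
        group = dataset.patients_in_arm(arm)
        if not group:
            continue
        per_arm[arm] = (sum(p.complete_12m for p in group), len(group))
    n_complete = sum(c for c, _ in per_arm.values())
    n_total = sum(t for _, t in per_arm.values())
    return CompletenessSummary(
        per_arm=per_arm,
        n_complete=n_complete,
        n_total=n_total,
        percentage=completeness_percentage(n_complete, n_total, decimals),
    )
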