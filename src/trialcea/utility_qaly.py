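"""HADS-to-utility mapping and area-under-the-curve QALY estimation.

The trial measured anxiety and depression with the two HADS subscales (each
0-21, higher = worse) but no generic preference-based instrument, so generic
health-state utilities are obtained by a published regression crosswalk from
(HADS-A, HADS-D) to the EQ-5D index.  This module implements the mapping as a
configurable linear-plus-optional-quadratic form with clamping to the tariff
range, and aggregates per-wave utilities into per-patient QALYs by the
trapezoid rule over each patient's actual assessment times.

The coefficients shipped as defaults are an *illustrative* linear set — the
published crosswalk coefficients are not restated here and should be supplied
via :meth:`MappingCoefficients.from_yaml` for substantive work (see README).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .trial_data import ARMS, HADS_MAX, HADS_MIN, TrialDataset, WAVE_LABELS

__all__ = [
    "MappingCoefficients",
    "QalyRecord",
    "QalyTable",
    "map_hads_to_utility",
    "auc_qaly",
    "qaly_table",
]

# Conventional floor of the UK EQ-5D tariff (worst health state).
EQ5D_UK_FLOOR = -0.594


@dataclass
class MappingCoefficients:
    """Coefficients of the HADS -> utility crosswalk.

    utility = intercept + coef_hads_a*A + coef_hads_d*D
              + coef_hads_a_sq*A^2 + coef_hads_d_sq*D^2 + coef_interaction*A*D,
    clamped to [floor, cap].
    """

    intercept: float
    coef_hads_a: float
    coef_hads_d: float
    coef_hads_a_sq: float = 0.0
    coef_hads_d_sq: float = 0.0
    coef_interaction: float = 0.0
    floor: float = EQ5D_UK_FLOOR
    cap: float = 1.0
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.cap < self.floor:
            raise ValueError(f"cap {self.cap} < floor {self.floor}")
        for name in (
            "intercept",
            "coef_hads_a",
            "coef_hads_d",
            "coef_hads_a_sq",
            "coef_hads_d_sq",
            "coef_interaction",
        ):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @property
    def is_linear(self) -> bool:
        return (
            self.coef_hads_a_sq == 0.0
            and self.coef_hads_d_sq == 0.0
            and self.coef_interaction == 0.0
        )

    @classmethod
    def illustrative_default(cls) -> "MappingCoefficients":
        """Illustrative linear mapping, NOT the published crosswalk.

        Full health (A=D=0) maps to 1.0; each HADS-A point costs 0.025 and
        each HADS-D point 0.035 utility, giving a plausible range
        [-0.26, 1.0] over the instrument's support.
        """
        return cls(
            intercept=1.0,
            coef_hads_a=-0.025,
            coef_hads_d=-0.035,
            provenance=(
                "illustrative linear mapping bundled with trialcea; substitute "
                "the published HADS-to-EQ-5D crosswalk coefficients for "
                "substantive analyses"
            ),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MappingCoefficients":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def map_hads_to_utility(
    hads_a: int | None, hads_d: int | None, coeffs: MappingCoefficients
) -> float | None:
    """Map one (HADS-A, HADS-D) pair to a utility; ``None`` if either is missing.

    Raises ``ValueError`` when a supplied score is outside [0, 21].
    """
    if hads_a is None or hads_d is None:
        return None
    for name, score in (("hads_a", hads_a), ("hads_d", hads_d)):
        if not (HADS_MIN <= score <= HADS_MAX):
            raise ValueError(f"{name}={score} outside [{HADS_MIN}, {HADS_MAX}]")
    a = float(hads_a)
    d = float(hads_d)
    value = (
        coeffs.intercept
        + coeffs.coef_hads_a * a
        + coeffs.coef_hads_d * d
        + coeffs.coef_hads_a_sq * a * a
        + coeffs.coef_hads_d_sq * d * d
        + coeffs.coef_interaction * a * d
    )
    return float(min(max(value, coeffs.floor), coeffs.cap))


def auc_qaly(times_years, utilities) -> float | None:
    """Trapezoid-rule QALY over one patient's utility trajectory.

    Returns ``None`` when any utility is missing.  Times must be strictly
    increasing; at least two waves are required.  Negative utilities (states
    worse than dead) integrate to negative QALY contributions.
    """
    t = list(times_years)
    u = list(utilities)
    if len(t) != len(u):
        raise ValueError("times and utilities differ in length")
    if len(t) < 2:
        raise ValueError("need at least two waves for an AUC QALY")
    if any(t[i] >= t[i + 1] for i in range(len(t) - 1)):
        raise ValueError(f"times {t} not strictly increasing")
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in u):
        return None
    return float(np.trapezoid(np.asarray(u, dtype=float), np.asarray(t, dtype=float)))


@dataclass
class QalyRecord:
    """Per-patient utilities, assessment times, and the AUC QALY."""

    patient_id: str
    arm: str
    times_years: tuple[float, ...]
    utilities: tuple[float | None, ...]
    qaly: float | None
    complete: bool


@dataclass
class QalyTable:
    """Per-patient QALY records with per-arm unadjusted summaries."""

    records: list[QalyRecord]
    frame: pd.DataFrame
    utility_summary: pd.DataFrame
    qaly_summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _summary_stats(values: pd.Series) -> dict[str, float]:
    values = values.dropna()
    if values.empty:
        return {"mean": math.nan, "sd": math.nan, "median": math.nan,
                "min": math.nan, "max": math.nan, "n": 0}
    return {
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "median": float(values.median()),
        "min": float(values.min()),
        "max": float(values.max()),
        "n": int(len(values)),
    }


def qaly_table(dataset: TrialDataset, coeffs: MappingCoefficients) -> QalyTable:
    """Map every wave to a utility and aggregate to per-patient QALYs.

    Wave-level utility summaries use all patients with that wave observed;
    QALYs are complete-case (all three waves observed).  Missingness is
    reported through the Ns, never imputed here.
    """
    records: list[QalyRecord] = []
    rows = []
    for p in dataset.patients:
        times = tuple(w.time_years for w in p.assessments)
        utilities = tuple(
            map_hads_to_utility(w.hads_a, w.hads_d, coeffs) for w in p.assessments
        )
        complete = all(u is not None for u in utilities)
        qaly = auc_qaly(times, utilities) if complete else None
        records.append(
            QalyRecord(
                patient_id=p.patient_id,
                arm=p.arm,
                times_years=times,
                utilities=utilities,
                qaly=qaly,
                complete=complete,
            )
        )
        row = {"patient_id": p.patient_id, "arm": p.arm}
        for label, t, u in zip(WAVE_LABELS, times, utilities):
            row[f"time_{label}"] = t
            row[f"utility_{label}"] = math.nan if u is None else u
        row["qaly"] = math.nan if qaly is None else qaly
        row["complete"] = complete
        rows.append(row)
    frame = pd.DataFrame(rows)

    present_arms = [a for a in ARMS if a in set(frame["arm"])] if len(frame) else []
    util_rows = []
    qaly_rows = []
    for arm in present_arms:
        sub = frame[frame["arm"] == arm]
        for label in WAVE_LABELS:
            util_rows.append(
                {"arm": arm, "wave": label, **_summary_stats(sub[f"utility_{label}"])}
            )
        qaly_rows.append({"arm": arm, **_summary_stats(sub["qaly"])})
    return QalyTable(
        records=records,
        frame=frame,
        utility_summary=pd.DataFrame(util_rows),
        qaly_summary=pd.DataFrame(qaly_rows),
    )
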