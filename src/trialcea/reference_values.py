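"""Published results of the source economic evaluation, bundled as fixtures.

The benzodiazepine-discontinuation trial whose analysis this package
re-implements deposited its patient-level data in a public archive; that
deposit is *not* bundled here.  What is bundled are the study's printed
summary numbers — unit costs, arm-level resource use and cost means, utility
and QALY summaries, the adjusted regression, and the headline
cost-effectiveness results — so that the worked example and the arithmetic
checks run without any external data.

Quantities that depend on the patient-level deposit (arm-level utility/QALY
distributions, the regression fit on real data, the acceptability-curve
probabilities 0.7983 / 0.9777) are recorded here as documented reference
values only; :func:`load_study_deposit` reproduces them when a user supplies
the deposited patient-level CSV.
"""

from __future__ import annotations

import os

from .trial_data import TrialDataset, read_trial_csv

__all__ = ["PUBLISHED", "load_study_deposit"]


PUBLISHED: dict = {
    # data availability at 12 months
    "n_complete_12m": 523,
    "n_randomised": 532,
    # per-arm sample sizes at baseline
    "n_per_arm": {"SIW": 168, "SIF": 191, "TAU": 173},
    # crude 12-month discontinuation proportions (share with no benzodiazepine)
    "discontinuation_12m": {"SIW": 0.452, "SIF": 0.450, "TAU": 0.150},
    "relative_risk_ci": {"SIW": (2.03, 4.46), "SIF": (2.04, 4.40)},
    # arm-level mean total cost per patient over 12 months (euro, 2013)
    "mean_total_cost": {"SIW": 201.05, "SIF": 301.51, "TAU": 83.11},
    "mean_total_cost_n": {"SIW": 149, "SIF": 173, "TAU": 152},
    # adjusted QALY regression: QALY ~ baseline utility + arm indicators
    "adjustment": {
        "Constant": {"coef": 0.2020, "se": 0.0290, "ci": (0.1453, 0.2588)},
        "Baseline utility": {"coef": 0.8658, "se": 0.0356, "ci": (0.796, 0.9357)},
        "SIW": {"coef": 0.0144, "se": 0.0143, "ci": (-0.0137, 0.0425)},
        "SIF": {"coef": 0.0340, "se": 0.0138, "ci": (0.0069, 0.0612)},
        "n": 463,
        "r_squared": 0.5606,
    },
    # unadjusted utility summaries by arm and wave: (mean, sd, median, min, max, n)
    "utility_summary": {
        "SIW": {
            "bl": (0.749, 0.165, 0.775, 0.257, 1.000, 160),
            "m6": (0.795, 0.152, 0.826, 0.346, 1.000, 159),
            "m12": (0.817, 0.174, 0.875, 0.224, 1.000, 155),
        },
        "SIF": {
            "bl": (0.731, 0.154, 0.744, 0.273, 1.000, 184),
            "m6": (0.799, 0.156, 0.834, 0.289, 1.000, 186),
            "m12": (0.811, 0.166, 0.850, 0.173, 1.000, 178),
        },
        "TAU": {
            "bl": (0.758, 0.158, 0.773, 0.338, 1.000, 168),
            "m6": (0.784, 0.152, 0.816, 0.346, 1.000, 171),
            "m12": (0.804, 0.163, 0.834, 0.349, 1.000, 160),
        },
    },
    # unadjusted annual QALYs by arm: (mean, sd, median, min, max, n)
    "qaly_summary": {
        "SIW": (0.8681, 0.2014, 0.8819, -0.1066, 1.6142, 145),
        "SIF": (0.8693, 0.1804, 0.8870, 0.3222, 1.3249, 169),
        "TAU": (0.8622, 0.1756, 0.8707, 0.3694, 1.1945, 149),
    },
    # headline results (point estimates as printed)
    "delta_cost": {"SIW": 117.94, "SIF": 218.40},
    "icer": {"SIW": 8190.28, "SIF": 6423.53},
    "relative_risk": {"SIW": 3.01, "SIF": 3.00},
    "threshold_eur_per_qaly": 45_000.0,
    # CEAC probability at the threshold; requires the patient-level deposit
    # to recompute (documented fixture, not unit-testable without it)
    "prob_cost_effective_at_threshold": {"SIW": 0.7983, "SIF": 0.9777},
    # reporting-time exchange-rate multipliers, exposed verbatim
    "exchange_rates": {"GBP_per_EUR": 0.8141, "GBP_per_USD": 0.6325},
}


def load_study_deposit(path, schema=None, layout: str = "auto") -> TrialDataset:
    """Load the deposited patient-level data, if the user has obtained it.

    The deposit is published in a public research-data archive and is not
    redistributed with this package.  Supplied as a CSV conforming to the
    ``trial_data`` column contract (use ``schema`` to map column names), it
    feeds the same pipeline as synthetic data, and the study's
    deposit-dependent results — utility/QALY summaries, the adjusted
    regression, and the CEAC probabilities at €45,000/QALY — should be
    reproduced by ``reporting.run_full_analysis``.

    Raises ``FileNotFoundError`` with guidance when the file is absent.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"study deposit not found at {path!r}: the patient-level trial data "
            "are not bundled with trialcea; download them from the public "
            "archive referenced in the README and export them as CSV with the "
            "trial_data column layout"
        )
    return read_trial_csv(path, schema=schema, layout=layout)
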