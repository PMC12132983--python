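"""Registry of the numeric clinical signs under quality surveillance.

Each sign carries the recording grid used by the point-of-care tablet
(e.g. 0.1 °C for temperature, whole beats/min for heart rate), an
eligibility rule (some signs are prompted for every child, others only
above six months of age or for respiratory complaints), the status
options a healthcare worker can tick, and a baseline sampling model used
by the synthetic-cohort simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# status codes used throughout the wide consultation table
MEASURED = "measured"
NOT_FEASIBLE = "not_feasible"
ESTIMATED = "estimated"
NOT_APPLICABLE = "not_applicable"
STATUSES = (MEASURED, NOT_FEASIBLE, ESTIMATED, NOT_APPLICABLE)

# eligibility rules
ALL_CHILDREN = "all"
AGE_OVER_6MO = "age_over_6mo"
RESPIRATORY = "respiratory"

#: first eligible age in days for MUAC (strictly more than six months)
MUAC_MIN_AGE_DAYS = 183

#: growth-standard z-score indicators derived from the anthropometric signs
Z_INDICATORS = ("muac_for_age", "weight_for_age", "weight_for_height")


@dataclass(frozen=True)
class SignSpec:
    """Static description of one numeric sign.

    ``family`` selects the simulator's baseline model: ``"truncnorm"``
    draws from a truncated normal with ``params = (mean, sd, lo, hi)``;
    ``"growth"`` draws coherently from the bundled growth curves
    (age/sex dependent, see :mod:`cdsaqc.simulate`).
    """

    sign_id: str
    unit: str
    precision: float
    eligibility: str
    family: str
    params: tuple = ()
    not_feasible_rate: float = 0.0
    estimated_rate: float = 0.0
    allows_not_feasible: bool = True
    allows_estimated: bool = False

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError(f"{self.sign_id}: recording precision must be positive")
        if not 0.0 <= self.not_feasible_rate <= 1.0:
            raise ValueError(f"{self.sign_id}: not_feasible_rate outside [0, 1]")
        if not 0.0 <= self.estimated_rate <= 1.0:
            raise ValueError(f"{self.sign_id}: estimated_rate outside [0, 1]")
        if self.eligibility not in (ALL_CHILDREN, AGE_OVER_6MO, RESPIRATORY):
            raise ValueError(f"{self.sign_id}: unknown eligibility {self.eligibility!r}")

    @property
    def decimals(self) -> int:
        return max(0, -math.floor(math.log10(self.precision) + 1e-9))

    def quantize(self, values: np.ndarray) -> np.ndarray:
        """Snap raw values onto the sign's recording grid."""
        values = np.asarray(values, dtype=float)
        return np.round(np.round(values / self.precision) * self.precision, self.decimals)


#: display order of the signs (basic measurements first, then vitals)
SIGN_ORDER = (
    "temperature",
    "muac",
    "weight",
    "height",
    "heart_rate",
    "spo2",
    "resp_rate",
)

SIGNS: dict[str, SignSpec] = {
    "temperature": SignSpec(
        "temperature", "degC", 0.1, ALL_CHILDREN,
        family="truncnorm", params=(36.8, 0.5, 35.0, 41.0),
        not_feasible_rate=0.02,
    ),
    "muac": SignSpec(
        "muac", "cm", 0.1, AGE_OVER_6MO,
        family="growth", not_feasible_rate=0.05,
    ),
    "weight": SignSpec(
        # weight is never "not feasible"; it can instead be flagged as
        # estimated, which downstream analyses count as missing
        "weight", "kg", 0.1, ALL_CHILDREN,
        family="growth", not_feasible_rate=0.0, estimated_rate=0.03,
        allows_not_feasible=False, allows_estimated=True,
    ),
    "height": SignSpec(
        "height", "cm", 0.1, ALL_CHILDREN,
        family="growth", not_feasible_rate=0.08,
    ),
    "heart_rate": SignSpec(
        "heart_rate", "beats/min", 1.0, RESPIRATORY,
        family="truncnorm", params=(115.0, 22.0, 50.0, 220.0),
        not_feasible_rate=0.10,
    ),
    "spo2": SignSpec(
        "spo2", "%", 1.0, RESPIRATORY,
        family="truncnorm", params=(97.3, 1.7, 80.0, 100.0),
        not_feasible_rate=0.08,
    ),
    "resp_rate": SignSpec(
        "resp_rate", "breaths/min", 1.0, RESPIRATORY,
        family="truncnorm", params=(38.0, 11.0, 12.0, 90.0),
        not_feasible_rate=0.12,
    ),
}

#: which z-score indicator is fed by which measured sign(s)
Z_INDICATOR_INPUTS = {
    "muac_for_age": ("muac",),
    "weight_for_age": ("weight",),
    "weight_for_height": ("weight", "height"),
}


def eligible_mask(df, sign_id: str) -> np.ndarray:
    """Boolean mask of consultations for which ``sign_id`` is prompted."""
    spec = SIGNS[sign_id]
    if spec.eligibility == ALL_CHILDREN:
        return np.ones(len(df), dtype=bool)
    if spec.eligibility == AGE_OVER_6MO:
        return (df["age_days"].to_numpy() >= MUAC_MIN_AGE_DAYS)
    return df["respiratory_complaint"].to_numpy().astype(bool)
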