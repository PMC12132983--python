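"""Synthetic multi-facility consultation cohorts with injectable skill-gap behaviors.

The generator emulates the data-producing setting of a tablet-guided
outpatient consultation: children aged 1 day to 14 years attend one of
several health centers; each numeric sign is prompted according to its
eligibility rule and is either measured (value on the recording grid) or
ticked "not feasible" (weight instead may be "estimated"); anthropometry
is drawn coherently from the same growth curves that back the bundled
z-score reference, so baseline extreme-z fractions are stable across
facilities.

Four behavior archetypes can be injected into a chosen (facility, sign):

* ``skipper`` - raises the not-feasible (missing) rate by ``intensity``;
* ``mono_repeater`` - moves probability mass ``intensity`` onto a single
  preferred value (digit preference / heaping);
* ``multi_repeater`` - same, split over 2-3 preferred values;
* ``wrongly_evaluated`` - for anthropometric signs, replaces a fraction
  ``intensity`` of measurements with values whose growth z-scores are
  extreme (|z| > 2); for temperature and vitals, adds a systematic bias
  of ``intensity`` in the sign's own units (an implausible mean shift).

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import ndtr, ndtri

from cdsaqc import curves
from cdsaqc.growth import lms_inverse
from cdsaqc.signs import (
    AGE_OVER_6MO,
    ESTIMATED,
    MEASURED,
    MUAC_MIN_AGE_DAYS,
    NOT_APPLICABLE,
    NOT_FEASIBLE,
    SIGN_ORDER,
    SIGNS,
    SignSpec,
    eligible_mask,
)

PATTERN_TYPES = ("skipper", "mono_repeater", "multi_repeater", "wrongly_evaluated")

#: signs a behavior can be injected into.  Skipping is impossible for
#: temperature/weight in the app's flow as analyzed (weight has no
#: not-feasible option); repeaters are not meaningful for weight/height
#: (their raw distributions are age-driven); wrong evaluation of weight
#: and MUAC surfaces through z-scores rather than the raw sign.
INJECTION_APPLICABILITY = {
    "skipper": {"muac", "height", "heart_rate", "spo2", "resp_rate"},
    "mono_repeater": {"temperature", "muac", "heart_rate", "spo2", "resp_rate"},
    "multi_repeater": {"temperature", "muac", "heart_rate", "spo2", "resp_rate"},
    "wrongly_evaluated": {"temperature", "muac", "weight", "heart_rate", "spo2", "resp_rate"},
}

#: growth signs corrupted through a z-scale draw, and the curve behind each
_GROWTH_WRONG = {
    "weight": ("weight_for_age", curves.weight_median),
    "muac": ("muac_for_age", curves.muac_median),
}

MAX_AGE_DAYS = 5110  # 14 years
UNDER5_MAX_AGE_DAYS = 1825


class ConfigError(ValueError):
    """Invalid cohort or behavior configuration."""


@dataclass(frozen=True)
class FacilitySpec:
    hc_id: str
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"facility {self.hc_id}: n must be >= 1")


@dataclass(frozen=True)
class BehaviorSpec:
    pattern_type: str
    intensity: float
    target_values: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.pattern_type not in PATTERN_TYPES:
            raise ConfigError(f"unknown pattern type {self.pattern_type!r}")
        if self.intensity < 0:
            raise ConfigError("behavior intensity must be >= 0")
        n_targets = len(self.target_values)
        if self.pattern_type == "mono_repeater" and n_targets != 1:
            raise ConfigError("mono_repeater requires exactly 1 target value")
        if self.pattern_type == "multi_repeater" and not 2 <= n_targets <= 3:
            raise ConfigError("multi_repeater requires 2-3 target values")


@dataclass(frozen=True)
class BehaviorAssignment:
    hc_id: str
    sign_id: str
    behavior: BehaviorSpec


@dataclass
class CohortConfig:
    """Cohort layout: facilities, sign specs, behaviors, demographics."""

    facilities: list[FacilitySpec]
    signs: dict[str, SignSpec] = field(default_factory=lambda: dict(SIGNS))
    behaviors: list[BehaviorAssignment] = field(default_factory=list)
    p_under5: float = 0.65
    p_respiratory: float = 0.40
    p_female: float = 0.50

    def validate(self) -> None:
        hc_ids = {f.hc_id for f in self.facilities}
        if len(hc_ids) != len(self.facilities):
            raise ConfigError("duplicate facility ids")
        for sign_id in self.signs:
            if sign_id not in SIGNS:
                raise ConfigError(f"unknown sign_id {sign_id!r}")
        for b in self.behaviors:
            if b.hc_id not in hc_ids:
                raise ConfigError(f"behavior references undeclared facility {b.hc_id!r}")
            if b.sign_id not in self.signs:
                raise ConfigError(f"behavior references unknown sign {b.sign_id!r}")
            _check_injectable(b.sign_id, b.behavior.pattern_type)


def _check_injectable(sign_id: str, pattern_type: str) -> None:
    if sign_id not in INJECTION_APPLICABILITY[pattern_type]:
        raise ConfigError(f"{pattern_type} cannot be injected into {sign_id}")


def default_config(n_facilities: int = 16, n_per_facility: int = 1250) -> CohortConfig:
    """Behavior-free default cohort: 16 facilities, ~20,000 consultations."""
    facilities = [FacilitySpec(f"HC-{i + 1:02d}", n_per_facility) for i in range(n_facilities)]
    return CohortConfig(facilities=facilities)


# ---------------------------------------------------------------------------
# configuration from YAML

_TRUNCNORM_KEYS = ("mean", "sd", "lo", "hi")


def load_cohort_config(source: str | Path | dict) -> CohortConfig:
    """Build a :class:`CohortConfig` from a YAML file or parsed mapping.

    Recognized blocks: ``facilities`` (list of ``{hc_id, n}`` or the
    shorthand ``{count, n_per_facility}``), ``signs`` (per-sign overrides
    of ``not_feasible_rate``, ``estimated_rate`` and truncated-normal
    parameters), ``behaviors`` (list of ``{hc_id, sign, pattern,
    intensity, targets}``) and the demographic probabilities.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)

    fac_block = raw.get("facilities", {"count": 16, "n_per_facility": 1250})
    if isinstance(fac_block, dict):
        count = int(fac_block.get("count", 16))
        n = int(fac_block.get("n_per_facility", 1250))
        facilities = [FacilitySpec(f"HC-{i + 1:02d}", n) for i in range(count)]
    else:
        facilities = [FacilitySpec(str(f["hc_id"]), int(f["n"])) for f in fac_block]

    signs = dict(SIGNS)
    for sign_id, overrides in (raw.get("signs") or {}).items():
        if sign_id not in signs:
            raise ConfigError(f"unknown sign_id {sign_id!r} in config")
        spec = signs[sign_id]
        fields: dict = {}
        for key in ("not_feasible_rate", "estimated_rate"):
            if key in overrides:
                fields[key] = float(overrides[key])
        if any(k in overrides for k in _TRUNCNORM_KEYS):
            if spec.family != "truncnorm":
                raise ConfigError(f"{sign_id}: distribution parameters only apply to truncnorm signs")
            mean, sd, lo, hi = spec.params
            params = dict(zip(_TRUNCNORM_KEYS, (mean, sd, lo, hi)))
            params.update({k: float(v) for k, v in overrides.items() if k in _TRUNCNORM_KEYS})
            fields["params"] = tuple(params[k] for k in _TRUNCNORM_KEYS)
        signs[sign_id] = replace(spec, **fields)

    behaviors = []
    for b in raw.get("behaviors") or []:
        behaviors.append(
            BehaviorAssignment(
                hc_id=str(b["hc_id"]),
                sign_id=str(b.get("sign", b.get("sign_id"))),
                behavior=BehaviorSpec(
                    pattern_type=str(b.get("pattern", b.get("pattern_type"))),
                    intensity=float(b["intensity"]),
                    target_values=tuple(float(t) for t in b.get("targets", ()) or ()),
                ),
            )
        )

    cfg = CohortConfig(
        facilities=facilities,
        signs=signs,
        behaviors=behaviors,
        p_under5=float(raw.get("p_under5", 0.65)),
        p_respiratory=float(raw.get("p_respiratory", 0.40)),
        p_female=float(raw.get("p_female", 0.50)),
    )
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# baseline generation

def _truncated_normal(rng, mean, sd, lo, hi, size) -> np.ndarray:
    a, b = ndtr((lo - mean) / sd), ndtr((hi - mean) / sd)
    u = rng.uniform(a, b, size)
    return mean + sd * ndtri(u)


def _facility_frame(cfg: CohortConfig, fac: FacilitySpec, rng) -> pd.DataFrame:
    n = fac.n
    under5 = rng.random(n) < cfg.p_under5
    age = np.where(
        under5,
        rng.integers(1, UNDER5_MAX_AGE_DAYS + 1, n),
        rng.integers(UNDER5_MAX_AGE_DAYS + 1, MAX_AGE_DAYS + 1, n),
    )
    sex = np.where(rng.random(n) < cfg.p_female, "female", "male")
    resp = rng.random(n) < cfg.p_respiratory

    df = pd.DataFrame(
        {
            "consultation_id": [f"{fac.hc_id}-{i + 1:05d}" for i in range(n)],
            "hc_id": fac.hc_id,
            "age_days": age.astype(int),
            "sex": sex,
            "respiratory_complaint": resp,
        }
    )

    # shared latent growth factor ties height, weight and MUAC together so
    # weight-for-height stays calibrated for a same-settings population
    g = rng.standard_normal(n)
    z_height = 0.8 * g + 0.6 * rng.standard_normal(n)
    z_weight = 0.5 * g + np.sqrt(1 - 0.25) * rng.standard_normal(n)
    z_muac = 0.6 * g + 0.8 * rng.standard_normal(n)

    height = curves.height_median(age, sex) * (1.0 + curves.HEIGHT_REL_SD * z_height)
    L, S = curves.LMS_SHAPE["weight_for_height"]
    weight = lms_inverse(z_weight, L, curves.weight_for_height_median(height, sex), S)
    L, S = curves.LMS_SHAPE["muac_for_age"]
    muac = lms_inverse(z_muac, L, curves.muac_median(age, sex), S)
    raw_values = {"height": height, "weight": weight, "muac": muac}

    for sign_id in SIGN_ORDER:
        spec = cfg.signs[sign_id]
        eligible = eligible_mask(df, sign_id)
        if spec.family == "truncnorm":
            mean, sd, lo, hi = spec.params
            values = _truncated_normal(rng, mean, sd, lo, hi, n)
        else:
            values = raw_values[sign_id]
        u = rng.random(n)
        status = np.full(n, MEASURED, dtype=object)
        if spec.allows_not_feasible and spec.not_feasible_rate > 0:
            status[u < spec.not_feasible_rate] = NOT_FEASIBLE
        if spec.allows_estimated and spec.estimated_rate > 0:
            lo_p = spec.not_feasible_rate if spec.allows_not_feasible else 0.0
            status[(u >= lo_p) & (u < lo_p + spec.estimated_rate)] = ESTIMATED
        status[~eligible] = NOT_APPLICABLE
        values = np.where(status == MEASURED, values, np.nan)
        df[f"{sign_id}_status"] = status
        df[f"{sign_id}_value"] = values
    return df


def generate_cohort(config: CohortConfig, seed: int) -> pd.DataFrame:
    """Generate a cohort, apply configured behaviors, quantize values.

    Deterministic given (config, seed).  Raw values are drawn first,
    behaviors are applied on the raw scale, and quantization to each
    sign's recording precision happens last so that heaping spikes land
    on representable grid values.
    """
    config.validate()
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(config.facilities) + len(config.behaviors))
    frames = [
        _facility_frame(config, fac, np.random.default_rng(s))
        for fac, s in zip(config.facilities, seeds)
    ]
    df = pd.concat(frames, ignore_index=True)
    for assignment, s in zip(config.behaviors, seeds[len(config.facilities):]):
        _apply_behavior(
            df,
            assignment.hc_id,
            assignment.sign_id,
            assignment.behavior,
            np.random.default_rng(s),
            config.signs,
        )
    _quantize_all(df, config.signs)
    return df


def _quantize_all(df: pd.DataFrame, signs: dict[str, SignSpec]) -> None:
    for sign_id in SIGN_ORDER:
        spec = signs[sign_id]
        col = f"{sign_id}_value"
        values = df[col].to_numpy(dtype=float)
        measured = np.isfinite(values)
        values[measured] = spec.quantize(values[measured])
        df[col] = values


# ---------------------------------------------------------------------------
# behavior injection

def inject_behavior(
    records: pd.DataFrame,
    hc_id: str,
    sign_id: str,
    behavior: BehaviorSpec,
    seed: int,
    signs: dict[str, SignSpec] | None = None,
) -> pd.DataFrame:
    """Return a copy of ``records`` with one behavior applied.

    Only rows of the targeted facility and sign change; everything else
    is bit-identical.  Modified values are re-quantized to the sign's
    recording grid.
    """
    signs = signs or SIGNS
    if sign_id not in signs:
        raise ConfigError(f"unknown sign_id {sign_id!r}")
    out = records.copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    _apply_behavior(out, hc_id, sign_id, behavior, rng, signs)
    spec = signs[sign_id]
    col = f"{sign_id}_value"
    values = out[col].to_numpy(dtype=float)
    measured = np.isfinite(values)
    values[measured] = spec.quantize(values[measured])
    out[col] = values
    return out


def _apply_behavior(df, hc_id, sign_id, behavior: BehaviorSpec, rng, signs) -> None:
    _check_injectable(sign_id, behavior.pattern_type)
    spec = signs[sign_id]
    fac = (df["hc_id"] == hc_id).to_numpy()
    status_col, value_col = f"{sign_id}_status", f"{sign_id}_value"
    status = df[status_col].to_numpy(dtype=object)
    values = df[value_col].to_numpy(dtype=float)
    measured = fac & (status == MEASURED)
    m = int(measured.sum())
    if m == 0 or behavior.intensity == 0:
        return

    if behavior.pattern_type == "skipper":
        eligible = fac & (status != NOT_APPLICABLE)
        measured_frac = m / eligible.sum()
        add = behavior.intensity
        if add > measured_frac:
            warnings.warn(
                f"skipper intensity {add} exceeds attainable mass {measured_frac:.3f}; clipped",
                stacklevel=3,
            )
            add = measured_frac
        flip = rng.random(m) < add / measured_frac
        idx = np.flatnonzero(measured)[flip]
        status[idx] = NOT_FEASIBLE
        values[idx] = np.nan

    elif behavior.pattern_type in ("mono_repeater", "multi_repeater"):
        targets = np.asarray(behavior.target_values, dtype=float)
        grid_targets = spec.quantize(targets)
        on_target = np.isin(spec.quantize(values[measured]), grid_targets)
        p_hat = on_target.mean()
        attainable = 1.0 - p_hat
        alpha = behavior.intensity / attainable if attainable > 0 else np.inf
        if alpha > 1.0:
            warnings.warn(
                f"repeater intensity {behavior.intensity} exceeds attainable mass "
                f"{attainable:.3f}; clipped",
                stacklevel=3,
            )
            alpha = 1.0
        hit = rng.random(m) < alpha
        pick = targets[rng.integers(0, len(targets), m)]
        mvals = values[measured]
        mvals[hit] = pick[hit]
        values[measured] = mvals

    else:  # wrongly_evaluated
        if sign_id in _GROWTH_WRONG:
            indicator, median_fn = _GROWTH_WRONG[sign_id]
            frac = behavior.intensity
            if frac > 1.0:
                warnings.warn(
                    f"wrongly_evaluated fraction {frac} exceeds 1; clipped", stacklevel=3
                )
                frac = 1.0
            hit = rng.random(m) < frac
            magnitude = rng.uniform(2.6, 4.5, m)
            sign_of_z = np.where(rng.random(m) < 0.5, -1.0, 1.0)
            age = df["age_days"].to_numpy(dtype=float)[measured]
            sex = df["sex"].to_numpy()[measured]
            L, S = curves.LMS_SHAPE[indicator]
            corrupted = lms_inverse(sign_of_z * magnitude, L, median_fn(age, sex), S)
            mvals = values[measured]
            mvals[hit] = corrupted[hit]
            values[measured] = mvals
        else:
            # systematic bias: intensity is a mean shift in sign units
            values[measured] = values[measured] + behavior.intensity

    df[status_col] = status
    df[value_col] = values


# ---------------------------------------------------------------------------
# cohort I/O and validation

BASE_COLUMNS = ("consultation_id", "hc_id", "age_days", "sex", "respiratory_complaint")


def cohort_columns() -> list[str]:
    cols = list(BASE_COLUMNS)
    for sign_id in SIGN_ORDER:
        cols += [f"{sign_id}_status", f"{sign_id}_value"]
    return cols


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write the consultation table (UTF-8 CSV, '.' decimal separator)."""
    cols = [c for c in cohort_columns() if c in df.columns]
    extra = [c for c in df.columns if c not in cols]
    df[cols + extra].to_csv(path, index=False, encoding="utf-8")


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={"consultation_id": str, "hc_id": str, "sex": str},
        encoding="utf-8",
    )
    df["respiratory_complaint"] = df["respiratory_complaint"].astype(bool)
    for sign_id in SIGN_ORDER:
        df[f"{sign_id}_value"] = pd.to_numeric(df[f"{sign_id}_value"], errors="coerce")
    return df


def validate_cohort(df: pd.DataFrame, signs: dict[str, SignSpec] | None = None) -> None:
    """Assert the consultation-table invariants; raise ValueError on breach."""
    signs = signs or SIGNS
    problems = []
    age = df["age_days"].to_numpy()
    if (age < 0).any():
        problems.append("negative age_days")
    for sign_id in SIGN_ORDER:
        spec = signs[sign_id]
        status = df[f"{sign_id}_status"].to_numpy(dtype=object)
        values = df[f"{sign_id}_value"].to_numpy(dtype=float)
        eligible = eligible_mask(df, sign_id)
        if (status[~eligible] != NOT_APPLICABLE).any():
            problems.append(f"{sign_id}: ineligible consultation carries a status")
        if (status[eligible] == NOT_APPLICABLE).any():
            problems.append(f"{sign_id}: eligible consultation marked not_applicable")
        if (~np.isnan(values) & (status != MEASURED)).any():
            problems.append(f"{sign_id}: value present with non-measured status")
        if np.isnan(values[status == MEASURED]).any():
            problems.append(f"{sign_id}: measured status without a value")
        if (status == ESTIMATED).any() and not spec.allows_estimated:
            problems.append(f"{sign_id}: 'estimated' status not allowed")
        bad = ~np.isin(status, ("measured", "not_feasible", "estimated", "not_applicable"))
        if bad.any():
            problems.append(f"{sign_id}: unknown status values {set(status[bad])}")
    if problems:
        raise ValueError("invalid cohort: " + "; ".join(problems))
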