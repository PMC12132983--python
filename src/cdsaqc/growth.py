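"""Growth-standard z-scores via the LMS method.

The tablet application converts MUAC, weight and height into
MUAC-for-age, weight-for-age and weight-for-height z-scores and shows
them as integers clamped to [-3, 3].  This module reproduces that
computation from a bundled LMS parameter table (power L, median M,
coefficient of variation S per indicator, sex and key):

    z = ((x / M)**L - 1) / (L * S)    if L != 0
    z = ln(x / M) / S                 if L == 0

Parameters between tabulated keys are linearly interpolated.  Raw
z-scores are retained next to the clamped integers, because fractions of
extreme values (|z| > 2) are computed on the raw scale.

The bundled table is synthetic (see :mod:`cdsaqc.curves`); analyses are
relative to it, not to official WHO values.  Following the growth
standards, z-scores are only computed for ages 2 months to 5 years.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from cdsaqc.signs import MEASURED, Z_INDICATORS

_REFERENCE_RESOURCE = "growth_reference_synthetic.csv"

#: z-score window in days (2 completed months to 5 years)
ZSCORE_MIN_AGE_DAYS = 61
ZSCORE_MAX_AGE_DAYS = 1826


class ReferenceLoadError(ValueError):
    """Raised when a reference CSV violates the table invariants."""


class ReferenceRangeError(KeyError):
    """Raised when a query key falls outside the table's coverage."""


@dataclass(frozen=True)
class ZScoreValue:
    """One computed z-score: the raw value and its clamped integer form."""

    indicator: str
    raw_z: float
    clamped_z: int


def clamp_z(raw_z) -> np.ndarray:
    """Integer display form: round half away from zero, clip to [-3, 3]."""
    z = np.asarray(raw_z, dtype=float)
    rounded = np.sign(z) * np.floor(np.abs(z) + 0.5)
    return np.clip(rounded, -3, 3).astype(int)


class GrowthReferenceTable:
    """Indexed LMS parameters with linear interpolation between keys."""

    def __init__(self, frame: pd.DataFrame):
        required = {"indicator", "sex", "key", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ReferenceLoadError(f"reference table missing columns: {sorted(missing)}")
        if (frame["M"] <= 0).any():
            raise ReferenceLoadError("reference table contains non-positive M")
        if (frame["S"] <= 0).any():
            raise ReferenceLoadError("reference table contains non-positive S")
        self._series: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for (indicator, sex), grp in frame.groupby(["indicator", "sex"], sort=True):
            keys = grp["key"].to_numpy(dtype=float)
            if len(keys) < 2 or (np.diff(keys) <= 0).any():
                raise ReferenceLoadError(
                    f"keys not strictly increasing for ({indicator}, {sex})"
                )
            self._series[(indicator, sex)] = (
                keys,
                grp["L"].to_numpy(dtype=float),
                grp["M"].to_numpy(dtype=float),
                grp["S"].to_numpy(dtype=float),
            )
        self.frame = frame.reset_index(drop=True)

    @property
    def indicators(self) -> tuple[str, ...]:
        return tuple(sorted({ind for ind, _ in self._series}))

    def coverage(self, indicator: str, sex: str) -> tuple[float, float]:
        keys = self._series[(indicator, sex)][0]
        return float(keys[0]), float(keys[-1])

    def lms(self, indicator: str, sex: str, key) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Interpolated (L, M, S) at ``key``; NaN outside coverage."""
        try:
            keys, L, M, S = self._series[(indicator, sex)]
        except KeyError as exc:
            raise ReferenceRangeError(f"no series for ({indicator}, {sex})") from exc
        k = np.asarray(key, dtype=float)
        inside = (k >= keys[0]) & (k <= keys[-1])
        li = np.where(inside, np.interp(k, keys, L), np.nan)
        mi = np.where(inside, np.interp(k, keys, M), np.nan)
        si = np.where(inside, np.interp(k, keys, S), np.nan)
        return li, mi, si


def load_reference(path: str | Path | None = None) -> GrowthReferenceTable:
    """Load an LMS reference CSV (``indicator,sex,key,L,M,S``).

    With no argument the bundled synthetic table is used.
    """
    if path is None:
        with resources.as_file(
            resources.files("cdsaqc").joinpath("data", _REFERENCE_RESOURCE)
        ) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    return GrowthReferenceTable(frame)


def lms_zscore(x, L, M, S) -> np.ndarray:
    """Forward LMS transform, vectorized; handles the L -> 0 limit."""
    x, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (x, L, M, S)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z_pow = (np.power(x / M, L) - 1.0) / (L * S)
        z_log = np.log(x / M) / S
    return np.where(L == 0, z_log, z_pow)


def lms_inverse(z, L, M, S) -> np.ndarray:
    """Measurement attaining z-score ``z`` (inverse transform)."""
    z, L, M, S = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (z, L, M, S)))
    with np.errstate(invalid="ignore"):
        x_pow = M * np.power(1.0 + L * S * z, 1.0 / np.where(L == 0, 1.0, L))
        x_log = M * np.exp(S * z)
    return np.where(L == 0, x_log, x_pow)


def compute_zscore(
    indicator: str,
    measurement: float,
    sex: str,
    key: float,
    reference: GrowthReferenceTable,
) -> ZScoreValue:
    """Z-score one measurement against the reference.

    ``key`` is age in days for the *-for-age indicators and height in cm
    for weight-for-height.  Raises :class:`ReferenceRangeError` when the
    key is outside the table's coverage (callers typically skip such
    records, mirroring the 2 month-5 year restriction).
    """
    if measurement <= 0:
        raise ValueError("measurement must be positive")
    L, M, S = reference.lms(indicator, sex, key)
    if np.isnan(M):
        lo, hi = reference.coverage(indicator, sex)
        raise ReferenceRangeError(
            f"{indicator}/{sex}: key {key} outside coverage [{lo}, {hi}]"
        )
    raw = float(lms_zscore(measurement, L, M, S))
    return ZScoreValue(indicator, raw, int(clamp_z(raw)))


def _measured_values(df: pd.DataFrame, sign: str) -> tuple[np.ndarray, np.ndarray]:
    status = df[f"{sign}_status"].to_numpy()
    values = pd.to_numeric(df[f"{sign}_value"], errors="coerce").to_numpy(dtype=float)
    return (status == MEASURED) & np.isfinite(values), values


def add_zscores(df: pd.DataFrame, reference: GrowthReferenceTable | None = None) -> pd.DataFrame:
    """Append raw and clamped z-score columns to a consultation table.

    Adds ``<indicator>_zraw`` (float, NaN when not computable) and
    ``<indicator>_z`` (clamped integer, pandas nullable Int64) for each
    indicator.  A z-score is computable when the input sign(s) were
    measured and the child's key lies within the reference coverage.
    """
    if reference is None:
        reference = load_reference()
    out = df.copy()
    age = out["age_days"].to_numpy(dtype=float)
    sex = out["sex"].to_numpy()
    in_window = (age >= ZSCORE_MIN_AGE_DAYS) & (age <= ZSCORE_MAX_AGE_DAYS)

    sources = {
        "muac_for_age": ("muac", age),
        "weight_for_age": ("weight", age),
        "weight_for_height": ("weight", None),  # keyed on measured height
    }
    height_ok, height_vals = _measured_values(out, "height")
    for indicator in Z_INDICATORS:
        sign, key = sources[indicator]
        ok, values = _measured_values(out, sign)
        if key is None:
            key = np.where(height_ok, height_vals, np.nan)
            ok = ok & height_ok
        raw = np.full(len(out), np.nan)
        computable = ok & in_window
        for s in ("male", "female"):
            mask = computable & (sex == s)
            if not mask.any():
                continue
            L, M, S = reference.lms(indicator, s, key[mask])
            raw[mask] = lms_zscore(values[mask], L, M, S)
        out[f"{indicator}_zraw"] = raw
        clamped = pd.array(
            np.where(np.isfinite(raw), clamp_z(np.nan_to_num(raw)), np.nan), dtype="Float64"
        )
        out[f"{indicator}_z"] = clamped.astype("Int64")
    return out
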