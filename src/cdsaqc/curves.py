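"""Smooth synthetic growth curves behind the bundled reference table.

The package ships a *synthetic* LMS reference (it is not an official WHO
release; redistributing one is out of scope and every analysis in the
package is relative to the bundled table, never to external values).
The curves here are constructed to be mutually coherent: the median
weight-for-height evaluated at the median height of a given age equals
the median weight-for-age at that age, so a median child is median under
every indicator simultaneously.  Anchor values approximate familiar
pediatric magnitudes (birth weight ~3.3 kg, length ~50 cm, MUAC ~14 cm
in the second year of life).

All medians are piecewise-linear in age (days) or height (cm); L and S
are held constant per indicator, which keeps the table easy to audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (age_days, value) anchors for the male median; female medians are scaled
_HEIGHT_ANCHORS = np.array([
    (0, 49.9), (30, 54.7), (61, 58.4), (91, 61.4), (122, 63.9),
    (152, 65.9), (182, 67.6), (274, 72.0), (365, 75.7), (456, 78.8),
    (547, 81.7), (730, 87.1), (912, 91.9), (1095, 96.1), (1278, 99.9),
    (1460, 103.3), (1642, 106.7), (1826, 110.0), (2555, 121.0),
    (3650, 138.0), (5110, 158.0),
])
_WEIGHT_ANCHORS = np.array([
    (0, 3.3), (30, 4.5), (61, 5.6), (91, 6.4), (122, 7.0),
    (152, 7.5), (182, 7.9), (274, 8.9), (365, 9.6), (456, 10.3),
    (547, 10.9), (730, 12.2), (912, 13.3), (1095, 14.3), (1278, 15.3),
    (1460, 16.3), (1642, 17.3), (1826, 18.3), (2555, 22.0),
    (3650, 31.0), (5110, 45.0),
])
_MUAC_ANCHORS = np.array([
    (61, 12.2), (91, 12.9), (122, 13.3), (152, 13.6), (182, 13.8),
    (274, 14.1), (365, 14.4), (547, 14.7), (730, 15.0), (1095, 15.4),
    (1460, 15.9), (1826, 16.3), (2555, 17.3), (3650, 19.5), (5110, 23.0),
])

_FEMALE_SCALE = {"height": 0.985, "weight": 0.95, "muac": 0.99}

#: constant L (Box-Cox power) and S (coefficient of variation) per indicator
LMS_SHAPE = {
    "weight_for_age": (0.2, 0.11),
    "muac_for_age": (0.5, 0.07),
    "weight_for_height": (0.3, 0.09),
}

#: key coverage of the bundled table
AGE_KEYS = np.append(np.arange(61, 1826, 15), 1826)
HEIGHT_KEYS = np.round(np.arange(45.0, 120.0 + 1e-9, 0.5), 1)

#: relative SD of height around its age median (simulator dispersion)
HEIGHT_REL_SD = 0.038


def _sex_scale(measure: str, sex) -> np.ndarray:
    sex = np.asarray(sex)
    scale = np.where(sex == "female", _FEMALE_SCALE[measure], 1.0)
    return scale


def height_median(age_days, sex) -> np.ndarray:
    age = np.asarray(age_days, dtype=float)
    base = np.interp(age, _HEIGHT_ANCHORS[:, 0], _HEIGHT_ANCHORS[:, 1])
    return base * _sex_scale("height", sex)


def weight_median(age_days, sex) -> np.ndarray:
    age = np.asarray(age_days, dtype=float)
    base = np.interp(age, _WEIGHT_ANCHORS[:, 0], _WEIGHT_ANCHORS[:, 1])
    return base * _sex_scale("weight", sex)


def muac_median(age_days, sex) -> np.ndarray:
    age = np.asarray(age_days, dtype=float)
    base = np.interp(age, _MUAC_ANCHORS[:, 0], _MUAC_ANCHORS[:, 1])
    return base * _sex_scale("muac", sex)


def weight_for_height_median(height_cm, sex) -> np.ndarray:
    """Median weight at a given height: weight-for-age composed with the
    inverse of height-for-age, linearly extrapolated below birth length."""
    h, sexes = np.broadcast_arrays(
        np.atleast_1d(np.asarray(height_cm, dtype=float)), np.atleast_1d(np.asarray(sex))
    )
    out = np.empty(h.shape, dtype=float)
    for s in ("male", "female"):
        mask = sexes == s
        if not mask.any():
            continue
        h_grid = _HEIGHT_ANCHORS[:, 1] * _FEMALE_SCALE["height"] ** (s == "female")
        w_grid = _WEIGHT_ANCHORS[:, 1] * _FEMALE_SCALE["weight"] ** (s == "female")
        hs = h[mask]
        w = np.interp(hs, h_grid, w_grid)
        # below the curve's smallest height, extrapolate along the first segment
        slope = (w_grid[1] - w_grid[0]) / (h_grid[1] - h_grid[0])
        below = hs < h_grid[0]
        w = np.where(below, w_grid[0] + (hs - h_grid[0]) * slope, w)
        out[mask] = w
    return out


def build_reference_frame() -> pd.DataFrame:
    """Assemble the synthetic LMS reference table shipped as CSV."""
    rows = []
    for sex in ("male", "female"):
        for indicator, median_fn, keys in (
            ("muac_for_age", muac_median, AGE_KEYS),
            ("weight_for_age", weight_median, AGE_KEYS),
        ):
            L, S = LMS_SHAPE[indicator]
            M = median_fn(keys, sex)
            for k, m in zip(keys, M):
                rows.append((indicator, sex, float(k), L, round(float(m), 4), S))
        L, S = LMS_SHAPE["weight_for_height"]
        M = weight_for_height_median(HEIGHT_KEYS, np.asarray(sex))
        for k, m in zip(HEIGHT_KEYS, M):
            rows.append(("weight_for_height", sex, float(k), L, round(float(m), 4), S))
    return pd.DataFrame(rows, columns=["indicator", "sex", "key", "L", "M", "S"])
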