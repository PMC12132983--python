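import numpy as np
import pandas as pd
import pytest

from cdsaqc import add_zscores, load_reference
from cdsaqc.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def small_cohort(reference):
    """Behavior-free cohort: 3 facilities x 400 consultations, z-scored."""
    df = generate_cohort(default_config(3, 400), seed=7)
    return add_zscores(df, reference)


@pytest.fixture()
def tiny_reference_frame():
    """Minimal hand-made LMS table for closed-form checks (L=1 reduces
    the transform to (x - M) / (M * S))."""
    rows = []
    for key, M in [(100.0, 10.0), (200.0, 20.0)]:
        rows.append(("weight_for_age", "male", key, 1.0, M, 0.1))
        rows.append(("weight_for_age", "female", key, 1.0, M * 0.95, 0.1))
    return pd.DataFrame(rows, columns=["indicator", "sex", "key", "L", "M", "S"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


def sign_frame(hc_ids, statuses, values, sign="temperature"):
    """Minimal wide consultation table with one sign of interest filled."""
    from cdsaqc.signs import SIGN_ORDER

    n = len(statuses)
    df = pd.DataFrame(
        {
            "consultation_id": [f"c{i}" for i in range(n)],
            "hc_id": hc_ids if not isinstance(hc_ids, str) else [hc_ids] * n,
            "age_days": 400,
            "sex": "male",
            "respiratory_complaint": True,
        }
    )
    for s in SIGN_ORDER:
        df[f"{s}_status"] = "not_feasible"
        df[f"{s}_value"] = np.nan
    df[f"{sign}_status"] = statuses
    df[f"{sign}_value"] = values
    return df


def brute_force_quantile(values, q):
    """Independent linear-interpolation quantile oracle: rank
    h = q * (n - 1) interpolated between sorted order statistics."""
    v = sorted(values)
    h = q * (len(v) - 1)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])
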