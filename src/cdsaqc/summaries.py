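"""Per-facility, per-sign summary statistics and the pooled reference.

For every (facility, sign) pair the module computes the statistics the
pattern classifier compares: the fraction of eligible consultations with
no usable value (not feasible or estimated), the modal value and its
frequency on the recording grid, the cumulative frequency of the top
three values, mean, median and IQR of the measured values, and - for
z-score indicators - the fraction of extreme values (raw z below -2 or
above 2).  The pooled reference ("ALL") is the same computation over all
facilities combined, the facility under scrutiny included.

Conventions (the upstream description leaves them open, so they are
fixed here for reproducibility): quantiles use linear interpolation
between order statistics; modal ties break toward the smallest value;
facility-sign cells with fewer than ``min_n_measured`` (default 20)
usable values are marked insufficient and skipped by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from cdsaqc.signs import (
    ESTIMATED,
    MEASURED,
    NOT_APPLICABLE,
    SIGN_ORDER,
    SIGNS,
    Z_INDICATORS,
)

POOLED_ID = "ALL"

#: facility-sign cells below this many measured values are not classifiable
MIN_N_MEASURED = 20


@dataclass
class SignSummary:
    hc_id: str
    sign: str
    n_eligible: int
    n_measured: int
    missing_frac: float
    modal_value: float
    modal_frac: float
    top3: list[tuple[float, float]] = field(default_factory=list)
    mean: float = float("nan")
    median: float = float("nan")
    iqr: float = float("nan")
    extreme_z_frac: float = float("nan")
    insufficient_data: bool = False

    @property
    def top3_cum_frac(self) -> float:
        return float(sum(f for _, f in self.top3))


def _empty_summary(hc_id: str, sign: str, n_eligible: int = 0) -> SignSummary:
    return SignSummary(
        hc_id, sign, n_eligible, 0,
        missing_frac=1.0 if n_eligible else float("nan"),
        modal_value=float("nan"), modal_frac=float("nan"),
        insufficient_data=True,
    )


def _value_stats(values: np.ndarray) -> dict:
    """Mode / top-3 / quantile block shared by signs and z-indicators."""
    counts = pd.Series(values).value_counts()
    # ties toward the smallest value, then by descending frequency
    counts = counts.sort_index().sort_values(ascending=False, kind="stable")
    fracs = counts / len(values)
    top3 = [(float(v), float(f)) for v, f in fracs.iloc[:3].items()]
    q25, q50, q75 = np.percentile(values, [25, 50, 75])  # linear interpolation
    return {
        "modal_value": top3[0][0],
        "modal_frac": top3[0][1],
        "top3": top3,
        "mean": float(np.mean(values)),
        "median": float(q50),
        "iqr": float(q75 - q25),
    }


def summarize_sign(
    records: pd.DataFrame,
    hc_id: str,
    sign_id: str,
    min_n_measured: int = MIN_N_MEASURED,
) -> SignSummary:
    """Summary of one raw sign in one facility (or pooled, ``hc_id="ALL"``).

    Statistics are over measured values only; the missing fraction is the
    share of eligible consultations without a usable measurement
    (not feasible and estimated both count as missing).
    """
    if sign_id in Z_INDICATORS:
        return summarize_zscores(records, hc_id, sign_id, min_n_measured)
    if sign_id not in SIGNS:
        raise KeyError(f"unknown sign {sign_id!r}")
    sub = records if hc_id == POOLED_ID else records[records["hc_id"] == hc_id]
    status = sub[f"{sign_id}_status"].to_numpy(dtype=object)
    eligible = status != NOT_APPLICABLE
    n_eligible = int(eligible.sum())
    if n_eligible == 0:
        return _empty_summary(hc_id, sign_id)
    values = pd.to_numeric(sub[f"{sign_id}_value"], errors="coerce").to_numpy(dtype=float)
    measured = (status == MEASURED) & np.isfinite(values)
    n_measured = int(measured.sum())
    missing_frac = 1.0 - n_measured / n_eligible
    if n_measured == 0:
        return _empty_summary(hc_id, sign_id, n_eligible)
    stats = _value_stats(values[measured])
    return SignSummary(
        hc_id, sign_id, n_eligible, n_measured, missing_frac,
        insufficient_data=n_measured < min_n_measured, **stats,
    )


def summarize_zscores(
    records: pd.DataFrame,
    hc_id: str,
    indicator: str,
    min_n_measured: int = MIN_N_MEASURED,
) -> SignSummary:
    """Summary of a z-score indicator; statistics are over raw z-scores.

    ``extreme_z_frac`` is the fraction of computable records with raw z
    strictly below -2 or above 2.  The z-score has no not-feasible
    option in the app (it is simply not calculated when inputs are
    missing), so the missing fraction is not defined here.
    """
    if indicator not in Z_INDICATORS:
        raise KeyError(f"unknown z indicator {indicator!r}")
    col = f"{indicator}_zraw"
    if col not in records.columns:
        raise KeyError(f"column {col} absent - run add_zscores first")
    sub = records if hc_id == POOLED_ID else records[records["hc_id"] == hc_id]
    z = pd.to_numeric(sub[col], errors="coerce").to_numpy(dtype=float)
    z = z[np.isfinite(z)]
    n = len(z)
    if n == 0:
        return _empty_summary(hc_id, indicator)
    stats = _value_stats(np.round(z, 6))
    # mode/top-k reported on the clamped integer grid the app displays
    clamped = np.clip(np.sign(z) * np.floor(np.abs(z) + 0.5), -3, 3)
    cstats = _value_stats(clamped)
    stats.update(
        modal_value=cstats["modal_value"],
        modal_frac=cstats["modal_frac"],
        top3=cstats["top3"],
    )
    extreme = float(np.mean((z < -2.0) | (z > 2.0)))
    return SignSummary(
        hc_id, indicator, n, n, float("nan"),
        extreme_z_frac=extreme,
        insufficient_data=n < min_n_measured, **stats,
    )


def pooled_reference(records: pd.DataFrame, sign_or_indicator: str) -> SignSummary:
    """All-facility reference: identical computation over the union."""
    return summarize_sign(records, POOLED_ID, sign_or_indicator)


def summarize_cohort(
    records: pd.DataFrame,
    include_zscores: bool | None = None,
    min_n_measured: int = MIN_N_MEASURED,
) -> list[SignSummary]:
    """Summaries for every (facility, sign/indicator) plus pooled rows."""
    if include_zscores is None:
        include_zscores = f"{Z_INDICATORS[0]}_zraw" in records.columns
    names = list(SIGN_ORDER) + (list(Z_INDICATORS) if include_zscores else [])
    out = []
    # slice each facility once; re-filtering inside summarize_sign is then cheap
    for hc, sub in records.groupby("hc_id", sort=False):
        for name in names:
            out.append(summarize_sign(sub, hc, name, min_n_measured))
    for name in names:
        out.append(summarize_sign(records, POOLED_ID, name, min_n_measured))
    return out


# ---------------------------------------------------------------------------
# CSV serialization

def _serialize_top3(top3: list[tuple[float, float]]) -> str:
    return ";".join(f"{v:g}:{f:.6g}" for v, f in top3)


def _parse_top3(text) -> list[tuple[float, float]]:
    if not isinstance(text, str) or not text:
        return []
    out = []
    for part in text.split(";"):
        v, f = part.split(":")
        out.append((float(v), float(f)))
    return out


def summaries_frame(summaries: list[SignSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "hc_id": s.hc_id,
                "sign": s.sign,
                "n_eligible": s.n_eligible,
                "n_measured": s.n_measured,
                "missing_frac": s.missing_frac,
                "modal_value": s.modal_value,
                "modal_frac": s.modal_frac,
                "top3": _serialize_top3(s.top3),
                "mean": s.mean,
                "median": s.median,
                "iqr": s.iqr,
                "extreme_z_frac": s.extreme_z_frac,
                "insufficient_data": s.insufficient_data,
            }
        )
    return pd.DataFrame(rows)


def write_summaries(summaries: list[SignSummary], path: str | Path) -> None:
    summaries_frame(summaries).to_csv(path, index=False, encoding="utf-8")


def read_summaries(path: str | Path) -> list[SignSummary]:
    df = pd.read_csv(path, dtype={"hc_id": str, "sign": str}, encoding="utf-8")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SignSummary(
                hc_id=row.hc_id,
                sign=row.sign,
                n_eligible=int(row.n_eligible),
                n_measured=int(row.n_measured),
                missing_frac=float(row.missing_frac),
                modal_value=float(row.modal_value),
                modal_frac=float(row.modal_frac),
                top3=_parse_top3(row.top3),
                mean=float(row.mean),
                median=float(row.median),
                iqr=float(row.iqr),
                extreme_z_frac=float(row.extreme_z_frac),
                insufficient_data=bool(row.insufficient_data),
            )
        )
    return out
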