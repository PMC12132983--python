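"""Descriptive analysis of prospectively observed consultations.

During structured observation of routine consultations, a study
clinician recorded for each prompted sign whether the assessment was
performed or skipped, graded performed assessments as sufficient or
insufficient, and collected the healthcare worker's reasons (a record
may carry several reasons, so reason prevalences within a category can
sum to more than 100%).

The module tabulates such observation records into per-sign
performed/skipped/sufficient/insufficient proportions and per-reason
counts and prevalences, and compares sufficiency between measurement
methods (respiratory rate by mobile app versus one-minute timer).  It
also bundles a record-level fixture whose marginal counts reproduce the
published tallies of one 188-consultation observation round; the
denominators of the signs prompted only in sub-groups are not printed in
that source and are chosen here to be consistent with its reported
percentages (see ``FIXTURE_TOTALS``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

OBSERVATION_COLUMNS = (
    "consultation_id", "hc_id", "sign", "performed", "quality", "method", "reasons"
)

SUFFICIENT = "sufficient"
INSUFFICIENT = "insufficient"
CATEGORY_SKIP = "skip"
CATEGORY_INSUFFICIENT = "insufficient"

#: per-sign number of observed consultations in the bundled fixture.
#: Temperature, weight and height were prompted for all 188 observed
#: consultations; the other totals are package-chosen denominators
#: consistent with the published skip/insufficiency percentages
#: (e.g. 33/89 = 37% skipped heart rate) and, for respiratory rate,
#: with the 39+39 app-versus-timer measurement counts.
FIXTURE_TOTALS = {
    "temperature": 188,
    "muac": 177,
    "weight": 188,
    "height": 188,
    "heart_rate": 89,
    "spo2": 82,
    "resp_rate": 136,
}

_SKIP_N = {
    "temperature": 14, "muac": 31, "weight": 25, "height": 39,
    "heart_rate": 33, "spo2": 27, "resp_rate": 58,
}
_INSUFFICIENT_N = {
    "temperature": 126, "muac": 122, "weight": 132, "height": 101,
    "heart_rate": 27, "spo2": 27, "resp_rate": 31,
}

#: reason code -> (count) per sign and category; order follows the
#: published tables (descending count)
FIXTURE_REASONS = {
    ("temperature", CATEGORY_SKIP): [
        ("forgot", 8), ("checked_hot_only", 5), ("no_thermometer", 1),
    ],
    ("temperature", CATEGORY_INSUFFICIENT): [
        ("thermometer_distance", 102), ("thermometer_location", 88), ("reading_too_early", 16),
    ],
    ("muac", CATEGORY_SKIP): [
        ("not_necessary", 16), ("child_too_old", 7), ("copied_health_card", 6),
        ("reused_previous_day", 1), ("child_agitated", 1),
    ],
    ("muac", CATEGORY_INSUFFICIENT): [
        ("ribbon_location", 111), ("child_too_young", 10), ("ribbon_too_tight", 5),
        ("ribbon_over_clothes", 2), ("ribbon_too_loose", 1),
    ],
    ("weight", CATEGORY_SKIP): [
        ("not_necessary", 14), ("copied_health_card", 9),
        ("reused_previous_day", 1), ("child_agitated", 1),
    ],
    ("weight", CATEGORY_INSUFFICIENT): [
        ("heavily_dressed", 117), ("wearing_shoes", 83), ("partially_supported", 13),
        ("balance_not_calibrated", 3), ("holding_objects", 3),
    ],
    ("height", CATEGORY_SKIP): [
        ("no_meter", 13), ("not_necessary", 11), ("estimated_visually", 11),
        ("agitated_or_injured", 4), ("reused_previous_day", 1),
    ],
    ("height", CATEGORY_INSUFFICIENT): [
        ("shoes_or_hat", 62), ("not_touching_board", 53), ("not_looking_straight", 25),
        ("meter_not_straight", 12), ("bad_zero_or_meter", 5),
    ],
    ("heart_rate", CATEGORY_SKIP): [
        ("not_necessary", 22), ("too_time_consuming", 17), ("oximeter_broken", 4),
        ("child_agitated", 4), ("forgot", 2), ("urgent_referral", 1),
    ],
    ("heart_rate", CATEGORY_INSUFFICIENT): [
        ("probe_size_unavailable", 15), ("probe_position", 14),
    ],
    ("spo2", CATEGORY_SKIP): [
        ("not_necessary", 16), ("too_time_consuming", 11), ("oximeter_broken", 4),
        ("child_agitated", 4), ("forgot", 2), ("urgent_referral", 1),
    ],
    ("spo2", CATEGORY_INSUFFICIENT): [
        ("probe_size_unavailable", 15), ("probe_position", 14),
    ],
    ("resp_rate", CATEGORY_SKIP): [
        ("not_necessary", 35), ("too_time_consuming", 16), ("forgot", 10),
        ("child_agitated", 5), ("no_timer_or_app", 3), ("used_oximeter", 2),
        ("urgent_referral", 1),
    ],
    ("resp_rate", CATEGORY_INSUFFICIENT): [
        ("underestimation", 7), ("abdomen_covered", 6), ("forgot_value", 5),
        ("not_full_minute", 4), ("child_agitated", 3), ("timer_not_reset", 3),
        ("overestimation", 2), ("child_standing", 2),
    ],
}

#: respiratory-rate measurement methods in the fixture:
#: (n performed, n sufficient) per method
FIXTURE_RR_METHODS = {"rrate_app": (39, 29), "timer": (39, 18)}


def reason_labels() -> dict[str, str]:
    """Human-readable labels for the reason codes (bundled YAML)."""
    text = resources.files("cdsaqc").joinpath("data", "reason_codes.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def round_half_up(x: float) -> int:
    """Round half away from zero (the convention of the printed tables)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


# ---------------------------------------------------------------------------
# bundled record-level fixture

def _assign_reasons(n: int, reason_counts: list[tuple[str, int]]) -> list[str]:
    """Distribute multi-select reasons over ``n`` records so that the
    marginal count of each reason is honored.  Assignment rotates a
    cursor through the records (deterministic and reproducible); the
    source reports only marginal counts, so co-occurrence is arbitrary."""
    slots: list[list[str]] = [[] for _ in range(n)]
    cursor = 0
    for code, count in reason_counts:
        if count > n:
            raise ValueError(f"reason {code}: count {count} exceeds category size {n}")
        for i in range(count):
            slots[(cursor + i) % n].append(code)
        cursor += count
    return [";".join(r) for r in slots]


def bundled_observation_records(n_facilities: int = 10) -> pd.DataFrame:
    """Record-level expansion of the bundled observation tallies.

    One row per consultation x prompted sign.  Consultations are spread
    round-robin over ``n_facilities`` facilities; which consultations
    fall in which tally cell is arbitrary (only marginal counts are
    reported by the source), so records are laid out in cell order.
    """
    rows = []
    for sign, total in FIXTURE_TOTALS.items():
        n_skip = _SKIP_N[sign]
        n_insuff = _INSUFFICIENT_N[sign]
        n_suff = total - n_skip - n_insuff
        skip_reasons = _assign_reasons(n_skip, FIXTURE_REASONS[(sign, CATEGORY_SKIP)])
        insuff_reasons = _assign_reasons(n_insuff, FIXTURE_REASONS[(sign, CATEGORY_INSUFFICIENT)])

        if sign == "resp_rate":
            methods = []
            quality_by_method = []
            for method, (n_meth, n_meth_suff) in FIXTURE_RR_METHODS.items():
                methods += [method] * n_meth
                quality_by_method += [SUFFICIENT] * n_meth_suff + [INSUFFICIENT] * (
                    n_meth - n_meth_suff
                )
            performed = list(zip(methods, quality_by_method))
            # lay out insufficient first to pair with the reason lists
            performed.sort(key=lambda mq: mq[1] == SUFFICIENT)
        else:
            performed = [("", INSUFFICIENT)] * n_insuff + [("", SUFFICIENT)] * n_suff

        insuff_iter = iter(insuff_reasons)
        idx = 0
        for reasons in skip_reasons:
            rows.append((f"OBS-{idx + 1:03d}", sign, "no", "", "", reasons))
            idx += 1
        for method, quality in performed:
            reasons = next(insuff_iter) if quality == INSUFFICIENT else ""
            rows.append((f"OBS-{idx + 1:03d}", sign, "yes", quality, method, reasons))
            idx += 1

    df = pd.DataFrame(
        rows, columns=["consultation_id", "sign", "performed", "quality", "method", "reasons"]
    )
    ids = df["consultation_id"].str.slice(4).astype(int)
    df.insert(1, "hc_id", "HC-" + ((ids - 1) % n_facilities + 1).astype(str).str.zfill(2))
    return df[list(OBSERVATION_COLUMNS)]


# ---------------------------------------------------------------------------
# validation and tabulation

def validate_observations(records: pd.DataFrame) -> None:
    """Check the observation-record invariants; raise ValueError listing
    the offending rows."""
    problems = []
    missing = [c for c in OBSERVATION_COLUMNS if c not in records.columns and c != "method"]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    performed = records["performed"].astype(str).str.lower()
    bad = ~performed.isin(("yes", "no"))
    if bad.any():
        problems.append(f"performed must be yes/no (rows {list(records.index[bad])[:5]})")
    quality = records["quality"].fillna("").astype(str)
    bad = (performed == "no") & (quality != "")
    if bad.any():
        problems.append(f"quality present for skipped assessments (rows {list(records.index[bad])[:5]})")
    bad = (performed == "yes") & ~quality.isin((SUFFICIENT, INSUFFICIENT))
    if bad.any():
        problems.append(f"performed assessments need a sufficient/insufficient grade (rows {list(records.index[bad])[:5]})")
    known = set(reason_labels())
    listed = records["reasons"].fillna("").astype(str)
    for idx, text in listed.items():
        codes = [c for c in text.split(";") if c]
        unknown = [c for c in codes if c not in known]
        if unknown:
            problems.append(f"row {idx}: unknown reason code(s) {unknown}")
    if problems:
        raise ValueError("invalid observation records: " + "; ".join(problems))


@dataclass(frozen=True)
class SignObservationTally:
    sign: str
    n_total: int
    n_skipped: int
    n_sufficient: int
    n_insufficient: int

    @property
    def pct_skipped(self) -> int:
        return round_half_up(100 * self.n_skipped / self.n_total)

    @property
    def pct_sufficient(self) -> int:
        return round_half_up(100 * self.n_sufficient / self.n_total)

    @property
    def pct_insufficient(self) -> int:
        return round_half_up(100 * self.n_insufficient / self.n_total)


def tabulate_observations(records: pd.DataFrame) -> list[SignObservationTally]:
    """Per-sign performed/skipped and quality tallies.

    Denominators are per-sign record counts, since signs differ in
    eligibility and hence in the number of observed assessments.
    """
    validate_observations(records)
    out = []
    for sign, grp in records.groupby("sign", sort=False):
        performed = grp["performed"].astype(str).str.lower() == "yes"
        quality = grp["quality"].fillna("").astype(str)
        n_skip = int((~performed).sum())
        n_suff = int((performed & (quality == SUFFICIENT)).sum())
        n_insuff = int((performed & (quality == INSUFFICIENT)).sum())
        out.append(SignObservationTally(sign, len(grp), n_skip, n_suff, n_insuff))
    return out


@dataclass(frozen=True)
class ReasonTally:
    sign: str
    category: str
    reason: str
    label: str
    count: int
    n_category: int

    @property
    def prevalence_pct(self) -> int:
        return round_half_up(100 * self.count / self.n_category)


def tabulate_reasons(records: pd.DataFrame, sign: str, category: str) -> list[ReasonTally]:
    """Reason counts and prevalences for one sign and category.

    ``category`` is ``"skip"`` (reasons for skipping; denominator = all
    skipped assessments) or ``"insufficient"`` (reasons for poor
    quality; denominator = all insufficient assessments).  Records carry
    multi-select reasons, so prevalences may sum above 100%.
    """
    validate_observations(records)
    if category not in (CATEGORY_SKIP, CATEGORY_INSUFFICIENT):
        raise ValueError(f"unknown category {category!r}")
    grp = records[records["sign"] == sign]
    performed = grp["performed"].astype(str).str.lower() == "yes"
    if category == CATEGORY_SKIP:
        grp = grp[~performed]
    else:
        grp = grp[performed & (grp["quality"].fillna("") == INSUFFICIENT)]
    n_cat = len(grp)
    counts: dict[str, int] = {}
    for text in grp["reasons"].fillna("").astype(str):
        for code in (c for c in text.split(";") if c):
            counts[code] = counts.get(code, 0) + 1
    labels = reason_labels()
    tallies = [
        ReasonTally(sign, category, code, labels[code], count, n_cat)
        for code, count in counts.items()
    ]
    tallies.sort(key=lambda t: (-t.count, t.reason))
    return tallies


def tabulate_all_reasons(records: pd.DataFrame) -> pd.DataFrame:
    """Long-format reason table across all signs and both categories."""
    rows = []
    for sign in records["sign"].unique():
        for category in (CATEGORY_SKIP, CATEGORY_INSUFFICIENT):
            for t in tabulate_reasons(records, sign, category):
                rows.append(
                    (t.sign, t.category, t.reason, t.label, t.count, t.n_category, t.prevalence_pct)
                )
    return pd.DataFrame(
        rows,
        columns=["sign", "category", "reason", "label", "count", "n_category", "prevalence_pct"],
    )


@dataclass(frozen=True)
class MethodTally:
    method: str
    n: int
    n_sufficient: int

    @property
    def pct_sufficient(self) -> int:
        return round_half_up(100 * self.n_sufficient / self.n)


def compare_methods(
    records: pd.DataFrame, sign: str, method_field: str = "method"
) -> list[MethodTally]:
    """Sufficiency proportions per measurement method for one sign.

    Only performed assessments with a recorded method are counted;
    methods with zero records are naturally absent from the output.
    """
    validate_observations(records)
    grp = records[records["sign"] == sign]
    performed = grp["performed"].astype(str).str.lower() == "yes"
    grp = grp[performed & grp[method_field].fillna("").astype(str).ne("")]
    out = []
    for method, sub in grp.groupby(method_field, sort=True):
        n_suff = int((sub["quality"] == SUFFICIENT).sum())
        out.append(MethodTally(str(method), len(sub), n_suff))
    return out


def read_observations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    if "method" not in df.columns:
        df["method"] = ""
    for col in ("quality", "method", "reasons"):
        df[col] = df[col].fillna("")
    return df


def observation_frame(tallies: list[SignObservationTally]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (t.sign, t.n_total, t.n_skipped, t.n_sufficient, t.n_insufficient,
             t.pct_skipped, t.pct_sufficient, t.pct_insufficient)
            for t in tallies
        ],
        columns=[
            "sign", "n_total", "n_skipped", "n_sufficient", "n_insufficient",
            "pct_skipped", "pct_sufficient", "pct_insufficient",
        ],
    )
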