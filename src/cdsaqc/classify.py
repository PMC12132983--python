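"""Rule-based pattern classification of facility-sign summaries.

Each (facility, sign) summary is compared against the pooled
all-facility reference and may be labeled with one or more of four
pattern types at one of three severities:

* **skipper** - excess missing/not-feasible fraction;
* **mono-repeater** - excess frequency of a single value (heaping on one
  preferred number), supported by IQR shrinkage;
* **multi-repeater** - excess cumulative frequency of the top 2-3
  values, supported by IQR shrinkage;
* **wrongly evaluated** - excess extreme z-score fraction, or an
  implausible mean for temperature and vitals.

Severity bands default to the 5-10 / 10-30 / >30 percentage-point
scheme for frequency-type statistics and 25-50 / 50-100 / >100 % for
IQR shrinkage.  "X% more frequent than the reference" is read as an
absolute percentage-point difference of fractions (a relative-ratio
reading is available via ``relative_excess``).  IQR shrinkage is
measured relative to the facility's own IQR, ``(ref - hc) / hc``, so
">100% smaller" means the facility's IQR is less than half the
reference.  A facility is shortlisted for in-person observation when at
least two of its signs are flagged and at least one flag is moderate or
severe.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from cdsaqc.signs import SIGN_ORDER, Z_INDICATORS
from cdsaqc.summaries import POOLED_ID, SignSummary

logger = logging.getLogger(__name__)

SEVERITIES = ("mild", "moderate", "severe")
_SEV_RANK = {s: i for i, s in enumerate(SEVERITIES)}

#: detection applicability: which pattern types are meaningful per sign.
#: Skipping cannot be detected for temperature (a follow-up question
#: replaces the value), weight (no not-feasible option) or z-scores
#: (never "skipped", only not calculated); repeaters are meaningless for
#: weight/height (age-driven distributions) and z-scores; wrong
#: evaluation of weight/height surfaces through the z-indicators.
APPLICABILITY: dict[str, frozenset] = {
    "temperature": frozenset({"mono_repeater", "multi_repeater", "wrongly_evaluated"}),
    "muac": frozenset({"skipper", "mono_repeater", "multi_repeater", "wrongly_evaluated"}),
    "weight": frozenset(),
    "height": frozenset({"skipper"}),
    "heart_rate": frozenset({"skipper", "mono_repeater", "multi_repeater", "wrongly_evaluated"}),
    "spo2": frozenset({"skipper", "mono_repeater", "multi_repeater", "wrongly_evaluated"}),
    "resp_rate": frozenset({"skipper", "mono_repeater", "multi_repeater", "wrongly_evaluated"}),
    "muac_for_age": frozenset({"wrongly_evaluated"}),
    "weight_for_age": frozenset({"wrongly_evaluated"}),
    "weight_for_height": frozenset({"wrongly_evaluated"}),
}

_DEFAULT_PLAUSIBLE = {
    "temperature": (35.0, 40.5),
    "muac": (8.0, 25.0),
    "heart_rate": (55.0, 185.0),
    "spo2": (88.0, 100.0),
    "resp_rate": (12.0, 80.0),
}


class ThresholdConfigError(ValueError):
    pass


def _check_bands(name: str, bands: tuple[float, float, float]) -> None:
    if not (0 < bands[0] < bands[1] < bands[2]):
        raise ThresholdConfigError(f"{name}: bands must be increasing and positive")


@dataclass
class ThresholdConfig:
    """Severity band edges and plausibility ranges.

    A triple ``(t1, t2, t3)`` maps an excess statistic ``e`` to: no flag
    for ``e < t1``, mild for ``t1 <= e < t2``, moderate for
    ``t2 <= e <= t3`` and severe for ``e > t3``.
    """

    skipper_bands: tuple[float, float, float] = (0.05, 0.10, 0.30)
    repeater_freq_bands: tuple[float, float, float] = (0.05, 0.10, 0.30)
    iqr_shrink_bands: tuple[float, float, float] = (0.25, 0.50, 1.00)
    wrong_z_bands: tuple[float, float, float] = (0.05, 0.10, 0.30)
    plausible_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_PLAUSIBLE)
    )
    #: read "X% more frequent" as a relative ratio instead of an
    #: absolute percentage-point difference
    relative_excess: bool = False
    #: a mono-repeater additionally requires the single modal excess to
    #: account for at least this share of the top-3 excess, so heaping
    #: spread over several values is not mislabeled as mono
    mono_dominance: float = 0.6

    def __post_init__(self) -> None:
        for name in ("skipper_bands", "repeater_freq_bands", "iqr_shrink_bands", "wrong_z_bands"):
            bands = tuple(float(x) for x in getattr(self, name))
            setattr(self, name, bands)
            _check_bands(name, bands)
        self.plausible_ranges = {
            k: (float(lo), float(hi)) for k, (lo, hi) in self.plausible_ranges.items()
        }


def load_thresholds(source: str | Path | dict | None = None) -> ThresholdConfig:
    """Threshold config from YAML (missing keys keep their defaults)."""
    if source is None:
        return ThresholdConfig()
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    kwargs = {}
    for key in ("skipper_bands", "repeater_freq_bands", "iqr_shrink_bands", "wrong_z_bands"):
        if key in raw:
            kwargs[key] = tuple(raw[key])
    if "plausible_ranges" in raw:
        ranges = dict(_DEFAULT_PLAUSIBLE)
        ranges.update({k: tuple(v) for k, v in raw["plausible_ranges"].items()})
        kwargs["plausible_ranges"] = ranges
    for key in ("relative_excess", "mono_dominance"):
        if key in raw:
            kwargs[key] = raw[key]
    return ThresholdConfig(**kwargs)


@dataclass(frozen=True)
class PatternFlag:
    hc_id: str
    sign: str
    pattern_type: str
    severity: str
    evidence: dict

    def __post_init__(self) -> None:
        if self.pattern_type not in APPLICABILITY.get(self.sign, frozenset()):
            raise ValueError(f"{self.pattern_type} is not applicable to {self.sign}")
        if self.severity not in SEVERITIES:
            raise ValueError(f"unknown severity {self.severity!r}")


def _band(value: float, bands: tuple[float, float, float]) -> str | None:
    # bands (t1, t2, t3): mild [t1, t2), moderate [t2, t3], severe > t3 -
    # the published wording puts the upper edge in the moderate range
    # ("10-30%" moderate, ">30%" severe)
    if not value == value or value < bands[0]:  # NaN-safe
        return None
    if value < bands[1]:
        return "mild"
    if value <= bands[2]:
        return "moderate"
    return "severe"


def _excess(summary_value: float, reference_value: float, relative: bool) -> float:
    e = summary_value - reference_value
    if relative:
        return e / reference_value if reference_value > 0 else float("inf") if e > 0 else 0.0
    return e


def _max_severity(*severities: str | None) -> str | None:
    present = [s for s in severities if s is not None]
    if not present:
        return None
    return max(present, key=_SEV_RANK.__getitem__)


def classify_skipper(
    summary: SignSummary, reference: SignSummary, config: ThresholdConfig
) -> PatternFlag | None:
    """Excess missing/not-feasible fraction against the pooled reference."""
    excess = _excess(summary.missing_frac, reference.missing_frac, config.relative_excess)
    severity = _band(excess, config.skipper_bands)
    if severity is None:
        return None
    return PatternFlag(
        summary.hc_id, summary.sign, "skipper", severity,
        evidence={
            "statistic": "missing_frac",
            "facility": summary.missing_frac,
            "reference": reference.missing_frac,
            "excess": excess,
        },
    )


def classify_repeater(
    summary: SignSummary, reference: SignSummary, config: ThresholdConfig
) -> PatternFlag | None:
    """Value heaping: mono (one value) or multi (2-3 values) repeater.

    The frequency criterion and the IQR-shrinkage criterion are combined
    by OR, with the final severity being the maximum of the two.  A mono
    flag takes precedence over multi when both frequency bands are met
    and the single modal excess dominates the top-3 excess.
    """
    excess_modal = _excess(summary.modal_frac, reference.modal_frac, config.relative_excess)
    excess_top3 = _excess(summary.top3_cum_frac, reference.top3_cum_frac, config.relative_excess)
    sev_mono = _band(excess_modal, config.repeater_freq_bands)
    sev_multi = _band(excess_top3, config.repeater_freq_bands)

    if summary.iqr == 0 and reference.iqr > 0:
        sev_iqr, shrink = "severe", float("inf")  # collapsed dispersion
    elif summary.iqr > 0:
        shrink = (reference.iqr - summary.iqr) / summary.iqr
        sev_iqr = _band(shrink, config.iqr_shrink_bands)
    else:
        sev_iqr, shrink = None, float("nan")

    mono_dominates = excess_top3 <= 0 or excess_modal >= config.mono_dominance * excess_top3
    if sev_mono is not None and mono_dominates:
        pattern, sev_freq = "mono_repeater", sev_mono
    elif sev_multi is not None:
        pattern, sev_freq = "multi_repeater", sev_multi
    elif sev_iqr is not None:
        pattern = "mono_repeater" if mono_dominates else "multi_repeater"
        sev_freq = None
    else:
        return None

    severity = _max_severity(sev_freq, sev_iqr)
    return PatternFlag(
        summary.hc_id, summary.sign, pattern, severity,
        evidence={
            "statistic": "modal_frac" if pattern == "mono_repeater" else "top3_cum_frac",
            "facility_modal_frac": summary.modal_frac,
            "reference_modal_frac": reference.modal_frac,
            "facility_top3_frac": summary.top3_cum_frac,
            "reference_top3_frac": reference.top3_cum_frac,
            "excess_modal": excess_modal,
            "excess_top3": excess_top3,
            "iqr_shrink": shrink,
            "frequency_severity": sev_freq,
            "iqr_severity": sev_iqr,
        },
    )


def classify_wrongly_evaluated(
    summary: SignSummary, reference: SignSummary, config: ThresholdConfig
) -> PatternFlag | None:
    """Outlier excess: extreme z-scores for indicators, implausible mean
    for temperature and vitals (the latter is always a mild flag)."""
    if summary.sign in Z_INDICATORS:
        excess = _excess(summary.extreme_z_frac, reference.extreme_z_frac, config.relative_excess)
        severity = _band(excess, config.wrong_z_bands)
        if severity is None:
            return None
        return PatternFlag(
            summary.hc_id, summary.sign, "wrongly_evaluated", severity,
            evidence={
                "statistic": "extreme_z_frac",
                "facility": summary.extreme_z_frac,
                "reference": reference.extreme_z_frac,
                "excess": excess,
            },
        )
    try:
        lo, hi = config.plausible_ranges[summary.sign]
    except KeyError as exc:
        raise ThresholdConfigError(
            f"no plausible range configured for sign {summary.sign!r}"
        ) from exc
    if lo <= summary.mean <= hi:
        return None
    return PatternFlag(
        summary.hc_id, summary.sign, "wrongly_evaluated", "mild",
        evidence={
            "statistic": "mean",
            "facility": summary.mean,
            "plausible_range": [lo, hi],
        },
    )


_CLASSIFIERS = {
    "skipper": classify_skipper,
    "mono_repeater": classify_repeater,       # repeater handles both subtypes
    "multi_repeater": classify_repeater,
    "wrongly_evaluated": classify_wrongly_evaluated,
}


def classify_facility(
    summaries: list[SignSummary],
    references: dict[str, SignSummary],
    config: ThresholdConfig | None = None,
) -> list[PatternFlag]:
    """All flags for one facility: union of the applicable classifiers.

    A sign may carry several flags (e.g. skipper and mono-repeater).
    Summaries marked as insufficient data are skipped with a log notice.
    """
    config = config or ThresholdConfig()
    flags: list[PatternFlag] = []
    for summary in summaries:
        if summary.sign not in references:
            raise KeyError(f"no reference summary for {summary.sign!r}")
        if summary.insufficient_data:
            logger.info(
                "skipping %s/%s: insufficient data (n_measured=%d)",
                summary.hc_id, summary.sign, summary.n_measured,
            )
            continue
        reference = references[summary.sign]
        allowed = APPLICABILITY.get(summary.sign, frozenset())
        if "skipper" in allowed:
            flag = classify_skipper(summary, reference, config)
            if flag:
                flags.append(flag)
        if "mono_repeater" in allowed or "multi_repeater" in allowed:
            flag = classify_repeater(summary, reference, config)
            if flag:
                flags.append(flag)
        if "wrongly_evaluated" in allowed:
            flag = classify_wrongly_evaluated(summary, reference, config)
            if flag:
                flags.append(flag)
    return flags


def classify_cohort_summaries(
    summaries: list[SignSummary], config: ThresholdConfig | None = None
) -> list[PatternFlag]:
    """Classify every facility in a full summary set (with "ALL" rows)."""
    references = {s.sign: s for s in summaries if s.hc_id == POOLED_ID}
    flags: list[PatternFlag] = []
    for hc_id in dict.fromkeys(s.hc_id for s in summaries):
        if hc_id == POOLED_ID:
            continue
        facility = [s for s in summaries if s.hc_id == hc_id]
        flags.extend(classify_facility(facility, references, config))
    return flags


def select_health_centers(flags: list[PatternFlag]) -> set[str]:
    """Facilities warranting observation: at least two flagged signs and
    at least one flag of moderate or severe deviation."""
    by_hc: dict[str, list[PatternFlag]] = {}
    for flag in flags:
        by_hc.setdefault(flag.hc_id, []).append(flag)
    selected = set()
    for hc_id, hc_flags in by_hc.items():
        n_signs = len({f.sign for f in hc_flags})
        strong = any(f.severity in ("moderate", "severe") for f in hc_flags)
        if n_signs >= 2 and strong:
            selected.add(hc_id)
    return selected


# ---------------------------------------------------------------------------
# flag serialization

def flags_frame(flags: list[PatternFlag]) -> pd.DataFrame:
    rows = [
        {
            "hc_id": f.hc_id,
            "sign": f.sign,
            "pattern_type": f.pattern_type,
            "severity": f.severity,
            "evidence": json.dumps(f.evidence, sort_keys=True),
        }
        for f in flags
    ]
    return pd.DataFrame(rows, columns=["hc_id", "sign", "pattern_type", "severity", "evidence"])


def write_flags(flags: list[PatternFlag], path: str | Path) -> None:
    flags_frame(flags).to_csv(path, index=False, encoding="utf-8")


def read_flags(path: str | Path) -> list[PatternFlag]:
    df = pd.read_csv(path, dtype=str, encoding="utf-8")
    return [
        PatternFlag(
            row.hc_id, row.sign, row.pattern_type, row.severity,
            evidence=json.loads(row.evidence) if isinstance(row.evidence, str) else {},
        )
        for row in df.itertuples(index=False)
    ]
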