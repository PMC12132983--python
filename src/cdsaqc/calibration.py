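"""Simulation-based calibration of the pattern classifier.

The retrospective dataset behind the method is not redistributable, so
the classifier is validated by two simulation experiments instead:

* **Null calibration** - behavior-free cohorts in which every facility
  shares the same generative settings.  Any flag is a false positive;
  the fraction of flag-free facility-sign pairs measures specificity.

* **Injection recovery** - one behavior injected per cohort at the
  center of a severity band; the classifier should recover the injected
  (sign, pattern type) and the injected severity.  The severe band is
  open-ended (anything above the top edge), so its "center" is a
  representative point at 1.5x the edge.

Repeater injections target popular or round values (the phenomenon the
repeater patterns describe is heaping on preferred numbers), e.g.
36.5/37 °C or the 14-16 cm integer grid for MUAC.  Wrong-evaluation
injections go into weight and MUAC and are recovered through the
z-score indicators they distort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cdsaqc.classify import ThresholdConfig, classify_cohort_summaries
from cdsaqc.growth import GrowthReferenceTable, load_reference
from cdsaqc.signs import SIGN_ORDER, Z_INDICATORS
from cdsaqc.simulate import BehaviorAssignment, BehaviorSpec, default_config, generate_cohort
from cdsaqc.summaries import POOLED_ID, summarize_cohort
from cdsaqc.growth import add_zscores

#: intensity at the center of each severity band of the default
#: frequency-type thresholds (0.05-0.10 / 0.10-0.30 / >0.30)
BAND_CENTER_INTENSITY = {"mild": 0.075, "moderate": 0.20, "severe": 0.45}

MONO_TARGETS = {
    "temperature": (36.5,),
    "heart_rate": (115.0,),
    "resp_rate": (38.0,),
    "spo2": (97.0,),
    "muac": (14.0,),
}
MULTI_TARGETS = {
    "temperature": (36.5, 36.8, 37.0),
    "heart_rate": (110.0, 115.0, 120.0),
    "resp_rate": (35.0, 38.0, 40.0),
    "muac": (14.0, 15.0, 16.0),
}

#: a wrong-evaluation injection into a raw sign is recovered when the
#: flag lands on any of these signs/indicators
RECOVERY_SIGNS = {
    "weight": frozenset({"weight_for_age", "weight_for_height"}),
    "muac": frozenset({"muac_for_age"}),
}

_SKIPPER_SIGNS = ("height", "heart_rate", "resp_rate", "spo2", "muac")
_MONO_SIGNS = ("temperature", "heart_rate", "resp_rate", "spo2", "muac")
_MULTI_SIGNS = ("temperature", "heart_rate", "resp_rate", "muac")
_WRONG_SIGNS = ("weight", "muac")


def recovery_combinations() -> list[tuple[str, str, str]]:
    """Deterministic cycle of (pattern, sign, severity) injection cases."""
    combos = []
    for severity in BAND_CENTER_INTENSITY:
        combos += [("skipper", s, severity) for s in _SKIPPER_SIGNS]
        combos += [("mono_repeater", s, severity) for s in _MONO_SIGNS]
        combos += [("multi_repeater", s, severity) for s in _MULTI_SIGNS]
        combos += [("wrongly_evaluated", s, severity) for s in _WRONG_SIGNS]
    return combos


def _run_seed(seed: int, run: int) -> int:
    return (seed * 1_000_003 + 7919 * run + 1) % (2**31)


@dataclass
class RecoveryResult:
    n_runs: int
    n_type_recovered: int
    n_severity_recovered: int

    @property
    def type_rate(self) -> float:
        return self.n_type_recovered / self.n_runs

    @property
    def severity_rate(self) -> float:
        return self.n_severity_recovered / self.n_runs


def run_injection_recovery(
    n_runs: int = 50,
    n_facilities: int = 16,
    n_per_facility: int = 2000,
    seed: int = 0,
    thresholds: ThresholdConfig | None = None,
    reference: GrowthReferenceTable | None = None,
) -> RecoveryResult:
    """Inject one behavior per seeded cohort and score classifier recovery."""
    reference = reference or load_reference()
    combos = recovery_combinations()
    target_hc = "HC-03"
    n_type = n_sev = 0
    for run in range(n_runs):
        pattern, sign, severity = combos[run % len(combos)]
        intensity = BAND_CENTER_INTENSITY[severity]
        if pattern == "mono_repeater":
            targets = MONO_TARGETS[sign]
        elif pattern == "multi_repeater":
            targets = MULTI_TARGETS[sign]
        else:
            targets = ()
        cfg = default_config(n_facilities, n_per_facility)
        cfg.behaviors = [
            BehaviorAssignment(target_hc, sign, BehaviorSpec(pattern, intensity, targets))
        ]
        cohort = add_zscores(generate_cohort(cfg, _run_seed(seed, run)), reference)
        flags = classify_cohort_summaries(summarize_cohort(cohort), thresholds)
        wanted = RECOVERY_SIGNS.get(sign, frozenset({sign})) if pattern == "wrongly_evaluated" else {sign}
        hits = [
            f for f in flags
            if f.hc_id == target_hc and f.sign in wanted and f.pattern_type == pattern
        ]
        n_type += bool(hits)
        n_sev += any(f.severity == severity for f in hits)
    return RecoveryResult(n_runs, n_type, n_sev)


@dataclass
class NullCalibrationResult:
    n_pairs: int
    n_flagged_pairs: int
    max_missing_frac_deviation: float
    max_modal_frac_deviation: float

    @property
    def clean_pair_rate(self) -> float:
        return 1.0 - self.n_flagged_pairs / self.n_pairs


def run_null_calibration(
    n_seeds: int = 20,
    n_facilities: int = 16,
    n_per_facility: int = 20000,
    seed: int = 0,
    thresholds: ThresholdConfig | None = None,
    reference: GrowthReferenceTable | None = None,
) -> NullCalibrationResult:
    """False-positive rate of the classifier on behavior-free cohorts.

    Also tracks how far individual facilities stray from the pooled
    reference (max absolute deviation of missing and modal fractions),
    a convergence diagnostic for the generator itself.
    """
    reference = reference or load_reference()
    cfg = default_config(n_facilities, n_per_facility)
    n_cells = n_facilities * (len(SIGN_ORDER) + len(Z_INDICATORS))
    flagged = 0
    max_missing_dev = max_modal_dev = 0.0
    for run in range(n_seeds):
        cohort = add_zscores(generate_cohort(cfg, _run_seed(seed, run)), reference)
        summaries = summarize_cohort(cohort)
        flags = classify_cohort_summaries(summaries, thresholds)
        flagged += len({(f.hc_id, f.sign) for f in flags})
        pooled = {s.sign: s for s in summaries if s.hc_id == POOLED_ID}
        for s in summaries:
            if s.hc_id == POOLED_ID:
                continue
            ref = pooled[s.sign]
            if np.isfinite(s.missing_frac) and np.isfinite(ref.missing_frac):
                max_missing_dev = max(max_missing_dev, abs(s.missing_frac - ref.missing_frac))
            if np.isfinite(s.modal_frac) and np.isfinite(ref.modal_frac):
                max_modal_dev = max(max_modal_dev, abs(s.modal_frac - ref.modal_frac))
    return NullCalibrationResult(n_seeds * n_cells, flagged, max_missing_dev, max_modal_dev)
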