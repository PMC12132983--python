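"""Pattern classification rules, severity bands, and facility selection."""

import itertools

import numpy as np
import pytest

from cdsaqc.classify import (
    APPLICABILITY,
    PatternFlag,
    ThresholdConfig,
    ThresholdConfigError,
    classify_cohort_summaries,
    classify_facility,
    classify_repeater,
    classify_skipper,
    classify_wrongly_evaluated,
    load_thresholds,
    select_health_centers,
)
from cdsaqc.summaries import SignSummary


def make_summary(
    hc_id="HC-A",
    sign="resp_rate",
    missing_frac=0.05,
    modal_frac=0.10,
    top3=None,
    mean=38.0,
    iqr=15.0,
    extreme_z_frac=float("nan"),
    n=1000,
    insufficient=False,
):
    top3 = top3 if top3 is not None else [(38.0, modal_frac), (36.0, 0.05), (40.0, 0.04)]
    return SignSummary(
        hc_id, sign, n, n, missing_frac,
        modal_value=top3[0][0], modal_frac=modal_frac, top3=top3,
        mean=mean, median=mean, iqr=iqr, extreme_z_frac=extreme_z_frac,
        insufficient_data=insufficient,
    )


CFG = ThresholdConfig()


class TestSkipper:
    def test_large_excess_is_severe(self):
        s = make_summary(missing_frac=0.40)
        r = make_summary(hc_id="ALL", missing_frac=0.05)
        flag = classify_skipper(s, r, CFG)
        assert flag.pattern_type == "skipper" and flag.severity == "severe"

    def test_no_excess_no_flag(self):
        s = make_summary(missing_frac=0.05)
        r = make_summary(hc_id="ALL", missing_frac=0.05)
        assert classify_skipper(s, r, CFG) is None

    def test_small_excess_is_mild(self):
        s = make_summary(missing_frac=0.12)
        r = make_summary(hc_id="ALL", missing_frac=0.05)
        assert classify_skipper(s, r, CFG).severity == "mild"

    def test_moderate_band(self):
        s = make_summary(missing_frac=0.25)
        r = make_summary(hc_id="ALL", missing_frac=0.05)
        assert classify_skipper(s, r, CFG).severity == "moderate"


class TestRepeater:
    def test_dominant_single_value_is_severe_mono(self):
        s = make_summary(modal_frac=0.60, top3=[(38.0, 0.60), (36.0, 0.05), (40.0, 0.04)])
        r = make_summary(hc_id="ALL", modal_frac=0.20)
        flag = classify_repeater(s, r, CFG)
        assert flag.pattern_type == "mono_repeater" and flag.severity == "severe"

    def test_identical_to_reference_no_flag(self):
        s = make_summary()
        r = make_summary(hc_id="ALL")
        assert classify_repeater(s, r, CFG) is None

    def test_iqr_shrinkage_alone_reaches_severe(self):
        # shrinkage (1.0 - 0.4) / 0.4 = 1.5 > 1.00
        s = make_summary(iqr=0.4)
        r = make_summary(hc_id="ALL", iqr=1.0)
        flag = classify_repeater(s, r, CFG)
        assert flag.severity == "severe"
        assert flag.evidence["iqr_severity"] == "severe"

    def test_zero_facility_iqr_with_positive_reference_is_severe(self):
        s = make_summary(iqr=0.0)
        r = make_summary(hc_id="ALL", iqr=1.0)
        assert classify_repeater(s, r, CFG).severity == "severe"

    def test_spread_heaping_labeled_multi(self):
        # top-3 excess 0.35 spread evenly: no single value dominates
        s = make_summary(
            modal_frac=0.22,
            top3=[(38.0, 0.22), (36.0, 0.19), (40.0, 0.13)],
        )
        r = make_summary(
            hc_id="ALL", modal_frac=0.10,
            top3=[(38.0, 0.10), (36.0, 0.05), (40.0, 0.04)],
        )
        flag = classify_repeater(s, r, CFG)
        assert flag.pattern_type == "multi_repeater" and flag.severity == "severe"

    def test_final_severity_is_max_of_frequency_and_iqr(self):
        # frequency mild (0.07 excess) but IQR shrinkage severe
        s = make_summary(modal_frac=0.17, top3=[(38.0, 0.17), (36.0, 0.05), (40.0, 0.04)], iqr=0.3)
        r = make_summary(hc_id="ALL", modal_frac=0.10, iqr=1.0)
        assert classify_repeater(s, r, CFG).severity == "severe"


class TestWronglyEvaluated:
    def test_extreme_z_excess_severe(self):
        s = make_summary(sign="weight_for_age", extreme_z_frac=0.40)
        r = make_summary(hc_id="ALL", sign="weight_for_age", extreme_z_frac=0.05)
        flag = classify_wrongly_evaluated(s, r, CFG)
        assert flag.pattern_type == "wrongly_evaluated" and flag.severity == "severe"

    def test_implausible_mean_temperature_is_mild(self):
        s = make_summary(sign="temperature", mean=41.0)
        r = make_summary(hc_id="ALL", sign="temperature", mean=36.8)
        flag = classify_wrongly_evaluated(s, r, CFG)
        assert flag.severity == "mild"
        assert flag.evidence["statistic"] == "mean"

    def test_plausible_mean_no_flag(self):
        s = make_summary(sign="temperature", mean=36.9)
        r = make_summary(hc_id="ALL", sign="temperature", mean=36.8)
        assert classify_wrongly_evaluated(s, r, CFG) is None

    def test_missing_plausible_range_is_config_error(self):
        cfg = ThresholdConfig(plausible_ranges={"temperature": (35.0, 40.5)})
        s = make_summary(sign="resp_rate", mean=38.0)
        r = make_summary(hc_id="ALL", sign="resp_rate")
        with pytest.raises(ThresholdConfigError, match="plausible range"):
            classify_wrongly_evaluated(s, r, cfg)


class TestSeverityMonotonicity:
    @pytest.mark.parametrize("classifier,field", [
        (classify_skipper, "missing_frac"),
        (classify_wrongly_evaluated, "extreme_z_frac"),
    ])
    def test_severity_never_decreases_with_excess(self, classifier, field):
        order = {None: 0, "mild": 1, "moderate": 2, "severe": 3}
        sign = "weight_for_age" if field == "extreme_z_frac" else "resp_rate"
        r = make_summary(hc_id="ALL", sign=sign, **{field: 0.05})
        prev = 0
        for excess in np.linspace(0.0, 0.6, 25):
            s = make_summary(sign=sign, **{field: 0.05 + excess})
            flag = classifier(s, r, CFG)
            rank = order[None if flag is None else flag.severity]
            assert rank >= prev
            prev = rank


class TestApplicability:
    def test_flag_outside_applicability_cannot_be_constructed(self):
        with pytest.raises(ValueError, match="not applicable"):
            PatternFlag("A", "temperature", "skipper", "mild", {})
        with pytest.raises(ValueError, match="not applicable"):
            PatternFlag("A", "weight", "mono_repeater", "mild", {})

    def test_raw_weight_and_height_never_flagged_as_repeater(self):
        # a facility with blatant heaping on weight: applicability routes
        # detection through z-scores only, so no raw-weight flag emerges
        summaries = [make_summary(sign="weight", modal_frac=0.9, iqr=0.0)]
        refs = {"weight": make_summary(hc_id="ALL", sign="weight", modal_frac=0.1, iqr=5.0)}
        assert classify_facility(summaries, refs, CFG) == []

    def test_multiple_flags_on_one_sign(self):
        s = make_summary(missing_frac=0.30, modal_frac=0.45,
                         top3=[(38.0, 0.45), (36.0, 0.05), (40.0, 0.04)])
        refs = {"resp_rate": make_summary(hc_id="ALL", missing_frac=0.05, modal_frac=0.10)}
        flags = classify_facility([s], refs, CFG)
        types = {f.pattern_type for f in flags}
        assert types == {"skipper", "mono_repeater"}

    def test_insufficient_data_skipped(self):
        s = make_summary(missing_frac=0.9, insufficient=True)
        refs = {"resp_rate": make_summary(hc_id="ALL")}
        assert classify_facility([s], refs, CFG) == []


class TestSelection:
    def _flag(self, hc, sign, severity):
        return PatternFlag(hc, sign, "skipper", severity, {})

    def test_two_signs_one_moderate_selected(self):
        flags = [self._flag("A", "height", "mild"), self._flag("A", "resp_rate", "moderate")]
        assert select_health_centers(flags) == {"A"}

    def test_single_mild_flag_not_selected(self):
        assert select_health_centers([self._flag("A", "height", "mild")]) == set()

    def test_two_flags_same_sign_not_selected(self):
        flags = [
            self._flag("A", "resp_rate", "severe"),
            PatternFlag("A", "resp_rate", "mono_repeater", "severe", {}),
        ]
        assert select_health_centers(flags) == set()

    def test_random_flag_sets_match_bruteforce_oracle(self, rng):
        signs = ["height", "muac", "resp_rate", "heart_rate", "spo2"]
        severities = ["mild", "moderate", "severe"]
        for _ in range(200):
            n = int(rng.integers(0, 6))
            flags = [
                self._flag(
                    "A",
                    signs[rng.integers(0, len(signs))],
                    severities[rng.integers(0, 3)],
                )
                for _ in range(n)
            ]
            expected = (
                len({f.sign for f in flags}) >= 2
                and any(f.severity in ("moderate", "severe") for f in flags)
            )
            assert (select_health_centers(flags) == {"A"}) == expected


def test_threshold_yaml_overrides(tmp_path):
    path = tmp_path / "thr.yaml"
    path.write_text(
        "skipper_bands: [0.02, 0.05, 0.10]\n"
        "plausible_ranges:\n  temperature: [35.0, 39.0]\n",
        encoding="utf-8",
    )
    cfg = load_thresholds(path)
    assert cfg.skipper_bands == (0.02, 0.05, 0.10)
    assert cfg.plausible_ranges["temperature"] == (35.0, 39.0)
    # untouched defaults survive
    assert cfg.repeater_freq_bands == (0.05, 0.10, 0.30)
    assert cfg.plausible_ranges["spo2"] == (88.0, 100.0)


def test_bands_must_increase():
    with pytest.raises(ThresholdConfigError):
        ThresholdConfig(skipper_bands=(0.3, 0.2, 0.1))


def test_self_reference_null(small_cohort):
    """A facility drawn from the same settings as the pool gets no flags
    when the cohort is large enough for noise to sit below the bands."""
    from cdsaqc.summaries import summarize_cohort

    flags = classify_cohort_summaries(summarize_cohort(small_cohort))
    # 3 x 400 is small; allow noise flags only at mild level
    assert all(f.severity == "mild" for f in flags)
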