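"""Synthetic cohort generator: determinism, eligibility, behavior injection."""

import io

import numpy as np
import pandas as pd
import pytest

from cdsaqc.signs import MEASURED, NOT_APPLICABLE, NOT_FEASIBLE, SIGN_ORDER
from cdsaqc.simulate import (
    BehaviorAssignment,
    BehaviorSpec,
    CohortConfig,
    ConfigError,
    FacilitySpec,
    default_config,
    generate_cohort,
    inject_behavior,
    load_cohort_config,
    read_cohort,
    validate_cohort,
    write_cohort,
)


def _csv_bytes(df):
    buf = io.StringIO()
    write_cohort(df, buf)
    return buf.getvalue()


class TestGeneration:
    def test_same_config_and_seed_give_byte_identical_output(self):
        cfg = default_config(3, 50)
        a, b = generate_cohort(cfg, seed=11), generate_cohort(cfg, seed=11)
        assert _csv_bytes(a) == _csv_bytes(b)

    def test_record_counts_match_config(self):
        cfg = CohortConfig(facilities=[FacilitySpec(f"F{i}", 50) for i in range(3)])
        df = generate_cohort(cfg, seed=0)
        assert len(df) == 150
        assert df["hc_id"].value_counts().eq(50).all()

    def test_pooled_mean_matches_configured_distribution(self):
        # temperature ~ truncated Normal(36.8, 0.5) on [35, 41]
        cfg = default_config(4, 2500)
        df = generate_cohort(cfg, seed=3)
        vals = df.loc[df["temperature_status"] == MEASURED, "temperature_value"]
        se = 0.5 / np.sqrt(len(vals))
        assert abs(vals.mean() - 36.8) < 3 * se

    def test_eligibility_rules_enforced(self, small_cohort):
        df = small_cohort
        validate_cohort(df)
        young = df["age_days"] < 183
        assert (df.loc[young, "muac_status"] == NOT_APPLICABLE).all()
        assert df.loc[young, "muac_value"].isna().all()
        no_resp = ~df["respiratory_complaint"]
        for sign in ("heart_rate", "resp_rate", "spo2"):
            assert (df.loc[no_resp, f"{sign}_status"] == NOT_APPLICABLE).all()

    def test_values_quantized_to_recording_grid(self, small_cohort):
        temp = small_cohort.loc[
            small_cohort["temperature_status"] == MEASURED, "temperature_value"
        ]
        assert np.allclose(np.round(temp * 10), temp * 10)
        hr = small_cohort.loc[
            small_cohort["heart_rate_status"] == MEASURED, "heart_rate_value"
        ]
        assert np.allclose(hr, np.round(hr))

    def test_cohort_csv_roundtrip(self, small_cohort, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(small_cohort, path)
        back = read_cohort(path)
        for sign in SIGN_ORDER:
            pd.testing.assert_series_equal(
                back[f"{sign}_value"], small_cohort[f"{sign}_value"].astype(float),
                check_names=True,
            )


class TestConfigValidation:
    def test_unknown_sign_rejected(self):
        with pytest.raises(ConfigError, match="unknown sign"):
            load_cohort_config({"signs": {"blood_pressure": {}}})

    def test_mono_repeater_needs_exactly_one_target(self):
        with pytest.raises(ConfigError, match="exactly 1 target"):
            BehaviorSpec("mono_repeater", 0.2, (36.0, 37.0))

    def test_multi_repeater_needs_two_to_three_targets(self):
        with pytest.raises(ConfigError, match="2-3 target"):
            BehaviorSpec("multi_repeater", 0.2, (36.0,))

    def test_behavior_on_undeclared_facility_rejected(self):
        cfg = default_config(2, 10)
        cfg.behaviors = [
            BehaviorAssignment("HC-99", "height", BehaviorSpec("skipper", 0.1))
        ]
        with pytest.raises(ConfigError, match="undeclared facility"):
            cfg.validate()

    def test_pattern_sign_applicability_enforced(self):
        with pytest.raises(ConfigError, match="cannot be injected"):
            inject_behavior(
                generate_cohort(default_config(1, 30), 0),
                "HC-01", "temperature", BehaviorSpec("skipper", 0.1), seed=0,
            )

    def test_yaml_config_loading(self, tmp_path):
        path = tmp_path / "cohort.yaml"
        path.write_text(
            "facilities:\n  - {hc_id: A, n: 20}\n  - {hc_id: B, n: 30}\n"
            "signs:\n  temperature: {mean: 37.0, not_feasible_rate: 0.1}\n"
            "behaviors:\n  - {hc_id: A, sign: resp_rate, pattern: mono_repeater,\n"
            "     intensity: 0.2, targets: [40]}\n",
            encoding="utf-8",
        )
        cfg = load_cohort_config(path)
        assert [f.n for f in cfg.facilities] == [20, 30]
        assert cfg.signs["temperature"].params[0] == 37.0
        assert cfg.signs["temperature"].not_feasible_rate == 0.1
        assert cfg.behaviors[0].behavior.target_values == (40.0,)


@pytest.fixture(scope="module")
def big_cohort():
    return generate_cohort(default_config(2, 5000), seed=21)


class TestBehaviorInjection:
    def test_skipper_raises_missing_rate_additively(self, big_cohort):
        # height baseline not-feasible 0.08; +0.35 -> ~0.43
        out = inject_behavior(big_cohort, "HC-01", "height", BehaviorSpec("skipper", 0.35), seed=5)
        sub = out[out["hc_id"] == "HC-01"]
        frac = (sub["height_status"] == NOT_FEASIBLE).mean()
        assert frac == pytest.approx(0.43, abs=0.03)

    def test_mono_repeater_reaches_requested_modal_mass(self, big_cohort):
        out = inject_behavior(
            big_cohort, "HC-01", "temperature",
            BehaviorSpec("mono_repeater", 0.5, (36.5,)), seed=5,
        )
        vals = out.loc[
            (out["hc_id"] == "HC-01") & (out["temperature_status"] == MEASURED),
            "temperature_value",
        ]
        assert (vals == 36.5).mean() >= 0.5

    def test_zero_intensity_is_identity(self, big_cohort):
        out = inject_behavior(big_cohort, "HC-01", "height", BehaviorSpec("skipper", 0.0), seed=5)
        pd.testing.assert_frame_equal(out, big_cohort)

    def test_untargeted_facilities_bit_identical(self, big_cohort):
        out = inject_behavior(
            big_cohort, "HC-01", "resp_rate",
            BehaviorSpec("multi_repeater", 0.4, (30.0, 40.0)), seed=5,
        )
        mask = big_cohort["hc_id"] != "HC-01"
        pd.testing.assert_frame_equal(out[mask], big_cohort[mask])
        # and only the targeted sign changed within the facility
        fac = big_cohort["hc_id"] == "HC-01"
        pd.testing.assert_series_equal(
            out.loc[fac, "temperature_value"], big_cohort.loc[fac, "temperature_value"]
        )

    def test_excessive_intensity_clipped_with_warning(self, big_cohort):
        with pytest.warns(UserWarning, match="clipped"):
            out = inject_behavior(
                big_cohort, "HC-01", "height", BehaviorSpec("skipper", 0.99), seed=5
            )
        sub = out[out["hc_id"] == "HC-01"]
        assert (sub["height_status"] == MEASURED).sum() == 0

    @pytest.mark.parametrize(
        "pattern,sign,targets,statistic",
        [
            ("skipper", "height", (), "missing"),
            ("mono_repeater", "temperature", (36.5,), "modal"),
            ("multi_repeater", "resp_rate", (30.0, 40.0), "top"),
            ("wrongly_evaluated", "weight", (), "extreme"),
        ],
    )
    def test_effect_statistic_monotone_in_intensity(self, big_cohort, pattern, sign, targets, statistic):
        """At fixed seed the targeted summary statistic never decreases
        as intensity grows."""
        from cdsaqc import add_zscores
        from cdsaqc.summaries import summarize_sign

        prev = -np.inf
        for intensity in (0.0, 0.1, 0.25, 0.5):
            out = inject_behavior(
                big_cohort, "HC-01", sign, BehaviorSpec(pattern, intensity, targets), seed=9
            )
            if statistic == "extreme":
                out = add_zscores(out)
                value = summarize_sign(out, "HC-01", "weight_for_age").extreme_z_frac
            else:
                s = summarize_sign(out, "HC-01", sign)
                value = {"missing": s.missing_frac, "modal": s.modal_frac, "top": s.top3_cum_frac}[statistic]
            assert value >= prev - 1e-12
            prev = value
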