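"""Resistance ratio, classification, caution flag, per-station assessment."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trflp
from trflp.datasets import kaneohe_storm_anosim
from trflp.resistance import (
    ResistanceAssessment,
    assess_station,
    classify_resistance,
    resistance_ratio,
    round_half_up,
    summarize_report,
)


class TestResistanceRatio:
    @pytest.mark.parametrize(
        "r_env,r_com,expected",
        [
            (0.444, 0.882, 1.99),  # strong paired response
            (-0.102, 0.646, 6.33),  # negative denominator: absolute convention
            (1.0, 0.0, 0.00),  # community unchanged despite env shift
            (0.017, -0.115, 6.76),  # near-zero denominator, negative numerator
        ],
    )
    def test_published_station_pairs(self, r_env, r_com, expected):
        assert round_half_up(resistance_ratio(r_com, r_env)) == expected

    def test_out_of_range_inputs_error(self):
        with pytest.raises(ValueError):
            resistance_ratio(1.5, 0.2)
        with pytest.raises(ValueError):
            resistance_ratio(0.2, -1.5)

    def test_zero_denominator_conventions(self):
        assert resistance_ratio(0.5, 0.0) == math.inf
        assert resistance_ratio(0.0, 0.0) == 0.0

    def test_signed_variant(self):
        assert resistance_ratio(0.646, -0.102, signed=True) == pytest.approx(-6.3333, abs=1e-3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=-1, max_value=1, allow_nan=False),
        st.floats(min_value=-1, max_value=1, allow_nan=False),
    )
    def test_sign_flip_symmetry(self, r_com, r_env):
        base = resistance_ratio(r_com, r_env)
        assert resistance_ratio(-r_com, r_env) == base
        assert resistance_ratio(r_com, -r_env) == base

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.floats(min_value=0.01, max_value=1, allow_nan=False),
        st.floats(min_value=0, max_value=1, allow_nan=False),
        st.floats(min_value=0, max_value=1, allow_nan=False),
    )
    def test_monotone_in_community_shift(self, r_env, a, b):
        lo, hi = sorted([a, b])
        assert resistance_ratio(lo, r_env) <= resistance_ratio(hi, r_env)


class TestClassifyResistance:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.0, "high"), (0.49, "high"), (0.5, "intermediate"), (1.0, "intermediate"),
         (1.5, "intermediate"), (1.51, "low"), (18.32, "low")],
    )
    def test_class_boundaries(self, ratio, expected):
        cls, _ = classify_resistance(ratio, 0.5, 0.5)
        assert cls == expected

    def test_caution_when_both_R_near_zero(self):
        _, caution = classify_resistance(0.26, 0.074, 0.019)
        assert caution
        _, caution = classify_resistance(0.45, 0.217, 0.098)
        assert not caution

    def test_infinite_ratio_forces_caution(self):
        cls, caution = classify_resistance(math.inf, 0.0, 0.5)
        assert cls == "low" and caution

    def test_negative_ratio_errors(self):
        with pytest.raises(ValueError):
            classify_resistance(-0.1, 0.5, 0.5)


class TestAssessStation:
    env_vars = ["temperature", "salinity", "NH4", "NO2", "NN", "SRP"]

    def _dataset(self, exposure, seed=7):
        stations = (trflp.StationSpec("ST", "coastal", exposure, dense=True),)
        cfg = trflp.ScenarioConfig(stations=stations, seed=seed, n_taxa=60)
        return trflp.simulate(cfg)

    def test_env_pulse_with_community_response(self):
        ds = self._dataset(exposure=1.0)
        a = assess_station(
            ds.matrix, ds.env, "ST", ds.config.storm_window,
            n_perm=199, seed=3, env_variables=self.env_vars,
        )
        assert a.p_env < 0.05 and a.p_com < 0.05

    def test_env_pulse_only(self):
        # environment responds but the community does not (responder fold 1)
        stations = (trflp.StationSpec("ST", "coastal", 1.0, dense=True),)
        cfg = trflp.ScenarioConfig(
            stations=stations, seed=11, n_taxa=60,
            responder_fold=1.0, dominant_storm_gain=0.0, washin_weight=0.0,
        )
        ds = trflp.simulate(cfg)
        a = assess_station(
            ds.matrix, ds.env, "ST", ds.config.storm_window,
            n_perm=199, seed=3, env_variables=self.env_vars,
        )
        assert a.p_env < 0.05 and a.p_com >= 0.05

    def test_single_storm_sample_station_skipped(self):
        stations = (trflp.StationSpec("ST", "coastal", 1.0, dense=False),)
        cfg = trflp.ScenarioConfig(stations=stations, seed=2, n_taxa=40)
        ds = trflp.simulate(cfg)  # routine-only: one storm date
        a = assess_station(
            ds.matrix, ds.env, "ST", ds.config.storm_window,
            n_perm=99, seed=3, env_variables=self.env_vars,
        )
        assert a is None


class TestSummarizeReport:
    def _assessments(self):
        table = kaneohe_storm_anosim()
        out = []
        for station, row in table.iterrows():
            ratio = resistance_ratio(row.r_com, row.r_env)
            cls, caution = classify_resistance(ratio, row.r_env, row.r_com)
            out.append(
                ResistanceAssessment(
                    station=station, r_env=row.r_env, p_env=row.p_env,
                    r_com=row.r_com, p_com=row.p_com, ratio=ratio,
                    resistance_class=cls, caution=caution,
                )
            )
        return out

    def test_counts_partition_all_stations(self):
        report = summarize_report(self._assessments(), alpha=0.05)
        assert sum(report.counts.values()) == len(report.assessments) == 22

    def test_alpha_one_puts_everything_in_both(self):
        report = summarize_report(self._assessments(), alpha=1.0)
        assert len(report.both) == 22 and not report.neither

    def test_tiny_alpha_puts_everything_in_neither(self):
        report = summarize_report(self._assessments(), alpha=1e-9)
        assert len(report.neither) == 22

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            summarize_report([])
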