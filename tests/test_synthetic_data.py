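"""Generator contracts: determinism, storm phenology, compositional effects."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import trflp
from trflp.resistance import assess_all_stations
from trflp.synthetic_data import (
    ScenarioConfig,
    StationSpec,
    _community_factor,
    _env_pulse_factor,
    ground_truth_eval,
    kaneohe_like,
    null_scenario,
    simulate,
)

ENV_VARS = ["temperature", "salinity", "NH4", "NO2", "NN", "SRP"]


class TestConfigValidation:
    def test_exposure_out_of_range(self):
        with pytest.raises(ValueError, match="exposure"):
            StationSpec("X", "coastal", 1.5)

    def test_unknown_regime(self):
        with pytest.raises(ValueError, match="regime"):
            StationSpec("X", "lagoon", 0.5)

    def test_too_many_special_taxa(self):
        with pytest.raises(ValueError):
            ScenarioConfig(
                stations=(StationSpec("X", "coastal", 0.0),),
                n_taxa=10, n_responders=8, n_dominant=5,
            )

    def test_duplicate_stations(self):
        with pytest.raises(ValueError, match="duplicate"):
            ScenarioConfig(
                stations=(StationSpec("X", "coastal", 0.0), StationSpec("X", "offshore", 0.0))
            )


class TestDeterminism:
    def test_identical_config_identical_dataset(self):
        a = simulate(kaneohe_like(seed=5, n_taxa=40))
        b = simulate(kaneohe_like(seed=5, n_taxa=40))
        pd.testing.assert_frame_equal(a.matrix.values, b.matrix.values)
        pd.testing.assert_frame_equal(a.env, b.env)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_adding_a_station_does_not_perturb_others(self):
        base = null_scenario(seed=3, n_stations=3, n_taxa=20)
        bigger = ScenarioConfig(
            stations=base.stations + (StationSpec("EXTRA", "offshore", 0.0, dense=True),),
            seed=3, n_taxa=20,
        )
        a = simulate(base)
        b = simulate(bigger)
        shared = a.matrix.values.index
        common_cols = a.matrix.values.columns.intersection(b.matrix.values.columns)
        pd.testing.assert_frame_equal(
            a.matrix.values.loc[shared, common_cols],
            b.matrix.values.loc[shared, common_cols],
        )

    def test_peak_table_roundtrips_through_prep(self):
        ds = simulate(null_scenario(seed=1, n_stations=2, n_taxa=20))
        peaks = ds.peak_table()
        import io

        recs = trflp.read_peak_table(io.StringIO(peaks.to_csv(sep="\t", index=False)), sep="\t")
        profiles = trflp.bin_peaks(recs)
        rebuilt = trflp.align_profiles(profiles, tolerance_bp=0)
        # binning the jittered sizes recovers the original integer T-RFs
        common = rebuilt.values.columns.intersection(ds.matrix.values.columns)
        assert len(common) >= 0.95 * len(ds.matrix.values.columns)
        np.testing.assert_allclose(
            rebuilt.values.loc[ds.matrix.values.index, common].to_numpy(),
            ds.matrix.values[common].to_numpy(),
            rtol=1e-9,
        )


class TestStormPhenology:
    def test_env_pulse_peaks_day_1_to_4_and_recovers_by_day_10(self):
        cfg = kaneohe_like(seed=0)
        days = np.arange(0, 22)
        pulse = np.array([_env_pulse_factor(t, cfg.env_tau) for t in days])
        assert 1 <= days[np.argmax(pulse)] <= 4
        assert pulse[10] < np.exp(-1)  # within one time-constant band of baseline

    def test_community_response_lagged_and_recovered_by_day_18(self):
        cfg = kaneohe_like(seed=0)
        days = np.arange(0, 22)
        resp = np.array(
            [
                _community_factor(t, cfg.lag_days, cfg.community_tau, cfg.env_tau, cfg.washin_weight)
                for t in days
            ]
        )
        assert days[np.argmax(resp)] >= cfg.lag_days  # bloom dominates post-lag
        assert resp[18] < 0.1  # near-complete recovery

    def test_nutrient_trajectory_in_generated_env(self):
        ds = simulate(kaneohe_like(seed=4))
        env = ds.env.copy()
        meta = ds.matrix.metadata
        storm_day = ds.config.storm_date
        exposed = ds.truth.index[(ds.truth.exposure == 1.0) & ds.truth.dense]
        nn = env.loc[meta.station.isin(exposed), "NN"]
        days = meta.loc[nn.index, "date"].map(
            lambda d: (dt.date.fromisoformat(d) - storm_day).days
        )
        by_day = nn.groupby(days).mean()
        peak_day = by_day.idxmax()
        assert 1 <= peak_day <= 4
        baseline = by_day[by_day.index < 0].mean()
        assert by_day[10] < baseline + 0.37 * (by_day[peak_day] - baseline)

    def test_dominants_rise_absolutely_but_fall_relatively(self):
        ds = simulate(kaneohe_like(seed=3))
        meta = ds.matrix.metadata
        exposed = ds.truth.index[(ds.truth.exposure == 1.0) & ds.truth.dense]
        sids = meta.index[meta.station.isin(exposed)]
        sub = ds.matrix.subset(list(sids))
        storm = (sub.metadata.condition == "storm").to_numpy()
        dom = [c for c in sub.values.columns if c in ds.dominant_trfs]
        absolute = sub.values[dom].sum(axis=1).to_numpy()
        relative = (sub.values[dom].sum(axis=1) / sub.values.sum(axis=1)).to_numpy()
        assert absolute[storm].mean() > absolute[~storm].mean()
        assert relative[storm].mean() < relative[~storm].mean()


class TestGroundTruthEval:
    def test_perfect_recovery_scenario(self):
        stations = tuple(
            [StationSpec(f"D{i}", "coastal", 1.0, dense=True) for i in range(3)]
            + [StationSpec(f"U{i}", "offshore", 0.0, dense=True) for i in range(3)]
        )
        cfg = ScenarioConfig(stations=stations, seed=8, n_taxa=60)
        ds = simulate(cfg)
        report = assess_all_stations(
            ds.matrix, ds.env, cfg.storm_window, n_perm=199, seed=1,
            env_variables=ENV_VARS,
        )
        summary = ground_truth_eval(ds, report)
        assert summary.sensitivity == 1.0
        assert summary.specificity == 1.0

    def test_empty_report_errors(self):
        ds = simulate(null_scenario(seed=0, n_stations=2, n_taxa=20))
        report = assess_all_stations(
            ds.matrix, ds.env, ds.config.storm_window, n_perm=9, seed=0,
            env_variables=ENV_VARS,
        )
        report.assessments = []
        with pytest.raises(ValueError, match="empty"):
            ground_truth_eval(ds, report)

    def test_unknown_station_errors(self):
        ds = simulate(null_scenario(seed=0, n_stations=2, n_taxa=20))
        report = assess_all_stations(
            ds.matrix, ds.env, ds.config.storm_window, n_perm=9, seed=0,
            env_variables=ENV_VARS,
        )
        report.assessments[0].station = "GHOST"
        with pytest.raises(ValueError, match="GHOST"):
            ground_truth_eval(ds, report)
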