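"""Synthetic station x date T-RFLP and environmental datasets.

The generator emulates the statistical structure of a storm disturbance
in a coastal embayment sampled at many stations over months:

* three spatial community regimes (offshore, coastal, freshwater) with
  distinct baseline composition;
* a localized storm pulse in environmental covariates (inorganic
  nutrients up, salinity down) that peaks 1-4 days post-storm and
  decays back to baseline by ~10 days;
* a community response lagged by ~3 days: rare "responder" taxa bloom
  and bust, while dominant taxa gain only modestly in absolute terms and
  therefore *decline in relative abundance* (the compositional paradox:
  absolute cell counts of the dominant cyanobacteria can rise during a
  heterotroph bloom even as their share of the community falls);
* recovery of the community signal within ~18 days.

Abundances are simulated on an absolute fluorescence scale and only
normalized downstream, so the compositional effects emerge from the
arithmetic rather than by fiat. Every random draw flows from a single
seed through named substreams (one per station, keyed by a stable hash
of the station name), so adding a station never perturbs the others.
"""

from __future__ import annotations

import datetime as dt
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io_profiles import ProfileMatrix
from .resistance import StormAssessmentReport

REGIMES = ("offshore", "coastal", "freshwater")


@dataclass(frozen=True)
class StationSpec:
    name: str
    regime: str  # offshore | coastal | freshwater
    exposure: float  # storm exposure in [0, 1]
    dense: bool = False  # sampled on the dense post-storm days

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if not 0.0 <= self.exposure <= 1.0:
            raise ValueError(f"exposure must be in [0, 1], got {self.exposure}")


#: Baseline environmental conditions per regime (units as in
#: :data:`trflp.distance.ENV_VARIABLES`).
ENV_BASELINES: dict[str, dict[str, float]] = {
    "offshore": {
        "temperature": 26.0, "salinity": 35.0, "NH4": 0.06, "NO2": 0.10,
        "NN": 0.25, "SRP": 0.08, "H2SiO4": 3.0, "chl_a": 1.6,
    },
    "coastal": {
        "temperature": 26.5, "salinity": 34.5, "NH4": 0.15, "NO2": 0.12,
        "NN": 0.40, "SRP": 0.10, "H2SiO4": 8.0, "chl_a": 2.2,
    },
    "freshwater": {
        "temperature": 25.0, "salinity": 23.0, "NH4": 2.4, "NO2": 0.29,
        "NN": 20.0, "SRP": 0.54, "H2SiO4": 124.0, "chl_a": 2.5,
    },
}

#: Storm pulse amplitudes at full exposure: the printed peak deviations
#: from non-storm conditions at the most affected coastal station.
ENV_PULSE: dict[str, float] = {
    "temperature": -1.0, "salinity": -13.0, "NH4": 12.5, "NO2": 0.5,
    "NN": 12.0, "SRP": 0.9, "H2SiO4": 58.0, "chl_a": 16.0,
}

#: Variables whose storm response is biological and therefore lagged.
LAGGED_ENV = ("chl_a",)


def _default_routine_dates() -> tuple[dt.date, ...]:
    """Every ~21 days Feb-Sep, plus day +10 post-storm at every station."""
    return (
        dt.date(2006, 2, 5), dt.date(2006, 2, 26), dt.date(2006, 3, 12),
        dt.date(2006, 4, 9), dt.date(2006, 4, 30), dt.date(2006, 5, 21),
        dt.date(2006, 6, 11), dt.date(2006, 7, 2), dt.date(2006, 7, 23),
        dt.date(2006, 8, 13), dt.date(2006, 9, 3), dt.date(2006, 9, 24),
    )


@dataclass
class ScenarioConfig:
    """Complete description of one simulated storm scenario."""

    stations: tuple[StationSpec, ...]
    routine_dates: tuple[dt.date, ...] = field(default_factory=_default_routine_dates)
    storm_date: dt.date = dt.date(2006, 3, 2)
    dense_offsets: tuple[int, ...] = (1, 4, 7, 10, 18, 21)
    storm_window: tuple[dt.date, dt.date] = (dt.date(2006, 3, 3), dt.date(2006, 3, 12))

    n_taxa: int = 120
    baseline_log_mean: float = 5.5  # log fluorescence units
    baseline_log_sd: float = 1.2
    regime_shift_sigma: float = 1.0  # log-scale regime composition shift
    station_sigma: float = 0.25  # within-regime station individuality
    noise_sigma: float = 0.4  # per-sample multiplicative noise (log-scale)
    scale_sigma: float = 0.2  # per-sample total-signal variability

    n_responders: int = 12
    responder_fold: float = 80.0  # peak fold-increase of responder taxa
    n_dominant: int = 5
    dominant_boost: float = 8.0  # baseline dominance factor
    dominant_storm_gain: float = 0.6  # muted *absolute* storm gain of dominants

    lag_days: float = 3.0  # nutrient injection -> bloom response
    washin_weight: float = 0.3  # immediate allochthonous wash-in fraction
    env_recovery_days: float = 10.0  # nutrients back near baseline
    community_recovery_days: float = 18.0  # community signal back near baseline
    env_noise_sigma: float = 0.15

    detection_threshold: float = 25.0  # fluorescence floor
    noise_peak_rate: float = 15.0  # mean spurious peaks per sample at unit scale
    noise_peak_frac: tuple[float, float] = (0.0005, 0.003)  # of total signal
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders + self.n_dominant > self.n_taxa:
            raise ValueError("responder + dominant taxa exceed n_taxa")
        for name in ("env_recovery_days", "community_recovery_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.lag_days < 0:
            raise ValueError("lag_days must be >= 0")
        names = [s.name for s in self.stations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate station names")

    @property
    def env_tau(self) -> float:
        """Decay constant: pulse down to ~5% at env_recovery_days."""
        return self.env_recovery_days / 3.0

    @property
    def community_tau(self) -> float:
        return (self.community_recovery_days - self.lag_days) / 3.0

    def station_dates(self, spec: StationSpec) -> list[dt.date]:
        dates = set(self.routine_dates)
        if spec.dense:
            dates.update(
                self.storm_date + dt.timedelta(days=off) for off in self.dense_offsets
            )
        return sorted(dates)


@dataclass
class SyntheticDataset:
    """Generated profiles + environment + per-station ground truth."""

    matrix: ProfileMatrix
    env: pd.DataFrame
    truth: pd.DataFrame  # per-station regime/exposure/true labels
    config: ScenarioConfig
    responder_trfs: list[int]
    dominant_trfs: list[int]
    taxon_trfs: np.ndarray

    def peak_table(self, jitter_sd: float = 0.15) -> pd.DataFrame:
        """Raw-style peak table with fractional fragment sizes.

        Re-expands the binned matrix into per-peak records with Gaussian
        size jitter, for exercising the reading/binning/alignment path.
        Deterministic given the dataset's config seed.
        """
        rng = np.random.default_rng(np.random.SeedSequence(self.config.seed, spawn_key=(99,)))
        rows = []
        values = self.matrix.values
        for sid in values.index:
            row = values.loc[sid]
            for bp, inten in row[row > 0].items():
                rows.append((sid, float(bp) + rng.normal(0.0, jitter_sd), float(inten)))
        return pd.DataFrame(rows, columns=["sample", "size", "intensity"])


def _hash(name: str) -> int:
    return zlib.crc32(name.encode())


def _stream(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _env_pulse_factor(t_days: float, tau: float) -> float:
    """Pulse time course: 0 before the storm, peak at day 1, exp decay."""
    if t_days <= 0:
        return 0.0
    if t_days < 1:
        return t_days  # ramp during the first day
    return math.exp(-(t_days - 1.0) / tau)


def _community_factor(
    t_days: float, lag: float, tau: float, env_tau: float, washin: float
) -> float:
    """Community response time course.

    Mixture of an immediate wash-in component (runoff introduces
    allochthonous organisms on the environmental pulse's time course)
    and a bloom component that is zero until the lag and then decays
    with the community time constant. The bloom dominates, so the
    response peaks shortly after the lag.
    """
    bloom = 0.0 if (t_days < lag or t_days <= 0) else math.exp(-(t_days - lag) / tau)
    return washin * _env_pulse_factor(t_days, env_tau) + (1.0 - washin) * bloom


def true_resistance_class(exposure: float) -> str:
    """Generator convention mapping exposure to the planted class."""
    if exposure < 0.2:
        return "high"
    if exposure <= 0.7:
        return "intermediate"
    return "low"


def simulate(config: ScenarioConfig) -> SyntheticDataset:
    """Generate one complete scenario dataset (deterministic in config.seed)."""
    cfg = config
    seed = cfg.seed

    # taxon-level draws (shared by all stations)
    rng_tax = _stream(seed, 0)
    g = np.exp(rng_tax.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_taxa))
    trfs = rng_tax.choice(np.arange(34, 601), size=cfg.n_taxa, replace=False)
    perm = rng_tax.permutation(cfg.n_taxa)
    dominants = np.sort(perm[: cfg.n_dominant])
    responders = np.sort(perm[cfg.n_dominant : cfg.n_dominant + cfg.n_responders])
    g[dominants] *= cfg.dominant_boost

    # regime composition shifts (shared within a regime)
    regime_factor = {
        regime: np.exp(
            _stream(seed, 1, _hash(regime)).normal(0.0, cfg.regime_shift_sigma, cfg.n_taxa)
        )
        for regime in REGIMES
    }

    env_vars = list(ENV_PULSE)
    sample_rows, env_rows, meta_rows, ids = [], [], [], []
    w0, w1 = cfg.storm_window
    for spec in cfg.stations:
        rng_st = _stream(seed, 2, _hash(spec.name))
        st_mod = np.exp(rng_st.normal(0.0, cfg.station_sigma, cfg.n_taxa))
        base = g * regime_factor[spec.regime] * st_mod
        env_base = ENV_BASELINES[spec.regime]
        for date in cfg.station_dates(spec):
            t = (date - cfg.storm_date).days
            noise = np.exp(rng_st.normal(0.0, cfg.noise_sigma, cfg.n_taxa))
            scale = math.exp(rng_st.normal(0.0, cfg.scale_sigma))
            env_noise = np.exp(rng_st.normal(0.0, cfg.env_noise_sigma, len(env_vars)))

            e = _env_pulse_factor(t, cfg.env_tau) * spec.exposure
            b = spec.exposure * _community_factor(
                t, cfg.lag_days, cfg.community_tau, cfg.env_tau, cfg.washin_weight
            )

            mult = np.ones(cfg.n_taxa)
            mult[responders] = 1.0 + (cfg.responder_fold - 1.0) * b
            mult[dominants] = 1.0 + cfg.dominant_storm_gain * b
            abund = base * noise * mult * scale
            abund[abund < cfg.detection_threshold] = 0.0

            # spurious instrument noise peaks: count scales with signal
            # strength, which is what VPT filtering exploits
            total = float(abund.sum())
            n_noise = int(rng_st.poisson(cfg.noise_peak_rate * scale))
            noise_bp = rng_st.integers(34, 601, size=n_noise)
            lo, hi = cfg.noise_peak_frac
            noise_int = total * rng_st.uniform(lo, hi, size=n_noise)
            noise_int[noise_int < cfg.detection_threshold] = 0.0
            sample_rows.append((abund, noise_bp, noise_int))

            env_row = {}
            for j, var in enumerate(env_vars):
                pulse = ENV_PULSE[var] * (b if var in LAGGED_ENV else e)
                env_row[var] = env_base[var] * env_noise[j] + pulse
            env_rows.append(env_row)

            sid = f"{spec.name}_{date.isoformat()}"
            ids.append(sid)
            meta_rows.append(
                {
                    "station": spec.name,
                    "date": date.isoformat(),
                    "condition": "storm" if w0 <= date <= w1 else "non-storm",
                }
            )

    # collapse taxa sharing a T-RF length into one column (the fingerprint
    # observes fragment lengths, not taxa) and fold in the noise peaks
    records = []
    for abund, noise_bp, noise_int in sample_rows:
        row: dict[int, float] = {}
        for bp, v in zip(trfs, abund):
            if v > 0:
                row[int(bp)] = row.get(int(bp), 0.0) + float(v)
        for bp, v in zip(noise_bp, noise_int):
            if v > 0:
                row[int(bp)] = row.get(int(bp), 0.0) + float(v)
        records.append(row)
    values = pd.DataFrame(records, index=ids).fillna(0.0).sort_index(axis=1)
    meta = pd.DataFrame(meta_rows, index=ids)
    matrix = ProfileMatrix(values, meta)
    env = pd.DataFrame(env_rows, index=ids)

    truth = pd.DataFrame(
        [
            {
                "station": s.name,
                "regime": s.regime,
                "exposure": s.exposure,
                "dense": s.dense,
                "true_disturbed": s.exposure > 0,
                "true_resistance_class": true_resistance_class(s.exposure),
            }
            for s in cfg.stations
        ]
    ).set_index("station")

    return SyntheticDataset(
        matrix=matrix, env=env, truth=truth, config=cfg,
        responder_trfs=sorted(int(trfs[i]) for i in responders),
        dominant_trfs=sorted(int(trfs[i]) for i in dominants),
        taxon_trfs=trfs,
    )


# ---------------------------------------------------------------------------
# default scenario


def kaneohe_like(seed: int = 0, **overrides) -> ScenarioConfig:
    """Default 23-station, 3-regime bay scenario with 12 dense-sampled stations.

    Exposure reflects the spatial pattern of a localized storm: full
    exposure at near-shore coastal stations, none offshore, partial at
    the remaining coastal and freshwater sites.
    """
    dense_coastal_full = ("AR", "CB", "NB", "SB", "SBC")
    dense_coastal_part = ("SBE", "SISLE")
    dense_offshore = ("CBS", "NR2", "SR2", "SR8")
    stations = [
        *(StationSpec(n, "coastal", 1.0, dense=True) for n in dense_coastal_full),
        *(StationSpec(n, "coastal", 0.3, dense=True) for n in dense_coastal_part),
        *(StationSpec(n, "offshore", 0.0, dense=True) for n in dense_offshore),
        StationSpec("KS", "freshwater", 0.3, dense=True),
        *(
            StationSpec(n, "coastal", 0.5, dense=False)
            for n in ("CBC", "JB", "JD2", "JD3", "MMRP", "MR", "NBD", "SY")
        ),
        StationSpec("NR4", "offshore", 0.0, dense=False),
        StationSpec("SR4", "offshore", 0.0, dense=False),
        StationSpec("JD1", "freshwater", 0.3, dense=False),
    ]
    return ScenarioConfig(stations=tuple(stations), seed=seed, **overrides)


def null_scenario(
    seed: int = 0, n_stations: int = 25, n_taxa: int = 30, **overrides
) -> ScenarioConfig:
    """Compact all-null scenario (exposure 0 everywhere) for calibration.

    Every station is dense-sampled so each provides a storm vs non-storm
    contrast; with zero exposure the two conditions are exchangeable.
    """
    stations = tuple(
        StationSpec(f"N{i:02d}", "coastal", 0.0, dense=True) for i in range(n_stations)
    )
    return ScenarioConfig(stations=stations, seed=seed, n_taxa=n_taxa, **overrides)


# ---------------------------------------------------------------------------
# ground-truth evaluation


@dataclass
class GroundTruthSummary:
    """Confusion of detected vs planted disturbance, and class agreement."""

    n_assessed: int
    true_positive: int
    false_positive: int
    true_negative: int
    false_negative: int
    sensitivity: float
    specificity: float
    class_confusion: pd.DataFrame  # planted class x assigned class


def ground_truth_eval(
    dataset: SyntheticDataset,
    report: StormAssessmentReport,
    alpha: float = 0.05,
) -> GroundTruthSummary:
    """Cross-tabulate the report's detections against the planted truth."""
    if not report.assessments:
        raise ValueError("empty report: nothing to evaluate")
    truth = dataset.truth
    unknown = [a.station for a in report.assessments if a.station not in truth.index]
    if unknown:
        raise ValueError(f"report contains stations absent from the dataset: {unknown}")

    tp = fp = tn = fn = 0
    rows = []
    for a in report.assessments:
        detected = a.p_com < alpha
        disturbed = bool(truth.loc[a.station, "true_disturbed"])
        if disturbed and detected:
            tp += 1
        elif disturbed:
            fn += 1
        elif detected:
            fp += 1
        else:
            tn += 1
        rows.append(
            (truth.loc[a.station, "true_resistance_class"], a.resistance_class)
        )
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    confusion = pd.crosstab(
        pd.Series([r[0] for r in rows], name="planted"),
        pd.Series([r[1] for r in rows], name="assigned"),
    )
    return GroundTruthSummary(
        n_assessed=len(report.assessments),
        true_positive=tp, false_positive=fp, true_negative=tn, false_negative=fn,
        sensitivity=sens, specificity=spec, class_confusion=confusion,
    )
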