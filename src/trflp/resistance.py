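"""Per-station disturbance resistance from paired ANOSIM statistics.

For every station, two one-way ANOSIMs contrast storm against non-storm
samples: one on the Euclidean matrix of standardized environmental
variables (R_env, a proxy for local disturbance strength) and one on the
Bray-Curtis matrix of rank-transformed T-RFLP profiles (R_com, the
community shift). The resistance ratio

    ratio = |R_com| / |R_env|

quantifies how strongly the community moved relative to its environment:
ratios near zero indicate high resistance, values around 1 intermediate
resistance, and ratios above 1.5 low resistance. Absolute values are
used because ANOSIM R can be (slightly) negative by sampling noise while
the ratio is read as a magnitude; when both R values are small the ratio
is numerically unstable and is flagged with a caution.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distance import community_distance, environment_distance
from .io_profiles import ProfileMatrix
from .permutation_tests import anosim

log = logging.getLogger(__name__)

#: Ratio below which resistance is classed "high" (midpoint convention).
HIGH_RESISTANCE_MAX = 0.5
#: Ratio above which resistance is classed "low".
LOW_RESISTANCE_MIN = 1.5
#: Both |R| below this -> ratio flagged as unreliable.
CAUTION_R_THRESHOLD = 0.2


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Presentation rounding, halves away from zero."""
    m = 10 ** ndigits
    return math.floor(x * m + 0.5) / m


@dataclass
class ResistanceAssessment:
    """One station's storm assessment (one report row)."""

    station: str
    r_env: float
    p_env: float
    r_com: float
    p_com: float
    ratio: float  # exact quotient; round only at presentation
    resistance_class: str  # "high" | "intermediate" | "low"
    caution: bool
    storm_window: tuple[str, str] | None = None
    n_storm: int | None = None
    n_nonstorm: int | None = None

    @property
    def ratio_2dp(self) -> float:
        return round_half_up(self.ratio) if math.isfinite(self.ratio) else self.ratio


@dataclass
class StormAssessmentReport:
    """Collection of station assessments with the significance partition."""

    assessments: list[ResistanceAssessment]
    alpha: float
    both: list[str]
    env_only: list[str]
    community_only: list[str]
    neither: list[str]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "both": len(self.both),
            "env_only": len(self.env_only),
            "community_only": len(self.community_only),
            "neither": len(self.neither),
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "station": a.station,
                "R_env": a.r_env,
                "p_env": a.p_env,
                "R_com": a.r_com,
                "p_com": a.p_com,
                "ratio": a.ratio_2dp,
                "class": a.resistance_class,
                "caution": a.caution,
            }
            for a in self.assessments
        ]
        return pd.DataFrame(rows)


def resistance_ratio(r_com: float, r_env: float, signed: bool = False) -> float:
    """|R_com| / |R_env| (default), or the signed quotient with ``signed=True``.

    A zero R_env gives +inf when R_com is nonzero (environment unchanged
    but community moved, e.g. dispersal-driven turnover) and 0.0 when
    both are zero; both cases carry a forced caution downstream.
    """
    for name, v in (("r_com", r_com), ("r_env", r_env)):
        if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
            raise ValueError(f"{name} must be in [-1, 1], got {v}")
    num, den = (r_com, r_env) if signed else (abs(r_com), abs(r_env))
    if den == 0:
        return 0.0 if num == 0 else math.inf
    return num / den


def classify_resistance(
    ratio: float,
    r_env: float,
    r_com: float,
    high_max: float = HIGH_RESISTANCE_MAX,
    low_min: float = LOW_RESISTANCE_MIN,
    caution_threshold: float = CAUTION_R_THRESHOLD,
) -> tuple[str, bool]:
    """Map a resistance ratio to a class and a reliability caution.

    high if ratio < ``high_max``; low if ratio > ``low_min``;
    intermediate otherwise. Caution is raised when
    max(|R_env|, |R_com|) < ``caution_threshold`` (both statistics near
    zero, so the quotient is noise-dominated) or when the ratio is
    infinite (zero denominator).
    """
    if ratio < 0:
        raise ValueError("ratio must be >= 0")
    if ratio < high_max:
        cls = "high"
    elif ratio <= low_min:
        cls = "intermediate"
    else:
        cls = "low"
    caution = max(abs(r_env), abs(r_com)) < caution_threshold or not math.isfinite(ratio)
    return cls, caution


def _parse_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return pd.Timestamp(value).date()


def storm_condition_labels(
    dates: Sequence, storm_window: tuple | None
) -> pd.Series | None:
    """Map sample dates to 'storm'/'non-storm' given a closed date window."""
    if storm_window is None:
        return None
    start, end = (_parse_date(storm_window[0]), _parse_date(storm_window[1]))
    parsed = [_parse_date(d) for d in dates]
    return pd.Series(
        ["storm" if start <= d <= end else "non-storm" for d in parsed]
    )


def assess_station(
    matrix: ProfileMatrix,
    env: pd.DataFrame,
    station: str,
    storm_window: tuple | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    env_variables: Sequence[str] | None = None,
    transform: str = "rank",
) -> ResistanceAssessment | None:
    """Run the full per-station storm assessment.

    Restricts the community matrix and environmental table to one
    station's samples, labels each sample storm/non-storm from the storm
    window (or an existing ``condition`` metadata column), runs ANOSIM
    on both data streams, and derives the resistance ratio and class.
    Returns None (with a logged reason) when the station lacks two storm
    and two non-storm samples with complete environmental data.
    """
    if matrix.metadata is None or "station" not in matrix.metadata.columns:
        raise ValueError("matrix.metadata with a 'station' column is required")
    mask = matrix.metadata["station"] == station
    sample_ids = [s for s, m in zip(matrix.sample_ids, mask) if m]
    if not sample_ids:
        log.warning("station %r: no samples; skipped", station)
        return None

    meta = matrix.metadata.loc[sample_ids]
    if storm_window is not None:
        cond = storm_condition_labels(meta["date"], storm_window)
        cond.index = sample_ids
    elif "condition" in meta.columns:
        cond = meta["condition"]
    else:
        raise ValueError("need either storm_window or a 'condition' metadata column")

    # complete environmental data only
    variables = list(env_variables) if env_variables is not None else list(env.columns)
    env_sub = env.reindex(sample_ids)[variables]
    complete = ~env_sub.isna().any(axis=1)
    keep = [s for s in sample_ids if complete[s]]
    if len(keep) < len(sample_ids):
        log.warning(
            "station %r: %d samples lack environmental data",
            station, len(sample_ids) - len(keep),
        )
    cond = cond.loc[keep]
    n_storm = int((cond == "storm").sum())
    n_nonstorm = int((cond == "non-storm").sum())
    if n_storm < 2 or n_nonstorm < 2:
        log.warning(
            "station %r skipped: %d storm / %d non-storm samples (need >= 2 each)",
            station, n_storm, n_nonstorm,
        )
        return None

    sub = matrix.subset(keep)
    com_dist = community_distance(sub, transform=transform)
    env_dist = environment_distance(env_sub.loc[keep], variables)

    s_env, s_com = (None, None) if seed is None else (seed, seed + 1)
    res_env = anosim(env_dist, cond.loc[keep], n_perm=n_perm, seed=s_env)
    res_com = anosim(com_dist, cond.loc[keep], n_perm=n_perm, seed=s_com)

    ratio = resistance_ratio(res_com.R, res_env.R)
    cls, caution = classify_resistance(ratio, res_env.R, res_com.R)
    window = None
    if storm_window is not None:
        window = (str(_parse_date(storm_window[0])), str(_parse_date(storm_window[1])))
    return ResistanceAssessment(
        station=station,
        r_env=res_env.R, p_env=res_env.p,
        r_com=res_com.R, p_com=res_com.p,
        ratio=ratio, resistance_class=cls, caution=caution,
        storm_window=window, n_storm=n_storm, n_nonstorm=n_nonstorm,
    )


def summarize_report(
    assessments: Sequence[ResistanceAssessment],
    alpha: float = 0.05,
    skipped: dict[str, str] | None = None,
) -> StormAssessmentReport:
    """Partition stations by which data stream differed significantly."""
    if not assessments:
        raise ValueError("no assessments to summarize")
    ordered = list(assessments)
    both, env_only, com_only, neither = [], [], [], []
    for a in ordered:
        sig_env, sig_com = a.p_env < alpha, a.p_com < alpha
        if sig_env and sig_com:
            both.append(a.station)
        elif sig_env:
            env_only.append(a.station)
        elif sig_com:
            com_only.append(a.station)
        else:
            neither.append(a.station)
    return StormAssessmentReport(
        assessments=ordered, alpha=alpha,
        both=both, env_only=env_only, community_only=com_only, neither=neither,
        skipped=dict(skipped or {}),
    )


def assess_all_stations(
    matrix: ProfileMatrix,
    env: pd.DataFrame,
    storm_window: tuple,
    stations: Sequence[str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
    env_variables: Sequence[str] | None = None,
) -> StormAssessmentReport:
    """Assess every station (in metadata order) and summarize."""
    if stations is None:
        stations = list(pd.unique(matrix.metadata["station"]))
    assessments, skipped = [], {}
    for k, st in enumerate(stations):
        sub_seed = None if seed is None else seed + 2 * k
        a = assess_station(
            matrix, env, st, storm_window, alpha=alpha, n_perm=n_perm,
            seed=sub_seed, env_variables=env_variables,
        )
        if a is None:
            skipped[st] = "insufficient storm/non-storm samples"
        else:
            assessments.append(a)
    return summarize_report(assessments, alpha=alpha, skipped=skipped)
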