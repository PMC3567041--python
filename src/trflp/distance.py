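"""Community and environmental distance matrices.

The community matrix is Bray-Curtis dissimilarity on within-sample
rank-transformed T-RFLP abundances; the environmental matrix is
Euclidean distance on variables standardized to zero mean and unit
(sample) standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io_profiles import ProfileMatrix

log = logging.getLogger(__name__)

#: Environmental variables measured in the bay survey, with units.
ENV_VARIABLES = {
    "temperature": "degC",
    "salinity": "permil",
    "NH4": "umol/L",
    "NO2": "umol/L",
    "NN": "umol/L",  # nitrate + nitrite
    "SRP": "umol/L",  # soluble reactive phosphorus
    "H2SiO4": "umol/L",
    "chl_a": "ug/L",
}


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with sample labels."""

    labels: list[str]
    values: np.ndarray
    kind: str = "community"  # "community" | "environment"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {self.values.shape}")
        if not np.allclose(self.values, self.values.T, atol=1e-12, rtol=0):
            raise ValueError("distance matrix must be symmetric")
        self.values = (self.values + self.values.T) / 2.0
        if np.any(np.abs(np.diag(self.values)) > 0):
            raise ValueError("distance matrix diagonal must be zero")
        np.fill_diagonal(self.values, 0.0)
        if np.any(self.values < -1e-12):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper triangle in scipy condensed order."""
        return squareform(self.values, checks=False)

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)], self.kind)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, kind: str = "community") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id")
        return cls(list(df.index), df.to_numpy(), kind)


def rank_transform(matrix: ProfileMatrix, mode: str = "within-sample") -> ProfileMatrix:
    """Replace abundances by ranks prior to Bray-Curtis.

    ``within-sample`` (default): within each sample, nonzero abundances
    are replaced by their ascending ranks (average ranks for ties);
    zeros stay zero. The subsequent Bray-Curtis then depends only on the
    abundance order within each sample.

    ``per-trf``: alternative convention ranking each T-RF column across
    samples (all entries, zeros included, average ties).
    """
    values = matrix.values.to_numpy().copy()
    if mode == "within-sample":
        for i in range(values.shape[0]):
            nz = values[i] > 0
            if nz.any():
                values[i, nz] = rankdata(values[i, nz], method="average")
    elif mode == "per-trf":
        for j in range(values.shape[1]):
            values[:, j] = rankdata(values[:, j], method="average")
    else:
        raise ValueError(f"unknown rank-transform mode {mode!r}")
    return ProfileMatrix(
        pd.DataFrame(values, index=matrix.values.index, columns=matrix.values.columns),
        matrix.metadata,
    )


def bray_curtis(matrix: ProfileMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(j,k) = sum_i |y_ij - y_ik| / sum_i (y_ij + y_ik)."""
    values = matrix.values.to_numpy()
    if np.any(values < 0):
        raise ValueError("Bray-Curtis requires non-negative abundances")
    sums = values.sum(axis=1)
    if np.any(sums <= 0):
        bad = [matrix.sample_ids[i] for i in np.where(sums <= 0)[0]]
        raise ValueError(f"samples with zero total abundance: {bad}")
    dist = squareform(pdist(values, metric="braycurtis"))
    return DistanceMatrix(matrix.sample_ids, dist, kind="community")


def standardize_env(env: pd.DataFrame, variables: Sequence[str] | None = None) -> pd.DataFrame:
    """Center each selected variable to mean 0 and scale to SD 1 (ddof=1).

    Rows with any missing value among the selected variables are
    excluded (logged) before standardization.
    """
    variables = list(variables) if variables is not None else list(env.columns)
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise KeyError(f"environmental variables not found: {missing}")
    sub = env[variables].apply(pd.to_numeric)
    incomplete = sub.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "excluding %d samples with missing environmental data: %s",
            int(incomplete.sum()), list(sub.index[incomplete]),
        )
        sub = sub[~incomplete]
    if len(sub) < 2:
        raise ValueError("need at least 2 complete samples to standardize")
    sd = sub.std(ddof=1)
    flat = sd[sd == 0].index.tolist()
    if flat:
        raise ValueError(f"zero-variance environmental variables: {flat}")
    return (sub - sub.mean()) / sd


def euclidean(
    data: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None
) -> DistanceMatrix:
    """Euclidean distance matrix over rows of ``data``."""
    if isinstance(data, pd.DataFrame):
        labels = list(data.index) if labels is None else list(labels)
        arr = data.to_numpy(dtype=float)
    else:
        arr = np.asarray(data, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(arr.shape[0])]
    dist = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(list(labels), dist, kind="environment")


def community_distance(
    matrix: ProfileMatrix, transform: str = "rank", rank_mode: str = "within-sample"
) -> DistanceMatrix:
    """Pipeline community distance: Bray-Curtis on (optionally) rank-transformed data."""
    if transform == "rank":
        matrix = rank_transform(matrix, mode=rank_mode)
    elif transform not in ("none", "relative"):
        raise ValueError(f"unknown transform {transform!r}")
    return bray_curtis(matrix)


def environment_distance(
    env: pd.DataFrame, variables: Sequence[str] | None = None
) -> DistanceMatrix:
    """Pipeline environmental distance: Euclidean on standardized variables."""
    z = standardize_env(env, variables)
    return euclidean(z)
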