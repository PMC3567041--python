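"""Sample ordination and station clustering.

Non-metric multidimensional scaling (NMDS) embeds samples in k
dimensions minimizing Kruskal stress-1; K-means groups stations by their
community time series; UPGMA (average linkage) clusters sites from a
matrix of pairwise ANOSIM R values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.manifold import smacof

from .distance import DistanceMatrix
from .io_profiles import ProfileMatrix, to_relative

log = logging.getLogger(__name__)


@dataclass
class NmdsResult:
    coordinates: np.ndarray  # n x k, centered
    stress: float  # Kruskal stress-1 of the best start
    n_starts: int
    converged: bool
    seed: int | None
    labels: list[str]
    start_stresses: list[float] = field(default_factory=list)


@dataclass
class StationClustering:
    stations: list[str]
    assignments: dict[str, int]
    k: int
    inertia: float  # total within-cluster sum of squares
    feature_info: dict
    seed: int | None = None


@dataclass
class Dendrogram:
    """UPGMA merge history over the input sites.

    ``merges`` is a scipy linkage matrix: each row (i, j, height, size)
    merges clusters i and j at the given height. ``shift`` is the
    constant added to the input values to make them non-negative
    dissimilarities (pairwise ANOSIM R can be negative).
    """

    labels: list[str]
    merges: np.ndarray
    shift: float

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def cut(self, height: float) -> dict[int, list[str]]:
        """Site groups at a height (on the shifted scale)."""
        flat = fcluster(self.merges, t=height, criterion="distance")
        groups: dict[int, list[str]] = {}
        for label, c in zip(self.labels, flat):
            groups.setdefault(int(c), []).append(label)
        return groups


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> NmdsResult:
    """Non-metric MDS by iterative majorization (SMACOF) with monotone regression.

    Runs ``n_starts`` random initializations and keeps the configuration
    with the lowest Kruskal stress-1, sqrt(sum (d - dhat)^2 / sum d^2)
    with dhat the isotonic disparities. Coordinates are centered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= dist.n:
        raise ValueError(f"k={k} must be smaller than the number of samples ({dist.n})")
    rng = np.random.default_rng(seed)
    best = None
    stresses: list[float] = []
    for s in range(n_starts):
        state = int(rng.integers(0, 2**31 - 1))
        coords, stress, n_iter = smacof(
            dist.values, metric=False, n_components=k, init=None, n_init=1,
            max_iter=max_iter, eps=tol, random_state=state,
            normalized_stress=True, return_n_iter=True,
        )
        stresses.append(float(stress))
        if best is None or stress < best[1]:
            best = (coords, float(stress), n_iter < max_iter)
    coords, stress, converged = best
    coords = coords - coords.mean(axis=0, keepdims=True)
    return NmdsResult(
        coordinates=coords, stress=stress, n_starts=n_starts,
        converged=converged, seed=seed, labels=list(dist.labels),
        start_stresses=stresses,
    )


def station_features(
    matrix: ProfileMatrix, dates: Sequence | None = None
) -> tuple[pd.DataFrame, dict]:
    """Per-station feature vectors: relative-abundance profiles across shared dates.

    ``dates=None`` uses every date observed anywhere in the matrix;
    stations missing any of the included dates are excluded (logged), as
    in surveys where some sites lack the dense storm-window sampling.
    """
    if matrix.metadata is None or not {"station", "date"} <= set(matrix.metadata.columns):
        raise ValueError("metadata with 'station' and 'date' columns is required")
    rel = to_relative(matrix)
    meta = matrix.metadata
    all_dates = sorted(pd.unique(meta["date"])) if dates is None else sorted(dates)

    rows, excluded = {}, []
    for station in pd.unique(meta["station"]):
        sids = meta.index[meta["station"] == station]
        by_date = {meta.loc[s, "date"]: s for s in sids}
        if not all(d in by_date for d in all_dates):
            excluded.append(str(station))
            continue
        rows[str(station)] = np.concatenate(
            [rel.values.loc[by_date[d]].to_numpy() for d in all_dates]
        )
    if excluded:
        log.warning("stations excluded from clustering (missing dates): %s", excluded)
    if not rows:
        raise ValueError("no station is sampled at every included date")
    feats = pd.DataFrame.from_dict(rows, orient="index")
    info = {
        "dates": [str(d) for d in all_dates],
        "excluded_stations": excluded,
        "n_trfs": len(matrix.trf_lengths),
        "transform": "relative-abundance",
    }
    return feats, info


def kmeans_stations(
    matrix: ProfileMatrix,
    k: int = 3,
    n_starts: int = 10,
    seed: int | None = None,
    dates: Sequence | None = None,
) -> StationClustering:
    """K-means grouping of stations by their community dynamics over time."""
    feats, info = station_features(matrix, dates)
    if k > len(feats):
        raise ValueError(f"k={k} exceeds the number of usable stations ({len(feats)})")
    km = KMeans(n_clusters=k, n_init=n_starts, random_state=seed)
    labels = km.fit_predict(feats.to_numpy())
    return StationClustering(
        stations=list(feats.index),
        assignments={s: int(c) for s, c in zip(feats.index, labels)},
        k=k, inertia=float(km.inertia_), feature_info=info, seed=seed,
    )


def hclust_average(
    r_matrix: pd.DataFrame | DistanceMatrix, labels: Sequence[str] | None = None
) -> Dendrogram:
    """UPGMA dendrogram from a symmetric matrix of pairwise ANOSIM R values.

    Negative R values are permitted: the whole matrix is shifted by
    max(0, -min(off-diagonal)) so UPGMA operates on a non-negative
    dissimilarity, and the shift is reported.
    """
    if isinstance(r_matrix, DistanceMatrix):
        values, labels = r_matrix.values, list(r_matrix.labels)
    elif isinstance(r_matrix, pd.DataFrame):
        values, labels = r_matrix.to_numpy(dtype=float), list(r_matrix.index)
    else:
        values = np.asarray(r_matrix, dtype=float)
        labels = list(labels) if labels is not None else [str(i) for i in range(len(values))]
    if values.shape[0] != values.shape[1] or not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("pairwise R matrix must be square and symmetric")
    off = values[~np.eye(len(values), dtype=bool)]
    shift = float(max(0.0, -off.min())) if len(off) else 0.0
    shifted = values + shift
    np.fill_diagonal(shifted, 0.0)
    z = linkage(squareform(shifted, checks=False), method="average")
    return Dendrogram(labels=labels, merges=z, shift=shift)
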