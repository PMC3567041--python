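"""Linking community structure to the environment: BIO-ENV and SIMPER.

BIO-ENV exhaustively searches subsets of environmental variables for the
Euclidean (standardized) environment matrix whose rank correlation with
the community distance matrix is highest. SIMPER decomposes the average
between-group Bray-Curtis dissimilarity into additive per-T-RF
percentage contributions, identifying which fragments drive the
storm/non-storm difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .distance import DistanceMatrix, euclidean, standardize_env
from .io_profiles import ProfileMatrix
from .permutation_tests import _spearman, relate


@dataclass
class BioEnvResult:
    ranking: list[tuple[tuple[str, ...], float]]  # sorted by rho descending
    best_subset: tuple[str, ...]
    best_rho: float
    p: float | None  # RELATE p for the best subset
    p_is_a_posteriori: bool = True  # selected-then-tested; biased by construction
    n_perm: int | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"subset": ",".join(s), "k": len(s), "rho": r} for s, r in self.ranking]
        )


@dataclass
class SimperResult:
    trf_lengths: list[int]
    contributions: np.ndarray  # average per-T-RF contribution (dissimilarity units)
    percent: np.ndarray  # % of the overall average dissimilarity
    overall_dissimilarity: float
    group_a: str
    group_b: str
    n_pairs: int
    degenerate: bool = False  # identical groups: zero dissimilarity

    def to_dataframe(self) -> pd.DataFrame:
        order = np.argsort(-self.percent, kind="stable")
        df = pd.DataFrame(
            {
                "trf_bp": np.asarray(self.trf_lengths)[order],
                "mean_contribution": self.contributions[order],
                "mean_contribution_pct": self.percent[order],
            }
        )
        df["cumulative_pct"] = df["mean_contribution_pct"].cumsum()
        return df

    def top_trfs(self, n: int = 5) -> list[int]:
        order = np.argsort(-self.percent, kind="stable")[:n]
        return [int(self.trf_lengths[i]) for i in order]


def bioenv(
    bio_dist: DistanceMatrix,
    env: pd.DataFrame,
    variables: Sequence[str] | None = None,
    max_subset_size: int | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> BioEnvResult:
    """Exhaustive variable-subset matching of environment to community.

    For every nonempty subset of ``variables`` up to ``max_subset_size``:
    standardize, build the Euclidean distance matrix, and compute the
    Spearman correlation of its upper triangle with ``bio_dist``'s.
    Subsets are ranked by rho (ties: smaller subset first, then
    lexicographic). A RELATE permutation p is attached for the winning
    subset only, flagged a-posteriori since testing a selected subset is
    biased.
    """
    variables = sorted(env.columns) if variables is None else list(variables)
    missing = [v for v in variables if v not in env.columns]
    if missing:
        raise KeyError(f"environmental variables not found: {missing}")
    if len(variables) > 15:
        raise ValueError("more than 15 variables: subset enumeration is infeasible")
    max_k = len(variables) if max_subset_size is None else min(max_subset_size, len(variables))

    env_sub = env.reindex(bio_dist.labels)
    if env_sub.isna().all(axis=None):
        raise ValueError("no environmental data for the community samples")

    bio_ranks = rankdata(bio_dist.condensed(), method="average")
    results: list[tuple[tuple[str, ...], float]] = []
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(variables, k):
            z = standardize_env(env_sub, list(subset))
            d = euclidean(z)
            if list(z.index) != bio_dist.labels:  # rows dropped for missing data
                raise ValueError(
                    "missing environmental values among selected samples; "
                    "complete the table or drop those samples first"
                )
            env_ranks = rankdata(d.condensed(), method="average")
            results.append((subset, _spearman(bio_ranks, env_ranks)))

    results.sort(key=lambda sr: (-sr[1], len(sr[0]), sr[0]))
    best_subset, best_rho = results[0]
    best_env = euclidean(standardize_env(env_sub, list(best_subset)))
    p = relate(bio_dist, best_env, n_perm=n_perm, seed=seed).p
    return BioEnvResult(
        ranking=results, best_subset=best_subset, best_rho=best_rho,
        p=p, n_perm=n_perm,
    )


def pair_contributions(y_j: np.ndarray, y_k: np.ndarray) -> np.ndarray:
    """Per-T-RF contribution of one sample pair to their Bray-Curtis distance.

    delta_i(j,k) = |y_ij - y_ik| / sum_s (y_sj + y_sk); the contributions
    sum exactly to the pair's Bray-Curtis dissimilarity.
    """
    denom = float(y_j.sum() + y_k.sum())
    if denom <= 0:
        raise ValueError("pair with zero joint abundance")
    return np.abs(y_j - y_k) / denom


def simper(
    matrix: ProfileMatrix,
    labels,
    group_a: str,
    group_b: str,
) -> SimperResult:
    """SIMPER: decompose average between-group dissimilarity by T-RF.

    ``labels`` assigns each sample a group (sequence aligned to the
    matrix rows, or a Series indexed by sample id). Contributions are
    averaged over all between-group sample pairs and expressed as % of
    the overall average dissimilarity. Operates on whatever transform
    the caller applied (relative abundance in the default pipeline).
    """
    if isinstance(labels, pd.Series):
        lab = labels.reindex(matrix.sample_ids).to_numpy()
    else:
        lab = np.asarray(labels)
        if len(lab) != len(matrix.sample_ids):
            raise ValueError("labels length does not match the matrix")
    for g in (group_a, group_b):
        if g not in lab:
            raise ValueError(f"unknown group label {g!r}")

    values = matrix.values.to_numpy()
    rows_a = values[lab == group_a]
    rows_b = values[lab == group_b]
    n_pairs = len(rows_a) * len(rows_b)
    acc = np.zeros(values.shape[1])
    for y_j in rows_a:
        for y_k in rows_b:
            acc += pair_contributions(y_j, y_k)
    contributions = acc / n_pairs
    overall = float(contributions.sum())
    if overall > 0:
        percent = contributions / overall * 100.0
        degenerate = False
    else:
        percent = np.zeros_like(contributions)
        degenerate = True
    return SimperResult(
        trf_lengths=matrix.trf_lengths, contributions=contributions,
        percent=percent, overall_dissimilarity=overall,
        group_a=group_a, group_b=group_b, n_pairs=n_pairs, degenerate=degenerate,
    )
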