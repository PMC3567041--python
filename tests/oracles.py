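"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive (double loops, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata


def anosim_R_bruteforce(dist: np.ndarray, labels) -> float:
    """ANOSIM R via explicit pair loops on the square matrix."""
    labels = list(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([dist[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if labels[i] == labels[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if labels[i] != labels[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2.0)


def anosim_exact_bruteforce(dist: np.ndarray, labels) -> tuple[float, float]:
    """(R, exact p) by enumerating every distinct labeling."""
    r_obs = anosim_R_bruteforce(dist, labels)
    seen, null = set(), []
    for perm in itertools.permutations(labels):
        if perm in seen:
            continue
        seen.add(perm)
        null.append(anosim_R_bruteforce(dist, perm))
    p = sum(r >= r_obs - 1e-12 for r in null) / len(null)
    return r_obs, p


def crossed_anosim_exact_bruteforce(
    dist: np.ndarray, tested, strata
) -> tuple[float, float]:
    """Two-way crossed ANOSIM (average within-stratum R) with exact
    stratum-constrained permutation p, by full enumeration."""
    tested, strata = list(tested), list(strata)
    levels = sorted(set(strata), key=str)
    members = {s: [i for i, v in enumerate(strata) if v == s] for s in levels}

    def stratum_R(level, labels_for_level):
        idx = members[level]
        sub = dist[np.ix_(idx, idx)]
        within = [
            labels_for_level[a] == labels_for_level[b]
            for a in range(len(idx)) for b in range(a + 1, len(idx))
        ]
        if not any(within) or all(within):
            return None
        return anosim_R_bruteforce(sub, labels_for_level)

    def average_R(assignment):
        rs = [stratum_R(s, assignment[s]) for s in levels]
        rs = [r for r in rs if r is not None]
        return np.mean(rs) if rs else None

    observed = {s: [tested[i] for i in members[s]] for s in levels}
    r_obs = average_R(observed)

    def distinct_perms(labels):
        return sorted({p for p in itertools.permutations(labels)})

    null = []
    per_stratum = [distinct_perms(observed[s]) for s in levels]
    for combo in itertools.product(*per_stratum):
        r = average_R(dict(zip(levels, combo)))
        if r is not None:
            null.append(r)
    p = sum(r >= r_obs - 1e-12 for r in null) / len(null)
    return float(r_obs), float(p)


def bray_curtis_loops(a: np.ndarray, b: np.ndarray) -> float:
    num = sum(abs(x - y) for x, y in zip(a, b))
    den = sum(x + y for x, y in zip(a, b))
    return num / den


def spearman_loops(x, y) -> float:
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def relate_exact_bruteforce(da: np.ndarray, db: np.ndarray) -> tuple[float, float]:
    """(rho, exact p) enumerating all simultaneous row/column permutations."""
    n = da.shape[0]
    triu = [(i, j) for i in range(n) for j in range(i + 1, n)]
    xa = [da[i, j] for i, j in triu]
    rho_obs = spearman_loops(xa, [db[i, j] for i, j in triu])
    null = []
    for perm in itertools.permutations(range(n)):
        xb = [db[perm[i], perm[j]] for i, j in triu]
        null.append(spearman_loops(xa, xb))
    p = sum(r >= rho_obs - 1e-12 for r in null) / len(null)
    return rho_obs, p


def upgma_naive(dist: np.ndarray) -> list[float]:
    """Merge heights of average-linkage clustering, O(n^3) by hand."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


def bioenv_bruteforce(bio: np.ndarray, env_cols: dict[str, np.ndarray]):
    """Ranked (subset, rho) list by direct re-computation."""
    n = bio.shape[0]
    triu = [(i, j) for i in range(n) for j in range(i + 1, n)]
    bio_vec = [bio[i, j] for i, j in triu]
    names = sorted(env_cols)
    out = []
    for k in range(1, len(names) + 1):
        for subset in itertools.combinations(names, k):
            z = np.column_stack(
                [
                    (env_cols[v] - env_cols[v].mean()) / env_cols[v].std(ddof=1)
                    for v in subset
                ]
            )
            evec = [np.sqrt(((z[i] - z[j]) ** 2).sum()) for i, j in triu]
            out.append((subset, spearman_loops(bio_vec, evec)))
    out.sort(key=lambda sr: (-sr[1], len(sr[0]), sr[0]))
    return out


def simper_pair_loops(rows_a: np.ndarray, rows_b: np.ndarray) -> np.ndarray:
    """Average per-column contribution over all between-group pairs."""
    acc = np.zeros(rows_a.shape[1])
    n = 0
    for ya in rows_a:
        for yb in rows_b:
            den = ya.sum() + yb.sum()
            acc += np.abs(ya - yb) / den
            n += 1
    return acc / n
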