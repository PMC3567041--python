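"""ANOSIM (one-way and two-way crossed), PERMANOVA, RELATE."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

from conftest import random_distance_matrix
from oracles import (
    anosim_exact_bruteforce,
    crossed_anosim_exact_bruteforce,
    relate_exact_bruteforce,
)
from trflp.distance import DistanceMatrix, euclidean
from trflp.permutation_tests import anosim, anosim_2way_crossed, permanova, relate

skbio_stats = pytest.importorskip("skbio.stats.distance")


def _separated_4() -> DistanceMatrix:
    """Two tight pairs far apart: within < every between distance."""
    d = np.array(
        [
            [0.0, 0.1, 0.9, 1.0],
            [0.1, 0.0, 0.8, 0.95],
            [0.9, 0.8, 0.0, 0.15],
            [1.0, 0.95, 0.15, 0.0],
        ]
    )
    return DistanceMatrix(list("abcd"), d)


class TestAnosim:
    def test_perfect_separation_gives_R_one(self):
        res = anosim(_separated_4(), ["A", "A", "B", "B"], n_perm=99, seed=0)
        assert res.R == pytest.approx(1.0)

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            anosim(_separated_4(), ["A"] * 4, n_perm=9, seed=0)

    def test_small_group_errors(self):
        with pytest.raises(ValueError, match="< 2 samples"):
            anosim(_separated_4(), ["A", "A", "A", "B"], n_perm=9, seed=0)

    @pytest.mark.parametrize("seed,labels", [
        (1, ["A", "A", "A", "B", "B", "B"]),
        (2, ["A", "A", "B", "B", "B", "B"]),
        (3, ["A", "B", "A", "B", "A", "B"]),
    ])
    def test_exact_matches_enumeration_oracle(self, seed, labels):
        dist = random_distance_matrix(6, seed)
        res = anosim(dist, labels, method="exact")
        r_oracle, p_oracle = anosim_exact_bruteforce(dist.values, labels)
        assert res.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)

    def test_monte_carlo_p_approximates_exact(self):
        dist = random_distance_matrix(6, 5)
        labels = ["A", "A", "A", "B", "B", "B"]
        exact = anosim(dist, labels, method="exact")
        mc = anosim(dist, labels, n_perm=999, seed=11)
        assert mc.R == pytest.approx(exact.R)
        assert mc.p == pytest.approx(exact.p, abs=0.08)

    def test_R_invariant_to_monotone_transform(self):
        dist = random_distance_matrix(7, 9)
        labels = ["A", "A", "A", "B", "B", "B", "B"]
        transformed = DistanceMatrix(dist.labels, np.sqrt(dist.values))
        r1 = anosim(dist, labels, n_perm=9, seed=0).R
        r2 = anosim(transformed, labels, n_perm=9, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_reproducible_given_seed(self):
        dist = random_distance_matrix(8, 3)
        labels = ["A"] * 4 + ["B"] * 4
        a = anosim(dist, labels, n_perm=99, seed=5)
        b = anosim(dist, labels, n_perm=99, seed=5)
        assert (a.R, a.p) == (b.R, b.p)

    def test_agrees_with_skbio(self):
        dist = random_distance_matrix(9, 13)
        labels = ["A"] * 4 + ["B"] * 5
        ours = anosim(dist, labels, n_perm=999, seed=1)
        ref = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(dist.values, dist.labels),
            grouping=list(labels), permutations=999,
        )
        assert ours.R == pytest.approx(ref["test statistic"], abs=1e-12)
        assert ours.p == pytest.approx(ref["p-value"], abs=0.05)

    def test_series_labels_align_by_sample_id(self):
        dist = _separated_4()
        labels = pd.Series(["B", "B", "A", "A"], index=["c", "d", "a", "b"])
        res = anosim(dist, labels, n_perm=9, seed=0)
        assert res.R == pytest.approx(1.0)


class TestTwoWayCrossedAnosim:
    def _two_strata(self, seed=0) -> tuple[DistanceMatrix, list, list]:
        rng = np.random.default_rng(seed)
        base = _separated_4().values
        n = 8
        d = np.zeros((n, n))
        d[:4, :4] = base
        d[4:, 4:] = base
        far = rng.uniform(2.0, 3.0, size=(4, 4))
        d[:4, 4:] = far
        d[4:, :4] = far.T
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        dist = DistanceMatrix([f"x{i}" for i in range(n)], d)
        factor_a = ["A", "A", "B", "B"] * 2
        strata = ["s1"] * 4 + ["s2"] * 4
        return dist, factor_a, strata

    def test_perfect_within_stratum_separation_gives_R_one(self):
        dist, a, b = self._two_strata()
        res = anosim_2way_crossed(dist, a, b, n_perm=99, seed=0)
        assert res.factor_a.R == pytest.approx(1.0)

    def test_constant_within_stratum_errors(self):
        dist, _, strata = self._two_strata()
        constant = ["A"] * 4 + ["B"] * 4  # tested factor == stratum blocks
        with pytest.raises(ValueError, match="stratum"):
            anosim_2way_crossed(dist, constant, strata, n_perm=9, seed=0)

    def test_exact_matches_constrained_enumeration_oracle(self):
        dist = random_distance_matrix(8, 21)
        a = ["A", "A", "B", "B", "A", "A", "B", "B"]
        b = ["s1"] * 4 + ["s2"] * 4
        res = anosim_2way_crossed(dist, a, b, method="exact")
        r_oracle, p_oracle = crossed_anosim_exact_bruteforce(dist.values, a, b)
        assert res.factor_a.R == pytest.approx(r_oracle, abs=1e-12)
        assert res.factor_a.p == pytest.approx(p_oracle, abs=1e-12)


class TestPermanova:
    def test_univariate_equals_classical_anova_F(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc, 1.0, size=6) for loc in (0.0, 0.7, 2.0)]
        data = np.concatenate(groups)[:, None]
        labels = ["g0"] * 6 + ["g1"] * 6 + ["g2"] * 6
        dist = euclidean(data, [f"s{i}" for i in range(18)])
        res = permanova(dist, labels, n_perm=99, seed=0)
        f_ref = f_oneway(*groups).statistic
        assert res.pseudo_F == pytest.approx(f_ref, abs=1e-9)

    def test_duplicated_groups_give_near_zero_F(self):
        pts = np.array([[0.0, 1.0], [2.0, 0.5], [1.0, 3.0]])
        data = np.vstack([pts, pts])
        labels = ["a", "a", "a", "b", "b", "b"]
        # group a and b are identical point sets -> no between-group signal
        dist = euclidean(data, [f"s{i}" for i in range(6)])
        res = permanova(dist, labels, n_perm=199, seed=0)
        assert res.pseudo_F < 0.5
        assert res.p > 0.5

    def test_invariant_to_sample_reordering(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(8, 2))
        labels = np.array(["a"] * 4 + ["b"] * 4)
        dist = euclidean(data, [f"s{i}" for i in range(8)])
        perm = rng.permutation(8)
        dist2 = euclidean(data[perm], [f"s{i}" for i in perm])
        f1 = permanova(dist, labels, n_perm=9, seed=0).pseudo_F
        f2 = permanova(dist2, labels[perm], n_perm=9, seed=0).pseudo_F
        assert f1 == pytest.approx(f2, abs=1e-12)

    def test_agrees_with_skbio(self):
        dist = random_distance_matrix(10, 31)
        labels = ["a"] * 5 + ["b"] * 5
        ours = permanova(dist, labels, n_perm=99, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(dist.values, dist.labels),
            grouping=list(labels), permutations=99,
        )
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], abs=1e-9)


class TestRelate:
    def test_identity_rho_one(self):
        dist = random_distance_matrix(6, 2)
        res = relate(dist, dist, n_perm=99, seed=0)
        assert res.rho == pytest.approx(1.0)

    def test_monotone_transform_rho_one(self):
        dist = random_distance_matrix(6, 2)
        mono = DistanceMatrix(dist.labels, dist.values**2)
        assert relate(dist, mono, n_perm=9, seed=0).rho == pytest.approx(1.0)

    def test_exact_matches_enumeration_oracle(self):
        da = random_distance_matrix(5, 7)
        db = random_distance_matrix(5, 8, labels=da.labels)
        res = relate(da, db, method="exact")
        rho_oracle, p_oracle = relate_exact_bruteforce(da.values, db.values)
        assert res.rho == pytest.approx(rho_oracle, abs=1e-12)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 120

    def test_label_mismatch_lists_differences(self):
        da = random_distance_matrix(4, 1)
        db = random_distance_matrix(4, 1, labels=["x0", "x1", "x2", "other"])
        with pytest.raises(ValueError, match="other"):
            relate(da, db, n_perm=9)

    def test_rho_agrees_with_skbio_mantel(self):
        da = random_distance_matrix(8, 17)
        db = random_distance_matrix(8, 18, labels=da.labels)
        ours = relate(da, db, n_perm=99, seed=0)
        rho_ref, _, _ = skbio_stats.mantel(
            skbio_stats.DistanceMatrix(da.values, da.labels),
            skbio_stats.DistanceMatrix(db.values, db.labels),
            method="spearman", permutations=0,
        )
        assert ours.rho == pytest.approx(rho_ref, abs=1e-12)
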