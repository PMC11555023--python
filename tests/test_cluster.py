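"""Cluster permutation machinery: scalar-t and flood-fill oracles, label
symmetry, exhaustive enumeration, determinism, extreme-effect limits."""

import numpy as np
import pytest
from scipy import stats

from tapjid.cluster import (
    Cluster,
    binwise_tmap,
    form_clusters,
    max_cluster_size,
    permutation_test,
)
from tapjid.errors import InferenceError
from tapjid.jid import JID, JIDGrid

from conftest import flood_fill_components

GRID = JIDGrid(n_bins=10)  # small grid keeps constructed cases readable


def _jids_from_stack(x: np.ndarray, grid: JIDGrid = GRID) -> list[JID]:
    return [JID(grid=grid, matrix=m, n_pairs=1) for m in x]


def _random_groups(rng, n_a=4, n_b=4, grid=GRID):
    shape = (grid.n_bins, grid.n_bins)
    a = _jids_from_stack(rng.random((n_a, *shape)), grid)
    b = _jids_from_stack(rng.random((n_b, *shape)), grid)
    return a, b


class TestBinwiseTmap:
    def test_identical_groups_give_zero_t(self):
        rng = np.random.default_rng(0)
        a, _ = _random_groups(rng)
        tmap = binwise_tmap(a, list(a))
        np.testing.assert_allclose(tmap.t_values, 0.0, atol=1e-10)

    def test_matches_scipy_per_bin(self):
        rng = np.random.default_rng(1)
        a, b = _random_groups(rng, n_a=4, n_b=5)
        tmap = binwise_tmap(a, b)
        xa = np.stack([j.matrix for j in a])
        xb = np.stack([j.matrix for j in b])
        expected = stats.ttest_ind(xa, xb, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(tmap.t_values, expected, atol=1e-10)
        assert tmap.df == 7

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(2)
        a, b = _random_groups(rng, n_a=4, n_b=7)
        tmap = binwise_tmap(a, b, variant="welch")
        xa = np.stack([j.matrix for j in a])
        xb = np.stack([j.matrix for j in b])
        expected = stats.ttest_ind(xa, xb, axis=0, equal_var=False).statistic
        np.testing.assert_allclose(tmap.t_values, expected, atol=1e-10)

    def test_sign_convention_a_greater_positive(self):
        rng = np.random.default_rng(3)
        base = rng.random((4, GRID.n_bins, GRID.n_bins))
        shifted = base + 1.0
        tmap = binwise_tmap(_jids_from_stack(shifted), _jids_from_stack(base.copy()))
        assert np.all(tmap.t_values[~tmap.flagged] > 0)

    def test_spiked_bin_has_largest_t(self):
        rng = np.random.default_rng(4)
        base = rng.normal(scale=1e-3, size=(4, GRID.n_bins, GRID.n_bins))
        spiked = base.copy()
        spiked[:, 3, 7] += 1.0
        tmap = binwise_tmap(
            _jids_from_stack(spiked), _jids_from_stack(rng.normal(scale=1e-3, size=base.shape))
        )
        assert np.unravel_index(np.argmax(np.abs(tmap.t_values)), tmap.t_values.shape) == (3, 7)

    def test_zero_variance_bins_flagged(self):
        x = np.random.default_rng(5).random((6, GRID.n_bins, GRID.n_bins))
        x[:, 0, 0] = 0.0  # dead corner bin in every day
        tmap = binwise_tmap(_jids_from_stack(x[:3]), _jids_from_stack(x[3:]))
        assert tmap.flagged[0, 0]
        assert tmap.t_values[0, 0] == 0.0

    def test_small_groups_rejected(self):
        rng = np.random.default_rng(6)
        a, b = _random_groups(rng)
        with pytest.raises(InferenceError):
            binwise_tmap(a[:1], b)


class TestFormClusters:
    def _tmap_from_values(self, t, df=10):
        from tapjid.cluster import TMap

        return TMap(grid=GRID, t_values=np.asarray(t, float), df=df, n_a=6, n_b=6)

    def test_all_zero_map_gives_no_clusters(self):
        assert form_clusters(self._tmap_from_values(np.zeros((10, 10)))) == []

    def test_two_disjoint_blobs(self):
        t = np.zeros((10, 10))
        t[1, 1:4] = 10.0  # size-3 blob
        t[6:8, 6:8] = 10.0
        t[8, 6] = 10.0  # size-5 blob
        clusters = form_clusters(self._tmap_from_values(t))
        assert sorted(c.size for c in clusters) == [3, 5]
        assert all(c.sign == 1 for c in clusters)

    def test_signs_clustered_separately(self):
        t = np.zeros((10, 10))
        t[2, 2] = 10.0
        t[2, 3] = -10.0  # adjacent but opposite sign: two clusters
        clusters = form_clusters(self._tmap_from_values(t))
        assert sorted((c.sign, c.size) for c in clusters) == [(-1, 1), (1, 1)]

    def test_diagonal_connectivity_flag(self):
        t = np.zeros((10, 10))
        t[0, 0] = t[1, 1] = 10.0  # touch only diagonally
        tm = self._tmap_from_values(t)
        assert sorted(c.size for c in form_clusters(tm, connectivity=4)) == [1, 1]
        assert [c.size for c in form_clusters(tm, connectivity=8)] == [2]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_components_match_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mask = rng.random((10, 10)) < 0.4
            t = np.where(mask, 10.0, 0.0)
            clusters = form_clusters(self._tmap_from_values(t), connectivity=connectivity)
            got = {c.member_bins for c in clusters}
            expected = set(flood_fill_components(mask, connectivity))
            assert got == expected

    def test_max_cluster_size_rules(self):
        assert max_cluster_size([]) == 0
        mk = lambda sign, size: Cluster(
            member_bins=frozenset((0, i) for i in range(size)), sign=sign, size=size
        )
        assert max_cluster_size([mk(1, 3), mk(1, 5)]) == 5
        assert max_cluster_size([mk(1, 7), mk(-1, 9)]) == 9  # sign-pooled max


class TestPermutationTest:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(8)
        a, b = _random_groups(rng, 6, 6)
        r1 = permutation_test(a, b, B=50, seed=123)
        r2 = permutation_test(a, b, B=50, seed=123)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert r1.null_max_sizes.size == 50

    def test_label_symmetry(self):
        # swapping groups negates the t-map; cluster membership is the same
        # with flipped signs, so exact (exhaustive) p-values are unchanged
        rng = np.random.default_rng(9)
        a, b = _random_groups(rng, 4, 4)
        r_ab = permutation_test(a, b, exhaustive=True)
        r_ba = permutation_test(b, a, exhaustive=True)
        np.testing.assert_allclose(
            r_ab.observed_tmap.t_values, -r_ba.observed_tmap.t_values, atol=1e-10
        )
        sizes = lambda r: sorted((c.sign, c.size, c.p_value) for c in r.observed_clusters)
        assert sorted((-s, n, p) for s, n, p in sizes(r_ab)) == sizes(r_ba)
        assert sorted(r_ab.null_max_sizes) == sorted(r_ba.null_max_sizes)

    def test_massive_effect_hits_floor_p(self):
        # extreme-effect limit, checked exactly by enumeration: with unit
        # day-to-day noise and a +5 blob, only the two label-aligned splits
        # of the 70 reproduce the full blob, so p hits its exact floor 2/70
        rng = np.random.default_rng(10)
        base = rng.normal(size=(4, GRID.n_bins, GRID.n_bins))
        shifted = base.copy()
        shifted[:, 2:7, 2:7] += 5.0
        res = permutation_test(
            _jids_from_stack(shifted),
            _jids_from_stack(rng.normal(size=base.shape)),
            exhaustive=True,
        )
        big = max(res.observed_clusters, key=lambda c: c.size)
        assert big.size == 25
        assert big.p_value == pytest.approx(2 / 70)
        assert big.significant
        assert int(np.sum(res.null_max_sizes == 25)) == 2

    def test_exhaustive_enumerates_all_splits(self):
        rng = np.random.default_rng(11)
        a, b = _random_groups(rng, 4, 4)
        res = permutation_test(a, b, exhaustive=True)
        assert res.B == 70  # C(8, 4)
        assert res.exhaustive

    def test_monte_carlo_p_close_to_exact(self):
        rng = np.random.default_rng(12)
        base = rng.normal(size=(8, GRID.n_bins, GRID.n_bins)) * 0.1
        base[:4, 4:7, 4:7] += 0.25  # moderate effect so p is interior
        a = _jids_from_stack(base[:4])
        b = _jids_from_stack(base[4:])
        exact = permutation_test(a, b, exhaustive=True)
        mc = permutation_test(a, b, B=10_000, seed=1)
        p_exact = {c.size: c.p_value for c in exact.observed_clusters}
        for c in mc.observed_clusters:
            assert c.p_value == pytest.approx(p_exact[c.size], abs=0.02)

    def test_p_values_in_unit_interval(self):
        rng = np.random.default_rng(13)
        a, b = _random_groups(rng, 5, 5)
        res = permutation_test(a, b, B=100, seed=2)
        for c in res.observed_clusters:
            assert 0.0 < c.p_value <= 1.0
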