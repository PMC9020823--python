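"""similarity: LOF denoising, gridding, mass-fraction comparison."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gridscreen.core import ChannelError, EventTable, ValidationError
from gridscreen.similarity import (GridSimilarity, LofParams, OccupancyMap,
                                   compare, grid_sample, remove_noise_lof,
                                   similarity_matrix, similarity_multitube,
                                   similarity_pair)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_lof(X: np.ndarray, k: int) -> np.ndarray:
    """Textbook LOF from pairwise distances (reachability/lrd ratios)."""
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(D, np.inf)
    knn = np.argsort(D, axis=1)[:, :k]
    kdist = np.array([D[i, knn[i][-1]] for i in range(n)])
    reach = np.maximum(D, kdist[None, :])          # reach-dist(i <- j)
    lrd = np.array([1.0 / np.mean(reach[i, knn[i]]) for i in range(n)])
    return np.array([np.mean(lrd[knn[i]]) / lrd[i] for i in range(n)])


def dense_grid_similarity(a: OccupancyMap, b: OccupancyMap) -> float:
    """Exhaustive enumeration of all n**d hypercubes."""
    acc, occupied = 0.0, 0
    for cube in itertools.product(range(a.n), repeat=a.d):
        p, q = a.masses.get(cube, 0.0), b.masses.get(cube, 0.0)
        if p or q:
            occupied += 1
            acc += min(p, q) / max(p, q)
    return 100.0 * acc / occupied


class TestRemoveNoiseLof:
    def test_distant_point_removed(self, rng):
        X = rng.normal(0, 0.3, size=(200, 2))
        X = np.vstack([X, [[50.0, 50.0]]])
        out = remove_noise_lof(EventTable(X, ("a", "b")), k=10, threshold=1.5)
        assert not np.any(np.all(out.events == [50.0, 50.0], axis=1))
        assert out.n_events >= 190  # only genuine outliers removed

    def test_matches_brute_force_scores(self, rng):
        """Removed set = {LOF > threshold} with LOF from the textbook formula."""
        X = np.vstack([rng.normal(0, 1, size=(60, 2)),
                       rng.normal(8, 0.2, size=(10, 2)),
                       rng.uniform(-20, 20, size=(6, 2))])
        k, thr = 8, 1.4
        scores = brute_force_lof(X, k)
        expected_removed = set(np.flatnonzero(scores > thr))
        cap = int(0.10 * len(X))
        if len(expected_removed) > cap:
            order = np.argsort(scores)[::-1]
            expected_removed = set(order[:cap])
        table = EventTable(X, ("a", "b"))
        out = remove_noise_lof(table, k=k, threshold=thr)
        kept_rows = {tuple(r) for r in out.events}
        removed = {i for i in range(len(X)) if tuple(X[i]) not in kept_rows}
        assert removed == expected_removed

    def test_infinite_threshold_identity(self, small_table):
        out = remove_noise_lof(small_table, k=10, threshold=np.inf)
        assert out is small_table

    def test_ten_percent_cap(self, rng):
        X = np.vstack([rng.normal(0, 0.1, size=(50, 2)),
                       rng.uniform(-100, 100, size=(50, 2))])
        out = remove_noise_lof(EventTable(X, ("a", "b")), k=5, threshold=1.1)
        assert out.n_events >= 90  # at most 10% removed

    @pytest.mark.parametrize("k", [0, 200, 500])
    def test_bad_k_rejected(self, small_table, k):
        with pytest.raises(ValidationError):
            remove_noise_lof(small_table, k=k)

    def test_subsampled_path_deterministic(self, rng):
        X = rng.normal(size=(500, 2))
        t = EventTable(X, ("a", "b"))
        a = remove_noise_lof(t, k=10, threshold=1.3, max_events=200, seed=5)
        b = remove_noise_lof(t, k=10, threshold=1.3, max_events=200, seed=5)
        np.testing.assert_array_equal(a.events, b.events)


class TestGridSample:
    def test_1d_hand_gridding(self):
        t = EventTable(np.array([[0.0], [1.0], [2.0], [3.0]]), ("c",))
        m = grid_sample(t, n=2)
        assert m.masses == {(0,): 0.5, (1,): 0.5}

    def test_own_range_shift_invariance(self):
        a = EventTable(np.array([[0.0], [1.0], [2.0], [3.0]]), ("c",))
        b = EventTable(np.array([[10.0], [11.0], [12.0], [13.0]]), ("c",))
        assert grid_sample(a, 2).masses == grid_sample(b, 2).masses

    def test_single_event_mass_one(self):
        t = EventTable(np.array([[3.0, 7.0]]), ("a", "b"))
        m = grid_sample(t, n=4)
        assert m.masses == {(0, 0): 1.0}

    def test_max_value_in_top_bin(self, rng):
        t = EventTable(rng.uniform(0, 1, size=(100, 1)), ("c",))
        m = grid_sample(t, n=5)
        assert max(k[0] for k in m.masses) == 4

    def test_constant_channel_dropped_with_warning(self, rng):
        X = np.column_stack([rng.normal(size=50), np.full(50, 7.0)])
        with pytest.warns(UserWarning, match="constant"):
            m = grid_sample(EventTable(X, ("a", "b")), n=3)
        assert m.d == 1 and m.channel_names == ("a",)

    def test_all_constant_rejected(self):
        t = EventTable(np.full((5, 2), 3.0), ("a", "b"))
        with pytest.raises(ValidationError):
            grid_sample(t, n=3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(2, 6), st.integers(1, 3))
    def test_masses_sum_to_one(self, seed, n, d):
        rng = np.random.default_rng(seed)
        t = EventTable(rng.normal(size=(50, d)),
                       tuple(f"c{i}" for i in range(d)))
        m = grid_sample(t, n=n)
        assert sum(m.masses.values()) == pytest.approx(1.0, abs=1e-12)


def _map(masses, n, d):
    return OccupancyMap(dict(masses), n=n,
                        channel_names=tuple(f"c{i}" for i in range(d)),
                        total_events=100)


class TestCompare:
    def test_identical_maps_exactly_100(self):
        m = _map({(0,): 0.75, (1,): 0.25}, 2, 1)
        assert compare(m, m) == 100.0

    def test_1d_hand_arithmetic(self):
        p = _map({(0,): 0.75, (1,): 0.25}, 2, 1)
        q = _map({(0,): 0.25, (1,): 0.75}, 2, 1)
        expected = 100 * ((0.25 / 0.75) + (0.25 / 0.75)) / 2
        assert compare(p, q) == pytest.approx(expected, abs=1e-12)
        assert compare(q, p) == compare(p, q)

    def test_2d_exclusive_cube_rule(self):
        p = _map({(0, 0): 0.5, (1, 1): 0.5}, 2, 2)
        q = _map({(0, 0): 0.5, (0, 1): 0.5}, 2, 2)
        assert compare(p, q) == pytest.approx(100 * (1 + 0 + 0) / 3, abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare(_map({(0,): 1.0}, 2, 1), _map({(0,): 1.0}, 3, 1))

    def test_matches_dense_enumeration(self):
        """Sparse comparison equals exhaustive n**d enumeration to 1e-12."""
        rng = np.random.default_rng(99)
        for _ in range(40):
            d = rng.integers(1, 4)
            n = rng.integers(2, 5)
            a = grid_sample(EventTable(
                rng.normal(size=(80, d)), tuple(f"c{i}" for i in range(d))), n)
            b = grid_sample(EventTable(
                rng.normal(0.5, 1.2, size=(60, d)),
                tuple(f"c{i}" for i in range(d))), n)
            assert compare(a, b) == pytest.approx(
                dense_grid_similarity(a, b), abs=1e-12)


class TestSimilarityPair:
    def test_self_similarity_100(self, small_table):
        assert similarity_pair(small_table, small_table,
                               lof_params=LofParams(k=10)) == 100.0

    def test_affine_shift_invariance(self, rng):
        a = EventTable(rng.normal(size=(300, 3)), ("x", "y", "z"))
        shifted = EventTable(a.events * [2.0, 1.0, 0.5] + [100.0, -7.0, 3.0],
                             a.channel_names)
        other = EventTable(rng.normal(1, 2, size=(300, 3)), ("x", "y", "z"))
        s0 = similarity_pair(a, other, n=4, lof_params=None)
        s1 = similarity_pair(shifted, other, n=4, lof_params=None)
        assert s0 == s1

    def test_similarity_grows_with_subsample_size(self, rng):
        """Size robustness: i.i.d. subsamples of one parent converge toward
        100 as the subsample grows (monotone in expectation)."""
        parent = np.vstack([rng.normal(0, 1, size=(6000, 2)),
                            rng.normal(6, 1, size=(4000, 2))])
        full = EventTable(parent, ("a", "b"))
        means = []
        for frac in (0.25, 0.5, 0.75):
            vals = []
            for seed in range(8):
                r = np.random.default_rng(seed)
                idx = r.choice(len(parent), size=int(frac * len(parent)),
                               replace=False)
                sub = EventTable(parent[idx], ("a", "b"))
                vals.append(similarity_pair(full, sub, n=5,
                                            lof_params=LofParams(k=15)))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2] < 100

    def test_shared_channel_restriction(self, rng):
        a = EventTable(rng.normal(size=(100, 2)), ("x", "y"))
        b = EventTable(np.column_stack([a.events[:, 0], rng.normal(100)
                                        * np.ones(100)]), ("x", "w"))
        # only "x" shared; identical there
        assert similarity_pair(a, EventTable(a.events[:, [0]], ("x",)),
                               lof_params=None) == 100.0
        with pytest.raises(ChannelError):
            similarity_pair(a, EventTable(rng.normal(size=(50, 1)), ("q",)),
                            lof_params=None)


class TestMultitube:
    def test_mean_of_tube_similarities(self, rng):
        t1a = EventTable(np.arange(8.0).reshape(-1, 1), ("m",))
        t1b = EventTable(np.arange(8.0).reshape(-1, 1), ("m",))
        t2a = EventTable(np.array([[0.0], [1.0], [2.0], [3.0]]), ("m",))
        t2b = EventTable(np.array([[0.0], [0.1], [0.2], [3.0]]), ("m",))
        s1 = similarity_pair(t1a, t1b, n=2, lof_params=None)
        s2 = similarity_pair(t2a, t2b, n=2, lof_params=None)
        got = similarity_multitube({"T1": t1a, "T2": t2a},
                                   {"T1": t1b, "T2": t2b}, n=2,
                                   lof_params=None)
        assert got == pytest.approx((s1 + s2) / 2, abs=1e-12)

    def test_single_tube_equals_pair(self, small_table):
        got = similarity_multitube({"T1": small_table}, {"T1": small_table},
                                   lof_params=LofParams(k=10))
        assert got == 100.0

    def test_no_common_tube_rejected(self, small_table):
        with pytest.raises(ValidationError):
            similarity_multitube({"T1": small_table}, {"T2": small_table})


class TestSimilarityMatrixEstimator:
    def test_workers_do_not_change_result(self, tiny_screen):
        a = GridSimilarity(n=3, lof_k=10, workers=1).fit(tiny_screen)
        b = GridSimilarity(n=3, lof_k=10, workers=2).fit(tiny_screen)
        np.testing.assert_array_equal(a.similarity_.values,
                                      b.similarity_.values)

    def test_pair_count_and_axioms(self, tiny_screen):
        est = GridSimilarity(n=3, lof_k=10).fit(tiny_screen)
        m = len(est.sample_ids_)
        assert est.n_comparisons_ == m * (m - 1) // 2
        S = est.similarity_.values
        np.testing.assert_array_equal(S, S.T)
        assert np.all(np.diag(S) == 100.0)
        assert S.min() >= 0 and S.max() <= 100

    def test_identical_samples_off_diagonal_100(self, small_table):
        est = GridSimilarity(n=3, lof_k=10).fit(
            {"a": small_table, "b": small_table})
        assert est.similarity_.between("a", "b") == 100.0

    def test_sklearn_param_interface(self):
        est = GridSimilarity(n=4)
        assert est.get_params()["n"] == 4
        est.set_params(lof_k=7)
        assert est.lof_k == 7
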