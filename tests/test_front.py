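"""Front metrics (cull/percentage/hypervolume/NDC) and surrogate metrics."""

import logging

import numpy as np
import pytest

from scpareto.front import (
    batch_entropy,
    clustering_metrics,
    cull_nondominated,
    hypervolume2d,
    ndc,
    nondominated_mask,
    percentage_nondominated,
    surrogate_trade_off_table,
    unsupervised_clustering_accuracy,
)


def _brute_force_mask(pts):
    n = pts.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i != j and np.all(pts[j] <= pts[i]) and np.any(pts[j] < pts[i]):
                mask[i] = False
                break
    return mask


class TestCull:
    def test_four_point_example(self):
        pts = np.array([[1, 3], [2, 2], [3, 1], [3, 3]], dtype=float)
        got = cull_nondominated(pts)
        np.testing.assert_array_equal(got, pts[:3])
        assert percentage_nondominated(pts) == pytest.approx(0.75)

    def test_single_point_and_schematic_domination(self):
        np.testing.assert_array_equal(cull_nondominated([[2.0, 5.0]]),
                                      [[2.0, 5.0]])
        # A=(1,3) and B=(3,1) both dominate C=(3,3)
        mask = nondominated_mask([[1, 3], [3, 1], [3, 3]])
        np.testing.assert_array_equal(mask, [True, True, False])

    def test_duplicates_of_nondominated_point_retained(self):
        pts = np.array([[1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_array_equal(nondominated_mask(pts),
                                      [True, True, False])

    def test_chain_percentage(self):
        pts = np.array([[i, i] for i in range(6)], dtype=float)
        assert percentage_nondominated(pts) == pytest.approx(1 / 6)

    def test_matches_pairwise_oracle_on_random_fronts(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = rng.integers(2, 25)
            pts = np.round(rng.standard_normal((n, 2)), rng.integers(0, 3))
            np.testing.assert_array_equal(nondominated_mask(pts),
                                          _brute_force_mask(pts))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cull_nondominated([])


class TestHypervolume:
    def test_single_point_unit_square(self):
        assert hypervolume2d([[0.0, 0.0]], [1.0, 1.0]) == pytest.approx(1.0)

    def test_two_point_inclusion_exclusion(self):
        assert hypervolume2d([[0.0, 1.0], [1.0, 0.0]],
                             [2.0, 2.0]) == pytest.approx(3.0)

    def test_invalid_reference_names_point(self):
        with pytest.raises(ValueError, match="0.5"):
            hypervolume2d([[0.0, 0.0], [2.0, 0.5]], [1.0, 1.0])

    def test_monotone_under_new_nondominated_point(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1, size=(8, 2))
        ref = np.array([1.5, 1.5])
        hv = hypervolume2d(pts, ref)
        extra = np.vstack([pts, [[0.01, 0.01]]])
        assert hypervolume2d(extra, ref) >= hv

    def test_matches_monte_carlo_area(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1, size=(10, 2))
        ref = np.array([1.2, 1.3])
        hv = hypervolume2d(pts, ref)
        m = 10**6
        samples = rng.uniform([0, 0], ref, size=(m, 2))
        front = cull_nondominated(pts)
        covered = np.zeros(m, dtype=bool)
        for p in front:
            covered |= np.all(samples >= p, axis=1)
        est = covered.mean() * ref.prod()
        se = np.sqrt(est * (ref.prod() - est) / m)  # binomial-scale error
        assert abs(hv - est) < 3 * max(se, 1e-4)


class TestNdc:
    def test_basic_counts(self):
        assert ndc([[0.2, 0.3]], 0.5, [0.0, 0.0]) == 1
        assert ndc([[0.1, 0.9], [0.2, 0.8]], 0.5, [0.0, 0.0]) == 1

    def test_three_point_half_grid(self):
        pts = [[0.1, 0.9], [0.4, 0.6], [0.9, 0.1]]
        assert ndc(pts, 0.5, [0.0, 0.0]) == 2

    def test_invariant_to_dominated_points(self):
        pts = np.array([[0.1, 0.9], [0.9, 0.1]])
        with_dom = np.vstack([pts, [[0.95, 0.95]]])
        assert ndc(pts, 0.3, [0, 0]) == ndc(with_dom, 0.3, [0, 0])

    def test_monotone_in_inverse_mu_against_enumeration(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1, size=(15, 2))
        front = cull_nondominated(pts)
        prev = 0
        for mu in (0.5, 0.25, 0.125):
            cells = {(int(x // mu), int(y // mu)) for x, y in front}
            got = ndc(pts, mu, [0.0, 0.0])
            assert got == len(cells)
            assert got >= prev
            prev = got

    def test_nonpositive_mu_rejected(self):
        with pytest.raises(ValueError):
            ndc([[0.0, 0.0]], 0.0, [0.0, 0.0])


class TestBatchEntropy:
    def test_single_batch_zero_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        with caplog.at_level(logging.WARNING):
            be = batch_entropy(rng.standard_normal((100, 2)),
                               np.zeros(100, dtype=int), n_neighbors=10)
        assert be == 0.0

    def test_interleaved_batches_approach_log2(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2000, 2))
        s = rng.integers(0, 2, 2000)
        be = batch_entropy(z, s, n_neighbors=50, seed=0)
        assert be == pytest.approx(np.log(2), abs=0.03)

    def test_separated_batches_near_zero(self):
        rng = np.random.default_rng(2)
        z = np.vstack([rng.standard_normal((500, 2)) + [50, 0],
                       rng.standard_normal((500, 2)) - [50, 0]])
        s = np.repeat([0, 1], 500)
        assert batch_entropy(z, s, n_neighbors=30, seed=0) < 0.01

    def test_monotone_along_separation_ladder(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(3)
        seps = [0.0, 0.5, 1.0, 2.0, 4.0]
        bes = []
        for sep in seps:
            z = np.vstack([rng.standard_normal((400, 2)) + [sep / 2, 0],
                           rng.standard_normal((400, 2)) - [sep / 2, 0]])
            s = np.repeat([0, 1], 400)
            bes.append(batch_entropy(z, s, n_neighbors=30, seed=0))
        assert spearmanr(seps, bes).statistic <= -0.9


class TestClusteringMetrics:
    def test_perfect_clustering_all_ones(self):
        rng = np.random.default_rng(0)
        z = np.vstack([rng.standard_normal((100, 2)) + [c * 30, 0]
                       for c in range(3)])
        labels = np.repeat([0, 1, 2], 100)
        m = clustering_metrics(z, labels, seed=0)
        assert m["ARI"] == pytest.approx(1.0)
        assert m["NMI"] == pytest.approx(1.0)
        assert m["UCA"] == pytest.approx(1.0)
        assert m["ASW"] > 0.8

    def test_uca_invariant_to_relabeling(self):
        labels = np.repeat([0, 1, 2], 50)
        permuted = (labels + 1) % 3
        assert unsupervised_clustering_accuracy(labels, permuted) == 1.0

    def test_ari_null_near_zero(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((2000, 2))
        labels = rng.integers(0, 4, 2000)
        m = clustering_metrics(z, labels, seed=0)
        assert abs(m["ARI"]) <= 0.05

    def test_single_type_rejected(self):
        with pytest.raises(ValueError):
            clustering_metrics(np.zeros((10, 2)), np.zeros(10, dtype=int))


class TestSurrogateTable:
    def _table(self, order):
        rng = np.random.default_rng(0)
        zs, tags, ubars = [], [], []
        for i in order:
            rng_i = np.random.default_rng(100 + i)
            z = np.vstack([rng_i.standard_normal((60, 2)) + [i, 0],
                           rng_i.standard_normal((60, 2)) - [i, 0]])
            zs.append(z)
            tags.append(f"cand{i}")
            ubars.append(0.1 * i)
        s = np.repeat([0, 1], 60)
        ct = np.tile(np.repeat([0, 1, 2], 20), 2)
        return surrogate_trade_off_table(
            tags, zs, s, ct, ubars, seed=0,
            be_kwargs={"n_neighbors": 15, "n_pools": 5, "pool_size": 40})

    def test_columns_lower_is_better_signs(self):
        tab = self._table([0, 1, 2])
        assert {"U_bar", "NN", "neg_BE", "neg_ASW", "neg_ARI", "neg_NMI",
                "neg_UCA"} <= set(tab.columns)
        assert np.all(tab["neg_BE"] <= 0)

    def test_invariant_to_candidate_ordering(self):
        t1 = self._table([0, 1, 2]).sort_index()
        t2 = self._table([2, 0, 1]).sort_index()
        np.testing.assert_allclose(t1.to_numpy(), t2.to_numpy())

    def test_culling_reuses_front_machinery(self):
        tab = self._table([0, 1, 2])
        pts = tab[["neg_ASW", "neg_BE"]].to_numpy()
        sub = cull_nondominated(pts)
        assert 1 <= sub.shape[0] <= pts.shape[0]

    def test_nn_column_matches_estimator(self):
        from scpareto.measures import nn_mutual_information

        tab = self._table([0, 2, 4])
        rng_i = np.random.default_rng(100)
        z = np.vstack([rng_i.standard_normal((60, 2)) + [0, 0],
                       rng_i.standard_normal((60, 2)) - [0, 0]])
        s = np.repeat([0, 1], 60)
        assert tab.loc["cand0", "NN"] == pytest.approx(
            nn_mutual_information(z, s))
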