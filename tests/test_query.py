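"""Posterior-distance querying: W1, NPD, nulls, p-values, consensus."""

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import linprog

import scquery as sq
from scquery.model import PosteriorSampleSet
from scquery.query import ReferenceIndex, _pairwise_npd


def _w1_lp(u, v):
    """Optimal-transport oracle: solve the assignment LP directly."""
    n, m = len(u), len(v)
    cost = np.abs(np.subtract.outer(u, v)).ravel()
    a_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1
        a_eq.append(row.ravel())
    for j in range(m):
        row = np.zeros((n, m))
        row[:, j] = 1
        a_eq.append(row.ravel())
    b_eq = np.concatenate([np.full(n, 1 / n), np.full(m, 1 / m)])
    res = linprog(cost, A_eq=np.array(a_eq), b_eq=b_eq, method="highs")
    return res.fun


class TestWasserstein1:
    def test_identical_zero(self, rng):
        u = rng.normal(size=12)
        assert sq.wasserstein1_empirical(u, u) == 0.0

    def test_translation(self, rng):
        u = rng.normal(size=9)
        assert sq.wasserstein1_empirical(u, u + 2.5) == pytest.approx(2.5)

    def test_lp_oracle(self, rng):
        for _ in range(100):
            u = rng.normal(size=10)
            v = rng.normal(size=10)
            assert sq.wasserstein1_empirical(u, v) == \
                pytest.approx(_w1_lp(u, v), abs=1e-8)

    def test_scipy_cross_check(self, rng):
        u, v = rng.normal(size=(2, 30))
        assert sq.wasserstein1_empirical(u, v) == \
            pytest.approx(stats.wasserstein_distance(u, v))

    def test_errors(self):
        with pytest.raises(ValueError):
            sq.wasserstein1_empirical([], [1.0])
        with pytest.raises(ValueError):
            sq.wasserstein1_empirical([1.0, 2.0], [1.0])


def _cell(point, samples):
    return PosteriorSampleSet(np.asarray(point, float), np.asarray(samples, float))


class TestNpd:
    def test_identical_cells_zero(self, rng):
        s = rng.normal(size=(20, 3))
        p = _cell(np.zeros(3), s)
        q = _cell(np.zeros(3) + 1e-9, s)
        assert sq.npd(p, q) == pytest.approx(0.0, abs=1e-6)

    def test_symmetry(self, rng):
        for _ in range(10):
            p = _cell(rng.normal(size=4), rng.normal(size=(15, 4)))
            q = _cell(rng.normal(size=4), rng.normal(size=(15, 4)))
            assert sq.npd(p, q) == pytest.approx(sq.npd(q, p))

    def test_worked_2d_example(self):
        # anisotropic clouds with point estimates 2 apart along x, evaluated
        # step by step from the definition (projection, two z-normalizations,
        # two 1-D transports)
        samples_p = np.array([[0.0, 0.0], [0.5, 1.0], [-0.5, -1.0], [1.0, 2.0]])
        samples_q = np.array([[2.0, 0.5], [2.5, -0.5], [1.5, 0.0], [2.0, 1.0]])
        p = _cell([0.25, 0.5], samples_p)
        q = _cell([2.0, 0.25], samples_q)

        d = np.array([2.0 - 0.25, 0.25 - 0.5])
        d = d / np.hypot(*d)
        proj_p = samples_p @ d
        proj_q = samples_q @ d
        mp, sp_ = proj_p.mean(), proj_p.std()
        mq, sq_ = proj_q.mean(), proj_q.std()
        w_p = np.mean(np.abs(np.sort((proj_p - mp) / sp_)
                             - np.sort((proj_q - mp) / sp_)))
        w_q = np.mean(np.abs(np.sort((proj_p - mq) / sq_)
                             - np.sort((proj_q - mq) / sq_)))
        expected = 0.5 * (w_p + w_q)
        assert sq.npd(p, q) == pytest.approx(expected)

    def test_coincident_points_zero(self, rng):
        p = _cell(np.ones(3), rng.normal(size=(10, 3)))
        q = _cell(np.ones(3), rng.normal(size=(10, 3)))
        assert sq.npd(p, q) == 0.0

    def test_zero_projected_variance_error(self):
        p = _cell([0.0, 0.0], np.zeros((5, 2)))
        q = _cell([1.0, 0.0], np.ones((5, 2)))
        with pytest.raises(ValueError, match="samples"):
            sq.npd(p, q)

    def test_monotone_in_euclidean_under_isotropic_posteriors(self, rng):
        # equal-variance isotropic clouds: NPD should rank pairs exactly as
        # the distance between point estimates does
        points = rng.normal(size=(40, 5)) * 3
        samples = points[:, None, :] + rng.normal(size=(40, 400, 5))
        a = np.repeat(np.arange(20), 1)
        b = a + 20
        npds = _pairwise_npd(points, samples, a, b)
        eucl = np.linalg.norm(points[a] - points[b], axis=1)
        rho = stats.spearmanr(npds, eucl).statistic
        assert rho > 0.99


class TestKnn:
    def test_exact_match_rank_one(self, rng):
        ref = rng.normal(size=(30, 4))
        assert sq.knn_candidates(ref, ref[17], k=3)[0] == 17

    def test_brute_force_oracle(self, rng):
        ref = rng.normal(size=(100, 3))
        q = rng.normal(size=3)
        mine = sq.knn_candidates(ref, q, k=10)
        d = np.linalg.norm(ref - q, axis=1)
        oracle = sorted(range(100), key=lambda i: (d[i], i))[:10]
        np.testing.assert_array_equal(mine, oracle)

    def test_k_equals_reference_size(self, rng):
        ref = rng.normal(size=(12, 2))
        assert len(sq.knn_candidates(ref, np.zeros(2), k=12)) == 12

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            sq.knn_candidates(np.empty((0, 2)), np.zeros(2), 1)
        with pytest.raises(ValueError):
            sq.knn_candidates(rng.normal(size=(3, 2)), np.zeros(2), 5)


class TestNull:
    def _ref(self, rng, n=60):
        points = rng.normal(size=(n, 4))
        samples = points[:, None, :] + rng.normal(size=(n, 30, 4))
        return points, samples

    def test_seed_reproducibility(self, rng):
        points, samples = self._ref(rng)
        n1 = sq.build_empirical_null(points, samples, n_pairs=200, seed=5)
        n2 = sq.build_empirical_null(points, samples, n_pairs=200, seed=5)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_nonnegative_sorted(self, rng):
        points, samples = self._ref(rng)
        null = sq.build_empirical_null(points, samples, n_pairs=300, seed=1)
        assert (null.values >= 0).all()
        assert (np.diff(null.values) >= 0).all()

    def test_median_stable_across_seeds(self, rng):
        # single-cluster isotropic reference; medians from two independent
        # 10000-pair draws agree within 20%
        points, samples = self._ref(rng, n=100)
        m1 = np.median(sq.build_empirical_null(points, samples, 10000, seed=1).values)
        m2 = np.median(sq.build_empirical_null(points, samples, 10000, seed=2).values)
        assert abs(m1 - m2) / m1 < 0.2


class TestPvalue:
    def test_below_all(self):
        null = sq.NullDistribution(np.linspace(1, 2, 99))
        assert sq.hit_pvalue(0.5, null) == pytest.approx(1 / 100)

    def test_above_all(self):
        null = sq.NullDistribution(np.linspace(1, 2, 99))
        assert sq.hit_pvalue(3.0, null) == 1.0

    def test_median_near_half(self):
        null = sq.NullDistribution(np.arange(1.0, 1000.0))
        med = np.median(null.values)
        assert sq.hit_pvalue(med, null) == pytest.approx(0.5, abs=1 / 999)


class _StubModel:
    """Duck-typed stand-in (synthetic): deterministic linear embeddings with
    isotropic posterior spread, standing in for a trained encoder."""

    def __init__(self, shift=0.0, scale=1.0, noise=0.05, seed=0):
        from types import SimpleNamespace

        self.shift = shift
        self.scale = scale
        self.noise = noise
        self.seed = seed
        self.config = SimpleNamespace(seed=seed)

    def _points(self, data):
        x = data.dense() if hasattr(data, "dense") else np.asarray(data)
        return self.scale * x[:, :2] + self.shift

    def point_estimates(self, data, gene_names=None):
        return self._points(data)

    def posterior_samples(self, data, gene_names=None, n_samples=None, seed=0):
        pts = self._points(data)
        rng = np.random.default_rng(seed + self.seed)
        m = n_samples or 20
        return pts[:, None, :] + self.noise * rng.standard_normal(
            (pts.shape[0], m, 2))


def _tiny_data(rng, n, center):
    from scquery.data import GeneExpressionMatrix

    x = rng.normal(center, 0.3, size=(n, 2)) ** 2 + 1.0
    return GeneExpressionMatrix(counts=x, gene_names=["g0", "g1"],
                                cell_ids=[f"c{center}{i}" for i in range(n)])


class TestConsensus:
    def test_single_model_reduces_to_own_calls(self, rng):
        ref = _tiny_data(rng, 30, 2)
        qry = _tiny_data(rng, 5, 2)
        model = _StubModel()
        idx = ReferenceIndex([model], ref, n_pairs=500, seed=0)
        res = sq.consensus_query(idx, qry, k=10, seed=0)
        for hits in res:
            for h in hits:
                assert h.significant == (h.pvalue_per_model[0] <= 0.05)

    def test_duplicated_models_match_single(self, rng):
        ref = _tiny_data(rng, 30, 2)
        qry = _tiny_data(rng, 4, 2)
        model = _StubModel()
        single = sq.consensus_query(
            ReferenceIndex([model], ref, n_pairs=500, seed=0), qry, k=8, seed=0)
        double = sq.consensus_query(
            ReferenceIndex([model, model], ref, n_pairs=500, seed=0), qry,
            k=8, seed=0)
        for hs, hd in zip(single, double):
            assert [h.reference_index for h in hs] == \
                [h.reference_index for h in hd]
            assert [h.significant for h in hs] == [h.significant for h in hd]

    def test_three_of_four_models_not_significant(self, rng):
        # one dissenting model embeds query cells far from the reference, so
        # its p-values are large; consensus must reject every hit
        ref = _tiny_data(rng, 40, 2)
        qry = _tiny_data(rng, 6, 2)
        agree = [_StubModel(seed=s) for s in range(3)]
        idx_aligned = ReferenceIndex(agree + [agree[0]], ref, n_pairs=500, seed=0)
        res_aligned = sq.consensus_query(idx_aligned, qry, k=10, seed=0)
        any_sig = any(h.significant for hits in res_aligned for h in hits)
        assert any_sig  # sanity: aligned ensemble does find significant hits

        class FarModel(_StubModel):
            def point_estimates(self, data, gene_names=None):
                pts = super().point_estimates(data)
                # queries land far away; reference cells stay put
                if data.cell_ids[0].startswith("c2") and pts.shape[0] <= 6:
                    return pts + 50.0
                return pts

            def posterior_samples(self, data, gene_names=None, n_samples=None,
                                  seed=0):
                pts = self.point_estimates(data)
                rng2 = np.random.default_rng(seed + 42)
                m = n_samples or 20
                return pts[:, None, :] + self.noise * rng2.standard_normal(
                    (pts.shape[0], m, 2))

        idx_mixed = ReferenceIndex(agree + [FarModel(seed=9)], ref,
                                   n_pairs=500, seed=0)
        res_mixed = sq.consensus_query(idx_mixed, qry, k=10, seed=0)
        assert not any(h.significant for hits in res_mixed for h in hits)
        # reported p is the max over models
        for hits in res_mixed:
            for h in hits:
                assert h.pvalue == max(h.pvalue_per_model.values())


class TestPredictions:
    def _hits(self, flags):
        return [
            sq.QueryHit(reference_cell_id=f"r{i}", reference_index=i,
                        euclidean_distance=0.0, npd=0.0,
                        pvalue_per_model={0: 0.01}, significant=f)
            for i, f in enumerate(flags)
        ]

    def test_too_few_hits_rejected(self):
        labels = np.array(["a"] * 5, dtype=object)
        assert sq.predict_discrete(self._hits([True] + [False] * 4),
                                   labels).status == "rejected"
        assert sq.predict_discrete(self._hits([False] * 5),
                                   labels).status == "rejected"

    def test_majority_vote(self):
        labels = np.array(["a", "a", "a", "a", "b"], dtype=object)
        res = sq.predict_discrete(self._hits([True] * 5), labels)
        assert res.status == "predicted" and res.label == "a"

    def test_even_split_ambiguous(self):
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        assert sq.predict_discrete(self._hits([True] * 4),
                                   labels).status == "ambiguous"

    def test_continuous_mean_and_simplex_closure(self, rng):
        vectors = np.array([[1.0, 0.0], [0.0, 1.0]])
        res = sq.predict_continuous(self._hits([True, True]), vectors)
        np.testing.assert_allclose(res.vector, [0.5, 0.5])
        simplex = rng.dirichlet(np.ones(4), size=6)
        res2 = sq.predict_continuous(self._hits([True] * 6), simplex)
        assert res2.vector.sum() == pytest.approx(1.0)
        assert (res2.vector >= 0).all()

    def test_identical_vectors_returned(self):
        vectors = np.tile([0.25, 0.75], (3, 1))
        res = sq.predict_continuous(self._hits([True] * 3), vectors)
        np.testing.assert_allclose(res.vector, [0.25, 0.75])
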