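"""Generative model: likelihood, prior, encoding, decoding, training."""

import warnings

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln, logsumexp

import scquery as sq
from scquery.model import GenerativeModel
from scquery.nn import Tensor


class TestNbLogPmf:
    def test_all_zero_closed_form(self, rng):
        theta = rng.uniform(0.5, 5.0, size=10)
        mu = rng.uniform(0.1, 8.0, size=10)
        expected = (theta * np.log(theta / (theta + mu))).sum()
        assert sq.nb_log_pmf(np.zeros(10), mu, theta) == pytest.approx(expected)

    def test_poisson_limit(self):
        x = np.arange(6.0)
        mu = np.linspace(0.5, 4.0, 6)
        val = sq.nb_log_pmf(x, mu, np.full(6, 1e8))
        poisson = stats.poisson.logpmf(x, mu).sum()
        assert val == pytest.approx(poisson, abs=1e-4)

    def test_single_gene_gamma_formula(self):
        # direct gamma-function evaluation at x=3, mu=2, theta=1
        x, mu, theta = 3.0, 2.0, 1.0
        expected = (
            gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
            + x * np.log(mu / (theta + mu)) + theta * np.log(theta / (theta + mu))
        )
        assert sq.nb_log_pmf([x], [mu], [theta]) == pytest.approx(expected)

    def test_oracle_1000_random_triples(self, rng):
        # independent oracle: scipy's nbinom with n=theta, p=theta/(theta+mu)
        x = rng.integers(0, 500, size=1000).astype(float)
        mu = rng.uniform(0.01, 100.0, size=1000)
        theta = rng.uniform(0.05, 50.0, size=1000)
        mine = np.array([sq.nb_log_pmf([a], [b], [c])
                         for a, b, c in zip(x, mu, theta)])
        oracle = stats.nbinom.logpmf(x, theta, theta / (theta + mu))
        np.testing.assert_allclose(mine, oracle, atol=1e-8)

    def test_large_counts_no_overflow(self):
        assert np.isfinite(sq.nb_log_pmf([10**6], [10**6], [5.0]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            sq.nb_log_pmf([-1], [1.0], [1.0])
        with pytest.raises(ValueError):
            sq.nb_log_pmf([1], [1.0], [0.0])

    def test_zero_mean_point_mass(self):
        assert sq.nb_log_pmf([0.0], [0.0], [2.0]) == 0.0
        assert sq.nb_log_pmf([1.0], [0.0], [2.0]) == -np.inf


class TestMixturePrior:
    def test_single_zero_component_is_standard_normal(self, rng):
        l = rng.normal(size=4)
        expected = stats.multivariate_normal.logpdf(l, np.zeros(4), np.eye(4))
        assert sq.mixture_prior_log_density(l, np.zeros((4, 1))) == \
            pytest.approx(expected)

    def test_column_permutation_invariance(self, rng):
        H = rng.normal(size=(3, 5))
        l = rng.normal(size=3)
        perm = rng.permutation(5)
        assert sq.mixture_prior_log_density(l, H) == \
            pytest.approx(sq.mixture_prior_log_density(l, H[:, perm]))

    def test_two_component_1d_value(self):
        # average of two unit gaussians at +-1 evaluated at 0
        expected = np.log(0.5 * (stats.norm.pdf(0, -1, 1) + stats.norm.pdf(0, 1, 1)))
        assert sq.mixture_prior_log_density(np.zeros(1), np.array([[-1.0, 1.0]])) \
            == pytest.approx(expected)

    def test_matches_explicit_summation(self, rng):
        H = rng.normal(size=(6, 9))
        l = rng.normal(size=6)
        terms = [
            stats.multivariate_normal.logpdf(l, H[:, k], np.eye(6))
            for k in range(9)
        ]
        expected = logsumexp(terms) - np.log(9)
        assert sq.mixture_prior_log_density(l, H) == pytest.approx(expected, abs=1e-10)

    def test_k_zero_standard_normal(self, rng):
        l = rng.normal(size=5)
        expected = stats.multivariate_normal.logpdf(l, np.zeros(5), np.eye(5))
        assert sq.mixture_prior_log_density(l, None) == pytest.approx(expected)


class TestEncodeDecode:
    def test_point_mode_deterministic(self, trained_model, sim_single_batch):
        matrix, _ = sim_single_batch
        sub = matrix.subset_cells(np.arange(5))
        np.testing.assert_array_equal(trained_model.point_estimates(sub),
                                      trained_model.point_estimates(sub))

    def test_stochastic_seed_reproducible(self, trained_model, sim_single_batch):
        matrix, _ = sim_single_batch
        sub = matrix.subset_cells(np.arange(3))
        s1 = trained_model.posterior_samples(sub, n_samples=5, seed=1)
        s2 = trained_model.posterior_samples(sub, n_samples=5, seed=1)
        s3 = trained_model.posterior_samples(sub, n_samples=5, seed=2)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, s3)

    def test_k_zero_latent_equals_z_head(self, rng):
        cfg = sq.ModelConfig(latent_dim=4, n_components=0, hidden_dim=8, seed=0)
        model = GenerativeModel([f"g{j}" for j in range(6)], {}, cfg)
        x = rng.poisson(5.0, size=(3, 6)).astype(float) + 1
        l = model.point_estimates(x, gene_names=[f"g{j}" for j in range(6)])
        u = Tensor(np.log1p(1e4 * x / x.sum(axis=1, keepdims=True)))
        z = model.enc_z(model.enc_trunk(u)).data
        np.testing.assert_allclose(l, z)

    def test_gene_mismatch_lists_missing(self, trained_model):
        with pytest.raises(ValueError, match="lacks"):
            trained_model.point_estimates(np.ones((1, 2)), gene_names=["a", "b"])

    def test_decode_mu_sums_to_size_factor(self, trained_model, rng):
        l = rng.normal(size=(4, trained_model.config.latent_dim))
        mu, theta = trained_model.decode(l, s=np.array([10.0, 20.0, 5.0, 7.5]))
        np.testing.assert_allclose(mu.sum(axis=1), [10.0, 20.0, 5.0, 7.5])
        assert (theta > 0).all()

    def test_decode_depends_on_batch(self, sim_single_batch, rng):
        # model with a 2-category batch level
        design = sq.SimulationDesign(n_cells=80, n_genes=30, n_clusters=2,
                                     n_batches=2, seed=4)
        matrix, _ = sq.simulate_dataset(design)
        matrix.selected_genes = list(matrix.gene_names)
        cfg = sq.ModelConfig(latent_dim=3, n_components=2, hidden_dim=8,
                             epochs=2, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sq.fit(matrix, cfg)
        l = rng.normal(size=(1, 3))
        mu0, _ = model.decode(l, {"batch": ["batch0"]}, s=100.0)
        mu1, _ = model.decode(l, {"batch": ["batch1"]}, s=100.0)
        assert np.abs(mu0 - mu1).max() > 0

    def test_decode_rejects_nonpositive_size_factor(self, trained_model):
        l = np.zeros((1, trained_model.config.latent_dim))
        with pytest.raises(ValueError, match="positive"):
            trained_model.decode(l, s=0.0)


class TestTrainingLosses:
    def test_zero_lambdas_reduce_to_reconstruction(self, sim_single_batch):
        matrix, _ = sim_single_batch
        cfg = sq.ModelConfig(latent_dim=4, n_components=3, hidden_dim=8,
                             lambda_prior=0.0, lambda_batch=0.0, seed=0)
        model = GenerativeModel(list(matrix.selected_genes), {}, cfg)
        named = model.training_losses(matrix, idx=np.arange(32))
        assert named["generator_total"] == pytest.approx(
            named["reconstruction_nll"])

    def test_losses_finite_at_random_init(self, sim_single_batch):
        matrix, _ = sim_single_batch
        cfg = sq.ModelConfig(latent_dim=4, n_components=3, hidden_dim=8, seed=1)
        model = GenerativeModel(list(matrix.selected_genes), {}, cfg)
        named = model.training_losses(matrix, idx=np.arange(64))
        assert all(np.isfinite(v) for v in named.values())

    def test_uniform_discriminators_give_log2_cross_entropy(self, sim_single_batch):
        # zeroing discriminator outputs makes each true/fake binary pair cost
        # 2*log 2 and each B-way batch term cost log B
        matrix, _ = sim_single_batch
        cfg = sq.ModelConfig(latent_dim=4, n_components=3, hidden_dim=8,
                             lambda_prior=1.0, lambda_batch=0.0, seed=2)
        model = GenerativeModel(list(matrix.selected_genes), {}, cfg)
        for disc in (model.disc_z, model.disc_c):
            disc.out.W.data[:] = 0.0
            disc.out.b.data[:] = 0.0
        named = model.training_losses(matrix, idx=np.arange(16))
        assert named["discriminator_total"] == pytest.approx(4 * np.log(2))


class TestFit:
    def test_reconstruction_improves_and_reproducible(self, trained_model,
                                                      sim_single_batch,
                                                      small_config):
        matrix, _ = sim_single_batch
        log = trained_model.training_log
        assert log[-1]["reconstruction_nll"] < log[0]["reconstruction_nll"]
        # smoothed NLL non-increasing over the first 80% of epochs
        nll = np.array([row["reconstruction_nll"] for row in log])
        n80 = int(0.8 * len(nll))
        smooth = np.convolve(nll, np.ones(5) / 5, mode="valid")[:n80]
        assert np.all(np.diff(smooth) < 1.0)  # allow sampling jitter, no blow-up
        assert smooth[-1] <= smooth[0]

    def test_seed_reproducibility(self, sim_single_batch):
        matrix, _ = sim_single_batch
        cfg = sq.ModelConfig(latent_dim=4, n_components=3, hidden_dim=8,
                             epochs=3, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = sq.fit(matrix, cfg)
            m2 = sq.fit(matrix, cfg)
        for p1, p2 in zip(m1.all_params(), m2.all_params()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_too_few_cells_rejected(self):
        design = sq.SimulationDesign(n_cells=20, n_genes=30, n_clusters=1, seed=0)
        matrix, _ = sq.simulate_dataset(design)
        with pytest.raises(ValueError, match="50"):
            sq.fit(matrix, sq.ModelConfig(epochs=1))

    def test_under_training_warning(self):
        design = sq.SimulationDesign(n_cells=60, n_genes=20, n_clusters=1, seed=0)
        matrix, _ = sq.simulate_dataset(design)
        matrix.selected_genes = list(matrix.gene_names)
        cfg = sq.ModelConfig(latent_dim=2, n_components=0, hidden_dim=4,
                             epochs=1, seed=0)
        with pytest.warns(UserWarning, match="under-train"):
            sq.fit(matrix, cfg)


class TestPersistence:
    def test_round_trip_bit_identical_embeddings(self, trained_model,
                                                 sim_single_batch, tmp_path):
        matrix, _ = sim_single_batch
        sub = matrix.subset_cells(np.arange(10))
        trained_model.save(tmp_path / "m")
        loaded = GenerativeModel.load(tmp_path / "m")
        np.testing.assert_array_equal(loaded.point_estimates(sub),
                                      trained_model.point_estimates(sub))
        assert loaded.genes == trained_model.genes
        assert len(loaded.training_log) == len(trained_model.training_log)
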