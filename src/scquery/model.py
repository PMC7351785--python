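"""Adversarially regularized autoencoder for cell embedding.

The model embeds cells in a low-dimensional latent space ``l = z + Hc``
where ``z`` captures continuous variation (standard-normal prior), ``c``
is a categorical head capturing discrete cluster structure (uniform
categorical prior) and ``H`` holds learnable Gaussian-mixture component
means, so the effective prior on ``l`` is a K-component Gaussian mixture
with identity covariances.

A decoder maps ``l`` (conditioned on batch membership and the cell's
size factor) to the mean and dispersion of a negative binomial count
likelihood over the informative genes. Prior matching for ``z`` and ``c``
and batch-effect alignment of ``l`` are enforced adversarially: each SGD
iteration first updates all discriminators, then the encoder/decoder/H,
using RMSProp without momentum.

Uncertainty in a cell's embedding is represented by posterior samples:
the normalized expression vector is Poisson-perturbed before encoding,
and each perturbation yields one embedding sample. Point estimates skip
the perturbation.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.special import gammaln

from .data import GeneExpressionMatrix, normalize_input, size_factor
from .nn import Tensor, MLP, Linear, RMSProp, concat

__all__ = [
    "ModelConfig", "GenerativeModel", "PosteriorSampleSet",
    "nb_log_pmf", "mixture_prior_log_density", "fit",
]

_THETA_EPS = 1e-4
_MIN_CELLS = 50
_WARN_CELLS = 1000


# -- distributions -------------------------------------------------------------


def nb_log_pmf(x, mu, theta):
    """Sum over genes of the negative binomial log pmf.

    Parameterized by mean ``mu`` >= 0 and dispersion ``theta`` > 0;
    variance is mu + mu^2/theta. Uses log-gamma arithmetic so counts up
    to ~1e6 are handled without overflow. ``mu = 0`` is the point mass
    at zero.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = np.asarray(mu, dtype=np.float64)
    theta = np.asarray(theta, dtype=np.float64)
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(theta <= 0):
        raise ValueError("dispersion theta must be positive")
    if np.any(mu < 0):
        raise ValueError("mean mu must be nonnegative")
    x, mu, theta = np.broadcast_arrays(x, mu, theta)
    out = np.where(
        mu > 0,
        gammaln(x + theta) - gammaln(theta) - gammaln(x + 1)
        + x * (np.log(np.where(mu > 0, mu, 1.0)) - np.log(theta + mu))
        + theta * (np.log(theta) - np.log(theta + mu)),
        np.where(x == 0, 0.0, -np.inf),
    )
    return float(out.sum())


def mixture_prior_log_density(l, H):
    """Log density of the latent Gaussian-mixture prior at ``l``.

    With K components the prior is (1/K) sum_k N(l; H[:, k], I); with
    K = 0 (mixture disabled) it degenerates to a standard normal.
    """
    l = np.asarray(l, dtype=np.float64)
    d = l.shape[-1]
    H = np.zeros((d, 0)) if H is None else np.asarray(H, dtype=np.float64)
    const = -0.5 * d * np.log(2 * np.pi)
    if H.shape[1] == 0:
        return float(const - 0.5 * (l**2).sum())
    sq = ((l[:, None] - H) ** 2).sum(axis=0)
    from scipy.special import logsumexp

    return float(const + logsumexp(-0.5 * sq) - np.log(H.shape[1]))


# -- configuration -------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of the generative model.

    ``lambda_batch`` may be a single weight (applied to every batch
    level) or a mapping from level name to weight. ``n_components = 0``
    disables the categorical head, giving ``l = z``.
    """

    latent_dim: int = 10
    n_components: int = 20
    hidden_dim: int = 128
    depth: int = 1
    lambda_prior: float = 0.001
    lambda_prior_c: float | None = None
    lambda_batch: object = 0.5
    likelihood: str = "nb"
    posterior_samples: int = 50
    learning_rate: float = 1e-3
    batch_size: int = 128
    epochs: int = 500
    theta_per_cell: bool = True
    batch_adversary: str = "confusion"
    seed: int = 0

    def __post_init__(self):
        if self.latent_dim < 1 or self.n_components < 0:
            raise ValueError("latent_dim >= 1 and n_components >= 0 required")
        if self.posterior_samples < 1:
            raise ValueError("posterior_samples must be >= 1")
        if self.lambda_prior < 0:
            raise ValueError("lambda_prior must be >= 0")
        if self.likelihood != "nb":
            raise ValueError("only the negative binomial likelihood is supported")
        if self.batch_adversary not in ("confusion", "minimax"):
            raise ValueError("batch_adversary must be 'confusion' or 'minimax'")

    def lambda_for_level(self, level: str) -> float:
        if isinstance(self.lambda_batch, dict):
            return float(self.lambda_batch.get(level, 0.0))
        return float(self.lambda_batch)


@dataclass
class PosteriorSampleSet:
    """Point estimate plus M posterior samples of one cell's embedding."""

    point_estimate: np.ndarray
    samples: np.ndarray

    def __post_init__(self):
        self.point_estimate = np.asarray(self.point_estimate, dtype=np.float64)
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not (np.isfinite(self.point_estimate).all() and np.isfinite(self.samples).all()):
            raise ValueError("non-finite embedding values")


# -- the model -----------------------------------------------------------------


class GenerativeModel:
    """Encoder/decoder/discriminator parameters plus the mixture matrix H."""

    def __init__(self, genes: list, batch_categories: dict, config: ModelConfig):
        self.config = config
        self.genes = list(genes)
        # level name -> ordered list of batch categories
        self.batch_categories = {k: list(v) for k, v in batch_categories.items()}
        self.training_log: list[dict] = []
        self.extra_decoder_dims = 0  # reference/query indicator added by tuning
        rng = np.random.default_rng(config.seed)
        g = len(self.genes)
        d, k, h = config.latent_dim, config.n_components, config.hidden_dim

        self.enc_trunk = MLP(g, h, config.depth, h, rng)
        self.enc_z = Linear(h, d, rng)
        self.enc_c = Linear(h, k, rng) if k > 0 else None
        self.H = Tensor(rng.normal(0, 1, size=(d, k)), requires_grad=True) if k > 0 else None

        dec_in = d + sum(len(c) for c in self.batch_categories.values())
        self.dec_trunk = MLP(dec_in, h, config.depth, h, rng)
        self.dec_mu = Linear(h, g, rng)
        if config.theta_per_cell:
            self.dec_theta = Linear(h, g, rng)
        else:
            self.dec_theta = Tensor(np.zeros(g), requires_grad=True)

        self.disc_z = MLP(d, h, config.depth, 1, rng)
        self.disc_c = MLP(k, h, config.depth, 1, rng) if k > 0 else None
        self.disc_b = {
            level: MLP(d, h, config.depth, len(cats), rng)
            for level, cats in self.batch_categories.items()
        }
        self.disc_tune = None  # reference/query discriminator added by tuning

    # -- parameter groups -----------------------------------------------------
    def generator_params(self) -> list[Tensor]:
        ps = self.enc_trunk.params + self.enc_z.params
        if self.enc_c is not None:
            ps += self.enc_c.params + [self.H]
        ps += self.dec_trunk.params + self.dec_mu.params
        ps += (self.dec_theta.params if isinstance(self.dec_theta, Linear)
               else [self.dec_theta])
        return ps

    def discriminator_params(self) -> list[Tensor]:
        ps = list(self.disc_z.params)
        if self.disc_c is not None:
            ps += self.disc_c.params
        for m in self.disc_b.values():
            ps += m.params
        if self.disc_tune is not None:
            ps += self.disc_tune.params
        return ps

    def all_params(self) -> list[Tensor]:
        return self.generator_params() + self.discriminator_params()

    # -- encoding --------------------------------------------------------------
    def _check_genes(self, gene_names) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(gene_names)}
        missing = [g for g in self.genes if g not in lookup]
        if missing:
            raise ValueError(
                f"input lacks {len(missing)} model genes, e.g. {missing[:5]}")
        return np.array([lookup[g] for g in self.genes], dtype=int)

    def _normalized_slice(self, data, gene_names=None) -> np.ndarray:
        """Normalized expression (scale 1e4 over all genes), restricted to G*."""
        if isinstance(data, GeneExpressionMatrix):
            x, gene_names = data.dense(), data.gene_names
        else:
            x = np.atleast_2d(np.asarray(data, dtype=np.float64))
            if gene_names is None:
                raise ValueError("gene_names required for raw array input")
        cols = self._check_genes(gene_names)
        return normalize_input(x)[:, cols]

    def _forward_latent(self, u_data: np.ndarray, with_grad: bool = False):
        u = Tensor(u_data, requires_grad=with_grad)
        hid = self.enc_trunk(u)
        z = self.enc_z(hid)
        if self.enc_c is None:
            return u, z, None, z
        c = self.enc_c(hid).log_softmax().exp()
        l = z + c @ _transpose(self.H)
        return u, z, c, l

    def point_estimates(self, data, gene_names=None) -> np.ndarray:
        """Deterministic embeddings (N x D): Poisson perturbation skipped."""
        xhat = self._normalized_slice(data, gene_names)
        _, _, _, l = self._forward_latent(np.log1p(xhat), with_grad=False)
        return l.data

    def posterior_samples(self, data, gene_names=None, n_samples=None,
                          seed=0) -> np.ndarray:
        """Stochastic embeddings (N x M x D) via Poisson-perturbed encoding."""
        m = n_samples or self.config.posterior_samples
        xhat = self._normalized_slice(data, gene_names)
        rng = np.random.default_rng(seed)
        n = xhat.shape[0]
        out = np.empty((n, m, self.config.latent_dim))
        for j in range(m):
            xt = rng.poisson(xhat).astype(np.float64)
            _, _, _, l = self._forward_latent(np.log1p(xt), with_grad=False)
            out[:, j, :] = l.data
        return out

    def encode(self, data, gene_names=None, mode="point", n_samples=None, seed=0):
        """Embed cells; ``mode='point'`` returns N x D, ``'stochastic'``
        returns a list of :class:`PosteriorSampleSet` (one per cell)."""
        points = self.point_estimates(data, gene_names)
        if mode == "point":
            return points
        samples = self.posterior_samples(data, gene_names, n_samples, seed)
        return [PosteriorSampleSet(p, s) for p, s in zip(points, samples)]

    def input_gradient(self, x_tilde: np.ndarray, direction: np.ndarray) -> np.ndarray:
        """Gradient of <l, direction> w.r.t. the normalized (pre-log1p)
        expression vector over G*."""
        t = Tensor(np.atleast_2d(x_tilde), requires_grad=True)
        u = t.log1p()
        hid = self.enc_trunk(u)
        z = self.enc_z(hid)
        if self.enc_c is None:
            l = z
        else:
            c = self.enc_c(hid).log_softmax().exp()
            l = z + c @ _transpose(self.H)
        (l * Tensor(direction[None, :])).sum().backward()
        return t.grad[0]

    # -- decoding --------------------------------------------------------------
    def _decoder_input(self, l: Tensor, onehots: dict, extra: np.ndarray | None):
        parts = [l]
        for level in self.batch_categories:
            parts.append(Tensor(onehots[level]))
        if self.extra_decoder_dims:
            if extra is None:
                extra = np.zeros((l.data.shape[0], self.extra_decoder_dims))
            parts.append(Tensor(extra))
        return concat(parts, axis=-1) if len(parts) > 1 else l

    def _decode_tensors(self, l: Tensor, onehots: dict, s: np.ndarray,
                        extra=None):
        """Returns (log_mu, theta) tensors; mu = s * softmax(mean head)."""
        hid = self.dec_trunk.hidden(self._decoder_input(l, onehots, extra))
        log_sm = self.dec_mu(hid).log_softmax()
        log_mu = log_sm + Tensor(np.log(np.asarray(s, dtype=np.float64))[:, None])
        if isinstance(self.dec_theta, Linear):
            theta = self.dec_theta(hid).softplus() + _THETA_EPS
        else:
            theta = self.dec_theta.softplus() + _THETA_EPS
        return log_mu, theta

    def decode(self, l: np.ndarray, batch_assignment: dict | None = None,
               s=1.0, extra=None):
        """Negative binomial parameters (mu, theta) over G*; sum(mu) = s."""
        l = np.atleast_2d(np.asarray(l, dtype=np.float64))
        s = np.broadcast_to(np.asarray(s, dtype=np.float64), (l.shape[0],))
        if np.any(s <= 0):
            raise ValueError("size factor s must be positive")
        onehots = {}
        for level, cats in self.batch_categories.items():
            oh = np.zeros((l.shape[0], len(cats)))
            if batch_assignment and level in batch_assignment:
                vals = np.broadcast_to(
                    np.asarray(batch_assignment[level], dtype=object), (l.shape[0],))
                idx = {c: i for i, c in enumerate(cats)}
                for i, v in enumerate(vals):
                    oh[i, idx[v]] = 1.0
            else:
                oh[:, 0] = 1.0
            onehots[level] = oh
        log_mu, theta = self._decode_tensors(Tensor(l), onehots, s, extra)
        mu = np.exp(log_mu.data)
        th = np.broadcast_to(theta.data, mu.shape)
        return mu, th

    # -- training --------------------------------------------------------------
    def _nb_nll(self, x: np.ndarray, log_mu: Tensor, theta: Tensor) -> Tensor:
        xt = Tensor(x)
        log_theta_mu = (theta + log_mu.exp()).log()
        ll = (
            (xt + theta).lgamma() - theta.lgamma()
            + xt * (log_mu - log_theta_mu)
            + theta * (theta.log() - log_theta_mu)
        )
        const = gammaln(x + 1).sum(axis=-1).mean()
        return -(ll.sum(axis=-1).mean()) + const

    def _losses(self, x_raw, xhat, onehots, s, rng, stochastic=True,
                mask_fn=None, extra=None):
        """Build generator- and discriminator-side loss graphs for one
        minibatch; the same posterior samples feed both sides."""
        cfg = self.config
        xt = rng.poisson(xhat).astype(np.float64) if stochastic else xhat
        # one stochastic encoding shared by generator- and discriminator-side
        # terms within the iteration
        _, z_g, c_g, l_g = self._forward_latent(np.log1p(xt))
        z, c, l = z_g.detach(), None if c_g is None else c_g.detach(), l_g.detach()
        n = xt.shape[0]
        gen_mask = None if mask_fn is None else mask_fn(l.data, extra)
        lam_z = cfg.lambda_prior
        lam_c = cfg.lambda_prior_c if cfg.lambda_prior_c is not None else lam_z

        # discriminator side (encoder outputs detached)
        z_prior = rng.standard_normal((n, cfg.latent_dim))
        d_loss = (self.disc_z(Tensor(z_prior)) * -1.0).softplus().mean() * lam_z \
            + self.disc_z(z).softplus().mean() * lam_z
        if self.disc_c is not None:
            c_prior = np.eye(cfg.n_components)[rng.integers(0, cfg.n_components, n)]
            d_loss = d_loss \
                + (self.disc_c(Tensor(c_prior)) * -1.0).softplus().mean() * lam_c \
                + self.disc_c(c).softplus().mean() * lam_c
        d_batch_terms = {}
        for level, disc in self.disc_b.items():
            lam = cfg.lambda_for_level(level)
            ce = -(Tensor(onehots[level]) * disc(l).log_softmax()).sum(axis=-1).mean()
            d_batch_terms[level] = ce
            d_loss = d_loss + ce * lam
        if self.disc_tune is not None and extra is not None:
            mask = gen_mask if gen_mask is not None else np.ones(n, bool)
            if mask.any():
                lp = self.disc_tune(l).log_softmax()
                w = mask.astype(float) / mask.sum()
                tune_ce_d = -((Tensor(extra) * lp).sum(axis=-1) * Tensor(w)).sum()
                d_loss = d_loss + tune_ce_d * cfg.lambda_for_level("__tune__")

        # generator side
        log_mu, theta = self._decode_tensors(l_g, onehots, s, extra)
        recon = self._nb_nll(x_raw, log_mu, theta)
        g_loss = recon
        z_adv = (self.disc_z(z_g) * -1.0).softplus().mean()  # -E log Dz(z)
        g_loss = g_loss + z_adv * lam_z
        c_adv = None
        if self.disc_c is not None:
            c_adv = (self.disc_c(c_g) * -1.0).softplus().mean()
            g_loss = g_loss + c_adv * lam_c
        b_adv = {}
        for level, disc in self.disc_b.items():
            lam = cfg.lambda_for_level(level)
            lp = disc(l_g).log_softmax()
            if cfg.batch_adversary == "minimax":
                # encoder maximizes the discriminator's cross-entropy
                term = (Tensor(onehots[level]) * lp).sum(axis=-1).mean()
            else:
                # non-saturating: pull discriminator output toward uniform
                term = -lp.mean(axis=-1).mean()
            b_adv[level] = term
            g_loss = g_loss + term * lam
        if self.disc_tune is not None and extra is not None:
            mask = gen_mask if gen_mask is not None else np.ones(n, bool)
            if mask.any():
                lp = self.disc_tune(l_g).log_softmax()
                w = mask.astype(float) / mask.sum()
                if cfg.batch_adversary == "minimax":
                    term = ((Tensor(extra) * lp).sum(axis=-1) * Tensor(w)).sum()
                else:
                    term = -(lp.mean(axis=-1) * Tensor(w)).sum()
                g_loss = g_loss + term * cfg.lambda_for_level("__tune__")

        named = {
            "reconstruction_nll": float(recon.data),
            "z_prior_adversarial": float(z_adv.data),
            "generator_total": float(g_loss.data),
            "discriminator_total": float(d_loss.data),
        }
        if c_adv is not None:
            named["c_prior_adversarial"] = float(c_adv.data)
        for level, t in b_adv.items():
            named[f"batch_adversarial[{level}]"] = float(t.data)
        for level, t in d_batch_terms.items():
            named[f"discriminator_batch[{level}]"] = float(t.data)
        return g_loss, d_loss, named

    def training_losses(self, dataset: GeneExpressionMatrix, idx=None, seed=0):
        """Named loss components on a (sub)set of cells, for inspection."""
        xhat, x_raw, onehots, s = _training_arrays(dataset, self)
        if idx is None:
            idx = np.arange(dataset.n_cells)
        rng = np.random.default_rng(seed)
        _, _, named = self._losses(
            x_raw[idx], xhat[idx], {k: v[idx] for k, v in onehots.items()},
            s[idx], rng)
        return named

    # -- persistence -----------------------------------------------------------
    def _param_dict(self) -> dict:
        return {f"p{i}": p.data for i, p in enumerate(self.all_params())}

    def save(self, path):
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self._param_dict())
        cfg = asdict(self.config)
        meta = {
            "config": cfg,
            "batch_categories": {k: [str(c) for c in v]
                                 for k, v in self.batch_categories.items()},
            "extra_decoder_dims": self.extra_decoder_dims,
            "has_tune_disc": self.disc_tune is not None,
        }
        (path / "config.json").write_text(json.dumps(meta, indent=2))
        (path / "genes.txt").write_text("\n".join(self.genes) + "\n")
        if self.training_log:
            with open(path / "training_log.csv", "w", newline="") as fh:
                w = csv.DictWriter(fh, fieldnames=list(self.training_log[0]))
                w.writeheader()
                w.writerows(self.training_log)

    @classmethod
    def load(cls, path) -> "GenerativeModel":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        config = ModelConfig(**meta["config"])
        genes = [g for g in (path / "genes.txt").read_text().splitlines() if g]
        model = cls(genes, meta["batch_categories"], config)
        if meta.get("extra_decoder_dims"):
            from .tune import _expand_decoder
            _expand_decoder(model, meta["extra_decoder_dims"],
                            add_disc=meta.get("has_tune_disc", False))
        weights = np.load(path / "weights.npz")
        params = model.all_params()
        for i, p in enumerate(params):
            p.data = weights[f"p{i}"].astype(np.float64)
        log_path = path / "training_log.csv"
        if log_path.exists():
            with open(log_path) as fh:
                model.training_log = [
                    {k: float(v) for k, v in row.items()}
                    for row in csv.DictReader(fh)
                ]
        return model


def _transpose(t: Tensor) -> Tensor:
    def bw(g):
        t._accum(g.T)

    return Tensor._make(t.data.T, (t,), bw)


# -- training driver -----------------------------------------------------------


def _training_arrays(dataset: GeneExpressionMatrix, model: GenerativeModel):
    cols = model._check_genes(dataset.gene_names)
    x = dataset.dense()
    xhat = normalize_input(x)[:, cols]
    x_raw = x[:, cols]
    onehots = {level: dataset.batch_onehot(level) for level in model.batch_categories}
    # guard: dataset categories must match the model's ordered categories
    for level in model.batch_categories:
        cats = list(dataset.batch_levels_of(level))
        if cats != list(model.batch_categories[level]):
            raise ValueError(f"batch categories for level {level!r} do not match model")
    s = size_factor(x, cols)
    if np.any(s <= 0):
        raise ValueError("cells with zero counts over the selected genes")
    return xhat, x_raw, onehots, s


def fit(dataset: GeneExpressionMatrix, config: ModelConfig | None = None,
        progress: bool = False) -> GenerativeModel:
    """Train the generative model on a dataset's informative genes.

    Each SGD iteration performs two steps: all discriminators are updated
    first, then the encoder, decoder and mixture matrix. Per-epoch loss
    means are recorded in ``model.training_log``. Deterministic for a
    fixed ``config.seed``.
    """
    config = config or ModelConfig()
    if dataset.n_cells < _MIN_CELLS:
        raise ValueError(f"at least {_MIN_CELLS} cells required for training")
    if dataset.n_cells < _WARN_CELLS:
        warnings.warn(
            f"training on {dataset.n_cells} cells; models trained on fewer "
            f"than {_WARN_CELLS} cells may be under-trained", UserWarning)
    genes = list(dataset.selected_genes) or list(dataset.gene_names)
    batch_categories = {
        level: list(dataset.batch_levels_of(level)) for level in dataset.batches
    }
    model = GenerativeModel(genes, batch_categories, config)
    xhat, x_raw, onehots, s = _training_arrays(dataset, model)
    _run_sgd(model, xhat, x_raw, onehots, s, config, progress=progress)
    return model


def _run_sgd(model, xhat, x_raw, onehots, s, config, gen_params=None,
             epochs=None, mask_fn=None, extra=None, post_step_fn=None,
             progress=False, log=None):
    """Two-step adversarial SGD shared by initial training and tuning."""
    rng = np.random.default_rng(config.seed + 1)
    n = xhat.shape[0]
    epochs = epochs if epochs is not None else config.epochs
    gen_opt = RMSProp(gen_params or model.generator_params(), lr=config.learning_rate)
    disc_opt = RMSProp(model.discriminator_params(), lr=config.learning_rate)
    log = log if log is not None else model.training_log
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_named: dict[str, float] = {}
        n_iter = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if idx.size < 2:
                continue
            mb_onehots = {k: v[idx] for k, v in onehots.items()}
            mb_extra = extra[idx] if extra is not None else None
            g_loss, d_loss, named = model._losses(
                x_raw[idx], xhat[idx], mb_onehots, s[idx], rng,
                mask_fn=mask_fn, extra=mb_extra)
            if not np.isfinite(named["generator_total"]):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {named}")
            # step 1: discriminators
            disc_opt.zero_grad()
            d_loss.backward()
            disc_opt.step()
            # step 2: encoder + decoder + H (the same-sample convention
            # keeps both sides consistent within the iteration)
            gen_opt.zero_grad()
            g_loss.backward()
            gen_opt.step()
            if post_step_fn is not None:
                post_step_fn()
            for k, v in named.items():
                epoch_named[k] = epoch_named.get(k, 0.0) + v
            n_iter += 1
        row = {"epoch": float(epoch)}
        row.update({k: v / max(n_iter, 1) for k, v in epoch_named.items()})
        log.append(row)
        if progress and (epoch % 20 == 0 or epoch == epochs - 1):
            print(f"epoch {epoch:4d}  nll={row.get('reconstruction_nll', float('nan')):.2f}")
    return model
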