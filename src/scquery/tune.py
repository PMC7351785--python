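"""Online tuning: align a query set to a pretrained reference model.

The reference-vs-query difference is treated as one more batch effect: a
dedicated two-class discriminator is added on the latent embedding, and
the decoder gains a two-column one-hot reference/query indicator whose
incoming weights start at zero, so the pre-tuning forward pass is
unchanged. Fine-tuning runs the usual two-step adversarial SGD on the
combined data with two safeguards against over-alignment: the
adversarial term only applies to cells currently participating in a
mutual-nearest-neighbour pair across the two sets, recomputed within
each minibatch on the current embeddings, and a quadratic penalty
anchors all pre-existing weights to their original values (applied as
an exact proximal shrink after each optimizer step).
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import GeneExpressionMatrix, normalize_input, size_factor
from .model import GenerativeModel, _run_sgd, _training_arrays
from .nn import MLP

__all__ = ["TuneConfig", "mutual_nearest_neighbors", "online_tune"]


@dataclass
class TuneConfig:
    """Tuning hyperparameters.

    ``deviation_penalty`` is the weight of the squared anchor to the
    original parameters; larger values keep the tuned model closer to
    the pretrained one (infinite weight freezes it).
    """

    lambda_query_batch: float = 5.0
    deviation_penalty: float = 1.0
    k_mnn: int = 10
    epochs: int = 100
    seed: int = 0

    def __post_init__(self):
        if min(self.lambda_query_batch, self.deviation_penalty) < 0:
            raise ValueError("weights must be nonnegative")
        if self.k_mnn < 1:
            raise ValueError("k_mnn must be >= 1")


def mutual_nearest_neighbors(embeddings_a: np.ndarray, embeddings_b: np.ndarray,
                             k_mnn: int) -> set:
    """Pairs (i, j) where j is among i's k nearest in B and vice versa."""
    a = np.atleast_2d(np.asarray(embeddings_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(embeddings_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("empty embedding set")
    k_ab = min(k_mnn, b.shape[0])
    k_ba = min(k_mnn, a.shape[0])
    d = cdist(a, b)
    nn_ab = np.argsort(d, axis=1, kind="stable")[:, :k_ab]
    nn_ba = np.argsort(d.T, axis=1, kind="stable")[:, :k_ba]
    back = [set(row) for row in nn_ba]
    return {
        (i, j)
        for i in range(a.shape[0])
        for j in nn_ab[i]
        if i in back[j]
    }


def _expand_decoder(model: GenerativeModel, n_extra: int, add_disc: bool = True):
    """Widen the decoder's first layer by zero-initialized indicator inputs
    and (optionally) attach the reference/query discriminator."""
    first = model.dec_trunk.hidden_layers[0]
    pad = np.zeros((n_extra, first.W.data.shape[1]))
    first.W.data = np.vstack([first.W.data, pad])
    model.extra_decoder_dims += n_extra
    if add_disc:
        rng = np.random.default_rng(model.config.seed + 7)
        model.disc_tune = MLP(model.config.latent_dim, model.config.hidden_dim,
                              model.config.depth, n_extra, rng)


def online_tune(models, reference: GeneExpressionMatrix,
                query: GeneExpressionMatrix,
                config: TuneConfig | None = None) -> list:
    """Fine-tune pretrained model(s) on combined reference + query data.

    Returns tuned copies; the inputs are left untouched. Query genes must
    cover each model's gene contract. Deterministic under
    ``config.seed``.
    """
    config = config or TuneConfig()
    single = isinstance(models, GenerativeModel)
    models = [models] if single else list(models)
    tuned = [_tune_one(m, reference, query, config) for m in models]
    return tuned[0] if single else tuned


def _tune_one(model: GenerativeModel, reference, query, config: TuneConfig):
    model = copy.deepcopy(model)
    model.training_log = []
    if not isinstance(model.config.lambda_batch, dict):
        model.config.lambda_batch = {
            level: model.config.lambda_for_level(level)
            for level in model.batch_categories
        }
    model.config.lambda_batch["__tune__"] = config.lambda_query_batch
    # anchor weights before expansion so indicator rows are unpenalized
    anchors = [p.data.copy() for p in model.generator_params()]
    _expand_decoder(model, 2, add_disc=True)

    # stack reference and query into one training set; query cells fall
    # into the first category of each original batch level at decode time
    xh_r, xr_r, oh_r, s_r = _training_arrays(reference, model)
    cols = model._check_genes(query.gene_names)
    xq = query.dense()
    xh_q = normalize_input(xq)[:, cols]
    xr_q = xq[:, cols]
    s_q = size_factor(xq, cols)
    if np.any(s_q <= 0):
        raise ValueError("query cells with zero counts over the model genes")
    oh_q = {}
    for level, cats in model.batch_categories.items():
        oh = np.zeros((xq.shape[0], len(cats)))
        if level in query.batches:
            idx = {c: i for i, c in enumerate(cats)}
            known = [idx.get(v, 0) for v in query.batches[level]]
            oh[np.arange(xq.shape[0]), known] = 1.0
        else:
            oh[:, 0] = 1.0
        oh_q[level] = oh

    n_ref, n_query = xh_r.shape[0], xh_q.shape[0]
    xhat = np.vstack([xh_r, xh_q])
    x_raw = np.vstack([xr_r, xr_q])
    onehots = {k: np.vstack([oh_r[k], oh_q[k]]) for k in oh_r}
    s = np.concatenate([s_r, s_q])
    is_query = np.zeros(n_ref + n_query, bool)
    is_query[n_ref:] = True
    indicator = np.stack([(~is_query).astype(float), is_query.astype(float)],
                         axis=1)

    def apply_deviation_penalty():
        """Proximal step of the quadratic anchor to the original weights.

        Applied after each optimizer step: w <- a + (w - a)/(1 + pen),
        the exact proximal operator of pen/2 * ||w - a||^2. As the
        penalty grows the tuned weights collapse onto the originals;
        rows added by decoder expansion carry a zero-extended anchor in
        shape only and are left unpenalized.
        """
        shrink = 1.0 / (1.0 + tune_cfg.learning_rate * config.deviation_penalty)
        for p, a in zip(model.generator_params(), anchors):
            if p.data.shape == a.shape:
                p.data = a + (p.data - a) * shrink
            else:
                old = a.shape[0]
                p.data[:old] = a + (p.data[:old] - a) * shrink

    mnn_state = {"any_pairs": False}

    def mnn_mask(l_data, mb_indicator):
        """Cells participating in an MNN pair across the reference/query
        split, computed within the current minibatch's embeddings."""
        is_q = mb_indicator[:, 1] > 0.5
        mask = np.zeros(l_data.shape[0], bool)
        if not is_q.any() or is_q.all():
            return mask
        ref_idx = np.nonzero(~is_q)[0]
        qry_idx = np.nonzero(is_q)[0]
        pairs = mutual_nearest_neighbors(l_data[ref_idx], l_data[qry_idx],
                                         config.k_mnn)
        for i, j in pairs:
            mask[ref_idx[i]] = True
            mask[qry_idx[j]] = True
        if mask.any():
            mnn_state["any_pairs"] = True
        return mask

    tune_cfg = copy.copy(model.config)
    tune_cfg.seed = config.seed
    _run_sgd(model, xhat, x_raw, onehots, s, tune_cfg,
             epochs=config.epochs, mask_fn=mnn_mask, extra=indicator,
             post_step_fn=apply_deviation_penalty)
    if not mnn_state["any_pairs"]:
        warnings.warn("no mutual nearest neighbours found in any minibatch; "
                      "adversarial alignment was inactive", UserWarning)
    return model
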