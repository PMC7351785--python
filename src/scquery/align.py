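"""Closed-form analytics for adversarial batch alignment.

A batch-membership discriminator trained to convergence on the latent
embeddings recovers, at every point, the weighted relative density of
each batch; the encoder-side adversarial objective then equals a
generalized Jensen-Shannon divergence among per-batch embedding
distributions (plus the constant sum_i w_i log w_i). These closed forms
serve both as documentation of what the training loss optimizes and as
oracles against the trained discriminators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BatchMixture", "optimal_discriminator", "generalized_jsd"]


@dataclass
class BatchMixture:
    """B per-batch densities with mixing weights on the simplex.

    ``component_densities`` are callables mapping an array of points
    (n x d) to densities (n,), or — for discrete problems — 1-D pmf
    arrays over a common support.
    """

    component_densities: list
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if len(self.component_densities) != self.weights.size:
            raise ValueError("one weight per component density required")
        if np.any(self.weights < 0) or not np.isclose(self.weights.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")

    @property
    def n_batches(self) -> int:
        return self.weights.size

    def densities_at(self, points) -> np.ndarray:
        """B x n matrix of component densities evaluated at points."""
        if callable(self.component_densities[0]):
            pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
            return np.stack([np.asarray(f(pts), dtype=np.float64).reshape(-1)
                             for f in self.component_densities])
        # discrete pmfs: points are support indices
        pmfs = np.stack([np.asarray(p, dtype=np.float64)
                         for p in self.component_densities])
        idx = np.asarray(points, dtype=int).reshape(-1)
        return pmfs[:, idx]


def optimal_discriminator(mixture: BatchMixture, points) -> np.ndarray:
    """Bayes-optimal batch membership probabilities at the given point(s).

    output_i = w_i q(l | b=i) / sum_k w_k q(l | b=k); this is the unique
    maximizer of the discriminator's expected log-likelihood.
    """
    dens = mixture.densities_at(points)  # B x n
    num = mixture.weights[:, None] * dens
    total = num.sum(axis=0)
    if np.any(total <= 0):
        raise ValueError("all component densities vanish at a query point")
    out = (num / total).T
    return out[0] if out.shape[0] == 1 else out


def generalized_jsd(mixture: BatchMixture, support=None,
                    samples_per_component=None) -> float:
    """Generalized Jensen-Shannon divergence sum_i w_i KL(q_i || q_mix).

    Zero iff all components agree; bounded above by the mixing-weight
    entropy -sum_i w_i log w_i (attained on disjoint supports). For
    discrete components (pmf arrays) the KL terms are summed exactly; for
    continuous densities they are estimated by sample averages over
    ``samples_per_component`` (a list of per-component sample arrays).
    """
    w = mixture.weights
    if not callable(mixture.component_densities[0]):
        pmfs = np.stack([np.asarray(p, dtype=np.float64)
                         for p in mixture.component_densities])
        if support is not None and pmfs.shape[1] != np.asarray(support).size:
            raise ValueError("support size does not match pmf length")
        mix = (w[:, None] * pmfs).sum(axis=0)
        total = 0.0
        for wi, qi in zip(w, pmfs):
            mask = qi > 0
            total += wi * float((qi[mask] * np.log(qi[mask] / mix[mask])).sum())
        return max(total, 0.0)
    if samples_per_component is None:
        raise ValueError("continuous densities require samples_per_component")
    total = 0.0
    for i, (wi, smp) in enumerate(zip(w, samples_per_component)):
        dens = mixture.densities_at(smp)  # B x n at this component's samples
        mix = (w[:, None] * dens).sum(axis=0)
        total += wi * float(np.mean(np.log(dens[i] / mix)))
    return max(total, 0.0)
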