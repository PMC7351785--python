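"""Posterior-based cell querying.

A query cell is compared to reference cells by the normalized projection
distance (NPD): posterior embedding samples of both cells are projected
onto the line through their point estimates, z-normalized by each cell's
projected spread, and the two resulting 1-D Wasserstein-1 distances are
averaged. Significance is calibrated against an empirical null of NPDs
between random reference-cell pairs, and a hit must be significant in
every model of an ensemble to count (consensus querying). Discrete
labels are transferred by majority vote among significant hits,
continuous annotations by their unweighted mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import PosteriorSampleSet

__all__ = [
    "QueryHit", "NullDistribution", "PredictionResult", "ReferenceIndex",
    "wasserstein1_empirical", "npd", "knn_candidates",
    "build_empirical_null", "hit_pvalue", "consensus_query",
    "predict_discrete", "predict_continuous",
]


# -- distances -----------------------------------------------------------------


def wasserstein1_empirical(u, v) -> float:
    """Wasserstein-1 distance between two equal-size empirical samples.

    For equal sample counts the optimal 1-D transport pairs order
    statistics, so W1 = mean |sort(u) - sort(v)|.
    """
    u = np.asarray(u, dtype=np.float64).ravel()
    v = np.asarray(v, dtype=np.float64).ravel()
    if u.size == 0 or v.size == 0:
        raise ValueError("empty sample set")
    if u.size != v.size:
        raise ValueError("equal sample counts required")
    return float(np.mean(np.abs(np.sort(u) - np.sort(v))))


def npd(p: PosteriorSampleSet, q: PosteriorSampleSet) -> float:
    """Normalized projection distance between two cells' posteriors.

    Symmetric; zero for identical posteriors and (by convention) for
    coincident point estimates, where the projection direction is
    undefined and the cells are maximally similar.
    """
    if p.point_estimate.shape != q.point_estimate.shape:
        raise ValueError("latent dimensions differ")
    if p.samples.shape != q.samples.shape:
        raise ValueError("posterior sample counts differ")
    direction = q.point_estimate - p.point_estimate
    norm = np.linalg.norm(direction)
    if norm == 0:
        return 0.0
    direction = direction / norm
    proj_p = p.samples @ direction
    proj_q = q.samples @ direction
    return _npd_from_projections(proj_p, proj_q)


def _npd_from_projections(proj_p: np.ndarray, proj_q: np.ndarray) -> float:
    sd_p, sd_q = proj_p.std(), proj_q.std()
    if sd_p == 0 or sd_q == 0:
        raise ValueError(
            "zero projected posterior variance; increase the number of "
            "posterior samples")
    w_p = wasserstein1_empirical((proj_p - proj_p.mean()) / sd_p,
                                 (proj_q - proj_p.mean()) / sd_p)
    w_q = wasserstein1_empirical((proj_p - proj_q.mean()) / sd_q,
                                 (proj_q - proj_q.mean()) / sd_q)
    return 0.5 * (w_p + w_q)


def _pairwise_npd(points: np.ndarray, samples: np.ndarray,
                  pairs_a: np.ndarray, pairs_b: np.ndarray) -> np.ndarray:
    """Vectorized NPD for index pairs into shared (N,D) points / (N,M,D)
    samples arrays."""
    out = np.empty(pairs_a.size)
    direction = points[pairs_b] - points[pairs_a]
    norms = np.linalg.norm(direction, axis=1)
    for i, (a, b, d, nrm) in enumerate(zip(pairs_a, pairs_b, direction, norms)):
        if nrm == 0:
            out[i] = 0.0
            continue
        out[i] = _npd_from_projections(samples[a] @ (d / nrm),
                                       samples[b] @ (d / nrm))
    return out


# -- nearest neighbours --------------------------------------------------------


def knn_candidates(reference_embeddings: np.ndarray, query_point: np.ndarray,
                   k: int) -> np.ndarray:
    """Indices of the k Euclidean-nearest reference cells, ties broken by
    reference index (deterministic)."""
    ref = np.asarray(reference_embeddings, dtype=np.float64)
    if ref.size == 0:
        raise ValueError("empty reference")
    if k > ref.shape[0]:
        raise ValueError(f"k={k} exceeds reference size {ref.shape[0]}")
    d = np.linalg.norm(ref - np.asarray(query_point, dtype=np.float64), axis=1)
    order = np.lexsort((np.arange(ref.shape[0]), d))
    return order[:k]


# -- empirical null ------------------------------------------------------------


@dataclass
class NullDistribution:
    """Sorted NPDs of random reference-cell pairs; the significance null."""

    values: np.ndarray
    seed: int = 0

    def __post_init__(self):
        self.values = np.sort(np.asarray(self.values, dtype=np.float64))
        if self.values.size and self.values[0] < 0:
            raise ValueError("NPD values must be nonnegative")

    @property
    def n_pairs(self) -> int:
        return self.values.size


def build_empirical_null(points: np.ndarray, samples: np.ndarray,
                         n_pairs: int = 10000, seed: int = 0) -> NullDistribution:
    """NPDs of uniformly sampled distinct reference-cell pairs.

    ``points``/``samples`` are a reference's posterior point estimates
    (N x D) and posterior samples (N x M x D) under one model.
    """
    n = points.shape[0]
    if n < 2:
        raise ValueError("need at least 2 reference cells")
    rng = np.random.default_rng(seed)
    a = rng.integers(0, n, size=n_pairs)
    offset = rng.integers(1, n, size=n_pairs)
    b = (a + offset) % n  # uniform over ordered distinct pairs
    return NullDistribution(_pairwise_npd(points, samples, a, b), seed=seed)


def hit_pvalue(npd_value, null: NullDistribution):
    """Empirical one-sided p-value: fraction of null pairs at least as
    similar, with an add-one correction so p is never 0."""
    if null.n_pairs == 0:
        raise ValueError("empty null distribution")
    rank = np.searchsorted(null.values, np.asarray(npd_value), side="right")
    return (1.0 + rank) / (1.0 + null.n_pairs)


# -- consensus querying --------------------------------------------------------


@dataclass
class QueryHit:
    reference_cell_id: object
    reference_index: int
    euclidean_distance: float
    npd: float
    pvalue_per_model: dict = field(default_factory=dict)
    significant: bool = False

    @property
    def pvalue(self) -> float:
        return max(self.pvalue_per_model.values())


def _model_stream(model, fallback: int) -> int:
    """Per-model RNG offset: a model's own seed where it has one, so that
    duplicated copies of one model draw identical posterior samples."""
    cfg = getattr(model, "config", None)
    seed = getattr(cfg, "seed", None)
    return fallback if seed is None else int(seed)


class ReferenceIndex:
    """Per-model reference embeddings, posterior samples and nulls.

    Building this once amortizes posterior sampling and null construction
    over all queries against the same reference.
    """

    def __init__(self, models: list, reference, n_pairs: int = 10000,
                 n_samples: int | None = None, seed: int = 0):
        if not models:
            raise ValueError("at least one model required")
        self.models = list(models)
        self.reference = reference
        self.cell_ids = np.asarray(reference.cell_ids)
        self.points = []
        self.samples = []
        self.nulls = []
        for i, m in enumerate(self.models):
            off = _model_stream(m, i)
            pts = m.point_estimates(reference)
            smp = m.posterior_samples(reference, n_samples=n_samples,
                                      seed=seed + 1000 + off)
            self.points.append(pts)
            self.samples.append(smp)
            self.nulls.append(build_empirical_null(
                pts, smp, n_pairs=n_pairs, seed=seed + 2000 + off))


def consensus_query(index: ReferenceIndex, query, k: int = 50,
                    pvalue_cutoff: float = 0.05, n_samples: int | None = None,
                    seed: int = 0) -> list:
    """Query cells against a reference under a model ensemble.

    The candidate set per query cell is the union of each model's k
    Euclidean nearest reference cells. A hit is significant only if its
    empirical p-value is at or below the cutoff in every model; the
    reported p-value is the maximum over models.

    Returns one list of :class:`QueryHit` per query cell.
    """
    q_points = [m.point_estimates(query) for m in index.models]
    q_samples = [
        m.posterior_samples(query, n_samples=n_samples,
                            seed=seed + 3000 + _model_stream(m, i))
        for i, m in enumerate(index.models)
    ]
    n_query = q_points[0].shape[0]
    results = []
    for iq in range(n_query):
        candidates: set[int] = set()
        for mi in range(len(index.models)):
            candidates |= set(knn_candidates(index.points[mi], q_points[mi][iq], k))
        cand = np.array(sorted(candidates), dtype=int)
        pvals = np.empty((len(index.models), cand.size))
        npds = np.empty((len(index.models), cand.size))
        for mi, m in enumerate(index.models):
            rp, rs = index.points[mi], index.samples[mi]
            qp, qs = q_points[mi][iq], q_samples[mi][iq]
            direction = rp[cand] - qp
            norms = np.linalg.norm(direction, axis=1)
            for ci, (r, d, nrm) in enumerate(zip(cand, direction, norms)):
                npds[mi, ci] = 0.0 if nrm == 0 else _npd_from_projections(
                    qs @ (d / nrm), rs[r] @ (d / nrm))
            pvals[mi] = hit_pvalue(npds[mi], index.nulls[mi])
        eucl = np.linalg.norm(
            np.mean([index.points[mi][cand] - q_points[mi][iq]
                     for mi in range(len(index.models))], axis=0), axis=1)
        significant = np.all(pvals <= pvalue_cutoff, axis=0)
        hits = []
        for ci, r in enumerate(cand):
            hits.append(QueryHit(
                reference_cell_id=index.cell_ids[r],
                reference_index=int(r),
                euclidean_distance=float(eucl[ci]),
                npd=float(npds[:, ci].mean()),
                pvalue_per_model={mi: float(pvals[mi, ci])
                                  for mi in range(len(index.models))},
                significant=bool(significant[ci]),
            ))
        hits.sort(key=lambda h: (h.pvalue, h.reference_index))
        results.append(hits)
    return results


# -- hit-based prediction ------------------------------------------------------


@dataclass
class PredictionResult:
    status: str  # predicted | ambiguous | rejected
    label: object = None
    vector: np.ndarray | None = None
    n_hits: int = 0


def predict_discrete(hits: list, reference_labels, majority_threshold: float = 0.5,
                     min_hits: int = 2) -> PredictionResult:
    """Majority vote among significant hits.

    Fewer than ``min_hits`` significant hits rejects the cell; a winning
    label must exceed (strictly) the majority threshold, otherwise the
    cell is ambiguous.
    """
    labels = np.asarray(reference_labels, dtype=object)
    sig = [h for h in hits if h.significant]
    if len(sig) < min_hits:
        return PredictionResult("rejected", n_hits=len(sig))
    votes: dict = {}
    for h in sig:
        lab = labels[h.reference_index]
        votes[lab] = votes.get(lab, 0) + 1
    best = max(votes, key=lambda k: (votes[k], str(k)))
    if votes[best] / len(sig) > majority_threshold:
        return PredictionResult("predicted", label=best, n_hits=len(sig))
    return PredictionResult("ambiguous", n_hits=len(sig))


def predict_continuous(hits: list, reference_vectors: np.ndarray,
                       min_hits: int = 2) -> PredictionResult:
    """Unweighted mean of significant hits' annotation vectors.

    Convexity preserves the probability simplex: simplex inputs give a
    simplex output.
    """
    vectors = np.asarray(reference_vectors, dtype=np.float64)
    sig = [h for h in hits if h.significant]
    if len(sig) < min_hits:
        return PredictionResult("rejected", n_hits=len(sig))
    mean = vectors[[h.reference_index for h in sig]].mean(axis=0)
    return PredictionResult("predicted", vector=mean, n_hits=len(sig))
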