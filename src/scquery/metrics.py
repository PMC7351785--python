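"""Evaluation metrics for embeddings and query-based annotation.

Covers cell-type resolution (mean average precision over k-nearest
neighbours), batch mixing (Seurat alignment score), query-based typing
accuracy against expected-prediction matrices (mean balanced accuracy),
Jensen-Shannon divergence for fate-probability transfer, and the
rejection enrichment ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "average_precision", "map_score", "seurat_alignment_score",
    "alignment_score_from_mean", "ExpectedPredictionMatrix", "mba",
    "jsd", "enrichment_ratio",
]


def average_precision(true_label, neighbor_labels) -> float:
    """Average precision of one cell's ordered nearest-neighbour labels.

    Mean, over the ranks where the neighbour matches the cell's own
    label, of the running precision at that rank; 0 if no neighbour
    matches.
    """
    matches = np.asarray([lab == true_label for lab in neighbor_labels], dtype=float)
    if matches.sum() == 0:
        return 0.0
    ranks = np.arange(1, matches.size + 1)
    precision_at = np.cumsum(matches) / ranks
    return float((precision_at * matches).sum() / matches.sum())


def _knn_indices(emb: np.ndarray, k: int) -> np.ndarray:
    """Each cell's k nearest neighbours by Euclidean distance, self
    excluded, ties broken by index."""
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)
    idx = np.argpartition(d, kth=k - 1, axis=1)[:, :k]
    # order the k selected neighbours deterministically
    rows = np.arange(emb.shape[0])[:, None]
    sub = d[rows, idx]
    order = np.lexsort((idx, sub), axis=1)
    return idx[rows, order]


def map_score(embeddings: np.ndarray, labels, k_fraction: float = 0.01,
              k: int | None = None) -> float:
    """Mean average precision of cell labels over Euclidean k-NN.

    k defaults to 1% of the cell count (at least 1); with k = 1 this is
    nearest-neighbour accuracy.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    labels = np.asarray(labels, dtype=object)
    n = emb.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells")
    if k is None:
        k = max(1, int(round(k_fraction * n)))
    k = min(k, n - 1)
    nbrs = _knn_indices(emb, k)
    return float(np.mean([
        average_precision(labels[i], labels[nbrs[i]]) for i in range(n)
    ]))


def alignment_score_from_mean(x_bar: float, k: int, n_batches: int) -> float:
    """Alignment score from the mean same-batch neighbour count x_bar:
    1 - (x_bar - k/N) / (k - k/N), clipped to [0, 1]."""
    kn = k / n_batches
    return float(np.clip(1.0 - (x_bar - kn) / (k - kn), 0.0, 1.0))


def seurat_alignment_score(embeddings: np.ndarray, batch_labels, k: int,
                           seed: int = 0) -> float:
    """Batch-mixing score in [0, 1]; 1 = perfect mixing, 0 = separation.

    Batches are first subsampled (without replacement) to the size of the
    smallest batch; x_bar is the average number of same-batch cells among
    each cell's k nearest neighbours in the subsampled set.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    batch = np.asarray(batch_labels, dtype=object)
    cats = sorted(set(batch))
    if len(cats) < 2:
        raise ValueError("need at least 2 batches")
    rng = np.random.default_rng(seed)
    m = min(int((batch == c).sum()) for c in cats)
    keep = np.concatenate([
        rng.choice(np.nonzero(batch == c)[0], size=m, replace=False)
        for c in cats
    ])
    if m < k + 1:
        raise ValueError(
            f"subsampled batch size {m} too small for k={k}; use a smaller k")
    emb, batch = emb[keep], batch[keep]
    nbrs = _knn_indices(emb, k)
    same = np.mean([(batch[nbrs[i]] == batch[i]).sum() for i in range(emb.shape[0])])
    return alignment_score_from_mean(float(same), k, len(cats))


@dataclass
class ExpectedPredictionMatrix:
    """Binary acceptability matrix: rows = actual types, columns =
    predictions (including 'rejected'); entry 1 marks an acceptable
    prediction."""

    table: pd.DataFrame

    def __post_init__(self):
        self.table = self.table.astype(int)
        if not self.table.isin([0, 1]).all().all():
            raise ValueError("entries must be 0/1")
        if (self.table.sum(axis=1) < 1).any():
            raise ValueError("every actual type needs >= 1 acceptable prediction")

    @classmethod
    def identity(cls, types, allow_rejected_for=()) -> "ExpectedPredictionMatrix":
        cols = list(types) + ["rejected"]
        tab = pd.DataFrame(0, index=list(types), columns=cols)
        for t in types:
            tab.loc[t, t] = 1
        for t in allow_rejected_for:
            if t not in tab.index:
                tab.loc[t] = 0
            tab.loc[t, "rejected"] = 1
        return cls(tab)

    def accepts(self, actual, predicted) -> bool:
        if actual not in self.table.index:
            raise KeyError(f"unknown actual type {actual!r}")
        if predicted not in self.table.columns:
            raise KeyError(f"unknown prediction {predicted!r}")
        return bool(self.table.loc[actual, predicted])


def mba(actual_labels, predictions, matrix: ExpectedPredictionMatrix,
        positive_types, negative_types):
    """Mean balanced accuracy of query-based typing.

    Per-type accuracy is the fraction of that type's cells whose
    prediction is acceptable under the expected-prediction matrix; MBA is
    the unweighted mean over types. Positive (in-reference) and negative
    (absent) type sets are scored separately and the overall value is
    their plain average, so the typically much larger negative set cannot
    dominate.

    Returns (mba_positive, mba_negative, overall); an empty type set
    yields None for its component and the overall falls back to the
    other.
    """
    actual = np.asarray(actual_labels, dtype=object)
    pred = np.asarray(predictions, dtype=object)
    if actual.size != pred.size:
        raise ValueError("label/prediction length mismatch")

    def type_accuracy(t):
        mask = actual == t
        if not mask.any():
            raise ValueError(f"no cells with actual type {t!r}")
        return float(np.mean([matrix.accepts(t, p) for p in pred[mask]]))

    def set_mba(types):
        types = list(types)
        if not types:
            return None
        return float(np.mean([type_accuracy(t) for t in types]))

    pos = set_mba(positive_types)
    neg = set_mba(negative_types)
    if pos is None and neg is None:
        raise ValueError("no types to evaluate")
    overall = pos if neg is None else neg if pos is None else 0.5 * (pos + neg)
    return pos, neg, overall


def jsd(p, q, tol: float = 1e-8) -> float:
    """Jensen-Shannon divergence between two probability vectors.

    Natural logarithm; symmetric; 0 iff p = q; at most log 2 (attained
    on disjoint supports). 0 * log 0 is taken as 0.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError("shape mismatch")
    if np.any(p < -tol) or np.any(q < -tol):
        raise ValueError("negative probabilities")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("inputs must sum to 1")
    m = 0.5 * (p + q)

    def kl_terms(a):
        mask = a > 0
        return float((a[mask] * np.log(a[mask] / m[mask])).sum())

    return max(0.5 * (kl_terms(p) + kl_terms(q)), 0.0)


def enrichment_ratio(n_class_total: int, n_total: int, n_class_rejected: int,
                     n_rejected: int, rejection_enrichment: bool = False) -> float:
    """Ratio of a class's overall frequency to its frequency among
    rejected cells: (n_class_total/n_total) / (n_class_rejected/n_rejected).

    Note the direction: values below 1 mean the class is *over*-represented
    among rejections. ``rejection_enrichment=True`` returns the
    reciprocal (rejected-fraction over overall-fraction), the
    conventional enrichment-in-rejections reading.
    """
    for name, v in [("n_class_total", n_class_total), ("n_total", n_total),
                    ("n_class_rejected", n_class_rejected),
                    ("n_rejected", n_rejected)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    ratio = (n_class_total / n_total) / (n_class_rejected / n_rejected)
    return 1.0 / ratio if rejection_enrichment else ratio
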