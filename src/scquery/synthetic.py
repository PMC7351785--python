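"""Synthetic scRNA-seq data with planted structure.

Generates negative-binomial UMI count matrices with known cluster, batch
and marker structure, Dirichlet fate-probability vectors, and a small
fixed ontology — enough ground truth to exercise embedding, alignment,
querying, annotation transfer and interpretation end to end without any
external download.

The generative scheme mirrors the model's own assumptions: each cell's
expected expression is its library size times a softmax over per-gene
log-rates composed of a shared baseline, a cluster effect (with planted
high-fold-change marker genes), a per-batch log-normal effect and
per-cell noise; counts are NB-distributed around that mean with fixed
dispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GeneExpressionMatrix
from .ontology import OntologyGraph

__all__ = [
    "SimulationDesign", "simulate_dataset", "simulate_fate_vectors",
    "toy_ontology", "split_reference_query",
]


@dataclass
class SimulationDesign:
    """Parameters of the planted-structure count simulation.

    ``sigma_batch`` scales per-gene log-normal batch effects (0 disables
    batch structure); ``marker_fold_change`` is the multiplicative
    up-regulation of each cluster's planted marker genes.
    """

    n_cells: int = 2000
    n_genes: int = 500
    n_clusters: int = 3
    cluster_proportions: list | None = None
    n_batches: int = 2
    sigma_cluster: float = 0.6
    sigma_batch: float = 0.5
    sigma_noise: float = 0.2
    n_factors: int = 2
    sigma_factor: float = 0.3
    n_markers: int = 10
    marker_fold_change: float = 8.0
    marker_baseline_range: tuple | None = None
    twin_of: dict | None = None
    mean_library_log: float = np.log(5000.0)
    sigma_library_log: float = 0.3
    theta: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_genes < 1 or self.n_clusters < 1:
            raise ValueError("cells, genes and clusters must all be positive")
        if self.theta <= 0:
            raise ValueError("NB dispersion theta must be positive")
        if self.marker_fold_change <= 1:
            raise ValueError("marker fold change must exceed 1")
        if self.cluster_proportions is None:
            self.cluster_proportions = [1.0 / self.n_clusters] * self.n_clusters
        props = np.asarray(self.cluster_proportions, dtype=np.float64)
        if props.size != self.n_clusters or not np.isclose(props.sum(), 1.0):
            raise ValueError("cluster proportions must sum to 1")


@dataclass
class GroundTruth:
    clusters: np.ndarray
    batches: np.ndarray
    marker_genes: dict = field(default_factory=dict)
    log_rates: np.ndarray | None = None
    factors: np.ndarray | None = None
    design: SimulationDesign | None = None


def simulate_dataset(design: SimulationDesign | None = None) -> tuple:
    """Simulate a count matrix with planted clusters, batches and markers.

    Returns ``(GeneExpressionMatrix, GroundTruth)``; deterministic for a
    fixed ``design.seed``. Cluster identity is stored both in the ground
    truth and as the matrix's ``labels``; batch membership is the batch
    level ``"batch"``.
    """
    design = design or SimulationDesign()
    rng = np.random.default_rng(design.seed)
    g, n = design.n_genes, design.n_cells

    baseline = rng.normal(0.0, 1.0, size=g)
    cluster_effects = rng.normal(0.0, design.sigma_cluster,
                                 size=(design.n_clusters, g))
    if design.twin_of:
        # near-twin subtypes (e.g. a rare secretory subtype): the cluster
        # inherits its twin's expression profile and differs only by its
        # planted markers
        for child, parent in design.twin_of.items():
            cluster_effects[int(child)] = cluster_effects[int(parent)].copy()
    marker_genes: dict = {}
    if design.n_markers > 0:
        if design.marker_baseline_range is not None:
            # restrict markers to a baseline-expression quantile band
            lo, hi = np.quantile(baseline, design.marker_baseline_range)
            pool = np.nonzero((baseline >= lo) & (baseline <= hi))[0]
            order = rng.permutation(pool)
        else:
            order = rng.permutation(g)
        for c in range(design.n_clusters):
            mg = order[c * design.n_markers:(c + 1) * design.n_markers]
            marker_genes[f"cluster{c}"] = mg
            cluster_effects[c, mg] += np.log(design.marker_fold_change)
    batch_effects = rng.normal(0.0, design.sigma_batch,
                               size=(design.n_batches, g))

    clusters = rng.choice(design.n_clusters, size=n,
                          p=np.asarray(design.cluster_proportions))
    batches = rng.integers(0, design.n_batches, size=n)
    log_rates = (
        baseline
        + cluster_effects[clusters]
        + batch_effects[batches]
        + rng.normal(0.0, design.sigma_noise, size=(n, g))
    )
    factors = None
    if design.n_factors > 0 and design.sigma_factor > 0:
        # low-rank continuous within-cluster variation (cell states along a
        # few shared axes), the structure real tissues show; without it the
        # within-cluster signal is isotropic noise no embedding can agree on
        loadings = rng.normal(0.0, design.sigma_factor,
                              size=(design.n_factors, g))
        factors = rng.normal(0.0, 1.0, size=(n, design.n_factors))
        log_rates = log_rates + factors @ loadings
    probs = np.exp(log_rates - log_rates.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    library = rng.lognormal(design.mean_library_log, design.sigma_library_log,
                            size=n)
    mu = library[:, None] * probs
    counts = rng.poisson(rng.gamma(design.theta, mu / design.theta))

    gene_names = np.array([f"gene{j:04d}" for j in range(g)], dtype=object)
    cell_ids = np.array([f"cell{i:05d}" for i in range(n)], dtype=object)
    cluster_labels = np.array([f"cluster{c}" for c in clusters], dtype=object)
    batch_labels = np.array([f"batch{b}" for b in batches], dtype=object)
    matrix = GeneExpressionMatrix(
        counts=counts.astype(np.float64),
        gene_names=gene_names,
        cell_ids=cell_ids,
        batches={"batch": batch_labels},
        labels=cluster_labels,
    )
    truth = GroundTruth(
        clusters=cluster_labels,
        batches=batch_labels,
        marker_genes={c: gene_names[idx] for c, idx in marker_genes.items()},
        log_rates=log_rates,
        factors=factors,
        design=design,
    )
    return matrix, truth


def split_reference_query(matrix: GeneExpressionMatrix, withheld_label,
                          query_fraction: float = 0.25, seed: int = 0) -> tuple:
    """Hold out one cluster entirely for the query side.

    The reference is a random (1 - query_fraction) subset of the cells
    whose label differs from ``withheld_label``; the query combines the
    remaining seen-label cells with every withheld-label cell, emulating
    a novel cell type absent from the reference.
    """
    labels = np.asarray(matrix.labels, dtype=object)
    rng = np.random.default_rng(seed)
    seen = np.nonzero(labels != withheld_label)[0]
    rng.shuffle(seen)
    n_query = int(round(query_fraction * seen.size))
    query_idx = np.concatenate([seen[:n_query],
                                np.nonzero(labels == withheld_label)[0]])
    ref_idx = np.sort(seen[n_query:])
    query_idx = np.sort(query_idx)
    return matrix.subset_cells(ref_idx), matrix.subset_cells(query_idx)


def simulate_fate_vectors(n_cells: int, n_lineages: int,
                          concentration: float = 0.5,
                          committed_fraction: float = 0.5,
                          seed: int = 0) -> np.ndarray:
    """Dirichlet lineage-probability vectors on the simplex.

    A ``committed_fraction`` of cells is drawn at one fifth of the
    concentration (near one-hot, low entropy); the rest at five times
    the concentration (diffuse, high entropy), so both committed and
    undifferentiated states are represented.
    """
    if n_lineages < 2:
        raise ValueError("need at least 2 lineages")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    n_committed = int(round(committed_fraction * n_cells))
    parts = []
    if n_committed:
        parts.append(rng.dirichlet([concentration / 5.0] * n_lineages,
                                   size=n_committed))
    if n_cells - n_committed:
        parts.append(rng.dirichlet([concentration * 5.0] * n_lineages,
                                   size=n_cells - n_committed))
    out = np.vstack(parts)
    rng.shuffle(out, axis=0)
    return out


def toy_ontology() -> OntologyGraph:
    """Fixed 15-term DAG with a diamond and four depth levels.

    ``secretory-epithelial`` has two parents (``epithelial`` and
    ``secretory``) that share the ancestor ``animal-cell``, forming a
    diamond; the deepest terms sit three edges below the root.
    """
    edges = [
        ("animal-cell", "cell"),
        ("epithelial", "animal-cell"),
        ("secretory", "animal-cell"),
        ("immune", "animal-cell"),
        ("stromal", "animal-cell"),
        # diamond: two paths from secretory-epithelial to animal-cell
        ("secretory-epithelial", "epithelial"),
        ("secretory-epithelial", "secretory"),
        ("ionocyte", "secretory-epithelial"),
        ("basal", "epithelial"),
        ("ciliated", "epithelial"),
        ("t-cell", "immune"),
        ("b-cell", "immune"),
        ("cytotoxic-t", "t-cell"),
        ("helper-t", "t-cell"),
        ("fibroblast", "stromal"),
    ]
    return OntologyGraph(edges)
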