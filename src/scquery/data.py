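"""Data model and preprocessing for cell-querying workflows.

The central container is :class:`GeneExpressionMatrix`: raw UMI counts for
cells x genes together with gene/cell names, one or more levels of batch
membership (e.g. donor, dataset), an ordered subset of informative genes,
and optional per-cell annotations (discrete labels, ontology term IDs,
continuous fate vectors).

Also provided: library-size normalization to a fixed scale of 1e4,
size-factor computation over the selected genes, dispersion-based
informative-gene selection with per-batch pooling, and multi-dataset
merging with optional gene-name/ortholog mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GeneExpressionMatrix",
    "GeneSelectionParams",
    "normalize_input",
    "size_factor",
    "select_variable_genes",
    "pool_genes_across_batches",
    "select_genes_by_batch",
    "merge_datasets",
    "read_mtx",
    "read_csv",
    "read_h5ad",
]

NORM_SCALE = 1e4


class DegenerateInputError(ValueError):
    """Raised for inputs the method cannot meaningfully process."""


def _as_2d(counts):
    if sp.issparse(counts):
        return counts.tocsr()
    return np.asarray(counts, dtype=np.float64)


@dataclass
class GeneExpressionMatrix:
    """Raw counts (cells x genes) with names, batch design and annotations.

    Parameters
    ----------
    counts
        Nonnegative matrix, cells as rows, genes as columns. Dense or
        scipy sparse; sparse input is kept sparse.
    gene_names, cell_ids
        Unique string identifiers for columns / rows.
    batches
        Mapping from batch-level name (e.g. ``"donor"``, ``"dataset"``) to a
        per-cell categorical assignment.
    selected_genes
        Ordered subset of ``gene_names`` used as model input (informative
        genes).
    labels, ontology_terms
        Optional per-cell discrete annotations.
    fate_vectors
        Optional per-cell continuous annotation on the probability simplex.
    """

    counts: object
    gene_names: np.ndarray
    cell_ids: np.ndarray
    batches: dict = field(default_factory=dict)
    selected_genes: list = field(default_factory=list)
    labels: np.ndarray | None = None
    ontology_terms: np.ndarray | None = None
    fate_vectors: np.ndarray | None = None

    def __post_init__(self):
        self.counts = _as_2d(self.counts)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n, g = self.counts.shape
        if len(self.gene_names) != g:
            raise ValueError(f"{len(self.gene_names)} gene names for {g} columns")
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {n} rows")
        if len(set(self.gene_names)) != g:
            raise ValueError("duplicate gene names")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids")
        mn = self.counts.min() if not sp.issparse(self.counts) else self.counts.data.min(initial=0.0)
        if mn < 0:
            raise ValueError("counts must be nonnegative")
        self.batches = {k: np.asarray(v, dtype=object) for k, v in self.batches.items()}
        for level, assign in self.batches.items():
            if len(assign) != n:
                raise ValueError(f"batch level {level!r} has {len(assign)} entries for {n} cells")
        missing = set(self.selected_genes) - set(self.gene_names)
        if missing:
            raise ValueError(f"selected genes not in gene_names: {sorted(missing)[:5]}")

    # -- basic views ----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return self.counts.toarray() if sp.issparse(self.counts) else self.counts

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_names)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def subset_cells(self, mask) -> "GeneExpressionMatrix":
        mask = np.asarray(mask)
        return GeneExpressionMatrix(
            counts=self.counts[mask],
            gene_names=self.gene_names,
            cell_ids=self.cell_ids[mask],
            batches={k: v[mask] for k, v in self.batches.items()},
            selected_genes=list(self.selected_genes),
            labels=None if self.labels is None else np.asarray(self.labels)[mask],
            ontology_terms=None if self.ontology_terms is None
            else np.asarray(self.ontology_terms)[mask],
            fate_vectors=None if self.fate_vectors is None else self.fate_vectors[mask],
        )

    # -- batch design ---------------------------------------------------------
    def batch_levels_of(self, level: str) -> np.ndarray:
        """Sorted distinct categories of one batch level."""
        return np.array(sorted(set(self.batches[level])), dtype=object)

    def batch_onehot(self, level: str) -> np.ndarray:
        """Cells x B one-hot matrix for one batch level (exactly one 1 per row)."""
        cats = self.batch_levels_of(level)
        idx = {c: i for i, c in enumerate(cats)}
        onehot = np.zeros((self.n_cells, len(cats)))
        for i, c in enumerate(self.batches[level]):
            onehot[i, idx[c]] = 1.0
        return onehot

    def batch_weights(self, level: str) -> np.ndarray:
        """Relative proportion of cells per batch; sums to 1."""
        onehot = self.batch_onehot(level)
        return onehot.sum(axis=0) / self.n_cells

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame(index=pd.Index(self.cell_ids.astype(str), name="cell_id"))
        for level, assign in self.batches.items():
            obs[level] = assign.astype(str)
        if self.labels is not None:
            obs["label"] = np.asarray(self.labels).astype(str)
        if self.ontology_terms is not None:
            obs["ontology_term"] = np.asarray(self.ontology_terms).astype(str)
        var = pd.DataFrame(index=pd.Index(self.gene_names.astype(str), name="gene"))
        var["selected"] = np.isin(self.gene_names, list(self.selected_genes))
        adata = anndata.AnnData(X=self.counts, obs=obs, var=var)
        if self.fate_vectors is not None:
            adata.obsm["fate"] = np.asarray(self.fate_vectors)
        return adata

    @classmethod
    def from_anndata(cls, adata, batch_keys=(), label_key=None,
                     ontology_key=None, fate_key=None) -> "GeneExpressionMatrix":
        batches = {k: adata.obs[k].to_numpy() for k in batch_keys}
        selected = (list(adata.var.index[adata.var["selected"]])
                    if "selected" in adata.var else [])
        return cls(
            counts=adata.X.copy(),
            gene_names=adata.var_names.to_numpy(),
            cell_ids=adata.obs_names.to_numpy(),
            batches=batches,
            selected_genes=selected,
            labels=adata.obs[label_key].to_numpy() if label_key else None,
            ontology_terms=adata.obs[ontology_key].to_numpy() if ontology_key else None,
            fate_vectors=adata.obsm[fate_key] if fate_key else None,
        )


# -- normalization ------------------------------------------------------------


def normalize_input(x: np.ndarray) -> np.ndarray:
    """Scale count vector(s) to a total of 1e4 over *all* genes.

    The denominator deliberately uses every detected gene, not only the
    informative subset, so that restriction of the normalized vector to a
    gene subset remains comparable across datasets.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        total = x.sum()
        if total <= 0:
            raise DegenerateInputError("all-zero expression vector cannot be normalized")
        return NORM_SCALE * x / total
    totals = x.sum(axis=1)
    zero = np.nonzero(totals <= 0)[0]
    if zero.size:
        raise DegenerateInputError(f"all-zero expression for cell row(s) {zero[:5].tolist()}")
    return NORM_SCALE * x / totals[:, None]


def size_factor(x: np.ndarray, selected_idx: np.ndarray) -> np.ndarray | float:
    """Sum of raw counts over the selected genes (per cell)."""
    selected_idx = np.asarray(selected_idx)
    if selected_idx.size == 0:
        raise ValueError("selected gene set is empty")
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 1:
        return float(x[selected_idx].sum())
    return x[:, selected_idx].sum(axis=1)


# -- gene selection -----------------------------------------------------------


@dataclass
class GeneSelectionParams:
    """Mean-dispersion binning parameters for informative-gene selection."""

    binning_method: str = "equal_frequency"
    n_bins: int = 20
    dispersion_z_cutoff: float = 0.5
    min_batch_fraction: float = 0.5

    def __post_init__(self):
        if self.binning_method not in ("equal_width", "equal_frequency"):
            raise ValueError(f"unknown binning method {self.binning_method!r}")
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not 0.0 <= self.min_batch_fraction <= 1.0:
            raise ValueError("min_batch_fraction must lie in [0, 1]")


def _bin_assignments(means: np.ndarray, params: GeneSelectionParams) -> np.ndarray:
    n_bins = min(params.n_bins, max(1, means.size))
    if params.binning_method == "equal_width":
        edges = np.linspace(means.min(), means.max(), n_bins + 1)
        bins = np.clip(np.digitize(means, edges[1:-1]), 0, n_bins - 1)
    else:
        order = np.argsort(means, kind="stable")
        bins = np.empty(means.size, dtype=int)
        bins[order] = np.minimum(
            (np.arange(means.size) * n_bins) // means.size, n_bins - 1
        )
    # merge bins with < 2 genes into the adjacent lower-mean bin so that
    # within-bin z-scores are defined
    while True:
        present = np.unique(bins)
        sizes = {b: int((bins == b).sum()) for b in present}
        small = [b for b in present if sizes[b] < 2]
        if not small or len(present) == 1:
            break
        b = small[0]
        lower = present[present < b]
        target = lower[-1] if lower.size else present[present > b][0]
        bins[bins == b] = target
    return bins


def select_variable_genes(matrix: GeneExpressionMatrix,
                          params: GeneSelectionParams | None = None) -> list:
    """Informative genes by binned dispersion z-scores.

    Dispersion (variance/mean) is computed on log1p of library-size
    normalized expression. Genes are grouped into bins of similar mean
    expression; within each bin dispersions are z-scored and genes with
    z-score above the cutoff are returned, ordered by gene position.
    """
    params = params or GeneSelectionParams()
    if matrix.n_cells < 2:
        raise ValueError("gene selection requires at least 2 cells")
    x = matrix.dense()
    expressed = x.sum(axis=0) > 0
    keep_cells = x.sum(axis=1) > 0
    x = normalize_input(x[keep_cells])
    logx = np.log1p(x)
    means = logx.mean(axis=0)
    variances = logx.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(means > 0, variances / means, 0.0)
    candidate = expressed & (means > 0)
    idx = np.nonzero(candidate)[0]
    if idx.size == 0:
        return []
    bins = _bin_assignments(means[idx], params)
    z = np.zeros(idx.size)
    for b in np.unique(bins):
        members = bins == b
        d = dispersion[idx][members]
        sd = d.std(ddof=1) if members.sum() > 1 else 0.0
        z[members] = 0.0 if sd == 0 else (d - d.mean()) / sd
    chosen = idx[z > params.dispersion_z_cutoff]
    return [matrix.gene_names[i] for i in sorted(chosen)]


def pool_genes_across_batches(per_batch_selections: list,
                              min_batch_fraction: float = 0.5) -> set:
    """Retain genes selected in at least the given fraction of batches."""
    if not per_batch_selections:
        raise ValueError("no per-batch selections provided")
    n = len(per_batch_selections)
    votes: dict = {}
    for sel in per_batch_selections:
        for g in set(sel):
            votes[g] = votes.get(g, 0) + 1
    return {g for g, v in votes.items() if v / n >= min_batch_fraction}


def select_genes_by_batch(matrix: GeneExpressionMatrix, level: str | None = None,
                          params: GeneSelectionParams | None = None) -> list:
    """Select genes independently per batch, then pool.

    With no batch level (or a single batch) this reduces to
    :func:`select_variable_genes` on the whole matrix.
    """
    params = params or GeneSelectionParams()
    if level is None or level not in matrix.batches:
        return select_variable_genes(matrix, params)
    cats = matrix.batch_levels_of(level)
    if len(cats) == 1:
        return select_variable_genes(matrix, params)
    selections = []
    for c in cats:
        sub = matrix.subset_cells(matrix.batches[level] == c)
        selections.append(select_variable_genes(sub, params))
    pooled = pool_genes_across_batches(selections, params.min_batch_fraction)
    return [g for g in matrix.gene_names if g in pooled]


# -- dataset merging ----------------------------------------------------------


def _apply_gene_map(matrix: GeneExpressionMatrix, gene_map: dict) -> GeneExpressionMatrix:
    """Collapse gene columns into mapped group IDs (summing collapsed columns)."""
    groups: dict = {}
    for j, g in enumerate(matrix.gene_names):
        groups.setdefault(gene_map.get(g, g), []).append(j)
    names = sorted(groups)
    x = matrix.dense()
    out = np.zeros((matrix.n_cells, len(names)))
    for k, name in enumerate(names):
        out[:, k] = x[:, groups[name]].sum(axis=1)
    selected = sorted({gene_map.get(g, g) for g in matrix.selected_genes})
    return GeneExpressionMatrix(
        counts=out, gene_names=np.array(names, dtype=object),
        cell_ids=matrix.cell_ids, batches=matrix.batches,
        selected_genes=selected, labels=matrix.labels,
        ontology_terms=matrix.ontology_terms, fate_vectors=matrix.fate_vectors,
    )


def merge_datasets(datasets: list, gene_map: dict | None = None,
                   dataset_names: list | None = None,
                   level_name: str = "dataset") -> GeneExpressionMatrix:
    """Merge datasets on shared genes; record origin as a batch level.

    The merged informative set is the union of per-dataset informative
    genes intersected with the genes detected in every dataset.
    """
    if len(datasets) < 2:
        raise ValueError("merging requires at least 2 datasets")
    if gene_map:
        datasets = [_apply_gene_map(d, gene_map) for d in datasets]
    if dataset_names is None:
        dataset_names = [f"dataset{i}" for i in range(len(datasets))]
    detected = set(datasets[0].gene_names)
    for d in datasets[1:]:
        detected &= set(d.gene_names)
    if not detected:
        raise ValueError(
            "no genes shared by all datasets "
            f"(sizes: {[d.n_genes for d in datasets]})"
        )
    shared = sorted(detected)
    informative_union = set()
    for d in datasets:
        informative_union |= set(d.selected_genes)
    merged_selected = [g for g in shared if g in informative_union]

    blocks, ids, origin = [], [], []
    batch_levels = set()
    for d in datasets:
        batch_levels |= set(d.batches)
    merged_batches: dict = {lv: [] for lv in batch_levels}
    labels, have_labels = [], all(d.labels is not None for d in datasets)
    for name, d in zip(dataset_names, datasets):
        cols = d.gene_index(shared)
        blocks.append(d.dense()[:, cols])
        ids.extend(f"{name}:{c}" for c in d.cell_ids)
        origin.extend([name] * d.n_cells)
        for lv in batch_levels:
            vals = d.batches.get(lv)
            merged_batches[lv].extend(
                [f"{name}:{v}" for v in vals] if vals is not None
                else [f"{name}:na"] * d.n_cells)
        if have_labels:
            labels.extend(np.asarray(d.labels))
    merged_batches[level_name] = origin
    return GeneExpressionMatrix(
        counts=np.vstack(blocks),
        gene_names=np.array(shared, dtype=object),
        cell_ids=np.array(ids, dtype=object),
        batches=merged_batches,
        selected_genes=merged_selected,
        labels=np.array(labels, dtype=object) if have_labels else None,
    )


# -- readers ------------------------------------------------------------------


def read_mtx(mtx_path, genes_path, barcodes_path, cells_as_rows=False,
             **kwargs) -> GeneExpressionMatrix:
    """MatrixMarket counts plus one-name-per-line gene/barcode files.

    MTX conventionally stores genes as rows; set ``cells_as_rows=True`` if
    the matrix is already cells x genes.
    """
    from scipy.io import mmread

    m = mmread(str(mtx_path)).tocsr()
    genes = [ln.split("\t")[0].strip() for ln in open(genes_path) if ln.strip()]
    cells = [ln.strip() for ln in open(barcodes_path) if ln.strip()]
    if not cells_as_rows:
        m = m.T.tocsr()
    return GeneExpressionMatrix(counts=m, gene_names=genes, cell_ids=cells, **kwargs)


def read_csv(path, sep=",", **kwargs) -> GeneExpressionMatrix:
    """Dense table, header row = gene names, first column = cell IDs."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GeneExpressionMatrix(
        counts=df.to_numpy(dtype=np.float64),
        gene_names=df.columns.to_numpy(),
        cell_ids=df.index.astype(str).to_numpy(),
        **kwargs,
    )


def read_h5ad(path, **kwargs) -> GeneExpressionMatrix:
    """HDF5 container following the AnnData on-disk layout."""
    import anndata

    return GeneExpressionMatrix.from_anndata(anndata.read_h5ad(path), **kwargs)


def read_gene_map(path) -> dict:
    """Two-column TSV (source_name, group_id), no header."""
    out = {}
    for ln in open(path):
        ln = ln.strip()
        if not ln:
            continue
        src, grp = ln.split("\t")[:2]
        out[src] = grp
    return out
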