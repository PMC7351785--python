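"""Ontology-aware cell-type inference from query hits.

Given hits annotated with Cell Ontology terms, each term receives a
confidence score equal to the summed similarity (1 - p-value) of the
hits carrying it, normalized over all hits. Scores are propagated
upwards along is_a edges (each annotated term counted once per ancestor,
regardless of path multiplicity). The prediction is the deepest
confident term: among induced-subgraph leaves of the terms whose
propagated confidence exceeds a threshold, the unique maximal-confidence
term of sufficient depth; ties give "ambiguous", no candidate gives
"rejected".

Also implements the ontology-aware accuracy (partial credit via
descendant-set-size ratios when an ancestor of the true term is
predicted) and its term-balanced mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "OntologyGraph", "ConfidenceMap", "load_ontology",
    "blast2co_base_scores", "propagate_scores", "blast2co_predict",
    "blast2co", "cl_accuracy", "cl_mba",
    "AMBIGUOUS", "REJECTED",
]

AMBIGUOUS = "ambiguous"
REJECTED = "rejected"
_TIE_TOL = 1e-12


class OntologyGraph:
    """DAG of ontology terms connected by child -> parent is_a edges."""

    def __init__(self, edges: list, names: dict | None = None):
        g = nx.DiGraph()
        names = names or {}
        for child, parent in edges:
            g.add_edge(child, parent)
        for term in names:
            g.add_node(term)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through edge {cycle[0]}")
        self.graph = g
        self.names = {t: names.get(t, t) for t in g.nodes}
        # inclusive descendant sets (a term is its own descendant) and
        # depth = longest is_a path to a root
        self._descendants = {
            t: frozenset(nx.ancestors(g, t)) | {t} for t in g.nodes
        }
        self._depth = {}
        for t in nx.topological_sort(g.reverse(copy=True)):
            parents = list(g.successors(t))
            self._depth[t] = 0 if not parents else 1 + max(
                self._depth[p] for p in parents)

    @property
    def terms(self) -> list:
        return sorted(self.graph.nodes)

    def __contains__(self, term) -> bool:
        return term in self.graph

    def parents(self, term) -> list:
        return sorted(self.graph.successors(term))

    def children(self, term) -> list:
        return sorted(self.graph.predecessors(term))

    def descendants(self, term) -> frozenset:
        """Inclusive descendant set (the term itself included)."""
        return self._descendants[term]

    def ancestors(self, term) -> frozenset:
        """Inclusive ancestor set."""
        return frozenset(nx.descendants(self.graph, term)) | {term}

    def is_a(self, child, parent) -> bool:
        """child <= parent: equal or reachable via is_a edges."""
        return child in self._descendants[parent]

    def depth(self, term) -> int:
        """Number of edges on the longest is_a path from the term to a root."""
        return self._depth[term]

    def roots(self) -> list:
        return sorted(t for t in self.graph.nodes
                      if self.graph.out_degree(t) == 0)


def load_ontology(obo_path) -> OntologyGraph:
    """Read an OBO 1.2 file, keeping [Term] stanzas and is_a edges only;
    obsolete terms are dropped."""
    import obonet

    g = obonet.read_obo(str(obo_path), ignore_obsolete=True)
    edges = []
    names = {}
    for term, attrs in g.nodes(data=True):
        names[term] = attrs.get("name", term)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            edges.append((child, parent))
    return OntologyGraph(edges, names)


@dataclass
class ConfidenceMap:
    """Term -> confidence in [0, 1]."""

    scores: dict = field(default_factory=dict)

    def __getitem__(self, term) -> float:
        return self.scores.get(term, 0.0)

    def items(self):
        return self.scores.items()


def blast2co_base_scores(hits: list, graph: OntologyGraph) -> ConfidenceMap | str:
    """Similarity-weighted term confidences from (pvalue, term) hits.

    score(term) = sum of (1 - p) over hits with that term, normalized by
    the sum over all hits. Returns the 'rejected' sentinel if the total
    similarity is zero (all p-values equal to 1).
    """
    if not hits:
        raise ValueError("no hits")
    totals: dict = {}
    for p, term in hits:
        if term not in graph:
            raise KeyError(f"term {term!r} not in ontology")
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
        totals[term] = totals.get(term, 0.0) + (1.0 - p)
    grand = sum(totals.values())
    if grand <= 0:
        return REJECTED
    return ConfidenceMap({t: v / grand for t, v in totals.items()})


def propagate_scores(scores: ConfidenceMap, graph: OntologyGraph) -> ConfidenceMap:
    """Propagate base confidences to ancestors along is_a edges.

    propagated(c) = sum of base scores of annotated terms that are
    (inclusive) descendants of c; diamond paths are counted once because
    the sum runs over terms, not paths.
    """
    out: dict = {}
    for term, score in scores.items():
        for anc in graph.ancestors(term):
            out[anc] = out.get(anc, 0.0) + score
    return ConfidenceMap(out)


def blast2co_predict(propagated: ConfidenceMap, graph: OntologyGraph,
                     threshold: float = 0.5, min_depth: int = 3):
    """Deepest confident term from propagated confidences.

    The confident subgraph holds terms with confidence > threshold;
    candidates are its induced leaves (no is_a child also in the
    subgraph) whose longest path to a root is at least ``min_depth``.
    A unique maximal-confidence candidate is the prediction; ties are
    'ambiguous'; no candidate is 'rejected'.
    """
    confident = {t for t, v in propagated.items() if v > threshold}
    if not confident:
        return REJECTED
    leaves = [t for t in confident
              if not any(ch in confident for ch in graph.children(t))]
    candidates = [t for t in leaves if graph.depth(t) >= min_depth]
    if not candidates:
        return REJECTED
    best = max(propagated[t] for t in candidates)
    top = [t for t in candidates if propagated[t] >= best - _TIE_TOL]
    if len(top) > 1:
        return AMBIGUOUS
    return top[0]


def blast2co(hits: list, graph: OntologyGraph, threshold: float = 0.5,
             min_depth: int = 3):
    """Full pipeline: (pvalue, term) hits -> predicted term or sentinel."""
    base = blast2co_base_scores(hits, graph)
    if base == REJECTED:
        return REJECTED
    return blast2co_predict(propagate_scores(base, graph), graph,
                            threshold=threshold, min_depth=min_depth)


# -- ontology-aware accuracy ---------------------------------------------------


def _term_positive(actual, graph: OntologyGraph, reference_terms) -> bool:
    return any(graph.is_a(actual, r) or graph.is_a(r, actual)
               for r in reference_terms)


def cl_accuracy(actual, predicted, graph: OntologyGraph, reference_terms) -> float:
    """Ontology-aware accuracy of one prediction in [0, 1].

    Positive actual terms (related to some reference term): 1 if the
    prediction is the actual term or one of its descendants; if an
    ancestor is predicted, partial credit equal to the mean over
    reference-inferable intermediate terms c_k (actual <= c_k <=
    predicted with some reference term below c_k) of
    |descendants(c_k)| / |descendants(predicted)|; otherwise 0.
    Negative actual terms score 1 iff rejected.
    """
    if actual not in graph:
        raise KeyError(f"actual term {actual!r} not in ontology")
    positive = _term_positive(actual, graph, reference_terms)
    if not positive:
        return 1.0 if predicted == REJECTED else 0.0
    if predicted in (REJECTED, AMBIGUOUS):
        return 0.0
    if predicted not in graph:
        raise KeyError(f"predicted term {predicted!r} not in ontology")
    if graph.is_a(predicted, actual):
        return 1.0
    if graph.is_a(actual, predicted) and actual != predicted:
        inferable = [
            ck for ck in graph.ancestors(actual)
            if graph.is_a(ck, predicted)
            and any(graph.is_a(r, ck) for r in reference_terms)
        ]
        if not inferable:
            return 0.0
        ratio = np.mean([
            len(graph.descendants(ck)) / len(graph.descendants(predicted))
            for ck in inferable
        ])
        return float(ratio)
    return 0.0


def cl_mba(per_cell_results: list, graph: OntologyGraph, reference_terms) -> float:
    """Term-balanced mean ontology-aware accuracy.

    ``per_cell_results`` holds (actual_term, predicted) pairs; accuracies
    are averaged within each distinct actual term first, so per-term
    cell-count imbalance does not skew the mean.
    """
    by_term: dict = {}
    for actual, predicted in per_cell_results:
        by_term.setdefault(actual, []).append(
            cl_accuracy(actual, predicted, graph, reference_terms))
    if not by_term:
        raise ValueError("no results")
    return float(np.mean([np.mean(v) for v in by_term.values()]))
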