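"""Ontology-aware annotation from query hits.

Hits carrying Cell-Ontology-style terms are converted to confidence
scores (summed 1 - p similarity, normalized), propagated to ancestor
terms along is_a edges, and the deepest sufficiently confident term is
predicted. When hits disagree between sibling subtypes, the method backs
off to their common ancestor instead of guessing.
"""

import scquery as sq

graph = sq.toy_ontology()
print("ontology terms:", ", ".join(graph.terms))

cases = {
    "concordant deep hits": [(0.01, "ionocyte")] * 4,
    "split between t subtypes": [(0.10, "cytotoxic-t")] * 2
                                + [(0.10, "helper-t")] * 2,
    "weak scattered hits": [(0.96, "basal"), (0.97, "fibroblast"),
                            (0.95, "b-cell")],
}
for name, hits in cases.items():
    base = sq.blast2co_base_scores(hits, graph)
    pred = sq.blast2co(hits, graph, threshold=0.5, min_depth=2)
    print(f"\n{name}:")
    if base != sq.REJECTED:
        prop = sq.propagate_scores(base, graph)
        interesting = {t: round(v, 2) for t, v in prop.items() if v > 0.3}
        print(f"  propagated confidences > 0.3: {interesting}")
    print(f"  prediction: {pred}")

# accuracy gives partial credit for predicting a correct ancestor
acc = sq.cl_accuracy("cytotoxic-t", "t-cell", graph,
                     reference_terms=["cytotoxic-t"])
print(f"\nontology-aware accuracy, ancestor predicted: {acc:.3f} "
      "(1.0 = exact or more specific)")
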