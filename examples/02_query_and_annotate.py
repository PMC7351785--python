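"""Query unannotated cells against a reference, including a novel type.

One cluster is withheld from the reference entirely. A 4-model ensemble
embeds reference and query cells; hits are scored by the normalized
projection distance with empirical p-values, and labels are transferred
by majority vote among consistently significant hits. Cells of the
withheld cluster should be rejected; cells of seen clusters should
inherit the right label.
"""

import warnings

import numpy as np

import scquery as sq

warnings.simplefilter("ignore", UserWarning)

design = sq.SimulationDesign(n_cells=1500, n_genes=300, n_clusters=3,
                             n_batches=1, sigma_batch=0.0, seed=21)
matrix, _ = sq.simulate_dataset(design)
matrix.selected_genes = sq.select_variable_genes(matrix)
reference, query = sq.split_reference_query(matrix, "cluster2", seed=0)
print(f"reference: {reference.n_cells} cells ({sorted(set(reference.labels))})")
print(f"query:     {query.n_cells} cells incl. withheld cluster2")

models = [
    sq.fit(reference, sq.ModelConfig(latent_dim=10, n_components=10,
                                     hidden_dim=64, epochs=60, seed=s))
    for s in range(4)
]
index = sq.ReferenceIndex(models, reference, n_pairs=5000, seed=0)
results = sq.consensus_query(index, query, k=50, pvalue_cutoff=0.05, seed=0)

labels = np.asarray(query.labels)
for cluster in sorted(set(labels)):
    preds = [sq.predict_discrete(hits, reference.labels)
             for hits, is_c in zip(results, labels == cluster) if is_c]
    rejected = np.mean([p.status == "rejected" for p in preds])
    correct = np.mean([p.status == "predicted" and p.label == cluster
                       for p in preds])
    print(f"{cluster}: rejected {rejected:.2f}, correctly labeled {correct:.2f}")
print("(the withheld cluster should be rejected; seen clusters labeled)")
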