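"""Cluster tangent-space points and pick the cluster count by three metrics.

Four well-separated groups are planted; silhouette (max), Davies-Bouldin
(min) and NPMI topic coherence (max) should all vote for k = 4.
"""

import numpy as np

from resilmine.cluster import select_k

rng = np.random.default_rng(0)
centers = [np.array([0.0, 0]), np.array([8.0, 0]), np.array([0, 8.0]), np.array([8.0, 8.0])]
pts = np.vstack([c + rng.normal(0, 0.2, (8, 2)) for c in centers])
truth = np.repeat(np.arange(4), 8)
# phrase/document co-occurrence aligned with the planted groups
doc_sets = [set(range(10 * t, 10 * t + 8)) for t in truth]

best_k, table = select_k(pts, range(3, 8), phrase_doc_sets=doc_sets, n_docs=40, seed=0)
print(table.to_string(index=False))
print(f"\nselected k = {best_k} (majority of: max silhouette, min Davies-Bouldin,")
print("max coherence; ties go to the smaller k)")
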