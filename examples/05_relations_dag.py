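"""Build an attention relation matrix and enforce acyclicity.

Indicator embeddings feed an 8-head self-attention block whose concatenated
outputs are bilinearly transformed into a directed relation matrix C.  The
acyclicity of the weighted relation graph is measured by the
trace-exponential penalty h(C) = tr(exp(C o C)) - n, which is zero exactly
when no directed cycle exists; enforcement projects C onto near-acyclicity.
"""

import numpy as np

from resilmine.relations import (
    AttentionParams,
    dag_penalty,
    enforce_dag,
    is_acyclic,
    mhsa_relation_matrix,
    symmetrize,
)

rng = np.random.default_rng(0)
H = rng.standard_normal((12, 16))  # 12 indicators, 16-dim embeddings
params = AttentionParams.create(d=16, n_heads=8, d_k=8, seed=0)
C = mhsa_relation_matrix(H, params)
C /= np.abs(C).max()

print(f"relation matrix: {C.shape[0]}x{C.shape[1]}")
print(f"penalty before enforcement: {dag_penalty(C):.4f}")
C_dag = enforce_dag(C)
print(f"penalty after enforcement:  {dag_penalty(C_dag):.2e}")
print(f"thresholded graph acyclic:  {is_acyclic(C_dag)}")
S = symmetrize(C_dag)
print(f"symmetrized similarity matrix: symmetric={np.allclose(S, S.T)}")
print("\nA zero penalty certifies the indicator relations contain no circular")
print("dependency; S averages each directed pair into an undirected strength.")
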