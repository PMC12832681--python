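"""From connectivity matrices to an edge-feature dataset.

Builds two toy subjects' symmetric connectivity matrices over 4 regions,
vectorizes their strictly-upper triangles into p = 6 edge features, and
shows how edge indices map back to region pairs.
"""

import numpy as np

import fcexplain as fx

rng = np.random.default_rng(0)

# two subjects: one "control" (label 1), one "patient" (label 0)
matrices = []
for _ in range(2):
    A = rng.uniform(-1, 1, size=(4, 4))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)  # self-connectivity is ignored by vectorization
    matrices.append(A)

ds = fx.from_matrices(matrices, labels=[1, 0], dataset_name="toy")
print(f"dataset: {ds.n} subjects x {ds.p} edges "
      f"(p = N(N-1)/2 = {4 * 3 // 2})")
print("edge names:", ", ".join(ds.edge_map.names))
print("subject 0 edge vector:", np.round(ds.X[0], 3))

# edge index <-> region pair round trip
j = 4
i, k = fx.edge_index_to_pair(j, 4)
print(f"edge {j} connects regions {i} and {k}; "
      f"inverse gives index {fx.pair_to_edge_index(i, k, 4)}")

# the 90-region AAL atlas used for real FC studies gives 4005 edges
print("AAL-90 edge count:", len(fx.EdgeIndexMap.aal90()))
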