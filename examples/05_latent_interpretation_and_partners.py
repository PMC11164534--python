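"""Interpret the latent space and predict partners for new types.

After a type-level fit, each latent dimension is a connectivity motif: its
rank-one reconstruction, the types' latent coordinates, and the
back-projected gene weights describe it.  A held-out type is then projected
into the trained space to rank its most likely synaptic partners.
"""

import numpy as np

from biconn.containers import TypeFeatureMatrix
from biconn.latent import (
    gene_weight_backprojection,
    latent_coordinates,
    predict_partners,
    reconstruct_single_dimension,
)
from biconn.workflows import retina_shaped_recovery

out = retina_shaped_recovery(seed=7, tol=1e-7, max_iter=25_000)
F = out["result"].factors
Xh, Yh = out["Xh"], out["Yh"]
print(f"type-level reconstruction Pearson r = {out['pearson_r']:.3f}")

for k in (1, 2):
    Zk = reconstruct_single_dimension(Xh, Yh, F, k)
    print(f"dimension {k}: reconstruction spans "
          f"[{Zk.values.min():.2f}, {Zk.values.max():.2f}]")

coords = latent_coordinates(Xh, F.A)
n_pos = int((coords[:, 0] >= 0).sum())
print(f"pre types on the positive half of dimension 1: {n_pos}/{len(coords)}")

# gene weights: here 'genes' are the synthetic features themselves, so the
# back-projection chain uses identity loadings and unit scale
table = gene_weight_backprojection(F.A, np.eye(Xh.n_features),
                                   np.ones(Xh.n_features),
                                   Xh.feature_ids, top_n=5)
top = table[(table.dimension == 1) & (table.sign == "positive")]
print("top positive-weight features for dimension 1:")
print(top[["gene_id", "weight", "rank"]].to_string(index=False))

# treat the last post type as new: predict its partners among pre types
new = TypeFeatureMatrix(Yh.values[[-1]], type_ids=["held-out"],
                        feature_ids=Yh.feature_ids)
pred = predict_partners(new, Xh, F, top_k=3)[0]
print(f"predicted top partners for the held-out type: "
      f"{[t for t, _ in pred.ranked_partners]}")
# the ranking orders pre types by predicted connectivity strength with the
# projected new type
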