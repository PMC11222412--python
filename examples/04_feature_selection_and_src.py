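"""Sparse feature selection and sparse-representation classification.

Feature selection sparse-codes the -1/+1 label vector on the feature
columns (orthogonal matching pursuit as the L0 solver); |w| ranks feature
importance. The classifier codes each test sample over a dictionary of
unit-norm training samples and assigns the class whose class-restricted
reconstruction residual is smallest.
"""

import numpy as np

from srstroke import omp_solve, select_features, src_fit, src_predict

rng = np.random.default_rng(0)

# 60 samples x 200 features; the first 5 features carry the class signal.
labels = (np.arange(60) < 30).astype(int)
target = np.where(labels == 1, 1.0, -1.0)
X = rng.normal(size=(60, 200))
X[:, :5] += 0.75 * target[:, None]
Xz = (X - X.mean(0)) / X.std(0)

sel = select_features(Xz, labels, n_select=10)
hits = sorted(set(sel.selected.tolist()) & set(range(5)))
print(f"selected features: {sorted(sel.selected.tolist())}")
print(f"informative features recovered: {hits} ({len(hits)}/5)")

# SRC on the selected (sd-scaled, uncentered) columns.
Xs = X[:, sel.selected] / X[:, sel.selected].std(0)
model = src_fit(Xs, labels, max_atoms=10)
res = src_predict(model, Xs[0])
print(f"sample 0: residuals per class = {np.round(res.residuals, 3)}, "
      f"predicted {res.predicted} (true {labels[0]})")
print(f"continuous score (larger => class 1): {res.score:+.3f}")

# OMP sanity: an orthonormal dictionary recovers a single atom exactly.
eye = np.eye(6)
coef = omp_solve(eye, 3.0 * eye[:, 2], max_atoms=1)
print("orthonormal recovery, coefficient on atom 2:", coef[2])
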