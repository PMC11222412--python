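"""L0 sparse-representation feature selection and classification.

Two l0-penalized least-squares problems drive the analysis:

* **Feature selection** — regress the label vector ``l`` (coded -1/+1) on
  the training feature matrix ``F`` under an l0 penalty,
  ``w_hat = argmin_w ||l - F w||^2 + eta ||w||_0``;
  the magnitudes ``|w_hat|`` rank feature importance.

* **Sparse-representation classification (SRC)** — code a test feature
  vector ``f`` over a dictionary whose columns are the (selected,
  unit-normalized) training samples grouped into class blocks,
  ``beta_hat = argmin_beta ||f - Fbar beta||^2 + gamma ||beta||_0``,
  then compute per-class reconstruction residuals
  ``r_c = ||f - Fbar delta_c(beta_hat)||`` (``delta_c`` zeroes coefficients
  outside class ``c``) and assign the class with the smallest residual.

Both problems are solved greedily by orthogonal matching pursuit with a
sparsity budget (``max_atoms``) as the practical surrogate for the penalty
weight; :func:`brute_force_l0` provides the exact combinatorial optimum on
small instances for testing. Nothing here is randomized.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations

import numpy as np

__all__ = [
    "SparseSelectionResult",
    "SRCModel",
    "SRCResult",
    "omp_solve",
    "brute_force_l0",
    "select_features",
    "src_fit",
    "src_predict",
    "src_predict_batch",
    "save_model",
    "load_model",
]


def omp_solve(dictionary: np.ndarray, target: np.ndarray, max_atoms: int,
              residual_tol: float = 1e-6) -> np.ndarray:
    """Orthogonal matching pursuit: greedy l0-constrained least squares.

    Atoms are picked by maximal absolute normalized correlation with the
    current residual; the active set is refit by least squares each step.
    Stops at ``max_atoms`` atoms or when the residual norm falls to
    ``residual_tol``. Returns a dense coefficient vector (zeros off-support).
    """
    d = np.asarray(dictionary, dtype=float)
    y = np.asarray(target, dtype=float)
    if d.ndim != 2 or y.shape != (d.shape[0],):
        raise ValueError("dictionary must be 2-D with rows matching the target")
    n_rows, n_cols = d.shape
    if max_atoms > min(n_rows, n_cols):
        raise ValueError("max_atoms must be <= min(rows, columns)")
    norms = np.linalg.norm(d, axis=0)
    coef = np.zeros(n_cols)
    support: list[int] = []
    residual = y.copy()
    if np.linalg.norm(residual) <= residual_tol:
        return coef
    safe_norms = np.where(norms > 0, norms, np.inf)
    for _ in range(max_atoms):
        corr = np.abs(d.T @ residual) / safe_norms
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        if not np.isfinite(corr[j]) or corr[j] <= 0:
            break
        support.append(j)
        sub = d[:, support]
        sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
        residual = y - sub @ sol
        if np.linalg.norm(residual) <= residual_tol:
            break
    if support:
        coef[support] = sol
    return coef


def brute_force_l0(dictionary: np.ndarray, target: np.ndarray, penalty: float,
                   max_support: int | None = None) -> np.ndarray:
    """Exact minimizer of ``||y - D c||^2 + penalty * ||c||_0`` by support
    enumeration. Testing oracle only: requires <= 15 columns."""
    d = np.asarray(dictionary, dtype=float)
    y = np.asarray(target, dtype=float)
    n_cols = d.shape[1]
    if n_cols > 15:
        raise ValueError("brute_force_l0 is guarded to <= 15 columns")
    if max_support is None:
        max_support = n_cols
    best_coef = np.zeros(n_cols)
    best_obj = float(y @ y)  # empty support
    for k in range(1, max_support + 1):
        for support in combinations(range(n_cols), k):
            sub = d[:, support]
            sol, *_ = np.linalg.lstsq(sub, y, rcond=None)
            r = y - sub @ sol
            obj = float(r @ r) + penalty * k
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_coef = np.zeros(n_cols)
                best_coef[list(support)] = sol
    return best_coef


@dataclass(frozen=True)
class SparseSelectionResult:
    """Coefficients, importance ranking and the selected top-s features."""

    w: np.ndarray
    ranking: np.ndarray
    selected: np.ndarray
    max_atoms: int
    names: tuple | None = None

    @property
    def selected_names(self):
        if self.names is None:
            return None
        return tuple(self.names[i] for i in self.selected)


def select_features(feature_matrix, labels=None, n_select: int = 20,
                    residual_tol: float = 1e-6) -> SparseSelectionResult:
    """Rank features by sparse-coding the label vector on feature columns.

    Accepts a :class:`~srstroke.radiomics.FeatureMatrix` (labels taken from
    it) or a plain (m, D) array plus ``labels``. Labels are coded -1/+1 and
    the greedy solver is budgeted at ``n_select`` atoms (capped at m, with a
    warning when the refit would be underdetermined). Ranking: selected
    atoms by |w| descending, then the remaining features by their final
    residual correlation; ties broken by lowest index.
    """
    import warnings

    names = None
    if hasattr(feature_matrix, "matrix"):
        names = feature_matrix.names
        labels = feature_matrix.labels if labels is None else labels
        f = feature_matrix.matrix
    else:
        f = np.asarray(feature_matrix, dtype=float)
    labels = np.asarray(labels)
    m, d = f.shape
    if n_select > d:
        raise ValueError("n_select exceeds the number of features")
    target = np.where(labels > 0, 1.0, -1.0)
    max_atoms = n_select
    if max_atoms > m:
        warnings.warn("n_select exceeds the sample count; the least-squares "
                      "refit is underdetermined — capping the budget at m",
                      stacklevel=2)
        max_atoms = m
    w = omp_solve(f, target, max_atoms=max_atoms, residual_tol=residual_tol)

    support = np.flatnonzero(w)
    # order: |w| desc on the support, then residual correlation for the rest
    residual = target - f @ w
    norms = np.linalg.norm(f, axis=0)
    corr = np.abs(f.T @ residual) / np.where(norms > 0, norms, np.inf)
    key_primary = np.zeros(d)
    key_primary[support] = np.abs(w[support])
    in_support = np.zeros(d, dtype=bool)
    in_support[support] = True
    order = np.lexsort((np.arange(d), -np.nan_to_num(corr), -key_primary, ~in_support))
    ranking = order.astype(int)
    selected = ranking[:n_select]
    return SparseSelectionResult(w=w, ranking=ranking, selected=selected,
                                 max_atoms=max_atoms, names=names)


@dataclass(frozen=True)
class SRCModel:
    """Dictionary of unit-norm training columns grouped into class blocks."""

    dictionary: np.ndarray         # (D, m) columns = training samples
    column_classes: np.ndarray     # (m,) class index per column
    classes: tuple                 # sorted distinct class labels
    feature_names: tuple | None = None
    max_atoms: int = 10
    residual_tol: float = 1e-6

    def class_support(self, c: int) -> np.ndarray:
        return self.column_classes == self.classes[c]


@dataclass(frozen=True)
class SRCResult:
    beta: np.ndarray
    residuals: np.ndarray
    predicted: int
    score: float
    tie: bool


def src_fit(train, labels=None, max_atoms: int = 10,
            residual_tol: float = 1e-6, names=None) -> SRCModel:
    """Build the SRC dictionary: training samples as unit-norm columns in
    class blocks. Non-parametric — no iterative training happens here."""
    if hasattr(train, "matrix"):
        names = train.names if names is None else names
        labels = train.labels if labels is None else labels
        x = train.matrix
    else:
        x = np.asarray(train, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) < 2:
        raise ValueError("need at least one sample of each of two classes")
    order = np.concatenate([np.flatnonzero(labels == c) for c in classes])
    cols = x[order].T.astype(float)
    norms = np.linalg.norm(cols, axis=0)
    if np.any(norms == 0):
        raise ValueError("zero-norm training sample cannot be a dictionary column")
    cols = cols / norms
    return SRCModel(dictionary=cols, column_classes=labels[order],
                    classes=classes, feature_names=tuple(names) if names else None,
                    max_atoms=min(max_atoms, cols.shape[1]),
                    residual_tol=residual_tol)


def src_predict(model: SRCModel, f: np.ndarray, max_atoms: int | None = None) -> SRCResult:
    """Classify one feature vector by minimum class-restricted residual.

    The continuous score is the normalized residual margin
    ``(r_first - r_last) / (r_first + r_last)`` over the two classes, so for
    the reversal(0)/enlargement(1) coding a larger score means enlargement.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (model.dictionary.shape[0],):
        raise ValueError("feature dimension does not match the model")
    budget = model.max_atoms if max_atoms is None else max_atoms
    budget = min(budget, *model.dictionary.shape)
    beta = omp_solve(model.dictionary, f, max_atoms=budget,
                     residual_tol=model.residual_tol)
    residuals = np.empty(len(model.classes))
    for c in range(len(model.classes)):
        masked = np.where(model.class_support(c), beta, 0.0)
        residuals[c] = np.linalg.norm(f - model.dictionary @ masked)
    tie = bool(np.isclose(residuals.min(), residuals).sum() > 1)
    predicted = int(model.classes[int(np.argmin(residuals))])
    denom = residuals[0] + residuals[-1]
    score = float((residuals[0] - residuals[-1]) / denom) if denom > 0 else 0.0
    return SRCResult(beta=beta, residuals=residuals, predicted=predicted,
                     score=score, tie=tie)


def src_predict_kproximity(model: SRCModel, f: np.ndarray, k: int = 5) -> int:
    """Optional nearest-residual variant of the decision rule.

    Each training atom's one-atom representation residual (the distance from
    ``f`` to the atom's span) is a proximity; the majority class among the
    ``k`` most proximate atoms wins. Offered as a variant only — the primary
    rule is the minimum class-restricted residual of the full sparse code.
    """
    f = np.asarray(f, dtype=float)
    proj = model.dictionary.T @ f  # coefficient on each unit-norm atom
    resid = np.sqrt(np.maximum(f @ f - proj**2, 0.0))
    idx = np.argsort(resid, kind="stable")[: max(1, k)]
    votes = model.column_classes[idx]
    counts = {c: int((votes == c).sum()) for c in model.classes}
    return int(max(model.classes, key=lambda c: (counts[c], -c)))


def src_predict_batch(model: SRCModel, test) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise :func:`src_predict`; returns (predicted labels, scores)."""
    x = test.matrix if hasattr(test, "matrix") else np.asarray(test, dtype=float)
    if x.ndim != 2 or (x.size and x.shape[1] != model.dictionary.shape[0]):
        raise ValueError("test matrix dimension mismatch")
    preds, scores = [], []
    for row in x:
        res = src_predict(model, row)
        preds.append(res.predicted)
        scores.append(res.score)
    return np.asarray(preds, dtype=int), np.asarray(scores, dtype=float)


def save_model(model: SRCModel, selection: SparseSelectionResult | None, path: str) -> None:
    """Serialize a model (and optionally its feature selection) to JSON."""
    payload = {
        "dictionary": model.dictionary.tolist(),
        "column_classes": model.column_classes.tolist(),
        "classes": list(model.classes),
        "feature_names": list(model.feature_names) if model.feature_names else None,
        "max_atoms": model.max_atoms,
        "residual_tol": model.residual_tol,
    }
    if selection is not None:
        payload["selection"] = {
            "w": selection.w.tolist(),
            "ranking": selection.ranking.tolist(),
            "selected": selection.selected.tolist(),
            "max_atoms": selection.max_atoms,
            "names": list(selection.names) if selection.names else None,
        }
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True)


def load_model(path: str):
    with open(path) as fh:
        payload = json.load(fh)
    model = SRCModel(
        dictionary=np.asarray(payload["dictionary"], dtype=float),
        column_classes=np.asarray(payload["column_classes"], dtype=int),
        classes=tuple(payload["classes"]),
        feature_names=tuple(payload["feature_names"]) if payload.get("feature_names") else None,
        max_atoms=int(payload["max_atoms"]),
        residual_tol=float(payload["residual_tol"]),
    )
    selection = None
    if payload.get("selection"):
        s = payload["selection"]
        selection = SparseSelectionResult(
            w=np.asarray(s["w"], dtype=float),
            ranking=np.asarray(s["ranking"], dtype=int),
            selected=np.asarray(s["selected"], dtype=int),
            max_atoms=int(s["max_atoms"]),
            names=tuple(s["names"]) if s.get("names") else None,
        )
    return model, selection
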