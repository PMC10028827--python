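"""Additive per-feature attributions for tree-ensemble regressors.

For scikit-learn trees the attribution of a sample is accumulated along
its decision path: every split changes the expected prediction from the
parent node's mean to the child node's mean, and that change is credited
to the feature the parent split on. Summing the credited changes over the
path (plus the root mean as base value) reconstructs the prediction
exactly, so local accuracy holds by construction. Forest and boosted
ensembles aggregate the per-tree attributions the same way the ensemble
aggregates predictions (mean, or learning-rate-weighted sum plus the
initial estimate).

XGBoost models use the booster's native ``pred_contribs`` output, which
is likewise exactly additive.
"""
from __future__ import annotations

from typing import Tuple

import numpy as np
import scipy.sparse as sp

from .exceptions import UnsupportedModelError

__all__ = ["additive_attributions"]


def _single_tree_attributions(tree, X: np.ndarray, n_features: int):
    """Path attributions for one fitted sklearn decision tree.

    Returns ``(contribs (n, p), base)`` with base the root node mean.
    """
    t = tree.tree_
    values = t.value.reshape(t.node_count)  # regression: one output
    left, right, feature = t.children_left, t.children_right, t.feature

    # delta[node] = value[node] - value[parent]; credited to the parent's feature
    delta = np.zeros(t.node_count)
    credit_feature = np.full(t.node_count, -1, dtype=int)
    for parent in range(t.node_count):
        for child in (left[parent], right[parent]):
            if child != -1:
                delta[child] = values[child] - values[parent]
                credit_feature[child] = feature[parent]

    # D[node, feat] = delta[node]; contribs = path_matrix @ D
    internal = credit_feature >= 0
    nodes = np.nonzero(internal)[0]
    D = sp.csr_matrix(
        (delta[nodes], (nodes, credit_feature[nodes])),
        shape=(t.node_count, n_features),
    )
    paths = tree.decision_path(X)  # (n_samples, n_nodes) CSR of 0/1
    contribs = np.asarray((paths @ D).todense())
    return contribs, float(values[0])


def additive_attributions(model, X) -> Tuple[np.ndarray, float]:
    """Exact additive attributions ``(contribs, base)`` for ``model`` on ``X``.

    ``base + contribs.sum(axis=1)`` equals ``model.predict(X)`` to
    numerical tolerance for every supported model: sklearn decision trees,
    random forests, extremely randomized trees, gradient boosting, and
    XGBoost regressors.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    cls = type(model).__name__

    if cls == "XGBRegressor":
        import xgboost as xgb

        booster = model.get_booster()
        contrib = booster.predict(xgb.DMatrix(X), pred_contribs=True)
        return contrib[:, :p], float(contrib[0, p])

    if hasattr(model, "tree_"):  # a single decision tree
        return _single_tree_attributions(model, X, p)

    if cls in ("RandomForestRegressor", "ExtraTreesRegressor"):
        contribs = np.zeros((n, p))
        base = 0.0
        for est in model.estimators_:
            c, b = _single_tree_attributions(est, X, p)
            contribs += c
            base += b
        k = len(model.estimators_)
        return contribs / k, base / k

    if cls == "GradientBoostingRegressor":
        # prediction = init + lr * sum(tree); each tree's root mean joins the base
        contribs = np.zeros((n, p))
        base = float(np.asarray(model.init_.predict(X[:1])).ravel()[0])
        lr = model.learning_rate
        for est in model.estimators_.ravel():
            c, b = _single_tree_attributions(est, X, p)
            contribs += lr * c
            base += lr * b
        return contribs, base

    raise UnsupportedModelError(
        f"additive attributions require a tree-ensemble regressor, got {cls}"
    )
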