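"""Quantile regression forest.

A bagged ensemble of CART regression trees whose leaves are re-used, in
Meinshausen's estimator, to weight the training responses and form a
conditional distribution function:

    w_i(x) = (1/B) sum_t  m_{t,i}(x) / n_t(leaf_t(x)),
    F_hat(y | x) = sum_i w_i(x) 1[y_i <= y],

where m_{t,i}(x) is the bootstrap multiplicity of training point i in the
leaf of tree t containing x, and n_t(.) the leaf's bootstrap size. Quantiles
are the inf-type generalized inverse of F_hat — always an observed training
response, no interpolation. Prediction intervals are pairs of conditional
quantiles, [q_{alpha/2}(Y|X=x), q_{1-alpha/2}(Y|X=x)].

Variable importance follows the random-forest conventions: %IncMSE from
permuting each feature on a tree's out-of-bag samples, and IncNodePurity as
the total reduction in the sum of squared errors attributed to splits on the
feature.

Tree growth is delegated to sklearn's deterministic seeded CART splitter;
everything the quantile machinery needs (bootstrap/OOB bookkeeping, leaf
membership, weights, CDF inversion, importances, JSON round-trip) lives here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.tree import DecisionTreeRegressor

__all__ = ["QuantileForest", "QuantileForestResults", "PredictionInterval", "fit_forest"]


@dataclass
class PredictionInterval:
    """Conditional-quantile interval for one trait observation."""

    trait: str
    lower: float
    upper: float
    alpha: float = 0.10

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower quantile exceeds upper quantile")

    def contains(self, y: float) -> bool:
        return self.lower <= y <= self.upper


@dataclass
class _Tree:
    """Flat array form of one fitted regression tree (serializable)."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray           # leaf means (for OOB point prediction)
    bootstrap_idx: np.ndarray   # training row of each bootstrap draw
    oob_idx: np.ndarray
    leaf_of_bootstrap: np.ndarray = field(default=None)  # node id per bootstrap draw
    leaf_of_train: np.ndarray = field(default=None)      # node id per original training row

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf node id for each row, by vectorized tree descent."""
        node = np.zeros(len(X), dtype=np.int64)
        active = self.children_left[node] != -1
        while active.any():
            idx = np.where(active)[0]
            nd = node[idx]
            go_left = X[idx, self.feature[nd]] <= self.threshold[nd]
            node[idx] = np.where(go_left, self.children_left[nd], self.children_right[nd])
            active = self.children_left[node] != -1
        return node

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.value[self.apply(X)]


class QuantileForest:
    """Quantile-regression-forest model over (y, X).

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) complete predictor matrix (DataFrame or array).
    n_trees : ensemble size (default 500).
    mtry : features sampled per split; default ceil(p / 3).
    min_node_size : nodes at or below this size become leaves (default 5).
    seed : integer seed; same seed reproduces the forest exactly.

    ``fit()`` returns a :class:`QuantileForestResults`.
    """

    def __init__(self, y, X, feature_names=None, n_trees: int = 500,
                 mtry: int | None = None, min_node_size: int = 5, seed: int = 0,
                 trait_name: str = "y"):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        n, p = self.X.shape
        if n < 20:
            raise ValueError("need at least 20 observations")
        if len(self.y) != n:
            raise ValueError("y and X length mismatch")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("missing values must be imputed before forest fitting")
        self.feature_names = list(feature_names) if feature_names else [f"x{j}" for j in range(p)]
        self.n_trees = int(n_trees)
        self.mtry = int(mtry) if mtry else int(np.ceil(p / 3))
        self.min_node_size = int(min_node_size)
        self.seed = int(seed)
        self.trait_name = trait_name

    def fit(self) -> "QuantileForestResults":
        n, _ = self.X.shape
        rng = np.random.default_rng(self.seed)
        if np.ptp(self.y) == 0:
            warnings.warn("constant response: every tree is a single leaf")
        trees: list[_Tree] = []
        all_idx = np.arange(n)
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(all_idx, boot)
            skl = DecisionTreeRegressor(
                max_features=self.mtry,
                min_samples_split=self.min_node_size + 1,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            skl.fit(self.X[boot], self.y[boot])
            t = skl.tree_
            tree = _Tree(
                children_left=t.children_left.copy(),
                children_right=t.children_right.copy(),
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                value=t.value.ravel().copy(),
                bootstrap_idx=boot,
                oob_idx=oob,
            )
            tree.leaf_of_bootstrap = tree.apply(self.X[boot])
            tree.leaf_of_train = tree.apply(self.X)
            trees.append(tree)
        return QuantileForestResults(self, trees)


class QuantileForestResults:
    """Fitted quantile regression forest.

    Exposes conditional quantiles, prediction intervals, OOB error and
    permutation/impurity variable importances.
    """

    def __init__(self, model: QuantileForest, trees: list[_Tree]):
        self.model = model
        self.trees = trees
        self._y_order = np.argsort(model.y, kind="stable")
        self._y_sorted = model.y[self._y_order]

    # -- Meinshausen weights ------------------------------------------------
    def weights(self, X) -> np.ndarray:
        """Dense (n_query, n_train) matrix of conditional-distribution weights.

        Rows sum to 1 (to numerical tolerance): each tree distributes weight
        1/leaf_size uniformly over the original training observations that
        share the query point's leaf. Using all training observations (not
        the bootstrap multiplicities) follows the original estimator and
        keeps the conditional distribution unbiased: points a tree did not
        resample still vote in the leaves they fall into.
        """
        X = self._coerce_X(X)
        n_train = len(self.model.y)
        n_query = len(X)
        W = np.zeros((n_query, n_train))
        for tree in self.trees:
            leaves_q = tree.apply(X)
            leaves_t = tree.leaf_of_train
            n_nodes = len(tree.children_left)
            sizes = np.bincount(leaves_t, minlength=n_nodes).astype(float)
            # A: query x leaf incidence; B: leaf x training-row weight
            A = sparse.csr_matrix(
                (np.ones(n_query), (np.arange(n_query), leaves_q)),
                shape=(n_query, n_nodes),
            )
            B = sparse.csr_matrix(
                (1.0 / sizes[leaves_t], (leaves_t, np.arange(n_train))),
                shape=(n_nodes, n_train),
            )
            C = (A @ B).tocoo()
            np.add.at(W, (C.row, C.col), C.data)
        W /= len(self.trees)
        return W

    def _coerce_X(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[self.model.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        return np.ascontiguousarray(X)

    def predict_quantiles(self, X, taus=(0.05, 0.5, 0.95)) -> np.ndarray:
        """Inf-type conditional quantiles; shape (n_query, len(taus)).

        Each returned quantile is an observed training response.
        """
        taus = np.atleast_1d(np.asarray(taus, dtype=float))
        if np.any((taus <= 0) | (taus >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        W = self.weights(X)
        cdf = np.cumsum(W[:, self._y_order], axis=1)
        out = np.empty((len(cdf), len(taus)))
        for k, tau in enumerate(taus):
            idx = (cdf < tau - 1e-12).sum(axis=1)
            idx = np.minimum(idx, len(self._y_sorted) - 1)
            out[:, k] = self._y_sorted[idx]
        return out

    def conditional_quantile(self, x, tau: float) -> float:
        """q_tau(Y | X = x) for a single query point."""
        return float(self.predict_quantiles(np.atleast_2d(x), [tau])[0, 0])

    def prediction_interval(self, X, alpha: float = 0.10):
        """90% (by default) conditional prediction intervals.

        Returns an (n_query, 2) array of [q_{alpha/2}, q_{1-alpha/2}]; for a
        single query point, a :class:`PredictionInterval`.
        """
        if not (0 < alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        Xc = self._coerce_X(X)
        q = self.predict_quantiles(Xc, [alpha / 2.0, 1.0 - alpha / 2.0])
        single = np.asarray(X).ndim == 1
        if single:
            return PredictionInterval(self.model.trait_name, float(q[0, 0]), float(q[0, 1]), alpha)
        return q

    # -- diagnostics --------------------------------------------------------
    def oob_mse(self) -> float:
        """Ensemble OOB mean squared error of the conditional-mean prediction."""
        n = len(self.model.y)
        pred_sum = np.zeros(n)
        cnt = np.zeros(n)
        for tree in self.trees:
            oob = tree.oob_idx
            if len(oob) == 0:
                continue
            pred_sum[oob] += tree.predict(self.model.X[oob])
            cnt[oob] += 1
        ok = cnt > 0
        return float(np.mean((self.model.y[ok] - pred_sum[ok] / cnt[ok]) ** 2))

    def variable_importance(self, seed: int = 0) -> pd.DataFrame:
        """Permutation (%IncMSE) and impurity (IncNodePurity) importances.

        %IncMSE_j = 100 * mean over trees of (OOB MSE with feature j permuted
        - OOB MSE) / OOB MSE. IncNodePurity_j = total SSE reduction of splits
        on j, summed over all trees. Sorted by %IncMSE descending.
        """
        rng = np.random.default_rng(seed)
        X, y = self.model.X, self.model.y
        p = X.shape[1]
        inc_mse = np.zeros(p)
        node_purity = np.zeros(p)
        n_used = 0
        for tree in self.trees:
            oob = tree.oob_idx
            node_purity += _tree_purity(tree, y[tree.bootstrap_idx], p)
            if len(oob) < 2:
                continue
            n_used += 1
            Xo = X[oob].copy()
            base = float(np.mean((y[oob] - tree.predict(Xo)) ** 2))
            base = max(base, 1e-300)
            for j in range(p):
                saved = Xo[:, j].copy()
                Xo[:, j] = saved[rng.permutation(len(saved))]
                perm = float(np.mean((y[oob] - tree.predict(Xo)) ** 2))
                Xo[:, j] = saved
                inc_mse[j] += (perm - base) / base
        if n_used:
            inc_mse = 100.0 * inc_mse / n_used
        table = pd.DataFrame(
            {"pct_inc_mse": inc_mse, "inc_node_purity": node_purity},
            index=pd.Index(self.model.feature_names, name="feature"),
        )
        return table.sort_values("pct_inc_mse", ascending=False)

    def summary(self) -> str:
        m = self.model
        lines = [
            "Quantile Regression Forest",
            "=" * 40,
            f"observations:      {len(m.y)}",
            f"features:          {m.X.shape[1]}",
            f"trees:             {m.n_trees}",
            f"mtry:              {m.mtry}",
            f"min node size:     {m.min_node_size}",
            f"OOB MSE:           {self.oob_mse():.4f}",
        ]
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path | None = None) -> str | None:
        """Serialize the fitted forest (trees as flat arrays) to JSON."""
        payload = {
            "trait_name": self.model.trait_name,
            "feature_names": self.model.feature_names,
            "params": {
                "n_trees": self.model.n_trees,
                "mtry": self.model.mtry,
                "min_node_size": self.model.min_node_size,
                "seed": self.model.seed,
            },
            "y": self.model.y.tolist(),
            "trees": [
                {
                    "children_left": t.children_left.tolist(),
                    "children_right": t.children_right.tolist(),
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "value": t.value.tolist(),
                    "bootstrap_idx": t.bootstrap_idx.tolist(),
                    "oob_idx": t.oob_idx.tolist(),
                }
                for t in self.trees
            ],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
            return None
        return text

    @classmethod
    def from_json(cls, source: str | Path, X_train) -> "QuantileForestResults":
        """Rebuild a fitted forest from :meth:`to_json` output.

        ``X_train`` must be the training predictor matrix (not stored in the
        JSON to keep exports small); it is re-applied to recover leaf
        memberships.
        """
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        payload = json.loads(text)
        y = np.asarray(payload["y"], dtype=float)
        model = QuantileForest(
            y, np.asarray(X_train, dtype=float),
            feature_names=payload["feature_names"],
            trait_name=payload["trait_name"],
            **payload["params"],
        )
        trees = []
        for td in payload["trees"]:
            t = _Tree(
                children_left=np.asarray(td["children_left"], dtype=np.int64),
                children_right=np.asarray(td["children_right"], dtype=np.int64),
                feature=np.asarray(td["feature"], dtype=np.int64),
                threshold=np.asarray(td["threshold"], dtype=float),
                value=np.asarray(td["value"], dtype=float),
                bootstrap_idx=np.asarray(td["bootstrap_idx"], dtype=np.int64),
                oob_idx=np.asarray(td["oob_idx"], dtype=np.int64),
            )
            t.leaf_of_bootstrap = t.apply(model.X[t.bootstrap_idx])
            t.leaf_of_train = t.apply(model.X)
            trees.append(t)
        return cls(model, trees)


def _tree_purity(tree: _Tree, y_boot: np.ndarray, p: int) -> np.ndarray:
    """IncNodePurity: per-feature sum of (parent SSE - child SSEs) over splits.

    Node statistics are rebuilt bottom-up: leaf count/sum/sum-of-squares from
    the bootstrap leaf membership, internal nodes as the sum of their
    children, then SSE(node) = s2 - s1^2/count.
    """
    n_nodes = len(tree.children_left)
    cnt = np.zeros(n_nodes)
    s1 = np.zeros(n_nodes)
    s2 = np.zeros(n_nodes)
    np.add.at(cnt, tree.leaf_of_bootstrap, 1.0)
    np.add.at(s1, tree.leaf_of_bootstrap, y_boot)
    np.add.at(s2, tree.leaf_of_bootstrap, y_boot**2)
    # children always have larger node ids than their parent in sklearn's
    # export, so a reverse sweep accumulates bottom-up
    for node in range(n_nodes - 1, -1, -1):
        left, right = tree.children_left[node], tree.children_right[node]
        if left != -1:
            cnt[node] = cnt[left] + cnt[right]
            s1[node] = s1[left] + s1[right]
            s2[node] = s2[left] + s2[right]
    with np.errstate(invalid="ignore", divide="ignore"):
        sse = s2 - np.where(cnt > 0, s1**2 / np.maximum(cnt, 1), 0.0)
    purity = np.zeros(p)
    internal = tree.children_left != -1
    for node in np.where(internal)[0]:
        left, right = tree.children_left[node], tree.children_right[node]
        reduction = sse[node] - sse[left] - sse[right]
        purity[tree.feature[node]] += max(reduction, 0.0)
    return purity


def fit_forest(X, y, **params) -> QuantileForestResults:
    """Functional convenience wrapper: fit a quantile forest on (X, y)."""
    return QuantileForest(y, X, **params).fit()
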