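"""Bagged regression forest with explicit bootstrap control.

A thin forest built on :class:`sklearn.tree.DecisionTreeRegressor` that
exposes the three behaviours the clock framework needs and scikit-learn's
own forest does not: a tunable per-tree bootstrap size (``sampsize``),
weighted case sampling (weights bias which samples enter each tree), and
per-tree out-of-bag permutation importance.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeRegressor


class RandomForest:
    """Regression forest with OOB predictions and permutation importance.

    Parameters
    ----------
    n_trees : number of bootstrap trees.
    sampsize : bootstrap draw size per tree (default n).
    mtry : features considered at each split (default max(1, s // 3)).
    seed : seed for bootstrap draws and tree randomness.
    """

    def __init__(self, n_trees=500, sampsize=None, mtry=None, seed=None):
        self.n_trees = int(n_trees)
        self.sampsize = sampsize
        self.mtry = mtry
        self.seed = seed

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, s = X.shape
        sampsize = int(self.sampsize) if self.sampsize else n
        mtry = int(self.mtry) if self.mtry else max(1, s // 3)
        mtry = min(mtry, s)
        rng = np.random.default_rng(self.seed)
        prob = None
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            if (sample_weight < 0).any() or sample_weight.sum() <= 0:
                raise ValueError("sample weights must be non-negative, not all zero")
            prob = sample_weight / sample_weight.sum()

        self.X_ = X
        self.y_ = y
        self.trees_ = []
        self.inbag_ = np.zeros((self.n_trees, n), dtype=bool)
        for t in range(self.n_trees):
            idx = rng.choice(n, size=sampsize, replace=True, p=prob)
            tree = DecisionTreeRegressor(
                max_features=mtry,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.inbag_[t, idx] = True
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        preds = np.zeros(len(X))
        for tree in self.trees_:
            preds += tree.predict(X)
        return preds / len(self.trees_)

    def oob_prediction(self) -> np.ndarray:
        """Mean prediction per sample over trees where it was out-of-bag.

        Samples that were in-bag for every tree get NaN.
        """
        n = len(self.y_)
        total = np.zeros(n)
        votes = np.zeros(n)
        for t, tree in enumerate(self.trees_):
            oob = ~self.inbag_[t]
            if oob.any():
                total[oob] += tree.predict(self.X_[oob])
                votes[oob] += 1
        with np.errstate(invalid="ignore"):
            out = total / votes
        out[votes == 0] = np.nan
        return out

    def oob_mse(self) -> float:
        pred = self.oob_prediction()
        ok = ~np.isnan(pred)
        if not ok.any():
            raise RuntimeError("no sample ever out-of-bag; grow more trees")
        return float(np.mean((pred[ok] - self.y_[ok]) ** 2))

    def permutation_importance(self, rng=None) -> np.ndarray:
        """Percent increase in OOB MSE when each feature is permuted.

        For each tree, each feature is shuffled among that tree's OOB
        samples and the tree's OOB squared error recomputed; the mean
        per-tree MSE increase is reported as a percentage of the forest
        OOB MSE.
        """
        rng = np.random.default_rng(rng)
        n, s = self.X_.shape
        delta = np.zeros(s)
        used = np.zeros(s)
        for t, tree in enumerate(self.trees_):
            oob = np.flatnonzero(~self.inbag_[t])
            if oob.size < 2:
                continue
            X_oob = self.X_[oob]
            y_oob = self.y_[oob]
            base_mse = np.mean((tree.predict(X_oob) - y_oob) ** 2)
            # one batched predict over all per-feature permuted copies
            stack = np.broadcast_to(X_oob, (s, oob.size, s)).copy()
            for j in range(s):
                stack[j, :, j] = X_oob[rng.permutation(oob.size), j]
            preds = tree.predict(stack.reshape(s * oob.size, s)).reshape(
                s, oob.size
            )
            perm_mse = np.mean((preds - y_oob) ** 2, axis=1)
            delta += perm_mse - base_mse
            used += 1
        if not used.all():
            raise RuntimeError("some feature never evaluated out-of-bag")
        baseline = self.oob_mse()
        return 100.0 * (delta / used) / baseline
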