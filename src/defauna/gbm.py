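"""Stochastic gradient boosting of regression trees, with Shapley attribution.

The driver analysis regresses per-hexcell defaunation on landscape
covariates with a least-squares boosted tree ensemble:
``F(x) = F0 + ν Σ_t T_t(x)`` where F0 is the training mean, each tree is
fitted to the current residuals on a seeded subsample, and ν is the
shrinkage.  Splits maximise variance reduction with deterministic
tie-breaking (lowest feature index, then lowest split value), so a
fixed seed reproduces the ensemble exactly.  Hyperparameters are tuned
by random search with k-fold cross-validation; attribution uses
interventional Shapley values with exact coalition enumeration for
small feature counts.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionTree",
    "GradientBoostedTrees",
    "GBTResults",
    "split_data",
    "tune_random_search",
    "CVResult",
    "evaluate",
    "shap_values",
    "ShapExplanation",
    "DEFAULT_SEARCH_SPACE",
]


class RegressionTree:
    """Depth-limited least-squares regression tree (CART-style).

    Stored as parallel node arrays; leaf nodes have ``feature = -1``.
    """

    def __init__(self, max_depth: int = 3, min_node: int = 2):
        self.max_depth = max_depth
        self.min_node = min_node
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.value: list[float] = []

    def _best_split(self, X: np.ndarray, y: np.ndarray):
        n, d = X.shape
        if n < 2 * self.min_node:
            return None
        parent_sse = ((y - y.mean()) ** 2).sum()
        best = None  # (reduction, feature, threshold)
        for j in range(d):
            order = np.argsort(X[:, j], kind="stable")
            xs, ys = X[order, j], y[order]
            csum = np.cumsum(ys)
            csum2 = np.cumsum(ys**2)
            total, total2 = csum[-1], csum2[-1]
            # candidate split after position i (left = 0..i)
            nl = np.arange(1, n)
            valid = (xs[1:] > xs[:-1]) & (nl >= self.min_node) & (n - nl >= self.min_node)
            if not valid.any():
                continue
            sl = csum[:-1]
            sl2 = csum2[:-1]
            sse = (sl2 - sl**2 / nl) + ((total2 - sl2) - (total - sl) ** 2 / (n - nl))
            sse = np.where(valid, sse, np.inf)
            i = int(np.argmin(sse))  # argmin takes the first => lowest threshold
            red = parent_sse - sse[i]
            if red <= 1e-12:
                continue
            thr = 0.5 * (xs[i] + xs[i + 1])
            # strict > keeps the lowest feature index on ties
            if best is None or red > best[0] + 1e-12:
                best = (red, j, thr)
        return best

    def _grow(self, X, y, depth) -> int:
        idx = len(self.feature)
        self.feature.append(-1)
        self.threshold.append(0.0)
        self.left.append(-1)
        self.right.append(-1)
        self.value.append(float(y.mean()))
        if depth >= self.max_depth or y.size < 2 * self.min_node:
            return idx
        split = self._best_split(X, y)
        if split is None:
            return idx
        _, j, thr = split
        mask = X[:, j] <= thr
        self.feature[idx] = j
        self.threshold[idx] = thr
        self.left[idx] = self._grow(X[mask], y[mask], depth + 1)
        self.right[idx] = self._grow(X[~mask], y[~mask], depth + 1)
        return idx

    def fit(self, X: np.ndarray, y: np.ndarray) -> "RegressionTree":
        self._grow(np.asarray(X, dtype=float), np.asarray(y, dtype=float), 0)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if self.feature[node] < 0:
                out[rows] = self.value[node]
                continue
            mask = X[rows, self.feature[node]] <= self.threshold[node]
            stack.append((self.left[node], rows[mask]))
            stack.append((self.right[node], rows[~mask]))
        return out

    def to_dict(self) -> dict:
        return {
            "max_depth": self.max_depth,
            "min_node": self.min_node,
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left,
            "right": self.right,
            "value": self.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionTree":
        t = cls(d["max_depth"], d["min_node"])
        t.feature = list(d["feature"])
        t.threshold = list(d["threshold"])
        t.left = list(d["left"])
        t.right = list(d["right"])
        t.value = list(d["value"])
        return t


@dataclass
class GBMParams:
    n_trees: int = 200
    depth: int = 3
    learning_rate: float = 0.1
    subsample: float = 1.0
    min_node: int = 3

    def to_dict(self) -> dict:
        return self.__dict__.copy()


class GradientBoostedTrees:
    """Boosted regression model (Model object, statsmodels-style).

    Parameters are the data; hyperparameters go to :meth:`fit`.
    """

    def __init__(
        self,
        X: np.ndarray | pd.DataFrame,
        y: np.ndarray | pd.Series,
        feature_names: list[str] | None = None,
    ):
        if isinstance(X, pd.DataFrame):
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy()
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float).ravel()
        if np.isnan(self.y).any():
            raise ValueError("missing values in the response")
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X/y shape mismatch")
        self.feature_names = feature_names or [
            f"x{j}" for j in range(self.X.shape[1])
        ]

    def fit(self, params: GBMParams | dict | None = None, seed: int = 0) -> "GBTResults":
        params = (
            params
            if isinstance(params, GBMParams)
            else GBMParams(**(params or {}))
        )
        X, y = self.X, self.y
        rng = np.random.default_rng(seed)
        f0 = float(y.mean())
        trees: list[RegressionTree] = []
        current = np.full(y.size, f0)
        train_mse = [float(((y - current) ** 2).mean())]
        if np.allclose(y, f0):
            warnings.warn("constant response; returning an empty ensemble")
            return GBTResults(self, params, f0, trees, np.array(train_mse), seed)
        n_sub = max(2, int(round(params.subsample * y.size)))
        for _ in range(params.n_trees):
            rows = (
                np.sort(rng.choice(y.size, size=n_sub, replace=False))
                if n_sub < y.size
                else np.arange(y.size)
            )
            resid = y - current
            tree = RegressionTree(params.depth, params.min_node).fit(
                X[rows], resid[rows]
            )
            current = current + params.learning_rate * tree.predict(X)
            trees.append(tree)
            train_mse.append(float(((y - current) ** 2).mean()))
        return GBTResults(self, params, f0, trees, np.array(train_mse), seed)


@dataclass
class GBTResults:
    """Fitted boosted ensemble with prediction, metrics, SHAP and I/O."""

    model: GradientBoostedTrees
    params: GBMParams
    f0: float
    trees: list[RegressionTree]
    train_mse_path: np.ndarray
    seed: int

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.full(X.shape[0], self.f0)
        for t in self.trees:
            out += self.params.learning_rate * t.predict(X)
        return out

    def evaluate(self, X, y) -> dict:
        return evaluate(self, X, y)

    def shap(self, X=None, method: str = "auto", n_perm: int = 200, seed: int = 0):
        X_eval = self.model.X if X is None else X
        return shap_values(
            self, X_eval, background=self.model.X, method=method,
            n_perm=n_perm, seed=seed,
        )

    def summary(self) -> pd.DataFrame:
        metrics = self.evaluate(self.model.X, self.model.y)
        return pd.DataFrame(
            {
                "quantity": ["n_trees", "depth", "learning_rate", "subsample",
                             "train_r2", "train_rmse"],
                "value": [
                    self.params.n_trees,
                    self.params.depth,
                    self.params.learning_rate,
                    self.params.subsample,
                    metrics["r2"],
                    metrics["rmse"],
                ],
            }
        )

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "params": self.params.to_dict(),
                "f0": self.f0,
                "seed": self.seed,
                "feature_names": self.model.feature_names,
                "trees": [t.to_dict() for t in self.trees],
            }
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, payload: str) -> "GBTResults":
        d = json.loads(payload)
        params = GBMParams(**d["params"])
        dummy = GradientBoostedTrees(
            np.zeros((2, len(d["feature_names"]))), np.zeros(2),
            feature_names=d["feature_names"],
        )
        trees = [RegressionTree.from_dict(t) for t in d["trees"]]
        return cls(dummy, params, d["f0"], trees, np.empty(0), d["seed"])


def split_data(records: pd.DataFrame, train_frac: float = 0.75, seed: int = 0):
    """Seeded uniform train/test split (⌊train_frac·n⌋ / remainder)."""
    n = len(records)
    if n < 8:
        raise ValueError("need at least 8 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(math.floor(train_frac * n))
    train = records.iloc[np.sort(perm[:n_train])].reset_index(drop=True)
    test = records.iloc[np.sort(perm[n_train:])].reset_index(drop=True)
    return train, test


def evaluate(results: GBTResults, X, y) -> dict:
    """R² (1 − SS_res/SS_tot) and RMSE of predictions against y."""
    y = np.asarray(y, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("empty evaluation data")
    pred = results.predict(X)
    ss_res = float(((y - pred) ** 2).sum())
    rmse = math.sqrt(ss_res / y.size)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return {"r2": r2, "rmse": rmse}


DEFAULT_SEARCH_SPACE = {
    "n_trees": (50, 1000),
    "depth": (1, 2, 3, 5),
    "learning_rate": (0.01, 0.3),  # log-uniform
    "subsample": (0.5, 1.0),
}


@dataclass
class CVResult:
    candidates: list[GBMParams]
    cv_rmse: list[float]
    selected: GBMParams
    results: GBTResults
    train_metrics: dict
    test_metrics: dict | None = None
    fold_rmse: list[list[float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "candidates": [c.to_dict() for c in self.candidates],
            "cv_rmse": self.cv_rmse,
            "fold_rmse": self.fold_rmse,
            "selected": self.selected.to_dict(),
            "train_metrics": self.train_metrics,
            "test_metrics": self.test_metrics,
        }


def _draw_candidates(space: dict, n: int, rng) -> list[GBMParams]:
    out = []
    for _ in range(n):
        lo, hi = space.get("n_trees", DEFAULT_SEARCH_SPACE["n_trees"])
        nt = int(rng.integers(lo, hi + 1))
        depth = int(rng.choice(space.get("depth", DEFAULT_SEARCH_SPACE["depth"])))
        llo, lhi = space.get("learning_rate", DEFAULT_SEARCH_SPACE["learning_rate"])
        lr = float(np.exp(rng.uniform(np.log(llo), np.log(lhi))))
        slo, shi = space.get("subsample", DEFAULT_SEARCH_SPACE["subsample"])
        sub = float(rng.uniform(slo, shi))
        out.append(GBMParams(nt, depth, lr, sub))
    return out


def tune_random_search(
    train: pd.DataFrame | np.ndarray,
    y: np.ndarray | str,
    space: dict | None = None,
    n_candidates: int = 25,
    k: int = 10,
    seed: int = 0,
    test: tuple | None = None,
    feature_names: list[str] | None = None,
) -> CVResult:
    """Random-search hyperparameter tuning with k-fold cross-validation.

    Candidates are drawn from the search space; each is scored by mean
    RMSE over a seeded k-fold partition of the training data; the
    winner is refitted on the full training set.  If ``test`` (X, y) is
    given, held-out metrics are reported too.
    """
    if isinstance(y, str):
        frame = train
        y_arr = frame[y].to_numpy(dtype=float)
        X = frame.drop(columns=[y])
        feature_names = feature_names or list(X.columns)
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(train, dtype=float)
        y_arr = np.asarray(y, dtype=float).ravel()
    n = y_arr.size
    if n < k:
        raise ValueError("fewer training rows than folds")
    space = space or DEFAULT_SEARCH_SPACE
    rng = np.random.default_rng(seed)
    candidates = _draw_candidates(space, n_candidates, rng)
    if not candidates:
        raise ValueError("empty candidate space")
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    cv_rmse, fold_rmse = [], []
    for ci, cand in enumerate(candidates):
        rmses = []
        for fi, hold in enumerate(folds):
            mask = np.ones(n, dtype=bool)
            mask[hold] = False
            res = GradientBoostedTrees(X[mask], y_arr[mask]).fit(
                cand, seed=seed + 1000 * ci + fi
            )
            rmses.append(evaluate(res, X[hold], y_arr[hold])["rmse"])
        fold_rmse.append(rmses)
        cv_rmse.append(float(np.mean(rmses)))
    best = int(np.argmin(cv_rmse))
    final = GradientBoostedTrees(X, y_arr, feature_names=feature_names).fit(
        candidates[best], seed=seed
    )
    train_metrics = evaluate(final, X, y_arr)
    test_metrics = None
    if test is not None:
        test_metrics = evaluate(final, test[0], np.asarray(test[1], dtype=float))
    return CVResult(
        candidates, cv_rmse, candidates[best], final, train_metrics,
        test_metrics, fold_rmse,
    )


@dataclass
class ShapExplanation:
    """Interventional Shapley attributions for a set of observations."""

    values: np.ndarray  # (n_obs, d)
    base: float  # mean prediction over the background
    method: str  # "exact" or "sampling"
    feature_names: list[str]
    X: np.ndarray

    def local_accuracy_gap(self, results: GBTResults) -> np.ndarray:
        pred = results.predict(self.X)
        return np.abs(self.base + self.values.sum(axis=1) - pred)

    def importance(self) -> pd.Series:
        """Mean |φ| per feature, descending."""
        imp = pd.Series(
            np.abs(self.values).mean(axis=0), index=self.feature_names
        )
        return imp.sort_values(ascending=False)

    def sign_trend(self) -> pd.Series:
        """Correlation of φ_j with x_j: the direction of each driver's effect."""
        out = {}
        for j, name in enumerate(self.feature_names):
            x = self.X[:, j]
            phi = self.values[:, j]
            if x.std() == 0 or phi.std() == 0:
                out[name] = 0.0
            else:
                out[name] = float(np.corrcoef(x, phi)[0, 1])
        return pd.Series(out)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "row", np.arange(len(df)))
        return df.melt(id_vars="row", var_name="feature", value_name="phi")


def shap_values(
    results: GBTResults,
    X,
    background=None,
    method: str = "auto",
    n_perm: int = 200,
    seed: int = 0,
) -> ShapExplanation:
    """Shapley attribution with the interventional value function.

    ``v(S)`` is the mean prediction over the background with the
    features in S fixed to the observation's values.  For d ≤ 12
    features all 2^d coalitions are enumerated (exact, satisfies the
    Shapley axioms to numerical precision); otherwise seeded permutation
    sampling is used.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    bg = results.model.X if background is None else np.asarray(background, dtype=float)
    if bg.shape[0] == 0:
        raise ValueError("empty background")
    d = X.shape[1]
    if method == "auto":
        method = "exact" if d <= 12 else "sampling"
    names = results.model.feature_names
    if method == "exact":
        phi = _shap_exact(results, X, bg)
    else:
        phi = _shap_sampling(results, X, bg, n_perm, seed)
    base = float(results.predict(bg).mean())
    return ShapExplanation(phi, base, method, names, X)


def _coalition_values(results: GBTResults, X, bg) -> dict[frozenset, np.ndarray]:
    n, d = X.shape
    nb = bg.shape[0]
    v: dict[frozenset, np.ndarray] = {}
    for r in range(d + 1):
        for S in itertools.combinations(range(d), r):
            hybrid = np.repeat(bg[None, :, :], n, axis=0)  # (n, nb, d)
            for j in S:
                hybrid[:, :, j] = X[:, j][:, None]
            pred = results.predict(hybrid.reshape(n * nb, d)).reshape(n, nb)
            v[frozenset(S)] = pred.mean(axis=1)
    return v


def _shap_exact(results: GBTResults, X, bg) -> np.ndarray:
    n, d = X.shape
    v = _coalition_values(results, X, bg)
    fact = [math.factorial(i) for i in range(d + 1)]
    phi = np.zeros((n, d))
    for j in range(d):
        others = [i for i in range(d) if i != j]
        for r in range(d):
            w = fact[r] * fact[d - r - 1] / fact[d]
            for S in itertools.combinations(others, r):
                fs = frozenset(S)
                phi[:, j] += w * (v[frozenset(S + (j,))] - v[fs])
    return phi


def _shap_sampling(results: GBTResults, X, bg, n_perm: int, seed: int) -> np.ndarray:
    n, d = X.shape
    nb = bg.shape[0]
    rng = np.random.default_rng(seed)
    phi = np.zeros((n, d))
    for _ in range(n_perm):
        order = rng.permutation(d)
        hybrid = np.repeat(bg[None, :, :], n, axis=0)
        prev = results.predict(hybrid.reshape(n * nb, d)).reshape(n, nb).mean(axis=1)
        for j in order:
            hybrid[:, :, j] = X[:, j][:, None]
            cur = results.predict(hybrid.reshape(n * nb, d)).reshape(n, nb).mean(axis=1)
            phi[:, j] += cur - prev
            prev = cur
    return phi / n_perm
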