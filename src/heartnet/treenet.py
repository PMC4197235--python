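"""Directed, signed gene-gene association networks via model trees.

Each gene in turn is treated as the regression target of a model tree
(piecewise-linear regression tree in the M5' family): recursive splits
maximise the standard-deviation reduction
SDR = sd(T) - sum_i (|T_i|/|T|) * sd(T_i), splitting stops when a node's
sd falls below 5% of the root sd or the node is too small, node linear
models use only predictors appearing in splits of the subtree (with
greedy backward attribute elimination under the (n+v)/(n-v) adjusted
error factor), subtrees whose estimated error exceeds the node model's
are pruned, and predictions are smoothed along the root path.

Targets whose tree has relative error above theta contribute no edges;
the linear dependency of each retained (predictor, target) pair is
tested by the two-sided correlation t-test and the family of p-values
is adjusted by the Benjamini-Yekutieli procedure, valid under the
arbitrary dependence of co-expression data.  Edge direction UP/DOWN is
the sign of the dependency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .study import ExpressionStudy


# ----------------------------------------------------------------------
# Model tree
# ----------------------------------------------------------------------

@dataclass
class _Node:
    indices: np.ndarray
    split_attr: int | None = None
    split_val: float = np.nan
    left: "_Node | None" = None
    right: "_Node | None" = None
    # linear model over `attrs` (column indices into X): y ~ intercept + X[:, attrs] @ coef
    attrs: list[int] = field(default_factory=list)
    coef: np.ndarray | None = None
    intercept: float = 0.0
    is_leaf: bool = False

    @property
    def n(self) -> int:
        return self.indices.size


@dataclass
class ModelTree:
    """Fitted model tree for one target gene."""

    root: _Node
    predictor_names: list[str]
    target: str
    relative_error: float
    smoothing_k: float = 15.0

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.array([self._predict_one(x) for x in X])

    def _node_value(self, node: _Node, x: np.ndarray) -> float:
        v = node.intercept
        if node.attrs:
            v += float(np.dot(x[node.attrs], node.coef))
        return v

    def _predict_one(self, x: np.ndarray) -> float:
        # descend, then smooth leaf prediction back up the path
        path = []
        node = self.root
        while not node.is_leaf:
            path.append(node)
            node = node.left if x[node.split_attr] <= node.split_val else node.right
        pred = self._node_value(node, x)
        n = node.n
        for parent in reversed(path):
            pred = (n * pred + self.smoothing_k * self._node_value(parent, x)) / (n + self.smoothing_k)
            n = parent.n
        return pred

    def leaves(self) -> list[_Node]:
        out = []

        def rec(node):
            if node.is_leaf:
                out.append(node)
            else:
                rec(node.left)
                rec(node.right)

        rec(self.root)
        return out

    def used_predictors(self) -> dict[str, float]:
        """Predictor -> size-weighted mean leaf coefficient (nonzero only)."""
        acc: dict[int, float] = {}
        wts: dict[int, float] = {}
        for leaf in self.leaves():
            for a, c in zip(leaf.attrs, leaf.coef if leaf.coef is not None else []):
                if c != 0.0:
                    acc[a] = acc.get(a, 0.0) + leaf.n * float(c)
                    wts[a] = wts.get(a, 0.0) + leaf.n
        return {self.predictor_names[a]: acc[a] / wts[a] for a in acc}

    def dump(self) -> str:
        lines: list[str] = []

        def rec(node, depth):
            pad = "  " * depth
            if node.is_leaf:
                terms = " + ".join(
                    f"{c:.4g}*{self.predictor_names[a]}"
                    for a, c in zip(node.attrs, node.coef if node.coef is not None else [])
                )
                model = f"{node.intercept:.4g}" + (f" + {terms}" if terms else "")
                lines.append(f"{pad}LM(n={node.n}): {model}")
            else:
                lines.append(
                    f"{pad}{self.predictor_names[node.split_attr]} <= {node.split_val:.4g}"
                )
                rec(node.left, depth + 1)
                lines.append(f"{pad}else")
                rec(node.right, depth + 1)

        rec(self.root, 0)
        return "\n".join(lines)


def _sd(y: np.ndarray) -> float:
    return float(np.std(y)) if y.size > 1 else 0.0


def _adjusted_mae(y: np.ndarray, pred: np.ndarray, n_params: int) -> float:
    n = y.size
    mae = float(np.mean(np.abs(y - pred)))
    denom = n - n_params
    factor = (n + n_params) / denom if denom > 0 else np.inf
    return mae * factor


def _fit_linear(X: np.ndarray, y: np.ndarray, attrs: list[int]) -> tuple[list[int], np.ndarray, float]:
    """Least-squares model on ``attrs`` with greedy backward elimination
    under the adjusted-MAE criterion; may reduce to a constant."""

    def fit(cols):
        if not cols:
            return np.zeros(0), float(np.mean(y))
        A = np.column_stack([X[:, cols], np.ones(y.size)])
        sol, *_ = np.linalg.lstsq(A, y, rcond=None)
        return sol[:-1], float(sol[-1])

    cols = list(attrs)
    coef, icpt = fit(cols)
    pred = X[:, cols] @ coef + icpt if cols else np.full(y.size, icpt)
    best_err = _adjusted_mae(y, pred, len(cols) + 1)
    improved = True
    while improved and cols:
        improved = False
        for drop in list(cols):
            trial = [c for c in cols if c != drop]
            tc, ti = fit(trial)
            tp = X[:, trial] @ tc + ti if trial else np.full(y.size, ti)
            err = _adjusted_mae(y, tp, len(trial) + 1)
            if err <= best_err + 1e-12:
                cols, coef, icpt, best_err = trial, tc, ti, err
                improved = True
                break
    coef = np.where(np.abs(coef) < 1e-10, 0.0, coef)
    keep = [c for c, v in zip(cols, coef) if v != 0.0]
    coef = coef[coef != 0.0]
    return keep, coef, icpt


def build_model_tree(
    target: str,
    study: ExpressionStudy,
    predictors: list[str] | None = None,
    min_leaf: int = 4,
    sd_fraction: float = 0.05,
    smoothing_k: float = 15.0,
) -> ModelTree:
    """Fit a model tree for ``target`` from the remaining genes.

    ``predictors`` defaults to every other feature in the study.
    A constant target yields a single-leaf constant model.
    """
    feats = list(study.values.index)
    if target not in feats:
        raise ValueError(f"target {target!r} not in study")
    if predictors is None:
        predictors = [f for f in feats if f != target]
    if target in predictors:
        raise ValueError("target cannot be its own predictor")
    y = study.values.loc[target].to_numpy(dtype=float)
    X = study.values.loc[predictors].to_numpy(dtype=float).T  # samples x predictors
    n = y.size
    if n < 2 * min_leaf:
        min_leaf = max(1, n // 2)
    root_sd = _sd(y)

    def grow(idx: np.ndarray) -> _Node:
        node = _Node(indices=idx)
        yy = y[idx]
        if idx.size < 2 * min_leaf or _sd(yy) < sd_fraction * root_sd:
            node.is_leaf = True
            return node
        best = None  # (sdr, attr, threshold, left_idx, right_idx)
        base = _sd(yy)
        for a in range(X.shape[1]):
            xa = X[idx, a]
            order = np.argsort(xa, kind="mergesort")
            xs = xa[order]
            for cut in range(min_leaf - 1, idx.size - min_leaf):
                if xs[cut] == xs[cut + 1]:
                    continue
                thr = (xs[cut] + xs[cut + 1]) / 2.0
                li = idx[order[: cut + 1]]
                ri = idx[order[cut + 1 :]]
                sdr = base - (li.size * _sd(y[li]) + ri.size * _sd(y[ri])) / idx.size
                if best is None or sdr > best[0] + 1e-12:
                    best = (sdr, a, thr, li, ri)
        if best is None or best[0] <= 1e-12:
            node.is_leaf = True
            return node
        _, a, thr, li, ri = best
        node.split_attr = a
        node.split_val = thr
        node.left = grow(li)
        node.right = grow(ri)
        return node

    root = grow(np.arange(n))

    def subtree_attrs(node: _Node) -> set[int]:
        if node.is_leaf:
            return set()
        return {node.split_attr} | subtree_attrs(node.left) | subtree_attrs(node.right)

    def fit_models_and_prune(node: _Node) -> tuple[float, int]:
        """Fit node model; prune a subtree when the node model's
        adjusted error does not exceed the subtree's, where the
        subtree's (n+v)/(n-v) factor counts every parameter below it
        (leaf coefficients, intercepts and split thresholds).
        Returns (sum of absolute residuals, parameter count) of the
        kept structure."""
        idx = node.indices
        attrs = sorted(subtree_attrs(node))
        keep, coef, icpt = _fit_linear(X[idx], y[idx], attrs)
        node.attrs, node.coef, node.intercept = keep, coef, icpt
        pred = X[np.ix_(idx, keep)] @ coef + icpt if keep else np.full(idx.size, icpt)
        model_abs = float(np.sum(np.abs(y[idx] - pred)))
        model_params = len(keep) + 1
        if node.is_leaf:
            return model_abs, model_params
        la, lp = fit_models_and_prune(node.left)
        ra, rp = fit_models_and_prune(node.right)
        sub_abs, sub_params = la + ra, lp + rp + 1  # +1 for the split
        n = idx.size

        def adj(abs_err, n_params):
            denom = n - n_params
            factor = (n + n_params) / denom if denom > 0 else np.inf
            return (abs_err / n) * factor

        if adj(model_abs, model_params) <= adj(sub_abs, sub_params) + 1e-12:
            node.is_leaf = True
            node.left = node.right = None
            return model_abs, model_params
        return sub_abs, sub_params

    fit_models_and_prune(root)
    tree = ModelTree(
        root=root,
        predictor_names=list(predictors),
        target=target,
        relative_error=np.nan,
        smoothing_k=smoothing_k,
    )
    tree.relative_error = tree_relative_error(tree, study)
    return tree


def relative_error(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute prediction error over mean absolute deviation of
    the target from its mean; 0 for a zero-variance target."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mad = float(np.mean(np.abs(y_true - y_true.mean())))
    if mad == 0.0:
        return 0.0
    return float(np.mean(np.abs(y_true - y_pred))) / mad


def tree_relative_error(tree: ModelTree, study: ExpressionStudy) -> float:
    y = study.values.loc[tree.target].to_numpy(dtype=float)
    X = study.values.loc[tree.predictor_names].to_numpy(dtype=float).T
    return relative_error(y, tree.predict(X))


# ----------------------------------------------------------------------
# FDR under dependence and network assembly
# ----------------------------------------------------------------------

def adjust_fdr_by(p_values) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment (harmonic correction)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or np.isnan(p).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_by")[1]


@dataclass
class DirectedAssociation:
    source: str
    target: str
    slope: float
    direction: str  # "UP" (positive) or "DOWN" (negative)
    p: float
    p_adj: float


def infer_directed_network(
    study: ExpressionStudy,
    genes: list[str] | None = None,
    theta: float = 0.30,
    alpha: float = 0.05,
    min_leaf: int = 4,
) -> list[DirectedAssociation]:
    """Model tree per target; gate by relative error theta; test each
    (predictor, target) linear dependency; keep BY-adjusted p < alpha."""
    ids = list(genes) if genes is not None else list(study.values.index)
    if len(ids) < 2:
        raise ValueError("need at least two genes")
    sub = study.subset_features(ids)
    vals = sub.values
    n = vals.shape[1]
    candidates: list[tuple[str, str, float, float]] = []  # source, target, slope, raw p
    for target in ids:
        tree = build_model_tree(target, sub, min_leaf=min_leaf)
        if tree.relative_error > theta:
            continue
        for pred, slope in sorted(tree.used_predictors().items()):
            x = vals.loc[pred].to_numpy(dtype=float)
            y = vals.loc[target].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            r = max(min(r, 1.0), -1.0)
            if abs(r) >= 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(t), n - 2))
            candidates.append((pred, target, slope, p))
    if not candidates:
        return []
    p_adj = adjust_fdr_by([c[3] for c in candidates])
    out = []
    for (src, tgt, slope, p), pa in zip(candidates, p_adj):
        if pa < alpha:
            out.append(
                DirectedAssociation(
                    source=src,
                    target=tgt,
                    slope=float(slope),
                    direction="UP" if slope > 0 else "DOWN",
                    p=p,
                    p_adj=float(pa),
                )
            )
    return out


def associations_table(assocs: list[DirectedAssociation]) -> pd.DataFrame:
    return pd.DataFrame(
        [(a.source, a.target, a.slope, a.direction, a.p, a.p_adj) for a in assocs],
        columns=["source", "target", "slope", "direction", "p", "p_adj"],
    )
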