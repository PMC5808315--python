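"""Conditional inference tree over normalisation-inflation predictors.

Classifies Sharpe-Schoolfield fits by whether the nominal normalised rate
B0 exceeds the peak rate P_pk — the regime of severe inflation — from three
temperature differences: T_pk - T_h, T_pk - T_ref and T_h - T_ref.

The tree follows the conditional-inference recipe: at each node, each
predictor is tested for association with the binary label by a permutation
test on the absolute difference of class means, the three p-values are
Bonferroni-adjusted, and the node is split on the winning predictor only
when the evidence is overwhelming (adjusted p below ``alpha``, default
1e-10).  Because 1e-10 is far below Monte-Carlo resolution, the stopping
rule is operationalised as a dual criterion: a normal-approximation p-value
below ``alpha`` AND an observed statistic exceeding every one of the
Monte-Carlo permutation statistics.  For tiny nodes (n <= 10) the
permutation distribution is enumerated exactly.

Split thresholds are searched over midpoints of consecutive observed values
of the winning predictor, maximising the standardised two-sample statistic;
ties at a threshold route left (<=).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .fit import SSFitResult
from .models import NoPeakError, p_pk, t_pk

__all__ = [
    "TreeInstance",
    "TreeNode",
    "TreeResults",
    "ConditionalInferenceTree",
    "label_fit",
    "instances_from_fits",
    "train_ctree",
    "mcc",
    "PREDICTOR_NAMES",
]

PREDICTOR_NAMES = ("d_pk_h", "d_pk_ref", "d_h_ref")


@dataclass(frozen=True)
class TreeInstance:
    """One training/testing instance: predictor differences (kelvin) + label.

    ``label`` is True when B0 exceeds the peak rate P_pk.
    """

    d_pk_h: float
    d_pk_ref: float
    d_h_ref: float
    label: bool
    curve_id: str | None = None

    @property
    def predictors(self) -> np.ndarray:
        return np.array([self.d_pk_h, self.d_pk_ref, self.d_h_ref])


def label_fit(fit: SSFitResult) -> TreeInstance:
    """Build a tree instance from a converged fit with a defined peak.

    The label is the exact comparison B0 > P_pk; ties (within 1e-12
    relative) are labelled False ("below").
    """
    if fit.params is None:
        raise ValueError("cannot label an unconverged fit")
    params = fit.params
    try:
        tpk = t_pk(params)
        ppk = p_pk(params)
    except (NoPeakError, ValueError) as err:
        raise NoPeakError(f"fit {fit.curve.curve_id!r} has no peak") from err
    label = params.B0 > ppk * (1.0 + 1e-12)
    return TreeInstance(
        d_pk_h=tpk - params.T_h,
        d_pk_ref=tpk - params.T_ref,
        d_h_ref=params.T_h - params.T_ref,
        label=bool(label),
        curve_id=fit.curve.curve_id,
    )


def instances_from_fits(fits: Sequence[SSFitResult]
                        ) -> tuple[list[TreeInstance], int]:
    """Label every fit that has a peak; returns (instances, n_skipped)."""
    out, skipped = [], 0
    for fit in fits:
        if fit.params is None or not fit.params.has_peak:
            skipped += 1
            continue
        try:
            out.append(label_fit(fit))
        except NoPeakError:
            skipped += 1
    return out, skipped


def mcc(truth: Sequence[bool], pred: Sequence[bool]) -> float:
    """Matthews correlation coefficient in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero factor in
    the denominator yields 0 by convention.
    """
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(pred, dtype=bool)
    if t.shape != p.shape or t.size == 0:
        raise ValueError("truth and pred must be equal-length, non-empty")
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class TreeNode:
    """A node of the fitted tree; internal nodes carry the split record."""

    n: int
    counts: tuple[int, int]  # (n False, n True)
    feature: int | None = None
    threshold: float | None = None
    p_adjusted: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def majority(self) -> bool:
        return self.counts[1] > self.counts[0]

    def to_dict(self) -> dict:
        d = {"n": self.n, "counts": list(self.counts)}
        if self.is_leaf:
            d["majority"] = self.majority
        else:
            d.update(
                predictor=PREDICTOR_NAMES[self.feature],
                threshold=self.threshold,
                p_adjusted=self.p_adjusted,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


def _perm_pvalue_normal(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Observed |mean difference| and its normal-approximation p-value."""
    n = x.size
    n1 = int(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0, 1.0
    stat = abs(x[y].mean() - x[~y].mean())
    s2 = x.var(ddof=1)
    if s2 <= 0:
        return stat, 1.0
    se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n0))
    z = stat / se
    return stat, float(2.0 * sps.norm.sf(z))


def _perm_exceedances_mc(x: np.ndarray, y: np.ndarray, stat: float,
                         n_perm: int, rng: np.random.Generator) -> int:
    """Count Monte-Carlo permutation statistics >= the observed one."""
    n = x.size
    n1 = int(y.sum())
    total = x.sum()
    count = 0
    idx = np.arange(n)
    for _ in range(n_perm):
        rng.shuffle(idx)
        s1 = x[idx[:n1]].sum()
        d = abs(s1 / n1 - (total - s1) / (n - n1))
        if d >= stat - 1e-12:
            count += 1
    return count


def _perm_pvalue_exact(x: np.ndarray, y: np.ndarray, stat: float) -> float:
    """Exact permutation p by enumerating all label assignments (n <= 10)."""
    n = x.size
    n1 = int(y.sum())
    total = x.sum()
    hits = 0
    n_comb = 0
    for subset in combinations(range(n), n1):
        s1 = x[list(subset)].sum()
        d = abs(s1 / n1 - (total - s1) / (n - n1))
        n_comb += 1
        if d >= stat - 1e-12:
            hits += 1
    return hits / n_comb


def _best_threshold(x: np.ndarray, y: np.ndarray) -> float | None:
    """Midpoint threshold maximising |p_left - p_right| * sqrt(nL*nR/n)."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order].astype(float)
    n = xs.size
    cum = np.cumsum(ys)
    # candidate cut after position i (0-based), only between distinct values
    distinct = xs[:-1] < xs[1:]
    if not distinct.any():
        return None
    i = np.nonzero(distinct)[0]
    n_l = i + 1.0
    n_r = n - n_l
    p_l = cum[i] / n_l
    p_r = (cum[-1] - cum[i]) / n_r
    score = np.abs(p_l - p_r) * np.sqrt(n_l * n_r / n)
    best = int(i[np.argmax(score)])
    return float((xs[best] + xs[best + 1]) / 2.0)


@dataclass
class TreeResults:
    """A fitted conditional inference tree.

    Provides prediction, text/JSON serialisation and training diagnostics.
    """

    root: TreeNode
    alpha: float
    n_train: int

    def predict_one(self, predictors: np.ndarray) -> bool:
        node = self.root
        while not node.is_leaf:
            node = node.left if predictors[node.feature] <= node.threshold else node.right
        return node.majority

    def predict(self, X) -> np.ndarray:
        X = _as_matrix(X)
        return np.array([self.predict_one(row) for row in X], dtype=bool)

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def to_json(self) -> str:
        return json.dumps({"alpha": self.alpha, "n_train": self.n_train,
                           "tree": self.root.to_dict()}, indent=2)

    def summary(self) -> str:
        lines = [f"Conditional inference tree (alpha={self.alpha:g}, "
                 f"n={self.n_train})"]

        def walk(node, indent):
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}leaf: n={node.n} counts(below,above)="
                             f"{node.counts} -> {'above' if node.majority else 'below'}")
            else:
                lines.append(f"{pad}{PREDICTOR_NAMES[node.feature]} <= "
                             f"{node.threshold:.4g} (p_adj={node.p_adjusted:.3g}, "
                             f"n={node.n})")
                walk(node.left, indent + 1)
                walk(node.right, indent + 1)

        walk(self.root, 1)
        return "\n".join(lines)


def _as_matrix(X) -> np.ndarray:
    if hasattr(X, "to_numpy"):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X


class ConditionalInferenceTree:
    """Model object: fit a conditional inference tree to (X, y).

    Parameters
    ----------
    X : array-like, shape (n, 3)
        Predictor matrix with columns (d_pk_h, d_pk_ref, d_h_ref); a
        DataFrame with those columns or a list of :class:`TreeInstance`
        also works.
    y : array-like of bool
        Binary labels (True = B0 above P_pk).  Not needed when ``X`` is a
        list of instances.
    alpha : float
        Maximum Bonferroni-adjusted node p-value allowed for a split.
    min_node_size : int
        Nodes smaller than this become leaves without testing.
    n_permutations : int
        Monte-Carlo permutations confirming each split.
    seed : int
        Seed for the permutation stream.
    """

    def __init__(self, X, y=None, alpha: float = 1e-10,
                 min_node_size: int = 20, n_permutations: int = 100_000,
                 seed: int = 0):
        if y is None and isinstance(X, (list, tuple)) and X \
                and isinstance(X[0], TreeInstance):
            y = [inst.label for inst in X]
            X = [[inst.d_pk_h, inst.d_pk_ref, inst.d_h_ref] for inst in X]
        self.X = _as_matrix(X)
        self.y = np.asarray(y, dtype=bool)
        if self.X.shape[0] != self.y.size:
            raise ValueError("X and y lengths differ")
        if self.X.shape[1] != 3:
            raise ValueError("expected exactly 3 predictors")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("predictors must be finite")
        self.alpha = alpha
        self.min_node_size = min_node_size
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self) -> TreeResults:
        rng = np.random.default_rng(self.seed)
        root = self._grow(self.X, self.y, rng)
        return TreeResults(root=root, alpha=self.alpha, n_train=self.y.size)

    # -- recursive partitioning -------------------------------------------

    def _node_test(self, x: np.ndarray, y: np.ndarray,
                   rng: np.random.Generator) -> tuple[float, float]:
        """(observed statistic, unadjusted p) for one predictor at a node.

        The p-value is exact for n <= 10; otherwise the normal-approximation
        p, confirmed by Monte-Carlo only when it undercuts ``alpha`` (the
        dual criterion): if any permutation statistic reaches the observed
        one, the p is floored at the Monte-Carlo resolution, which blocks
        the split.
        """
        n = x.size
        stat, p_norm = _perm_pvalue_normal(x, y)
        if n <= 10:
            return stat, _perm_pvalue_exact(x, y, stat)
        if p_norm * 3.0 >= self.alpha:  # cannot pass even before adjustment
            return stat, p_norm
        exceed = _perm_exceedances_mc(x, y, stat, self.n_permutations, rng)
        if exceed > 0:
            return stat, max(p_norm, (exceed + 1) / (self.n_permutations + 1))
        return stat, p_norm

    def _grow(self, X: np.ndarray, y: np.ndarray,
              rng: np.random.Generator) -> TreeNode:
        n = y.size
        counts = (int(np.sum(~y)), int(np.sum(y)))
        node = TreeNode(n=n, counts=counts)
        if n < self.min_node_size or counts[0] == 0 or counts[1] == 0:
            return node
        pvals = []
        for jcol in range(3):
            _, p = self._node_test(X[:, jcol], y, rng)
            pvals.append(min(p * 3.0, 1.0))  # Bonferroni across 3 predictors
        j_best = int(np.argmin(pvals))
        if pvals[j_best] >= self.alpha:
            return node
        thr = _best_threshold(X[:, j_best], y)
        if thr is None:
            return node
        mask = X[:, j_best] <= thr
        if mask.all() or not mask.any():
            return node
        node.feature = j_best
        node.threshold = thr
        node.p_adjusted = pvals[j_best]
        node.left = self._grow(X[mask], y[mask], rng)
        node.right = self._grow(X[~mask], y[~mask], rng)
        return node


def train_ctree(instances: Sequence[TreeInstance], alpha: float = 1e-10,
                seed: int = 0, **kwargs) -> TreeResults:
    """Train a tree from labelled instances (functional wrapper)."""
    if len(instances) < 1:
        raise ValueError("need at least one instance")
    return ConditionalInferenceTree(list(instances), alpha=alpha, seed=seed,
                                    **kwargs).fit()
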