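"""Linear support-vector machines on precomputed Gram matrices.

The binary classifier is a soft-margin (C-)SVM solved in the dual with an
SMO solver (maximal-violating-pair working-set selection, the libsvm
formulation), operating on a linear-kernel Gram matrix.  Solving on the Gram
matrix lets the leave-one-trial-out and permutation machinery reuse
precomputed fold-normalized kernels, which is what makes label-permutation
inference affordable.

Multiclass classification is one-vs-one with majority vote: one binary
max-margin classifier per unordered class pair, ties broken by the summed
signed decision values and then by lexicographic class order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .exceptions import DegenerateLabelsError, InvalidParameterError, ShapeError

_TAU = 1e-12


@njit(cache=True)
def smo_iterate(K, y, C, tol, max_iter, alpha, G, skip):
    """Run SMO working-set iterations in place.

    ``alpha`` must be feasible and ``G`` its gradient (Q alpha - e); both are
    updated.  ``skip`` freezes one variable index (-1 for none), which turns
    the solver into a leave-one-point-out refit on an unchanged kernel.
    """
    n = K.shape[0]
    for _ in range(max_iter):
        # first-order max violator i over I_up, plus the stopping gap
        gmax = -1e300
        gmin = 1e300
        i = -1
        for t in range(n):
            if t == skip:
                continue
            yt = y[t]
            if (yt > 0 and alpha[t] < C) or (yt < 0 and alpha[t] > 0):
                v = -yt * G[t]
                if v > gmax:
                    gmax = v
                    i = t
            if (yt > 0 and alpha[t] > 0) or (yt < 0 and alpha[t] < C):
                v = -yt * G[t]
                if v < gmin:
                    gmin = v
        if i == -1 or gmax - gmin < tol:
            break
        # second-order selection of j (libsvm WSS2): maximize b^2 / a among
        # violating candidates in I_low
        j = -1
        best = -1e300
        Kii = K[i, i]
        for t in range(n):
            if t == skip:
                continue
            yt = y[t]
            if (yt > 0 and alpha[t] > 0) or (yt < 0 and alpha[t] < C):
                b = gmax + yt * G[t]
                if b > 0:
                    a = Kii + K[t, t] - 2.0 * y[i] * yt * K[i, t]
                    if a <= 0:
                        a = _TAU
                    gain = b * b / a
                    if gain > best:
                        best = gain
                        j = t
        if j == -1:
            break
        old_ai = alpha[i]
        old_aj = alpha[j]
        if y[i] != y[j]:
            quad = K[i, i] + K[j, j] + 2.0 * y[i] * y[j] * K[i, j]
            if quad <= 0:
                quad = _TAU
            delta = (-G[i] - G[j]) / quad
            diff = alpha[i] - alpha[j]
            alpha[i] += delta
            alpha[j] += delta
            if diff > 0:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = diff
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = -diff
            if diff > 0:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = C - diff
            else:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = C + diff
        else:
            quad = K[i, i] + K[j, j] - 2.0 * y[i] * y[j] * K[i, j]
            if quad <= 0:
                quad = _TAU
            delta = (G[i] - G[j]) / quad
            s = alpha[i] + alpha[j]
            alpha[i] -= delta
            alpha[j] += delta
            if s > C:
                if alpha[i] > C:
                    alpha[i] = C
                    alpha[j] = s - C
            else:
                if alpha[j] < 0:
                    alpha[j] = 0.0
                    alpha[i] = s
            if s > C:
                if alpha[j] > C:
                    alpha[j] = C
                    alpha[i] = s - C
            else:
                if alpha[i] < 0:
                    alpha[i] = 0.0
                    alpha[j] = s
        dai = alpha[i] - old_ai
        daj = alpha[j] - old_aj
        for t in range(n):
            G[t] += y[t] * (y[i] * K[i, t] * dai + y[j] * K[j, t] * daj)


@njit(cache=True)
def smo_rho(y, alpha, G, C, skip):
    """Bias term of the converged solution (libsvm's rho), excluding a
    frozen index."""
    n = y.shape[0]
    ub = 1e300
    lb = -1e300
    sum_free = 0.0
    n_free = 0
    for t in range(n):
        if t == skip:
            continue
        yg = y[t] * G[t]
        if alpha[t] >= C:
            if y[t] < 0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        elif alpha[t] <= 0:
            if y[t] > 0:
                if yg < ub:
                    ub = yg
            else:
                if yg > lb:
                    lb = yg
        else:
            n_free += 1
            sum_free += yg
    if n_free > 0:
        return sum_free / n_free
    return (ub + lb) / 2.0


@njit(cache=True)
def smo_warm(K, y, C, tol, max_iter, alpha):
    """SMO on kernel ``K`` starting from a feasible ``alpha`` (modified in
    place); returns the bias term rho.

    ``alpha`` must satisfy the box constraints and ``sum(alpha * y) == 0``;
    warm starts from a nearby problem's solution cut iteration counts by an
    order of magnitude in leave-one-out sweeps.
    """
    n = K.shape[0]
    G = np.empty(n)
    for t in range(n):
        g = -1.0
        for s in range(n):
            if alpha[s] != 0.0:
                g += y[t] * y[s] * K[t, s] * alpha[s]
        G[t] = g
    smo_iterate(K, y, C, tol, max_iter, alpha, G, -1)
    return smo_rho(y, alpha, G, C, -1)


@njit(cache=True)
def smo_solve(K, y, C, tol, max_iter):
    """Solve the dual C-SVM on kernel ``K`` with labels ``y`` in {-1, +1}.

    Returns (alpha, rho); the decision value of a point with kernel row k is
    ``sum(alpha * y * k) - rho``, positive for the +1 class.
    """
    alpha = np.zeros(K.shape[0])
    rho = smo_warm(K, y, C, tol, max_iter, alpha)
    return alpha, rho


class BinaryLinearSVM:
    """Two-class linear soft-margin SVM.

    The positive decision side corresponds to the lexicographically larger
    class (``classes_[1]``), matching the usual scikit-learn orientation.
    """

    def __init__(self, cost: float = 1.0, tol: float = 1e-4,
                 max_iter: int = 100_000):
        if cost <= 0:
            raise InvalidParameterError("cost must be > 0")
        self.cost = float(cost)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self, X, labels):
        X = np.asarray(X, dtype=np.float64)
        labels = np.asarray(labels)
        if X.ndim != 2 or X.shape[0] != labels.shape[0]:
            raise ShapeError("X must be 2-D with one row per label")
        self.classes_ = np.unique(labels)
        if self.classes_.size != 2:
            raise DegenerateLabelsError(
                f"binary SVM needs exactly 2 classes, got {self.classes_.size}"
            )
        y = np.where(labels == self.classes_[1], 1.0, -1.0)
        K = X @ X.T
        alpha, rho = smo_solve(K, y, self.cost, self.tol, self.max_iter)
        self.alpha_ = alpha
        self.coef_ = (alpha * y) @ X
        self.intercept_ = -rho
        self._X = X
        self._y = y
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


class PairwiseVotingSVM:
    """One-vs-one multiclass linear SVM with majority vote.

    A binary classifier is trained for every unordered class pair; a point's
    class is the one with most pairwise votes.  Vote ties are broken by the
    summed signed decision values toward each class, residual ties by
    lexicographic class order.
    """

    def __init__(self, cost: float = 1.0, tol: float = 1e-4,
                 max_iter: int = 100_000):
        if cost <= 0:
            raise InvalidParameterError("cost must be > 0")
        self.cost = float(cost)
        self.tol = float(tol)
        self.max_iter = int(max_iter)

    def fit(self, X, labels):
        X = np.asarray(X, dtype=np.float64)
        labels = np.asarray(labels)
        self.classes_ = np.unique(labels)
        if self.classes_.size < 2:
            raise DegenerateLabelsError("training requires at least 2 classes")
        self.pair_models_ = {}
        for ia in range(self.classes_.size):
            for ib in range(ia + 1, self.classes_.size):
                a, b = self.classes_[ia], self.classes_[ib]
                sel = (labels == a) | (labels == b)
                clf = BinaryLinearSVM(self.cost, self.tol, self.max_iter)
                clf.fit(X[sel], labels[sel])
                self.pair_models_[(a, b)] = clf
        return self

    def vote_matrix(self, X):
        """Per-sample (votes, signed-decision scores) over classes."""
        X = np.asarray(X, dtype=np.float64)
        n = X.shape[0]
        k = self.classes_.size
        votes = np.zeros((n, k))
        scores = np.zeros((n, k))
        index = {c: i for i, c in enumerate(self.classes_)}
        for (a, b), clf in self.pair_models_.items():
            d = clf.decision_function(X)  # positive -> b
            ia, ib = index[a], index[b]
            win_b = d > 0
            votes[win_b, ib] += 1
            votes[~win_b, ia] += 1
            scores[:, ib] += d
            scores[:, ia] -= d
        return votes, scores

    def predict(self, X):
        votes, scores = self.vote_matrix(X)
        n, k = votes.shape
        out = np.empty(n, dtype=self.classes_.dtype)
        for i in range(n):
            best = 0
            for c in range(1, k):
                if votes[i, c] > votes[i, best] or (
                    votes[i, c] == votes[i, best]
                    and scores[i, c] > scores[i, best]
                ):
                    best = c
            out[i] = self.classes_[best]
        return out


def train_linear_svm(patterns, labels, cost: float = 1.0) -> PairwiseVotingSVM:
    """Train a one-vs-one linear SVM on a trials x voxels matrix."""
    return PairwiseVotingSVM(cost=cost).fit(patterns, labels)
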