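"""Numba kernels for leave-one-trial-out decoding and label permutation.

The expensive object in this pipeline is the permutation test, which reruns
the full leave-one-trial-out one-vs-one SVM analysis for every label
permutation.  Two facts make this cheap:

* per-fold feature normalization (z-scoring with training-fold statistics)
  does not depend on the labels, so the fold-wise normalized Gram matrices
  can be computed once per participant and reused across all permutations;
* the dual SMO solver only needs Gram sub-blocks, which are index slices of
  those precomputed matrices.

``fold_grams`` builds the (n_folds, n, n) Gram stack in numpy; the numba
kernels below run the entire fold x pair x permutation loop without Python
overhead.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .svm import smo_iterate, smo_rho, smo_solve, smo_warm

N_CLASSES = 4


def fold_grams(P: np.ndarray, normalize: str = "zscore") -> np.ndarray:
    """Per-fold normalized Gram matrices, shape (n, n, n).

    Fold ``f``'s matrix is the Gram of all n trials after z-scoring every
    voxel with mean/sd computed over the n-1 training trials (the held-out
    trial's own values never enter its fold's statistics).  With
    ``normalize="none"`` every fold shares the raw Gram.
    """
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    if normalize == "none":
        G = P @ P.T
        return np.repeat(G[None], n, axis=0)
    if normalize != "zscore":
        raise ValueError(f"unknown normalization {normalize!r}")
    sums = P.sum(axis=0)
    sqs = (P * P).sum(axis=0)
    G3 = np.empty((n, n, n))
    cnt = n - 1
    for f in range(n):
        m = (sums - P[f]) / cnt
        var = (sqs - P[f] * P[f]) / cnt - m * m
        sd = np.sqrt(np.clip(var, 0.0, None))
        sd[sd < 1e-12] = 1.0
        Z = (P - m) / sd
        G3[f] = Z @ Z.T
    return G3


@njit(cache=True)
def loto_predict(G3, y, C, tol, max_iter):
    """Leave-one-trial-out one-vs-one predictions.

    ``G3`` is the per-fold Gram stack, ``y`` integer class codes (0..3).
    Fold f trains the six pairwise SVMs on all trials except f under fold-f
    normalization and predicts trial f by majority vote (ties: summed signed
    decision values, then smallest class index).

    The loop runs pair-outer / fold-inner so that consecutive folds differ
    only by the held-out trial and its normalization, letting each solve
    warm-start from the previous solution.  When the held-out trial belongs
    to the pair, the warm start drops its dual weight and repairs the
    equality constraint by redistributing that weight within the box.
    """
    n = y.shape[0]
    votes = np.zeros((n, N_CLASSES))
    score = np.zeros((n, N_CLASSES))
    members = np.empty(n, dtype=np.int64)
    for a in range(N_CLASSES):
        for b in range(a + 1, N_CLASSES):
            m = 0
            for t in range(n):
                if y[t] == a or y[t] == b:
                    members[m] = t
                    m += 1
            if m == 0:
                continue
            yv = np.empty(m)
            has_a = False
            has_b = False
            for p in range(m):
                if y[members[p]] == b:
                    yv[p] = 1.0
                    has_b = True
                else:
                    yv[p] = -1.0
                    has_a = True
            K = np.empty((m, m))
            kt = np.empty(m)
            alpha_full = np.zeros(m)
            warm = False
            mr = m - 1
            Kr = np.empty((mr, mr)) if mr > 0 else np.empty((0, 0))
            yr = np.empty(mr)
            ar = np.empty(mr)
            kr = np.empty(mr)
            idxr = np.empty(mr, dtype=np.int64)
            for f in range(n):
                Gf = G3[f]
                in_pair = y[f] == a or y[f] == b
                if not in_pair:
                    if not (has_a and has_b):
                        if has_b:
                            votes[f, b] += 1.0
                        else:
                            votes[f, a] += 1.0
                        continue
                    for p in range(m):
                        tp = members[p]
                        kt[p] = Gf[f, tp]
                        for q in range(p, m):
                            v = Gf[tp, members[q]]
                            K[p, q] = v
                            K[q, p] = v
                    if not warm:
                        for p in range(m):
                            alpha_full[p] = 0.0
                        warm = True
                    rho = smo_warm(K, yv, C, tol, max_iter, alpha_full)
                    d = -rho
                    for p in range(m):
                        d += alpha_full[p] * yv[p] * kt[p]
                    if d > 0:
                        votes[f, b] += 1.0
                    else:
                        votes[f, a] += 1.0
                    score[f, b] += d
                    score[f, a] -= d
                else:
                    if mr == 0:
                        continue
                    pf = -1
                    k2 = 0
                    has_ra = False
                    has_rb = False
                    for p in range(m):
                        if members[p] == f:
                            pf = p
                        else:
                            idxr[k2] = members[p]
                            yr[k2] = yv[p]
                            ar[k2] = alpha_full[p] if warm else 0.0
                            if yv[p] > 0:
                                has_rb = True
                            else:
                                has_ra = True
                            k2 += 1
                    if not (has_ra and has_rb):
                        if has_rb:
                            votes[f, b] += 1.0
                        elif has_ra:
                            votes[f, a] += 1.0
                        continue
                    if warm and pf >= 0:
                        # repair sum(alpha*y) == 0 after dropping pf's weight
                        r = alpha_full[pf]
                        ysign = yv[pf]
                        for p in range(mr):
                            if r <= 0.0:
                                break
                            if yr[p] == ysign and ar[p] < C:
                                add = C - ar[p]
                                if add > r:
                                    add = r
                                ar[p] += add
                                r -= add
                        for p in range(mr):
                            if r <= 0.0:
                                break
                            if yr[p] != ysign and ar[p] > 0.0:
                                sub = ar[p]
                                if sub > r:
                                    sub = r
                                ar[p] -= sub
                                r -= sub
                    for p in range(mr):
                        tp = idxr[p]
                        kr[p] = Gf[f, tp]
                        for q in range(p, mr):
                            v = Gf[tp, idxr[q]]
                            Kr[p, q] = v
                            Kr[q, p] = v
                    rho = smo_warm(Kr, yr, C, tol, max_iter, ar)
                    d = -rho
                    for p in range(mr):
                        d += ar[p] * yr[p] * kr[p]
                    if d > 0:
                        votes[f, b] += 1.0
                    else:
                        votes[f, a] += 1.0
                    score[f, b] += d
                    score[f, a] -= d
    pred = np.empty(n, dtype=np.int64)
    for f in range(n):
        best = 0
        for c in range(1, N_CLASSES):
            if votes[f, c] > votes[f, best] or (
                votes[f, c] == votes[f, best] and score[f, c] > score[f, best]
            ):
                best = c
        pred[f] = best
    return pred


@njit(cache=True)
def loto_predict_raw(G, y, C, tol, max_iter):
    """Leave-one-trial-out one-vs-one predictions on a fold-independent Gram.

    With raw (un-normalized) features the kernel does not depend on the
    fold, so each class pair is solved once on its full member set; folds
    whose held-out trial is outside the pair reuse that solution directly,
    and folds inside the pair refit with the held-out trial's dual variable
    frozen at zero, warm-starting from the full solution with the equality
    constraint repaired in place (gradient maintained incrementally).
    """
    n = y.shape[0]
    votes = np.zeros((n, N_CLASSES))
    score = np.zeros((n, N_CLASSES))
    members = np.empty(n, dtype=np.int64)
    for a in range(N_CLASSES):
        for b in range(a + 1, N_CLASSES):
            m = 0
            n_pos = 0
            n_neg = 0
            for t in range(n):
                if y[t] == a or y[t] == b:
                    members[m] = t
                    m += 1
                    if y[t] == b:
                        n_pos += 1
                    else:
                        n_neg += 1
            if m == 0:
                continue
            if n_pos == 0 or n_neg == 0:
                # degenerate pair: only one class present anywhere
                w = b if n_pos > 0 else a
                for f in range(n):
                    if not (y[f] == a or y[f] == b) or m > 1:
                        votes[f, w] += 1.0
                continue
            yv = np.empty(m)
            for p in range(m):
                yv[p] = 1.0 if y[members[p]] == b else -1.0
            K = np.empty((m, m))
            for p in range(m):
                tp = members[p]
                for q in range(p, m):
                    v = G[tp, members[q]]
                    K[p, q] = v
                    K[q, p] = v
            alpha = np.zeros(m)
            Gd = -np.ones(m)
            smo_iterate(K, yv, C, tol, max_iter, alpha, Gd, -1)
            rho_full = smo_rho(yv, alpha, Gd, C, -1)
            # folds outside the pair share one classifier
            for f in range(n):
                if y[f] == a or y[f] == b:
                    continue
                d = -rho_full
                for p in range(m):
                    d += alpha[p] * yv[p] * G[f, members[p]]
                if d > 0:
                    votes[f, b] += 1.0
                else:
                    votes[f, a] += 1.0
                score[f, b] += d
                score[f, a] -= d
            # folds inside the pair: frozen-variable leave-one-out refits
            asave = np.empty(m)
            gsave = np.empty(m)
            for pf in range(m):
                f = members[pf]
                if (yv[pf] > 0 and n_pos == 1) or (yv[pf] < 0 and n_neg == 1):
                    # training set degenerates to one class
                    w = a if yv[pf] > 0 else b
                    votes[f, w] += 1.0
                    continue
                for p in range(m):
                    asave[p] = alpha[p]
                    gsave[p] = Gd[p]
                r = alpha[pf]
                if r != 0.0:
                    ysign = yv[pf]
                    for t2 in range(m):
                        Gd[t2] -= yv[t2] * ysign * K[pf, t2] * r
                    alpha[pf] = 0.0
                    for p in range(m):
                        if r <= 0.0:
                            break
                        if p != pf and yv[p] == ysign and alpha[p] < C:
                            add = C - alpha[p]
                            if add > r:
                                add = r
                            alpha[p] += add
                            r -= add
                            for t2 in range(m):
                                Gd[t2] += yv[t2] * ysign * K[p, t2] * add
                    for p in range(m):
                        if r <= 0.0:
                            break
                        if p != pf and yv[p] != ysign and alpha[p] > 0.0:
                            sub = alpha[p]
                            if sub > r:
                                sub = r
                            alpha[p] -= sub
                            r -= sub
                            for t2 in range(m):
                                Gd[t2] += yv[t2] * ysign * K[p, t2] * sub
                smo_iterate(K, yv, C, tol, max_iter, alpha, Gd, pf)
                rho = smo_rho(yv, alpha, Gd, C, pf)
                d = -rho
                for p in range(m):
                    if p != pf:
                        d += alpha[p] * yv[p] * K[pf, p]
                if d > 0:
                    votes[f, b] += 1.0
                else:
                    votes[f, a] += 1.0
                score[f, b] += d
                score[f, a] -= d
                for p in range(m):
                    alpha[p] = asave[p]
                    Gd[p] = gsave[p]
    pred = np.empty(n, dtype=np.int64)
    for f in range(n):
        best = 0
        for c in range(1, N_CLASSES):
            if votes[f, c] > votes[f, best] or (
                votes[f, c] == votes[f, best] and score[f, c] > score[f, best]
            ):
                best = c
        pred[f] = best
    return pred


@njit(cache=True)
def perm_fourway_acc_raw(G, label_perms, C, tol, max_iter):
    """Four-way LOTO accuracy per permuted label row, raw-feature Gram."""
    R = label_perms.shape[0]
    acc = np.empty(R)
    for r in range(R):
        y = label_perms[r]
        pred = loto_predict_raw(G, y, C, tol, max_iter)
        correct = 0
        for t in range(y.shape[0]):
            if pred[t] == y[t]:
                correct += 1
        acc[r] = correct / y.shape[0]
    return acc


@njit(cache=True)
def perm_fourway_acc(G3, label_perms, C, tol, max_iter):
    """Four-way LOTO accuracy for each row of permuted class codes."""
    R = label_perms.shape[0]
    acc = np.empty(R)
    for r in range(R):
        y = label_perms[r]
        pred = loto_predict(G3, y, C, tol, max_iter)
        correct = 0
        for t in range(y.shape[0]):
            if pred[t] == y[t]:
                correct += 1
        acc[r] = correct / y.shape[0]
    return acc


@njit(cache=True)
def transfer_acc_one(P, y, train0, train1, test0, test1,
                     C, tol, max_iter, zscore):
    """Cross-classification accuracy for one label assignment.

    Trains ``train0`` (negative side) vs ``train1`` (positive side) and
    scores test trials of class ``test0``/``test1`` as correct when the
    predicted training class maps to them via the shared factor
    (train0 -> test0, train1 -> test1).  Feature z-scoring uses
    training-trial statistics only.
    """
    n, v = P.shape
    tr_idx = np.empty(n, dtype=np.int64)
    te_idx = np.empty(n, dtype=np.int64)
    m = 0
    q = 0
    for t in range(n):
        if y[t] == train0 or y[t] == train1:
            tr_idx[m] = t
            m += 1
        elif y[t] == test0 or y[t] == test1:
            te_idx[q] = t
            q += 1
    if m == 0 or q == 0:
        return np.nan
    mean = np.zeros(v)
    sd = np.ones(v)
    if zscore:
        for p in range(m):
            row = P[tr_idx[p]]
            for j in range(v):
                mean[j] += row[j]
        for j in range(v):
            mean[j] /= m
        var = np.zeros(v)
        for p in range(m):
            row = P[tr_idx[p]]
            for j in range(v):
                d = row[j] - mean[j]
                var[j] += d * d
        for j in range(v):
            s = np.sqrt(var[j] / m)
            sd[j] = 1.0 if s < 1e-12 else s
    Ztr = np.empty((m, v))
    for p in range(m):
        row = P[tr_idx[p]]
        for j in range(v):
            Ztr[p, j] = (row[j] - mean[j]) / sd[j]
    Zte = np.empty((q, v))
    for s in range(q):
        row = P[te_idx[s]]
        for j in range(v):
            Zte[s, j] = (row[j] - mean[j]) / sd[j]
    K = Ztr @ Ztr.T
    yv = np.empty(m)
    has_pos = False
    has_neg = False
    for p in range(m):
        if y[tr_idx[p]] == train1:
            yv[p] = 1.0
            has_pos = True
        else:
            yv[p] = -1.0
            has_neg = True
    if not (has_pos and has_neg):
        return np.nan
    alpha, rho = smo_solve(K, yv, C, tol, max_iter)
    K_cross = Ztr @ Zte.T  # m x q
    correct = 0
    for s in range(q):
        d = -rho
        for p in range(m):
            d += alpha[p] * yv[p] * K_cross[p, s]
        pred_test = test1 if d > 0 else test0
        if pred_test == y[te_idx[s]]:
            correct += 1
    return correct / q


@njit(cache=True)
def perm_transfer_acc(P, label_perms, train0, train1, test0, test1,
                      C, tol, max_iter, zscore):
    """Transfer accuracy for each row of permuted class codes."""
    R = label_perms.shape[0]
    out = np.empty(R)
    for r in range(R):
        out[r] = transfer_acc_one(
            P, label_perms[r], train0, train1, test0, test1,
            C, tol, max_iter, zscore,
        )
    return out
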