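"""Fuzzy-weighted least-squares SVM classifier with K-fold evaluation.

The classifier is a TSK-style combination of per-rule LS-SVMs: fuzzy
c-means clustering (FCM) partitions the training inputs into C rules,
one RBF-kernel LS-SVM is fitted per rule with membership-weighted error
terms, and a new point's prediction is the membership-weighted average of
the per-rule outputs

    y_hat(x) = sum_i P_i(x) y_i(x) / sum_i P_i(x),

where P_i(x) = prod_t exp(-|x_t - theta_it| / beta_it), theta_i the rule
(cluster) center and beta_it the membership-weighted coordinate spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.model_selection import StratifiedKFold


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, gamma: float = 0.5) -> float:
    """Gaussian kernel exp(-gamma ||x1 - x2||^2)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape:
        raise ValueError("x1 and x2 must have equal dimension")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return float(np.exp(-gamma * np.sum((x1 - x2) ** 2)))


def _rbf_gram(X1: np.ndarray, X2: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(X1, X2, "sqeuclidean"))


@dataclass
class FCMModel:
    """Fuzzy c-means result: centers (C x d), memberships (C x n), J trace."""

    centers: np.ndarray
    memberships: np.ndarray
    m: float
    objective_trace: list[float] = field(default_factory=list)


def fcm_cluster(
    X: np.ndarray,
    C: int,
    m: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
    seed: int = 0,
) -> FCMModel:
    """Fuzzy c-means clustering minimizing J_m = sum mu_ij^m ||x_j - z_i||^2.

    Alternating updates with seeded random membership initialization; stops
    when the objective change falls below tol. Memberships always satisfy
    sum_i mu_ij = 1.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= C <= n:
        raise ValueError("require 1 <= C <= n samples")
    if m <= 1.0:
        raise ValueError("fuzzifier m must be > 1")
    if C == 1:
        centers = X.mean(axis=0, keepdims=True)
        mu = np.ones((1, n))
        J = float(np.sum((X - centers) ** 2))
        return FCMModel(centers=centers, memberships=mu, m=m, objective_trace=[J])
    if np.allclose(X, X[0]):
        raise ValueError("degenerate data: all points identical with C > 1")
    rng = np.random.default_rng(seed)
    mu = rng.random((C, n))
    mu /= mu.sum(axis=0)
    trace: list[float] = []
    centers = np.empty((C, X.shape[1]))
    for _ in range(max_iter):
        w = mu**m
        centers = (w @ X) / w.sum(axis=1, keepdims=True)
        d2 = cdist(centers, X, "sqeuclidean")
        J = float(np.sum(w * d2))
        trace.append(J)
        d2c = np.maximum(d2, 1e-300)
        inv = d2c ** (-1.0 / (m - 1.0))
        mu_new = inv / inv.sum(axis=0)
        zero = d2 <= 0.0  # point coincides with a center
        if zero.any():
            cols = zero.any(axis=0)
            mu_new[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0)
        mu = mu_new
        if len(trace) >= 2 and abs(trace[-2] - trace[-1]) < tol:
            break
    return FCMModel(centers=centers, memberships=mu, m=m, objective_trace=trace)


@dataclass
class WLSSVMModel:
    """Per-rule LS-SVM solutions plus the fuzzy membership geometry."""

    support_X: np.ndarray  # training inputs (n x d)
    alphas: np.ndarray  # per-rule dual coefficients (C x n)
    biases: np.ndarray  # per-rule biases (C,)
    centers: np.ndarray  # rule centers theta_i (C x d)
    spreads: np.ndarray  # beta_it > 0 (C x d)
    kernel_gamma: float
    penalty_c: float
    fcm: FCMModel


def _log_membership(X: np.ndarray, centers: np.ndarray, spreads: np.ndarray) -> np.ndarray:
    """log P_i(x) = -sum_t |x_t - theta_it| / beta_it, shape (C, n)."""
    # (C, n, d) broadcast kept small: C is the rule count (a few)
    diff = np.abs(X[None, :, :] - centers[:, None, :])
    return -(diff / spreads[:, None, :]).sum(axis=2)


def membership_grade(x: np.ndarray, model: WLSSVMModel) -> np.ndarray:
    """Fuzzy weights P_i(x) = prod_t exp(-|x_t - theta_it| / beta_it)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.exp(_log_membership(x, model.centers, model.spreads))[:, 0]


def wls_svm_train(
    X: np.ndarray,
    y: np.ndarray,
    C_rules: int = 2,
    penalty_c: float = 9.7656e-4,
    kernel_gamma: float = 0.5,
    lam: float = 1.0,
    fuzzifier: float = 2.0,
    seed: int = 0,
) -> WLSSVMModel:
    """Train the fuzzy-weighted LS-SVM.

    FCM with C_rules clusters defines the rule structure; each rule fits an
    RBF LS-SVM whose error weights are the rule's memberships, solved as the
    usual dual linear system

        [0      1^T          ] [b    ]   [0]
        [1  K + diag(1/(c v))] [alpha] = [y]

    with v_j the membership of sample j in the rule.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if not np.all(np.isin(classes, (-1.0, 1.0))):
        raise ValueError("labels must be -1/+1")
    if classes.size < 2:
        raise ValueError("need both classes present for training")
    n, d = X.shape
    fcm = fcm_cluster(X, C_rules, m=fuzzifier, seed=seed)
    w = fcm.memberships**fuzzifier
    # beta_it: lambda-scaled membership-weighted coordinate variance
    var = np.empty((C_rules, d))
    for i in range(C_rules):
        diff2 = (X - fcm.centers[i]) ** 2
        var[i] = (w[i] @ diff2) / w[i].sum()
    spreads = lam * var
    floor = np.finfo(float).eps
    if np.any(spreads <= floor):
        import warnings

        warnings.warn("degenerate cluster coordinate; flooring spread", stacklevel=2)
        spreads = np.maximum(spreads, floor)

    K = _rbf_gram(X, X, kernel_gamma)
    alphas = np.empty((C_rules, n))
    biases = np.empty(C_rules)
    for i in range(C_rules):
        v = np.maximum(fcm.memberships[i], 1e-6)
        A = np.zeros((n + 1, n + 1))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.diag(1.0 / (penalty_c * v))
        rhs = np.concatenate([[0.0], y])
        sol = np.linalg.solve(A, rhs)
        biases[i] = sol[0]
        alphas[i] = sol[1:]
    return WLSSVMModel(
        support_X=X,
        alphas=alphas,
        biases=biases,
        centers=fcm.centers,
        spreads=spreads,
        kernel_gamma=kernel_gamma,
        penalty_c=penalty_c,
        fcm=fcm,
    )


def wls_svm_decision(model: WLSSVMModel, X: np.ndarray) -> np.ndarray:
    """Fuzzy-weighted decision values for one or many inputs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.support_X.shape[1]:
        raise ValueError("input dimension mismatch")
    K = _rbf_gram(model.support_X, X, model.kernel_gamma)  # (n_train, n_query)
    rule_out = model.alphas @ K + model.biases[:, None]  # (C, n_query)
    logP = _log_membership(X, model.centers, model.spreads)
    P = np.exp(logP - logP.max(axis=0, keepdims=True))  # rescaling-invariant
    return (P * rule_out).sum(axis=0) / P.sum(axis=0)


def wls_svm_predict(model: WLSSVMModel, x: np.ndarray) -> np.ndarray | float:
    """Predicted label(s): sign of the decision value, sign(0) -> +1."""
    x = np.asarray(x, dtype=float)
    dec = wls_svm_decision(model, x)
    labels = np.where(dec >= 0.0, 1.0, -1.0)
    return float(labels[0]) if x.ndim == 1 else labels


@dataclass
class CVReport:
    """Stratified K-fold cross-validation summary."""

    fold_accuracies: list[float]
    mean_accuracy: float
    fold_sizes: list[int]
    seed: int
    confusion: np.ndarray  # pooled 2x2 [[TN, FP], [FN, TP]] with +1 positive


def kfold_cv(X: np.ndarray, y: np.ndarray, K: int = 6, trainer=None, seed: int = 0) -> CVReport:
    """Stratified K-fold cross-validation of a trainer(X, y) -> model.

    The trainer's model must be usable with wls_svm_predict, or the trainer
    may return any object with a .predict(X) method. Mean accuracy is the
    unweighted average of per-fold accuracies.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if K > len(y):
        raise ValueError("K must not exceed the number of samples")
    if trainer is None:
        trainer = wls_svm_train
    skf = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    accs: list[float] = []
    sizes: list[int] = []
    confusion = np.zeros((2, 2), dtype=int)
    for train_idx, test_idx in skf.split(X, y):
        model = trainer(X[train_idx], y[train_idx])
        if hasattr(model, "predict"):
            pred = np.asarray(model.predict(X[test_idx]), dtype=float)
        else:
            pred = np.asarray(wls_svm_predict(model, X[test_idx]), dtype=float)
        truth = y[test_idx]
        accs.append(float(np.mean(pred == truth)))
        sizes.append(len(test_idx))
        for t, p in ((-1.0, -1.0), (-1.0, 1.0), (1.0, -1.0), (1.0, 1.0)):
            confusion[int(t > 0), int(p > 0)] += int(np.sum((truth == t) & (pred == p)))
    return CVReport(
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        fold_sizes=sizes,
        seed=seed,
        confusion=confusion,
    )
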