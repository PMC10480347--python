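"""Weighted multinomial logistic regression by Newton-Raphson.

This solver accepts fractional ("soft") class responses and per-record
observation weights, which the package needs in two places where off-the-shelf
fitters do not fit cleanly:

* the class-membership submodel of the growth mixture model, whose M-step is a
  multinomial regression on posterior class probabilities, and
* probability-weighted association regressions, where each subject contributes
  one record per class weighted by posterior probability times an inverse
  probability of response weight, with cluster-robust (sandwich) covariance by
  subject.

Class 0 is always the reference; coefficients are a (K-1, p) array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.special import logsumexp


class RankDeficiencyError(ValueError):
    """Design matrix is not full rank; names the offending columns."""


@dataclass
class MultinomialFit:
    coef: np.ndarray                 # (K-1, p), reference class 0
    loglik: float
    converged: bool
    n_iter: int
    separation: bool
    info: np.ndarray                 # observed information, ((K-1)p, (K-1)p)
    cov_model: np.ndarray            # inverse information
    cov_robust: np.ndarray | None = None   # cluster sandwich, if clusters given
    column_names: list[str] | None = None
    grad_norm: float = field(default=np.nan)

    @property
    def n_classes(self) -> int:
        return self.coef.shape[0] + 1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _probs(np.asarray(X, dtype=float), self.coef)


def _probs(X: np.ndarray, coef: np.ndarray) -> np.ndarray:
    """Softmax class probabilities with an implicit zero row for class 0."""
    eta = np.column_stack([np.zeros(X.shape[0]), X @ coef.T])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _check_rank(X: np.ndarray, names: list[str] | None) -> None:
    n, p = X.shape
    if n < p:
        raise RankDeficiencyError(f"more columns ({p}) than records ({n})")
    r = np.linalg.matrix_rank(X)
    if r < p:
        # pivoted QR puts dependent columns last
        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(piv[r:].tolist())
        labels = [names[j] if names else f"col{j}" for j in bad]
        raise RankDeficiencyError(f"design matrix rank {r} < {p}; dependent columns: {labels}")


def fit_multinomial(
    X: np.ndarray,
    y,
    sample_weight: np.ndarray | None = None,
    clusters: np.ndarray | None = None,
    *,
    column_names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 200,
    check_rank: bool = True,
    start: np.ndarray | None = None,
) -> MultinomialFit:
    """Maximize the weighted multinomial log-likelihood.

    Parameters
    ----------
    X
        (n, p) design matrix including any intercept column.
    y
        Either integer labels in 0..K-1 (shape (n,)) or a fractional response
        matrix (n, K) whose rows sum to 1 (e.g. posterior class
        probabilities).
    sample_weight
        Non-negative per-record weights; default all ones.
    clusters
        Optional per-record cluster labels; when given, a cluster-robust
        sandwich covariance is computed alongside the model-based one.
    tol
        Convergence threshold on the max-norm of the score vector.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    y = np.asarray(y)
    if y.ndim == 1:
        K = int(y.max()) + 1
        Y = np.zeros((n, K))
        Y[np.arange(n), y.astype(int)] = 1.0
    else:
        Y = np.asarray(y, dtype=float)
        K = Y.shape[1]
    if K < 2:
        raise ValueError("need at least two classes")
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    if (w < 0).any():
        raise ValueError("negative weights")
    if check_rank:
        _check_rank(X * np.sqrt(np.maximum(w, 1e-300))[:, None], column_names)

    q = (K - 1) * p
    coef = np.zeros((K - 1, p)) if start is None else np.array(start, dtype=float)

    def loglik_of(c: np.ndarray) -> float:
        eta = np.column_stack([np.zeros(n), X @ c.T])
        return float(np.sum(w * (np.sum(Y[:, 1:] * eta[:, 1:], axis=1) - logsumexp(eta, axis=1))))

    ll = loglik_of(coef)
    converged = False
    grad_norm = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        P = _probs(X, coef)
        R = w[:, None] * (Y[:, 1:] - P[:, 1:])          # (n, K-1)
        grad = (X.T @ R).T.ravel()                      # (K-1)*p, class-major
        grad_norm = float(np.abs(grad).max())
        if grad_norm < tol:
            converged = True
            break
        info = np.empty((q, q))
        WP = w[:, None] * P[:, 1:]
        for a in range(K - 1):
            for b in range(a, K - 1):
                if a == b:
                    d = WP[:, a] * (1.0 - P[:, a + 1])
                else:
                    d = -WP[:, a] * P[:, b + 1]
                blk = X.T @ (d[:, None] * X)
                info[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
                info[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk.T
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(q), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step halving keeps the likelihood monotone
        scale = 1.0
        for _ in range(30):
            cand = coef + scale * step.reshape(K - 1, p)
            ll_new = loglik_of(cand)
            if ll_new >= ll - 1e-12 * max(1.0, abs(ll)):
                break
            scale *= 0.5
        coef = cand
        ll = ll_new

    separation = bool(np.abs(coef).max() > 30.0) and not converged

    P = _probs(X, coef)
    WP = w[:, None] * P[:, 1:]
    info = np.empty((q, q))
    for a in range(K - 1):
        for b in range(a, K - 1):
            if a == b:
                d = WP[:, a] * (1.0 - P[:, a + 1])
            else:
                d = -WP[:, a] * P[:, b + 1]
            blk = X.T @ (d[:, None] * X)
            info[a * p:(a + 1) * p, b * p:(b + 1) * p] = blk
            info[b * p:(b + 1) * p, a * p:(a + 1) * p] = blk.T
    cov_model = np.linalg.pinv(info)

    cov_robust = None
    if clusters is not None:
        clusters = np.asarray(clusters)
        R = w[:, None] * (Y[:, 1:] - P[:, 1:])
        # per-record score contributions, class-major layout to match `info`
        S = np.concatenate([X * R[:, [a]] for a in range(K - 1)], axis=1)
        order = np.argsort(clusters, kind="stable")
        Ss, cs = S[order], clusters[order]
        cuts = np.flatnonzero(np.r_[True, cs[1:] != cs[:-1]])
        G = np.add.reduceat(Ss, cuts, axis=0)
        meat = G.T @ G
        cov_robust = cov_model @ meat @ cov_model

    return MultinomialFit(
        coef=coef,
        loglik=ll,
        converged=converged,
        n_iter=it,
        separation=separation,
        info=info,
        cov_model=cov_model,
        cov_robust=cov_robust,
        column_names=list(column_names) if column_names else None,
        grad_norm=grad_norm,
    )
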