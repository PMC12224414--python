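"""Multitask linear decoders with structured-sparsity regularization.

The decoding model is U = X beta: item coordinates on r orthogonal semantic
components (columns of U) are predicted jointly from m spatiotemporal neural
features (columns of X) through a single m x r coefficient matrix beta.
Three fitting families are supported:

``none``
    Ordinary least squares (requires n > m, or an explicit pseudo-inverse
    opt-in, since a wide X admits infinitely many perfect interpolants).
``lasso``
    Elementwise L1 penalty, alpha * sum |beta_ij| (plain sparsity).
``growl``
    Group ordered-weighted LASSO: H(beta) = sum_i w_i * rho_(i), where
    rho_(i) are the row L2 norms of beta sorted in nonincreasing order and
    w is a nonincreasing weight sequence w_i = lam + omega * (m - i)/(m - 1).
    Large rows pay the largest weights, so the penalty simultaneously
    promotes row sparsity (the lam floor acts like a group lasso) and ties
    the coefficient rows of correlated features together (the omega decay,
    OSCAR-style, makes equal row norms cost no more than unequal ones).

The regularized objective (1/(2n)) ||U - X beta||_F^2 + alpha * H(beta) is
minimized by FISTA (accelerated proximal gradient) with fixed step 1/L,
L = sigma_max(X)^2 / n, adaptive function restart, and beta initialized at
zero.  The grOWL proximal operator reduces to an ordered-weighted-L1 prox on
the vector of row norms, solved exactly by sort + pool-adjacent-violators +
clip, after which each row is rescaled to its shrunken norm.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import RSLError, RankDeficientError

__all__ = [
    "growl_weights",
    "growl_penalty",
    "prox_growl",
    "prox_lasso",
    "RSLDecoder",
    "fit_ols",
    "fit_regularized",
    "predict",
]


# ---------------------------------------------------------------------------
# penalty primitives


def growl_weights(m: int, lam: float, omega: float) -> np.ndarray:
    """Linear (OSCAR-style) grOWL weight sequence.

    w_i = lam + omega * (m - i) / (m - 1) for i = 1..m (w_1 = lam + omega,
    w_m = lam); for m = 1 the single weight is lam + omega.  omega = 0 gives
    the constant sequence, i.e. the group-lasso limit.
    """
    if m <= 0:
        raise RSLError("m must be positive")
    if lam < 0 or omega < 0:
        raise RSLError("lam and omega must be nonnegative")
    if m == 1:
        return np.array([lam + omega])
    i = np.arange(1, m + 1)
    return lam + omega * (m - i) / (m - 1)


def growl_penalty(beta: np.ndarray, weights: np.ndarray) -> float:
    """H(beta) = sum_i w_i * rho_(i) with rho the row norms sorted descending."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != beta.shape[0]:
        raise RSLError("need one weight per row of beta")
    rho = np.sort(np.linalg.norm(beta, axis=1))[::-1]
    return float(weights @ rho)


def _pava_decreasing_py(y: np.ndarray) -> np.ndarray:
    """Euclidean projection of y onto the nonincreasing cone (pool adjacent
    violators, uniform weights)."""
    n = len(y)
    # block representation: means and lengths
    means = np.empty(n)
    sizes = np.empty(n, dtype=np.int64)
    k = 0
    for v in y:
        means[k] = v
        sizes[k] = 1
        k += 1
        # merge while the tail violates nonincreasing order
        while k > 1 and means[k - 2] < means[k - 1]:
            tot = sizes[k - 2] + sizes[k - 1]
            means[k - 2] = (means[k - 2] * sizes[k - 2] + means[k - 1] * sizes[k - 1]) / tot
            sizes[k - 2] = tot
            k -= 1
    out = np.empty(n)
    pos = 0
    for b in range(k):
        out[pos : pos + sizes[b]] = means[b]
        pos += sizes[b]
    return out


try:  # the prox runs thousands of times per fit; JIT when numba is present
    from numba import njit

    _pava_decreasing = njit(cache=True)(_pava_decreasing_py)
except Exception:  # pragma: no cover - numba is an optional accelerator
    _pava_decreasing = _pava_decreasing_py


def _prox_owl_vector(v: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Prox of the OWL norm sum_i w_i |v|_(i) at a nonnegative vector v.

    Sort descending, subtract the weights, project onto the nonincreasing
    cone (PAVA), clip at zero, undo the sort.
    """
    order = np.argsort(v)[::-1]
    z = v[order] - w
    z = np.clip(_pava_decreasing(z), 0.0, None)
    out = np.empty_like(z)
    out[order] = z
    return out


def prox_growl(V: np.ndarray, weights: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Proximal map of step * H at V (rows shrink toward zero, large rows most).

    Applies the ordered-weighted-L1 prox to the vector of row norms, then
    rescales each row of V to its new norm; rows shrunk to zero stay zero.
    """
    if step <= 0:
        raise RSLError("step must be positive")
    V = np.atleast_2d(np.asarray(V, dtype=float))
    weights = np.asarray(weights, dtype=float)
    rho = np.linalg.norm(V, axis=1)
    new_rho = _prox_owl_vector(rho, step * weights)
    scale = np.divide(new_rho, rho, out=np.zeros_like(rho), where=rho > 0)
    return V * scale[:, None]


def prox_lasso(V: np.ndarray, lam_eff: float) -> np.ndarray:
    """Elementwise soft threshold by lam_eff."""
    if lam_eff < 0:
        raise RSLError("lam_eff must be nonnegative")
    V = np.asarray(V, dtype=float)
    return np.sign(V) * np.maximum(np.abs(V) - lam_eff, 0.0)


# ---------------------------------------------------------------------------
# estimator


class RSLDecoder(RegressorMixin, BaseEstimator):
    """Multitask linear decoder with optional grOWL or LASSO regularization.

    Parameters
    ----------
    family : {"none", "lasso", "growl"}
        Regularizer.  ``none`` fits least squares directly.
    alpha : float
        Overall penalty scale (ignored for ``none``).
    lam : float
        Base row-sparsity weight (grOWL only): the floor of the weight
        sequence, analogous to a group-lasso penalty.
    omega : float
        Weight-decay range (grOWL only): how steeply weights decline across
        the sorted row norms; larger values press correlated features toward
        shared coefficient rows.
    standardize : bool
        Z-score predictor columns using training statistics (constant
        columns are left at zero).  Prediction applies the stored training
        transform, so cross-validation cannot leak holdout statistics.
    max_iter, tol : int, float
        FISTA iteration cap and relative-objective stopping tolerance.
    allow_singular : bool
        For ``family="none"`` only: permit a rank-deficient design and
        return the minimum-norm (pseudo-inverse) solution.

    Attributes
    ----------
    coef_ : ndarray of shape (n_targets, n_features)
        Fitted coefficients, sklearn layout.
    beta_ : ndarray of shape (n_features, n_targets)
        The decoding matrix (transpose of ``coef_``).
    n_iter_, objective_, converged_ : fit log.
    """

    def __init__(
        self,
        family: str = "growl",
        alpha: float = 0.01,
        lam: float = 1.0,
        omega: float = 1.0,
        standardize: bool = True,
        max_iter: int = 10_000,
        tol: float = 1e-8,
        allow_singular: bool = False,
    ):
        self.family = family
        self.alpha = alpha
        self.lam = lam
        self.omega = omega
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol
        self.allow_singular = allow_singular

    # -- internals ---------------------------------------------------------

    def _prepare(self, X):
        if self.standardize:
            mean = X.mean(axis=0)
            scale = X.std(axis=0, ddof=0)
            scale = np.where(scale == 0, 1.0, scale)
        else:
            mean = np.zeros(X.shape[1])
            scale = np.ones(X.shape[1])
        return (X - mean) / scale, mean, scale

    def _objective(self, Xs, U, beta, weights):
        n = Xs.shape[0]
        resid = U - Xs @ beta
        loss = 0.5 * np.sum(resid * resid) / n
        if self.family == "growl":
            return loss + self.alpha * growl_penalty(beta, weights)
        if self.family == "lasso":
            return loss + self.alpha * np.abs(beta).sum()
        return loss

    def _fit_fista(self, Xs, U):
        n, m = Xs.shape
        r = U.shape[1]
        weights = growl_weights(m, self.lam, self.omega) if self.family == "growl" else None
        # sigma_max(X)^2 via the smaller Gram matrix (n x n or m x m)
        G = Xs @ Xs.T if n <= m else Xs.T @ Xs
        L = float(np.linalg.eigvalsh(G)[-1]) / n
        L = max(L, 0.0)
        if L == 0:
            self.beta_raw_ = np.zeros((m, r))
            self.n_iter_, self.converged_ = 0, True
            self.objective_path_ = [self._objective(Xs, U, self.beta_raw_, weights)]
            return
        t_step = 1.0 / L
        beta = np.zeros((m, r))
        y = beta.copy()
        t_mom = 1.0
        f_prev = self._objective(Xs, U, beta, weights)
        path = [f_prev]
        converged = False
        XtU = Xs.T @ U
        XtX = Xs.T @ Xs if m <= n else None  # precompute in the tall regime
        it = 0
        for it in range(1, self.max_iter + 1):
            if XtX is not None:
                grad = (XtX @ y - XtU) / n
            else:
                grad = Xs.T @ (Xs @ y - U) / n
            v = y - t_step * grad
            if self.family == "growl":
                beta_new = prox_growl(v, weights, step=t_step * self.alpha)
            elif self.family == "lasso":
                beta_new = prox_lasso(v, t_step * self.alpha)
            else:
                beta_new = v
            f_new = self._objective(Xs, U, beta_new, weights)
            if f_new > f_prev:  # adaptive restart on objective increase
                t_mom = 1.0
                y = beta.copy()
                path.append(f_prev)
                continue
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom * t_mom))
            y = beta_new + ((t_mom - 1.0) / t_next) * (beta_new - beta)
            beta, t_mom = beta_new, t_next
            path.append(f_new)
            if abs(f_prev - f_new) <= self.tol * max(1.0, abs(f_new)):
                converged = True
                f_prev = f_new
                break
            f_prev = f_new
        self.beta_raw_ = beta
        self.n_iter_ = it
        self.converged_ = converged
        self.objective_path_ = path
        if not converged and self.family != "none":
            warnings.warn(
                f"FISTA did not converge in {self.max_iter} iterations "
                f"(last objective {path[-1]:.6g})",
                stacklevel=2,
            )

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        U = np.asarray(y, dtype=float)
        if U.ndim == 1:
            U = U[:, None]
        if X.ndim != 2 or X.shape[0] != U.shape[0]:
            raise RSLError("X and U must be 2-D with matching item counts")
        if not (np.isfinite(X).all() and np.isfinite(U).all()):
            raise RSLError("X and U must be finite")
        if self.family not in ("none", "lasso", "growl"):
            raise RSLError(f"unknown family {self.family!r}")
        n, m = X.shape
        Xs, self.x_mean_, self.x_scale_ = self._prepare(X)
        if self.family == "none":
            rank = np.linalg.matrix_rank(Xs)
            if rank < m and not self.allow_singular:
                raise RankDeficientError(
                    f"design has rank {rank} < {m} columns: infinitely many "
                    "least-squares solutions exist; pass allow_singular=True "
                    "for the minimum-norm fit or use a regularized family"
                )
            self.beta_raw_, *_ = np.linalg.lstsq(Xs, U, rcond=None)
            self.n_iter_, self.converged_ = 0, True
            self.objective_path_ = [self._objective(Xs, U, self.beta_raw_, None)]
        else:
            if self.alpha < 0 or self.lam < 0 or self.omega < 0:
                raise RSLError("alpha, lam, omega must be nonnegative")
            self._fit_fista(Xs, U)
        self.objective_ = float(self.objective_path_[-1])
        # coefficients live in standardized-predictor space; predict()
        # re-applies the stored training transform
        self.coef_ = self.beta_raw_.T
        self.n_features_in_ = m
        self.n_targets_ = U.shape[1]
        return self

    @property
    def beta_(self) -> np.ndarray:
        """Decoding matrix in standardized-predictor space, shape (m, r)."""
        check_is_fitted(self, "coef_")
        return self.coef_.T

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise RSLError(
                f"X has {X.shape[1]} columns; model was fit with {self.n_features_in_}"
            )
        Xs = (X - self.x_mean_) / self.x_scale_
        return Xs @ self.beta_raw_

    def nonzero_rows(self, atol: float = 0.0) -> np.ndarray:
        """Indices of features with nonzero coefficient rows."""
        check_is_fitted(self, "coef_")
        return np.flatnonzero(np.linalg.norm(self.beta_raw_, axis=1) > atol)


# ---------------------------------------------------------------------------
# functional wrappers (spec-level operations)


def fit_ols(X, U, allow_singular: bool = False) -> RSLDecoder:
    """Ordinary least squares U = X beta (no standardization, no penalty)."""
    return RSLDecoder(family="none", standardize=False, allow_singular=allow_singular).fit(X, U)


def fit_regularized(
    X,
    U,
    family: str = "growl",
    alpha: float = 0.01,
    lam: float = 1.0,
    omega: float = 1.0,
    standardize: bool = False,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> RSLDecoder:
    """Proximal-gradient fit of the penalized multitask regression."""
    if family == "none" or alpha == 0:
        est = RSLDecoder(
            family="none", standardize=standardize, allow_singular=X.shape[0] <= X.shape[1]
        )
        return est.fit(X, U)
    return RSLDecoder(
        family=family, alpha=alpha, lam=lam, omega=omega,
        standardize=standardize, max_iter=max_iter, tol=tol,
    ).fit(X, U)


def predict(model: RSLDecoder, X_new) -> np.ndarray:
    """Predicted coordinates X_new @ beta for held-out items."""
    return model.predict(X_new)
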