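"""Independent reference implementations used only to cross-check the package.

These deliberately avoid the package's own algorithmic choices: the
reference prox uses scipy's isotonic_regression (not the hand-written pool
adjacent violators), the reference solver is plain unaccelerated proximal
gradient (no FISTA momentum, no restarts), and the penalty reference
enumerates row-norm/weight pairings by brute force.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.optimize import isotonic_regression


def penalty_bruteforce(beta: np.ndarray, weights: np.ndarray) -> float:
    """max over all pairings of weights with row norms of sum w_i * rho_pi(i).

    The ordered-weighted penalty pairs the sorted weights with sorted norms;
    by the rearrangement inequality that pairing attains the maximum over
    permutations, which this evaluates directly (small m only).
    """
    rho = np.linalg.norm(np.atleast_2d(beta), axis=1)
    best = -np.inf
    for perm in itertools.permutations(range(len(rho))):
        best = max(best, float(np.dot(weights, rho[list(perm)])))
    return best


def prox_reference(V: np.ndarray, weights: np.ndarray, step: float = 1.0) -> np.ndarray:
    """Reference grOWL prox via scipy's isotonic regression."""
    V = np.atleast_2d(np.asarray(V, dtype=float))
    rho = np.linalg.norm(V, axis=1)
    order = np.argsort(rho)[::-1]
    z = rho[order] - step * np.asarray(weights, dtype=float)
    iso = isotonic_regression(z, increasing=False).x
    new = np.clip(iso, 0.0, None)
    out = np.empty_like(new)
    out[order] = new
    scale = np.divide(out, rho, out=np.zeros_like(rho), where=rho > 0)
    return V * scale[:, None]


def prox_objective(B: np.ndarray, V: np.ndarray, weights: np.ndarray, step: float) -> float:
    """0.5 ||B - V||_F^2 + step * H(B) with H evaluated by sorting."""
    B, V = np.atleast_2d(B), np.atleast_2d(V)
    rho = np.sort(np.linalg.norm(B, axis=1))[::-1]
    return float(0.5 * np.sum((B - V) ** 2) + step * np.dot(weights, rho))


def solve_ista(
    X: np.ndarray,
    U: np.ndarray,
    family: str,
    alpha: float,
    weights: np.ndarray | None = None,
    max_iter: int = 200_000,
    tol: float = 1e-14,
) -> np.ndarray:
    """Plain proximal gradient on (1/(2n))||U - X beta||_F^2 + alpha*penalty."""
    n, m = X.shape
    beta = np.zeros((m, U.shape[1]))
    L = np.linalg.norm(X, 2) ** 2 / n
    t = 1.0 / L
    f_prev = np.inf
    for _ in range(max_iter):
        grad = X.T @ (X @ beta - U) / n
        v = beta - t * grad
        if family == "growl":
            beta = prox_reference(v, weights, step=t * alpha)
        elif family == "lasso":
            beta = np.sign(v) * np.maximum(np.abs(v) - t * alpha, 0.0)
        else:
            beta = v
        resid = U - X @ beta
        f = 0.5 * np.sum(resid * resid) / n
        if family == "growl":
            rho = np.sort(np.linalg.norm(beta, axis=1))[::-1]
            f += alpha * float(np.dot(weights, rho))
        elif family == "lasso":
            f += alpha * np.abs(beta).sum()
        if abs(f_prev - f) <= tol * max(1.0, abs(f)):
            break
        f_prev = f
    return beta
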