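"""Exact Gaussian-process regression with the Tanimoto kernel.

The kernel on binary fingerprints is ``k(a, b) = amplitude * T(a, b)``
with ``T`` the Tanimoto (Jaccard) similarity, plus observation noise on the
diagonal, around a constant mean.  Because ``T(a, a) = 1``, the prior
variance of every point is exactly the amplitude, and a query with zero
similarity to all training points reverts to the constant mean.

Hyperparameters are chosen by maximizing the log-marginal likelihood with
L-BFGS on log-transformed scales.  All linear algebra is dense Cholesky;
an incremental state (:class:`TanimotoGPState`) supports cheap row appends
for Bayesian-optimization loops.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

from ..chemspace import Fingerprint, fingerprint_array, tanimoto_matrix

logger = logging.getLogger(__name__)

_JITTER = 1e-8


@dataclass(frozen=True)
class GPHyperparams:
    amplitude: float = 1.0
    noise: float = 0.1
    constant_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")


def _as_array(fps: Union[Sequence[Fingerprint], np.ndarray]) -> np.ndarray:
    if isinstance(fps, np.ndarray):
        return fps.astype(np.float32, copy=False)
    return fingerprint_array(list(fps))


def _kernel(params: GPHyperparams, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return params.amplitude * tanimoto_matrix(A, B)


def log_marginal_likelihood(params: GPHyperparams,
                            fps: Union[Sequence[Fingerprint], np.ndarray],
                            y: Sequence[float]) -> float:
    """Gaussian log-marginal likelihood of the data under the kernel."""
    X = _as_array(fps)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    K = _kernel(params, X, X) + (params.noise + _JITTER) * np.eye(n)
    try:
        factor = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        logger.warning("kernel matrix singular; applying extra jitter")
        factor = cho_factor(K + 1e-6 * np.eye(n), lower=True)
    r = yv - params.constant_mean
    alpha = cho_solve(factor, r)
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return float(-0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi))


def gp_fit(fps: Union[Sequence[Fingerprint], np.ndarray], y: Sequence[float],
           init: GPHyperparams = GPHyperparams()) -> GPHyperparams:
    """Maximize the log-marginal likelihood over (amplitude, noise, mean).

    Optimization runs on log scales for the positive parameters.  The
    returned hyperparameters never have lower marginal likelihood than the
    initial ones (the optimizer result is discarded if it is worse).
    """
    X = _as_array(fps)
    yv = np.asarray(y, dtype=float)
    if len(yv) < 2:
        raise ValueError("need at least 2 training points")

    T = tanimoto_matrix(X, X)
    n = len(yv)
    eye = np.eye(n)

    def unpack(theta: np.ndarray) -> GPHyperparams:
        return GPHyperparams(amplitude=float(np.exp(theta[0])),
                             noise=float(np.exp(theta[1])),
                             constant_mean=float(theta[2]))

    def neg_lml_and_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
        a, s2, m = np.exp(theta[0]), np.exp(theta[1]), theta[2]
        K = a * T + (s2 + _JITTER) * eye
        try:
            factor = cho_factor(K, lower=True)
        except np.linalg.LinAlgError:
            return 1e12, np.zeros(3)
        r = yv - m
        alpha = cho_solve(factor, r)
        logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
        lml = -0.5 * r @ alpha - 0.5 * logdet - 0.5 * n * np.log(2 * np.pi)
        Kinv = cho_solve(factor, eye)
        # d/d log a with dK = a*T ; d/d log s2 with dK = s2*I ; d/dm
        g_a = 0.5 * a * (alpha @ (T @ alpha) - np.sum(Kinv * T))
        g_s = 0.5 * s2 * (alpha @ alpha - np.trace(Kinv))
        g_m = float(np.sum(alpha))
        return -lml, -np.array([g_a, g_s, g_m])

    starts = [
        np.array([np.log(init.amplitude), np.log(max(init.noise, 1e-6)),
                  init.constant_mean]),
        np.array([np.log(max(yv.var(), 1e-6)),
                  np.log(max(0.1 * yv.var(), 1e-6)), yv.mean()]),
    ]
    best_theta, best_val = None, np.inf
    for theta0 in starts:
        res = optimize.minimize(neg_lml_and_grad, theta0, jac=True,
                                method="L-BFGS-B",
                                bounds=[(-10, 10), (-12, 10), (None, None)])
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun
    fitted = unpack(best_theta)
    if log_marginal_likelihood(fitted, X, yv) < log_marginal_likelihood(init, X, yv):
        logger.warning("hyperparameter optimization did not improve on init")
        return init
    return fitted


def gp_predict(params: GPHyperparams,
               train: tuple[Union[Sequence[Fingerprint], np.ndarray], Sequence[float]],
               query_fps: Union[Sequence[Fingerprint], np.ndarray]
               ) -> tuple[np.ndarray, np.ndarray]:
    """Exact GP posterior mean and (latent) variance at the query points."""
    state = TanimotoGPState(params, _as_array(train[0]), np.asarray(train[1], dtype=float))
    return state.predict(_as_array(query_fps))


class TanimotoGPState:
    """Posterior state with O(n^2 b) incremental updates.

    Appending a batch of b observations updates the Cholesky factor by a
    block bordering step instead of refactorizing, which keeps
    Bayesian-optimization loops cheap.
    """

    def __init__(self, params: GPHyperparams, train_arr: np.ndarray,
                 y: np.ndarray):
        self.params = params
        self.X = train_arr.astype(np.float32, copy=True)
        self.y = np.asarray(y, dtype=float).copy()
        n = len(self.y)
        K = _kernel(params, self.X, self.X) + (params.noise + _JITTER) * np.eye(n)
        self.L = cholesky(K, lower=True)
        self._refresh_alpha()

    def _refresh_alpha(self) -> None:
        r = self.y - self.params.constant_mean
        z = solve_triangular(self.L, r, lower=True)
        self.alpha = solve_triangular(self.L.T, z, lower=False)

    def add(self, arr_new: np.ndarray, y_new: np.ndarray) -> None:
        arr_new = arr_new.astype(np.float32, copy=False)
        y_new = np.asarray(y_new, dtype=float)
        B = _kernel(self.params, self.X, arr_new)            # n x b
        D = (_kernel(self.params, arr_new, arr_new)
             + (self.params.noise + _JITTER) * np.eye(len(y_new)))
        Xb = solve_triangular(self.L, B, lower=True)          # n x b
        S = D - Xb.T @ Xb
        try:
            Ls = cholesky(S + _JITTER * np.eye(len(y_new)), lower=True)
        except np.linalg.LinAlgError:
            Ls = cholesky(S + 1e-6 * np.eye(len(y_new)), lower=True)
        n, b = self.L.shape[0], len(y_new)
        L = np.zeros((n + b, n + b))
        L[:n, :n] = self.L
        L[n:, :n] = Xb.T
        L[n:, n:] = Ls
        self.L = L
        self.X = np.vstack([self.X, arr_new])
        self.y = np.concatenate([self.y, y_new])
        self._refresh_alpha()

    def predict(self, query_arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Ks = _kernel(self.params, self.X, query_arr)          # n x q
        mean = self.params.constant_mean + Ks.T @ self.alpha
        V = solve_triangular(self.L, Ks, lower=True)
        var = self.params.amplitude - np.sum(V ** 2, axis=0)
        return mean, np.maximum(var, 0.0)
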