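"""Scanner-Conditioned Normalization (SCN).

A feature embedding x is standardized with its own instance-wise mean and
population variance over the feature axis (as in layer normalization),

    x_hat = (x - mu_x) / sqrt(sigma_x^2 + eps),

and then recalibrated with a learnable, manufacturer-indexed affine pair:

    y = x_hat * gamma_s + beta_s,

where s is the scanner-manufacturer index of the item.  gamma starts at ones
and beta at zeros (identity recalibration); both are learned jointly with the
rest of the network by backpropagation.  Statistics are never pooled across
items, so train and eval behaviour are identical and batch-size independent.

A manufacturer never seen during training has no learned row; by default this
is a hard error, with an explicit opt-in fallback that uses the mean of the
learned gamma and beta rows (a prototype vendor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Param


@dataclass
class SCNParams:
    """Per-manufacturer scale/shift tables: gamma, beta of shape (S, D)."""

    gamma: np.ndarray
    beta: np.ndarray
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        if self.gamma.shape != self.beta.shape or self.gamma.ndim != 2:
            raise ValueError("gamma and beta must both have shape (S, D)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @property
    def n_manufacturers(self) -> int:
        return self.gamma.shape[0]

    @property
    def dim(self) -> int:
        return self.gamma.shape[1]


def init_scn(n_manufacturers: int, dim: int, epsilon: float = 1e-6) -> SCNParams:
    """Identity initialization: gamma = 1, beta = 0."""
    if n_manufacturers < 1 or dim < 1:
        raise ValueError("n_manufacturers and dim must be >= 1")
    return SCNParams(
        np.ones((n_manufacturers, dim)), np.zeros((n_manufacturers, dim)), epsilon
    )


def _as_batch(x: np.ndarray, s) -> tuple[np.ndarray, np.ndarray, bool]:
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    s = np.atleast_1d(np.asarray(s, dtype=int))
    if s.size == 1 and x.shape[0] > 1:
        s = np.full(x.shape[0], s[0])
    if s.shape[0] != x.shape[0]:
        raise ValueError("one manufacturer index per item required")
    return x, s, single


def scn_forward(x: np.ndarray, s, params: SCNParams) -> np.ndarray:
    """Apply SCN to a D-vector or an (N, D) batch with per-item indices s."""
    x, s, single = _as_batch(x, s)
    if not np.all(np.isfinite(x)):
        raise ValueError("SCN input must be finite")
    if np.any(s < 0) or np.any(s >= params.n_manufacturers):
        raise ValueError(
            f"manufacturer index out of range [0, {params.n_manufacturers})"
        )
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)  # population variance over features
    xhat = (x - mu) / np.sqrt(var + params.epsilon)
    y = xhat * params.gamma[s] + params.beta[s]
    return y[0] if single else y


def scn_backward(
    dy: np.ndarray, x: np.ndarray, s, params: SCNParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of a scalar loss wrt x, gamma, beta given upstream dL/dy.

    Only the rows of gamma/beta indexed by each item's s receive gradient.
    """
    x, s, single = _as_batch(x, s)
    dy = np.asarray(dy, dtype=np.float64)
    if single:
        dy = dy[None, :]
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + params.epsilon)
    xhat = (x - mu) * inv

    dgamma = np.zeros_like(params.gamma)
    dbeta = np.zeros_like(params.beta)
    np.add.at(dgamma, s, dy * xhat)
    np.add.at(dbeta, s, dy)

    dxhat = dy * params.gamma[s]
    dx = inv * (
        dxhat
        - dxhat.mean(axis=1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
    )
    if single:
        dx = dx[0]
    return dx, dgamma, dbeta


def scn_gradcheck(
    params: SCNParams, x: np.ndarray, s, step: float = 1e-5, seed: int = 0
) -> float:
    """Max relative error of the analytic gradients vs central differences.

    The probe loss is L = sum(R * y) for a fixed random R, which exercises
    every output coordinate.  Returns the worst relative error over all
    coordinates of x, gamma and beta.
    """
    x = np.asarray(x, dtype=np.float64)
    rng = np.random.default_rng(seed)
    y = scn_forward(x, s, params)
    r = rng.normal(size=y.shape)

    dx, dgamma, dbeta = scn_backward(r, x, s, params)

    def loss(xv: np.ndarray, g: np.ndarray, b: np.ndarray) -> float:
        p = SCNParams(g, b, params.epsilon)
        return float(np.sum(r * scn_forward(xv, s, p)))

    def numeric(arr: np.ndarray, which: str) -> np.ndarray:
        grad = np.zeros_like(arr, dtype=np.float64)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = arr[idx]
            for sign in (+1, -1):
                arr[idx] = orig + sign * step
                val = loss(
                    x if which != "x" else arr,
                    params.gamma if which != "gamma" else arr,
                    params.beta if which != "beta" else arr,
                )
                grad[idx] += sign * val
            arr[idx] = orig
            it.iternext()
        return grad / (2.0 * step)

    errs = []
    for analytic, arr, which in (
        (dx, x.copy(), "x"),
        (dgamma, params.gamma.copy(), "gamma"),
        (dbeta, params.beta.copy(), "beta"),
    ):
        num = numeric(arr, which)
        denom = np.maximum(np.abs(num), 1e-3)
        errs.append(np.max(np.abs(analytic - num) / denom))
    return float(max(errs))


class SCNLayer:
    """Network-facing SCN with Param-backed tables (float32 training path)."""

    def __init__(self, n_manufacturers: int, dim: int, epsilon: float = 1e-6):
        init = init_scn(n_manufacturers, dim, epsilon)
        self.gamma = Param(init.gamma)
        self.beta = Param(init.beta)
        self.epsilon = epsilon
        self.n_manufacturers = n_manufacturers

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def _tables(self, s: np.ndarray, fallback: bool) -> tuple[np.ndarray, np.ndarray]:
        gamma, beta = self.gamma.value, self.beta.value
        unseen = s >= self.n_manufacturers
        if np.any(unseen):
            if not fallback:
                raise ValueError(
                    "manufacturer index outside the trained vocabulary; "
                    "pass unseen_manufacturer='mean' to use the mean-row fallback"
                )
            g = np.where(unseen[:, None], gamma.mean(axis=0), gamma[np.minimum(s, self.n_manufacturers - 1)])
            b = np.where(unseen[:, None], beta.mean(axis=0), beta[np.minimum(s, self.n_manufacturers - 1)])
            return g.astype(np.float32), b.astype(np.float32)
        return gamma[s], beta[s]

    def forward(self, x: np.ndarray, s: np.ndarray, fallback: bool = False) -> np.ndarray:
        s = np.asarray(s, dtype=int)
        if np.any(s < 0):
            raise ValueError("manufacturer index must be nonnegative")
        g, b = self._tables(s, fallback)
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.epsilon)
        self._xhat = (x - mu) * self._inv
        self._s = s
        self._g = g
        return self._xhat * g + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # gradient only reaches rows actually indexed (in-vocabulary items)
        in_vocab = self._s < self.n_manufacturers
        np.add.at(self.gamma.grad, self._s[in_vocab], (dout * self._xhat)[in_vocab])
        np.add.at(self.beta.grad, self._s[in_vocab], dout[in_vocab])
        dxhat = dout * self._g
        dx = self._inv * (
            dxhat
            - dxhat.mean(axis=1, keepdims=True)
            - self._xhat * (dxhat * self._xhat).mean(axis=1, keepdims=True)
        )
        return dx.astype(np.float32)
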