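"""Feed-forward neural-network baseline trained by Levenberg-Marquardt.

One hidden layer of tanh units (10 by default) and a linear output, trained
on squared-error loss with the Marquardt-Levenberg damped Gauss-Newton
update: delta = (J^T J + mu I)^{-1} J^T r, where mu shrinks after a
successful step (toward Gauss-Newton) and grows on failure (toward steepest
descent). Inputs and target are standardised internally; training stops
early when validation error stops improving. Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

__all__ = ["LMNet", "train_lm_net"]


@dataclass
class LMNet:
    """Fitted network: weights plus the standardisation constants."""

    W1: np.ndarray  # (hidden, n_in)
    b1: np.ndarray  # (hidden,)
    W2: np.ndarray  # (hidden,)
    b2: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    n_epochs: int = 0
    stopped_early: bool = False

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.x_mean) / self.x_scale
        H = np.tanh(Z @ self.W1.T + self.b1)
        out = H @ self.W2 + self.b2
        return out * self.y_scale + self.y_mean

    @property
    def n_params(self) -> int:
        return self.W1.size + self.b1.size + self.W2.size + 1


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2, [b2]])


def _unpack(theta: np.ndarray, hidden: int, n_in: int):
    i = hidden * n_in
    W1 = theta[:i].reshape(hidden, n_in)
    b1 = theta[i : i + hidden]
    W2 = theta[i + hidden : i + 2 * hidden]
    b2 = theta[-1]
    return W1, b1, W2, b2


def _forward_jac(theta: np.ndarray, Z: np.ndarray, hidden: int):
    """Network output and Jacobian of outputs w.r.t. parameters."""
    n, n_in = Z.shape
    W1, b1, W2, b2 = _unpack(theta, hidden, n_in)
    H = np.tanh(Z @ W1.T + b1)  # (n, hidden)
    out = H @ W2 + b2
    dH = 1.0 - H**2  # tanh'
    # d out / d W1[h, j] = W2[h] * dH[:, h] * Z[:, j]
    J_W1 = (W2 * dH)[:, :, None] * Z[:, None, :]  # (n, hidden, n_in)
    J_b1 = W2 * dH  # (n, hidden)
    J = np.concatenate([J_W1.reshape(n, -1), J_b1, H, np.ones((n, 1))], axis=1)
    return out, J


def train_lm_net(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden: int = 10,
    seed: int = 0,
    mu0: float = 0.001,
    mu_factor: float = 10.0,
    max_epochs: int = 150,
    patience: int = 6,
    max_restarts: int = 3,
) -> LMNet:
    """Train the network; returns the weights with the best validation MSE.

    ``mu0`` is the initial damping (the "learning rate" of the damped
    Gauss-Newton scheme). Divergence triggers a re-initialised restart with
    a larger initial damping, at most ``max_restarts`` times.
    """
    X_train = np.atleast_2d(np.asarray(X_train, float))
    X_val = np.atleast_2d(np.asarray(X_val, float))
    y_train = np.asarray(y_train, float).ravel()
    y_val = np.asarray(y_val, float).ravel()

    x_mean = X_train.mean(axis=0)
    x_scale = X_train.std(axis=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y_train.mean())
    y_scale = float(y_train.std()) or 1.0
    Zt = (X_train - x_mean) / x_scale
    Zv = (X_val - x_mean) / x_scale
    yt = (y_train - y_mean) / y_scale
    yv = (y_val - y_mean) / y_scale

    n_in = Zt.shape[1]
    best_overall: LMNet | None = None
    best_overall_val = np.inf

    for restart in range(max_restarts):
        rng = np.random.default_rng(seed + 1000 * restart)
        scale = 1.0 / np.sqrt(n_in)
        theta = _pack(
            rng.uniform(-scale, scale, (hidden, n_in)),
            rng.uniform(-scale, scale, hidden),
            rng.uniform(-scale, scale, hidden),
            0.0,
        )
        mu = mu0 * (mu_factor**restart)
        out, J = _forward_jac(theta, Zt, hidden)
        r = yt - out
        sse = float(r @ r)
        best_val = np.inf
        best_theta = theta.copy()
        best_epoch = 0
        bad_epochs = 0
        diverged = False
        epoch = 0
        for epoch in range(1, max_epochs + 1):
            # damped Gauss-Newton step, retried with larger mu on failure
            stepped = False
            for _ in range(30):
                H = J.T @ J + mu * np.eye(theta.size)
                try:
                    delta = sla.solve(H, J.T @ r, assume_a="pos")
                except sla.LinAlgError:
                    mu *= mu_factor
                    continue
                cand = theta + delta
                out_c, J_c = _forward_jac(cand, Zt, hidden)
                r_c = yt - out_c
                sse_c = float(r_c @ r_c)
                if np.isfinite(sse_c) and sse_c < sse:
                    theta, out, J, r, sse = cand, out_c, J_c, r_c, sse_c
                    mu = max(mu / mu_factor, 1e-12)
                    stepped = True
                    break
                mu *= mu_factor
                if mu > 1e12:
                    break
            if not stepped:
                diverged = mu > 1e12 and not np.isfinite(sse)
                break
            val_pred, _ = _forward_jac(theta, Zv, hidden)
            val_mse = float(np.mean((yv - val_pred) ** 2))
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_theta = theta.copy()
                best_epoch = epoch
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= patience:
                    break
        if diverged:
            continue
        if best_val < best_overall_val:
            W1, b1, W2, b2 = _unpack(best_theta, hidden, n_in)
            best_overall_val = best_val
            best_overall = LMNet(
                W1=W1, b1=b1, W2=W2, b2=float(b2),
                x_mean=x_mean, x_scale=x_scale, y_mean=y_mean, y_scale=y_scale,
                n_epochs=best_epoch, stopped_early=epoch < max_epochs,
            )
        if best_overall is not None:
            break
    if best_overall is None:
        raise RuntimeError("LM training diverged in every restart")
    return best_overall
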