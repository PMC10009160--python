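"""The convex log-linear EMG-force model.

The force produced about a joint is modelled as an affine function of the
natural log of each contributing muscle's sEMG envelope:

    f(t) = w0 + sum_i  w_i * ln(sEMG_i(t)),   i = 1..M

Because the parameters enter linearly, fitting is an ordinary least-squares
problem — convex, with a closed-form global optimum — while the log keeps
the *input* nonlinearity that the EMG-amplitude/force relationship is known
to need. The weights w_i are interpretable as per-muscle contributions
(load sharing), and w0 is the intercept in force units.

Envelope values are floored at a small epsilon before the log; by default
the floor is relative (1e-8 times the global envelope maximum) so the fix
is independent of amplitude units.

The statsmodels-style entry point is :class:`LogLinearForceModel`; the
functional layer (``build_design_matrix``, ``fit_loglinear``,
``predict_force``) underneath is what the class calls.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .leastsq import lstsq_info
from .signals import AlignmentError, DataError, Envelope, SignalMatrix

__all__ = [
    "DesignMatrix",
    "LogLinearModel",
    "build_design_matrix",
    "fit_loglinear",
    "predict_force",
    "LogLinearForceModel",
    "LogLinearForceResults",
]

#: default relative floor applied to envelopes before the log transform
RELATIVE_EPSILON = 1e-8


def resolve_epsilon(envelopes: Sequence[Envelope], epsilon_floor: float | None) -> float:
    """Absolute log floor: the given value, or RELATIVE_EPSILON times the
    global maximum envelope value across muscles."""
    if epsilon_floor is not None:
        if epsilon_floor <= 0:
            raise DataError("epsilon_floor must be positive")
        return float(epsilon_floor)
    global_max = max(float(np.max(e.values)) for e in envelopes)
    if global_max <= 0:
        return RELATIVE_EPSILON
    return RELATIVE_EPSILON * global_max


@dataclass
class DesignMatrix:
    """Design of the log-linear LS problem: A = [1 | ln env_1 | ... | ln env_M]."""

    A: np.ndarray
    b: np.ndarray
    muscle_ids: list[str]
    epsilon_floor: float

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise DataError("design matrix contains non-finite entries")
        if not np.all(self.A[:, 0] == 1.0):
            raise DataError("first design column must be identically 1")

    @property
    def n_samples(self) -> int:
        return self.A.shape[0]

    @property
    def n_muscles(self) -> int:
        return self.A.shape[1] - 1


@dataclass
class LogLinearModel:
    """Fitted weights of the log-linear force model plus fit metadata."""

    w0: float
    w: np.ndarray
    muscle_ids: list[str]
    epsilon_floor: float
    condition_number: float
    solver_path: str

    @property
    def n_muscles(self) -> int:
        return len(self.w)

    def to_dict(self) -> dict:
        return {
            "muscle_ids": list(self.muscle_ids),
            "w0": float(self.w0),
            "w": [float(v) for v in self.w],
            "epsilon_floor": float(self.epsilon_floor),
            "condition_number": float(self.condition_number),
            "solver_path": self.solver_path,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "LogLinearModel":
        return cls(
            w0=float(d["w0"]),
            w=np.asarray(d["w"], dtype=float),
            muscle_ids=list(d["muscle_ids"]),
            epsilon_floor=float(d["epsilon_floor"]),
            condition_number=float(d["condition_number"]),
            solver_path=str(d["solver_path"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LogLinearModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_alignment(envelopes: Sequence[Envelope], force: SignalMatrix | np.ndarray) -> np.ndarray:
    if len(envelopes) < 1:
        raise DataError("at least one muscle envelope is required")
    n = len(envelopes[0])
    for e in envelopes:
        if len(e) != n:
            raise AlignmentError("envelopes differ in length")
    if isinstance(force, SignalMatrix):
        if force.n_channels != 1:
            raise DataError("force must be a single-channel signal")
        fvec = force.column(0)
        if envelopes[0].fs != force.fs:
            raise AlignmentError("envelope and force sampling rates differ")
    else:
        fvec = np.asarray(force, dtype=float).ravel()
    if fvec.size != n:
        raise AlignmentError(f"force has {fvec.size} samples, envelopes have {n}")
    return fvec


def build_design_matrix(
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    epsilon_floor: float | None = None,
) -> DesignMatrix:
    """Assemble A (ones column followed by floored-log envelope columns)
    and the target vector b."""
    b = _check_alignment(envelopes, force)
    eps = resolve_epsilon(envelopes, epsilon_floor)
    n, m = b.size, len(envelopes)
    A = np.empty((n, m + 1))
    A[:, 0] = 1.0
    for j, env in enumerate(envelopes):
        if np.max(env.values) <= eps:
            warnings.warn(
                f"envelope {env.muscle_id or j} never exceeds the log floor; "
                "its column is constant ln(epsilon)",
                stacklevel=2,
            )
        A[:, j + 1] = np.log(np.maximum(env.values, eps))
    if n < m + 1:
        warnings.warn(f"under-determined system: {n} samples for {m + 1} weights", stacklevel=2)
    return DesignMatrix(A=A, b=b, muscle_ids=[e.muscle_id or f"m{j}" for j, e in enumerate(envelopes)], epsilon_floor=eps)


def fit_loglinear(
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    epsilon_floor: float | None = None,
    detrend: bool = False,
) -> LogLinearModel:
    """Least-squares fit of the log-linear model.

    With ``detrend`` the force mean is removed before fitting and restored
    into the intercept afterwards; predictions are identical either way
    (the intercept column absorbs the mean), so the default keeps b as is.
    """
    design = build_design_matrix(envelopes, force, epsilon_floor)
    b = design.b
    offset = float(np.mean(b)) if detrend else 0.0
    x, path, cond = lstsq_info(design.A, b - offset)
    return LogLinearModel(
        w0=float(x[0]) + offset,
        w=x[1:].copy(),
        muscle_ids=design.muscle_ids,
        epsilon_floor=design.epsilon_floor,
        condition_number=cond,
        solver_path=path,
    )


def predict_force(model: LogLinearModel, envelopes: Sequence[Envelope]) -> np.ndarray:
    """Evaluate f(t) = w0 + sum_i w_i ln(max(env_i, eps)) per sample."""
    if len(envelopes) != model.n_muscles:
        raise DataError(f"model has {model.n_muscles} muscles, got {len(envelopes)} envelopes")
    ids = [e.muscle_id or f"m{j}" for j, e in enumerate(envelopes)]
    if ids != list(model.muscle_ids):
        raise DataError(f"muscle ids {ids} do not match model's {model.muscle_ids}")
    n = len(envelopes[0])
    out = np.full(n, model.w0)
    for wi, env in zip(model.w, envelopes):
        out += wi * np.log(np.maximum(env.values, model.epsilon_floor))
    return out


def weighted_activities(model: LogLinearModel, envelopes: Sequence[Envelope]) -> np.ndarray:
    """Per-muscle weighted activity w_i * ln(env_i(t)), shape (N, M).

    These traces decompose the predicted force into per-muscle
    contributions — the load-sharing readout of the model.
    """
    n = len(envelopes[0])
    out = np.empty((n, model.n_muscles))
    for j, (wi, env) in enumerate(zip(model.w, envelopes)):
        out[:, j] = wi * np.log(np.maximum(env.values, model.epsilon_floor))
    return out


class LogLinearForceModel:
    """Log-linear EMG-force model bound to data, statsmodels style.

    Parameters
    ----------
    envelopes : sequence of Envelope
        Representative envelope per muscle, time-aligned with ``force``.
    force : SignalMatrix or 1-D array
        Measured force/target signal.
    epsilon_floor : float, optional
        Absolute floor applied to envelopes before the log; defaults to
        1e-8 times the global envelope maximum.

    Examples
    --------
    >>> res = LogLinearForceModel(envelopes, force).fit()
    >>> res.params           # (w0, w1, ..., wM)
    >>> res.predict(new_envelopes)
    >>> print(res.summary())
    """

    def __init__(
        self,
        envelopes: Sequence[Envelope],
        force: SignalMatrix | np.ndarray,
        epsilon_floor: float | None = None,
    ) -> None:
        self.envelopes = list(envelopes)
        self.force = force
        self.endog = _check_alignment(self.envelopes, force)
        self.epsilon_floor = epsilon_floor
        self.design = build_design_matrix(self.envelopes, force, epsilon_floor)

    @classmethod
    def from_dataframe(
        cls,
        df,
        force_col: str,
        muscle_cols: Sequence[str] | None = None,
        fs: float = 2048.0,
        epsilon_floor: float | None = None,
    ) -> "LogLinearForceModel":
        """Build from a dataframe of per-muscle envelope columns plus a
        force column (all time-aligned rows)."""
        if muscle_cols is None:
            muscle_cols = [c for c in df.columns if c != force_col]
        envelopes = [Envelope(df[c].to_numpy(dtype=float), fs=fs, muscle_id=str(c)) for c in muscle_cols]
        force = SignalMatrix(df[force_col].to_numpy(dtype=float), fs=fs)
        return cls(envelopes, force, epsilon_floor)

    def fit(self, detrend: bool = False) -> "LogLinearForceResults":
        model = fit_loglinear(self.envelopes, self.force, self.epsilon_floor, detrend=detrend)
        return LogLinearForceResults(self, model)


class LogLinearForceResults:
    """Fit results: weights, standard errors, diagnostics and predictions.

    Attributes
    ----------
    params : ndarray, (M+1,)
        (w0, w1..wM).
    bse : ndarray
        Classical OLS standard errors (from the SVD of the design; NaN on
        the rank-deficient path where they are not identified).
    condition_number, solver_path : fit diagnostics.
    fittedvalues, resid : training-set predictions and residuals.
    """

    def __init__(self, model: LogLinearForceModel, fitted: LogLinearModel) -> None:
        self.model = model
        self.fitted = fitted
        A, b = model.design.A, model.design.b
        self.params = np.concatenate(([fitted.w0], fitted.w))
        self.fittedvalues = A @ self.params
        self.resid = b - self.fittedvalues
        n, p = A.shape
        self.nobs = n
        self.df_resid = max(n - p, 1)
        self.scale = float(self.resid @ self.resid) / self.df_resid
        if np.isfinite(fitted.condition_number):
            # var(w) = sigma^2 (A^T A)^{-1}; diagonal via the SVD of A.
            U, s, Vt = np.linalg.svd(A, full_matrices=False)
            diag = np.einsum("ji,i,ji->j", Vt.T, 1.0 / s**2, Vt.T)
            self.bse = np.sqrt(self.scale * diag)
        else:
            self.bse = np.full(p, np.nan)

    # -- convenience passthroughs ------------------------------------
    @property
    def condition_number(self) -> float:
        return self.fitted.condition_number

    @property
    def solver_path(self) -> str:
        return self.fitted.solver_path

    @property
    def muscle_ids(self) -> list[str]:
        return self.fitted.muscle_ids

    def predict(self, envelopes: Sequence[Envelope] | None = None) -> np.ndarray:
        if envelopes is None:
            return self.fittedvalues.copy()
        return predict_force(self.fitted, envelopes)

    def weighted_activities(self, envelopes: Sequence[Envelope] | None = None) -> np.ndarray:
        return weighted_activities(self.fitted, envelopes or self.model.envelopes)

    def metrics(self, measured=None, predicted=None):
        """Goodness-of-fit (r, R2, adj R2, RMSE, MAE) — training set by
        default, or on supplied measured/predicted vectors."""
        from .evaluation import compute_metrics

        y = self.model.design.b if measured is None else np.asarray(measured, float).ravel()
        yhat = self.fittedvalues if predicted is None else np.asarray(predicted, float).ravel()
        return compute_metrics(y, yhat, k=self.fitted.n_muscles + 1)

    def bland_altman(self, measured=None, predicted=None, n_sd: float = 1.0):
        from .evaluation import bland_altman

        y = self.model.design.b if measured is None else np.asarray(measured, float).ravel()
        yhat = self.fittedvalues if predicted is None else np.asarray(predicted, float).ravel()
        return bland_altman(y, yhat, n_sd=n_sd)

    def save(self, path: str | Path) -> None:
        self.fitted.save(path)

    def summary(self) -> str:
        lines = [
            "Log-linear EMG-force model (least squares)",
            "=" * 58,
            f"{'n samples':<22}{self.nobs:>10}",
            f"{'n muscles':<22}{self.fitted.n_muscles:>10}",
            f"{'solver path':<22}{self.solver_path:>16}",
            f"{'condition number':<22}{self.condition_number:>16.4g}",
            f"{'residual RMS':<22}{np.sqrt(np.mean(self.resid ** 2)):>16.4g}",
            "-" * 58,
            f"{'term':<20}{'weight':>14}{'std err':>14}",
        ]
        names = ["intercept"] + [f"ln({m})" for m in self.muscle_ids]
        for name, w, se in zip(names, self.params, self.bse):
            lines.append(f"{name:<20}{w:>14.6g}{se:>14.4g}")
        lines.append("=" * 58)
        return "\n".join(lines)
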