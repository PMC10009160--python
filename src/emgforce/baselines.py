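"""The comparison estimators: nine classical EMG-amplitude-to-force model
families, ordinary least squares, ridge regression, linear support-vector
regression and a Levenberg-Marquardt neural network.

Model families (per muscle, summed over muscles; env = representative
sEMG envelope):

========  ===========================================  params  fitting
model 1   a*env + b*env (duplicated term as printed)   2       LS (min-norm)
model 2   a*env^b                                      2       PSO
model 3   a*exp(b*env)                                 2       PSO
model 4   a*env^b + c*env^d                            4       PSO
model 5   a*env^4 + b*env^3 + c*env^2 + d*env + e      5       LS
model 6   a + b*env                                    2       LS
model 7   env^a + exp(b - c*env)                       3       PSO
model 8   a + b*cos(env) + c*sin(env)                  3       LS
model 9   a + b*sin(env)                               2       LS
OLS       intercept + sum_i c_i*env_i                  1+1     LS
RLS       ridge-penalised OLS, lambda = 0.01           1+1     closed form
SVR       linear support-vector regression             1+1     CV-tuned C
ANN       10 tanh units, LM training, early stopping   --      damped GN
========  ===========================================  ======  ==========

Families 1, 5, 6, 8, 9 and OLS are linear in the parameters (LIP): their
global optimum comes from least squares. Families 2, 3, 4 and 7 are
non-convex and are fitted by particle swarm optimisation with restart
selection on validation RMSE. All baselines regress on the *raw* envelopes
(no log transform) — the log-linear model lives in :mod:`emgforce.model`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ann import LMNet, train_lm_net
from .leastsq import lstsq_info, solve_least_squares
from .model import resolve_epsilon
from .pso import PSOConfig, pso_optimize
from .signals import DataError, Envelope, SignalMatrix

__all__ = [
    "ModelSpec",
    "ParameterVector",
    "RidgeConfig",
    "evaluate_model",
    "fit_lip_model",
    "fit_pso_model",
    "fit_ridge",
    "fit_svr",
    "fit_ann",
    "BaselineForceModel",
    "LIP_FAMILIES",
    "PSO_FAMILIES",
]

_EXP_CLIP = 1e12  # model 3/7 exponentials are clipped here (known blow-up)

# family -> (params per muscle, fitting route, has global intercept)
_FAMILY_TABLE: dict[str, tuple[int, str, bool]] = {
    "model1": (2, "LS", False),
    "model2": (2, "PSO", False),
    "model3": (2, "PSO", False),
    "model4": (4, "PSO", False),
    "model5": (5, "LS", False),
    "model6": (2, "LS", False),
    "model7": (3, "PSO", False),
    "model8": (3, "LS", False),
    "model9": (2, "LS", False),
    "OLS": (1, "LS", True),
    "RLS": (1, "ridge", True),
    "SVR": (1, "svr", True),
    "ANN": (0, "ann", False),
    "proposed": (1, "LS-log", True),
}

LIP_FAMILIES = ("model1", "model5", "model6", "model8", "model9", "OLS")
PSO_FAMILIES = ("model2", "model3", "model4", "model7")


@dataclass(frozen=True)
class ModelSpec:
    """One estimator family with its fixed fitting recipe."""

    family: str
    params_per_muscle: int
    fitting: str
    global_intercept: bool

    @classmethod
    def for_family(cls, family: str) -> "ModelSpec":
        if family not in _FAMILY_TABLE:
            raise ValueError(f"unknown model family {family!r}; choose from {sorted(_FAMILY_TABLE)}")
        p, fit, icpt = _FAMILY_TABLE[family]
        return cls(family=family, params_per_muscle=p, fitting=fit, global_intercept=icpt)

    def n_weights(self, n_muscles: int) -> int:
        return self.params_per_muscle * n_muscles + (1 if self.global_intercept else 0)


@dataclass
class ParameterVector:
    """Fitted coefficients of one baseline: per-muscle tuples
    (a_i, b_i, ... as the family requires) plus a global intercept where
    the family has one, and fitting metadata."""

    family: str
    coeffs: np.ndarray  # (M, params_per_muscle)
    muscle_ids: list[str]
    intercept: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        spec = ModelSpec.for_family(self.family)
        self.coeffs = np.atleast_2d(np.asarray(self.coeffs, dtype=float))
        if self.coeffs.shape[1] != spec.params_per_muscle:
            raise DataError(
                f"{self.family} takes {spec.params_per_muscle} coefficients per muscle, "
                f"got {self.coeffs.shape[1]}"
            )
        if spec.global_intercept and self.intercept is None:
            raise DataError(f"{self.family} requires a global intercept")

    @property
    def flat(self) -> np.ndarray:
        parts = [self.coeffs.ravel()]
        if self.intercept is not None:
            parts.insert(0, np.array([self.intercept]))
        return np.concatenate(parts)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "muscle_ids": list(self.muscle_ids),
            "coeffs": self.coeffs.tolist(),
            "intercept": self.intercept,
            "metadata": {k: v for k, v in self.metadata.items() if not callable(v)},
        }


@dataclass
class RidgeConfig:
    """Ridge (regularised LS) settings; the penalty never touches the
    intercept unless asked, so the fit still recovers the force mean."""

    lam: float = 0.01
    penalize_intercept: bool = False

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")


def _env_matrix(envelopes: Sequence[Envelope]) -> np.ndarray:
    n = len(envelopes[0])
    for e in envelopes:
        if len(e) != n:
            raise DataError("envelopes differ in length")
    return np.column_stack([e.values for e in envelopes])


def _force_vec(force: SignalMatrix | np.ndarray) -> np.ndarray:
    if isinstance(force, SignalMatrix):
        return force.column(0)
    return np.asarray(force, dtype=float).ravel()


def _family_predict(family: str, E: np.ndarray, coeffs: np.ndarray, eps: float) -> np.ndarray:
    """Sum of the family's per-muscle formula over muscles. E is (N, M)."""
    Ef = np.maximum(E, eps)  # floor for power terms (0^negative guard)
    M = E.shape[1]
    out = np.zeros(E.shape[0])
    clipped = False

    def _bounded_exp(x: np.ndarray) -> np.ndarray:
        nonlocal clipped
        y = np.exp(np.clip(x, -745.0, 709.0))
        if np.any(y > _EXP_CLIP):
            clipped = True
        return np.minimum(y, _EXP_CLIP)

    for i in range(M):
        e, ef, c = E[:, i], Ef[:, i], coeffs[i]
        if family == "model1":
            out += c[0] * e + c[1] * e
        elif family == "model2":
            out += c[0] * np.power(ef, c[1])
        elif family == "model3":
            out += c[0] * _bounded_exp(c[1] * e)
        elif family == "model4":
            out += c[0] * np.power(ef, c[1]) + c[2] * np.power(ef, c[3])
        elif family == "model5":
            out += c[0] * e**4 + c[1] * e**3 + c[2] * e**2 + c[3] * e + c[4]
        elif family == "model6":
            out += c[0] + c[1] * e
        elif family == "model7":
            out += np.power(ef, c[0]) + _bounded_exp(c[1] - c[2] * e)
        elif family == "model8":
            out += c[0] + c[1] * np.cos(e) + c[2] * np.sin(e)
        elif family == "model9":
            out += c[0] + c[1] * np.sin(e)
        else:  # OLS / RLS / SVR share the linear form
            out += c[0] * e
    bad = ~np.isfinite(out)
    if bad.any():
        out = np.nan_to_num(out, nan=0.0, posinf=_EXP_CLIP, neginf=-_EXP_CLIP)
    if clipped or bad.any() or np.any(np.abs(out) > _EXP_CLIP):
        warnings.warn(f"{family}: predictions exceeded 1e12 and were clipped", stacklevel=3)
    return np.clip(out, -_EXP_CLIP, _EXP_CLIP)


def evaluate_model(
    spec: ModelSpec | str,
    params: ParameterVector,
    envelopes: Sequence[Envelope],
) -> np.ndarray:
    """Predicted force TR(t) of a fitted baseline on the given envelopes."""
    family = spec.family if isinstance(spec, ModelSpec) else spec
    if params.family != family:
        raise DataError(f"parameters are for {params.family}, not {family}")
    E = _env_matrix(envelopes)
    if E.shape[1] != params.coeffs.shape[0]:
        raise DataError(
            f"{params.coeffs.shape[0]} muscles in parameters, {E.shape[1]} envelopes given"
        )
    eps = params.metadata.get("epsilon_floor") or resolve_epsilon(envelopes, None)
    out = _family_predict(family, E, params.coeffs, eps)
    if params.intercept is not None:
        out = out + params.intercept
    return out


# ---------------------------------------------------------------- LIP fits

def _lip_basis(family: str, E: np.ndarray) -> np.ndarray:
    """Basis expansion whose LS solution gives the family's coefficients in
    (a_i, b_i, ...) order; OLS puts the global intercept first."""
    cols: list[np.ndarray] = []
    if family == "OLS":
        cols.append(np.ones(E.shape[0]))
    for i in range(E.shape[1]):
        e = E[:, i]
        if family == "model1":
            cols += [e, e]  # duplicated term as printed -> rank deficient
        elif family == "model5":
            cols += [e**4, e**3, e**2, e, np.ones_like(e)]
        elif family == "model6":
            cols += [np.ones_like(e), e]
        elif family == "model8":
            cols += [np.ones_like(e), np.cos(e), np.sin(e)]
        elif family == "model9":
            cols += [np.ones_like(e), np.sin(e)]
        elif family == "OLS":
            cols += [e]
        else:
            raise ValueError(f"{family} is not linear in the parameters")
    return np.column_stack(cols)


def fit_lip_model(
    spec: ModelSpec | str,
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
) -> ParameterVector:
    """Least-squares fit of a linear-in-the-parameters family.

    Collinear bases (model 1's duplicated term; the repeated per-muscle
    intercepts of models 6, 8, 9) are resolved by the minimum-norm
    pseudo-inverse path of the solver.
    """
    family = spec.family if isinstance(spec, ModelSpec) else spec
    mspec = ModelSpec.for_family(family)
    if mspec.fitting != "LS":
        raise ValueError(f"{family} is not a LIP family")
    E = _env_matrix(envelopes)
    b = _force_vec(force)
    A = _lip_basis(family, E)
    x, path, cond = lstsq_info(A, b)
    intercept = None
    if mspec.global_intercept:
        intercept, x = float(x[0]), x[1:]
    coeffs = x.reshape(E.shape[1], mspec.params_per_muscle)
    return ParameterVector(
        family=family,
        coeffs=coeffs,
        muscle_ids=[e.muscle_id or f"m{j}" for j, e in enumerate(envelopes)],
        intercept=intercept,
        metadata={"solver_path": path, "condition_number": cond},
    )


# ---------------------------------------------------------------- PSO fits

def default_bounds(family: str, n_muscles: int) -> list[tuple[float, float]]:
    """Search bounds: [-10, 10] for multiplicative/additive coefficients,
    [-5, 5] for parameters that sit in an exponent."""
    wide, narrow = (-10.0, 10.0), (-5.0, 5.0)
    per_muscle = {
        "model2": [wide, narrow],
        "model3": [wide, narrow],
        "model4": [wide, narrow, wide, narrow],
        "model7": [narrow, narrow, narrow],
    }[family]
    return per_muscle * n_muscles


def fit_pso_model(
    spec: ModelSpec | str,
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    split,
    config: PSOConfig | None = None,
    seed: int = 0,
) -> ParameterVector:
    """PSO fit of a non-convex family with restart selection.

    The swarm minimises the sum of squared errors on the estimation subset;
    the optimisation is repeated ``n_restarts`` times (independent seeded
    swarms) and the restart with the lowest RMSE on the *validation* subset
    is returned.
    """
    family = spec.family if isinstance(spec, ModelSpec) else spec
    mspec = ModelSpec.for_family(family)
    if mspec.fitting != "PSO":
        raise ValueError(f"{family} is not a PSO family")
    E = _env_matrix(envelopes)
    b = _force_vec(force)
    eps = resolve_epsilon(envelopes, None)
    M = E.shape[1]
    est, val = np.asarray(split.estimation_idx), np.asarray(split.validation_idx)
    if val.size == 0:
        val = est  # degenerate: select on estimation error
    E_est, b_est = E[est], b[est]
    E_val, b_val = E[val], b[val]

    def sse_est(theta: np.ndarray) -> float:
        pred = _family_predict(family, E_est, theta.reshape(M, mspec.params_per_muscle), eps)
        return float(np.sum((pred - b_est) ** 2))

    if config is None:
        config = PSOConfig(bounds=default_bounds(family, M), seed=seed)
    best: tuple[float, np.ndarray, float, int] | None = None
    for r in range(config.n_restarts):
        cfg_r = PSOConfig(
            bounds=config.bounds,
            max_iter=config.max_iter,
            swarm_size=config.swarm_size,
            min_neighborhood_fraction=config.min_neighborhood_fraction,
            self_adjustment=config.self_adjustment,
            social_adjustment=config.social_adjustment,
            inertia_range=config.inertia_range,
            n_restarts=1,
            seed=config.seed + r,
            max_stall_iter=config.max_stall_iter,
            function_tolerance=config.function_tolerance,
        )
        x, f = pso_optimize(sse_est, cfg_r)
        pred_val = _family_predict(family, E_val, x.reshape(M, mspec.params_per_muscle), eps)
        rmse_val = float(np.sqrt(np.mean((pred_val - b_val) ** 2)))
        if best is None or rmse_val < best[0]:
            best = (rmse_val, x, f, r)
    rmse_val, x, f_est, r_idx = best
    return ParameterVector(
        family=family,
        coeffs=x.reshape(M, mspec.params_per_muscle),
        muscle_ids=[e.muscle_id or f"j{j}" for j, e in enumerate(envelopes)],
        metadata={
            "epsilon_floor": eps,
            "restart": r_idx,
            "validation_rmse": rmse_val,
            "estimation_sse": f_est,
        },
    )


# -------------------------------------------------------------- ridge, SVR

def fit_ridge(
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    config: RidgeConfig | None = None,
) -> ParameterVector:
    """Closed-form ridge regression on the raw envelopes:
    min ||Ax - b||^2 + lambda ||x~||^2, intercept unpenalised by default."""
    config = config or RidgeConfig()
    E = _env_matrix(envelopes)
    b = _force_vec(force)
    A = np.column_stack([np.ones(E.shape[0]), E])
    D = np.eye(A.shape[1])
    if not config.penalize_intercept:
        D[0, 0] = 0.0
    x = np.linalg.solve(A.T @ A + config.lam * D, A.T @ b)
    return ParameterVector(
        family="RLS",
        coeffs=x[1:][:, None],
        muscle_ids=[e.muscle_id or f"m{j}" for j, e in enumerate(envelopes)],
        intercept=float(x[0]),
        metadata={"lambda": config.lam},
    )


def fit_svr(
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    split,
    c_grid: Sequence[float] | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> ParameterVector:
    """Linear support-vector regression, penalty C tuned by k-fold
    cross-validation over a logarithmic grid on the estimation set.

    A constant target has no margin to fit; it falls back to the constant
    predictor with a warning.
    """
    from sklearn.model_selection import GridSearchCV, KFold
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import LinearSVR

    E = _env_matrix(envelopes)
    b = _force_vec(force)
    est = np.asarray(split.estimation_idx)
    X_est, y_est = E[est], b[est]
    ids = [e.muscle_id or f"m{j}" for j, e in enumerate(envelopes)]
    if np.ptp(y_est) == 0:
        warnings.warn("constant force target: SVR falls back to a constant predictor")
        return ParameterVector(
            family="SVR", coeffs=np.zeros((E.shape[1], 1)), muscle_ids=ids,
            intercept=float(y_est[0]), metadata={"fallback": "constant"},
        )
    if c_grid is None:
        c_grid = np.logspace(-3, 3, 7)
    c_grid = list(c_grid)

    def pipe(C: float):
        return make_pipeline(
            StandardScaler(),
            LinearSVR(C=C, epsilon=0.0, max_iter=20000, random_state=seed, dual=True),
        )

    if len(c_grid) == 1:
        best_C = c_grid[0]
        model = pipe(best_C).fit(X_est, y_est)
    else:
        cv = KFold(n_splits=min(n_folds, len(y_est)), shuffle=True, random_state=seed)
        search = GridSearchCV(
            pipe(1.0), {"linearsvr__C": c_grid}, cv=cv,
            scoring="neg_mean_squared_error", n_jobs=1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            search.fit(X_est, y_est)
        best_C = float(search.best_params_["linearsvr__C"])
        model = search.best_estimator_
    scaler = model.named_steps["standardscaler"]
    svr = model.named_steps["linearsvr"]
    # fold the standardisation into envelope-unit coefficients
    coef = svr.coef_.ravel() / scaler.scale_
    intercept = float(svr.intercept_.ravel()[0] - np.sum(svr.coef_.ravel() * scaler.mean_ / scaler.scale_))
    return ParameterVector(
        family="SVR", coeffs=coef[:, None], muscle_ids=ids,
        intercept=intercept, metadata={"C": best_C},
    )


def fit_ann(
    envelopes: Sequence[Envelope],
    force: SignalMatrix | np.ndarray,
    split,
    seed: int = 0,
    hidden: int = 10,
) -> LMNet:
    """Feed-forward network baseline (Levenberg-Marquardt training with
    early stopping on the validation subset). Returns the fitted network;
    predictions come from ``net.predict(envelope_matrix)``."""
    E = _env_matrix(envelopes)
    b = _force_vec(force)
    est = np.asarray(split.estimation_idx)
    val = np.asarray(split.validation_idx)
    if val.size == 0:
        # hold out the last fifth of the estimation block for early stopping
        cut = max(1, int(0.8 * est.size))
        est, val = est[:cut], est[cut:]
    return train_lm_net(E[est], b[est], E[val], b[val], hidden=hidden, seed=seed)


# -------------------------------------------------- statsmodels-style face

class BaselineForceModel:
    """One comparison estimator bound to data.

    ``BaselineForceModel("model2", envelopes, force, split).fit(seed=0)``
    dispatches to the family's fitting recipe (LS, PSO with restarts,
    closed-form ridge, CV-tuned SVR, or LM-trained network) and returns a
    results object with predictions and goodness-of-fit helpers.
    """

    def __init__(
        self,
        family: str,
        envelopes: Sequence[Envelope],
        force: SignalMatrix | np.ndarray,
        split=None,
        pso_config: PSOConfig | None = None,
        ridge_config: RidgeConfig | None = None,
        ann_hidden: int = 10,
    ) -> None:
        self.spec = ModelSpec.for_family(family)
        self.envelopes = list(envelopes)
        self.force = _force_vec(force)
        self.split = split
        self.pso_config = pso_config
        self.ridge_config = ridge_config
        self.ann_hidden = ann_hidden

    def fit(self, seed: int = 0) -> "BaselineForceResults":
        fam = self.spec.family
        net = None
        params = None
        if self.spec.fitting == "LS":
            params = fit_lip_model(fam, self.envelopes, self.force)
        elif self.spec.fitting == "PSO":
            if self.split is None:
                raise DataError(f"{fam} needs a data split for restart selection")
            params = fit_pso_model(
                fam, self.envelopes, self.force, self.split,
                config=self.pso_config, seed=seed,
            )
        elif self.spec.fitting == "ridge":
            params = fit_ridge(self.envelopes, self.force, self.ridge_config)
        elif self.spec.fitting == "svr":
            if self.split is None:
                raise DataError("SVR needs a data split for cross-validation")
            params = fit_svr(self.envelopes, self.force, self.split, seed=seed)
        elif self.spec.fitting == "ann":
            if self.split is None:
                raise DataError("ANN needs a data split for early stopping")
            net = fit_ann(self.envelopes, self.force, self.split, seed=seed, hidden=self.ann_hidden)
        else:
            raise ValueError(
                f"{fam} is fitted by emgforce.model.LogLinearForceModel, not as a baseline"
            )
        return BaselineForceResults(self, params=params, net=net)


class BaselineForceResults:
    """Fit results of one baseline family."""

    def __init__(self, model: BaselineForceModel, params: ParameterVector | None, net: LMNet | None):
        self.model = model
        self.params = params
        self.net = net
        self.fittedvalues = self.predict()
        self.resid = model.force - self.fittedvalues

    @property
    def family(self) -> str:
        return self.model.spec.family

    @property
    def k(self) -> int:
        """Number of fitted parameters (for adjusted R^2)."""
        if self.net is not None:
            return self.net.n_params
        return self.model.spec.n_weights(len(self.model.envelopes))

    def predict(self, envelopes: Sequence[Envelope] | None = None) -> np.ndarray:
        envs = envelopes if envelopes is not None else self.model.envelopes
        if self.net is not None:
            return self.net.predict(_env_matrix(envs))
        return evaluate_model(self.family, self.params, envs)

    def metrics(self, measured=None, predicted=None):
        from .evaluation import compute_metrics

        y = self.model.force if measured is None else np.asarray(measured, float).ravel()
        yhat = self.fittedvalues if predicted is None else np.asarray(predicted, float).ravel()
        return compute_metrics(y, yhat, k=self.k)

    def summary(self) -> str:
        lines = [
            f"Baseline force model: {self.family} ({self.model.spec.fitting})",
            "=" * 58,
            f"{'n samples':<22}{self.model.force.size:>10}",
            f"{'n muscles':<22}{len(self.model.envelopes):>10}",
            f"{'n parameters':<22}{self.k:>10}",
        ]
        if self.params is not None:
            if self.params.intercept is not None:
                lines.append(f"{'intercept':<22}{self.params.intercept:>16.6g}")
            letters = "abcde"
            for mid, row in zip(self.params.muscle_ids, self.params.coeffs):
                terms = ", ".join(f"{letters[j]}={v:.6g}" for j, v in enumerate(row))
                lines.append(f"  {mid:<18}{terms}")
            for key in ("restart", "validation_rmse", "C", "lambda"):
                if key in self.params.metadata:
                    lines.append(f"{key:<22}{self.params.metadata[key]!s:>16}")
        else:
            lines.append(f"{'ANN epochs':<22}{self.net.n_epochs:>10}")
        lines.append("=" * 58)
        return "\n".join(lines)
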