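"""Data allocation, goodness-of-fit metrics, residual diagnostics and the
statistical test battery.

Metrics follow the classical definitions: Pearson r, R^2 = 1 - SSE/SST
(SST with squared deviations), and adjusted R^2 penalised by the model's
parameter count k. Bland-Altman residual diagnostics use bias +/- 1 SD
limits by default (the convention used for the EMG-force residual plots
this mirrors; pass ``n_sd=1.96`` for the conventional clinical limits).

The test battery: paired-t bias test, one-way repeated-measures ANOVA with
Bonferroni-corrected pairwise comparisons, Mann-Whitney U, ROC with the
Youden-optimal cutoff, a paired DeLong-style AUC comparison, and the
noncentral-F sample-size computation for multiple regression.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .signals import DataError

__all__ = [
    "Split",
    "allocate_data",
    "Metrics",
    "compute_metrics",
    "BlandAltmanSummary",
    "bland_altman",
    "StatTestResult",
    "bias_t_test",
    "compare_models_rm",
    "mann_whitney",
    "ROCResult",
    "roc_youden",
    "compare_auc",
    "regression_sample_size",
    "normality_test",
    "TimingReport",
    "timing_harness",
]


# ------------------------------------------------------------ allocation

@dataclass
class Split:
    """Partition of N time samples into estimation / validation / test."""

    estimation_idx: np.ndarray
    validation_idx: np.ndarray
    test_idx: np.ndarray
    scheme: str = "contiguous"
    fractions: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        e = np.asarray(self.estimation_idx, dtype=int)
        v = np.asarray(self.validation_idx, dtype=int)
        t = np.asarray(self.test_idx, dtype=int)
        all_idx = np.concatenate([e, v, t])
        if len(np.unique(all_idx)) != all_idx.size:
            raise DataError("split index sets overlap")
        self.estimation_idx, self.validation_idx, self.test_idx = e, v, t

    @property
    def n(self) -> int:
        return self.estimation_idx.size + self.validation_idx.size + self.test_idx.size


def allocate_data(n: int, fractions: Sequence[float], scheme: str = "contiguous") -> Split:
    """Partition ``n`` samples into 2 (estimation/test) or 3
    (estimation/validation/test) sets.

    contiguous: time-ordered blocks in fraction order — the default,
    because consecutive samples are strongly autocorrelated and block
    splits keep the held-out data genuinely unseen. interleaved: samples
    assigned round-robin in proportion to the fractions.
    """
    fr = tuple(float(f) for f in fractions)
    if len(fr) not in (2, 3):
        raise DataError("fractions must name 2 or 3 subsets")
    if abs(sum(fr) - 1.0) > 1e-9:
        raise DataError(f"fractions must sum to 1, got {sum(fr)}")
    if any(f < 0 or f > 1 for f in fr):
        raise DataError("fractions must lie in [0, 1]")
    n_nonzero = sum(1 for f in fr if f > 0)
    if n < n_nonzero:
        raise DataError(f"cannot split {n} samples into {n_nonzero} nonempty sets")

    if scheme == "contiguous":
        # cumulative rounding keeps every block within 1 of n*fraction
        edges = np.round(np.cumsum((0.0,) + fr) * n).astype(int)
        sets = [np.arange(edges[i], edges[i + 1]) for i in range(len(fr))]
    elif scheme == "interleaved":
        targets = np.asarray(fr) * n
        counts = np.zeros(len(fr), dtype=int)
        owner = np.empty(n, dtype=int)
        for i in range(n):
            deficit = targets * (i + 1) / n - counts
            j = int(np.argmax(deficit))
            owner[i] = j
            counts[j] += 1
        sets = [np.flatnonzero(owner == j) for j in range(len(fr))]
    else:
        raise DataError(f"unknown split scheme {scheme!r}")

    if len(fr) == 2:
        est, test = sets
        val = np.array([], dtype=int)
    else:
        est, val, test = sets
    return Split(est, val, test, scheme=scheme, fractions=fr)


# --------------------------------------------------------------- metrics

@dataclass
class Metrics:
    r: float
    R2: float
    adjR2: float
    RMSE: float
    MAE: float
    SSE: float
    SST: float
    N: int
    k: int


def compute_metrics(measured: np.ndarray, predicted: np.ndarray, k: int) -> Metrics:
    """Goodness-of-fit between measured and predicted force.

    R^2 may be negative for models worse than the mean predictor; it is
    reported as computed, never clipped.
    """
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise DataError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 3:
        raise DataError("metrics need at least 3 samples")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DataError("measured signal is constant: R^2 undefined (SST = 0)")
    sse = float(np.sum((y - yhat) ** 2))
    dy = y - y.mean()
    dyh = yhat - yhat.mean()
    denom = math.sqrt(float(dy @ dy) * float(dyh @ dyh))
    r = float(dy @ dyh) / denom if denom > 0 else 0.0
    r2 = 1.0 - sse / sst
    n = y.size
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1) if n - k - 1 > 0 else float("nan")
    return Metrics(
        r=r, R2=r2, adjR2=adj,
        RMSE=float(np.sqrt(sse / n)), MAE=float(np.mean(np.abs(y - yhat))),
        SSE=sse, SST=sst, N=n, k=k,
    )


# ---------------------------------------------------------- Bland-Altman

@dataclass
class BlandAltmanSummary:
    bias: float
    sd: float
    upper: float
    lower: float
    residual_regression: tuple[float, float]  # (slope, intercept)
    n_sd: float = 1.0


def bland_altman(measured: np.ndarray, predicted: np.ndarray, n_sd: float = 1.0) -> BlandAltmanSummary:
    """Residual (predicted - measured) agreement summary: bias, SD,
    bias +/- n_sd*SD limits, and the LS regression line of the residual on
    the measured signal (homogeneity-of-variance diagnostic)."""
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size:
        raise DataError(f"length mismatch: {y.size} vs {yhat.size}")
    if y.size < 2:
        raise DataError("Bland-Altman needs at least 2 samples")
    resid = yhat - y
    bias = float(resid.mean())
    sd = float(resid.std(ddof=1))
    if np.ptp(y) > 0:
        slope, intercept = np.polyfit(y, resid, 1)
    else:
        slope, intercept = 0.0, bias
    return BlandAltmanSummary(
        bias=bias, sd=sd, upper=bias + n_sd * sd, lower=bias - n_sd * sd,
        residual_regression=(float(slope), float(intercept)), n_sd=n_sd,
    )


# ---------------------------------------------------------- test battery

@dataclass
class StatTestResult:
    statistic: float
    p_value: float
    test_name: str
    df: float | tuple | None = None
    adj_p_value: float | None = None
    extra: dict = field(default_factory=dict)


def bias_t_test(measured: np.ndarray, predicted: np.ndarray) -> StatTestResult:
    """Paired-sample t test of the residuals against zero bias.

    Identical inputs (zero residual variance, zero mean) return t = 0,
    p = 1 by convention.
    """
    y = np.asarray(measured, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.size != yhat.size or y.size < 2:
        raise DataError("paired t test needs >= 2 paired samples")
    resid = yhat - y
    if np.allclose(resid.std(), 0.0):
        if np.allclose(resid.mean(), 0.0):
            return StatTestResult(0.0, 1.0, "paired t (bias)", df=y.size - 1)
        return StatTestResult(float("inf"), 0.0, "paired t (bias)", df=y.size - 1)
    t, p = stats.ttest_1samp(resid, 0.0)
    return StatTestResult(float(t), float(p), "paired t (bias)", df=y.size - 1)


def compare_models_rm(
    scores: np.ndarray,
    reference: int = 0,
) -> tuple[StatTestResult, list[StatTestResult]]:
    """One-way repeated-measures ANOVA across models plus Bonferroni-
    corrected paired t tests of the reference model against each other.

    ``scores`` is (subjects x models), complete. Classical within-subject
    decomposition, no sphericity correction. Degenerate data (zero error
    mean square) return F = 0, p = 1 when models do not differ, else
    F = inf, p = 0.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[0] < 2 or S.shape[1] < 2:
        raise DataError("scores must be a (subjects >= 2) x (models >= 2) matrix")
    if not np.all(np.isfinite(S)):
        raise DataError("score matrix is incomplete (non-finite entries)")
    n_sub, n_mod = S.shape
    grand = S.mean()
    ss_models = n_sub * float(np.sum((S.mean(axis=0) - grand) ** 2))
    ss_subjects = n_mod * float(np.sum((S.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((S - grand) ** 2))
    ss_error = ss_total - ss_models - ss_subjects
    df_m = n_mod - 1
    df_e = (n_sub - 1) * (n_mod - 1)
    ms_m = ss_models / df_m
    ms_e = max(ss_error, 0.0) / df_e
    # relative tolerance: numerically-zero effect SS counts as no effect
    no_effect = ss_models <= 1e-12 * max(ss_total, 1e-300)
    if ms_e <= 1e-12 * max(ss_total / max(df_e, 1), 1e-300):
        F, p = (0.0, 1.0) if no_effect else (float("inf"), 0.0)
    else:
        F = ms_m / ms_e
        p = float(stats.f.sf(F, df_m, df_e))
    omnibus = StatTestResult(float(F), p, "rm-ANOVA", df=(df_m, df_e))

    pairwise: list[StatTestResult] = []
    m_comp = n_mod - 1
    for j in range(n_mod):
        if j == reference:
            continue
        diff = S[:, reference] - S[:, j]
        if np.allclose(diff.std(), 0.0):
            t, p_raw = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (float("inf"), 0.0)
        else:
            t, p_raw = stats.ttest_rel(S[:, reference], S[:, j])
        pairwise.append(
            StatTestResult(
                float(t), float(p_raw), f"paired t (model {reference} vs {j})",
                df=n_sub - 1, adj_p_value=min(1.0, m_comp * float(p_raw)),
            )
        )
    return omnibus, pairwise


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Brute-force-equivalent U of group a: number of (a, b) pairs with
    a > b, plus half the ties (computed via midranks)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    return float(np.sum(ranks[: a.size]) - a.size * (a.size + 1) / 2.0)


def mann_whitney(group_a: np.ndarray, group_b: np.ndarray) -> StatTestResult:
    """Two-sided Mann-Whitney U test.

    Small tie-free samples use the exact null distribution; small samples
    with ties use full enumeration over label assignments (bounded by the
    number of assignments, not the sample product, because C(n, n_a)
    explodes far earlier than n_a*n_b); otherwise the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise DataError("both groups must be nonempty")
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n_assign = math.comb(a.size + b.size, a.size)
    if not has_ties and a.size * b.size <= 400:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        return StatTestResult(float(res.statistic), float(res.pvalue), "Mann-Whitney U (exact)")
    if has_ties and n_assign <= 20_000:
        # full enumeration of label assignments under the null
        mu = a.size * b.size / 2.0
        obs_dev = abs(u - mu)
        idx = np.arange(pooled.size)
        count = 0
        for comb in combinations(idx, a.size):
            mask = np.zeros(pooled.size, dtype=bool)
            mask[list(comb)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u_perm - mu) >= obs_dev - 1e-12:
                count += 1
        return StatTestResult(u, count / n_assign, "Mann-Whitney U (enumeration)")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return StatTestResult(float(res.statistic), float(res.pvalue), "Mann-Whitney U (normal approx.)")


# ------------------------------------------------------------------- ROC

@dataclass
class ROCResult:
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    scores: np.ndarray = field(default=None, repr=False)
    labels: np.ndarray = field(default=None, repr=False)

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def roc_youden(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve with the Youden-optimal operating point.

    AUC uses the rank (Mann-Whitney) identity U/(n1*n0), so it equals the
    probability that a random positive outscores a random negative (ties
    counted half). The cutoff maximises J = sensitivity + specificity - 1;
    ties are broken toward higher specificity.
    """
    from sklearn.metrics import roc_curve

    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(int)
    if s.size != y.size:
        raise DataError("scores and labels differ in length")
    if np.unique(y).size < 2:
        raise DataError("ROC needs both classes present")
    pos, neg = s[y == 1], s[y == 0]
    auc = _u_statistic(pos, neg) / (pos.size * neg.size)
    fpr, tpr, thr = roc_curve(y, s)
    j = tpr - fpr
    best_j = np.max(j)
    # among J-ties take the lowest false-positive rate (highest specificity)
    candidates = np.flatnonzero(j >= best_j - 1e-12)
    best = candidates[np.argmin(fpr[candidates])]
    return ROCResult(
        auc=float(auc), cutoff=float(thr[best]),
        sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
        fpr=fpr, tpr=tpr, thresholds=thr, scores=s, labels=y,
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placements: V10[i] = fraction of negatives that positive i
    outscores (ties half), and symmetrically V01."""
    v10 = np.empty(pos.size)
    for i, x in enumerate(pos):
        v10[i] = (np.sum(x > neg) + 0.5 * np.sum(x == neg)) / neg.size
    v01 = np.empty(neg.size)
    for i, x in enumerate(neg):
        v01[i] = (np.sum(pos > x) + 0.5 * np.sum(pos == x)) / pos.size
    return v10, v01


def compare_auc(result_a: ROCResult, result_b: ROCResult) -> StatTestResult:
    """Paired comparison of two AUCs measured on the same subjects, using
    the covariance of DeLong placements; two-sided normal p."""
    for r in (result_a, result_b):
        if r.scores is None or r.labels is None:
            raise DataError("compare_auc needs ROCResults carrying their data")
    if result_a.labels.size != result_b.labels.size or np.any(result_a.labels != result_b.labels):
        raise DataError("AUC comparison requires the same subjects/labels (paired)")
    y = result_a.labels
    pa, na = result_a.scores[y == 1], result_a.scores[y == 0]
    pb, nb = result_b.scores[y == 1], result_b.scores[y == 0]
    v10a, v01a = _placements(pa, na)
    v10b, v01b = _placements(pb, nb)
    n1, n0 = pa.size, na.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / n1 + s01 / n0  # 2x2 covariance of (auc_a, auc_b)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    d = result_a.auc - result_b.auc
    if var_diff <= 1e-300:
        z, p = (0.0, 1.0) if abs(d) < 1e-12 else (float("inf"), 0.0)
    else:
        z = d / math.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return StatTestResult(float(z), p, "DeLong paired AUC", extra={"auc_diff": d})


# ----------------------------------------------------- power / timing

def regression_sample_size(
    r2_expected: float,
    k: int,
    power: float = 0.80,
    alpha: float = 0.05,
    max_n: int = 1_000_000,
) -> int:
    """Minimum N for the overall F test of a k-predictor regression to
    reach the requested power.

    Effect size f^2 = R^2/(1 - R^2); the F statistic under the alternative
    is noncentral with lambda = f^2 * N, numerator df k, denominator df
    N - k - 1 (the common software convention for this computation).
    """
    if not (0 < r2_expected < 1):
        raise ValueError("R2 must lie strictly between 0 and 1")
    if k < 1 or not (0 < power < 1) or not (0 < alpha < 1):
        raise ValueError("invalid k, power or alpha")
    f2 = r2_expected / (1.0 - r2_expected)
    n = k + 2  # smallest N with denominator df >= 1
    while n <= max_n:
        df2 = n - k - 1
        fcrit = stats.f.isf(alpha, k, df2)
        achieved = float(stats.ncf.sf(fcrit, k, df2, f2 * n))
        if achieved >= power:
            return n
        n += 1
    raise DataError(f"requested power {power} not reachable below N = {max_n}")


def normality_test(x: np.ndarray) -> StatTestResult:
    """Shapiro-Wilk normality check (delegated to scipy)."""
    w, p = stats.shapiro(np.asarray(x, dtype=float).ravel())
    return StatTestResult(float(w), float(p), "Shapiro-Wilk")


@dataclass
class TimingReport:
    train_times_s: np.ndarray
    test_times_s: np.ndarray
    epoch_ms: float
    samples_per_epoch: int

    @staticmethod
    def _summ(t: np.ndarray) -> dict:
        if t.size == 0:
            return {"mean": None, "sd": None, "min": None, "max": None, "n": 0}
        return {
            "mean": float(t.mean()), "sd": float(t.std(ddof=1)) if t.size > 1 else 0.0,
            "min": float(t.min()), "max": float(t.max()), "n": int(t.size),
        }

    def summary(self) -> dict:
        return {
            "train_s": self._summ(self.train_times_s),
            "test_s": self._summ(self.test_times_s),
            "epoch_ms": self.epoch_ms,
            "samples_per_epoch": self.samples_per_epoch,
        }


def timing_harness(
    fit_fn: Callable[[np.ndarray], object],
    predict_fn: Callable[[object, np.ndarray], np.ndarray],
    epochs: Sequence[np.ndarray],
    epoch_ms: float = 250.0,
    fs: float = 2048.0,
) -> TimingReport:
    """Wall-clock timing of per-epoch training and prediction.

    ``epochs`` is a sequence of per-epoch sample index arrays (each of
    ``round(fs * epoch_ms / 1000)`` samples); fit_fn and predict_fn receive
    the index array. Timings are reported, never asserted against any
    particular hardware.
    """
    samples_per_epoch = int(round(fs * epoch_ms / 1000.0))
    train_t, test_t = [], []
    for idx in epochs:
        t0 = time.perf_counter()
        fitted = fit_fn(idx)
        train_t.append(time.perf_counter() - t0)
        t0 = time.perf_counter()
        predict_fn(fitted, idx)
        test_t.append(time.perf_counter() - t0)
    return TimingReport(
        train_times_s=np.asarray(train_t),
        test_times_s=np.asarray(test_t),
        epoch_ms=epoch_ms,
        samples_per_epoch=samples_per_epoch,
    )
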