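"""Exponential-decay fitting of time-course monoisotopic RIAs.

During continuous ²H₂O labeling, the monoisotopic RIA of a peptide
decays from its natural value I0(0) toward a plateau I0_asymp as the
protein pool turns over:

    I0(t) = I0_asymp + (I0(0) - I0_asymp) * exp(-k t)

with k the first-order turnover rate in day^-1.  Two fitting modes are
provided:

* one-parameter: I0_asymp is fixed from the enrichment model
  (I0(0) * (1 - pW/(1-pH))**NEH) and only k is fitted;
* two-parameter: k and I0_asymp are fitted jointly, which also yields
  an experimental estimate of the labeling plateau.

Both minimise the sum of squared residuals with BFGS on unconstrained
parameters, using the transforms k = exp(-theta) (rates cannot be
negative) and I0_asymp = I0(0)/(1 + exp(-alpha)) (the plateau cannot
exceed the natural RIA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import minimize
from scipy.stats import t as student_t

from .isotope_model import EnrichmentModel, PeptideSpec, asymptotic_ria

__all__ = [
    "QuantSource",
    "TimePoint",
    "PeptideTimeCourse",
    "FitResult",
    "predict_ria",
    "transform_parameters",
    "fit_one_parameter",
    "fit_two_parameter",
    "goodness_of_fit",
    "rate_confidence_interval",
]

# BFGS controls: iteration cap and the absolute SSE change between two
# successive iterates below which the fit is declared converged.
MAX_ITERATIONS = 500
SSE_TOL = 1e-10
FD_STEP = 1e-6  # central-difference gradient step
DEFAULT_K0 = 0.05  # day^-1, physically typical starting rate


class QuantSource(str, Enum):
    """Provenance of a quantified time point."""

    IDENTIFIED = "identified"
    MBR_TRANSFERRED = "mbr_transferred"


@dataclass
class TimePoint:
    t: float  # labeling duration, days
    I0: float  # monoisotopic RIA
    raw: np.ndarray | None = None  # raw isotopomer abundances, if kept
    quant_source: QuantSource = QuantSource.IDENTIFIED


@dataclass
class PeptideTimeCourse:
    """Per-time-point monoisotopic RIAs for one peptide/charge."""

    spec: PeptideSpec
    points: list[TimePoint]
    I0_natural: float
    average_monoisotope_abundance: float = 0.0

    def __post_init__(self) -> None:
        self.points = sorted(self.points, key=lambda p: p.t)
        for p in self.points:
            if p.t < 0:
                raise ValueError("labeling times must be nonnegative")
            if np.isfinite(p.I0) and not (0.0 < p.I0 <= 1.0):
                raise ValueError("RIA values must lie in (0, 1]")

    @property
    def ndp(self) -> int:
        """Number of quantified (finite-RIA) data points."""
        return sum(1 for p in self.points if np.isfinite(p.I0))

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, RIAs) over the quantified points only."""
        pts = [(p.t, p.I0) for p in self.points if np.isfinite(p.I0)]
        if not pts:
            return np.empty(0), np.empty(0)
        t, y = map(np.asarray, zip(*pts))
        return t.astype(float), y.astype(float)


@dataclass
class FitResult:
    k: float
    I0_asymp: float
    model: str  # "one_parameter" | "two_parameter"
    theta: float
    alpha: float | None
    NDP: int
    converged: bool
    sse: float
    R2: float = math.nan
    pearson_r: float = math.nan
    RMSE: float = math.nan
    SD: float = math.nan
    ci_lower: float = math.nan
    ci_upper: float = math.nan
    ci_unbounded: bool = False
    n_parameters: int = 1
    I0_natural: float = math.nan
    predicted: np.ndarray = field(default_factory=lambda: np.empty(0))
    observed: np.ndarray = field(default_factory=lambda: np.empty(0))
    times: np.ndarray = field(default_factory=lambda: np.empty(0))


def predict_ria(t, k: float, I0_natural: float, I0_asymp: float):
    """Model monoisotopic RIA at labeling time ``t`` (days)."""
    if k < 0:
        raise ValueError("turnover rate must be nonnegative")
    if I0_asymp > I0_natural + 1e-12:
        raise ValueError("plateau RIA cannot exceed the natural RIA")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("labeling times must be nonnegative")
    out = I0_asymp + (I0_natural - I0_asymp) * np.exp(-k * t)
    return float(out) if out.ndim == 0 else out


def transform_parameters(
    theta: float, alpha: float, I0_natural: float
) -> tuple[float, float]:
    """Map unconstrained (theta, alpha) to admissible (k, I0_asymp).

    k = exp(-theta) is always positive; I0_asymp = I0(0)/(1+exp(-alpha))
    always lies in (0, I0(0)).
    """
    k = math.exp(-theta)
    I0_asymp = I0_natural / (1.0 + math.exp(-alpha))
    return k, I0_asymp


def _central_gradient(fun, x: np.ndarray, h: float = FD_STEP) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(x.size):
        e = np.zeros_like(x)
        e[i] = h
        g[i] = (fun(x + e) - fun(x - e)) / (2.0 * h)
    return g


def _minimize_bfgs(fun, x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """BFGS with central-difference gradients.

    Convergence is declared when scipy reports success, when the SSE
    change between the two final iterates drops below ``SSE_TOL``, or
    when the final gradient is numerically zero (BFGS may exit with a
    precision-loss status at an effectively exact optimum).
    """
    history: list[float] = [float(fun(x0))]

    def callback(xk):
        history.append(float(fun(xk)))

    res = minimize(
        fun,
        x0,
        method="BFGS",
        jac=lambda x: _central_gradient(fun, x),
        callback=callback,
        options={"maxiter": MAX_ITERATIONS, "gtol": 1e-14},
    )
    small_change = len(history) >= 2 and abs(history[-1] - history[-2]) < SSE_TOL
    tiny_grad = np.linalg.norm(np.atleast_1d(res.jac), np.inf) < 1e-7
    converged = bool(res.success) or small_change or tiny_grad
    return np.atleast_1d(res.x), float(res.fun), converged


def _finalize(
    fit: FitResult, tc: PeptideTimeCourse, level: float = 0.95
) -> FitResult:
    goodness_of_fit(tc, fit, attach=True)
    if fit.converged and fit.NDP > fit.n_parameters:
        rate_confidence_interval(tc, fit, level=level, attach=True)
    return fit


def fit_one_parameter(
    tc: PeptideTimeCourse,
    model: EnrichmentModel,
    I0_asymp: float | None = None,
    level: float = 0.95,
) -> FitResult:
    """Fit the turnover rate with the plateau fixed by the enrichment model.

    ``I0_asymp`` may be supplied directly; otherwise it is computed as
    I0(0) * (1 - pW/(1-pH))**NEH from the peptide's NEH.
    """
    t, y = tc.arrays()
    if t.size < 3:
        raise ValueError(f"one-parameter fit needs NDP >= 3, got {t.size}")
    if I0_asymp is None:
        I0_asymp = asymptotic_ria(tc.I0_natural, model, tc.spec.neh)

    def sse(x):
        k = math.exp(-x[0])
        resid = y - predict_ria(t, k, tc.I0_natural, I0_asymp)
        return float(resid @ resid)

    x0 = np.array([-math.log(DEFAULT_K0)])
    x, fval, converged = _minimize_bfgs(sse, x0)
    k = math.exp(-x[0])
    fit = FitResult(
        k=k,
        I0_asymp=I0_asymp,
        model="one_parameter",
        theta=float(x[0]),
        alpha=None,
        NDP=t.size,
        converged=converged,
        sse=fval,
        n_parameters=1,
        I0_natural=tc.I0_natural,
    )
    return _finalize(fit, tc, level)


def fit_two_parameter(
    tc: PeptideTimeCourse,
    model: EnrichmentModel | None = None,
    level: float = 0.95,
) -> FitResult:
    """Fit the turnover rate and the plateau RIA jointly.

    The plateau initial guess comes from the enrichment model when one
    is given (start at the physically expected plateau), else from the
    smallest observed RIA.
    """
    t, y = tc.arrays()
    if t.size < 4:
        raise ValueError(f"two-parameter fit needs NDP >= 4, got {t.size}")
    I0n = tc.I0_natural
    if model is not None:
        plateau0 = asymptotic_ria(I0n, model, tc.spec.neh)
    else:
        plateau0 = min(float(np.min(y)), I0n * 0.999)
    plateau0 = min(max(plateau0, 1e-6 * I0n), (1.0 - 1e-9) * I0n)
    # invert the sigmoid transform for the initial alpha
    alpha0 = -math.log(I0n / plateau0 - 1.0)

    def sse(x):
        k = math.exp(-x[0])
        I0a = I0n / (1.0 + math.exp(-x[1]))
        resid = y - predict_ria(t, k, I0n, I0a)
        return float(resid @ resid)

    x0 = np.array([-math.log(DEFAULT_K0), alpha0])
    x, fval, converged = _minimize_bfgs(sse, x0)
    k, I0a = transform_parameters(x[0], x[1], I0n)
    fit = FitResult(
        k=k,
        I0_asymp=I0a,
        model="two_parameter",
        theta=float(x[0]),
        alpha=float(x[1]),
        NDP=t.size,
        converged=converged,
        sse=fval,
        n_parameters=2,
        I0_natural=I0n,
    )
    return _finalize(fit, tc, level)


def goodness_of_fit(
    tc: PeptideTimeCourse, fit: FitResult, attach: bool = False
) -> tuple[float, float, float, float]:
    """GOF metrics of a fit: (R2, pearson_r, RMSE, SD).

    R2 = 1 - SSE/SStot; r is the Pearson correlation of observed vs
    predicted RIAs; RMSE = sqrt(SSE/NDP); SD = sqrt(SSE/(NDP - p)) is
    the residual standard deviation with p fitted parameters.  When the
    observations have zero variance, r is undefined (NaN) and R2 is
    reported as 0.
    """
    t, y = tc.arrays()
    n = t.size
    if n < 3:
        raise ValueError("GOF needs at least 3 data points")
    pred = predict_ria(t, fit.k, fit.I0_natural, fit.I0_asymp)
    resid = y - pred
    sse = float(resid @ resid)
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot > 0:
        r2 = 1.0 - sse / sstot
    else:
        r2 = 0.0
    if sstot > 0 and np.ptp(pred) > 0:
        r = float(np.corrcoef(y, pred)[0, 1])
    else:
        r = math.nan
    rmse = math.sqrt(sse / n)
    p = fit.n_parameters
    sd = math.sqrt(sse / (n - p)) if n > p else math.nan
    if attach:
        fit.R2, fit.pearson_r, fit.RMSE, fit.SD = r2, r, rmse, sd
        fit.sse = sse
        fit.times, fit.observed, fit.predicted = t, y, pred
    return r2, r, rmse, sd


def _sse_in_natural_params(tc: PeptideTimeCourse, fit: FitResult):
    t, y = tc.arrays()
    I0n = fit.I0_natural

    if fit.n_parameters == 1:
        def sse(v):
            resid = y - predict_ria(t, max(v[0], 0.0), I0n, fit.I0_asymp)
            return float(resid @ resid)
    else:
        def sse(v):
            resid = y - predict_ria(t, max(v[0], 0.0), I0n, min(v[1], I0n))
            return float(resid @ resid)
    return sse


def rate_confidence_interval(
    tc: PeptideTimeCourse,
    fit: FitResult,
    level: float = 0.95,
    attach: bool = False,
) -> tuple[float, float]:
    """Wald confidence interval for the turnover rate.

    The standard error of k comes from the delta method: the Hessian of
    the SSE in natural parameters is differenced numerically at the
    optimum, the parameter covariance is 2*sigma^2*H^-1 with sigma^2 the
    residual variance SSE/(NDP-p), and the interval uses the Student-t
    quantile with NDP-p degrees of freedom.  The lower bound is clamped
    at zero.  A singular Hessian yields an unbounded interval, flagged
    on the result.
    """
    if not fit.converged:
        raise ValueError("confidence interval requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    n, p = fit.NDP, fit.n_parameters
    if n <= p:
        raise ValueError("need NDP > number of fitted parameters")
    sse = _sse_in_natural_params(tc, fit)
    x = np.array([fit.k] if p == 1 else [fit.k, fit.I0_asymp])
    h = np.maximum(1e-5 * np.abs(x), 1e-8)
    H = np.empty((p, p))
    f0 = sse(x)
    for i in range(p):
        ei = np.zeros(p)
        ei[i] = h[i]
        H[i, i] = (sse(x + ei) - 2.0 * f0 + sse(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                sse(x + ei + ej) - sse(x + ei - ej)
                - sse(x - ei + ej) + sse(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    sigma2 = fit.sse / (n - p)
    try:
        cov = 2.0 * sigma2 * np.linalg.inv(H)
        var_k = float(cov[0, 0])
        if not np.isfinite(var_k) or var_k < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        if attach:
            fit.ci_lower, fit.ci_upper, fit.ci_unbounded = 0.0, math.inf, True
        return 0.0, math.inf
    se = math.sqrt(var_k)
    q = student_t.ppf(0.5 + level / 2.0, n - p)
    lo, hi = max(fit.k - q * se, 0.0), fit.k + q * se
    if attach:
        fit.ci_lower, fit.ci_upper, fit.ci_unbounded = lo, hi, False
    return lo, hi
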