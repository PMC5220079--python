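"""Six single-predictor regression models and their fit statistics.

The screening modules relate a trait y to one predictor x (a single
wavelength's reflectance, or one spectral index) through:

========== =============================== ==========
model      formula                         parameters
========== =============================== ==========
poly1       y = p1*x + p2                   2
poly2       y = p1*x^2 + p2*x + p3          2 + 1
weibull     y = p1*p2*x^(p2-1)*e^(-p1*x^p2) 2
exponential y = p1*e^(p2*x)                 2
power       y = p1 + p2*x^p3                3
logarithmic y = p1*ln(x) + p2               2
========== =============================== ==========

poly1/poly2/logarithmic are solved exactly by linear least squares; the
other three by damped (Levenberg-Marquardt-style) nonlinear least squares
with deterministic data-driven seeds, so repeated runs are bit-identical.
Statistics are the usual SSE, DFE = n - m, R^2 = 1 - SSE/SST,
adjR^2 = 1 - (1-R^2)(n-1)/(n-m) and RMSE = sqrt(SSE/DFE); R^2 for the
nonlinear models keeps the same definition and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DomainError, InsufficientDataError

#: canonical model order; also the tie-break order when best models tie
MODEL_ORDER: tuple[str, ...] = (
    "poly1", "poly2", "weibull", "exponential", "power", "logarithmic",
)

_N_PARAMS = {
    "poly1": 2, "poly2": 3, "weibull": 2,
    "exponential": 2, "power": 3, "logarithmic": 2,
}

#: models whose domain requires strictly positive x
_POSITIVE_X = {"weibull", "power", "logarithmic"}

_EXP_CLIP = 700.0  # keep exp() finite inside the optimizer


def n_params(model: str) -> int:
    try:
        return _N_PARAMS[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; one of {MODEL_ORDER}") from None


def predict(model: str, params: tuple[float, ...], x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    p = params
    if model == "poly1":
        return p[0] * x + p[1]
    if model == "poly2":
        return p[0] * x**2 + p[1] * x + p[2]
    if model == "weibull":
        with np.errstate(over="ignore", invalid="ignore"):
            return p[0] * p[1] * x ** (p[1] - 1) * np.exp(
                -np.clip(p[0] * x ** p[1], -_EXP_CLIP, _EXP_CLIP)
            )
    if model == "exponential":
        return p[0] * np.exp(np.clip(p[1] * x, -_EXP_CLIP, _EXP_CLIP))
    if model == "power":
        with np.errstate(over="ignore", invalid="ignore"):
            return p[0] + p[1] * x ** p[2]
    if model == "logarithmic":
        return p[0] * np.log(x) + p[1]
    raise ValueError(f"unknown model {model!r}")


@dataclass
class FitStats:
    sse: float
    dfe: int
    r2: float
    adj_r2: float
    rmse: float
    degenerate: bool = False  # True when SST == 0 (constant response)


def fit_statistics(y: np.ndarray, yhat: np.ndarray, m: int) -> FitStats:
    """SSE/DFE/R2/adjR2/RMSE for observed y against fitted yhat."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    n = y.size
    if n <= m:
        raise InsufficientDataError(f"n={n} observations for m={m} parameters")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - np.mean(y)) ** 2))
    dfe = n - m
    if sst == 0.0:
        r2, degenerate = 0.0, True
    else:
        r2, degenerate = 1.0 - sse / sst, False
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - m)
    rmse = float(np.sqrt(sse / dfe))
    return FitStats(sse=sse, dfe=dfe, r2=r2, adj_r2=adj_r2, rmse=rmse,
                    degenerate=degenerate)


@dataclass
class RegressionFit:
    model: str
    params: tuple[float, ...]
    n: int
    m: int
    sse: float
    dfe: int
    r2: float
    adj_r2: float
    rmse: float
    converged: bool
    degenerate: bool = False

    @property
    def p1(self) -> float:
        return self.params[0]

    @property
    def p2(self) -> float:
        return self.params[1]

    @property
    def p3(self) -> float:
        return self.params[2] if len(self.params) > 2 else np.nan


def _drop_missing(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~np.isnan(x) & ~np.isnan(y)
    return x[keep], y[keep]


def _linear_solve(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _seed_exponential(x, y):
    if np.all(y > 0) or np.all(y < 0):
        sign = 1.0 if y[0] > 0 else -1.0
        coef = _linear_solve(np.column_stack([x, np.ones_like(x)]), np.log(np.abs(y)))
        return [(sign * float(np.exp(coef[1])), float(coef[0]))]
    return [(float(np.mean(y)), 0.0)]


def _seed_power(x, y):
    eps = 1e-6 * (np.ptp(y) if np.ptp(y) > 0 else 1.0)
    shifted = y - y.min() + eps
    coef = _linear_solve(
        np.column_stack([np.log(x), np.ones_like(x)]), np.log(shifted)
    )
    p3 = float(coef[0])
    seeds = []
    for exp_seed in (p3, 1.0):
        basis = x ** exp_seed
        lin = _linear_solve(np.column_stack([np.ones_like(x), basis]), y)
        seeds.append((float(lin[0]), float(lin[1]), exp_seed))
    return seeds


def _seed_weibull(x, y):
    # standard Weibull density f(x) = p1*p2*x^(p2-1)*exp(-p1*x^p2) with
    # p1 = scale^(-p2); seed the scale from the mean of x and sweep shapes
    scale = float(np.mean(x))
    return [(scale ** (-p2), p2) for p2 in (0.5, 1.0, 2.0, 5.0)]


def fit_model(x: np.ndarray, y: np.ndarray, model: str) -> RegressionFit:
    """Fit one model of y on x; pairs with a missing member are dropped.

    Raises DomainError when x violates the model's domain (x <= 0 for the
    logarithm/power/Weibull forms) and InsufficientDataError when fewer
    observations than parameters remain.  Nonconvergent nonlinear fits are
    returned with ``converged=False`` so report generators can exclude them.
    """
    m = n_params(model)
    x, y = _drop_missing(x, y)
    n = x.size
    if n <= m:
        raise InsufficientDataError(
            f"{model}: n={n} complete pairs for m={m} parameters"
        )
    if model in _POSITIVE_X and np.any(x <= 0):
        raise DomainError(f"{model} requires all x > 0")

    if model == "poly1":
        coef = _linear_solve(np.column_stack([x, np.ones_like(x)]), y)
        params, converged = (float(coef[0]), float(coef[1])), True
    elif model == "poly2":
        coef = _linear_solve(np.column_stack([x**2, x, np.ones_like(x)]), y)
        params, converged = tuple(float(c) for c in coef), True
    elif model == "logarithmic":
        coef = _linear_solve(np.column_stack([np.log(x), np.ones_like(x)]), y)
        params, converged = (float(coef[0]), float(coef[1])), True
    else:
        params, converged = _fit_nonlinear(x, y, model)

    yhat = predict(model, params, x)
    if not np.all(np.isfinite(yhat)):
        converged = False
        yhat = np.where(np.isfinite(yhat), yhat, np.mean(y))
    stats = fit_statistics(y, yhat, m)
    return RegressionFit(
        model=model, params=params, n=n, m=m,
        sse=stats.sse, dfe=stats.dfe, r2=stats.r2, adj_r2=stats.adj_r2,
        rmse=stats.rmse, converged=converged, degenerate=stats.degenerate,
    )


def _fit_nonlinear(x, y, model):
    seeds = {
        "exponential": _seed_exponential,
        "power": _seed_power,
        "weibull": _seed_weibull,
    }[model](x, y)

    def sse_of(params):
        r = predict(model, params, x) - y
        r = np.where(np.isfinite(r), r, 1e150)
        return float(np.sum(r * r))

    best_params, best_sse, converged = None, np.inf, False
    seed_floor = min(sse_of(s) for s in seeds)
    for seed in seeds:
        def residuals(p):
            r = predict(model, tuple(p), x) - y
            return np.where(np.isfinite(r), r, 1e150)

        try:
            res = least_squares(
                residuals, x0=np.asarray(seed, dtype=float),
                method="lm" if x.size >= len(seed) else "trf",
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=500 * len(seed),
            )
        except Exception:
            continue
        cand = tuple(float(v) for v in res.x)
        cand_sse = sse_of(cand)
        if cand_sse < best_sse:
            best_params, best_sse = cand, cand_sse
            converged = bool(res.success)
    if best_params is None or best_sse > seed_floor:
        # optimizer failed or moved uphill: fall back to the best seed
        best_params = min(seeds, key=sse_of)
        best_params = tuple(float(v) for v in best_params)
        converged = False
    return best_params, converged
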