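"""AR(p) mean models with GARCH(1,1) conditional variance.

The mean of each physiological series is modelled as an autoregression

    Z_t = c + a_1 Z_{t-1} + ... + a_p Z_{t-p} + tau_t,

and the innovation variance follows the GARCH(1,1) recursion

    sigma2_t = delta + beta * tau_{t-1}^2 + gamma * sigma2_{t-1},

with tau_t = sigma_t * eps_t, eps_t ~ iid(0, 1).  Estimation is two-stage:
the AR stage by conditional least squares, the variance stage by Gaussian
quasi-maximum likelihood (QMLE) on the AR residuals.  The Gaussian
likelihood is used even when innovations are heavy-tailed; QMLE remains
consistent for the variance parameters in that case.

Persistence (beta + gamma) governs how long a variance shock lingers; the
process is covariance-stationary iff persistence < 1, with unconditional
variance delta / (1 - beta - gamma) and volatility half-life
ln(0.5) / ln(beta + gamma) steps.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, signal
from scipy.special import expit, logit

__all__ = [
    "ARFit",
    "ARGarchFit",
    "VolatilitySummary",
    "fit_ar",
    "select_ar_order",
    "fit_garch",
    "fit_ar_garch",
    "conditional_variance_path",
    "volatility_summary",
    "one_step_forecasts",
]

_MAX_PERSISTENCE = 0.999
_LOGLIK_TOL = 1e-8
_MAX_ITER = 500


# ---------------------------------------------------------------------------
# AR mean model
# ---------------------------------------------------------------------------

@dataclass
class ARFit:
    """Conditional-least-squares AR(p) fit.

    ``residuals`` has length ``len(series) - p``; ``sigma2`` is the ML
    (1/n) residual variance and ``loglik`` the Gaussian log-likelihood of
    the residuals at that variance.
    """

    order_p: int
    coeffs: np.ndarray
    intercept: float
    residuals: np.ndarray
    sigma2: float
    loglik: float

    @property
    def n_params(self) -> int:
        # intercept + p AR coefficients + innovation variance
        return self.order_p + 2

    def to_dict(self) -> dict:
        return {
            "order_p": self.order_p,
            "coeffs": list(np.asarray(self.coeffs, dtype=float)),
            "intercept": float(self.intercept),
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
        }


def _gaussian_loglik_const_var(resid: np.ndarray, sigma2: float) -> float:
    n = resid.size
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def fit_ar(series, p: int) -> ARFit:
    """Fit AR(p) with intercept by conditional least squares.

    ``p = 0`` reduces to the sample mean.  A constant series with
    ``p >= 1`` has a singular lag design and is rejected.
    """
    z = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("series contains non-finite values")
    if p < 0:
        raise ValueError("p must be non-negative")
    n = z.size
    if n <= p + 2:
        raise ValueError(f"series length {n} too short for AR({p}); need > p + 2")

    if p == 0:
        intercept = float(z.mean())
        resid = z - intercept
        coeffs = np.empty(0)
    else:
        if np.ptp(z) == 0.0:
            raise ValueError("constant series with p >= 1: singular lag design")
        # design: [1, Z_{t-1}, ..., Z_{t-p}] for t = p .. n-1
        X = np.column_stack(
            [np.ones(n - p)] + [z[p - k - 1 : n - k - 1] for k in range(p)]
        )
        y = z[p:]
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise ValueError("singular lag design in AR regression")
        intercept = float(beta[0])
        coeffs = beta[1:]
        resid = y - X @ beta

    sigma2 = float(np.mean(resid**2))
    if sigma2 <= 0.0:
        sigma2 = np.finfo(float).tiny
    return ARFit(
        order_p=p,
        coeffs=coeffs,
        intercept=intercept,
        residuals=resid,
        sigma2=sigma2,
        loglik=_gaussian_loglik_const_var(resid, sigma2),
    )


def select_ar_order(series, p_max: int, criterion: str = "bic") -> int:
    """Pick the AR order minimising an information criterion.

    All candidate orders are fitted on the common sample that conditions on
    the first ``p_max`` observations, so the criteria are comparable.  Ties
    break toward the smaller order.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    criterion = criterion.lower()
    if criterion not in {"aic", "bic", "hqc"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    z = np.asarray(series, dtype=float)
    n = z.size
    # need at least a handful of effective observations at the largest order
    usable = n - p_max - 2
    if usable < 8:
        p_eff = max(1, n - 10)
        warnings.warn(
            f"series too short for p_max={p_max}; reduced to {p_eff}",
            UserWarning,
            stacklevel=2,
        )
        p_max = p_eff

    m = n - p_max  # common effective sample
    y = z[p_max:]
    best_p, best_val = 0, math.inf
    for p in range(p_max + 1):
        if p == 0:
            resid = y - y.mean()
        else:
            X = np.column_stack(
                [np.ones(m)] + [z[p_max - k - 1 : n - k - 1] for k in range(p)]
            )
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            if rank < X.shape[1]:
                continue
            resid = y - X @ beta
        sigma2 = max(float(np.mean(resid**2)), np.finfo(float).tiny)
        ll = _gaussian_loglik_const_var(resid, sigma2)
        k = p + 2
        if criterion == "aic":
            val = -2 * ll + 2 * k
        elif criterion == "bic":
            val = -2 * ll + k * math.log(m)
        else:  # hqc
            val = -2 * ll + 2 * k * math.log(math.log(m))
        if val < best_val - 1e-12:
            best_p, best_val = p, val
    return best_p


# ---------------------------------------------------------------------------
# GARCH(1,1) variance model
# ---------------------------------------------------------------------------

def conditional_variance_path(
    delta: float,
    beta: float,
    gamma: float,
    residuals,
    init: float | None = None,
    constrained: bool = True,
) -> np.ndarray:
    """Run the GARCH(1,1) variance recursion over a residual series.

    ``path[0]`` is the initial variance ``init`` (default: the unconditional
    variance when persistence < 1, else the sample variance of the
    residuals); for t >= 1,

        path[t] = delta + beta * residuals[t-1]**2 + gamma * path[t-1].

    The recursion is linear in sigma2 and is evaluated with a C-level IIR
    filter, keeping repeated likelihood evaluations cheap.
    """
    tau = np.asarray(residuals, dtype=float)
    if not np.all(np.isfinite(tau)):
        raise ValueError("residuals contain non-finite values")
    if constrained and delta < 0:
        raise ValueError("delta must be positive under constraints")
    if init is None:
        pers = beta + gamma
        if 0 <= pers < 1 and delta > 0:
            init = delta / (1.0 - pers)
        else:
            init = float(np.mean(tau**2))
    n = tau.size
    path = np.empty(n)
    path[0] = init
    if n > 1:
        drive = delta + beta * tau[:-1] ** 2
        # sigma2_t = drive_t + gamma * sigma2_{t-1}
        zi = signal.lfiltic([1.0], [1.0, -gamma], [init])
        path[1:], _ = signal.lfilter([1.0], [1.0, -gamma], drive, zi=zi)
    return path


def _garch_negloglik(delta, beta, gamma, tau, init):
    sigma2 = conditional_variance_path(delta, beta, gamma, tau, init=init,
                                       constrained=False)
    if np.any(sigma2 <= 0) or not np.all(np.isfinite(sigma2)):
        return math.inf, None
    nll = 0.5 * np.sum(np.log(2 * math.pi * sigma2) + tau**2 / sigma2)
    if not math.isfinite(nll):
        return math.inf, None
    return nll, sigma2


def fit_garch(
    residuals,
    constrained: bool = True,
) -> tuple[float, float, float, float, bool]:
    """Gaussian QMLE of GARCH(1,1) parameters on a residual series.

    Returns ``(delta, beta, gamma, loglik, converged)``.  The constrained
    fit enforces delta > 0, beta, gamma >= 0, beta + gamma <= 0.999 through
    a smooth reparametrisation; the homoskedastic boundary point
    (delta = sample variance, beta = gamma = 0) is always evaluated as a
    candidate so the fit never scores below the constant-variance model it
    nests.  The unconstrained mode performs raw QMLE subject only to a
    positive variance path and can return parameter sets (negative beta,
    gamma > 1) outside the stationarity region, with a warning.
    """
    tau = np.asarray(residuals, dtype=float)
    if tau.size < 20:
        raise ValueError("need at least 20 residuals for GARCH estimation")
    svar = float(np.var(tau))
    if svar <= 0:
        raise ValueError("zero-variance residuals: GARCH not identifiable")
    init = svar

    if constrained:
        def unpack(x):
            delta = math.exp(x[0])
            s = _MAX_PERSISTENCE * expit(x[1])
            w = expit(x[2])
            return delta, s * w, s * (1.0 - w)

        def nll(x):
            d, b, g = unpack(x)
            val, _ = _garch_negloglik(d, b, g, tau, init)
            return val

        # documented starting point: beta=0.05, gamma=0.85,
        # delta = (1 - beta - gamma) * sample variance
        s0, w0 = 0.90, 0.05 / 0.90
        x0 = np.array([math.log(0.10 * svar), logit(s0 / _MAX_PERSISTENCE), logit(w0)])
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": _LOGLIK_TOL, "maxiter": 4000},
        )
        d, b, g = unpack(res.x)
        best_nll = res.fun
        converged = bool(res.success)
        # Homoskedastic candidate (nested constant-variance model).  gamma is
        # unidentified when beta = 0, so when the likelihood gain over the
        # nested point does not cover the two extra parameters (AIC-style
        # margin) the boundary point is preferred.
        nll0 = 0.5 * tau.size * (math.log(2 * math.pi * svar) + 1.0)
        if nll0 < best_nll + 2.0:
            d, b, g, best_nll, converged = svar, 0.0, 0.0, nll0, True
        return d, b, g, -best_nll, converged

    def nll_raw(x):
        val, _ = _garch_negloglik(x[0], x[1], x[2], tau, init)
        return val

    x0 = np.array([0.10 * svar, 0.05, 0.85])
    res = optimize.minimize(
        nll_raw, x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": _LOGLIK_TOL, "maxiter": 4000},
    )
    d, b, g = res.x
    if b < 0 or g < 0 or b + g >= 1:
        warnings.warn(
            "unconstrained GARCH estimate violates stationarity constraints "
            f"(beta={b:.3g}, gamma={g:.3g})",
            UserWarning,
            stacklevel=2,
        )
    return float(d), float(b), float(g), -res.fun, bool(res.success)


@dataclass
class ARGarchFit:
    """Two-stage AR(p)+GARCH(1,1) fit."""

    ar: ARFit
    delta: float
    beta: float
    gamma: float
    cond_var_path: np.ndarray
    std_resid: np.ndarray
    loglik: float
    converged: bool
    constrained: bool

    @property
    def n_params(self) -> int:
        # intercept + p AR coefficients + (delta, beta, gamma)
        return self.ar.order_p + 4

    def to_dict(self) -> dict:
        return {
            "ar": self.ar.to_dict(),
            "delta": float(self.delta),
            "beta": float(self.beta),
            "gamma": float(self.gamma),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "constrained": bool(self.constrained),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def fit_ar_garch(series, p: int | None = None, constrained: bool = True,
                 p_max: int = 5, criterion: str = "bic") -> ARGarchFit:
    """Fit the AR(p) mean model, then GARCH(1,1) on its residuals.

    When ``p`` is None the order is chosen by ``select_ar_order``.  A
    non-converged variance optimisation is returned with
    ``converged=False``, never silently.
    """
    z = np.asarray(series, dtype=float)
    if z.size < 50:
        raise ValueError("series length must be >= 50 for stable QMLE")
    if np.ptp(z) == 0.0:
        raise ValueError("zero-variance series cannot be fitted")
    if p is None:
        p = select_ar_order(z, p_max=p_max, criterion=criterion)
    ar = fit_ar(z, p)
    d, b, g, ll, converged = fit_garch(ar.residuals, constrained=constrained)
    sigma2 = conditional_variance_path(d, b, g, ar.residuals,
                                       init=float(np.var(ar.residuals)),
                                       constrained=False)
    std_resid = ar.residuals / np.sqrt(sigma2)
    return ARGarchFit(
        ar=ar,
        delta=d,
        beta=b,
        gamma=g,
        cond_var_path=sigma2,
        std_resid=std_resid,
        loglik=ll,
        converged=converged,
        constrained=constrained,
    )


# ---------------------------------------------------------------------------
# Volatility summaries
# ---------------------------------------------------------------------------

@dataclass
class VolatilitySummary:
    """Persistence, shock half-life and unconditional variance.

    ``half_life_steps`` is infinite when persistence >= 1 and NaN
    (not applicable) when persistence <= 0; ``uncond_var`` is NaN when the
    process is not covariance-stationary.
    """

    persistence: float
    half_life_steps: float
    uncond_var: float


def volatility_summary(fit_or_params) -> VolatilitySummary:
    """Summarise a fitted variance equation.

    Accepts an :class:`ARGarchFit` or a ``(delta, beta, gamma)`` triple.
    Persistence is beta + gamma; half-life is ln(0.5)/ln(persistence) steps
    when 0 < persistence < 1.
    """
    if isinstance(fit_or_params, ARGarchFit):
        d, b, g = fit_or_params.delta, fit_or_params.beta, fit_or_params.gamma
    else:
        d, b, g = fit_or_params
    pers = b + g
    if 0.0 < pers < 1.0:
        half_life = math.log(0.5) / math.log(pers)
        uncond = d / (1.0 - pers) if d > 0 else math.nan
    elif pers >= 1.0:
        half_life = math.inf
        uncond = math.nan
    else:  # persistence <= 0: a shock does not decay geometrically
        half_life = math.nan
        uncond = d / (1.0 - pers) if d > 0 else math.nan
    return VolatilitySummary(persistence=pers, half_life_steps=half_life,
                             uncond_var=uncond)


def one_step_forecasts(fit: ARFit, series) -> tuple[np.ndarray, np.ndarray]:
    """In-sample one-step-ahead mean forecasts from an AR fit.

    Returns ``(actual, forecast)`` aligned on t = p .. n-1.
    """
    z = np.asarray(series, dtype=float)
    p = fit.order_p
    n = z.size
    if p == 0:
        fc = np.full(n, fit.intercept)
        return z, fc
    X = np.column_stack(
        [np.ones(n - p)] + [z[p - k - 1 : n - k - 1] for k in range(p)]
    )
    fc = X @ np.concatenate([[fit.intercept], fit.coeffs])
    return z[p:], fc
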