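"""Model-utility benchmarking: gating, fit gain, proxies, incremental validity.

The volatility model earns its keep in three steps:

1. *Precondition*: fit AR(p) (order by BIC), run ARCH-LM on the residuals,
   and proceed to GARCH only when heteroskedasticity is detected
   (p <= 0.05).
2. *Fit gain*: compare AR-only vs AR-GARCH by AIC/BIC (positive delta
   favours GARCH) and check that the GARCH standardised residuals no
   longer show volatility clustering (Ljung-Box on their squares).
3. *Incremental validity*: nested participant-level linear models of a
   clinical outcome — session means only vs means + volatility metrics
   (persistence, half-life, or model-free proxies) — compared by
   likelihood-ratio test, delta AIC and delta R^2.

Model-free volatility proxies (trailing rolling SD and EWMA variance over
30-60 s windows) allow the incremental test to be replicated without any
time-series model; the EWMA decay maps the requested window to
lambda = 1 - 2/(window + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .diagnostics import arch_lm_test, ljung_box_squared, DEFAULT_ARCH_LM_LAGS
from .garch import fit_ar, fit_ar_garch, select_ar_order

__all__ = [
    "UtilityReport",
    "volatility_proxy",
    "fit_gain",
    "incremental_validity",
]


@dataclass
class UtilityReport:
    arch_lm_p: float | None = None
    gated_garch: bool | None = None
    delta_aic: float | None = None
    delta_bic: float | None = None
    residual_vol_removed: bool | None = None
    garch_converged: bool | None = None
    lr_stat: float | None = None
    lr_df: int | None = None
    lr_p: float | None = None
    incr_delta_aic: float | None = None
    delta_r2: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def volatility_proxy(series, kind: str = "rolling_sd", window_s: int = 30,
                     enforce_window_range: bool = True) -> np.ndarray:
    """Model-free volatility proxy series (trailing windows).

    ``rolling_sd`` is the trailing rolling standard deviation;
    ``ewma`` is the exponentially weighted variance of the demeaned series
    with decay lambda = 1 - 2/(window_s + 1).
    """
    z = np.asarray(series, dtype=float)
    if enforce_window_range and not 30 <= window_s <= 60:
        raise ValueError("window_s outside the default [30, 60] s range; "
                         "pass enforce_window_range=False to override")
    if window_s >= z.size:
        raise ValueError("window longer than series")
    s = pd.Series(z)
    if kind == "rolling_sd":
        return s.rolling(window_s, min_periods=1).std(ddof=0).fillna(0.0).to_numpy()
    if kind == "ewma":
        lam = 1.0 - 2.0 / (window_s + 1.0)
        dev2 = (z - z.mean()) ** 2
        out = np.empty(z.size)
        v = dev2[0]
        for t in range(z.size):
            v = lam * v + (1.0 - lam) * dev2[t]
            out[t] = v
        return out
    raise ValueError(f"unknown proxy kind {kind!r}")


def fit_gain(series, p: int | None = None, arch_lm_lags: int = DEFAULT_ARCH_LM_LAGS,
             alpha: float = 0.05, p_max: int = 5) -> UtilityReport:
    """Gated AR vs AR-GARCH comparison on one series.

    Delta AIC/BIC are AR-only minus AR-GARCH (positive favours GARCH).
    When the ARCH-LM precondition fails, GARCH is not fitted and the deltas
    stay missing.  GARCH non-convergence is reported, never raised.
    """
    z = np.asarray(series, dtype=float)
    if p is None:
        p = select_ar_order(z, p_max=p_max, criterion="bic")
    ar = fit_ar(z, p)
    lm_stat, lm_p = arch_lm_test(ar.residuals, lags=arch_lm_lags)
    report = UtilityReport(arch_lm_p=lm_p, gated_garch=bool(lm_p <= alpha))
    if not report.gated_garch:
        return report
    try:
        fit = fit_ar_garch(z, p=p)
    except Exception:
        report.garch_converged = False
        return report
    report.garch_converged = fit.converged
    n = ar.residuals.size
    aic_ar = -2 * ar.loglik + 2 * ar.n_params
    bic_ar = -2 * ar.loglik + ar.n_params * math.log(n)
    aic_g = -2 * fit.loglik + 2 * fit.n_params
    bic_g = -2 * fit.loglik + fit.n_params * math.log(n)
    report.delta_aic = aic_ar - aic_g
    report.delta_bic = bic_ar - bic_g
    lags = min(arch_lm_lags, fit.std_resid.size - 3)
    _, lb_p = ljung_box_squared(fit.std_resid, lags=lags)
    report.residual_vol_removed = bool(lb_p > alpha)
    return report


def incremental_validity(cohort: pd.DataFrame, outcome_col: str,
                         mean_cols, vol_cols) -> UtilityReport:
    """Do volatility metrics predict the outcome beyond session means?

    Fits nested OLS models by maximum likelihood — M0: outcome ~ means,
    M1: outcome ~ means + volatility — and reports the likelihood-ratio
    chi-squared test (df = number of linearly independent added
    predictors), delta AIC (M0 - M1) and delta R^2.  Collinear added
    predictors reduce the LR degrees of freedom.
    """
    mean_cols = list(mean_cols)
    vol_cols = list(vol_cols)
    y = cohort[outcome_col].to_numpy(dtype=float)
    X0 = sm.add_constant(cohort[mean_cols].to_numpy(dtype=float)) if mean_cols \
        else np.ones((len(cohort), 1))
    m0 = sm.OLS(y, X0).fit()
    if not vol_cols:
        return UtilityReport(lr_stat=0.0, lr_df=0, lr_p=1.0,
                             incr_delta_aic=0.0, delta_r2=0.0)
    X1 = np.column_stack([X0, cohort[vol_cols].to_numpy(dtype=float)])
    df_added = np.linalg.matrix_rank(X1) - np.linalg.matrix_rank(X0)
    m1 = sm.OLS(y, X1).fit()
    lr = max(0.0, 2.0 * (m1.llf - m0.llf))
    lr_p = float(stats.chi2.sf(lr, df_added)) if df_added > 0 else 1.0
    return UtilityReport(
        lr_stat=float(lr),
        lr_df=int(df_added),
        lr_p=lr_p,
        incr_delta_aic=float(m0.aic - m1.aic),
        delta_r2=float(max(0.0, m1.rsquared - m0.rsquared)),
    )
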