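"""Normality, autocorrelation, heteroskedasticity and criterion diagnostics.

Moment diagnostics (skewness, kurtosis, Jarque-Bera) follow the
(m-1)-divisor moment-ratio convention with kurtosis on the raw scale
(normal reference = 3).  The Jarque-Bera statistic

    JB = n * (S^2 / 6 + (K - 3)^2 / 24)

is referred to the asymptotic chi-squared(2) distribution; rejection means
*departure from* normality (the standard reading).

Information criteria come in two conventions.  The "printed" forms,

    AIC = -2 ll + 2T,   SIC = -2 ll + (T + T ln M),   HQC = -2 ll + 2 (T + T ln M),

are the defaults used in this package's session tables, reported both raw
and per observation; the textbook forms (BIC = -2 ll + T ln M,
HQC = -2 ll + 2T ln ln M) are returned alongside as explicit variants.

Autocorrelation / heteroskedasticity / stationarity tests delegate to
statsmodels (Durbin-Watson, ARCH-LM, Ljung-Box, ADF).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import acorr_ljungbox, het_arch
from statsmodels.stats.stattools import durbin_watson as _sm_dw
from statsmodels.tsa.stattools import adfuller

__all__ = [
    "skewness",
    "kurtosis",
    "jarque_bera",
    "durbin_watson",
    "arch_lm_test",
    "ljung_box_squared",
    "adf_test",
    "information_criteria",
    "InformationCriteria",
    "DiagnosticsReport",
    "diagnostics_report",
]

DEFAULT_ARCH_LM_LAGS = 5


def _validate_moments_input(z: np.ndarray) -> float:
    if z.size < 3:
        raise ValueError("need at least 3 observations")
    sd = float(np.std(z, ddof=1))
    if sd == 0.0:
        raise ValueError("constant series: moment ratios undefined (zero sd)")
    return sd


def skewness(series) -> float:
    """Third moment ratio with (m-1) divisor and sample-sd scaling."""
    z = np.asarray(series, dtype=float)
    sd = _validate_moments_input(z)
    m = z.size
    return float(np.sum((z - z.mean()) ** 3) / ((m - 1) * sd**3))


def kurtosis(series) -> float:
    """Fourth moment ratio, raw scale (normal = 3), (m-1) divisor."""
    z = np.asarray(series, dtype=float)
    sd = _validate_moments_input(z)
    m = z.size
    return float(np.sum((z - z.mean()) ** 4) / ((m - 1) * sd**4))


def jarque_bera(series) -> tuple[float, float]:
    """Jarque-Bera normality statistic and chi-squared(2) p-value."""
    z = np.asarray(series, dtype=float)
    n = z.size
    s = skewness(z)
    k = kurtosis(z)
    stat = n * (s**2 / 6.0 + (k - 3.0) ** 2 / 24.0)
    return float(stat), float(stats.chi2.sf(stat, 2))


def durbin_watson(residuals) -> float:
    """First-order serial-correlation statistic, sum((de)^2)/sum(e^2).

    2 indicates no serial correlation; below 2 positive, 2-4 negative.
    """
    e = np.asarray(residuals, dtype=float)
    if e.size < 2:
        raise ValueError("need at least 2 residuals")
    if np.all(e == 0.0):
        raise ValueError("all-zero residuals: statistic undefined")
    return float(_sm_dw(e))


def durbin_watson_band(dw: float) -> str:
    """Interpretive band label for a Durbin-Watson value."""
    if dw < 2.0:
        return "positive autocorrelation"
    if dw > 2.0:
        return "negative autocorrelation"
    return "no autocorrelation"


def arch_lm_test(residuals, lags: int = DEFAULT_ARCH_LM_LAGS) -> tuple[float, float]:
    """Engle's ARCH-LM: n*R^2 of squared residuals on their own lags.

    Chi-squared(lags) p-value; significance indicates conditional
    heteroskedasticity in the residuals.
    """
    e = np.asarray(residuals, dtype=float)
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if e.size <= lags + 2:
        raise ValueError(f"need more than lags + 2 = {lags + 2} residuals")
    if np.ptp(e**2) == 0.0:
        raise ValueError("constant squared residuals: test degenerate")
    stat, pval, _, _ = het_arch(e, nlags=lags)
    return float(stat), float(pval)


def ljung_box_squared(residuals, lags: int) -> tuple[float, float]:
    """Ljung-Box portmanteau test applied to squared residuals."""
    e = np.asarray(residuals, dtype=float)
    if lags < 1:
        raise ValueError("lags must be >= 1")
    if e.size <= lags + 2:
        raise ValueError("series too short for requested lags")
    if np.ptp(e**2) == 0.0:
        raise ValueError("constant squared residuals: test degenerate")
    out = acorr_ljungbox(e**2, lags=[lags], return_df=True)
    return float(out["lb_stat"].iloc[0]), float(out["lb_pvalue"].iloc[0])


def adf_test(series, max_lag: int | None = None) -> tuple[float, float]:
    """Augmented Dickey-Fuller unit-root test (constant, AIC lag choice)."""
    z = np.asarray(series, dtype=float)
    if z.size < 25:
        raise ValueError("need at least 25 observations for the ADF test")
    if np.ptp(z) == 0.0:
        raise ValueError("constant series: ADF regression degenerate")
    stat, pval, *_ = adfuller(z, maxlag=max_lag, regression="c", autolag="AIC")
    return float(stat), float(pval)


@dataclass
class InformationCriteria:
    """Raw and per-observation criteria, printed and textbook conventions."""

    aic: float
    sic: float
    hqc: float
    aic_per_obs: float
    sic_per_obs: float
    hqc_per_obs: float
    bic_textbook: float
    hqc_textbook: float


def information_criteria(loglik: float, n_params: int, n_obs: int) -> InformationCriteria:
    """Model-selection criteria from a log-likelihood.

    ``n_params`` (T) counts estimated parameters, ``n_obs`` (M) the
    observations the likelihood covers.
    """
    if n_params < 0 or n_obs <= n_params:
        raise ValueError("require n_obs > n_params >= 0")
    T, M = n_params, n_obs
    neg2ll = -2.0 * loglik
    aic = neg2ll + 2.0 * T
    lnM = math.log(M)
    sic = neg2ll + (T + T * lnM)
    hqc = neg2ll + 2.0 * (T + T * lnM)
    return InformationCriteria(
        aic=aic,
        sic=sic,
        hqc=hqc,
        aic_per_obs=aic / M,
        sic_per_obs=sic / M,
        hqc_per_obs=hqc / M,
        bic_textbook=neg2ll + T * lnM,
        hqc_textbook=neg2ll + 2.0 * T * math.log(lnM) if M > 2 else math.nan,
    )


@dataclass
class DiagnosticsReport:
    """One series' descriptive, normality and dependence diagnostics."""

    n: int
    mean: float
    median: float
    sd: float
    skewness: float
    kurtosis: float
    jarque_bera: float
    jarque_bera_p: float
    durbin_watson: float
    durbin_watson_band: str
    arch_lm: float
    arch_lm_p: float
    ljung_box_sq: float
    ljung_box_sq_p: float
    adf: float
    adf_p: float
    criteria: InformationCriteria | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def to_frame(self) -> pd.DataFrame:
        d = self.to_dict()
        crit = d.pop("criteria")
        if crit:
            d.update({f"crit_{k}": v for k, v in crit.items()})
        return pd.DataFrame([d])


def diagnostics_report(
    series,
    residuals=None,
    lags: int = DEFAULT_ARCH_LM_LAGS,
    criteria: InformationCriteria | None = None,
) -> DiagnosticsReport:
    """Assemble the full diagnostic battery for one series.

    ``residuals`` (defaults to the demeaned series) feed the
    Durbin-Watson, ARCH-LM and Ljung-Box tests; the ADF and moment tests
    run on the series itself.
    """
    z = np.asarray(series, dtype=float)
    e = np.asarray(residuals, dtype=float) if residuals is not None else z - z.mean()
    jb, jb_p = jarque_bera(z)
    dw = durbin_watson(e)
    lm, lm_p = arch_lm_test(e, lags=lags)
    lb, lb_p = ljung_box_squared(e, lags=lags)
    if z.size >= 25:
        adf_stat, adf_p = adf_test(z)
    else:  # ADF needs a minimum sample; report as unavailable
        adf_stat, adf_p = math.nan, math.nan
    return DiagnosticsReport(
        n=z.size,
        mean=float(z.mean()),
        median=float(np.median(z)),
        sd=float(np.std(z, ddof=1)),
        skewness=skewness(z),
        kurtosis=kurtosis(z),
        jarque_bera=jb,
        jarque_bera_p=jb_p,
        durbin_watson=dw,
        durbin_watson_band=durbin_watson_band(dw),
        arch_lm=lm,
        arch_lm_p=lm_p,
        ljung_box_sq=lb,
        ljung_box_sq_p=lb_p,
        adf=adf_stat,
        adf_p=adf_p,
        criteria=criteria,
    )
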