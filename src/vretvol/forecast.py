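"""Forecast-accuracy metrics: MAE, MAPE, RMSE and Theil's U.

Theil's U is the U1 form

    U1 = RMS(error) / (RMS(forecast) + RMS(actual)),

which is bounded in [0, 1] and is 0 exactly when forecasts equal actuals.
A ``theil="raw"`` flag exposes the unnormalised ratio
RMS(error) / (RMS(forecast) * RMS(actual)) for comparison; it carries no
boundedness guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = ["ForecastScores", "score_forecasts"]


@dataclass
class ForecastScores:
    mae: float
    mape: float  # percent; NaN when any actual is zero
    rmse: float
    theils_u: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


def score_forecasts(actual, forecast, theil: str = "u1") -> ForecastScores:
    """Score one-step forecasts against actuals.

    MAPE is reported as NaN (undefined) when any actual is zero; the other
    metrics are always returned.
    """
    z = np.asarray(actual, dtype=float)
    g = np.asarray(forecast, dtype=float)
    if z.shape != g.shape:
        raise ValueError(f"length mismatch: {z.shape} vs {g.shape}")
    if z.size < 1:
        raise ValueError("need at least one observation")
    err = g - z
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    if np.any(z == 0.0):
        mape = float("nan")
    else:
        mape = float(np.mean(np.abs(err / z)) * 100.0)

    rms_g = np.sqrt(np.mean(g**2))
    rms_z = np.sqrt(np.mean(z**2))
    if theil == "u1":
        denom = rms_g + rms_z
        u = float(rmse / denom) if denom > 0 else 0.0
    elif theil == "raw":
        u = float(rmse / (rms_g * rms_z)) if rms_g * rms_z > 0 else float("nan")
    else:
        raise ValueError(f"unknown theil convention {theil!r}")
    return ForecastScores(mae=mae, mape=mape, rmse=rmse, theils_u=u)
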