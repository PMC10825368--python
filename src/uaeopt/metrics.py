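"""Model validation statistics: R², RMSE (n−1 divisor) and relative deviation.

The RMSE here uses the (n−1) divisor conventional in response-surface
validation work; the relative deviation Rd is the mean absolute prediction
error as a percentage of the observed values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitReport", "r_squared", "rmse", "rel_dev", "fit_report"]


def _pair(predicted, observed) -> tuple[np.ndarray, np.ndarray]:
    yp = np.asarray(predicted, dtype=float).ravel()
    ye = np.asarray(observed, dtype=float).ravel()
    if yp.shape != ye.shape:
        raise ValueError("predicted and observed must have equal length")
    return yp, ye


def r_squared(predicted, observed) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot."""
    yp, ye = _pair(predicted, observed)
    if ye.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((ye - ye.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed vector is constant; R² undefined")
    return 1.0 - float(np.sum((yp - ye) ** 2)) / ss_tot


def rmse(predicted, observed) -> float:
    """Root mean square error with the (n−1) divisor."""
    yp, ye = _pair(predicted, observed)
    if ye.size < 2:
        raise ValueError("need at least two observations")
    return float(np.sqrt(np.sum((yp - ye) ** 2) / (ye.size - 1)))


def rel_dev(predicted, observed) -> float:
    """Relative deviation percentage: (100/n) Σ |Ye − Yp| / Ye."""
    yp, ye = _pair(predicted, observed)
    if ye.size < 1:
        raise ValueError("need at least one observation")
    if np.any(ye == 0):
        raise ValueError("relative deviation undefined for zero observations")
    return float(100.0 / ye.size * np.sum(np.abs(ye - yp) / ye))


@dataclass(frozen=True)
class FitReport:
    r_squared: float
    rmse: float
    rel_dev_percent: float
    n: int


def fit_report(predicted, observed) -> FitReport:
    """All three validation statistics for one predicted/observed pair."""
    yp, ye = _pair(predicted, observed)
    return FitReport(
        r_squared=r_squared(yp, ye),
        rmse=rmse(yp, ye),
        rel_dev_percent=rel_dev(yp, ye),
        n=int(ye.size),
    )
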