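"""Signed relative influence of process factors on modelled responses.

For each (factor, response) pair the trained surrogate is swept along that
factor across the coded design range [−α, +α] with all other factors held
at the center (coded 0), and the ordinary-least-squares slope of the
predicted response against the coded level is divided by the sample
standard deviation of the observed response.  The result is a
dimensionless signed score: its sign says whether raising the factor
raises or lowers the response, its magnitude ranks the factors'
leverage on a common scale.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .doe import FactorSpec, code_to_actual

__all__ = ["relative_effects"]


def relative_effects(
    models: Mapping[str, object],
    factor_specs: Sequence[FactorSpec],
    observed: pd.DataFrame,
    alpha: float = 2.0,
    grid_points: int = 101,
) -> pd.DataFrame:
    """Signed relative-influence matrix (factors × responses).

    Parameters
    ----------
    models
        Mapping response name -> fitted regressor predicting that
        response from the factors in **actual units**.
    factor_specs
        The factors, in model input order.
    observed
        Response table with one column per response name; its per-column
        standard deviation normalizes the slopes.
    alpha
        Coded half-width of the sweep (the design's axial distance).
    grid_points
        Sweep resolution per factor.

    Returns
    -------
    DataFrame indexed by factor name with one column per response.
    """
    specs = tuple(factor_specs)
    coded_grid = np.linspace(-alpha, alpha, grid_points)
    center = np.array([s.mean for s in specs])
    table = np.zeros((len(specs), len(models)))
    names = list(models)
    for k, name in enumerate(names):
        model = models[name]
        y_obs = np.asarray(observed[name], dtype=float)
        sd = float(np.std(y_obs, ddof=1))
        if sd == 0:
            raise ValueError(f"response {name!r} has zero variance")
        for j, spec in enumerate(specs):
            X = np.tile(center, (grid_points, 1))
            X[:, j] = [code_to_actual(c, spec, alpha) for c in coded_grid]
            pred = np.asarray(model.predict(X), dtype=float)
            slope = np.polyfit(coded_grid, pred, 1)[0]
            table[j, k] = slope / sd
    return pd.DataFrame(table, index=[s.name for s in specs], columns=names)
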