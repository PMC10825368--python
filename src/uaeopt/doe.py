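"""Central composite designs for multi-factor extraction experiments.

A face/star central composite design (CCD) for ``k`` factors consists of a
full two-level factorial block (coded levels ±1), two axial ("star") runs per
factor at coded ±alpha, and a block of replicated center runs (all factors at
coded 0).  With ``alpha`` different from 0 and 1, every factor takes five
distinct coded levels {-alpha, -1, 0, +1, +alpha}, which is what makes the
design suitable for fitting full quadratic response surfaces.

The coding map is affine: ``actual = mean + coded * (maximum - mean) / alpha``
so that coded 0 is the factor mean and coded ±alpha are the axial extremes
(the stated minimum / maximum of the factor).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "DEFAULT_FACTORS",
    "generate_ccd",
    "code_to_actual",
    "actual_to_code",
]


@dataclass(frozen=True)
class FactorSpec:
    """One process factor with its axial extremes and center level.

    ``minimum`` and ``maximum`` are the axial (star) extremes of the design;
    ``mean`` is the center level.  For a symmetric design the mean is the
    midpoint of the extremes.
    """

    name: str
    unit: str
    minimum: float
    mean: float
    maximum: float

    def __post_init__(self) -> None:
        for v in (self.minimum, self.mean, self.maximum):
            if not math.isfinite(v):
                raise ValueError(f"non-finite level in factor {self.name!r}")
        if not (self.minimum < self.mean < self.maximum):
            raise ValueError(
                f"factor {self.name!r} requires minimum < mean < maximum, "
                f"got {self.minimum}, {self.mean}, {self.maximum}"
            )


#: Factor table of the ultrasound-assisted extraction study: ultrasonication
#: power, bath temperature, solvent (DES) molar ratio and solvent water
#: content, each spanning its axial extremes around the printed center level.
DEFAULT_FACTORS: tuple[FactorSpec, ...] = (
    FactorSpec("power", "W", 100.0, 200.0, 300.0),
    FactorSpec("temperature", "degC", 30.0, 50.0, 70.0),
    FactorSpec("molar_ratio", "-", 0.5, 1.5, 2.5),
    FactorSpec("water_content", "%", 15.0, 25.0, 35.0),
)


def code_to_actual(coded: float, spec: FactorSpec, alpha: float = 2.0) -> float:
    """Map a coded level to actual factor units.

    coded 0 -> mean, coded +alpha -> maximum, coded -alpha -> minimum.
    """
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    return spec.mean + coded * (spec.maximum - spec.mean) / alpha


def actual_to_code(actual: float, spec: FactorSpec, alpha: float = 2.0) -> float:
    """Inverse of :func:`code_to_actual`."""
    if alpha == 0:
        raise ValueError("alpha must be nonzero")
    half_range = spec.maximum - spec.mean
    if half_range == 0:
        raise ValueError(f"degenerate factor {spec.name!r}: maximum == mean")
    return (actual - spec.mean) * alpha / half_range


@dataclass
class DesignTable:
    """A CCD run table with coded and actual factor levels."""

    coded: np.ndarray  # (n_runs, k)
    factor_specs: tuple[FactorSpec, ...]
    alpha: float = 2.0
    run_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        self.factor_specs = tuple(self.factor_specs)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factor_specs):
            raise ValueError("coded matrix shape does not match factor specs")
        if self.run_ids is None:
            self.run_ids = np.arange(1, len(self.coded) + 1)
        self.run_ids = np.asarray(self.run_ids)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded.shape[1]

    @property
    def actual(self) -> np.ndarray:
        cols = [
            np.array([code_to_actual(c, s, self.alpha) for c in self.coded[:, j]])
            for j, s in enumerate(self.factor_specs)
        ]
        return np.column_stack(cols)

    def to_frame(self) -> pd.DataFrame:
        """Run table as a DataFrame: run_id, coded_<name>..., actual_<name>..."""
        data: dict[str, np.ndarray] = {"run_id": self.run_ids}
        actual = self.actual
        for j, s in enumerate(self.factor_specs):
            data[f"coded_{s.name}"] = self.coded[:, j]
        for j, s in enumerate(self.factor_specs):
            data[f"actual_{s.name}"] = actual[:, j]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        factor_specs: Sequence[FactorSpec],
        alpha: float = 2.0,
    ) -> "DesignTable":
        coded = frame[[f"coded_{s.name}" for s in factor_specs]].to_numpy(float)
        run_ids = frame["run_id"].to_numpy() if "run_id" in frame else None
        return cls(coded=coded, factor_specs=tuple(factor_specs), alpha=alpha,
                   run_ids=run_ids)

    @classmethod
    def from_csv(
        cls, path, factor_specs: Sequence[FactorSpec], alpha: float = 2.0
    ) -> "DesignTable":
        return cls.from_frame(pd.read_csv(path), factor_specs, alpha)


def generate_ccd(
    specs: Sequence[FactorSpec],
    n_center: int = 6,
    alpha: float = 2.0,
) -> DesignTable:
    """Generate a central composite design.

    Row order is deterministic: the 2^k factorial block in standard
    (Yates) order, then axial pairs per factor (low first), then the
    center replicates.  Total row count is ``2**k + 2*k + n_center``.

    Parameters
    ----------
    specs
        Factor definitions; the axial runs sit at each factor's
        minimum/maximum and the center at its mean.
    n_center
        Number of replicated center runs (6 gives the classical 30-run
        design for 4 factors).
    alpha
        Axial distance in coded units; 2.0 is the rotatable value for
        four factors and places the ±1 levels halfway between center
        and extremes.
    """
    specs = tuple(specs)
    if not specs:
        raise ValueError("at least one factor is required")
    if n_center < 0:
        raise ValueError("n_center must be >= 0")
    if not (alpha > 0) or not math.isfinite(alpha):
        raise ValueError("alpha must be a positive finite real")
    k = len(specs)
    # factorial block, standard order: first factor cycles fastest
    factorial = np.array(
        [levels[::-1] for levels in itertools.product([-1.0, 1.0], repeat=k)]
    )
    axial_rows = []
    for j in range(k):
        for sign in (-1.0, 1.0):
            row = np.zeros(k)
            row[j] = sign * alpha
            axial_rows.append(row)
    axial = np.array(axial_rows) if axial_rows else np.empty((0, k))
    center = np.zeros((n_center, k))
    coded = np.vstack([factorial, axial, center])
    return DesignTable(coded=coded, factor_specs=specs, alpha=alpha)
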