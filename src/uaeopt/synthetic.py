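"""Synthetic response-surface data emulating the extraction study.

The study's raw 30-run dataset is not deposited, so this module generates
datasets with the same statistical structure: a 30-run, 4-factor,
5-level central composite design whose four responses follow smooth full
quadratic surfaces in coded factor units, with

* linear-effect signs fixed to the published relative-influence sign
  pattern (e.g. phenolic content rises with power, molar ratio and water
  content and falls with temperature),
* each noiseless surface affinely rescaled so its range over the coded
  box matches the published response range (e.g. 4.154–8.163 mg GAE/g
  d.w. for total phenolics), and
* additive Gaussian measurement noise, by default 2 % of each response's
  range — consistent with the sub-5 % validation deviations such assays
  achieve.

Surfaces are full quadratics (linear + pure quadratic + pairwise
interaction terms), the canonical family a CCD is built to estimate.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doe import DEFAULT_FACTORS, DesignTable, generate_ccd

__all__ = [
    "RESPONSE_NAMES",
    "DEFAULT_SIGNS",
    "DEFAULT_RANGES",
    "RSMGroundTruth",
    "SyntheticDataset",
    "make_ground_truth",
    "evaluate_truth",
    "simulate_dataset",
    "coded_grid",
]

RESPONSE_NAMES: tuple[str, ...] = ("Y_PC", "Y_AA", "Y_AC", "Y_FC")
FACTOR_NAMES: tuple[str, ...] = tuple(s.name for s in DEFAULT_FACTORS)

#: Sign of each factor's linear effect on each response (rows: power,
#: temperature, molar ratio, water content), matching the published
#: relative-influence pattern.
DEFAULT_SIGNS = pd.DataFrame(
    {
        "Y_PC": [+1, -1, +1, +1],
        "Y_AA": [+1, -1, +1, +1],
        "Y_AC": [+1, -1, +1, -1],
        "Y_FC": [+1, +1, +1, -1],
    },
    index=FACTOR_NAMES,
)

#: Published observed range of each response across the design
#: (units: mg GAE/g, % DPPH inhibition, mg/g, mg QE/g dry weight).
DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "Y_PC": (4.154, 8.163),
    "Y_AA": (45.588, 88.639),
    "Y_AC": (0.452, 0.750),
    "Y_FC": (0.213, 0.545),
}

#: Default measurement noise as a fraction of each response's range.
DEFAULT_NOISE_FRACTION = 0.02


@dataclass
class RSMGroundTruth:
    """Quadratic ground-truth surfaces in coded units, one per response.

    For response k the noiseless surface at coded point x is::

        y_k(x) = intercept[k] + linear[k] . x + quadratic[k] . x**2
                 + sum_{j<l} interaction[k][(j,l)] * x_j * x_l

    ``noise_sd`` is the additive Gaussian measurement noise and
    ``ranges`` the target output range each surface was rescaled to.
    """

    intercept: np.ndarray  # (K,)
    linear: np.ndarray  # (K, d)
    quadratic: np.ndarray  # (K, d)
    interaction: np.ndarray  # (K, d, d), upper triangle used
    noise_sd: np.ndarray  # (K,)
    ranges: dict[str, tuple[float, float]]
    response_names: tuple[str, ...] = RESPONSE_NAMES
    alpha: float = 2.0

    def to_json(self, path) -> None:
        doc = {
            "intercept": self.intercept.tolist(),
            "linear": self.linear.tolist(),
            "quadratic": self.quadratic.tolist(),
            "interaction": self.interaction.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "response_names": list(self.response_names),
            "alpha": self.alpha,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "RSMGroundTruth":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(
            intercept=np.asarray(doc["intercept"]),
            linear=np.asarray(doc["linear"]),
            quadratic=np.asarray(doc["quadratic"]),
            interaction=np.asarray(doc["interaction"]),
            noise_sd=np.asarray(doc["noise_sd"]),
            ranges={k: tuple(v) for k, v in doc["ranges"].items()},
            response_names=tuple(doc["response_names"]),
            alpha=float(doc["alpha"]),
        )


@dataclass
class SyntheticDataset:
    """A simulated design + response table with its generating truth."""

    design: DesignTable
    responses: pd.DataFrame
    truth: RSMGroundTruth
    seed: int


def coded_grid(n_levels: int = 3, alpha: float = 2.0, d: int = 4) -> np.ndarray:
    """Full factorial grid of coded points, n_levels per factor over [−α, α]."""
    levels = np.linspace(-alpha, alpha, n_levels)
    return np.array(list(itertools.product(levels, repeat=d)))


def make_ground_truth(
    seed: int = 0,
    sign_matrix: pd.DataFrame | None = None,
    ranges: dict[str, tuple[float, float]] | None = None,
    noise_fraction: float = DEFAULT_NOISE_FRACTION,
    alpha: float = 2.0,
) -> RSMGroundTruth:
    """Draw seeded quadratic ground-truth surfaces.

    Linear coefficient magnitudes are drawn from U(0.5, 1.0) and signed
    by ``sign_matrix``; pure quadratic terms are mildly concave
    (U(−0.25, −0.05)) so each surface has an interior optimum; pairwise
    interactions are small (U(−0.08, 0.08)).  Each surface is then
    affinely rescaled so its extrema over a dense coded grid hit the
    target range exactly (an order-preserving map, so effect signs
    survive), and the noise SD is set to ``noise_fraction`` of the range.
    """
    signs = DEFAULT_SIGNS if sign_matrix is None else sign_matrix
    ranges = dict(DEFAULT_RANGES if ranges is None else ranges)
    if not set(signs.abs().to_numpy().ravel()) <= {1}:
        raise ValueError("sign matrix entries must be +1 or -1")
    names = tuple(signs.columns)
    for name in names:
        lo, hi = ranges[name]
        if not hi > lo:
            raise ValueError(f"zero-width range for {name!r}")
    d = signs.shape[0]
    K = signs.shape[1]
    rng = np.random.default_rng(seed)
    linear = rng.uniform(0.5, 1.0, size=(K, d)) * signs.to_numpy().T
    quadratic = rng.uniform(-0.25, -0.05, size=(K, d))
    interaction = np.zeros((K, d, d))
    for j in range(d):
        for l in range(j + 1, d):
            interaction[:, j, l] = rng.uniform(-0.08, 0.08, size=K)
    intercept = np.zeros(K)
    truth = RSMGroundTruth(
        intercept=intercept,
        linear=linear,
        quadratic=quadratic,
        interaction=interaction,
        noise_sd=np.zeros(K),
        ranges=ranges,
        response_names=names,
        alpha=alpha,
    )
    # affine range matching on a dense grid over the coded box
    grid = coded_grid(9, alpha=alpha, d=d)
    raw = evaluate_truth(truth, grid)
    noise_sd = np.zeros(K)
    for k, name in enumerate(names):
        lo_t, hi_t = ranges[name]
        y_min, y_max = raw[:, k].min(), raw[:, k].max()
        scale = (hi_t - lo_t) / (y_max - y_min)
        shift = lo_t - scale * y_min
        truth.intercept[k] = truth.intercept[k] * scale + shift
        truth.linear[k] *= scale
        truth.quadratic[k] *= scale
        truth.interaction[k] *= scale
        noise_sd[k] = noise_fraction * (hi_t - lo_t)
    truth.noise_sd = noise_sd
    return truth


def evaluate_truth(truth: RSMGroundTruth, coded_x) -> np.ndarray:
    """Noiseless surface values at coded points; shape (n, n_responses)."""
    X = np.atleast_2d(np.asarray(coded_x, dtype=float))
    n = X.shape[0]
    K = truth.linear.shape[0]
    out = np.empty((n, K))
    for k in range(K):
        y = (
            truth.intercept[k]
            + X @ truth.linear[k]
            + (X**2) @ truth.quadratic[k]
        )
        for j in range(X.shape[1]):
            for l in range(j + 1, X.shape[1]):
                y = y + truth.interaction[k, j, l] * X[:, j] * X[:, l]
        out[:, k] = y
    return out


def simulate_dataset(
    truth: RSMGroundTruth,
    design: DesignTable | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a response table for a design under the ground truth.

    Responses are the noiseless surface plus N(0, noise_sd) measurement
    error, clipped to ±10 % beyond the target range (so noise cannot
    push an assay value to an unphysical level).
    """
    if design is None:
        design = generate_ccd(DEFAULT_FACTORS, n_center=6, alpha=truth.alpha)
    rng = np.random.default_rng(seed)
    clean = evaluate_truth(truth, design.coded)
    noisy = clean + rng.normal(0.0, truth.noise_sd, size=clean.shape)
    for k, name in enumerate(truth.response_names):
        lo, hi = truth.ranges[name]
        noisy[:, k] = np.clip(noisy[:, k], lo * 0.9, hi * 1.1)
    responses = pd.DataFrame(noisy, columns=list(truth.response_names))
    responses.insert(0, "run_id", design.run_ids)
    return SyntheticDataset(design=design, responses=responses,
                            truth=truth, seed=seed)
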