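"""End-to-end modelling pipeline: train surrogates, score fits, rank
factor influences and locate the optimum operating point.

``run_pipeline`` reproduces the study's computational chain on any
design+response table: one ANFIS surrogate per response, validation
statistics, the signed relative-influence matrix, and a GA search for
the factor combination maximizing the combined normalized responses.
All randomness flows from one global seed through named per-stage
substreams, so a rerun with the same config and data is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .anfis import AnfisRegressor
from .doe import DEFAULT_FACTORS, FactorSpec
from .ga import FitnessSpec, GAConfig, optimize_models
from .influence import relative_effects
from .metrics import FitReport, fit_report
from .synthetic import RESPONSE_NAMES

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "report_text"]


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, serializable to JSON."""

    factor_specs: tuple[FactorSpec, ...] = DEFAULT_FACTORS
    response_names: tuple[str, ...] = RESPONSE_NAMES
    alpha: float = 2.0
    n_center: int = 6
    n_mfs: int = 3
    epochs: int = 500
    method: str | None = "hybrid"
    train_fraction: float = 0.7
    ga: GAConfig = field(default_factory=GAConfig)
    weights: tuple[float, ...] | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "factor_specs": [
                {"name": s.name, "unit": s.unit, "minimum": s.minimum,
                 "mean": s.mean, "maximum": s.maximum}
                for s in self.factor_specs
            ],
            "response_names": list(self.response_names),
            "alpha": self.alpha,
            "n_center": self.n_center,
            "n_mfs": self.n_mfs,
            "epochs": self.epochs,
            "method": self.method,
            "train_fraction": self.train_fraction,
            "ga": vars(self.ga) | {},
            "weights": list(self.weights) if self.weights else None,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        ga = GAConfig(**doc["ga"]) if "ga" in doc else GAConfig()
        return cls(
            factor_specs=tuple(FactorSpec(**f) for f in doc["factor_specs"]),
            response_names=tuple(doc.get("response_names", RESPONSE_NAMES)),
            alpha=doc.get("alpha", 2.0),
            n_center=doc.get("n_center", 6),
            n_mfs=doc.get("n_mfs", 3),
            epochs=doc.get("epochs", 500),
            method=doc.get("method", "hybrid"),
            train_fraction=doc.get("train_fraction", 0.7),
            ga=ga,
            weights=tuple(doc["weights"]) if doc.get("weights") else None,
            seed=doc.get("seed", 0),
        )


@dataclass
class RunManifest:
    """Provenance record: config echo, input digests, stage summaries."""

    config: dict
    input_digest: str
    stages: dict
    version: str
    timestamp: str


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed derived from the global seed."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _validate_schema(
    data: pd.DataFrame,
    factor_specs: Sequence[FactorSpec],
    response_names: Sequence[str],
) -> tuple[np.ndarray, pd.DataFrame]:
    needed = [f"actual_{s.name}" for s in factor_specs] + list(response_names)
    for col in needed:
        if col not in data.columns:
            raise ValueError(f"missing required column {col!r}")
        coerced = pd.to_numeric(data[col], errors="coerce")
        bad = coerced.isna() & data[col].notna()
        if bad.any() or coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna())[0])
            raise ValueError(
                f"non-numeric or missing value in column {col!r}, row {row}"
            )
    X = data[[f"actual_{s.name}" for s in factor_specs]].to_numpy(float)
    Y = data[list(response_names)].astype(float)
    return X, Y


def run_pipeline(
    config: PipelineConfig, data: pd.DataFrame
) -> tuple[RunManifest, dict]:
    """Run the full chain on a design+response table.

    ``data`` must carry one ``actual_<factor>`` column per factor and
    one column per response.  Returns the provenance manifest and the
    report: per-response fit statistics, the influence matrix, and the
    GA optimum with its predicted responses.
    """
    X, Y = _validate_schema(data, config.factor_specs, config.response_names)
    domains = [(s.minimum, s.maximum) for s in config.factor_specs]

    models: dict[str, AnfisRegressor] = {}
    reports: dict[str, FitReport] = {}
    for name in config.response_names:
        est = AnfisRegressor(
            n_mfs=config.n_mfs,
            epochs=config.epochs,
            method=config.method,
            train_fraction=config.train_fraction,
            domain=domains,
            random_state=stage_seed(config.seed, f"train:{name}"),
        )
        est.fit(X, Y[name].to_numpy())
        models[name] = est
        reports[name] = fit_report(est.predict(X), Y[name].to_numpy())

    infl = relative_effects(models, config.factor_specs, Y, alpha=config.alpha)

    spec = FitnessSpec.from_observed(
        Y, weights=config.weights,
        factor_bounds=[(s.minimum, s.maximum) for s in config.factor_specs],
    )
    ga_config = GAConfig(**{**vars(config.ga),
                            "seed": stage_seed(config.seed, "ga")})
    result = optimize_models(models, spec, ga_config)

    report = {
        "n_runs": int(len(data)),
        "fit_reports": {
            name: vars(rep) for name, rep in reports.items()
        },
        "influence": {
            resp: {fac: float(infl.loc[fac, resp]) for fac in infl.index}
            for resp in infl.columns
        },
        "optimum": {
            "point": {
                s.name: float(v)
                for s, v in zip(config.factor_specs, result.best_point)
            },
            "fitness": result.best_fitness,
            "predicted_responses": {
                name: float(v)
                for name, v in zip(models, result.predicted_responses)
            },
        },
        "archive": [
            {"point": p.tolist(), "fitness": f} for p, f in result.archive
        ],
    }
    digest = hashlib.sha256(
        data.to_csv(index=False).encode("utf-8")
    ).hexdigest()
    manifest = RunManifest(
        config=config.to_dict(),
        input_digest=digest,
        stages={
            "train": {n: {"method": m.method_,
                          "best_checking_epoch": m.history_.best_checking_epoch}
                      for n, m in models.items()},
            "influence": "ok",
            "optimize": {"generations": ga_config.generations,
                         "population": ga_config.population},
        },
        version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    return manifest, report


def report_text(report: dict, config: PipelineConfig | None = None) -> str:
    """Human-readable report mirroring the influence-matrix and
    optimum-condition table layouts."""
    lines = ["Relative influence of process factors on responses", ""]
    infl = report["influence"]
    responses = list(infl)
    factors = list(next(iter(infl.values())))
    header = "factor".ljust(16) + "".join(r.rjust(10) for r in responses)
    lines.append(header)
    for fac in factors:
        lines.append(
            fac.ljust(16)
            + "".join(f"{infl[r][fac]:10.3f}" for r in responses)
        )
    lines += ["", "Optimum operating point", ""]
    for k, v in report["optimum"]["point"].items():
        lines.append(f"  {k}: {v:.3f}")
    lines.append(f"  fitness: {report['optimum']['fitness']:.3f}")
    lines += ["", "Predicted responses at the optimum", ""]
    for k, v in report["optimum"]["predicted_responses"].items():
        lines.append(f"  {k}: {v:.4f}")
    lines += ["", "Model fit statistics", ""]
    for name, rep in report["fit_reports"].items():
        lines.append(
            f"  {name}: R2={rep['r_squared']:.4f}  RMSE={rep['rmse']:.4f}"
            f"  Rd%={rep['rel_dev_percent']:.3f}  n={rep['n']}"
        )
    return "\n".join(lines) + "\n"
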