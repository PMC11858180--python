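"""End-to-end workflow: read inputs, fit, ANOVA, optimize, report.

`run_pipeline` wires the stages together and collects every number a study
report needs -- the fitted equation, the ANOVA with lack-of-fit split, R^2,
the stationary point in natural units, and an optional comparison at rounded
"practical" settings.  Reports are deterministic given the same inputs and
seed, so rerunning a config reproduces the report byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .anova import AnovaTable, anova_partition
from .design import DesignTable, ResponseTable
from .io import read_factors, read_run_table
from .model import (
    QuadraticModel,
    adjusted_r_squared,
    fit_quadratic,
    format_equation,
    r_squared,
)
from .optimize import StationaryPoint, bounded_maximize, stationary_point
from .simulate import TruthSpec, simulate_bbd_experiment


@dataclass
class RunReport:
    """Everything the workflow computed, serializable to JSON and text."""

    input_digests: dict[str, str]
    factors: tuple
    equation: str
    model: QuadraticModel
    anova: AnovaTable
    r2: float
    adj_r2: float
    optimum: StationaryPoint
    validation: dict | None = None
    version: str = __version__
    seed: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "input_digests": self.input_digests,
            "factors": [
                {"name": f.name, "units": f.units, "low": f.low,
                 "center": f.center, "high": f.high}
                for f in self.factors
            ],
            "equation": self.equation,
            "coefficients": dict(
                zip(self.model.labels, self.model.coef.tolist())
            ),
            "r2": round(self.r2, 4),
            "adjusted_r2": round(self.adj_r2, 4),
            "anova": self.anova.to_frame().to_dict(orient="records"),
            "optimum": {
                "coded": [round(c, 6) for c in self.optimum.coded],
                "natural": {
                    f.name: round(v, 3)
                    for f, v in zip(self.factors, self.optimum.natural)
                },
                "predicted": round(self.optimum.predicted, 3),
                "classification": self.optimum.classification,
                "interior": self.optimum.interior,
            },
            "validation": self.validation,
            "warnings": self.warnings,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_text(self) -> str:
        lines = [
            f"rsmkit {self.version} run report",
            "",
            "Fitted model (coded units):",
            "  " + self.equation,
            f"  R^2 = {self.r2:.4f}, adjusted R^2 = {self.adj_r2:.4f}",
            "",
            "ANOVA:",
        ]
        lines += [
            "  " + line
            for line in self.anova.formatted().to_string(index=False).splitlines()
        ]
        lines += ["", "Optimum:", "  " + self.optimum.describe(self.factors)]
        if self.validation:
            v = self.validation
            lines += [
                "",
                "Validation at practical settings "
                f"{v['settings']}: predicted {v['predicted']:.3f} "
                f"(gap below optimum {v['gap']:.3f})",
            ]
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines) + "\n"


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def analyze(
    design: DesignTable,
    responses: ResponseTable,
    practical: list[float] | None = None,
    input_digests: dict[str, str] | None = None,
    seed: int | None = None,
) -> RunReport:
    """Run fit -> ANOVA -> optimization on in-memory tables."""
    model = fit_quadratic(design, responses)
    anova = anova_partition(model, design, responses)
    warnings: list[str] = []
    try:
        opt = stationary_point(model)
        if opt.classification != "maximum" or not opt.interior:
            warnings.append(
                f"stationary point is a non-interior or non-maximum "
                f"({opt.classification}); reporting the box optimum instead"
            )
            opt = bounded_maximize(model)
    except np.linalg.LinAlgError:
        warnings.append("singular Hessian; using bounded search")
        opt = bounded_maximize(model)
    validation = None
    if practical is not None:
        from .optimize import validate_settings

        pred, gap = validate_settings(model, practical)
        validation = {
            "settings": list(map(float, practical)),
            "predicted": round(pred, 3),
            "gap": round(gap, 3),
        }
    return RunReport(
        input_digests=input_digests or {},
        factors=design.factors,
        equation=format_equation(model),
        model=model,
        anova=anova,
        r2=r_squared(model),
        adj_r2=adjusted_r_squared(model),
        optimum=opt,
        validation=validation,
        seed=seed,
    )


def run_pipeline(config: dict) -> RunReport:
    """Execute the full workflow from a config mapping.

    Config keys:

    - ``factors``: path to a factor JSON config (required unless simulating)
    - ``run_table``: path to a CSV run table with responses
    - ``units``: 'coded' or 'natural' if the table does not declare them
    - ``practical``: optional natural settings to validate against the optimum
    - ``simulate``: optional truth spec mapping (coef, noise_sd, n_center)
      that replaces ``run_table`` with a seeded synthetic experiment
    - ``seed``: seed for simulation mode
    """
    digests = {}
    seed = config.get("seed")
    if "simulate" in config:
        factors = read_factors(config["factors"])
        sim = config["simulate"]
        spec = TruthSpec(
            factors=factors,
            coef=np.asarray(sim["coef"], dtype=float),
            noise_sd=float(sim.get("noise_sd", 0.0)),
            n_center=int(sim.get("n_center", 5)),
            seed=int(seed or 0),
        )
        design, responses = simulate_bbd_experiment(spec)
        digests["factors"] = _digest(config["factors"])
    else:
        factors = read_factors(config["factors"])
        design, responses = read_run_table(
            config["run_table"], factors, units=config.get("units")
        )
        if responses is None:
            raise ValueError(
                f"{config['run_table']}: run table has no response column"
            )
        digests["factors"] = _digest(config["factors"])
        digests["run_table"] = _digest(config["run_table"])
    return analyze(
        design,
        responses,
        practical=config.get("practical"),
        input_digests=digests,
        seed=seed,
    )
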