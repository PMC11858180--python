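"""Synthetic experiments with the statistical structure the analysis assumes.

`simulate_bbd_experiment` draws a Box-Behnken response table from a known
quadratic truth plus i.i.d. Gaussian noise -- the data-generating process the
least-squares fit and the single-pure-error-variance ANOVA both assume.  All
randomness flows through one explicitly passed seeded generator, so tables
are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assay import ColonyMeasurement
from .design import DesignTable, ResponseTable, make_bbd
from .factors import Factor
from .model import model_matrix, term_labels


@dataclass(frozen=True)
class TruthSpec:
    """Ground truth for a simulated experiment.

    ``coef`` follows the quadratic model layout (intercept, linear terms,
    pairwise interactions, quadratic terms) in coded units.
    """

    factors: tuple[Factor, ...]
    coef: np.ndarray = field(repr=False)
    noise_sd: float = 0.0
    n_center: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        coef = np.asarray(self.coef, dtype=float)
        object.__setattr__(self, "coef", coef)
        object.__setattr__(self, "factors", tuple(self.factors))
        expected = len(term_labels(self.factors))
        if coef.shape != (expected,):
            raise ValueError(
                f"expected {expected} coefficients for {len(self.factors)} "
                f"factors, got {coef.shape}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def true_response(spec: TruthSpec, coded: np.ndarray) -> np.ndarray:
    """Noise-free truth polynomial evaluated at coded points."""
    return model_matrix(coded) @ spec.coef


def simulate_bbd_experiment(
    spec: TruthSpec, rng: np.random.Generator | None = None
) -> tuple[DesignTable, ResponseTable]:
    """Generate one BBD experiment: design plus noisy responses.

    Responses are y = truth(x) + Gaussian(0, noise_sd^2), independent across
    runs.  With ``noise_sd=0`` the responses equal the truth exactly.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    design = make_bbd(spec.factors, n_center=spec.n_center)
    y = true_response(spec, design.coded)
    if spec.noise_sd > 0:
        y = y + rng.normal(0.0, spec.noise_sd, size=len(y))
    responses = ResponseTable(
        values={rid: float(v) for rid, v in zip(design.run_ids, y)}
    )
    return design, responses


def simulate_response_batch(
    spec: TruthSpec, n_replicates: int, rng: np.random.Generator | None = None
) -> tuple[DesignTable, np.ndarray]:
    """Vectorized draw of many replicate experiments on one design.

    Returns the design and an (n_replicates, n_runs) response matrix; used
    by Monte-Carlo calibration checks where constructing one table at a time
    would dominate the cost.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    design = make_bbd(spec.factors, n_center=spec.n_center)
    mu = true_response(spec, design.coded)
    noise = rng.normal(0.0, spec.noise_sd, size=(n_replicates, len(mu)))
    return design, mu[None, :] + noise


def simulate_colonies(
    n: int, seed: int | None = None, top_strain: str = "XM"
) -> list[ColonyMeasurement]:
    """Simulate Congo-red plate measurements for ``n`` isolates.

    Colony diameters and clearance ratios are drawn from plausible plate
    ranges (colonies 2-10 mm, D/d between 1 and 3); the designated top
    strain receives a ratio above every other isolate so ranking tests have
    a known winner.
    """
    if n < 1:
        raise ValueError("need n >= 1 colonies")
    rng = np.random.default_rng(seed)
    colonies = rng.uniform(2.0, 10.0, size=n)
    ratios = rng.uniform(1.0, 3.0, size=n)
    ratios[0] = 3.5  # designated champion outranks the rest
    out = [
        ColonyMeasurement(
            strain=top_strain if i == 0 else f"S{i:03d}",
            clear_zone=float(colonies[i] * ratios[i]),
            colony=float(colonies[i]),
        )
        for i in range(n)
    ]
    return out
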