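"""Stationary-point analysis and bounded optimization of the fitted surface.

For a fitted quadratic y = b0 + g'x + x'Bx the gradient is g + 2Bx, so the
stationary point solves 2B x = -g.  The Hessian 2B is constant; its
eigenvalue signs classify the point (all negative -> maximum, all positive ->
minimum, mixed -> saddle).  Optimization always uses the full-precision
fitted coefficients, never rounded report values.

The default search region is the coded cube [-1, 1]^k -- the experimental
region.  A stationary point outside it is still reported, flagged as
non-interior, since predictions there extrapolate beyond the data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .factors import to_natural
from .model import QuadraticModel, predict

_EIG_TOL = 1e-10


class RidgeSystemError(np.linalg.LinAlgError):
    """Singular Hessian: the surface has a ridge; use bounded_maximize."""


@dataclass(frozen=True)
class StationaryPoint:
    """Location where the fitted surface's gradient vanishes (or, for
    bounded search, the box optimum), with curvature classification."""

    coded: np.ndarray
    natural: np.ndarray
    predicted: float
    classification: str  # "maximum" | "minimum" | "saddle"
    interior: bool       # all |coded| <= 1

    def describe(self, factors) -> str:
        parts = [
            f"{f.name} = {v:.3f} {f.units}".rstrip()
            for f, v in zip(factors, self.natural)
        ]
        return (
            f"{self.classification} at " + ", ".join(parts)
            + f"; predicted response {self.predicted:.3f}"
            + ("" if self.interior else " (outside the experimental region)")
        )


@dataclass(frozen=True)
class SurfaceGrid:
    """Predicted response over a rectangular slice in two factors, the
    others held fixed; used for response-surface / contour plots."""

    factor_i: str
    factor_j: str
    held: dict[str, float]
    coded_i: np.ndarray
    coded_j: np.ndarray
    natural_i: np.ndarray
    natural_j: np.ndarray
    predicted: np.ndarray  # shape (len(coded_i), len(coded_j))


def _classify(hessian: np.ndarray) -> str:
    eig = np.linalg.eigvalsh(hessian)
    if np.all(eig < -_EIG_TOL):
        return "maximum"
    if np.all(eig > _EIG_TOL):
        return "minimum"
    return "saddle"


def _as_point(model: QuadraticModel, coded: np.ndarray) -> StationaryPoint:
    natural = np.array(
        [to_natural(f, c) for f, c in zip(model.factors, coded)]
    )
    return StationaryPoint(
        coded=coded,
        natural=natural,
        predicted=float(predict(model, coded)),
        classification=_classify(model.hessian()),
        interior=bool(np.all(np.abs(coded) <= 1.0 + 1e-9)),
    )


def stationary_point(model: QuadraticModel) -> StationaryPoint:
    """Solve grad = 0 for the fitted surface and classify the solution.

    Raises
    ------
    RidgeSystemError
        If the Hessian is singular (a stationary ridge rather than a point);
        `bounded_maximize` still applies in that case.
    """
    H = model.hessian()
    g = np.asarray(model.b_lin, dtype=float)
    cond = np.linalg.cond(H)
    if not np.isfinite(cond) or cond > 1e12:
        raise RidgeSystemError(
            "Hessian is singular or near-singular (stationary ridge); "
            "use bounded_maximize over the experimental region instead"
        )
    coded = np.linalg.solve(H, -g)
    return _as_point(model, coded)


def bounded_maximize(
    model: QuadraticModel, bounds: list[tuple[float, float]] | None = None
) -> StationaryPoint:
    """Maximize the fitted quadratic over a coded box (default [-1, 1]^k).

    Multi-start L-BFGS-B from every box corner and the box center; a
    quadratic over a box attains its maximum at a stationary point or on the
    boundary, and the corner/center starts cover both basins in practice.
    """
    k = model.k
    if bounds is None:
        bounds = [(-1.0, 1.0)] * k
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    if any(lo > hi for lo, hi in bounds):
        raise ValueError("each bound must satisfy lo <= hi")

    def neg(x):
        return -predict(model, x)

    starts = [np.array(c) for c in itertools.product(*bounds)]
    starts.append(np.array([(lo + hi) / 2 for lo, hi in bounds]))
    best_x, best_v = None, np.inf
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-14, "gtol": 1e-12})
        if res.fun < best_v:
            best_v, best_x = res.fun, res.x
    return _as_point(model, np.asarray(best_x))


def surface_grid(
    model: QuadraticModel,
    factor_i: int | str,
    factor_j: int | str,
    held: dict | None = None,
    resolution: int = 50,
) -> SurfaceGrid:
    """Evaluate the fitted surface on a coded [-1,1]^2 grid in two factors.

    ``held`` maps the remaining factor names (or indices) to their coded
    values; unspecified factors are held at 0.
    """
    names = [f.name for f in model.factors]

    def _idx(f):
        return names.index(f) if isinstance(f, str) else int(f)

    i, j = _idx(factor_i), _idx(factor_j)
    if i == j:
        raise ValueError("the two grid factors must differ")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    held_coded = np.zeros(model.k)
    for key, val in (held or {}).items():
        held_coded[_idx(key)] = val

    ci = np.linspace(-1.0, 1.0, resolution)
    cj = np.linspace(-1.0, 1.0, resolution)
    pts = np.tile(held_coded, (resolution * resolution, 1))
    gi, gj = np.meshgrid(ci, cj, indexing="ij")
    pts[:, i] = gi.ravel()
    pts[:, j] = gj.ravel()
    z = np.asarray(predict(model, pts)).reshape(resolution, resolution)
    return SurfaceGrid(
        factor_i=names[i],
        factor_j=names[j],
        held={names[t]: float(held_coded[t]) for t in range(model.k)
              if t not in (i, j)},
        coded_i=ci,
        coded_j=cj,
        natural_i=np.array([to_natural(model.factors[i], c) for c in ci]),
        natural_j=np.array([to_natural(model.factors[j], c) for c in cj]),
        predicted=z,
    )


def validate_settings(
    model: QuadraticModel, practical: list[float] | np.ndarray
) -> tuple[float, float]:
    """Prediction at rounded, practically achievable natural settings and
    its gap below the surface optimum over the experimental region.

    Returns (predicted at practical settings, optimum - predicted).
    """
    practical = np.asarray(practical, dtype=float)
    if practical.shape != (model.k,):
        raise ValueError(f"expected {model.k} natural settings")
    at_practical = float(predict(model, practical, natural=True))
    optimum = bounded_maximize(model).predicted
    return at_practical, optimum - at_practical
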