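"""Full second-order (quadratic) response-surface model, fitted in coded units.

For k factors the model is

    y = b0 + sum_i b_i x_i + sum_{i<j} b_ij x_i x_j + sum_i b_ii x_i^2 + e,

with 1 + k + k(k-1)/2 + k coefficients estimated by ordinary least squares.
Fitting is always done in coded units, where the linear and interaction
columns of a Box-Behnken design are mutually orthogonal; natural-unit display
is a presentation transform only.  The full model is always fitted -- no term
selection, even when interactions are non-significant.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr as _pivoted_qr

from .design import DesignTable, ResponseTable
from .factors import Factor, to_coded


class SingularDesignError(np.linalg.LinAlgError):
    """Model matrix is rank deficient; names the collinear columns."""


class UndefinedRSquaredError(ZeroDivisionError):
    """All responses identical: the total sum of squares is zero."""


def term_labels(factors: tuple[Factor, ...]) -> list[str]:
    """Column labels of the quadratic model matrix: intercept, linear,
    pairwise interactions (lexicographic), then quadratic terms."""
    names = [f.name for f in factors]
    labels = ["Intercept"] + list(names)
    labels += [f"{a}:{b}" for a, b in itertools.combinations(names, 2)]
    labels += [f"{n}^2" for n in names]
    return labels


def model_matrix(coded: np.ndarray) -> np.ndarray:
    """Expand coded points (n, k) into the quadratic model matrix (n, p)."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass(frozen=True)
class QuadraticModel:
    """Fitted second-order polynomial in coded units.

    ``coef`` stores full-precision coefficients in `term_labels` order.
    ``b0``, ``b_lin``, ``b_int``, ``b_quad`` expose the same values by role.
    """

    factors: tuple[Factor, ...]
    coef: np.ndarray = field(repr=False)
    residuals: np.ndarray = field(repr=False)
    residual_df: int
    ss_total: float
    ss_model: float
    ss_residual: float

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def b0(self) -> float:
        return float(self.coef[0])

    @property
    def b_lin(self) -> np.ndarray:
        return self.coef[1 : 1 + self.k]

    @property
    def b_int(self) -> dict[tuple[str, str], float]:
        names = [f.name for f in self.factors]
        pairs = list(itertools.combinations(names, 2))
        start = 1 + self.k
        return {p: float(c) for p, c in zip(pairs, self.coef[start : start + len(pairs)])}

    @property
    def b_quad(self) -> np.ndarray:
        return self.coef[-self.k :]

    @property
    def labels(self) -> list[str]:
        return term_labels(self.factors)

    def interaction_matrix(self) -> np.ndarray:
        """Symmetric (k, k) matrix B with b_quad on the diagonal and half the
        interaction coefficients off-diagonal, so that the non-linear part of
        the polynomial is x' B x."""
        k = self.k
        B = np.diag(np.asarray(self.b_quad, dtype=float))
        start = 1 + k
        for (i, j), c in zip(itertools.combinations(range(k), 2), self.coef[start:]):
            B[i, j] = B[j, i] = c / 2.0
        return B

    def hessian(self) -> np.ndarray:
        """Hessian of the fitted polynomial (2B); constant for a quadratic."""
        return 2.0 * self.interaction_matrix()

    def to_dict(self) -> dict:
        return {
            "factors": [
                {"name": f.name, "units": f.units, "low": f.low,
                 "center": f.center, "high": f.high}
                for f in self.factors
            ],
            "terms": dict(zip(self.labels, self.coef.tolist())),
            "residual_df": self.residual_df,
            "ss_total": self.ss_total,
            "ss_model": self.ss_model,
            "ss_residual": self.ss_residual,
            "residuals": self.residuals.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        factors = tuple(Factor(**f) for f in d["factors"])
        coef = np.array([d["terms"][lab] for lab in term_labels(factors)])
        return cls(
            factors=factors,
            coef=coef,
            residuals=np.asarray(d["residuals"], dtype=float),
            residual_df=int(d["residual_df"]),
            ss_total=float(d["ss_total"]),
            ss_model=float(d["ss_model"]),
            ss_residual=float(d["ss_residual"]),
        )

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_quadratic(design: DesignTable, responses: ResponseTable) -> QuadraticModel:
    """Fit the full quadratic model by least squares (QR-based lstsq, no
    explicit normal-equation inversion).

    Raises
    ------
    SingularDesignError
        If the model matrix is rank deficient, naming the collinear columns.
    """
    y = responses.aligned(design)
    X = model_matrix(design.coded)
    n, p = X.shape
    if n < p:
        raise SingularDesignError(
            f"{n} runs cannot identify {p} quadratic-model coefficients"
        )
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        labels = term_labels(design.factors)
        # columns involved in the rank deficiency: QR with pivoting
        _, R, piv = _pivoted_qr(X, pivoting=True, mode="economic")
        diag = np.abs(np.diag(R))
        bad = [labels[piv[i]] for i in range(len(diag)) if diag[i] < diag[0] * 1e-10]
        bad += [labels[piv[i]] for i in range(len(diag), p)]
        raise SingularDesignError(
            f"model matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {bad}"
        )
    resid = y - X @ coef
    ss_residual = float(resid @ resid)
    ss_total = float(((y - y.mean()) ** 2).sum())
    return QuadraticModel(
        factors=design.factors,
        coef=coef,
        residuals=resid,
        residual_df=n - p,
        ss_total=ss_total,
        ss_model=ss_total - ss_residual,
        ss_residual=ss_residual,
    )


def predict(model: QuadraticModel, point, natural: bool = False) -> float | np.ndarray:
    """Evaluate the fitted polynomial at one point or an array of points.

    With ``natural=True`` the coordinates are converted to coded units through
    each factor's coding map first.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if pts.shape[1] != model.k:
        raise ValueError(f"expected {model.k} coordinates, got {pts.shape[1]}")
    if natural:
        pts = np.column_stack(
            [to_coded(f, pts[:, j]) for j, f in enumerate(model.factors)]
        )
    out = model_matrix(pts) @ model.coef
    return float(out[0]) if np.ndim(point) <= 1 else out


def r_squared(model: QuadraticModel) -> float:
    """Coefficient of determination, ss_model / ss_total."""
    if model.ss_total <= 0:
        raise UndefinedRSquaredError("constant responses: R^2 is undefined")
    return model.ss_model / model.ss_total


def adjusted_r_squared(model: QuadraticModel) -> float:
    """1 - (ss_residual/residual_df) / (ss_total/(n-1))."""
    if model.ss_total <= 0:
        raise UndefinedRSquaredError("constant responses: R^2 is undefined")
    n = model.residual_df + len(model.coef)
    return 1.0 - (model.ss_residual / model.residual_df) / (model.ss_total / (n - 1))


def _round_coef(value: float) -> str:
    # report style: 2 decimals, 3 for small coefficients (e.g. 0.015) that
    # would otherwise lose their leading digit
    if value != 0 and abs(value) < 0.1:
        return f"{value:.3f}"
    return f"{value:.2f}"


def format_equation(model: QuadraticModel, response_name: str = "Y") -> str:
    """Render the fitted equation in report style with positional letters
    (first factor A, second B, ...) and rounded coefficients."""
    letters = [chr(ord("A") + i) for i in range(model.k)]
    terms = [f"{model.b0:.2f}"]
    parts = list(zip(letters, model.b_lin))
    parts += [
        (f"{letters[i]}{letters[j]}", c)
        for (i, j), c in zip(
            itertools.combinations(range(model.k), 2), list(model.b_int.values())
        )
    ]
    parts += [(f"{l}^2", c) for l, c in zip(letters, model.b_quad)]
    for label, c in parts:
        sign = "+" if c >= 0 else "-"
        terms.append(f"{sign} {_round_coef(abs(float(c)))} {label}")
    return f"{response_name} = " + " ".join(terms)
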