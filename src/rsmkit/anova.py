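"""ANOVA for the quadratic response-surface fit.

Term sums of squares are *partial* (Type III): SS(term) is the increase in
residual SS when that single column is dropped from the full model.  For the
orthogonal linear and interaction columns of a Box-Behnken design this equals
the closed forms 8*b^2 and 4*b^2 (3 factors); the quadratic columns are
non-orthogonal to the intercept and to each other, so their partial SS differ
from sequential values.

The residual is further split into *pure error* -- within-group variation of
runs replicated at identical settings, usually the center replicates -- and
*lack of fit*, whose F test against pure error checks model adequacy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import betainc

from .design import DesignTable, ResponseTable
from .model import QuadraticModel, model_matrix, term_labels


class NoReplicatesError(ValueError):
    """No group of runs shares identical settings: pure error is undefined."""


class NoErrorEstimateError(ValueError):
    """Residual degrees of freedom are zero: F tests are impossible."""


def f_upper_tail(F: float, df1: int, df2: int) -> float:
    """Upper-tail probability of the F(df1, df2) distribution.

    Computed through the regularized incomplete beta function:
    P(X > F) = I_{df2/(df2 + df1*F)}(df2/2, df1/2).
    """
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if F < 0:
        raise ValueError(f"F statistic must be nonnegative, got {F}")
    x = df2 / (df2 + df1 * F)
    return float(betainc(df2 / 2.0, df1 / 2.0, x))


class LackOfFitResult(NamedTuple):
    ss_lof: float
    df_lof: int
    ss_pe: float
    df_pe: int
    F: float
    p: float


@dataclass(frozen=True)
class AnovaTable:
    """Ordered ANOVA rows: Model, each term, Residual, Lack of Fit,
    Pure Error, Cor Total.  F/p are NaN where the test is not defined."""

    rows: pd.DataFrame

    def row(self, term: str) -> pd.Series:
        match = self.rows[self.rows["term"] == term]
        if match.empty:
            raise KeyError(f"no ANOVA row for term {term!r}")
        return match.iloc[0]

    def to_frame(self) -> pd.DataFrame:
        return self.rows.copy()

    def formatted(self) -> pd.DataFrame:
        """Report-style table: p-values below 1e-4 shown as '<0.0001'."""
        out = self.rows.copy()
        out["p"] = [
            "" if np.isnan(p) else ("<0.0001" if p < 1e-4 else f"{p:.4f}")
            for p in self.rows["p"]
        ]
        out["F"] = ["" if np.isnan(f) else f"{f:.2f}" for f in self.rows["F"]]
        return out


def lack_of_fit(
    design: DesignTable, responses: ResponseTable, model: QuadraticModel
) -> LackOfFitResult:
    """Split residual SS into lack-of-fit and pure-error components.

    Pure error is the pooled within-group SS over all groups of runs with
    identical coded settings; its df is sum(group size - 1).
    """
    y = responses.aligned(design)
    groups = design.replicate_groups()
    if not groups:
        raise NoReplicatesError(
            "no replicated runs: residual cannot be decomposed into "
            "lack of fit and pure error"
        )
    ss_pe = 0.0
    df_pe = 0
    for idx in groups:
        g = y[idx]
        ss_pe += float(((g - g.mean()) ** 2).sum())
        df_pe += len(g) - 1
    ss_lof = model.ss_residual - ss_pe
    df_lof = model.residual_df - df_pe
    if df_lof < 1 or df_pe < 1:
        raise NoErrorEstimateError(
            f"cannot test lack of fit with df_lof={df_lof}, df_pe={df_pe}"
        )
    ms_pe = ss_pe / df_pe
    F = (ss_lof / df_lof) / ms_pe if ms_pe > 0 else np.inf
    p = f_upper_tail(F, df_lof, df_pe) if np.isfinite(F) else 0.0
    return LackOfFitResult(ss_lof, df_lof, ss_pe, df_pe, F, p)


def anova_partition(
    model: QuadraticModel, design: DesignTable, responses: ResponseTable
) -> AnovaTable:
    """Full ANOVA of the quadratic fit.

    Each term row tests F = MS(term) / MS(Residual) on (term df, residual df).
    Lack-of-fit / pure-error rows are included when the design has replicated
    runs; otherwise the residual is reported undecomposed.
    """
    if model.residual_df < 1:
        raise NoErrorEstimateError("saturated model: residual df is zero")
    y = responses.aligned(design)
    X = model_matrix(design.coded)
    labels = term_labels(design.factors)
    ms_res = model.ss_residual / model.residual_df

    rows: list[dict] = []

    def add(term, ss, df, F=np.nan, p=np.nan):
        ms = ss / df if df > 0 else np.nan
        rows.append(dict(term=term, ss=ss, df=df, ms=ms, F=F, p=p))

    df_model = len(labels) - 1
    F_model = (model.ss_model / df_model) / ms_res
    add("Model", model.ss_model, df_model, F_model,
        f_upper_tail(F_model, df_model, model.residual_df))

    # partial (Type III) SS: refit with the single column removed
    for i, label in enumerate(labels):
        if label == "Intercept":
            continue
        Xi = np.delete(X, i, axis=1)
        coef_i, *_ = np.linalg.lstsq(Xi, y, rcond=None)
        resid_i = y - Xi @ coef_i
        ss = float(resid_i @ resid_i) - model.ss_residual
        F = ss / ms_res
        add(label, ss, 1, F, f_upper_tail(F, 1, model.residual_df))

    add("Residual", model.ss_residual, model.residual_df)
    try:
        lof = lack_of_fit(design, responses, model)
        add("Lack of Fit", lof.ss_lof, lof.df_lof, lof.F, lof.p)
        add("Pure Error", lof.ss_pe, lof.df_pe)
    except NoReplicatesError:
        pass
    add("Cor Total", model.ss_total, len(y) - 1)

    return AnovaTable(rows=pd.DataFrame(rows))
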