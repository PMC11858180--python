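"""Wet-lab support statistics: DNS glucose standard curve and activity
conversion, Congo-red clearance-ratio ranking, and single-factor screening.

The DNS (3,5-dinitrosalicylic acid) assay measures reducing sugar released
from carboxymethyl cellulose: absorbance at 520 nm is read against a glucose
standard curve, and enzyme activity follows from the glucose released per
unit time.  The enzyme unit is configurable; the default is the common
definition 1 U = 1 umol glucose released per minute.

Congo-red plate screening ranks isolates by D/d -- clear-zone diameter over
colony diameter on CMC agar; larger ratios indicate stronger cellulolytic
clearing.  Single-factor screening picks the level of one factor with the
highest mean activity, which then seeds the center level of the follow-up
response-surface design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

GLUCOSE_MOLAR_MASS = 180.16  # g/mol


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares line absorbance = slope * concentration + intercept."""

    concentrations: np.ndarray  # mg/mL
    absorbances: np.ndarray     # OD at 520 nm
    slope: float
    intercept: float
    r2: float


@dataclass(frozen=True)
class ColonyMeasurement:
    """One isolate's Congo-red plate measurement (diameters in mm)."""

    strain: str
    clear_zone: float  # D
    colony: float      # d

    def __post_init__(self) -> None:
        if self.colony <= 0:
            raise ValueError(f"strain {self.strain!r}: colony diameter must be > 0")
        if self.clear_zone < self.colony:
            raise ValueError(
                f"strain {self.strain!r}: clear zone ({self.clear_zone}) "
                f"cannot be smaller than the colony ({self.colony})"
            )

    @property
    def ratio(self) -> float:
        return self.clear_zone / self.colony


@dataclass(frozen=True)
class SingleFactorSeries:
    """Mean activity at each tested level of one factor, e.g. activity
    (U/mL) versus shaker speed with everything else fixed."""

    factor: str
    levels: np.ndarray
    activities: np.ndarray
    replicates: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=float)
        acts = np.asarray(self.activities, dtype=float)
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "activities", acts)
        if levels.size != acts.size:
            raise ValueError("levels and activities must align")
        if levels.size and np.any(np.diff(levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(acts < 0):
            raise ValueError("activities must be nonnegative")


def fit_standard_curve(points) -> StandardCurve:
    """Fit the glucose standard line by ordinary least squares.

    ``points`` is an iterable of (concentration mg/mL, absorbance) pairs
    covering at least two distinct concentrations.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (concentration, absorbance) pairs")
    conc, absb = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate curve: all concentrations identical")
    fit = stats.linregress(conc, absb)
    return StandardCurve(
        concentrations=conc,
        absorbances=absb,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
    )


def activity_from_absorbance(
    curve: StandardCurve,
    a520: float,
    reaction_minutes: float,
    volume_factor: float = 1.0,
    umol_per_unit: float = 1.0,
) -> float:
    """Convert an absorbance reading to enzyme activity in U/mL.

    Glucose released (mg/mL) is read off the standard curve, converted to
    umol/mL through the glucose molar mass, divided by the reaction time and
    any dilution/volume factor applied.  ``umol_per_unit`` sets the unit
    definition (default 1 U = 1 umol glucose per minute).  A reading below
    the curve intercept clamps to zero activity.
    """
    if curve.slope == 0:
        raise ValueError("standard curve slope is zero")
    if reaction_minutes <= 0:
        raise ValueError("reaction time must be positive")
    glucose_mg_ml = (a520 - curve.intercept) / curve.slope
    if glucose_mg_ml < 0:
        import warnings

        warnings.warn("absorbance below curve intercept; activity clamped to 0")
        return 0.0
    umol_per_ml = glucose_mg_ml / GLUCOSE_MOLAR_MASS * 1000.0
    return umol_per_ml / reaction_minutes * volume_factor / umol_per_unit


def dd_ratio_rank(
    measurements: list[ColonyMeasurement],
) -> list[tuple[ColonyMeasurement, float]]:
    """Rank isolates by descending D/d ratio; ties break by strain id so the
    ordering is deterministic under input permutation."""
    return sorted(
        ((m, m.ratio) for m in measurements),
        key=lambda t: (-t[1], t[0].strain),
    )


def best_level(series: SingleFactorSeries) -> tuple[float, float]:
    """Level with the maximum mean activity; ties go to the lower level
    (the cheaper condition).  Feeds the center level of a follow-up design."""
    if series.levels.size < 2:
        raise ValueError("need at least two levels to screen")
    i = int(np.argmax(series.activities))  # argmax takes the first = lowest level
    return float(series.levels[i]), float(series.activities[i])
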