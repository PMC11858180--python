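"""Controllable experimental factors and coded-unit transforms.

A factor is a controllable fermentation variable (shaker speed, temperature,
incubation time, ...) studied at three natural levels: low, center, high.
Response-surface fitting works in *coded units*, where low/center/high map to
-1/0/+1.  Coding uses the affine map

    natural = offset + coded * step,   step = (high - low) / 2,
                                       offset = (low + high) / 2,

so the center level need not sit exactly halfway between low and high;
asymmetric level spacing is allowed and the coded value of the center level
is then not exactly 0.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Factor:
    """One controllable variable with its three design levels.

    Parameters
    ----------
    name
        Short label, e.g. ``"shaker_speed"``.
    units
        Free-text units, e.g. ``"r/min"``, ``"degC"``, ``"h"``.
    low, center, high
        Natural values at coded -1, 0 and +1.  Must be strictly increasing.
    """

    name: str
    units: str
    low: float
    center: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got {self.low}, {self.center}, {self.high}"
            )

    @property
    def step(self) -> float:
        """Half-range of the factor: one coded unit in natural units."""
        return (self.high - self.low) / 2.0

    @property
    def offset(self) -> float:
        """Natural value at coded 0 under the symmetric coding map."""
        return (self.low + self.high) / 2.0


def to_natural(factor: Factor, coded: float) -> float:
    """Convert a coded coordinate to natural units.

    Values beyond +/-1 extrapolate outside the experimental region; the
    transform itself is defined everywhere.
    """
    return factor.offset + coded * factor.step


def to_coded(factor: Factor, natural: float) -> float:
    """Convert a natural coordinate to coded units (inverse of `to_natural`)."""
    return (natural - factor.offset) / factor.step
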