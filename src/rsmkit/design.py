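"""Box-Behnken designs and run/response tables.

A Box-Behnken design (BBD) for k factors places runs at the midpoints of the
edges of the factor cube: every pair of factors takes all four (+/-1, +/-1)
sign combinations while the remaining factors sit at 0, giving 2*k*(k-1) edge
runs, plus ``n_center`` replicated all-zero center runs.  The replicated
centers provide a model-free estimate of pure experimental error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .factors import Factor, to_coded, to_natural

_CENTER_TOL = 1e-9

# canonical sign order for each factor pair: (-,-), (+,-), (-,+), (+,+)
_EDGE_SIGNS = ((-1, -1), (1, -1), (-1, 1), (1, 1))


class UnsupportedDesignError(ValueError):
    """Raised when the requested design is outside the supported family."""


@dataclass(frozen=True)
class DesignTable:
    """A coded run matrix with its factor definitions.

    ``coded`` has one row per run and one column per factor; ``run_ids``
    aligns with the rows.  Center runs are those with all coordinates 0.
    """

    factors: tuple[Factor, ...]
    run_ids: tuple[int, ...]
    coded: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coded = np.asarray(self.coded, dtype=float)
        object.__setattr__(self, "coded", coded)
        if coded.ndim != 2 or coded.shape != (len(self.run_ids), len(self.factors)):
            raise ValueError(
                f"coded matrix shape {coded.shape} does not match "
                f"{len(self.run_ids)} runs x {len(self.factors)} factors"
            )
        if len(set(self.run_ids)) != len(self.run_ids):
            raise ValueError("run_ids must be unique")
        if not np.all(np.isfinite(coded)):
            raise ValueError("coded levels must be finite")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.run_ids)

    @property
    def center_mask(self) -> np.ndarray:
        return np.all(np.abs(self.coded) <= _CENTER_TOL, axis=1)

    @property
    def n_center(self) -> int:
        return int(self.center_mask.sum())

    def natural(self) -> np.ndarray:
        """Run settings in natural units, same shape as ``coded``."""
        out = np.empty_like(self.coded)
        for j, f in enumerate(self.factors):
            out[:, j] = to_natural(f, self.coded[:, j])
        return out

    def replicate_groups(self) -> list[np.ndarray]:
        """Indices of runs grouped by identical coded settings (size >= 2)."""
        groups: dict[tuple, list[int]] = {}
        for i, row in enumerate(np.round(self.coded / _CENTER_TOL) * _CENTER_TOL):
            groups.setdefault(tuple(row), []).append(i)
        return [np.array(v) for v in groups.values() if len(v) >= 2]

    def to_frame(self, units: str = "coded") -> pd.DataFrame:
        """Export as a table with a ``run_id`` column; units 'coded' or 'natural'."""
        if units not in ("coded", "natural"):
            raise ValueError("units must be 'coded' or 'natural'")
        values = self.coded if units == "coded" else self.natural()
        df = pd.DataFrame(values, columns=[f.name for f in self.factors])
        df.insert(0, "run_id", list(self.run_ids))
        return df


@dataclass(frozen=True)
class ResponseTable:
    """Measured responses keyed by run_id (e.g. cellulase activity, U/mL)."""

    values: dict[int, float]
    units: str = ""

    def __post_init__(self) -> None:
        vals = {int(k): float(v) for k, v in self.values.items()}
        if not all(np.isfinite(list(vals.values()))):
            raise ValueError("responses must be finite")
        object.__setattr__(self, "values", vals)

    def aligned(self, design: DesignTable) -> np.ndarray:
        """Response vector in the design's run order; every run must appear."""
        missing = [rid for rid in design.run_ids if rid not in self.values]
        if missing:
            raise ValueError(f"missing responses for run_ids {missing}")
        extra = set(self.values) - set(design.run_ids)
        if extra:
            raise ValueError(f"responses for unknown run_ids {sorted(extra)}")
        return np.array([self.values[rid] for rid in design.run_ids])


def bbd_edge_runs(k: int) -> np.ndarray:
    """Canonical edge-run block of a k-factor BBD.

    Rows are ordered lexicographically over factor pairs, then over the four
    sign combinations within each pair.
    """
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in _EDGE_SIGNS:
            row = np.zeros(k)
            row[i], row[j] = si, sj
            rows.append(row)
    return np.array(rows)


def make_bbd(
    factors: list[Factor] | tuple[Factor, ...],
    n_center: int = 5,
    seed: int | None = None,
) -> DesignTable:
    """Construct a Box-Behnken design.

    Parameters
    ----------
    factors
        3 to 7 factor definitions.
    n_center
        Number of replicated center runs (>= 1); 5 is the usual choice for
        three factors.
    seed
        If given, the run order is permuted reproducibly; run_ids travel with
        their settings, so the set of runs is the same for every seed.

    Returns
    -------
    DesignTable with 2*k*(k-1) + n_center runs.
    """
    factors = tuple(factors)
    k = len(factors)
    if not 3 <= k <= 7:
        raise UnsupportedDesignError(
            f"Box-Behnken designs are supported for 3-7 factors, got {k}"
        )
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    coded = np.vstack([bbd_edge_runs(k), np.zeros((n_center, k))])
    run_ids = np.arange(1, len(coded) + 1)
    if seed is not None:
        perm = np.random.default_rng(seed).permutation(len(coded))
        coded, run_ids = coded[perm], run_ids[perm]
    return DesignTable(factors=factors, run_ids=tuple(int(r) for r in run_ids), coded=coded)


def design_from_settings(
    factors: list[Factor] | tuple[Factor, ...],
    run_ids,
    settings,
    units: str = "coded",
) -> DesignTable:
    """Build a DesignTable from externally supplied run settings.

    Accepts coded or natural units; natural settings are converted through
    the factor coding maps.  Used for run tables recorded by lab software,
    whose run order is treated as given rather than regenerated.
    """
    factors = tuple(factors)
    settings = np.asarray(settings, dtype=float)
    if units == "natural":
        settings = np.column_stack(
            [to_coded(f, settings[:, j]) for j, f in enumerate(factors)]
        )
    elif units != "coded":
        raise ValueError("units must be 'coded' or 'natural'")
    return DesignTable(
        factors=factors, run_ids=tuple(int(r) for r in run_ids), coded=settings
    )
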