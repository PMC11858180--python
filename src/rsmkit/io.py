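"""Reading and writing the package's text formats.

Factor configs are JSON; design/response run tables are comma-separated text
with a header row.  Whether a run table is in coded or natural units is
declared -- via a ``# units: coded|natural`` comment line above the header
or an explicit argument -- never guessed from value ranges.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .design import DesignTable, ResponseTable, design_from_settings
from .factors import Factor

RESPONSE_COLUMN = "response"


class TableFormatError(ValueError):
    """A run table violates the expected schema; messages name file/row."""


def read_factors(path) -> tuple[Factor, ...]:
    """Load factor definitions from a JSON config.

    The file is either a list of factor objects or ``{"factors": [...]}``,
    each object carrying name/units/low/center/high.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = data.get("factors", data)
    try:
        return tuple(
            Factor(
                name=f["name"],
                units=f.get("units", ""),
                low=float(f["low"]),
                center=float(f["center"]),
                high=float(f["high"]),
            )
            for f in data
        )
    except (KeyError, TypeError) as exc:
        raise TableFormatError(f"{path}: malformed factor config: {exc}") from exc


def write_factors(factors, path) -> None:
    payload = {
        "factors": [
            {"name": f.name, "units": f.units, "low": f.low,
             "center": f.center, "high": f.high}
            for f in factors
        ]
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def _declared_units(path) -> str | None:
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith("#") and "units:" in first:
        return first.split("units:")[1].strip()
    return None


def read_run_table(
    path, factors, units: str | None = None
) -> tuple[DesignTable, ResponseTable | None]:
    """Read a run table (CSV: run_id, one column per factor, optional
    ``response``) into validated design and response tables.

    ``units`` must be 'coded' or 'natural', given either here or as a
    ``# units: ...`` comment on the file's first line.
    """
    declared = _declared_units(path)
    units = units or declared
    if units not in ("coded", "natural"):
        raise TableFormatError(
            f"{path}: units must be declared as 'coded' or 'natural' "
            "(argument or '# units:' header line)"
        )
    df = pd.read_csv(path, comment="#")
    factors = tuple(factors)
    names = [f.name for f in factors]
    expected = {"run_id", *names}
    missing = expected - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df.columns) - expected - {RESPONSE_COLUMN}
    if unknown:
        raise TableFormatError(f"{path}: unknown columns {sorted(unknown)}")
    dup = df["run_id"][df["run_id"].duplicated()]
    if not dup.empty:
        raise TableFormatError(
            f"{path}: duplicate run_id {sorted(dup.unique().tolist())}"
        )
    for col in names + (["response"] if RESPONSE_COLUMN in df.columns else []):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if not bad.empty:
            row = int(bad.index[0]) + 2  # 1-based, after header
            raise TableFormatError(
                f"{path}: non-numeric value in column {col!r} at row {row}"
            )
        df[col] = pd.to_numeric(df[col])
    design = design_from_settings(
        factors, run_ids=df["run_id"].tolist(), settings=df[names].to_numpy(),
        units=units,
    )
    responses = None
    if RESPONSE_COLUMN in df.columns:
        responses = ResponseTable(
            values=dict(zip(df["run_id"].astype(int), df[RESPONSE_COLUMN]))
        )
    return design, responses


def write_run_table(
    design: DesignTable,
    path,
    responses: ResponseTable | None = None,
    units: str = "coded",
) -> None:
    """Write a design (and optionally responses) as a units-annotated CSV."""
    df = design.to_frame(units=units)
    if responses is not None:
        df[RESPONSE_COLUMN] = [responses.values[r] for r in design.run_ids]
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)
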