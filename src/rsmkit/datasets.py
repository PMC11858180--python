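"""Bundled example dataset: cellulase-activity fermentation optimization.

A published three-factor Box-Behnken experiment optimizing CMCase production
by a cellulolytic *Bacillus* isolate from deer feces: shaker speed (100-200
r/min), culture temperature (29-37 degC) and incubation time (18-36 h), 12
edge runs plus 5 center replicates, response in U/mL by the DNS assay.  The
run order is the one recorded by the original experimenters.
"""

from __future__ import annotations

from .design import DesignTable, ResponseTable, design_from_settings
from .factors import Factor

CELLULASE_FACTORS = (
    Factor("shaker_speed", "r/min", 100.0, 150.0, 200.0),
    Factor("temperature", "degC", 29.0, 33.0, 37.0),
    Factor("incubation_time", "h", 18.0, 27.0, 36.0),
)

# run_id, coded A (speed), coded B (temperature), coded C (time), activity U/mL
CELLULASE_RUNS = (
    (1, 0, 0, 0, 10.32),
    (2, -1, 0, 1, 4.13),
    (3, 1, 0, 1, 5.19),
    (4, 1, -1, 0, 4.62),
    (5, 0, -1, 1, 4.00),
    (6, 0, 0, 0, 10.68),
    (7, 0, 0, 0, 10.26),
    (8, -1, -1, 0, 2.71),
    (9, 1, 0, -1, 3.54),
    (10, 0, -1, -1, 3.13),
    (11, 0, 0, 0, 10.81),
    (12, 1, 1, 0, 6.60),
    (13, 0, 0, 0, 10.98),
    (14, 0, 1, -1, 6.36),
    (15, 0, 1, 1, 8.55),
    (16, -1, 1, 0, 4.95),
    (17, -1, 0, -1, 2.54),
)


def cellulase_experiment() -> tuple[DesignTable, ResponseTable]:
    """The 17-run cellulase optimization experiment (design + responses)."""
    design = design_from_settings(
        CELLULASE_FACTORS,
        run_ids=[r[0] for r in CELLULASE_RUNS],
        settings=[r[1:4] for r in CELLULASE_RUNS],
        units="coded",
    )
    responses = ResponseTable(
        values={r[0]: r[4] for r in CELLULASE_RUNS}, units="U/mL"
    )
    return design, responses
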