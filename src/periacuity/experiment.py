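"""Experiment orchestration: run staircases over the 16-condition grid for a
cohort of simulated participants and emit a tidy threshold table, plus the
logMAR bookkeeping used to express acuity changes in chart letters.
"""

from __future__ import annotations

import hashlib
import json
import math

import numpy as np
import pandas as pd

from .conditions import Condition, build_condition_grid  # noqa: F401  (re-export)
from .staircase import StaircaseConfig, run_staircase
from .stimuli import DisplayGeometry

THRESHOLD_TABLE_COLUMNS = (
    "participant_id",
    "target_state",
    "background_state",
    "staircase_id",
    "threshold_deg",
)
THRESHOLD_TABLE_SCHEMA_VERSION = 1


def validate_threshold_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in THRESHOLD_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"threshold table missing columns: {missing}")
    if (table["threshold_deg"] <= 0).any():
        raise ValueError("thresholds must be positive")
    for _, row in table[["target_state", "background_state"]].drop_duplicates().iterrows():
        Condition(row["target_state"], row["background_state"])  # raises if invalid
    dup = table.duplicated(subset=["participant_id", "staircase_id"])
    if dup.any():
        raise ValueError("staircase_id must be unique within participant")
    return table


def _config_hash(config: StaircaseConfig, geometry: DisplayGeometry) -> str:
    payload = json.dumps([repr(config), repr(geometry)]).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_experiment(
    cohort,
    grid: list[Condition] | None = None,
    staircase_config: StaircaseConfig | None = None,
    n_staircases: int = 6,
    master_seed: int = 0,
    geometry: DisplayGeometry | None = None,
    n_staircases_override: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full grid for every participant; returns (table, manifest).

    ``cohort`` is a sequence of participants exposing ``participant_id`` and
    ``observer_for(condition)`` (see :mod:`periacuity.cohort`).  Condition
    order is shuffled independently per participant; staircase seeds are
    spawned hierarchically from ``master_seed`` so any single staircase can
    be replayed in isolation.  ``n_staircases_override`` maps participant id
    (or ``(participant_id, condition_label)``) to a per-cell staircase count,
    emulating participants who ran more than the minimum six.
    """
    if not len(cohort):
        raise ValueError("cohort must be nonempty")
    if n_staircases < 1:
        raise ValueError("n_staircases must be >= 1")
    grid = grid if grid is not None else build_condition_grid()
    config = staircase_config if staircase_config is not None else StaircaseConfig()
    geometry = geometry if geometry is not None else DisplayGeometry()
    override = n_staircases_override or {}

    root = np.random.SeedSequence(master_seed)
    participant_seeds = root.spawn(len(cohort))

    rows = []
    orders = {}
    for participant, pseed in zip(cohort, participant_seeds):
        pid = participant.participant_id
        order_rng = np.random.default_rng(pseed.spawn(1)[0])
        order = list(order_rng.permutation(len(grid)))
        orders[pid] = [grid[i].label for i in order]
        cond_seeds = pseed.spawn(len(grid))
        staircase_counter = 0
        for gi in order:
            condition = grid[gi]
            n_sc = override.get(
                (pid, condition.label), override.get(pid, n_staircases)
            )
            sc_seeds = cond_seeds[gi].spawn(n_sc)
            observer = participant.observer_for(condition)
            for k in range(n_sc):
                try:
                    threshold, _log = run_staircase(
                        observer, condition, config, geometry, sc_seeds[k]
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"staircase failed in cell participant={pid} "
                        f"condition={condition.label} staircase={k + 1}: {exc}"
                    ) from exc
                staircase_counter += 1
                rows.append(
                    {
                        "participant_id": pid,
                        "target_state": condition.target_state,
                        "background_state": condition.background_state,
                        "staircase_id": staircase_counter,
                        "threshold_deg": threshold,
                    }
                )

    table = pd.DataFrame(rows, columns=list(THRESHOLD_TABLE_COLUMNS))
    manifest = {
        "schema_version": THRESHOLD_TABLE_SCHEMA_VERSION,
        "master_seed": master_seed,
        "n_participants": len(cohort),
        "n_conditions": len(grid),
        "n_staircases_default": n_staircases,
        "condition_orders": orders,
        "config_hash": _config_hash(config, geometry),
        "n_rows": len(table),
        "mode": "staircase",
    }
    return validate_threshold_table(table), manifest


# ----------------------------------------------------------------------
# logMAR utilities
# ----------------------------------------------------------------------

LOGMAR_PER_LETTER = 0.02
LOGMAR_PER_LINE = 0.1


def logmar_difference(size_a_deg: float, size_b_deg: float) -> float:
    """logMAR difference log10(a/b); positive when ``a`` is worse (larger)."""
    if size_a_deg <= 0 or size_b_deg <= 0:
        raise ValueError("letter sizes must be positive")
    return math.log10(size_a_deg / size_b_deg)


def logmar_to_letters(delta_logmar: float, rounded: bool = False) -> float:
    """Convert a logMAR difference to chart letters (0.02 logMAR per letter)."""
    letters = delta_logmar / LOGMAR_PER_LETTER
    return float(round(letters)) if rounded else letters
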