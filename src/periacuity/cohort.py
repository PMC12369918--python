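"""Synthetic participant cohorts.

Each simulated participant has, for every condition, a true 79.4%-correct
letter size equal to the condition's population mean plus a participant
intercept shared across conditions (and, optionally, a participant-by-
condition jitter).  The Weibull scale alpha is then solved so the observer's
``0.5^(1/3)``-correct point sits exactly at that true threshold.  Threshold
tables can be produced either by running the full staircase pipeline or by
a fast path that samples directly from a normal approximation to the
staircase estimator's sampling distribution.

The default cell means are the group means measured for the 16 conditions
(degrees); the variability defaults (``sd_participant`` 0.04 deg,
``sd_staircase`` 0.02 deg) are synthetic choices, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditions import Condition, build_condition_grid
from .experiment import (
    THRESHOLD_TABLE_COLUMNS,
    run_experiment,
    validate_threshold_table,
)
from .observers import P_THREE_DOWN_ONE_UP, PsychometricObserver, alpha_for_threshold
from .staircase import StaircaseConfig
from .stimuli import DisplayGeometry


class CohortError(ValueError):
    pass


#: group-mean thresholds (degrees) per condition, target letter first.
#: The target-L-on-uniform cell is printed in two pooled contexts (0.464 and
#: 0.474); the first-printed value is used here.
DEFAULT_CELL_MEANS: dict[str, float] = {
    "BU": 0.459,
    "WU": 0.506,
    "LU": 0.464,
    "HU": 0.476,
    "BN": 0.552,
    "WN": 0.602,
    "LN": 0.457,
    "HN": 0.495,
    "BL": 0.532,
    "BH": 0.475,
    "WL": 0.602,
    "WH": 0.581,
    "LL": 0.525,
    "LH": 0.463,
    "HL": 0.438,
    "HH": 0.520,
}


@dataclass(frozen=True)
class CohortSpec:
    n_participants: int = 10
    cell_mean_map: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CELL_MEANS)
    )
    sd_participant: float = 0.04
    sd_staircase: float = 0.02
    #: participant-by-condition jitter; 0 keeps the data-generating process
    #: exactly within the random-intercept structure the mixed model assumes
    sd_cell: float = 0.0
    psychometric_beta: float = 2.5
    lapse: float = 0.01
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise CohortError("n_participants must be >= 1")
        if min(self.sd_participant, self.sd_staircase, self.sd_cell) < 0:
            raise CohortError("standard deviations must be >= 0")
        grid_labels = {c.label for c in build_condition_grid()}
        unknown = set(self.cell_mean_map) - grid_labels
        if unknown:
            raise CohortError(f"unknown condition labels in cell_mean_map: {unknown}")


@dataclass
class SimulatedParticipant:
    participant_id: str
    true_thresholds_deg: dict[str, float]
    observers: dict[str, PsychometricObserver]

    def observer_for(self, condition: Condition) -> PsychometricObserver:
        return self.observers[condition.label]


def generate_cohort(spec: CohortSpec) -> list[SimulatedParticipant]:
    """Draw per-participant, per-condition Weibull observers (deterministic in seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.master_seed))
    labels = list(spec.cell_mean_map)
    participants = []
    for i in range(spec.n_participants):
        offset = rng.normal(0.0, spec.sd_participant) if spec.sd_participant else 0.0
        thresholds: dict[str, float] = {}
        observers: dict[str, PsychometricObserver] = {}
        for label in labels:
            jitter = rng.normal(0.0, spec.sd_cell) if spec.sd_cell else 0.0
            t = spec.cell_mean_map[label] + offset + jitter
            if t <= 0:
                raise CohortError(
                    f"drawn threshold {t:.4f} deg for cell {label} is not in the "
                    "solvable range of the psychometric function"
                )
            alpha = alpha_for_threshold(
                t,
                p_target=P_THREE_DOWN_ONE_UP,
                beta=spec.psychometric_beta,
                guess_rate=0.25,
                lapse_rate=spec.lapse,
            )
            thresholds[label] = t
            observers[label] = PsychometricObserver(
                alpha_deg=alpha,
                beta=spec.psychometric_beta,
                lapse_rate=spec.lapse,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        participants.append(
            SimulatedParticipant(f"P{i + 1:02d}", thresholds, observers)
        )
    return participants


def generate_threshold_table(
    spec: CohortSpec,
    staircase_config: StaircaseConfig | None = None,
    n_staircases: int = 6,
    mode: str = "full",
    geometry: DisplayGeometry | None = None,
    n_staircases_override: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy threshold table; returns (table, manifest).

    ``mode='full'`` runs the actual staircase per cell; ``mode='fast'``
    samples each staircase threshold from N(true threshold, sd_staircase),
    the normal approximation to the staircase estimator.  The mode is
    recorded in the manifest.
    """
    if mode not in ("full", "fast"):
        raise CohortError(f"mode must be 'full' or 'fast', got {mode!r}")
    config = staircase_config if staircase_config is not None else StaircaseConfig()
    cohort = generate_cohort(spec)

    if mode == "full":
        table, manifest = run_experiment(
            cohort,
            grid=[Condition(l[0], l[1]) for l in spec.cell_mean_map],
            staircase_config=config,
            n_staircases=n_staircases,
            master_seed=spec.master_seed,
            geometry=geometry,
            n_staircases_override=n_staircases_override,
        )
        manifest["mode"] = "full"
        return table, manifest

    rng = np.random.default_rng(np.random.SeedSequence((spec.master_seed, 1)))
    override = n_staircases_override or {}
    rows = []
    for participant in cohort:
        counter = 0
        for label, true_t in participant.true_thresholds_deg.items():
            n_sc = override.get(
                (participant.participant_id, label),
                override.get(participant.participant_id, n_staircases),
            )
            draws = true_t + rng.normal(0.0, spec.sd_staircase, size=n_sc)
            draws = np.clip(draws, config.size_floor_deg, config.size_ceiling_deg)
            for value in draws:
                counter += 1
                rows.append(
                    {
                        "participant_id": participant.participant_id,
                        "target_state": label[0],
                        "background_state": label[1],
                        "staircase_id": counter,
                        "threshold_deg": float(value),
                    }
                )
    table = pd.DataFrame(rows, columns=list(THRESHOLD_TABLE_COLUMNS))
    manifest = {
        "mode": "fast",
        "master_seed": spec.master_seed,
        "n_participants": spec.n_participants,
        "n_conditions": len(spec.cell_mean_map),
        "n_staircases_default": n_staircases,
        "n_rows": len(table),
    }
    return validate_threshold_table(table), manifest
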