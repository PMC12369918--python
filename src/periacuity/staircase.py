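"""3-down/1-up transformed up-down staircase with a reversal-indexed step
schedule and reversal-averaged threshold estimation.

The rule converges on the letter size supporting ``0.5^(1/3) ~ 79.4%``
correct.  Size starts at 1.5 deg and moves down after three consecutive
correct responses and up after any error; the step size follows the
schedule 0.4, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05, 0.025, 0.025 deg, advancing
one slot at each reversal (and holding at the last slot thereafter).  A
staircase is complete at the first trial where it has at least 50 trials
and nine reversals; the threshold is the mean of the final six reversal
sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conditions import Condition
from .stimuli import (
    ORIENTATIONS_DEG,
    DisplayGeometry,
    NoiseSpec,
    compose_trial,
)
from .observers import (
    PsychometricObserver,
    TemplateObserver,
    respond_parametric,
    respond_template,
)

DEFAULT_STEP_SCHEDULE = (0.4, 0.2, 0.2, 0.1, 0.1, 0.05, 0.05, 0.025, 0.025)

#: smallest renderable letter on the default display (2 pixels)
DEFAULT_SIZE_FLOOR_DEG = 2 * 0.98 / 60.0

TRIAL_LOG_COLUMNS = (
    "trial",
    "size_deg",
    "orientation_deg",
    "response",
    "correct",
    "reversal_flag",
    "step_deg",
)


class StaircaseError(RuntimeError):
    pass


class NonConvergenceError(StaircaseError):
    pass


@dataclass(frozen=True)
class StaircaseConfig:
    start_size_deg: float = 1.5
    n_down: int = 3
    n_up: int = 1
    step_schedule_deg: tuple[float, ...] = DEFAULT_STEP_SCHEDULE
    min_trials: int = 50
    min_reversals: int = 9
    n_reversals_for_threshold: int = 6
    size_floor_deg: float = DEFAULT_SIZE_FLOOR_DEG
    size_ceiling_deg: float = 3.0
    # step-index advance convention: by default the move that causes a
    # reversal still uses the pre-reversal step and the schedule advances
    # for subsequent moves; the alternative advances before that move.
    advance_step_before_move: bool = False

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.step_schedule_deg):
            raise ValueError("step schedule must be strictly positive")
        if self.n_reversals_for_threshold > self.min_reversals:
            raise ValueError("n_reversals_for_threshold must be <= min_reversals")
        if not (0 < self.size_floor_deg < self.start_size_deg <= self.size_ceiling_deg):
            raise ValueError("require floor < start <= ceiling")


@dataclass
class StaircaseState:
    current_size_deg: float
    consecutive_correct: int = 0
    trial_count: int = 0
    reversal_sizes_deg: list[float] = field(default_factory=list)
    last_direction: str | None = None  # "down" | "up" | None
    step_index: int = 0
    trial_log: list[dict] = field(default_factory=list)


def new_staircase(config: StaircaseConfig) -> StaircaseState:
    return StaircaseState(current_size_deg=config.start_size_deg)


def is_complete(state: StaircaseState, config: StaircaseConfig) -> bool:
    return (
        state.trial_count >= config.min_trials
        and len(state.reversal_sizes_deg) >= config.min_reversals
    )


def _current_step(state: StaircaseState, config: StaircaseConfig) -> float:
    idx = min(state.step_index, len(config.step_schedule_deg) - 1)
    return config.step_schedule_deg[idx]


def staircase_update(
    state: StaircaseState,
    config: StaircaseConfig,
    correct: bool,
    orientation_deg: float = math.nan,
    response: float = math.nan,
) -> StaircaseState:
    """Apply one trial outcome to the staircase (mutates and returns state)."""
    if is_complete(state, config):
        raise StaircaseError("staircase_update called after completion")
    state.trial_count += 1
    presented_size = state.current_size_deg

    move: str | None = None
    if correct:
        state.consecutive_correct += 1
        if state.consecutive_correct >= config.n_down:
            state.consecutive_correct = 0
            move = "down"
    else:
        state.consecutive_correct = 0
        move = "up"

    reversal = False
    step_used = math.nan
    if move is not None:
        reversal = state.last_direction is not None and move != state.last_direction
        if reversal and config.advance_step_before_move:
            state.step_index += 1
        step_used = _current_step(state, config)
        delta = -step_used if move == "down" else step_used
        state.current_size_deg = float(
            np.clip(
                presented_size + delta, config.size_floor_deg, config.size_ceiling_deg
            )
        )
        if reversal:
            state.reversal_sizes_deg.append(presented_size)
            if not config.advance_step_before_move:
                state.step_index += 1
        state.last_direction = move

    state.trial_log.append(
        {
            "trial": state.trial_count,
            "size_deg": presented_size,
            "orientation_deg": orientation_deg,
            "response": response,
            "correct": bool(correct),
            "reversal_flag": reversal,
            "step_deg": step_used,
        }
    )
    return state


def estimate_threshold(state: StaircaseState, config: StaircaseConfig) -> float:
    """Mean of the final ``n_reversals_for_threshold`` reversal sizes."""
    if not is_complete(state, config):
        raise StaircaseError("estimate_threshold called before completion")
    tail = state.reversal_sizes_deg[-config.n_reversals_for_threshold :]
    return float(np.mean(tail))


def run_staircase(
    observer,
    condition: Condition,
    config: StaircaseConfig,
    geometry: DisplayGeometry,
    seed,
    noise_spec: NoiseSpec | None = None,
    max_ceiling_trials: int = 200,
    max_trials: int = 10_000,
) -> tuple[float, list[dict]]:
    """Run a full staircase; returns (threshold_deg, trial log).

    Parametric observers respond from letter size alone; template observers
    receive a freshly composed frame sequence each trial.  The trial
    orientation is drawn uniformly from the four alternatives.  A staircase
    pinned at the size ceiling for more than ``max_ceiling_trials``
    consecutive trials raises :class:`NonConvergenceError`; one pinned at the
    floor for that long (an observer who is never wrong down to the smallest
    renderable letter) terminates with the floor as its threshold, since no
    further reversals can occur.  ``max_trials`` is a hard safety cap.
    """
    rng = np.random.default_rng(seed)
    state = new_staircase(config)
    ceiling_run = 0
    floor_run = 0
    while not is_complete(state, config):
        if state.trial_count >= max_trials:
            raise NonConvergenceError(
                f"staircase did not complete within {max_trials} trials"
            )
        orientation = int(rng.choice(ORIENTATIONS_DEG))
        size = state.current_size_deg
        if isinstance(observer, TemplateObserver):
            frames = compose_trial(
                condition, size, orientation, geometry, rng, noise_spec=noise_spec
            )
            chosen, correct = respond_template(observer, frames, rng=rng)
        elif isinstance(observer, PsychometricObserver):
            chosen, correct = respond_parametric(observer, size, orientation, rng=rng)
        else:  # duck-typed observer: callable (size, orientation, rng) -> (resp, ok)
            chosen, correct = observer(size, orientation, rng)
        staircase_update(
            state, config, correct, orientation_deg=orientation, response=chosen
        )
        if state.current_size_deg >= config.size_ceiling_deg - 1e-12:
            ceiling_run += 1
            if ceiling_run > max_ceiling_trials:
                raise NonConvergenceError(
                    f"non-converging observer: staircase pinned at the "
                    f"{config.size_ceiling_deg} deg ceiling for more than "
                    f"{max_ceiling_trials} trials"
                )
        else:
            ceiling_run = 0
        if state.current_size_deg <= config.size_floor_deg + 1e-12:
            floor_run += 1
            if floor_run > max_ceiling_trials and state.trial_count >= config.min_trials:
                return config.size_floor_deg, state.trial_log
        else:
            floor_run = 0
    return estimate_threshold(state, config), state.trial_log


def trial_log_frame(trial_log: list[dict]):
    """Trial log as a pandas DataFrame with the canonical column order."""
    import pandas as pd

    return pd.DataFrame(trial_log, columns=list(TRIAL_LOG_COLUMNS))
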