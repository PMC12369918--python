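"""The 16-condition target/background grid.

Targets are static black (B), static white (W), or contrast-reversing at
8.5 Hz (L) or 17 Hz (H).  Backgrounds are uniform gray (U), static Brownian
noise (N), or noise reversing contrast at 8.5 Hz (L) or 17 Hz (H).  A
condition label such as "HL" reads target-first: target reversing at 17 Hz
on a background reversing at 8.5 Hz.  Reversing backgrounds necessarily
carry the noise texture — a uniform field has no contrast to reverse — so
the dynamic background states are only defined on the noise carrier.
"""

from __future__ import annotations

from dataclasses import dataclass

TARGET_STATES = ("B", "W", "L", "H")
BACKGROUND_STATES = ("U", "N", "L", "H")

#: square-wave polarity-flip rates, Hz
REVERSAL_RATE_HZ = {"L": 8.5, "H": 17.0}

SUBGROUP_NAMES = (
    "static_on_static",
    "reversing_on_static",
    "static_on_reversing",
    "reversing_on_reversing",
)


class InvalidConditionError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    """One cell of the 4 (target) x 4 (background) grid."""

    target_state: str
    background_state: str

    def __post_init__(self) -> None:
        if self.target_state not in TARGET_STATES:
            raise InvalidConditionError(
                f"target_state must be one of {TARGET_STATES}, got {self.target_state!r}"
            )
        if self.background_state not in BACKGROUND_STATES:
            raise InvalidConditionError(
                f"background_state must be one of {BACKGROUND_STATES}, "
                f"got {self.background_state!r}"
            )

    @property
    def label(self) -> str:
        return self.target_state + self.background_state

    @property
    def target_reversing(self) -> bool:
        return self.target_state in ("L", "H")

    @property
    def background_reversing(self) -> bool:
        return self.background_state in ("L", "H")

    @property
    def background_has_noise(self) -> bool:
        # reversing backgrounds always ride on the noise texture
        return self.background_state != "U"

    @property
    def target_rate_hz(self) -> float:
        return REVERSAL_RATE_HZ[self.target_state] if self.target_reversing else 0.0

    @property
    def background_rate_hz(self) -> float:
        return (
            REVERSAL_RATE_HZ[self.background_state]
            if self.background_reversing
            else 0.0
        )

    @property
    def subgroup(self) -> str:
        if self.target_reversing and self.background_reversing:
            return "reversing_on_reversing"
        if self.target_reversing:
            return "reversing_on_static"
        if self.background_reversing:
            return "static_on_reversing"
        return "static_on_static"

    @property
    def synchronous(self) -> bool | None:
        """For reversing-on-reversing cells, whether the rates match; else None."""
        if self.subgroup != "reversing_on_reversing":
            return None
        return self.target_state == self.background_state


def build_condition_grid() -> list[Condition]:
    """All 16 conditions in canonical (target-major) order.

    Order: targets B, W, L, H; within each target, backgrounds U, N, L, H.
    Exactly four conditions fall in each of the four subgroups.
    """
    return [
        Condition(t, b) for t in TARGET_STATES for b in BACKGROUND_STATES
    ]


def condition_from_label(label: str) -> Condition:
    if len(label) != 2:
        raise InvalidConditionError(f"condition label must be 2 letters, got {label!r}")
    return Condition(label[0], label[1])
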