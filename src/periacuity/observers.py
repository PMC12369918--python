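"""Simulated 4AFC observers.

Two observer families:

* :class:`PsychometricObserver` — a parametric Weibull observer used to
  validate the staircase machinery and to stand in for human participants
  in cohort simulations.  P(correct | size s) follows
  ``gamma + (1 - gamma - lapse) * (1 - exp(-(s/alpha)^beta))``.
* :class:`TemplateObserver` — an image-computable template matcher that
  responds to rendered frame sequences, used to check that composed stimuli
  actually support the orientation task.

Neither observer models the perceptual effects the human data show (e.g.
the black-target advantage); they are validation instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stimuli import (
    ORIENTATIONS_DEG,
    DisplayGeometry,
    FrameSequence,
    OptotypeSpec,
    render_optotype,
)

#: the percent-correct level a 3-down/1-up staircase converges to
P_THREE_DOWN_ONE_UP = 0.5 ** (1.0 / 3.0)


class ObserverError(ValueError):
    pass


@dataclass
class PsychometricObserver:
    """Weibull 4AFC observer.

    ``alpha_deg`` is the Weibull scale (degrees), ``beta`` the slope,
    ``guess_rate`` the 4AFC floor (0.25) and ``lapse_rate`` the asymptotic
    miss rate.  Defaults beta=2.5, lapse=0.01 are conventional values for
    letter acuity tasks.
    """

    alpha_deg: float
    beta: float = 2.5
    guess_rate: float = 0.25
    lapse_rate: float = 0.01
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.alpha_deg <= 0:
            raise ObserverError("alpha_deg must be positive")
        if not (0 <= self.guess_rate < 1 - self.lapse_rate):
            raise ObserverError("require 0 <= guess_rate < 1 - lapse_rate")
        self._rng = np.random.default_rng(self.seed)


def psychometric_prob(observer: PsychometricObserver, size_deg: float) -> float:
    """P(correct) at a given letter size."""
    if size_deg < 0:
        raise ObserverError("size_deg must be non-negative")
    g, lam = observer.guess_rate, observer.lapse_rate
    return g + (1 - g - lam) * (
        1 - math.exp(-((size_deg / observer.alpha_deg) ** observer.beta))
    )


def alpha_for_threshold(
    threshold_deg: float,
    p_target: float = P_THREE_DOWN_ONE_UP,
    beta: float = 2.5,
    guess_rate: float = 0.25,
    lapse_rate: float = 0.01,
) -> float:
    """Weibull scale alpha placing the ``p_target``-correct point at ``threshold_deg``."""
    if threshold_deg <= 0:
        raise ObserverError("threshold must be positive")
    if not (guess_rate < p_target < 1 - lapse_rate):
        raise ObserverError(
            f"target probability {p_target} outside the attainable range "
            f"({guess_rate}, {1 - lapse_rate})"
        )
    q = 1 - (p_target - guess_rate) / (1 - guess_rate - lapse_rate)
    return threshold_deg / (-math.log(q)) ** (1.0 / beta)


def threshold_for_probability(
    observer: PsychometricObserver,
    p_target: float = P_THREE_DOWN_ONE_UP,
    lo: float = 1e-9,
    hi: float = 1e3,
    tol: float = 1e-12,
) -> float:
    """Invert the psychometric function by bisection (brute-force inverse)."""
    if not (psychometric_prob(observer, lo) < p_target < psychometric_prob(observer, hi)):
        raise ObserverError("p_target outside the psychometric range")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if psychometric_prob(observer, mid) < p_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def respond_parametric(
    observer: PsychometricObserver,
    size_deg: float,
    truth_orientation_deg: int,
    rng: np.random.Generator | None = None,
) -> tuple[int, bool]:
    """One 4AFC response: (chosen orientation, correct?).

    Incorrect responses are uniform over the three wrong alternatives.
    """
    if truth_orientation_deg not in ORIENTATIONS_DEG:
        raise ObserverError(f"invalid orientation {truth_orientation_deg}")
    rng = rng if rng is not None else observer._rng
    p = psychometric_prob(observer, size_deg)
    if rng.random() < p:
        return truth_orientation_deg, True
    wrong = [o for o in ORIENTATIONS_DEG if o != truth_orientation_deg]
    return int(rng.choice(wrong)), False


# ----------------------------------------------------------------------
# image-computable template observer
# ----------------------------------------------------------------------

@dataclass
class TemplateObserver:
    """Noisy template-matching observer on rendered frame sequences.

    The stimulus patch at the target location is pooled over frames
    (``temporal_window``: 'mean' plain average, 'single-frame' first frame,
    or the default 'rectified-mean' — the average of absolute luminance
    deviations from the mean, which keeps contrast-reversing targets from
    self-cancelling).  The pooled, mean-subtracted patch is correlated with
    each orientation's template (maximized over template polarity), an
    independent Gaussian internal-noise sample is added per orientation, and
    the argmax is returned.  By construction the observer is blind to target
    polarity, so it cannot reproduce polarity asymmetries.
    """

    internal_noise_sd: float = 0.2
    temporal_window: str = "rectified-mean"
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.temporal_window not in ("mean", "single-frame", "rectified-mean"):
            raise ObserverError(f"unknown temporal_window {self.temporal_window!r}")
        if self.internal_noise_sd < 0:
            raise ObserverError("internal_noise_sd must be >= 0")
        self._rng = np.random.default_rng(self.seed)


def _pool_patch(observer: TemplateObserver, frames: FrameSequence) -> np.ndarray:
    mean_lum = frames.geometry.mean_luminance
    if observer.temporal_window == "single-frame":
        return frames.target_patch(frames.frame(0)) - mean_lum
    weights = frames.frame_weights()
    total = sum(weights.values())
    pooled = np.zeros(frames.target_patch(frames.frame(0)).shape)
    for key, w in weights.items():
        patch = frames.target_patch(frames.unique_frames[key]) - mean_lum
        if observer.temporal_window == "rectified-mean":
            patch = np.abs(patch)
        pooled += (w / total) * patch
    return pooled


def _correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def respond_template(
    observer: TemplateObserver,
    frames: FrameSequence,
    rng: np.random.Generator | None = None,
) -> tuple[int, bool]:
    """One 4AFC response of the template observer to a rendered trial."""
    rng = rng if rng is not None else observer._rng
    geometry: DisplayGeometry = frames.geometry
    d_px = geometry.degrees_to_pixels(frames.size_deg)
    if d_px > min(frames.shape):
        raise ObserverError("template larger than the stimulus patch")
    pooled = _pool_patch(observer, frames)

    scores = np.empty(len(ORIENTATIONS_DEG))
    for i, orient in enumerate(ORIENTATIONS_DEG):
        best = -np.inf
        for polarity in ("black", "white"):
            img, _ = render_optotype(
                OptotypeSpec(frames.size_deg, orient, polarity), geometry
            )
            template = img - geometry.mean_luminance
            if observer.temporal_window == "rectified-mean":
                template = np.abs(template)
            best = max(best, _correlation(pooled, template))
        scores[i] = best + rng.normal(0.0, observer.internal_noise_sd)

    top = np.flatnonzero(scores >= scores.max() - 1e-12)
    chosen = int(ORIENTATIONS_DEG[int(rng.choice(top))])
    return chosen, chosen == frames.truth_orientation_deg
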