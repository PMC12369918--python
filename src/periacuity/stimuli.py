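"""Stimulus synthesis: Sloan-style C optotypes, Brownian (1/f^2) noise
backgrounds, square-wave contrast-polarity timelines, and composed trial
frame sequences.

All images are luminance maps in cd/m^2.  The display model is a linear
luminance grid (no gamma stage): a pixel pitch in arcmin, a frame rate, and
a symmetric displayable range about the mean background luminance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .conditions import Condition

ORIENTATIONS_DEG = (45, 135, 225, 315)

#: gap direction -> response category (key codes follow the numeric keypad:
#: 1 lower-left, 4 upper-left, 5 upper-right, 2 lower-right)
ORIENTATION_RESPONSE = {
    45: "upper-right",
    135: "upper-left",
    225: "lower-left",
    315: "lower-right",
}
ORIENTATION_KEY = {45: 5, 135: 4, 225: 1, 315: 2}


class StimulusError(ValueError):
    pass


class UnrenderableSizeError(StimulusError):
    pass


# ----------------------------------------------------------------------
# display geometry
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class DisplayGeometry:
    """Linear display model.

    Defaults describe a CRT at 114 cm viewing distance: 0.98 arcmin/pixel,
    85 Hz refresh, 45 cd/m^2 mean background luminance with a symmetric
    0–90 cd/m^2 displayable range.
    """

    arcmin_per_pixel: float = 0.98
    frame_rate: float = 85.0
    mean_luminance: float = 45.0
    luminance_min: float = 0.0
    luminance_max: float = 90.0

    def __post_init__(self) -> None:
        if self.arcmin_per_pixel <= 0:
            raise ValueError("arcmin_per_pixel must be positive")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not (self.luminance_min < self.mean_luminance < self.luminance_max):
            raise ValueError("require luminance_min < mean_luminance < luminance_max")

    @property
    def pixel_pitch_deg(self) -> float:
        return self.arcmin_per_pixel / 60.0

    @property
    def nyquist_cpd(self) -> float:
        return 0.5 / self.pixel_pitch_deg

    @property
    def contrast_amplitude(self) -> float:
        """Largest luminance excursion displayable symmetrically about the mean."""
        return min(
            self.mean_luminance - self.luminance_min,
            self.luminance_max - self.mean_luminance,
        )

    def degrees_to_pixels(self, degrees: float) -> int:
        return int(round(degrees * 60.0 / self.arcmin_per_pixel))

    def pixels_to_degrees(self, pixels: float) -> float:
        return pixels * self.arcmin_per_pixel / 60.0

    def seconds_to_frames(self, seconds: float) -> int:
        return int(round(seconds * self.frame_rate))


# ----------------------------------------------------------------------
# optotype
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class OptotypeSpec:
    """A letter-C annulus on the standard 5x5 construction.

    Stroke width and gap width each default to one fifth of the letter
    diameter.  ``orientation_deg`` is the gap direction, measured counter-
    clockwise from rightward horizontal (45 = upper-right).
    """

    diameter_deg: float
    orientation_deg: int
    polarity: str = "black"
    stroke_fraction: float = 0.2
    gap_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.orientation_deg not in ORIENTATIONS_DEG:
            raise StimulusError(
                f"orientation must be one of {ORIENTATIONS_DEG}, got {self.orientation_deg}"
            )
        if self.polarity not in ("black", "white"):
            raise StimulusError(f"polarity must be 'black' or 'white', got {self.polarity!r}")
        if not (0 < self.stroke_fraction <= 0.5):
            raise StimulusError("stroke_fraction must lie in (0, 1/2]")
        if not (0 < self.gap_fraction < 1):
            raise StimulusError("gap_fraction must lie in (0, 1)")


def render_optotype(
    spec: OptotypeSpec, geometry: DisplayGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Render a letter-C patch.

    Returns ``(image, mask)``: a square luminance patch of side equal to the
    letter diameter in pixels (background pixels at mean luminance, letter
    pixels at the displayable minimum or maximum per ``spec.polarity``) and
    the boolean letter mask.
    """
    d_px = geometry.degrees_to_pixels(spec.diameter_deg)
    if d_px < 2:
        raise UnrenderableSizeError(
            f"unrenderable size: {spec.diameter_deg} deg is {d_px} px "
            f"at {geometry.arcmin_per_pixel} arcmin/px"
        )
    c = (d_px - 1) / 2.0
    rows, cols = np.mgrid[0:d_px, 0:d_px]
    x = cols - c
    y = c - rows  # image rows grow downward; flip so +y is up
    r = np.hypot(x, y)

    outer_r = d_px / 2.0
    inner_r = outer_r - spec.stroke_fraction * d_px
    annulus = (r <= outer_r) & (r > inner_r)

    theta = math.radians(spec.orientation_deg)
    along = x * math.cos(theta) + y * math.sin(theta)
    across = -x * math.sin(theta) + y * math.cos(theta)
    gap_half = spec.gap_fraction * d_px / 2.0
    gap = (along > 0) & (np.abs(across) <= gap_half)

    mask = annulus & ~gap
    value = (
        geometry.luminance_min if spec.polarity == "black" else geometry.luminance_max
    )
    image = np.full((d_px, d_px), geometry.mean_luminance, dtype=float)
    image[mask] = value
    return image, mask


# ----------------------------------------------------------------------
# noise background
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Band-limited Brownian-noise texture.

    Synthesis is direct in the Fourier domain: white Gaussian noise is
    filtered so the power spectrum falls as f^(-spectral_exponent) within
    (sf_lower_cpd, sf_upper_cpd] and is zero outside, then scaled so the
    0.1–99.9 percentile range spans ``contrast_fraction`` of the displayable
    Michelson range about the mean luminance (residual out-of-range pixels
    are clipped).  ``base_sf_cpd``/``bandwidth_octaves`` record the nominal
    element parameters of the texture family for provenance.
    """

    extent_deg: float = 16.7
    base_sf_cpd: float = 4.0
    bandwidth_octaves: float = 1.0
    spectral_exponent: float = 2.0
    sf_lower_cpd: float = 0.0
    sf_upper_cpd: float = 6.0
    contrast_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.sf_lower_cpd < self.sf_upper_cpd):
            raise StimulusError("require 0 <= sf_lower_cpd < sf_upper_cpd")
        if not (0 < self.contrast_fraction <= 1):
            raise StimulusError("contrast_fraction must lie in (0, 1]")
        if self.extent_deg <= 0:
            raise StimulusError("extent_deg must be positive")


def make_noise_background(spec: NoiseSpec, geometry: DisplayGeometry) -> np.ndarray:
    """Synthesize one Brownian-noise luminance image (deterministic in seed)."""
    if spec.sf_upper_cpd > geometry.nyquist_cpd:
        raise StimulusError(
            f"sf_upper_cpd {spec.sf_upper_cpd} exceeds the display Nyquist "
            f"frequency {geometry.nyquist_cpd:.2f} c/deg"
        )
    n = geometry.degrees_to_pixels(spec.extent_deg)
    if n < 8:
        raise StimulusError("noise extent below 8 pixels")

    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((n, n))
    spectrum = np.fft.fft2(white)

    f1 = np.fft.fftfreq(n, d=geometry.pixel_pitch_deg)
    fy, fx = np.meshgrid(f1, f1, indexing="ij")
    f = np.hypot(fx, fy)

    amp = np.zeros_like(f)
    band = (f > spec.sf_lower_cpd) & (f <= spec.sf_upper_cpd) & (f > 0)
    amp[band] = f[band] ** (-spec.spectral_exponent / 2.0)
    spectrum *= amp
    texture = np.fft.ifft2(spectrum).real
    texture -= texture.mean()  # exact DC removal

    lo, hi = np.percentile(texture, [0.1, 99.9])
    span = hi - lo
    if span <= 0:
        raise StimulusError("degenerate noise texture (zero contrast)")
    target_span = spec.contrast_fraction * 2.0 * geometry.contrast_amplitude
    texture *= target_span / span

    amp_max = geometry.contrast_amplitude
    deviation = np.clip(texture, -amp_max, amp_max)
    # snap deviations onto a fine symmetric grid (2^32 levels per amplitude,
    # ~1e-8 cd/m^2) so that contrast reversal about the mean is exactly
    # involutive in floating point
    quantum = amp_max / 2**32
    deviation = np.round(deviation / quantum) * quantum
    return geometry.mean_luminance + deviation


def flip_contrast(image: np.ndarray, geometry: DisplayGeometry) -> np.ndarray:
    """Reverse contrast polarity about the mean luminance (an involution)."""
    return 2.0 * geometry.mean_luminance - image


def radial_power_spectrum(
    image: np.ndarray, geometry: DisplayGeometry, n_bins: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Radially averaged power spectrum of a luminance image.

    Returns bin-center spatial frequencies (c/deg) and mean power per bin;
    the DC component is excluded.
    """
    centered = image - image.mean()
    power = np.abs(np.fft.fft2(centered)) ** 2
    n = image.shape[0]
    f1 = np.fft.fftfreq(n, d=geometry.pixel_pitch_deg)
    fy, fx = np.meshgrid(f1, np.fft.fftfreq(image.shape[1], d=geometry.pixel_pitch_deg), indexing="ij")
    f = np.hypot(fx, fy).ravel()
    p = power.ravel()
    keep = f > 0
    f, p = f[keep], p[keep]
    edges = np.linspace(0, f.max(), n_bins + 1)
    idx = np.clip(np.digitize(f, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=p, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore"):
        mean_power = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return centers, mean_power


def spectral_slope(
    image: np.ndarray,
    geometry: DisplayGeometry,
    f_lo: float = 0.5,
    f_hi: float = 6.0,
) -> float:
    """Log-log slope of the radially averaged power spectrum over [f_lo, f_hi]."""
    freqs, power = radial_power_spectrum(image, geometry)
    sel = (freqs >= f_lo) & (freqs <= f_hi) & np.isfinite(power) & (power > 0)
    if sel.sum() < 3:
        raise StimulusError("too few spectral bins in the requested band")
    coef = np.polyfit(np.log10(freqs[sel]), np.log10(power[sel]), 1)
    return float(coef[0])


# ----------------------------------------------------------------------
# temporal profiles
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class TemporalProfile:
    """Per-frame square-wave polarity timeline.

    ``signs`` holds +1 for frames in the initial polarity state and -1 for
    frames in the reversed state; static profiles are all +1.
    """

    state: str  # static_black | static_white | reversing
    reversal_rate_hz: float
    initial_polarity: str
    n_frames: int
    signs: np.ndarray = field(repr=False)

    @property
    def frames_per_state(self) -> int:
        if self.state != "reversing":
            return self.n_frames
        changes = np.flatnonzero(np.diff(self.signs))
        return int(changes[0] + 1) if changes.size else self.n_frames

    def polarities(self) -> list[str]:
        """Per-frame polarity labels ('black' / 'white')."""
        other = "white" if self.initial_polarity == "black" else "black"
        return [self.initial_polarity if s > 0 else other for s in self.signs]


def make_temporal_profile(
    state: str,
    rate_hz: float,
    n_frames: int,
    initial_polarity: str,
    geometry: DisplayGeometry,
) -> TemporalProfile:
    """Build a polarity timeline on the display frame grid.

    For reversing profiles the polarity flips every ``frame_rate / rate_hz``
    frames, which must be a positive integer (e.g. 85/17 = 5, 85/8.5 = 10).
    """
    if n_frames < 1:
        raise StimulusError("n_frames must be >= 1")
    if initial_polarity not in ("black", "white"):
        raise StimulusError("initial_polarity must be 'black' or 'white'")
    if state in ("static_black", "static_white"):
        signs = np.ones(n_frames, dtype=np.int8)
        pol = "black" if state == "static_black" else "white"
        return TemporalProfile(state, 0.0, pol, n_frames, signs)
    if state != "reversing":
        raise StimulusError(f"unknown temporal state {state!r}")
    if rate_hz <= 0:
        raise StimulusError("reversing profile needs a positive rate")
    fps = geometry.frame_rate / rate_hz
    if abs(fps - round(fps)) > 1e-9 or round(fps) < 1:
        raise StimulusError(
            f"rate incompatible with frame grid: {geometry.frame_rate} Hz / "
            f"{rate_hz} Hz = {fps} frames per polarity state"
        )
    fps = int(round(fps))
    blocks = (np.arange(n_frames) // fps) % 2
    signs = np.where(blocks == 0, 1, -1).astype(np.int8)
    return TemporalProfile("reversing", rate_hz, initial_polarity, n_frames, signs)


# ----------------------------------------------------------------------
# trial composition
# ----------------------------------------------------------------------

@dataclass
class FrameSequence:
    """A rendered trial: unique polarity-state frames plus per-frame indices.

    Only the distinct (target polarity, background sign) images are stored;
    ``frames`` materializes the dense (n_frames, H, W) luminance stack on
    demand and ``frame(i)`` returns a single frame without copying the rest.
    """

    geometry: DisplayGeometry
    condition: Condition
    size_deg: float
    truth_orientation_deg: int
    duration_s: float
    n_frames: int
    unique_frames: dict[tuple[str, int], np.ndarray]
    frame_keys: list[tuple[str, int]]
    target_polarity_timeline: list[str]
    background_polarity_timeline: np.ndarray  # +1/-1, NaN for uniform bg
    target_mask: np.ndarray
    target_slices: tuple[slice, slice]

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.unique_frames.values())).shape

    def frame(self, i: int) -> np.ndarray:
        return self.unique_frames[self.frame_keys[i]]

    @property
    def frames(self) -> np.ndarray:
        return np.stack([self.frame(i) for i in range(self.n_frames)])

    def frame_weights(self) -> dict[tuple[str, int], int]:
        """Number of frames shown for each unique polarity-state image."""
        weights: dict[tuple[str, int], int] = {}
        for k in self.frame_keys:
            weights[k] = weights.get(k, 0) + 1
        return weights

    def target_patch(self, image: np.ndarray) -> np.ndarray:
        return image[self.target_slices]


TRIAL_DURATION_S = 0.530


def _target_profile(
    condition: Condition,
    n_frames: int,
    geometry: DisplayGeometry,
    initial_polarity: str,
) -> TemporalProfile:
    if condition.target_state == "B":
        return make_temporal_profile("static_black", 0.0, n_frames, "black", geometry)
    if condition.target_state == "W":
        return make_temporal_profile("static_white", 0.0, n_frames, "white", geometry)
    return make_temporal_profile(
        "reversing", condition.target_rate_hz, n_frames, initial_polarity, geometry
    )


def compose_trial(
    condition: Condition,
    size_deg: float,
    orientation_deg: int,
    geometry: DisplayGeometry,
    seed,
    duration_s: float = TRIAL_DURATION_S,
    noise_spec: NoiseSpec | None = None,
) -> FrameSequence:
    """Compose one trial movie for a condition at a given letter size.

    The background (uniform gray, or a freshly seeded noise texture) is
    centered on the target; the target is overlaid opaquely.  Reversing
    elements follow square-wave timelines on the frame grid; the initial
    target polarity of a reversing target is drawn at random.  ``seed`` may
    be an int, a SeedSequence, or a Generator.
    """
    rng = np.random.default_rng(seed)
    if orientation_deg not in ORIENTATIONS_DEG:
        raise StimulusError(f"invalid orientation {orientation_deg}")
    if noise_spec is None:
        noise_spec = NoiseSpec()

    n_frames = geometry.seconds_to_frames(duration_s)

    # background carrier
    if condition.background_has_noise:
        trial_noise = replace(noise_spec, seed=int(rng.integers(0, 2**31 - 1)))
        background = make_noise_background(trial_noise, geometry)
    else:
        m = geometry.degrees_to_pixels(noise_spec.extent_deg)
        background = np.full((m, m), geometry.mean_luminance)

    # timelines
    initial_target_pol = rng.choice(["black", "white"])
    tprofile = _target_profile(condition, n_frames, geometry, initial_target_pol)
    target_polarities = tprofile.polarities()
    if condition.background_reversing:
        bprofile = make_temporal_profile(
            "reversing", condition.background_rate_hz, n_frames, "black", geometry
        )
        bg_signs = bprofile.signs.astype(float)
    elif condition.background_has_noise:
        bg_signs = np.ones(n_frames)
    else:
        bg_signs = np.full(n_frames, np.nan)

    # target patch placement (centered)
    d_px = geometry.degrees_to_pixels(size_deg)
    m = background.shape[0]
    if d_px > m:
        raise StimulusError("target larger than background extent")
    r0 = (m - d_px) // 2
    sl = (slice(r0, r0 + d_px), slice(r0, r0 + d_px))

    _, mask = render_optotype(
        OptotypeSpec(size_deg, orientation_deg, "black"), geometry
    )

    unique: dict[tuple[str, int], np.ndarray] = {}
    frame_keys: list[tuple[str, int]] = []
    flipped = flip_contrast(background, geometry)
    for i in range(n_frames):
        bsign = 1 if not np.isfinite(bg_signs[i]) else int(bg_signs[i])
        key = (target_polarities[i], bsign)
        frame_keys.append(key)
        if key not in unique:
            frame = np.array(background if bsign > 0 else flipped, copy=True)
            value = (
                geometry.luminance_min
                if target_polarities[i] == "black"
                else geometry.luminance_max
            )
            patch = frame[sl]
            patch[mask] = value
            unique[key] = frame

    return FrameSequence(
        geometry=geometry,
        condition=condition,
        size_deg=size_deg,
        truth_orientation_deg=orientation_deg,
        duration_s=duration_s,
        n_frames=n_frames,
        unique_frames=unique,
        frame_keys=frame_keys,
        target_polarity_timeline=target_polarities,
        background_polarity_timeline=bg_signs,
        target_mask=mask,
        target_slices=sl,
    )


def export_frames(seq: FrameSequence, path: str, fps: float | None = None) -> None:
    """Export a frame sequence as an animated GIF or a 16-bit PNG (first frame).

    Luminance maps linearly onto the code-value range.
    """
    import imageio.v3 as iio

    lo, hi = seq.geometry.luminance_min, seq.geometry.luminance_max
    stack = seq.frames
    scaled = (stack - lo) / (hi - lo)
    if path.endswith(".gif"):
        frames8 = (np.clip(scaled, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(path, frames8, duration=1000.0 / (fps or seq.geometry.frame_rate), loop=0)
    elif path.endswith(".png"):
        img16 = (np.clip(scaled[0], 0, 1) * 65535).astype(np.uint16)
        iio.imwrite(path, img16)
    else:
        raise ValueError("export path must end in .gif or .png")
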