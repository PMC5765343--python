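"""Synthetic high-speed video of a beating sperm flagellum.

Real recordings of hyperactivated Drosophila sperm were acquired with a
high-speed monochrome camera (300 frames/s, 228 x 320 pixels, 1000
frames, 28 pixels per 10 um).  This module renders a minimal stand-in
with analytically known kinematics: a bright flagellum following a
traveling sinusoidal wave on a dark background, with a bright head and
optional additive Gaussian noise.  Because the midline is a pure sine,

    y(s, t) = A(s) * sin(2*pi*f*t - 2*pi*s/lambda + phi)

every motion estimator downstream has a closed-form target: the beat
frequency is ``f`` and the period-averaged lateral speed at a fixed
arc position is ``4*A*f``.

Geometry conventions: row-major frames, origin at the top-left pixel
centre, 0-based indices, row increasing downward.  The flagellum axis
starts at the head anchor and runs along ``orientation_deg`` measured
from the +column axis toward +row; positive lateral displacement points
along the axis normal ``(-cos(theta), sin(theta))`` in (row, col).
Frame ``k`` represents ``t = k / fps`` exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .video_io import FrameStack

__all__ = [
    "AcquisitionConfig",
    "FlagellumModel",
    "GroundTruth",
    "render_frame",
    "generate_video",
    "ground_truth_displacement",
    "default_measurement_points",
    "DEFAULT_ARC_FRACTIONS",
]

#: arc-length fractions of the five default measurement points
DEFAULT_ARC_FRACTIONS = (0.1, 0.3, 0.5, 0.7, 0.9)

# curve sampled at <= this spacing (px) along the axis for rendering
_SAMPLE_SPACING_PX = 0.25
# contributions are zero beyond this many PSF sigmas from the object
_SUPPORT_SIGMAS = 4.0


@dataclass(frozen=True)
class AcquisitionConfig:
    """Camera geometry and calibration of a recording.

    Defaults reproduce the original acquisition: 228 x 320 px frames at
    300 frames/s for 1000 frames, 28 pixels per 10 um.
    """

    height_px: int = 228
    width_px: int = 320
    fps: float = 300.0
    n_frames: int = 1000
    px_per_10um: float = 28.0

    def __post_init__(self) -> None:
        for name in ("height_px", "width_px", "n_frames"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_10um <= 0:
            raise ValueError("px_per_10um must be positive")

    @property
    def px_per_um(self) -> float:
        return self.px_per_10um / 10.0

    @property
    def pixels_per_frame(self) -> int:
        return self.height_px * self.width_px

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


@dataclass(frozen=True)
class FlagellumModel:
    """Parametric traveling-wave description of a beating flagellum.

    ``amplitude_taper`` linearly scales the local amplitude from
    ``amplitude_um`` at the head end to ``amplitude_um * amplitude_taper``
    at the tail tip (1.0 = uniform amplitude).
    """

    length_um: float = 40.0
    amplitude_um: float = 5.0
    beat_frequency_hz: float = 15.0
    wavelength_um: float = 25.0
    head_position_px: tuple[float, float] = (114.0, 80.0)
    orientation_deg: float = 0.0
    head_radius_px: float = 3.0
    psf_sigma_px: float = 1.5
    amplitude_taper: float = 1.0
    phase_deg: float = 0.0
    flagellum_intensity: float = 200.0
    background_level: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_um <= 0:
            raise ValueError("length_um must be positive")
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be >= 0")
        if self.beat_frequency_hz <= 0:
            raise ValueError("beat_frequency_hz must be positive")
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.head_radius_px < 0:
            raise ValueError("head_radius_px must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.amplitude_taper < 0:
            raise ValueError("amplitude_taper must be >= 0")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if not 0 <= self.flagellum_intensity <= 255:
            raise ValueError("flagellum_intensity must lie in [0, 255]")

    def local_amplitude_um(self, arc_fraction) -> np.ndarray | float:
        """Amplitude A(s) at arc-length fraction s in [0, 1]."""
        u = np.asarray(arc_fraction, dtype=float)
        return self.amplitude_um * (1.0 + (self.amplitude_taper - 1.0) * u)

    def displacement_um(self, arc_fraction, t) -> np.ndarray | float:
        """Lateral midline displacement (um) at arc fraction s, time t (s)."""
        u = np.asarray(arc_fraction, dtype=float)
        if np.any(u < 0) or np.any(u > 1):
            raise ValueError("arc_fraction must lie in [0, 1]")
        phase = 2.0 * math.pi * u * self.length_um / self.wavelength_um
        omega = 2.0 * math.pi * self.beat_frequency_hz
        phi0 = math.radians(self.phase_deg)
        return self.local_amplitude_um(u) * np.sin(omega * np.asarray(t, float) - phase + phi0)

    def _axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit tangent and normal of the centreline in (row, col)."""
        th = math.radians(self.orientation_deg)
        tangent = np.array([math.sin(th), math.cos(th)])
        normal = np.array([-math.cos(th), math.sin(th)])
        return tangent, normal

    def midline_px(self, arc_fraction, t, config: AcquisitionConfig) -> np.ndarray:
        """(row, col) pixel coordinates of the midline at arc fraction(s)."""
        u = np.atleast_1d(np.asarray(arc_fraction, dtype=float))
        s_px = u * self.length_um * config.px_per_um
        y_px = np.asarray(self.displacement_um(u, t)) * config.px_per_um
        tangent, normal = self._axes()
        head = np.asarray(self.head_position_px, dtype=float)
        return head[None, :] + s_px[:, None] * tangent[None, :] + y_px[:, None] * normal[None, :]


@dataclass(frozen=True)
class GroundTruth:
    """Analytic kinematics of a generated recording.

    Wraps the generating model so estimator tests can query the exact
    lateral displacement, local amplitude, and beat frequency.
    """

    model: FlagellumModel
    config: AcquisitionConfig

    @property
    def beat_frequency_hz(self) -> float:
        return self.model.beat_frequency_hz

    def amplitude_um(self, arc_fraction) -> np.ndarray | float:
        return self.model.local_amplitude_um(arc_fraction)

    def displacement_um(self, arc_fraction, t) -> np.ndarray | float:
        if np.any(np.asarray(t, float) < 0) or np.any(
            np.asarray(t, float) > self.config.duration_s
        ):
            raise ValueError("t outside the recording duration")
        return self.model.displacement_um(arc_fraction, t)

    def displacement_px(self, arc_fraction, t) -> np.ndarray | float:
        return np.asarray(self.displacement_um(arc_fraction, t)) * self.config.px_per_um

    def midline_px(self, arc_fraction, t) -> np.ndarray:
        return self.model.midline_px(arc_fraction, t, self.config)


def ground_truth_displacement(gt: GroundTruth, arc_fraction: float, t: float):
    """Lateral displacement (um) of the midline at ``arc_fraction`` and time ``t``."""
    return gt.displacement_um(arc_fraction, t)


def _check_nyquist(model: FlagellumModel, config: AcquisitionConfig) -> None:
    if model.beat_frequency_hz >= config.fps / 2.0:
        raise ValueError(
            f"beat_frequency_hz={model.beat_frequency_hz} violates the Nyquist limit "
            f"fps/2={config.fps / 2.0}"
        )


def render_frame(
    model: FlagellumModel, config: AcquisitionConfig, frame_index: int
) -> np.ndarray:
    """Render one 8-bit grayscale frame at ``t = frame_index / fps``.

    The flagellum midline is sampled as a dense polyline; each pixel's
    brightness falls off as a Gaussian of ``psf_sigma_px`` in its
    distance to the curve, so the intensity ridge lies exactly on the
    analytic midline.  The head is a filled disc with the same Gaussian
    roll-off beyond its radius.  Noise is added after rendering; the
    result is clipped to [0, 255] and quantized by rounding half up.
    """
    if not 0 <= frame_index < config.n_frames:
        raise ValueError(f"frame_index {frame_index} outside [0, {config.n_frames})")
    _check_nyquist(model, config)

    t = frame_index / config.fps
    length_px = model.length_um * config.px_per_um
    n_samples = max(2, int(math.ceil(length_px / _SAMPLE_SPACING_PX)) + 1)
    u = np.linspace(0.0, 1.0, n_samples)
    pts = model.midline_px(u, t, config)
    head = np.asarray(model.head_position_px, dtype=float)

    margin = _SUPPORT_SIGMAS * model.psf_sigma_px + model.head_radius_px + 1.0
    rmin = min(pts[:, 0].min(), head[0]) - margin
    rmax = max(pts[:, 0].max(), head[0]) + margin
    cmin = min(pts[:, 1].min(), head[1]) - margin
    cmax = max(pts[:, 1].max(), head[1]) + margin
    r0, r1 = int(math.floor(rmin)), int(math.ceil(rmax)) + 1
    c0, c1 = int(math.floor(cmin)), int(math.ceil(cmax)) + 1
    r0c, r1c = max(r0, 0), min(r1, config.height_px)
    c0c, c1c = max(c0, 0), min(c1, config.width_px)
    if r0c >= r1c or c0c >= c1c:
        raise ValueError(
            "flagellum lies entirely outside the frame: object spans rows "
            f"[{rmin:.1f}, {rmax:.1f}], cols [{cmin:.1f}, {cmax:.1f}] in a "
            f"{config.height_px} x {config.width_px} frame"
        )

    rr, cc = np.mgrid[r0c:r1c, c0c:c1c]
    grid = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, _ = cKDTree(pts).query(grid, workers=1)
    two_s2 = 2.0 * model.psf_sigma_px**2
    curve = model.flagellum_intensity * np.exp(-dist**2 / two_s2)
    d_head = np.maximum(np.linalg.norm(grid - head, axis=1) - model.head_radius_px, 0.0)
    head_int = model.flagellum_intensity * np.exp(-d_head**2 / two_s2)
    patch = np.maximum(curve, head_int).reshape(rr.shape)

    img = np.full((config.height_px, config.width_px), float(model.background_level))
    img[r0c:r1c, c0c:c1c] += patch
    if model.noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([model.seed, frame_index]))
        img += rng.normal(0.0, model.noise_sd, size=img.shape)
    return np.floor(np.clip(img, 0.0, 255.0) + 0.5).astype(np.uint8)


def generate_video(
    model: FlagellumModel, config: AcquisitionConfig | None = None
) -> tuple[FrameStack, GroundTruth]:
    """Render the full recording; deterministic given (model, config, seed)."""
    if config is None:
        config = AcquisitionConfig()
    _check_nyquist(model, config)
    frames = np.empty(
        (config.n_frames, config.height_px, config.width_px), dtype=np.uint8
    )
    for k in range(config.n_frames):
        frames[k] = render_frame(model, config, k)
    stack = FrameStack(frames=frames, fps=config.fps, px_per_10um=config.px_per_10um)
    return stack, GroundTruth(model=model, config=config)


def default_measurement_points(
    model: FlagellumModel,
    config: AcquisitionConfig | None = None,
    arc_fractions: tuple[float, ...] = DEFAULT_ARC_FRACTIONS,
):
    """Five measurement points for beat-frequency readout.

    Each point carries a window spanning laterally from the centreline
    to just above the wave crest of its arc position, so the flagellum
    is inside the window during exactly the upper half of each beat
    cycle.  The window-averaged intensity is then a near-50%-duty wave
    at the beat frequency with evenly spaced mean crossings, which keeps
    the zero-crossing estimate within one count quantum of the true
    frequency at every point.
    """
    from .motion_metrics import MeasurementPoint

    if config is None:
        config = AcquisitionConfig()
    tangent, normal = model._axes()
    head = np.asarray(model.head_position_px, dtype=float)
    margin = 3.0 * model.psf_sigma_px + 2.0
    points = []
    for u in arc_fractions:
        s_px = u * model.length_um * config.px_per_um
        a_px = float(model.local_amplitude_um(u)) * config.px_per_um
        half_span = (a_px + margin) / 2.0
        pos = head + s_px * tangent + half_span * normal
        points.append(
            MeasurementPoint(
                row=int(round(pos[0])),
                col=int(round(pos[1])),
                window_radius=max(1, int(round(half_span))),
            )
        )
    return points
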