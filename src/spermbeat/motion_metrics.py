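"""The three sperm-motion parameters measured from a frame stack.

* **beat frequency** (Hz): zero-crossing rate of a mean-centred pixel
  intensity trace at a measurement point, divided by two (a full beat
  cycle produces two sign changes).
* **beat speed** (um/s): mean absolute frame-to-frame displacement of
  the flagellum along a probe line perpendicular to its axis, tracked
  at subpixel resolution and converted with the pixel calibration
  (10 um per ``px_per_10um`` pixels).
* **intensity index** (%): whole-field motion statistic, the mean
  absolute lag-``d`` brightness difference over all m pixels and all
  n - d valid frame pairs, normalised by the brightness depth g:

      index = 1/(m(n-d)) * sum_{i=d+1..n} sum_{j=1..m} |p_ji - p_j,i-d| / g * 100

The frame lag ``d`` defaults to 1 (finest temporal resolution at 300
frames/s); it is a free parameter of the statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .video_io import BRIGHTNESS_DEPTH, FrameStack

__all__ = [
    "MeasurementPoint",
    "IntensitySeries",
    "IntensityIndexParams",
    "MotionParams",
    "extract_series",
    "beat_frequency",
    "kymograph",
    "beat_speed",
    "intensity_index",
    "motion_report",
]


@dataclass(frozen=True)
class MeasurementPoint:
    """A pixel location with a square averaging window of half-width
    ``window_radius`` (window side 2r+1)."""

    row: int
    col: int
    window_radius: int = 1

    def __post_init__(self) -> None:
        if self.window_radius < 0:
            raise ValueError("window_radius must be >= 0")


@dataclass(frozen=True)
class IntensitySeries:
    """Per-frame mean window intensity (gray levels) at one point."""

    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.values) / self.fps


@dataclass(frozen=True)
class IntensityIndexParams:
    """Frame lag d and brightness depth g of the intensity index."""

    d: int = 1
    g: int = BRIGHTNESS_DEPTH

    def __post_init__(self) -> None:
        if self.d < 1:
            raise ValueError("lag d must be >= 1")
        if self.g < 2:
            raise ValueError("brightness depth g must be >= 2")


@dataclass(frozen=True)
class MotionParams:
    beat_frequency_hz: float
    beat_speed_um_s: float
    intensity_index: float


def extract_series(stack: FrameStack, point: MeasurementPoint) -> IntensitySeries:
    """Mean intensity of the point's (2r+1)^2 window, one real value per frame."""
    r = point.window_radius
    r0, r1 = point.row - r, point.row + r
    c0, c1 = point.col - r, point.col + r
    if r0 < 0 or c0 < 0 or r1 > stack.height - 1 or c1 > stack.width - 1:
        raise ValueError(
            f"measurement window rows [{r0}, {r1}], cols [{c0}, {c1}] not fully "
            f"inside the {stack.height} x {stack.width} frame"
        )
    values = stack.frames[:, r0 : r1 + 1, c0 : c1 + 1].mean(axis=(1, 2))
    return IntensitySeries(values=values, fps=stack.fps)


def _count_sign_changes(centered: np.ndarray) -> int:
    """Sign changes between consecutive samples; zero samples inherit the
    previous sign so plateaus are not double-counted."""
    signs = np.sign(centered)
    crossings = 0
    prev = 0.0
    for s in signs:
        if s == 0:
            continue
        if prev != 0 and s != prev:
            crossings += 1
        prev = s
    return crossings


def beat_frequency(
    series: IntensitySeries,
    smoothing_window: int = 3,
    centering: str = "mean",
) -> float:
    """Zero-crossing beat frequency in Hz.

    The trace is smoothed by a centred moving average (suppressing 8-bit
    quantisation chatter), centred by subtracting its mean or median,
    and the sign changes of consecutive samples are counted; the beat
    frequency is crossings / (2 * duration).  A trace that is constant
    after centring returns 0 Hz.
    """
    if len(series.values) < 2:
        raise ValueError("series must contain at least 2 samples")
    if smoothing_window < 1 or smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be odd and >= 1")
    if centering not in ("mean", "median"):
        raise ValueError("centering must be 'mean' or 'median'")

    x = series.values
    if smoothing_window > 1:
        kernel = np.full(smoothing_window, 1.0 / smoothing_window)
        x = np.convolve(x, kernel, mode="valid")
    center = np.mean(x) if centering == "mean" else np.median(x)
    centered = x - center
    duration = len(x) / series.fps
    return _count_sign_changes(centered) / (2.0 * duration)


def kymograph(
    stack: FrameStack,
    point: MeasurementPoint,
    probe_length_px: int,
    probe_angle_deg: float,
) -> np.ndarray:
    """Intensity profiles along a fixed probe line, one row per frame.

    The probe is a segment of ``probe_length_px`` samples at 1 px
    spacing, centred on the point, oriented at ``probe_angle_deg``
    (measured from the +column axis toward +row); to track a flagellum
    the probe is set perpendicular to its axis.  Off-grid samples are
    bilinearly interpolated.
    """
    if probe_length_px < 1:
        raise ValueError("probe_length_px must be >= 1")
    offsets = np.arange(probe_length_px, dtype=float) - (probe_length_px - 1) / 2.0
    th = np.deg2rad(probe_angle_deg)
    rows = point.row + offsets * np.sin(th)
    cols = point.col + offsets * np.cos(th)
    if (
        rows.min() < 0
        or cols.min() < 0
        or rows.max() > stack.height - 1
        or cols.max() > stack.width - 1
    ):
        raise ValueError(
            f"probe exits the frame: rows [{rows.min():.1f}, {rows.max():.1f}], "
            f"cols [{cols.min():.1f}, {cols.max():.1f}]"
        )
    coords = np.stack([rows, cols])
    out = np.empty((stack.n_frames, probe_length_px))
    for k in range(stack.n_frames):
        out[k] = ndimage.map_coordinates(
            stack.frames[k].astype(float), coords, order=1, mode="nearest"
        )
    return out


def _subpixel_peak(profile: np.ndarray) -> float:
    """Peak position via a parabola through the argmax and its neighbours."""
    i = int(np.argmax(profile))
    if i == 0 or i == len(profile) - 1:
        return float(i)
    y0, y1, y2 = profile[i - 1], profile[i], profile[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * (y0 - y2) / denom


def beat_speed(
    kymo: np.ndarray,
    fps: float,
    px_per_10um: float,
    max_dropped_fraction: float = 0.5,
) -> float:
    """Mean lateral flagellum speed (um/s) from a kymograph.

    Per frame the flagellum position is the subpixel intensity peak of
    the probe profile.  Frames whose peak does not rise above the
    background (kymograph median) plus three robust SDs are dropped as
    untracked; if more than half the frames drop, the input is deemed
    untrackable.  Speed is the mean absolute per-frame displacement
    times fps, converted to um with 10 / px_per_10um.
    """
    kymo = np.asarray(kymo, dtype=float)
    if kymo.ndim != 2 or kymo.shape[0] < 2:
        raise ValueError("kymograph must be 2-D with at least 2 frames")
    background = float(np.median(kymo))
    sigma = 1.4826 * float(np.median(np.abs(kymo - background)))
    threshold = background + 3.0 * sigma
    peaks = kymo.max(axis=1)
    kept = np.flatnonzero(peaks > threshold)
    if len(kept) < (1.0 - max_dropped_fraction) * kymo.shape[0] or len(kept) < 2:
        raise ValueError(
            f"untrackable input: only {len(kept)}/{kymo.shape[0]} frames have a "
            "peak above background + 3 sigma"
        )
    positions = np.array([_subpixel_peak(kymo[k]) for k in kept])
    # displacement per frame interval, tolerant of dropped frames in between
    dpos = np.abs(np.diff(positions)) / np.diff(kept)
    um_per_px = 10.0 / px_per_10um
    return float(dpos.mean() * fps * um_per_px)


def intensity_index(
    stack: FrameStack, params: IntensityIndexParams | None = None
) -> float:
    """Whole-field intensity index (%): mean |lag-d difference| / g * 100."""
    if params is None:
        params = IntensityIndexParams()
    n = stack.n_frames
    d = params.d
    if d >= n:
        raise ValueError(f"lag d={d} requires at least d+1={d + 1} frames, got {n}")
    a = stack.frames[d:].astype(np.int16)
    b = stack.frames[:-d].astype(np.int16)
    return float(np.abs(a - b).mean() / params.g * 100.0)


def motion_report(
    stack: FrameStack,
    points: list[MeasurementPoint],
    params: IntensityIndexParams | None = None,
    smoothing_window: int = 3,
    centering: str = "mean",
    probe_length_px: int | None = None,
    probe_angle_deg: float = 90.0,
) -> pd.DataFrame:
    """Per-point beat frequency and speed plus a summary row.

    Beat speed is measured on a kymograph at each point; the probe is
    perpendicular to the flagellum axis, whose direction the caller
    states via ``probe_angle_deg``.  With ``probe_length_px=None`` the
    speed column is left out (frequency-only report).  The summary row
    carries the across-point mean, the standard error (sample SD /
    sqrt(N), the Mean +/- SE convention), and the whole-stack intensity
    index.
    """
    if not points:
        raise ValueError("at least one measurement point is required")
    rows = []
    for idx, pt in enumerate(points):
        freq = beat_frequency(
            extract_series(stack, pt), smoothing_window=smoothing_window, centering=centering
        )
        if probe_length_px is not None:
            kymo = kymograph(stack, pt, probe_length_px, probe_angle_deg)
            speed = beat_speed(kymo, stack.fps, stack.px_per_10um)
        else:
            speed = np.nan
        rows.append(
            {
                "point_id": f"p{idx}",
                "beat_frequency_hz": freq,
                "beat_speed_um_s": speed,
            }
        )
    df = pd.DataFrame(rows)

    def _se(x: pd.Series) -> float:
        x = x.dropna()
        if len(x) < 2:
            return np.nan
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    summary = {
        "point_id": "summary",
        "beat_frequency_hz": df["beat_frequency_hz"].mean(),
        "beat_speed_um_s": df["beat_speed_um_s"].mean(),
        "beat_frequency_se": _se(df["beat_frequency_hz"]),
        "beat_speed_se": _se(df["beat_speed_um_s"]),
        "intensity_index": intensity_index(stack, params),
    }
    df = pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
    return df
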