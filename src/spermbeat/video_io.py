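"""Frame-stack I/O and acquisition calibration.

A recording is an ordered stack of 8-bit grayscale frames plus two
calibration numbers: the acquisition rate (frames per second) and the
spatial scale expressed, as on the microscope used for the original
recordings, in pixels per 10 micrometres.  Calibration never travels in
image headers; it lives in a plain-text sidecar config (see
:func:`read_calibration` / :func:`write_calibration`) or is passed
explicitly, because TIFF resolution tags are unreliable across writers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "FrameStack",
    "read_stack",
    "write_stack",
    "read_calibration",
    "write_calibration",
]

#: gray-level depth of the supported videos (8 bit)
BRIGHTNESS_DEPTH = 256

DEFAULT_FPS = 300.0
DEFAULT_PX_PER_10UM = 28.0

_FRAME_EXTENSIONS = (".png", ".tif", ".tiff", ".bmp")


@dataclass
class FrameStack:
    """Ordered 8-bit grayscale frames with acquisition calibration.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width), dtype uint8
        Pixel data, frame-major; row index increases downward.
    fps : float
        Acquisition rate in frames per second.
    px_per_10um : float
        Spatial calibration: number of pixels spanning 10 um.
    """

    frames: np.ndarray
    fps: float = DEFAULT_FPS
    px_per_10um: float = DEFAULT_PX_PER_10UM

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (n, height, width) array, got ndim={self.frames.ndim}"
            )
        if self.frames.dtype != np.uint8:
            raise ValueError(f"frames must be uint8, got {self.frames.dtype}")
        if self.frames.shape[0] < 1:
            raise ValueError("empty stack")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.px_per_10um <= 0:
            raise ValueError("px_per_10um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def pixels_per_frame(self) -> int:
        """Number of pixels analyzed per frame (m in the intensity index)."""
        return self.height * self.width

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    @property
    def um_per_px(self) -> float:
        """Micron size of one pixel: 10 / px_per_10um."""
        return 10.0 / self.px_per_10um


def _load_single(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def _check_frame(arr: np.ndarray, origin: str, allow_rescale: bool) -> np.ndarray:
    if arr.ndim == 3:
        raise ValueError(f"{origin}: RGB/multichannel frames are not supported")
    if arr.ndim != 2:
        raise ValueError(f"{origin}: expected a 2-D grayscale frame, got ndim={arr.ndim}")
    if arr.dtype == np.uint8:
        return arr
    if arr.dtype == np.uint16:
        if not allow_rescale:
            raise ValueError(
                f"{origin}: 16-bit input; pass allow_rescale=True to scale to 8 bit"
            )
        return np.floor(arr / 257.0 + 0.5).astype(np.uint8)
    raise ValueError(f"{origin}: unsupported dtype {arr.dtype}")


def read_stack(
    path: str | os.PathLike,
    fps: float = DEFAULT_FPS,
    px_per_10um: float = DEFAULT_PX_PER_10UM,
    allow_rescale: bool = False,
) -> FrameStack:
    """Load a multi-page TIFF or a directory of single-frame images.

    Directory frames are taken in lexicographic filename order, so they
    must be zero-padded.  RGB input is rejected; 16-bit input is rejected
    unless ``allow_rescale`` is set, in which case it is scaled to 8 bit.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTENSIONS
        )
        if not files:
            raise ValueError(f"{path}: no frame files found")
        frames = []
        shape = None
        for p in files:
            arr = _check_frame(_load_single(p), str(p), allow_rescale)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"{p}: frame shape {arr.shape} differs from first frame {shape}"
                )
            frames.append(arr)
        data = np.stack(frames)
    else:
        raw = tifffile.imread(path)
        if raw.ndim == 2:
            raw = raw[None]
        if raw.ndim != 3:
            raise ValueError(f"{path}: expected a grayscale stack, got shape {raw.shape}")
        data = np.stack(
            [_check_frame(fr, f"{path}[frame {i}]", allow_rescale) for i, fr in enumerate(raw)]
        )
    return FrameStack(frames=data, fps=fps, px_per_10um=px_per_10um)


def write_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a stack as an uncompressed multi-page 8-bit grayscale TIFF."""
    tifffile.imwrite(Path(path), stack.frames, photometric="minisblack")


def read_calibration(path: str | os.PathLike) -> dict:
    """Read the sidecar calibration config (keys fps, px_per_10um, bit_depth)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {
        "fps": float(cfg.get("fps", DEFAULT_FPS)),
        "px_per_10um": float(cfg.get("px_per_10um", DEFAULT_PX_PER_10UM)),
        "bit_depth": int(cfg.get("bit_depth", 8)),
    }
    if out["fps"] <= 0 or out["px_per_10um"] <= 0:
        raise ValueError(f"{path}: calibration values must be positive")
    return out


def write_calibration(
    path: str | os.PathLike,
    fps: float = DEFAULT_FPS,
    px_per_10um: float = DEFAULT_PX_PER_10UM,
    bit_depth: int = 8,
) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"fps": float(fps), "px_per_10um": float(px_per_10um), "bit_depth": int(bit_depth)},
            fh,
            default_flow_style=False,
        )
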