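"""Loading, saving and calibrating video frame stacks.

A video is held in memory as a :class:`FrameStack`: a ``(T, H, W)`` array of
8-bit intensities plus the acquisition rate (frames per second) and the
spatial calibration (cm per pixel).  Pixel coordinates are ``(x=column,
y=row)`` with the origin at the top-left corner and y increasing downward;
centroids are real-valued in pixel units.  All downstream geometry uses the
same frame.

Multi-page TIFF is the canonical interchange format: stacks written by
:func:`save_stack` embed fps and pixel size in the image description, so a
round trip preserves the full calibration.  AVI files are read through
imageio when an ffmpeg-capable plugin is available.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError, FormatError

DEFAULT_FPS = 25.0  # common acquisition rate for behavioral video


@dataclass(frozen=True)
class FrameStack:
    """A calibrated image sequence.

    Parameters
    ----------
    frames:
        ``(T, H, W)`` uint8 array, T >= 2.
    fps:
        Acquisition rate in frames per second (> 0).  The inter-frame
        interval used by speed computations is ``1 / fps``.
    pixel_size:
        Spatial calibration in cm per pixel (> 0).
    origin:
        Coordinate convention tag; always ``"upper-left"`` here.
    """

    frames: np.ndarray
    fps: float
    pixel_size: float = 1.0
    origin: str = "upper-left"

    def __post_init__(self):
        f = np.asarray(self.frames)
        if f.ndim != 3 or f.shape[0] < 2:
            raise ValueError("frames must be (T, H, W) with T >= 2")
        if f.dtype != np.uint8:
            if f.min() < 0 or f.max() > 255:
                raise ValueError("intensities must lie within [0, 255]")
            f = np.round(f).astype(np.uint8)
        object.__setattr__(self, "frames", f)
        if not self.fps > 0:
            raise ValueError("fps must be > 0")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    @property
    def dt(self) -> float:
        """Inter-frame interval in seconds."""
        return 1.0 / self.fps

    @property
    def duration_s(self) -> float:
        """Elapsed time spanned by the stack, (T - 1) / fps."""
        return (self.n_frames - 1) / self.fps


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing color axis by unweighted channel averaging."""
    if arr.ndim == 4 or (arr.ndim == 3 and arr.shape[-1] in (3, 4)):
        arr = arr[..., :3].mean(axis=-1)
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def _apply_crop(frames: np.ndarray, crop: tuple[int, int, int, int]) -> np.ndarray:
    x, y, w, h = crop
    H, W = frames.shape[1:3]
    if x < 0 or y < 0 or w <= 0 or h <= 0 or x + w > W or y + h > H:
        raise ValueError(f"crop rectangle {crop} outside frame bounds {(W, H)}")
    return frames[:, y : y + h, x : x + w]


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None, float | None]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        fps = pixel_size = None
        desc = tif.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                fps = meta.get("fps")
                pixel_size = meta.get("pixel_size")
            except (ValueError, AttributeError):
                pass
        if fps is None and tif.imagej_metadata:
            fps = tif.imagej_metadata.get("fps")
    if arr.ndim == 2:
        arr = arr[None]
    return arr, fps, pixel_size


def _read_imageio(path: Path) -> tuple[np.ndarray, float | None]:
    try:
        import imageio.v3 as iio

        arr = iio.imread(path)
        meta = iio.immeta(path)
        fps = meta.get("fps")
    except Exception as exc:  # pragma: no cover - depends on runtime plugins
        raise FormatError(f"cannot decode '{path}': {exc}") from exc
    return np.asarray(arr), fps


def load_stack(
    path,
    fps_override: float | None = None,
    crop: tuple[int, int, int, int] | None = None,
    pixel_size: float | None = None,
    accept_default_fps: bool = False,
) -> FrameStack:
    """Load an AVI or multi-page TIFF into a :class:`FrameStack`.

    Parameters
    ----------
    path:
        Input video/stack file.
    fps_override:
        Use this frame rate instead of container metadata.
    crop:
        Optional ``(x, y, width, height)`` rectangle applied to every frame;
        output pixel (0, 0) equals source pixel ``(x, y)``.
    pixel_size:
        Optional cm-per-pixel calibration to attach (default 1.0; see
        :func:`calibrate`).
    accept_default_fps:
        When no frame rate is found in the container and no override is
        given, fall back to 25 fps only if this flag is set explicitly; a
        silent default would hide acquisition errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta_px = None
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            arr, fps_meta, meta_px = _read_tiff(path)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"cannot decode '{path}' as TIFF: {exc}") from exc
    else:
        arr, fps_meta = _read_imageio(path)

    fps = fps_override if fps_override is not None else fps_meta
    if fps is None:
        if accept_default_fps:
            fps = DEFAULT_FPS
        else:
            raise ConfigError(
                "frame rate not present in file metadata; pass fps_override "
                "or accept_default_fps=True for the 25 fps default"
            )
    frames = _to_gray(arr)
    if frames.ndim == 2:
        frames = frames[None]
    if crop is not None:
        frames = _apply_crop(frames, crop)
    px = pixel_size if pixel_size is not None else (meta_px or 1.0)
    return FrameStack(frames=frames, fps=float(fps), pixel_size=float(px))


def save_stack(stack: FrameStack, path) -> Path:
    """Write a stack as multi-page TIFF with fps/pixel-size metadata."""
    import tifffile

    path = Path(path)
    meta = json.dumps({"fps": stack.fps, "pixel_size": stack.pixel_size})
    tifffile.imwrite(path, stack.frames, description=meta)
    return path


def crop_stack(stack: FrameStack, crop: tuple[int, int, int, int]) -> FrameStack:
    """Crop every frame with an ``(x, y, width, height)`` rectangle."""
    return replace(stack, frames=_apply_crop(stack.frames, crop))


def calibrate(stack: FrameStack, known_length_cm: float, measured_length_px: float) -> FrameStack:
    """Attach the cm-per-pixel scale from a known distance in the arena.

    ``pixel_size = known_length_cm / measured_length_px``, e.g. a 38 cm
    arena wall spanning 380 px gives 0.1 cm/px.
    """
    if not (known_length_cm > 0 and measured_length_px > 0):
        raise ValueError("calibration lengths must be > 0")
    return replace(stack, pixel_size=known_length_cm / measured_length_px)
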