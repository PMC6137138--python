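"""Optional Gaussian smoothing, static background model, difference stack.

The segmentation pipeline works on a *difference stack*: the per-frame
absolute deviation from a static background image estimated from the whole
video.  Taking the absolute difference makes a dark animal on a light floor
and a light animal on a dark floor look identical to the detector, so one
code path serves both.

The blur radius follows the convention of common image-analysis toolkits:
the radius at which the Gaussian has decayed to ``e^(-1/2)`` of its peak,
i.e. the radius equals the standard deviation sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage as ndi

from .video_io import FrameStack


@dataclass(frozen=True)
class BackgroundModel:
    """Static per-pixel background estimate.

    ``image`` is a float H x W array; ``method`` records whether it is the
    per-pixel mean over all frames (the default: an average projection of
    the stack) or the per-pixel median, which is more robust when the
    animal rests in one spot for a large share of the video.
    """

    image: np.ndarray
    method: str

    def __post_init__(self):
        if self.method not in ("mean", "median"):
            raise ValueError("method must be 'mean' or 'median'")


def blur_image(image: np.ndarray, radius_px: float) -> np.ndarray:
    """Isotropic Gaussian blur of a single image, returned as float.

    ``radius_px`` is the distance at which the kernel falls to e^(-1/2) of
    its central value, i.e. sigma.  Reflect padding avoids dark borders
    that would bias the intensity histogram.  Radius 0 is the identity.
    """
    if radius_px < 0:
        raise ValueError("blur radius must be >= 0")
    img = np.asarray(image, dtype=float)
    if radius_px == 0:
        return img.copy()
    return ndi.gaussian_filter(img, sigma=radius_px, mode="reflect")


def gaussian_blur(stack: FrameStack, radius_px: float) -> FrameStack:
    """Blur every frame of a stack (see :func:`blur_image`)."""
    if radius_px < 0:
        raise ValueError("blur radius must be >= 0")
    if radius_px == 0:
        return stack
    out = np.empty_like(stack.frames)
    for i, frame in enumerate(stack.frames):
        out[i] = np.clip(np.round(blur_image(frame, radius_px)), 0, 255).astype(np.uint8)
    return replace(stack, frames=out)


def compute_background(stack: FrameStack, method: str = "mean") -> BackgroundModel:
    """Estimate the static background over all frames of the stack."""
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames for a background model")
    if method == "mean":
        img = np.mean(stack.frames, axis=0, dtype=np.float64)
    elif method == "median":
        img = np.median(stack.frames, axis=0).astype(np.float64)
    else:
        raise ValueError("method must be 'mean' or 'median'")
    return BackgroundModel(image=img, method=method)


def difference_stack(stack: FrameStack, bg: BackgroundModel) -> FrameStack:
    """Per-frame |frame - background|, clipped into [0, 255].

    The absolute value makes the output invariant under swapping a bright
    animal on a dark floor for an equally contrasting dark animal.
    """
    if bg.image.shape != stack.shape:
        raise ValueError(
            f"background shape {bg.image.shape} does not match frames {stack.shape}"
        )
    out = np.empty_like(stack.frames)
    for i in range(stack.n_frames):  # frame-wise to bound peak memory
        d = np.abs(stack.frames[i].astype(np.float64) - bg.image)
        out[i] = np.clip(np.round(d), 0, 255).astype(np.uint8)
    return replace(stack, frames=out)
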