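"""Per-frame animal segmentation on the difference stack.

The detector binarizes each difference frame at a threshold found by the
classic "Minimum" bimodal-histogram method (Prewitt & Mendelsohn): the
256-bin intensity histogram is repeatedly smoothed with a 3-bin moving mean
until exactly two local maxima remain, and the threshold is the valley
between them.  By default one threshold is computed from the pooled
histogram of the whole difference stack, which is stabler than per-frame
thresholds; a per-frame mode is available.

Thresholded pixels are grouped into 8-connected components, components
below a minimum area are discarded, and the surviving blob is smoothed with
one expansion/erosion (morphological closing) cycle before the centroid and
perimeter are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import ConvergenceError
from .video_io import FrameStack

_S8 = np.ones((3, 3), bool)  # 8-connectivity / 3x3 structuring element


@dataclass(frozen=True)
class DetectionConfig:
    """Segmentation preferences.

    min_area_px2:
        Components smaller than this are noise, not animal.  The default of
        50 px^2 is a placeholder that must be set per setup (it depends on
        animal size, camera height and pixel calibration).
    threshold_override:
        Manual threshold in [0, 255]; skips the automatic method entirely
        when set, and serves as fallback if the histogram never becomes
        bimodal.
    max_histogram_smoothing_iters:
        Iteration cap for the histogram smoothing loop.
    per_frame_threshold:
        Compute a separate threshold per frame instead of one pooled
        stack-level threshold.
    """

    min_area_px2: int = 50
    threshold_override: int | None = None
    max_histogram_smoothing_iters: int = 10000
    per_frame_threshold: bool = False

    def __post_init__(self):
        if self.min_area_px2 < 1:
            raise ValueError("min_area_px2 must be >= 1")
        if self.threshold_override is not None and not (
            0 <= self.threshold_override <= 255
        ):
            raise ValueError("threshold_override must lie in [0, 255]")


@dataclass
class BlobDetection:
    """One segmented animal candidate in one frame.

    ``centroid`` is the mean (x, y) of the mask pixels; ``perimeter_points``
    are the mask pixels 8-adjacent to background (or on the image border),
    ordered by polar angle around the centroid.
    """

    frame_index: int
    mask: np.ndarray | None
    area_px2: int
    centroid: tuple[float, float]
    perimeter_points: np.ndarray
    detected: bool = True
    extras: dict = field(default_factory=dict)

    def drop_mask(self) -> None:
        """Release the full-frame mask once perimeter/centroid are extracted."""
        self.mask = None


def _count_local_maxima(h: np.ndarray) -> int:
    pad = np.concatenate(([-np.inf], h, [-np.inf]))
    return int(np.sum((pad[1:-1] > pad[:-2]) & (pad[1:-1] > pad[2:])))


def _peak_indices(h: np.ndarray) -> np.ndarray:
    pad = np.concatenate(([-np.inf], h, [-np.inf]))
    return np.nonzero((pad[1:-1] > pad[:-2]) & (pad[1:-1] > pad[2:]))[0]


def minimum_auto_threshold(histogram, max_iters: int = 10000) -> int:
    """Bimodal "Minimum" threshold of a 256-bin intensity histogram.

    Smooth the histogram with a 3-bin moving mean until it has exactly two
    local maxima, then return the bin index of the minimum between them
    (first bin of the valley on ties).

    Raises
    ------
    ConvergenceError
        If the histogram still has more than two maxima after ``max_iters``
        smoothing passes, or fewer than two from the start (unimodal data
        has no valley).
    """
    h = np.asarray(histogram, dtype=np.float64)
    if h.ndim != 1 or len(h) != 256:
        raise ValueError("histogram must have 256 bins")
    if np.sum(h > 0) < 2:
        raise ConvergenceError("histogram has fewer than 2 nonzero bins")
    iters = 0
    while _count_local_maxima(h) != 2:
        if _count_local_maxima(h) < 2 and iters > 0:
            # smoothing can only merge peaks; once below 2 it will never be 2
            raise ConvergenceError("histogram became unimodal before bimodal")
        if iters >= max_iters:
            raise ConvergenceError(
                f"histogram not bimodal after {max_iters} smoothing iterations"
            )
        # 3-bin moving mean; edge bins replicate their single neighbor
        pad = np.pad(h, 1, mode="edge")
        h = (pad[:-2] + pad[1:-1] + pad[2:]) / 3.0
        iters += 1
    p1, p2 = _peak_indices(h)
    valley = h[p1 + 1 : p2]
    if len(valley) == 0:
        raise ConvergenceError("adjacent peaks leave no valley")
    return int(p1 + 1 + np.argmin(valley))


def stack_histogram(diff: FrameStack) -> np.ndarray:
    """Pooled 256-bin histogram over every pixel of every frame."""
    return np.bincount(diff.frames.ravel(), minlength=256)


def stack_threshold(diff: FrameStack, cfg: DetectionConfig) -> int:
    """Threshold for the whole difference stack, honoring the override."""
    if cfg.threshold_override is not None:
        return cfg.threshold_override
    return minimum_auto_threshold(
        stack_histogram(diff), cfg.max_histogram_smoothing_iters
    )


def mask_perimeter(mask: np.ndarray, origin: tuple[int, int] = (0, 0)) -> np.ndarray:
    """(N, 2) array of (x, y) mask pixels 8-adjacent to background or the
    image border, ordered by polar angle around the mask centroid.

    ``origin`` offsets the returned coordinates (for masks held as patches
    of a larger frame).
    """
    ys, xs = np.nonzero(mask)
    cx, cy = xs.mean(), ys.mean()
    interior = ndi.binary_erosion(mask, structure=_S8, border_value=0)
    by, bx = np.nonzero(mask & ~interior)
    ang = np.arctan2(by - cy, bx - cx)
    order = np.argsort(ang, kind="stable")
    return np.column_stack(
        [bx[order] + origin[0], by[order] + origin[1]]
    ).astype(np.int64)


def _make_blob(frame_index: int, mask: np.ndarray) -> BlobDetection:
    area = int(mask.sum())
    ys, xs = np.nonzero(mask)
    centroid = (float(xs.mean()), float(ys.mean()))
    perimeter = mask_perimeter(mask)
    return BlobDetection(
        frame_index=frame_index,
        mask=mask,
        area_px2=area,
        centroid=centroid,
        perimeter_points=perimeter,
    )


def segment_frame(
    diff_frame: np.ndarray, threshold: int, cfg: DetectionConfig, frame_index: int = 0
) -> list[BlobDetection]:
    """Binarize one difference frame and return area-filtered components.

    Pixels strictly above ``threshold`` are foreground; 8-connected
    components below ``cfg.min_area_px2`` are dropped.  An empty list is a
    valid result (no animal visible).
    """
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    fg = np.asarray(diff_frame) > threshold
    labels, n = ndi.label(fg, structure=_S8)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.nonzero(areas >= cfg.min_area_px2)[0] + 1
    return [_make_blob(frame_index, labels == lab) for lab in keep]


def smooth_roi(blob: BlobDetection) -> BlobDetection:
    """One expansion/erosion cycle (3x3 closing) to remove rough edges.

    The erosion treats pixels beyond the image border as foreground so the
    cycle is extensive everywhere: the smoothed mask contains the original.
    """
    if blob.mask is None or blob.area_px2 == 0:
        raise ValueError("cannot smooth an empty blob")
    dilated = ndi.binary_dilation(blob.mask, structure=_S8)
    closed = ndi.binary_erosion(dilated, structure=_S8, border_value=1)
    return _make_blob(blob.frame_index, closed)


def select_animal(
    candidates: list[BlobDetection], previous: tuple[float, float] | None = None
) -> BlobDetection | None:
    """Pick the animal among candidate blobs.

    Nearest centroid to the previous position when one is known, else the
    largest area.  Ties go to the larger area, then earlier scan order.
    """
    if not candidates:
        return None
    if previous is not None:
        px, py = previous

        def key(item):
            idx, b = item
            d2 = (b.centroid[0] - px) ** 2 + (b.centroid[1] - py) ** 2
            return (d2, -b.area_px2, idx)

    else:

        def key(item):
            idx, b = item
            return (-b.area_px2, idx)

    return min(enumerate(candidates), key=key)[1]


def detect_stack(
    diff: FrameStack, cfg: DetectionConfig, keep_masks: bool = False
) -> tuple[list[BlobDetection | None], int]:
    """Run threshold -> segment -> smooth -> select over a difference stack.

    Returns the per-frame selected blob (None on detection dropouts) and
    the threshold used.  Masks are dropped frame-by-frame unless
    ``keep_masks`` (needed e.g. for head-dip overlap measurement).
    """
    thr = None if cfg.per_frame_threshold else stack_threshold(diff, cfg)
    out: list[BlobDetection | None] = []
    previous = None
    for i, frame in enumerate(diff.frames):
        t = thr
        if t is None:
            try:
                t = minimum_auto_threshold(
                    np.bincount(frame.ravel(), minlength=256),
                    cfg.max_histogram_smoothing_iters,
                )
            except ConvergenceError:
                if cfg.threshold_override is None:
                    out.append(None)
                    continue
                t = cfg.threshold_override
        cands = segment_frame(frame, t, cfg, frame_index=i)
        chosen = select_animal(cands, previous)
        if chosen is not None:
            chosen = smooth_roi(chosen)
            previous = chosen.centroid
            if not keep_masks:
                chosen.drop_mask()
        out.append(chosen)
    used = thr if thr is not None else -1
    return out, int(used)
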