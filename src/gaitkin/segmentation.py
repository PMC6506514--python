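"""Frame segmentation: from a raw grayscale frame to the single blob assumed
to be the fish.

The stage order mirrors a silhouette-imaging pipeline for a fish in a flow
tunnel: intensity normalization (percentile stretch), Gaussian smoothing,
motion-based clipping of the region of interest, Otsu binarization, connected
component (blob) extraction, and rule-based selection of the fish blob by
size and shape.

Conventions fixed package-wide:

* frames are 2-D numpy arrays indexed ``[row, col]`` with intensities in
  [0, 255]; points are ``(x, y)`` with ``x = col``, ``y = row``, origin at the
  top-left, y increasing downward;
* the fish is darker than the background (``dark_fish`` polarity) unless
  configured otherwise;
* blob and skeleton connectivity is 8-connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure


class DegenerateHistogramError(ValueError):
    """Raised when Otsu thresholding is asked to split a constant region."""


@dataclass(frozen=True)
class Roi:
    """Axis-aligned region of interest, half-open: [x0, x0+w) x [y0, y0+h)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.x0 < 0 or self.y0 < 0 or self.width <= 0 or self.height <= 0:
            raise ValueError(f"invalid ROI {self}")

    @property
    def area(self) -> int:
        return self.width * self.height

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height),
                slice(self.x0, self.x0 + self.width))

    def contains(self, other: "Roi") -> bool:
        return (self.x0 <= other.x0 and self.y0 <= other.y0
                and other.x0 + other.width <= self.x0 + self.width
                and other.y0 + other.height <= self.y0 + self.height)

    def intersect(self, other: "Roi") -> "Roi":
        x0 = max(self.x0, other.x0)
        y0 = max(self.y0, other.y0)
        x1 = min(self.x0 + self.width, other.x0 + other.width)
        y1 = min(self.y0 + self.height, other.y0 + other.height)
        if x1 <= x0 or y1 <= y0:
            raise ValueError("empty ROI intersection")
        return Roi(x0, y0, x1 - x0, y1 - y0)

    @staticmethod
    def full(frame_shape: tuple[int, int]) -> "Roi":
        h, w = frame_shape[:2]
        return Roi(0, 0, w, h)


@dataclass
class Blob:
    """A single 8-connected foreground component with shape descriptors.

    ``mask`` is a boolean array over the *source region* (same shape as the
    binary mask the blob was found in); ``bbox`` is expressed in that same
    local coordinate system.  ``elongation`` is the ratio of major to minor
    axis lengths of the intensity-equivalent ellipse (>= 1, may be inf for
    1-px-wide blobs); ``solidity`` is area over convex-hull area.
    """

    mask: np.ndarray
    area_px: int
    bbox: Roi
    centroid: tuple[float, float]  # (x, y)
    elongation: float
    solidity: float

    def contains_points(self, points: np.ndarray) -> bool:
        """True if every (x, y) point, rounded to a pixel, is in the blob."""
        pts = np.asarray(points, dtype=float)
        cols = np.rint(pts[:, 0]).astype(int)
        rows = np.rint(pts[:, 1]).astype(int)
        h, w = self.mask.shape
        inside = (cols >= 0) & (cols < w) & (rows >= 0) & (rows < h)
        if not inside.all():
            return False
        return bool(self.mask[rows, cols].all())


@dataclass(frozen=True)
class SelectionCriteria:
    """Size/shape gates for picking the fish blob.

    Area bounds are fractions of the ROI area; an adult fish silhouette is
    elongated and (when bending) non-convex, hence the elongation floor and
    the solidity band.
    """

    min_area_frac: float = 0.002
    max_area_frac: float = 0.25
    min_elongation: float = 2.5
    min_solidity: float = 0.3
    max_solidity: float = 0.95

    def __post_init__(self) -> None:
        if not (0 < self.min_area_frac < self.max_area_frac < 1):
            raise ValueError("need 0 < min_area_frac < max_area_frac < 1")
        if self.min_elongation < 1:
            raise ValueError("min_elongation must be >= 1")
        if not (0 < self.min_solidity <= self.max_solidity <= 1):
            raise ValueError("need 0 < min_solidity <= max_solidity <= 1")

    def accepts(self, blob: Blob, roi_area: float) -> bool:
        frac = blob.area_px / roi_area
        return (self.min_area_frac <= frac <= self.max_area_frac
                and blob.elongation >= self.min_elongation
                and self.min_solidity <= blob.solidity <= self.max_solidity)


def preprocess(frame: np.ndarray, gaussian_sigma: float = 1.5,
               low_pct: float = 1.0, high_pct: float = 99.0) -> np.ndarray:
    """Percentile contrast stretch followed by Gaussian smoothing.

    Intensities are rescaled linearly so the ``low_pct`` percentile maps to 0
    and ``high_pct`` to 255, clipping outside; this saturates faint structures
    (fins, shadows) toward the background before thresholding.  A constant
    frame degenerates to all zeros.  ``gaussian_sigma = 0`` skips the blur.

    Returns a float64 array in [0, 255] of the same shape.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    lo, hi = np.percentile(frame, [low_pct, high_pct])
    if hi > lo:
        out = np.clip((frame - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    else:
        out = np.zeros_like(frame)
    if gaussian_sigma > 0:
        out = ndimage.gaussian_filter(out, sigma=gaussian_sigma)
    return out


def motion_clip(frames: np.ndarray, roi: Roi, margin_px: int = 10,
                diff_threshold: float = 10.0, min_motion_frac: float = 1e-4,
                background_frames: int = 25) -> list[Roi]:
    """Per-frame clipping box around moving pixels inside ``roi``.

    The static background is the per-pixel median of the first
    ``background_frames`` frames.  For each frame, pixels whose absolute
    difference from the background exceeds ``diff_threshold`` are "changed";
    their bounding box, dilated by ``margin_px`` and intersected with ``roi``,
    is returned.  If the changed fraction falls below ``min_motion_frac``
    (static scene) the full ``roi`` is returned for that frame.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, h, w) stack")
    n = frames.shape[0]
    if not Roi.full(frames.shape[1:]).contains(roi):
        raise ValueError("ROI exceeds frame bounds")
    if n < 2:
        warnings.warn("motion_clip needs >= 2 frames; returning full ROI")
        return [roi] * n

    sl = roi.slices()
    k = min(background_frames, n)
    background = np.median(frames[:k, sl[0], sl[1]], axis=0)
    boxes: list[Roi] = []
    for i in range(n):
        changed = np.abs(frames[i, sl[0], sl[1]] - background) > diff_threshold
        if changed.mean() < min_motion_frac:
            boxes.append(roi)
            continue
        rows, cols = np.nonzero(changed)
        x0 = roi.x0 + int(cols.min()) - margin_px
        y0 = roi.y0 + int(rows.min()) - margin_px
        x1 = roi.x0 + int(cols.max()) + 1 + margin_px
        y1 = roi.y0 + int(rows.max()) + 1 + margin_px
        box = Roi(max(x0, roi.x0), max(y0, roi.y0),
                  min(x1, roi.x0 + roi.width) - max(x0, roi.x0),
                  min(y1, roi.y0 + roi.height) - max(y0, roi.y0))
        boxes.append(box)
    return boxes


def otsu_threshold(region: np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit region.

    Returns the integer t in [0, 255] maximizing the between-class variance
    when pixels <= t form one class and pixels > t the other; ties are broken
    toward the smallest t so the result is deterministic.

    Raises :class:`DegenerateHistogramError` on a constant region, where no
    threshold separates anything and the caller should mark the frame invalid.
    """
    region = np.asarray(region)
    if region.size == 0:
        raise ValueError("empty region")
    vals = np.clip(np.round(region.astype(np.float64)), 0, 255).astype(np.uint8)
    hist = np.bincount(vals.ravel(), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("constant region: no threshold exists")

    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist) / total              # P(class <= t)
    mu_cum = np.cumsum(hist * levels) / total
    mu_total = mu_cum[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu_cum / w0
        mu1 = (mu_total - mu_cum) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    return int(np.argmax(sigma_b))            # argmax takes the smallest tie


def binarize(region: np.ndarray, threshold: int,
             polarity: str = "dark_fish") -> np.ndarray:
    """Threshold a region into a boolean foreground mask.

    ``dark_fish``: foreground where intensity <= threshold (silhouette
    imaging); ``bright_fish``: the complement (intensity > threshold).
    """
    region = np.asarray(region, dtype=np.float64)
    if polarity == "dark_fish":
        return region <= threshold
    if polarity == "bright_fish":
        return region > threshold
    raise ValueError(f"unknown polarity {polarity!r}")


def find_blobs(mask: np.ndarray) -> list[Blob]:
    """All 8-connected foreground components, sorted by area descending."""
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    blobs: list[Blob] = []
    for rp in measure.regionprops(labels):
        minr, minc, maxr, maxc = rp.bbox
        minor = rp.axis_minor_length
        elong = rp.axis_major_length / minor if minor > 0 else np.inf
        cy, cx = rp.centroid
        blobs.append(Blob(
            mask=labels == rp.label,
            area_px=int(rp.area),
            bbox=Roi(minc, minr, maxc - minc, maxr - minr),
            centroid=(float(cx), float(cy)),
            elongation=float(elong),
            solidity=float(rp.solidity),
        ))
    blobs.sort(key=lambda b: (-b.area_px, -b.elongation, b.bbox.x0))
    return blobs


def qualifying_blobs(blobs: list[Blob], criteria: SelectionCriteria,
                     roi_area: float) -> list[Blob]:
    """Blobs passing all selection criteria, in the input (area-sorted) order."""
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    return [b for b in blobs if criteria.accepts(b, roi_area)]


def select_fish_blob(blobs: list[Blob], criteria: SelectionCriteria,
                     roi_area: float) -> Blob | None:
    """Pick the fish among candidate blobs, or None if nothing qualifies.

    Among blobs passing the size/shape gates the largest wins; exact area
    ties go to the more elongated blob, then to the smaller bounding-box x0,
    giving a total order.
    """
    passing = qualifying_blobs(blobs, criteria, roi_area)
    if not passing:
        return None
    return min(passing, key=lambda b: (-b.area_px, -b.elongation, b.bbox.x0))
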