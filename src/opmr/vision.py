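"""Classical image pipeline: adaptive binarization, min-area-rectangle
rectification, grid bit recognition, and signal retention / intensity analytics.

The decoding side of the system has to turn a raw fluorescence photo of a
patch — at an unknown small rotation, scale and offset — into an N x N binary
array with zero per-bit error on clean captures.  That is done in three
classical stages, each free of per-image manual thresholds:

1. ``binarize_adaptive`` — local-mean thresholding plus small-object removal
   separates fluorescent spots from the skin background.
2. ``rectify`` — the minimum-area rotated rectangle covering all foreground
   pixels gives the patch pose; the image is rotated to axis alignment,
   cropped 35% larger than the rectangle about its centre, and resized.
3. ``read_grid`` — spot centroids anchor the N x N cell lattice; each cell is
   scored by mean intensity over its central half and labelled ON/OFF by a
   parameter-free two-class split of the scores.

The retention/intensity analytics mirror the longitudinal bookkeeping used to
follow patches over weeks: retention is the percentage of detectable bits out
of the bits originally transferred, intensity the per-bit maximum pixel value
(comparable only at fixed gain/exposure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import MultiPoint, minimum_rotated_rectangle
from skimage import measure, morphology, transform

__all__ = [
    "NoPatchError",
    "ComparabilityError",
    "RectifiedImage",
    "IntensityReport",
    "binarize_adaptive",
    "clean_binary",
    "count_bits",
    "rectify",
    "read_grid",
    "signal_retention",
    "signal_intensity",
    "compare_intensity",
]

CROP_MARGIN = 1.35  # crop side relative to the min-area rectangle side


class NoPatchError(ValueError):
    """No usable foreground found in the image."""


class ComparabilityError(ValueError):
    """Intensity comparison attempted across different acquisition settings."""


@dataclass
class RectifiedImage:
    """Axis-aligned, centre-preserved crop of the patch region."""

    image: np.ndarray          # (side, side) float
    crop_margin: float
    recovered_angle: float     # degrees of compensation applied, in (-45, 45]
    crop_side: float           # pre-resize crop side in source pixels


@dataclass(frozen=True)
class IntensityReport:
    """Per-ON-bit maximum pixel values under one acquisition setting."""

    values: np.ndarray         # one entry per ON bit
    settings_id: str | None


def binarize_adaptive(image: np.ndarray, window: int = 41,
                      offset: float = 0.02) -> np.ndarray:
    """Local-mean threshold: pixel ON iff value > mean over ``window`` + offset.

    ``offset`` is in intensity units (fraction of the [0, 1] dynamic range);
    a positive offset maps any constant image to all OFF.
    """
    image = np.asarray(image, dtype=float)
    if window > min(image.shape):
        raise ValueError(f"window {window} larger than image {image.shape}")
    local_mean = ndimage.uniform_filter(image, size=window, mode="reflect")
    return (image > local_mean + offset).astype(np.uint8)


def clean_binary(binary: np.ndarray, min_size: int = 12) -> np.ndarray:
    """Drop connected components smaller than ``min_size`` pixels."""
    return morphology.remove_small_objects(
        np.asarray(binary, bool), max_size=min_size - 1).astype(np.uint8)


def count_bits(image: np.ndarray, window: int = 41, offset: float = 0.02,
               min_size: int = 12) -> int:
    """Number of detectable bits: connected spots after adaptive thresholding."""
    cleaned = clean_binary(binarize_adaptive(image, window, offset), min_size)
    return int(measure.label(cleaned).max())


def rectify(binary: np.ndarray, target_side: int,
            intensity: np.ndarray | None = None,
            crop_margin: float = CROP_MARGIN) -> RectifiedImage:
    """Normalise patch pose via the minimum-area enclosing rotated rectangle.

    Finds the minimum-area rectangle over all ON pixels, rotates the image
    about the rectangle centre so the rectangle is axis-aligned, crops a
    square ``crop_margin`` times the rectangle's long side (centre preserved)
    and resizes to ``target_side``.  If ``intensity`` is given, that image is
    transformed instead of the binary mask (with the pose estimated from the
    binary mask), so greyscale cell values survive rectification.
    """
    binary = np.asarray(binary)
    ys, xs = np.nonzero(binary)
    if len(ys) < 3:
        raise NoPatchError("fewer than 3 foreground pixels")
    rect = minimum_rotated_rectangle(MultiPoint(np.column_stack([xs, ys])))
    if rect.geom_type != "Polygon":     # collinear foreground
        raise NoPatchError("foreground is degenerate (collinear)")
    corners = np.asarray(rect.exterior.coords)[:4]
    e1 = corners[1] - corners[0]
    e2 = corners[2] - corners[1]
    long_side = max(np.hypot(*e1), np.hypot(*e2))
    angle = np.degrees(np.arctan2(e1[1], e1[0]))
    angle = (angle + 45.0) % 90.0 - 45.0          # fold into (-45, 45]
    cx, cy = np.asarray(rect.centroid.coords)[0]

    src = np.asarray(intensity if intensity is not None else binary, dtype=float)
    crop_side = crop_margin * long_side
    pad = int(np.ceil(crop_side / 2)) + 2
    padded = np.pad(src, pad, mode="constant")
    rotated = transform.rotate(padded, angle, center=(cx + pad, cy + pad),
                               order=1, preserve_range=True)
    half = crop_side / 2
    y0 = int(round(cy + pad - half))
    x0 = int(round(cx + pad - half))
    side = int(round(crop_side))
    crop = rotated[y0:y0 + side, x0:x0 + side]
    out = transform.resize(crop, (target_side, target_side), order=1,
                           preserve_range=True, anti_aliasing=True)
    return RectifiedImage(image=out, crop_margin=crop_margin,
                          recovered_angle=float(angle), crop_side=crop_side)


def _two_class_split(scores: np.ndarray) -> np.ndarray:
    """Parameter-free 1-D two-means labelling; ties and degeneracy go OFF."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    n = s.size
    if s[-1] - s[0] < 1e-9:
        warnings.warn("degenerate cell-score distribution; labelling all OFF")
        return np.zeros(n, dtype=np.uint8)
    csum = np.cumsum(s)
    total = csum[-1]
    best_cost, best_split = np.inf, n
    for split in range(1, n):          # OFF class = s[:split]
        m0 = csum[split - 1] / split
        m1 = (total - csum[split - 1]) / (n - split)
        cost = np.sum((s[:split] - m0) ** 2) + np.sum((s[split:] - m1) ** 2)
        if cost < best_cost:
            best_cost, best_split = cost, split
    labels = np.zeros(n, dtype=np.uint8)
    labels[order[best_split:]] = 1
    return labels


def read_grid(rectified: RectifiedImage, N: int) -> np.ndarray:
    """Recognise the N x N bit array in a rectified patch image.

    The extreme spot centroids along each axis anchor the first and last grid
    rows/columns (the always-ON corner markers guarantee they exist); cell
    scores are mean intensity over the central 50% of each cell; ON/OFF is a
    global two-class split of the scores.
    """
    img = np.asarray(rectified.image, dtype=float)
    mask = img > 0.5 * img.max() if img.max() > 0 else img > 0.5
    labelled = measure.label(mask)
    props = measure.regionprops(labelled)
    if len(props) < 2:
        warnings.warn("no resolvable spots; returning all-OFF grid")
        return np.zeros((N, N), dtype=np.uint8)
    cents = np.array([p.centroid for p in props])
    y0, y1 = cents[:, 0].min(), cents[:, 0].max()
    x0, x1 = cents[:, 1].min(), cents[:, 1].max()
    if y1 - y0 < 1 or x1 - x0 < 1:
        warnings.warn("degenerate spot layout; returning all-OFF grid")
        return np.zeros((N, N), dtype=np.uint8)
    py = (y1 - y0) / (N - 1)
    px = (x1 - x0) / (N - 1)
    scores = np.zeros((N, N))
    hy, hx = 0.25 * py, 0.25 * px
    for i in range(N):
        for j in range(N):
            cy = y0 + i * py
            cx = x0 + j * px
            ya, yb = int(round(cy - hy)), int(round(cy + hy)) + 1
            xa, xb = int(round(cx - hx)), int(round(cx + hx)) + 1
            ya, xa = max(0, ya), max(0, xa)
            scores[i, j] = img[ya:yb, xa:xb].mean()
    labels = _two_class_split(scores.ravel())
    return labels.reshape(N, N)


def signal_retention(images, baseline_total: int, timepoints=None,
                     window: int = 41, offset: float = 0.02,
                     min_size: int = 12) -> pd.DataFrame:
    """Longitudinal retention: detected bits / transferred bits, per timepoint.

    Returns a DataFrame with columns ``timepoint, detected, total,
    retention_pct`` (retention in percent).
    """
    if baseline_total <= 0:
        raise ValueError("baseline_total must be positive")
    images = list(images)
    if not images:
        raise ValueError("need at least one timepoint")
    if timepoints is None:
        timepoints = list(range(len(images)))
    rows = []
    for t, img in zip(timepoints, images):
        detected = count_bits(img, window, offset, min_size)
        rows.append({"timepoint": t, "detected": detected,
                     "total": baseline_total,
                     "retention_pct": 100.0 * detected / baseline_total})
    return pd.DataFrame(rows)


def signal_intensity(image: np.ndarray, grid: np.ndarray, transform_params: dict,
                     settings_id: str | None = None) -> IntensityReport:
    """Per-ON-bit maximum pixel value within each bit's cell region.

    ``transform_params`` is the grid-to-image mapping (as produced by the
    simulator); the search box per bit is half a pitch around the bit centre.
    """
    from .nir_sim import grid_to_image

    image = np.asarray(image, dtype=float)
    grid = np.asarray(grid, dtype=np.uint8)
    N = grid.shape[0]
    on_cells = np.argwhere(grid == 1)
    centres = grid_to_image(on_cells, N, transform_params)
    half = transform_params["pitch"] * transform_params.get("scale", 1.0) / 2
    vals = []
    for cy, cx in centres:
        y0, y1 = max(0, int(cy - half)), min(image.shape[0], int(cy + half) + 1)
        x0, x1 = max(0, int(cx - half)), min(image.shape[1], int(cx + half) + 1)
        vals.append(image[y0:y1, x0:x1].max())
    return IntensityReport(values=np.asarray(vals), settings_id=settings_id)


def compare_intensity(a: IntensityReport, b: IntensityReport,
                      allow_cross_settings: bool = False) -> float:
    """Difference of median per-bit intensity; refuses mismatched settings."""
    if a.settings_id != b.settings_id and not allow_cross_settings:
        raise ComparabilityError(
            f"acquisition settings differ ({a.settings_id!r} vs "
            f"{b.settings_id!r}); pass allow_cross_settings=True to override")
    return float(np.median(a.values) - np.median(b.values))
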