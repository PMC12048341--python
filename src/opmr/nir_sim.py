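"""Synthetic near-infrared fluorescence patch images with paired ground truth.

Each dye-loaded needle deposits a roughly round fluorophore dose in the
dermis; under NIR excitation it images as a bright, approximately Gaussian
spot over a dim, noisy skin background.  The simulator renders an encoded
grid as such spots under a randomized imaging transform (rotation, scale
jitter, translation), defocus and motion blur, and gain/exposure variation,
and models signal fading over time as whole-bit dropout: every ON bit
survives independently with a retention probability, optionally dimmed by a
per-spot attenuation factor.  Datasets mix four retention tiers —
100%, 75%, 50% and 25% of ON bits surviving — in 5/15/60/20 proportions.

All sampling is driven by one seeded generator per sample so any dataset can
be reconstructed bit-for-bit from its manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RenderParams",
    "DegradationSpec",
    "SyntheticSample",
    "default_pitch",
    "render",
    "degrade",
    "sample_dataset",
    "augment_impulse",
    "grid_to_image",
    "image_to_grid",
]

RETENTION_LEVELS = (1.00, 0.75, 0.50, 0.25)
PORTION_WEIGHTS = (0.05, 0.15, 0.60, 0.20)


def default_pitch(N: int, image_size: int = 256) -> float:
    """Bit spacing that leaves room for the +/-5 deg rotation and jitter."""
    return round(0.69 * image_size / (N - 1), 1)


@dataclass(frozen=True)
class RenderParams:
    """Sampling ranges for the imaging variation space.

    Ranges are inclusive intervals sampled uniformly per image.  Intensities
    are normalized to [0, 1]; geometry is in pixels and degrees.
    """

    image_size: int = 256
    pitch: float = 19.6                       # px between adjacent bit centres
    spot_sigma: float | None = None           # default pitch / 6
    intensity_range: tuple[float, float] = (0.55, 0.95)
    background_level: float = 0.08
    background_noise_sigma: float = 0.012
    rotation_range: tuple[float, float] = (-5.0, 5.0)
    scale_jitter: tuple[float, float] = (0.95, 1.05)
    translation_jitter: float = 4.0           # max |shift| px per axis
    blur_sigma_range: tuple[float, float] = (0.0, 1.2)
    motion_blur_len_range: tuple[float, float] = (0.0, 3.0)
    gain_range: tuple[float, float] = (0.9, 1.1)
    exposure_range: tuple[float, float] = (0.9, 1.1)

    @property
    def sigma(self) -> float:
        return self.pitch / 6.0 if self.spot_sigma is None else self.spot_sigma


@dataclass(frozen=True)
class DegradationSpec:
    """Temporal signal-loss model: whole-bit dropout tiers plus dimming."""

    retention_levels: tuple[float, ...] = RETENTION_LEVELS
    portion_weights: tuple[float, ...] = PORTION_WEIGHTS
    #: brightness multiplier range for surviving spots
    intensity_attenuation: tuple[float, float] = (0.6, 1.0)

    def __post_init__(self):
        if abs(sum(self.portion_weights) - 1.0) > 1e-9:
            raise ValueError("portion weights must sum to 1")


@dataclass
class SyntheticSample:
    """A rendered image with its full ground truth."""

    image: np.ndarray                 # (size, size) float in [0, 1]
    truth_grid: np.ndarray            # pre-degradation encoded pattern
    observed_grid: np.ndarray         # after bit dropout
    transform: dict                   # rotation_deg, scale, center, pitch
    retention_level: float
    seed: int
    payload: int | None = None
    split: str | None = None          # "train" | "val"


def grid_to_image(cells: np.ndarray, N: int, transform: dict) -> np.ndarray:
    """Map (row, col) cell coordinates to (y, x) image coordinates."""
    cells = np.atleast_2d(np.asarray(cells, dtype=float))
    a = np.deg2rad(transform["rotation_deg"])
    step = transform["pitch"] * transform["scale"]
    dy = (cells[:, 0] - (N - 1) / 2) * step
    dx = (cells[:, 1] - (N - 1) / 2) * step
    cy, cx = transform["center"]
    y = cy + dx * np.sin(a) + dy * np.cos(a)
    x = cx + dx * np.cos(a) - dy * np.sin(a)
    return np.column_stack([y, x])


def image_to_grid(points: np.ndarray, N: int, transform: dict) -> np.ndarray:
    """Inverse of :func:`grid_to_image`: (y, x) pixels to fractional (row, col)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = np.deg2rad(transform["rotation_deg"])
    step = transform["pitch"] * transform["scale"]
    cy, cx = transform["center"]
    py = points[:, 0] - cy
    px = points[:, 1] - cx
    dx = px * np.cos(a) + py * np.sin(a)
    dy = -px * np.sin(a) + py * np.cos(a)
    return np.column_stack([dy / step + (N - 1) / 2,
                            dx / step + (N - 1) / 2])


def _motion_kernel(length: float, angle_deg: float) -> np.ndarray | None:
    n = int(round(length))
    if n < 2:
        return None
    k = np.zeros((n, n))
    c = (n - 1) / 2
    a = np.deg2rad(angle_deg)
    for s in np.linspace(-c, c, 4 * n):
        i = int(round(c + s * np.sin(a)))
        j = int(round(c + s * np.cos(a)))
        k[i, j] = 1.0
    return k / k.sum()


def render(grid: np.ndarray, params: RenderParams, seed: int,
           attenuation: np.ndarray | None = None) -> SyntheticSample:
    """Render an (already degraded, if applicable) grid as a NIR image.

    ON cells become Gaussian spots at their transformed centres with
    per-spot peak brightness; background level, Gaussian pixel noise, defocus
    and motion blur and a gain/exposure factor are then applied and the image
    clipped to [0, 1].  Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If the transformed grid (plus a 3-sigma spot margin) leaves the image.
    """
    grid = np.asarray(grid, dtype=np.uint8)
    N = grid.shape[0]
    rng = np.random.default_rng(seed)
    size = params.image_size

    rotation = rng.uniform(*params.rotation_range)
    scale = rng.uniform(*params.scale_jitter)
    t = params.translation_jitter
    center = (size / 2 + rng.uniform(-t, t), size / 2 + rng.uniform(-t, t))
    transform = {"rotation_deg": float(rotation), "scale": float(scale),
                 "center": (float(center[0]), float(center[1])),
                 "pitch": float(params.pitch)}

    corners = np.array([[0, 0], [0, N - 1], [N - 1, 0], [N - 1, N - 1]])
    pts = grid_to_image(corners, N, transform)
    margin = 3 * params.sigma
    if (pts.min() < margin) or (pts.max() > size - 1 - margin):
        raise ValueError("grid exceeds image bounds at this pitch/scale")

    image = np.zeros((size, size))
    on_cells = np.argwhere(grid == 1)
    centres = grid_to_image(on_cells, N, transform) if len(on_cells) else np.empty((0, 2))
    peaks = rng.uniform(*params.intensity_range, size=len(on_cells))
    if attenuation is not None:
        peaks = peaks * np.asarray(attenuation, dtype=float)
    sig = params.sigma
    half = int(np.ceil(4 * sig))
    for (cy, cx), peak in zip(centres, peaks):
        y0, y1 = max(0, int(cy) - half), min(size, int(cy) + half + 1)
        x0, x1 = max(0, int(cx) - half), min(size, int(cx) + half + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        image[y0:y1, x0:x1] += peak * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig ** 2))

    blur = rng.uniform(*params.blur_sigma_range)
    if blur > 0:
        image = ndimage.gaussian_filter(image, blur)
    mk = _motion_kernel(rng.uniform(*params.motion_blur_len_range),
                        rng.uniform(0, 180))
    if mk is not None:
        image = ndimage.convolve(image, mk, mode="nearest")

    image = image + params.background_level
    image = image + rng.normal(0, params.background_noise_sigma, image.shape)
    image = image * rng.uniform(*params.gain_range)
    image = image * rng.uniform(*params.exposure_range)
    image = np.clip(image, 0.0, 1.0)

    return SyntheticSample(image=image, truth_grid=grid.copy(),
                           observed_grid=grid.copy(), transform=transform,
                           retention_level=1.0, seed=seed)


def degrade(grid: np.ndarray, retention: float, seed: int) -> np.ndarray:
    """Drop each ON bit independently with probability ``1 - retention``.

    OFF bits never turn ON; degradation is strictly one-sided.
    """
    if not (0 < retention <= 1):
        raise ValueError(f"retention must be in (0, 1], got {retention}")
    grid = np.asarray(grid, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    survive = rng.random(grid.shape) < retention
    return (grid & survive).astype(np.uint8)


def sample_dataset(n: int, config, seed: int,
                   spec: DegradationSpec | None = None) -> list[SyntheticSample]:
    """Draw ``n`` fully-labelled samples under the study's variation space.

    ``config`` is a :class:`opmr.pipeline.CodecConfig` (or anything with
    ``N``, ``code``, ``mask``, ``template``, ``render_params`` attributes).
    Retention tiers are drawn with the 5/15/60/20 weights, payloads uniformly,
    and each sample gets its own child seed recorded on the sample.  The last
    tenth of samples (by index) is labelled the validation split.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from . import rmcode
    spec = spec or DegradationSpec()
    rng = np.random.default_rng(seed)
    code = config.code
    samples = []
    n_train = int(round(0.9 * n))
    for i in range(n):
        child = int(rng.integers(0, 2 ** 31 - 1))
        crng = np.random.default_rng(child)
        payload = int(crng.integers(0, 1 << code.k))
        info = rmcode.bits_from_int(payload, code.k)
        from .gridcodec import place_bits, apply_mask
        truth = apply_mask(place_bits(config.template, rmcode.encode(code, info)),
                           config.mask)
        level = float(crng.choice(spec.retention_levels, p=spec.portion_weights))
        observed = degrade(truth, level, int(crng.integers(0, 2 ** 31 - 1)))
        atten = crng.uniform(*spec.intensity_attenuation,
                             size=int(observed.sum()))
        if level == 1.0:
            atten = np.ones_like(atten)
        sample = render(observed, config.render_params,
                        int(crng.integers(0, 2 ** 31 - 1)), attenuation=atten)
        sample.truth_grid = truth
        sample.observed_grid = observed
        sample.retention_level = level
        sample.seed = child
        sample.payload = payload
        sample.split = "train" if i < n_train else "val"
        samples.append(sample)
    return samples


def augment_impulse(image: np.ndarray, seed: int, density: float = 0.02,
                    n_rectangles: int = 2, rect_side: tuple[int, int] = (4, 16),
                    blur_sigma: float = 0.0,
                    background_level: float = 0.08) -> np.ndarray:
    """Impulse-noise augmentation: salt & pepper, small erased rectangles, blur."""
    img = np.asarray(image, dtype=float).copy()
    rng = np.random.default_rng(seed)
    h, w = img.shape
    if density > 0:
        hit = rng.random(img.shape) < density
        img[hit] = rng.integers(0, 2, int(hit.sum())).astype(float)
    for _ in range(n_rectangles):
        rh = int(rng.integers(rect_side[0], rect_side[1] + 1))
        rw = int(rng.integers(rect_side[0], rect_side[1] + 1))
        y = int(rng.integers(0, h - rh + 1))
        x = int(rng.integers(0, w - rw + 1))
        img[y:y + rh, x:x + rw] = background_level
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, blur_sigma)
    return np.clip(img, 0.0, 1.0)
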