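"""Tissue segmentation, ROI enumeration/sampling, augmentation, normalization.

Coordinate convention: 0-based, half-open boxes, x rightward and y
downward, stored at the working magnification.  A ``downsample`` factor
on the tissue mask maps mask pixels back to working-magnification pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage import filters
from skimage.color import rgb2hsv, hsv2rgb
from skimage.measure import block_reduce
from skimage.transform import resize

__all__ = [
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "TissueMask",
    "tissue_mask",
    "enumerate_rois",
    "sample_rois",
    "extract_patch",
    "augment",
    "normalize",
    "open_slide",
    "ArraySlide",
    "ImageFileSlide",
]

#: ImageNet per-channel statistics used to normalize patches before the model.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


# ---------------------------------------------------------------------------
# slide readers
# ---------------------------------------------------------------------------

class ArraySlide:
    """Reader over an in-memory RGB array in [0, 1] at working magnification."""

    def __init__(self, image: np.ndarray, slide_id: str = "slide"):
        image = np.asarray(image, dtype=float)
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an H x W x 3 image")
        self.image = image
        self.slide_id = slide_id

    @property
    def dims(self) -> tuple[int, int]:
        """(height, width) in working-magnification pixels."""
        return self.image.shape[:2]

    def read_region(self, x: int, y: int, w: int, h: int, downsample: float = 1.0):
        region = self.image[y : y + h, x : x + w]
        if downsample != 1.0:
            f = int(round(downsample))
            region = block_reduce(region, (f, f, 1), np.mean)
        return region

    def thumbnail(self, downsample: float = 1.0) -> np.ndarray:
        if downsample == 1.0:
            return self.image
        f = int(round(downsample))
        return block_reduce(self.image, (f, f, 1), np.mean)


class ImageFileSlide(ArraySlide):
    """Reader for plain raster slides (PNG/TIFF) without a pyramid.

    The working magnification is reached by average-pooling the level-0
    image by ``level0_downsample``.
    """

    def __init__(self, path, level0_downsample: float = 1.0):
        import imageio.v3 as iio

        img = np.asarray(iio.imread(str(path)), dtype=float)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        if img.shape[2] == 4:
            img = img[..., :3]
        if img.max() > 1.0:
            img = img / 255.0
        if level0_downsample != 1.0:
            f = int(round(level0_downsample))
            img = block_reduce(img, (f, f, 1), np.mean)
        super().__init__(img, slide_id=Path(path).stem)


def open_slide(path, level0_downsample: float = 1.0) -> ArraySlide:
    """Open a raster slide file as a reader at the working magnification."""
    return ImageFileSlide(path, level0_downsample=level0_downsample)


# ---------------------------------------------------------------------------
# tissue segmentation
# ---------------------------------------------------------------------------

@dataclass
class TissueMask:
    """Binary tissue map at a stated downsample of the working magnification."""

    mask: np.ndarray
    threshold: float
    downsample: float = 1.0

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean())


def tissue_mask(thumbnail: np.ndarray, downsample: float = 1.0) -> TissueMask:
    """Otsu-threshold a grayscale thumbnail into tissue vs glass.

    The threshold maximizes between-class variance over a 256-bin
    histogram; tissue is the dark class (H&E tissue is darker than the
    glass background).  Raises on a constant image, where no
    foreground/background separation exists.
    """
    img = np.asarray(thumbnail)
    if img.size == 0:
        raise ValueError("empty image")
    if img.ndim == 3:
        img = img.mean(axis=2)
    if np.ptp(img) == 0:
        raise ValueError("degenerate histogram: constant image, no tissue/background separation")
    # threshold on the native scale (exact 256-level histogram for 8-bit
    # input), then report on the normalized [0, 1] grayscale
    threshold = float(filters.threshold_otsu(img, nbins=256))
    scale = 255.0 if img.dtype.kind in "iu" or img.max() > 1.0 else 1.0
    # the dark class includes the threshold level itself (<=), matching the
    # histogram split the between-class-variance maximization evaluates
    return TissueMask(mask=img <= threshold, threshold=threshold / scale, downsample=downsample)


# ---------------------------------------------------------------------------
# ROI enumeration and sampling
# ---------------------------------------------------------------------------

def enumerate_rois(mask: TissueMask, size: int, stride: int | None = None,
                   min_tissue: float = 0.5) -> list[tuple[int, int]]:
    """Raster-order grid of candidate ROI top-left corners.

    Boxes are half-open ``[x, x+size) x [y, y+size)`` at the working
    magnification, never exceeding slide bounds; boxes whose tissue
    fraction under ``mask`` falls below ``min_tissue`` are dropped.
    Default stride is 50% of the tile size (maximum overlap of one half).
    """
    if stride is None:
        stride = size // 2
    if not (0 < stride <= size):
        raise ValueError("require 0 < stride <= size")
    if not (0 <= min_tissue <= 1):
        raise ValueError("min_tissue must be in [0, 1]")

    ds = mask.downsample
    mh, mw = mask.mask.shape
    slide_h, slide_w = int(round(mh * ds)), int(round(mw * ds))
    if size > slide_h or size > slide_w:
        return []

    # integral image for O(1) tissue-fraction queries at mask resolution
    ii = np.zeros((mh + 1, mw + 1))
    ii[1:, 1:] = np.cumsum(np.cumsum(mask.mask.astype(float), axis=0), axis=1)

    coords = []
    for y in range(0, slide_h - size + 1, stride):
        my0 = int(np.floor(y / ds))
        my1 = min(int(np.ceil((y + size) / ds)), mh)
        for x in range(0, slide_w - size + 1, stride):
            mx0 = int(np.floor(x / ds))
            mx1 = min(int(np.ceil((x + size) / ds)), mw)
            area = (my1 - my0) * (mx1 - mx0)
            tissue = ii[my1, mx1] - ii[my0, mx1] - ii[my1, mx0] + ii[my0, mx0]
            if area > 0 and tissue / area >= min_tissue:
                coords.append((x, y))
    return coords


def sample_rois(coords, n: int, seed: int = 0) -> list[tuple[int, int]]:
    """Sample ``n`` ROI coordinates, deterministically given ``seed``.

    Draws without replacement when enough candidates exist; otherwise the
    full candidate set is kept and topped up by draws with replacement, so
    every candidate appears at least once.
    """
    coords = list(coords)
    if not coords:
        raise ValueError("no tissue ROIs to sample from")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if n <= len(coords):
        idx = rng.choice(len(coords), size=n, replace=False)
    else:
        extra = rng.choice(len(coords), size=n - len(coords), replace=True)
        idx = np.concatenate([rng.permutation(len(coords)), extra])
    return [coords[i] for i in idx]


def extract_patch(slide, x: int, y: int, size: int) -> np.ndarray:
    """Read one size x size x 3 patch at the working magnification."""
    if isinstance(slide, np.ndarray):
        slide = ArraySlide(slide)
    patch = slide.read_region(x, y, size, size)
    if patch.shape[:2] != (size, size):
        raise ValueError(f"box ({x},{y},{size}) exceeds slide bounds {slide.dims}")
    return patch


# ---------------------------------------------------------------------------
# augmentation and normalization
# ---------------------------------------------------------------------------

def augment(patch: np.ndarray, seed: int) -> np.ndarray:
    """Stochastic label-preserving augmentation; pure function of (patch, seed).

    Each transform fires with independent probability 1/2: horizontal
    flip, vertical flip, right-angle rotation, hue shift (within +/-0.05
    of the hue scale), crop-and-resize (crop covering at least 80% of the
    area), and random erasing (a rectangle covering 2-20% of the area
    replaced by uniform noise).  Shape and the [0, 1] value range are
    preserved.
    """
    img = np.asarray(patch, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 patch")
    h, w = img.shape[:2]
    rng = np.random.default_rng(seed)

    if rng.random() < 0.5:
        img = img[:, ::-1]
    if rng.random() < 0.5:
        img = img[::-1]
    if rng.random() < 0.5:
        img = np.rot90(img, k=int(rng.integers(4)))
        if img.shape[:2] != (h, w):  # non-square patch: undo a shape-changing turn
            img = np.rot90(img)
    if rng.random() < 0.5:
        shift = rng.uniform(-0.05, 0.05)
        hsv = rgb2hsv(np.clip(img, 0, 1))
        hsv[..., 0] = (hsv[..., 0] + shift) % 1.0
        img = hsv2rgb(hsv)
    if rng.random() < 0.5:
        area = rng.uniform(0.8, 1.0)
        side = np.sqrt(area)
        ch, cw = max(1, round(side * h)), max(1, round(side * w))
        oy = int(rng.integers(h - ch + 1))
        ox = int(rng.integers(w - cw + 1))
        crop = img[oy : oy + ch, ox : ox + cw]
        img = resize(crop, (h, w), order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    if rng.random() < 0.5:
        frac = rng.uniform(0.02, 0.20)
        aspect = rng.uniform(0.5, 2.0)
        eh = int(np.clip(round(np.sqrt(frac * h * w * aspect)), 1, h))
        ew = int(np.clip(round(frac * h * w / eh), 1, w))
        # keep the realized erased fraction inside [0.02, 0.20]
        ew = int(np.clip(ew, np.ceil(0.02 * h * w / eh), np.floor(0.20 * h * w / eh)))
        ew = int(np.clip(ew, 1, w))
        oy = int(rng.integers(h - eh + 1))
        ox = int(rng.integers(w - ew + 1))
        img = img.copy()
        img[oy : oy + eh, ox : ox + ew] = rng.uniform(size=(eh, ew, 3))

    return np.ascontiguousarray(np.clip(img, 0.0, 1.0))


def normalize(patch: np.ndarray) -> np.ndarray:
    """Standardize [0, 1] RGB values with the ImageNet channel statistics."""
    img = np.asarray(patch, dtype=float)
    return (img - IMAGENET_MEAN) / IMAGENET_STD
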