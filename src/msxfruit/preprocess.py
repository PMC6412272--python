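"""Pre-processing chain for pseudo-color fruit images.

Warm objects (fruit, sun-heated soil) render with a high red channel in the
warm-palette pseudo-color image, so the chain projects the raster onto its
red component, binarizes it with Otsu's threshold, cleans the mask with a
disk-shaped morphological opening and a relative small-area filter, labels
the surviving connected regions, and restores the original colors inside
them:

    red gray -> Otsu binarize -> open(disk r) -> drop area <= A_max/10
             -> label regions -> restore pseudo-color
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, opening

from .io_images import (
    BinaryMask,
    GrayImage,
    LabelMap,
    MsxImage,
    RunConfig,
    ValidationError,
    log,
)

__all__ = [
    "PreprocessResult",
    "to_red_gray",
    "otsu_threshold",
    "binarize",
    "morph_open_disk",
    "remove_small_regions",
    "label_regions",
    "restore_color",
    "preprocess_pipeline",
]


@dataclass(frozen=True, eq=False)
class PreprocessResult:
    """All intermediates of the pre-processing chain for one image."""

    gray: GrayImage
    binary_raw: BinaryMask
    binary_clean: BinaryMask
    labels: LabelMap
    restored: MsxImage
    otsu_threshold: int
    otsu_degenerate: bool


def to_red_gray(img: MsxImage) -> GrayImage:
    """Project the pseudo-color image onto its red component."""
    return GrayImage(img.red.copy())


def otsu_threshold(gray: GrayImage) -> tuple[int, bool]:
    """Otsu's threshold over the 256-bin histogram.

    Returns ``(t, degenerate)`` where *t* maximizes the between-class
    variance of the split into classes ``<= t`` and ``> t`` (ties broken
    toward the lowest maximizing threshold).  A constant image is degenerate:
    one class is empty for every split, so *t* is the constant value itself
    and the flag is set.
    """
    px = gray.pixels
    if px.size == 0:
        raise ValidationError("cannot threshold an empty image")
    hist = np.bincount(px.ravel(), minlength=256).astype(np.float64)
    p = hist / hist.sum()
    lv = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(p)                      # P(class0) for t = 0..255
    mu0 = np.cumsum(p * lv)                # unnormalized class-0 mean
    mu_t = mu0[-1]
    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        return int(nonzero[0]), True
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu0) ** 2 / (w0 * (1.0 - w0))
    sigma_b[(w0 <= 0) | (w0 >= 1)] = -np.inf
    t = int(np.argmax(sigma_b))
    return t, False


def binarize(gray: GrayImage, threshold: int, bright_foreground: bool = True) -> BinaryMask:
    """Apply the threshold: foreground = pixel > t (or <= t for dark-object palettes)."""
    if bright_foreground:
        return BinaryMask(gray.pixels > threshold)
    return BinaryMask(gray.pixels <= threshold)


def morph_open_disk(mask: BinaryMask, radius: int) -> BinaryMask:
    """Morphological opening with a Euclidean disk structuring element.

    Erosion followed by dilation; the disk contains all offsets with
    Euclidean norm <= radius, so radius 0 is the identity.
    """
    if radius < 0:
        raise ValidationError("structuring-element radius must be >= 0")
    if radius == 0:
        return BinaryMask(mask.pixels.copy())
    # out-of-image pixels count as foreground for the erosion step, so
    # border-touching regions are retained
    return BinaryMask(opening(mask.pixels, footprint=disk(radius)))


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndi.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndi.generate_binary_structure(2, 2)
    raise ValidationError("connectivity must be 4 or 8")


def remove_small_regions(mask: BinaryMask, fraction: float, connectivity: int = 8) -> BinaryMask:
    """Keep components with area strictly greater than fraction x (largest area).

    The relative rule adapts to scene scale: with the default fraction 1/10,
    any component not larger than one tenth of the biggest one is treated as
    noise.  The comparison is strict ("larger than"), so a component of
    exactly the threshold area is removed.
    """
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must lie in (0, 1]")
    lab, n = ndi.label(mask.pixels, structure=_structure(connectivity))
    if n == 0:
        return BinaryMask(np.zeros_like(mask.pixels))
    areas = np.bincount(lab.ravel())[1:]  # area per label 1..n
    cutoff = fraction * float(areas.max())
    keep = np.flatnonzero(areas.astype(np.float64) > cutoff) + 1
    return BinaryMask(np.isin(lab, keep))


def label_regions(mask: BinaryMask, connectivity: int = 8) -> LabelMap:
    """Label connected components 1..n in raster-scan first-encounter order."""
    lab, n = ndi.label(mask.pixels, structure=_structure(connectivity))
    if n == 0:
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), n_regions=0)
    flat = lab.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    idx = np.flatnonzero(flat)
    # first occurrence index of each label in raster order
    np.minimum.at(first, flat[idx], idx)
    order = np.argsort(first[1:], kind="stable") + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[order] = np.arange(1, n + 1)
    return LabelMap(remap[lab], n_regions=n)


def restore_color(img: MsxImage, mask: BinaryMask) -> MsxImage:
    """Restore the original pseudo-color inside the mask; black elsewhere."""
    if mask.shape != (img.height, img.width):
        raise ValidationError(
            f"mask shape {mask.shape} does not match image {(img.height, img.width)}"
        )
    out = np.where(mask.pixels[:, :, None], img.pixels, 0)
    return MsxImage(out.astype(np.uint8))


def preprocess_pipeline(img: MsxImage, cfg: RunConfig | None = None) -> PreprocessResult:
    """Run the full pre-processing chain and retain every intermediate."""
    cfg = cfg or RunConfig()
    gray = to_red_gray(img)
    t, degenerate = otsu_threshold(gray)
    if degenerate:
        log.warning("Otsu threshold is degenerate (constant image, value %d)", t)
    binary_raw = binarize(gray, t, cfg.bright_foreground)
    opened = morph_open_disk(binary_raw, cfg.disk_radius)
    binary_clean = remove_small_regions(opened, cfg.small_area_fraction, cfg.connectivity)
    labels = label_regions(binary_clean, cfg.connectivity)
    restored = restore_color(img, binary_clean)
    log.debug(
        "preprocess: t=%d, %d px raw -> %d px clean, %d regions",
        t, binary_raw.area, binary_clean.area, labels.n_regions,
    )
    return PreprocessResult(
        gray=gray,
        binary_raw=binary_raw,
        binary_clean=binary_clean,
        labels=labels,
        restored=restored,
        otsu_threshold=t,
        otsu_degenerate=degenerate,
    )
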