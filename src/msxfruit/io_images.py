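"""Raster types, image/mask/label I/O, run configuration and logging.

The pipeline consumes 3-channel 8-bit pseudo-color rasters (MSX exports are
400x300 JPG/PNG files) and produces single-channel masks and label maps.
Masks and label maps are written as lossless PNG; JPEG is accepted on input
only.  Coordinates are row-major, origin top-left, 0-based; bounding boxes
are half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from PIL import Image, UnidentifiedImageError

log = logging.getLogger("msxfruit")


class ValidationError(ValueError):
    """An input violates a documented precondition or type invariant."""


def setup_logging(verbose: bool = False) -> None:
    """Route package logs to stderr (used by the CLI)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# Raster types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class MsxImage:
    """H x W x 3 8-bit pseudo-color raster, channel order red-green-blue."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(f"MsxImage requires an HxWx3 raster, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("MsxImage must have H >= 1 and W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("MsxImage values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def red(self) -> np.ndarray:
        return self.pixels[:, :, 0]


@dataclass(frozen=True, eq=False)
class GrayImage:
    """H x W 8-bit grayscale raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"GrayImage requires an HxW raster, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("GrayImage values must lie in [0, 255]")
            px = px.astype(np.uint8)
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True, eq=False)
class BinaryMask:
    """H x W boolean raster."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"BinaryMask requires an HxW raster, got shape {px.shape}")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True, eq=False)
class LabelMap:
    """H x W non-negative integer raster; 0 is background, regions are 1..n."""

    pixels: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValidationError(f"LabelMap requires an HxW raster, got shape {px.shape}")
        px = px.astype(np.int32)
        present = np.unique(px)
        present = present[present > 0]
        expected = np.arange(1, self.n_regions + 1)
        if present.size != expected.size or not np.array_equal(present, expected):
            raise ValidationError(
                f"LabelMap labels must be exactly 1..{self.n_regions}, found {present.tolist()}"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def region_mask(self, region_id: int) -> BinaryMask:
        if not 1 <= region_id <= self.n_regions:
            raise ValidationError(f"unknown region_id {region_id} (have 1..{self.n_regions})")
        return BinaryMask(self.pixels == region_id)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_FEATURE_NAMES = ("contrast", "entropy", "correlation")


@dataclass(frozen=True)
class RunConfig:
    """Parameters shared by the whole detection pipeline.

    Defaults follow the method's published choices where stated (small-area
    fraction 1/10, GLCM step 2 at angles 0/45/90/135, contrast+entropy feature
    set); structuring-element radius, gray-level count and connectivity are
    not published and are exposed here with conventional values.
    """

    disk_radius: int = 3
    small_area_fraction: float = 0.1
    connectivity: int = 8
    glcm_levels: int = 16
    glcm_distance: int = 2
    glcm_angles: tuple[int, ...] = (0, 45, 90, 135)
    feature_set: tuple[str, ...] = ("contrast", "entropy")
    entropy_log_base: float = 2
    seed: int = 0
    # polarity of the binarization rule: True keeps pixels brighter than the
    # Otsu threshold (fruit are bright in the warm palette's red channel)
    bright_foreground: bool = True
    # count only pixel pairs with both endpoints inside the region (instead of
    # the whole bounding rectangle) when building GLCMs
    glcm_masked_pairs: bool = False
    # "region": per-region metric averaging; "image": pool counts per image
    eval_pooling: str = "region"

    def __post_init__(self) -> None:
        if self.disk_radius < 0:
            raise ValidationError("disk_radius must be >= 0")
        if not 0 < self.small_area_fraction <= 1:
            raise ValidationError("small_area_fraction must lie in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")
        if self.glcm_levels < 2:
            raise ValidationError("glcm_levels must be >= 2")
        if self.glcm_distance < 1:
            raise ValidationError("glcm_distance must be >= 1")
        if not self.glcm_angles:
            raise ValidationError("glcm_angles must be non-empty")
        object.__setattr__(self, "glcm_angles", tuple(self.glcm_angles))
        if any(a not in (0, 45, 90, 135) for a in self.glcm_angles):
            raise ValidationError("glcm_angles must be a subset of {0, 45, 90, 135}")
        object.__setattr__(self, "feature_set", tuple(self.feature_set))
        if not self.feature_set or any(f not in _FEATURE_NAMES for f in self.feature_set):
            raise ValidationError(
                f"feature_set must be a non-empty subset of {_FEATURE_NAMES}"
            )
        if self.entropy_log_base not in (2, np.e):
            raise ValidationError("entropy_log_base must be 2 or e")
        if self.eval_pooling not in ("region", "image"):
            raise ValidationError("eval_pooling must be 'region' or 'image'")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON run configuration; missing keys take the defaults.

    Unknown keys and out-of-range values raise :class:`ValidationError`
    naming the offending key.
    """
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ValidationError(f"unknown config key: {key!r}")
    if "entropy_log_base" in data and data["entropy_log_base"] == "e":
        data["entropy_log_base"] = np.e
    try:
        return RunConfig(**data)
    except ValidationError:
        raise
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"invalid config value: {exc}") from exc


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = dataclasses.asdict(cfg)
    data["glcm_angles"] = list(cfg.glcm_angles)
    data["feature_set"] = list(cfg.feature_set)
    if cfg.entropy_log_base not in (2,):
        data["entropy_log_base"] = "e"
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Image / mask / label I/O
# ---------------------------------------------------------------------------

def _open(path: str | Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except (UnidentifiedImageError, OSError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-sized raster in {path}")
    return arr


def read_image(path: str | Path) -> MsxImage:
    """Read a PNG/JPG file as a 3-channel 8-bit pseudo-color image.

    Grayscale files are replicated across the three channels, an alpha
    channel is dropped, and 16-bit inputs are rescaled to 8-bit by integer
    division.
    """
    arr = _open(path)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype == np.uint16:
        arr = (arr // 256).astype(np.uint8)
    elif arr.dtype == np.int32:  # PIL mode "I": 16-bit PNG content
        arr = np.clip(arr // 256, 0, 255).astype(np.uint8)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] >= 3:
        arr = arr[:, :, :3]
    else:
        raise ValidationError(f"unsupported channel layout {arr.shape} in {path}")
    return MsxImage(arr.astype(np.uint8))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a single-channel raster as a binary mask (nonzero -> 1)."""
    arr = _open(path)
    if arr.ndim != 2:
        raise ValidationError(
            f"mask file {path} has {arr.shape[2]} channels; a single-channel raster is required"
        )
    return BinaryMask(arr != 0)


def read_label_map(path: str | Path) -> LabelMap:
    arr = _open(path)
    if arr.ndim != 2:
        raise ValidationError(f"label map file {path} must be single-channel")
    arr = arr.astype(np.int32)
    return LabelMap(arr, n_regions=int(arr.max()))


def write_image(img: MsxImage, path: str | Path) -> None:
    Image.fromarray(img.pixels, mode="RGB").save(path)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a binary mask as single-channel PNG (0 / 255)."""
    Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L").save(path)


def write_label_map(labels: LabelMap, path: str | Path) -> None:
    """Write a label map as 16-bit single-channel PNG (lossless)."""
    if labels.n_regions > 65535:
        raise ValidationError("label map has too many regions for 16-bit PNG")
    Image.fromarray(labels.pixels.astype(np.uint16)).save(path)


def write_overlay(
    img: MsxImage,
    mask: BinaryMask,
    path: str | Path,
    manual: BinaryMask | None = None,
    color: tuple[int, int, int] = (255, 90, 0),
) -> None:
    """Render detected regions in a distinct color over the input image.

    If a manual ground-truth mask is supplied its contours are drawn in
    white, mirroring side-by-side presentations of algorithmic vs. manual
    segmentations.
    """
    if mask.shape != (img.height, img.width):
        raise ValidationError("overlay mask shape does not match image")
    out = img.pixels.astype(np.float64)
    m = mask.pixels
    out[m] = 0.5 * out[m] + 0.5 * np.asarray(color, dtype=np.float64)
    if manual is not None:
        from skimage.segmentation import find_boundaries

        contour = find_boundaries(manual.pixels, mode="inner")
        out[contour] = 255.0
    Image.fromarray(np.clip(out, 0, 255).astype(np.uint8), mode="RGB").save(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
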