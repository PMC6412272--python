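"""Per-region GLCM texture features.

Each labeled region is cropped to its minimum bounding rectangle (keeping
the constant zero background as small as possible), quantized to a small
number of gray levels, and described by a gray-level co-occurrence matrix
(GLCM) at pixel distance 2 along the four directions 0/45/90/135 degrees.
Three Haralick statistics are computed per direction and averaged:

    contrast    = sum (a-b)^2 p(a,b)          (texture groove depth)
    entropy     = -sum p log p                (co-occurrence heterogeneity)
    correlation = sum (a-mu_r)(b-mu_c) p / (sigma_r sigma_c)

Smooth fruit surfaces yield low contrast; rough sun-warmed soil, the main
color confounder, yields markedly higher contrast and a more concentrated
(lower-entropy) co-occurrence distribution — the separation the region
classifier exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_images import (
    BinaryMask,
    LabelMap,
    MsxImage,
    RunConfig,
    ValidationError,
)
from .preprocess import PreprocessResult

__all__ = [
    "ANGLE_UNIT_OFFSETS",
    "RegionPatch",
    "Glcm",
    "TextureFeatures",
    "angle_offset",
    "crop_min_bounding_rect",
    "quantize",
    "glcm",
    "glcm_contrast",
    "glcm_entropy",
    "glcm_correlation",
    "region_features",
    "extract_features",
    "features_frame",
]

# direction -> unit (dr, dc); scaled by the pixel distance, diagonals not
# unit-normalized (distance d maps 45 deg to (-d, d), not (-d/sqrt2, d/sqrt2))
ANGLE_UNIT_OFFSETS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


def angle_offset(angle: int, distance: int) -> tuple[int, int]:
    if angle not in ANGLE_UNIT_OFFSETS:
        raise ValidationError(f"unsupported GLCM angle {angle}")
    dr, dc = ANGLE_UNIT_OFFSETS[angle]
    return dr * distance, dc * distance


@dataclass(frozen=True, eq=False)
class RegionPatch:
    """One connected region cropped to its minimum bounding rectangle.

    ``gray`` is the red component of the restored image inside the
    rectangle, zero outside the region; ``mask`` marks the region's own
    pixels within the rectangle.
    """

    region_id: int
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    gray: np.ndarray
    mask: np.ndarray
    area: int


@dataclass(frozen=True, eq=False)
class Glcm:
    """Gray-level co-occurrence matrix for one region and offset."""

    matrix: np.ndarray
    levels: int
    offset: tuple[int, int]
    normalized: bool
    degenerate: bool = False


@dataclass(frozen=True, eq=False)
class TextureFeatures:
    """Direction-averaged GLCM features for one region.

    ``per_direction`` maps each angle to its (contrast, entropy,
    correlation) triple; the top-level values are their arithmetic means.
    A region too small to contain a single co-occurring pixel pair in some
    direction is flagged degenerate with all features zero.
    """

    region_id: int
    contrast: float
    entropy: float
    correlation: float
    per_direction: dict[int, tuple[float, float, float]]
    degenerate: bool


def crop_min_bounding_rect(labels: LabelMap, restored: MsxImage, region_id: int) -> RegionPatch:
    """Crop one region of the restored image to its minimal bounding rectangle."""
    if not 1 <= region_id <= labels.n_regions:
        raise ValidationError(f"unknown region_id {region_id} (have 1..{labels.n_regions})")
    if labels.shape != (restored.height, restored.width):
        raise ValidationError("label map and image shapes differ")
    region = labels.pixels == region_id
    rows = np.flatnonzero(region.any(axis=1))
    cols = np.flatnonzero(region.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    sub_mask = region[r0:r1, c0:c1]
    gray = np.where(sub_mask, restored.red[r0:r1, c0:c1], 0).astype(np.uint8)
    return RegionPatch(
        region_id=region_id,
        bbox=(r0, c0, r1, c1),
        gray=gray,
        mask=sub_mask,
        area=int(sub_mask.sum()),
    )


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly bin 8-bit values into ``levels`` equal-width bins.

    q = floor(v * levels / 256), so 0 -> 0 and 255 -> levels - 1.
    """
    if levels < 2:
        raise ValidationError("levels must be >= 2")
    g = np.asarray(gray)
    if g.min() < 0 or g.max() > 255:
        raise ValidationError("quantize expects 8-bit values")
    return (g.astype(np.int64) * levels) // 256


def glcm(
    qpatch: np.ndarray,
    offset: tuple[int, int],
    levels: int,
    mask: np.ndarray | None = None,
    symmetric: bool = True,
    normalize: bool = True,
) -> Glcm:
    """Co-occurrence matrix of ordered level pairs at a fixed pixel offset.

    ``matrix[a, b]`` counts pairs (value a at p, value b at p + offset) over
    all positions p with both endpoints inside the patch rectangle (and, if
    ``mask`` is given, inside the region).  With ``symmetric`` both orderings
    are counted; with ``normalize`` entries sum to one.  A patch with no
    valid pair yields a degenerate uniform matrix.
    """
    q = np.asarray(qpatch)
    if q.ndim != 2:
        raise ValidationError("quantized patch must be 2-D")
    dr, dc = offset
    if dr == 0 and dc == 0:
        raise ValidationError("offset magnitude must be >= 1")
    H, W = q.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r0 >= r1 or c0 >= c1:
        uniform = np.full((levels, levels), 1.0 / (levels * levels))
        return Glcm(uniform, levels, (dr, dc), normalized=True, degenerate=True)
    a = q[r0:r1, c0:c1]
    b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        valid = m[r0:r1, c0:c1] & m[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        a, b = a[valid], b[valid]
        if a.size == 0:
            uniform = np.full((levels, levels), 1.0 / (levels * levels))
            return Glcm(uniform, levels, (dr, dc), normalized=True, degenerate=True)
    counts = np.bincount(
        (a.ravel() * levels + b.ravel()).astype(np.int64), minlength=levels * levels
    ).reshape(levels, levels).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    if normalize:
        counts = counts / counts.sum()
    return Glcm(counts, levels, (dr, dc), normalized=normalize)


def _require_normalized(g: Glcm) -> np.ndarray:
    if not g.normalized:
        raise ValidationError("feature computation requires a normalized GLCM")
    p = g.matrix
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValidationError("normalized GLCM entries must sum to 1")
    return p


def glcm_contrast(g: Glcm) -> float:
    """Moment of squared level difference: sum (a-b)^2 p(a,b)."""
    p = _require_normalized(g)
    idx = np.arange(g.levels)
    diff2 = (idx[:, None] - idx[None, :]) ** 2
    return float((diff2 * p).sum())


def glcm_entropy(g: Glcm, log_base: float = 2) -> float:
    """Shannon entropy of the co-occurrence distribution over nonzero entries."""
    p = _require_normalized(g)
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(log_base))).sum())


def glcm_correlation(g: Glcm) -> float:
    """Normalized covariance of the marginal level distributions, in [-1, 1].

    Zero marginal variance (a single occupied level) is degenerate and maps
    to 0 by convention.
    """
    p = _require_normalized(g)
    idx = np.arange(g.levels, dtype=np.float64)
    pr = p.sum(axis=1)
    pc = p.sum(axis=0)
    mu_r = float(idx @ pr)
    mu_c = float(idx @ pc)
    var_r = float(((idx - mu_r) ** 2) @ pr)
    var_c = float(((idx - mu_c) ** 2) @ pc)
    if var_r <= 0 or var_c <= 0:
        return 0.0
    cov = float(((idx[:, None] - mu_r) * (idx[None, :] - mu_c) * p).sum())
    return cov / np.sqrt(var_r * var_c)


def region_features(patch: RegionPatch, cfg: RunConfig | None = None) -> TextureFeatures:
    """Compute the three features per direction and their arithmetic means.

    If any configured direction admits no co-occurring pair (single-pixel or
    sliver regions), the region is flagged degenerate and all features are
    zero so downstream classification can skip it.
    """
    cfg = cfg or RunConfig()
    q = quantize(patch.gray, cfg.glcm_levels)
    mask = patch.mask if cfg.glcm_masked_pairs else None
    per_direction: dict[int, tuple[float, float, float]] = {}
    degenerate = False
    for angle in cfg.glcm_angles:
        g = glcm(q, angle_offset(angle, cfg.glcm_distance), cfg.glcm_levels, mask=mask)
        if g.degenerate:
            degenerate = True
            break
        per_direction[angle] = (
            glcm_contrast(g),
            glcm_entropy(g, cfg.entropy_log_base),
            glcm_correlation(g),
        )
    if degenerate:
        return TextureFeatures(patch.region_id, 0.0, 0.0, 0.0, {}, True)
    triples = np.asarray([per_direction[a] for a in cfg.glcm_angles])
    means = triples.mean(axis=0)
    return TextureFeatures(
        region_id=patch.region_id,
        contrast=float(means[0]),
        entropy=float(means[1]),
        correlation=float(means[2]),
        per_direction=per_direction,
        degenerate=False,
    )


def extract_features(pre: PreprocessResult, cfg: RunConfig | None = None) -> list[TextureFeatures]:
    """Texture features for every labeled region of a preprocessed image."""
    cfg = cfg or RunConfig()
    out = []
    for rid in range(1, pre.labels.n_regions + 1):
        patch = crop_min_bounding_rect(pre.labels, pre.restored, rid)
        out.append(region_features(patch, cfg))
    return out


def features_frame(
    pre: PreprocessResult,
    feats: list[TextureFeatures],
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """One row per region: id, bbox, area, per-direction and averaged features."""
    cfg = cfg or RunConfig()
    rows = []
    for f in feats:
        patch = crop_min_bounding_rect(pre.labels, pre.restored, f.region_id)
        row: dict[str, object] = {
            "region_id": f.region_id,
            "r0": patch.bbox[0], "c0": patch.bbox[1],
            "r1": patch.bbox[2], "c1": patch.bbox[3],
            "area": patch.area,
            "contrast": f.contrast,
            "entropy": f.entropy,
            "correlation": f.correlation,
            "degenerate": f.degenerate,
        }
        for angle in cfg.glcm_angles:
            c, e, r = f.per_direction.get(angle, (np.nan, np.nan, np.nan))
            row[f"contrast_{angle}"] = c
            row[f"entropy_{angle}"] = e
            row[f"correlation_{angle}"] = r
        rows.append(row)
    columns = (
        ["region_id", "r0", "c0", "r1", "c1", "area",
         "contrast", "entropy", "correlation", "degenerate"]
        + [f"{name}_{angle}" for angle in cfg.glcm_angles
           for name in ("contrast", "entropy", "correlation")]
    )
    return pd.DataFrame(rows, columns=columns)
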