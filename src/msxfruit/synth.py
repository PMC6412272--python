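"""Synthetic MSX-like orchard scenes with exact ground truth.

The generator emulates the statistical structure of warm-palette
pseudo-color orchard images so that every pipeline stage is testable with
known truth: smooth, warm (high-red) elliptical fruit with gentle radial
shading on a rough, cool background; dark branch-like strips that occlude
fruit; and, as the characteristic confounder, a sun-warmed soil patch whose
color matches fruit but whose surface is rough.  It models image
appearance only — the underlying thermal physics (fruit cooling more slowly
than foliage, soil staying fruit-warm) enters solely as the color and
texture contrasts it produces.

Scene annotations follow the field protocol: a fruit is *incomplete* when
any of it is hidden (branch/leaf occlusion or overlap with another fruit)
and *non-target* when more than 60% of its area is occluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .io_images import BinaryMask, LabelMap, MsxImage, RunConfig, ValidationError
from .preprocess import preprocess_pipeline
from .texture import extract_features, features_frame

__all__ = [
    "SynthConfig",
    "FruitAnnotation",
    "SynthScene",
    "generate_scene",
    "scene_ground_truth",
    "generate_training_set",
]

NON_TARGET_OCCLUSION = 0.6  # occluded fraction above which a fruit is non-target


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic scene generator.

    Defaults reproduce the study conditions: 400 x 300 rasters, 2-10 fruit
    per scene, warm smooth fruit vs. cool rough background, branch
    occluders, and one fruit-colored rough soil patch.  Intensities are
    8-bit display values, lengths are pixels at the 400 x 300 scale.
    """

    image_size: tuple[int, int] = (300, 400)  # (H, W)
    n_fruit: tuple[int, int] = (2, 10)        # inclusive range per scene
    fruit_axis_px: tuple[int, int] = (14, 32)  # semi-axis range
    fruit_center_red: tuple[int, int] = (232, 252)  # red at fruit center
    fruit_edge_red: tuple[int, int] = (168, 188)    # red at fruit rim
    fruit_shading_amp: float = 4.0     # amplitude of smooth within-fruit noise
    background_red: tuple[int, int] = (45, 70)      # cool background red base
    background_roughness: float = 22.0  # amplitude of blocky background texture
    background_corr_px: int = 3        # background texture correlation length
    occluder_density: float = 0.8      # expected branch strips per fruit
    occluder_width_px: tuple[int, int] = (3, 7)
    soil_enabled: bool = True
    soil_tones: tuple[int, int] = (136, 248)  # two-tone rough warm-palette reds
    soil_corr_px: int = 1
    soil_axis_px: tuple[int, int] = (16, 34)
    noise_sigma: float = 2.0           # global Gaussian pixel noise
    edge_prob: float = 0.1             # chance a fruit may straddle the border
    seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.image_size
        if H < 1 or W < 1:
            raise ValidationError("image_size must be positive")
        if self.n_fruit[0] < 0 or self.n_fruit[1] < self.n_fruit[0]:
            raise ValidationError("n_fruit must be a non-empty non-negative range")
        if 2 * self.fruit_axis_px[1] >= min(H, W):
            raise ValidationError("fruit axes too large for the image")
        if self.soil_enabled and 2 * self.soil_axis_px[1] >= min(H, W):
            raise ValidationError("soil patch too large for the image")
        for name in ("fruit_axis_px", "occluder_width_px", "soil_axis_px"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValidationError(f"{name} must be an increasing positive range")
        for name in ("fruit_center_red", "fruit_edge_red", "background_red", "soil_tones"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= 255 and 0 <= hi <= 255):
                raise ValidationError(f"{name} must lie in [0, 255]")
        # warm fruit vs. cool background contrast margin
        if min(self.fruit_edge_red) <= max(self.background_red) + self.background_roughness:
            raise ValidationError(
                "fruit red must exceed background red by more than the roughness amplitude"
            )


@dataclass(frozen=True)
class FruitAnnotation:
    """Ground-truth annotation for one generated fruit."""

    fruit_id: int
    occluded_fraction: float
    overlap: bool
    category: str  # "complete" | "incomplete"
    target: bool


@dataclass(frozen=True, eq=False)
class SynthScene:
    """A generated scene: image, ground-truth masks, and annotations."""

    image: MsxImage
    fruit_mask: BinaryMask                 # union of visible fruit pixels
    per_fruit_masks: tuple[BinaryMask, ...]  # visible pixels of each fruit
    annotations: tuple[FruitAnnotation, ...]
    confounder_mask: BinaryMask            # visible soil-patch pixels
    seed: int


def _blocky_noise(rng: np.random.Generator, shape: tuple[int, int], corr: int) -> np.ndarray:
    """Uniform [0,1) noise with a blocky correlation length of ``corr`` px."""
    if corr <= 1:
        return rng.random(shape)
    H, W = shape
    coarse = rng.random((math.ceil(H / corr), math.ceil(W / corr)))
    return np.kron(coarse, np.ones((corr, corr)))[:H, :W]


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float], axes: tuple[float, float], theta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean ellipse mask and the normalized radius field (0 center, 1 rim)."""
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    u = dr * math.cos(theta) + dc * math.sin(theta)
    v = -dr * math.sin(theta) + dc * math.cos(theta)
    radius2 = (u / axes[0]) ** 2 + (v / axes[1]) ** 2
    return radius2 <= 1.0, np.sqrt(np.clip(radius2, 0.0, 1.0))


def generate_scene(cfg: SynthConfig | None = None, seed: int | None = None) -> SynthScene:
    """Draw one scene; fully deterministic given the seed.

    Composition order: rough cool background, soil confounder, fruit
    (later fruit occlude earlier ones), branch strips on top, then global
    Gaussian pixel noise clipped to [0, 255].
    """
    cfg = cfg or SynthConfig()
    scene_seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(scene_seed)
    H, W = cfg.image_size

    # --- background: cool palette, rough surface -------------------------
    base_red = rng.uniform(*cfg.background_red)
    rough = _blocky_noise(rng, (H, W), cfg.background_corr_px)
    red = base_red + cfg.background_roughness * (rough - 0.5) * 2.0
    green = 85.0 + 45.0 * _blocky_noise(rng, (H, W), cfg.background_corr_px)
    blue = 150.0 + 70.0 * _blocky_noise(rng, (H, W), cfg.background_corr_px)

    # --- fruit geometry: warm smooth ellipses, sampled first -------------
    n_fruit = int(rng.integers(cfg.n_fruit[0], cfg.n_fruit[1] + 1))
    shading = gaussian_filter(rng.standard_normal((H, W)), 3.0) * cfg.fruit_shading_amp
    ellipses: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    for _ in range(n_fruit):
        a = rng.uniform(*cfg.fruit_axis_px)
        b = rng.uniform(*cfg.fruit_axis_px)
        m = max(a, b)
        if rng.random() < cfg.edge_prob:
            center = (rng.uniform(0, H), rng.uniform(0, W))
        else:
            center = (rng.uniform(m, H - m), rng.uniform(m, W - m))
        geom, rad = _ellipse_mask((H, W), center, (a, b), rng.uniform(0, math.pi))
        ellipses.append(geom)
        radii.append(rad)
    fruit_geom_union = np.zeros((H, W), dtype=bool)
    for geom in ellipses:
        fruit_geom_union |= geom

    # --- soil confounder: fruit-like color, rough two-tone texture ------
    # placed clear of the canopy fruit (ground vs. canopy), by rejection
    soil_geom = np.zeros((H, W), dtype=bool)
    if cfg.soil_enabled:
        margin = cfg.soil_axis_px[1]
        for _ in range(20):
            center = (rng.uniform(margin, H - margin), rng.uniform(margin, W - margin))
            axes = (rng.uniform(*cfg.soil_axis_px), rng.uniform(*cfg.soil_axis_px))
            theta = rng.uniform(0, math.pi)
            candidate, _ = _ellipse_mask((H, W), center, axes, theta)
            grown, _ = _ellipse_mask((H, W), center, (axes[0] + 4, axes[1] + 4), theta)
            if not (grown & fruit_geom_union).any():
                soil_geom = candidate
                break
        lo, hi = cfg.soil_tones
        tone = np.where(_blocky_noise(rng, (H, W), cfg.soil_corr_px) > 0.5, float(hi), float(lo))
        red[soil_geom] = tone[soil_geom]
        green[soil_geom] = 0.52 * tone[soil_geom]
        blue[soil_geom] = 35.0

    # --- paint fruit over background and soil -----------------------------
    for geom, rad in zip(ellipses, radii):
        c_red = rng.uniform(*cfg.fruit_center_red)
        e_red = rng.uniform(*cfg.fruit_edge_red)
        fruit_red = c_red - (c_red - e_red) * rad + shading
        red[geom] = fruit_red[geom]
        green[geom] = 0.55 * fruit_red[geom] + 10.0
        blue[geom] = 30.0

    # --- branch-like occluder strips -------------------------------------
    occluder = np.zeros((H, W), dtype=bool)
    if n_fruit > 0 and cfg.occluder_density > 0:
        n_strips = int(rng.poisson(cfg.occluder_density * n_fruit))
        rr, cc = np.mgrid[0:H, 0:W].astype(np.float64)
        for _ in range(n_strips):
            k = int(rng.integers(n_fruit))
            target = ellipses[k]
            if not target.any():
                continue
            pts = np.argwhere(target)
            p = pts[rng.integers(len(pts))].astype(np.float64)
            phi = rng.uniform(0, math.pi)
            width = rng.integers(cfg.occluder_width_px[0], cfg.occluder_width_px[1] + 1)
            # signed distance to the line through p with direction phi
            d = np.abs(-(rr - p[0]) * math.sin(phi) + (cc - p[1]) * math.cos(phi))
            reach = np.hypot(rr - p[0], cc - p[1]) <= 2.2 * max(cfg.fruit_axis_px)
            occluder |= (d <= width / 2.0) & reach
        red[occluder] = 55.0 + 18.0 * _blocky_noise(rng, (H, W), 2)[occluder]
        green[occluder] = 72.0
        blue[occluder] = 58.0

    # --- compose, add noise ----------------------------------------------
    img = np.stack([red, green, blue], axis=2)
    if cfg.noise_sigma > 0:
        img = img + rng.normal(0.0, cfg.noise_sigma, img.shape)
    image = MsxImage(np.clip(img, 0, 255).astype(np.uint8))

    # --- ground truth -----------------------------------------------------
    visible: list[np.ndarray] = []
    annotations: list[FruitAnnotation] = []
    for i, geom in enumerate(ellipses):
        in_front = np.zeros((H, W), dtype=bool)
        for j in range(i + 1, n_fruit):
            in_front |= ellipses[j]
        vis = geom & ~in_front & ~occluder
        visible.append(vis)
        area = int(geom.sum())
        occluded = float((geom & occluder).sum() / area) if area else 1.0
        overlap = any(
            j != i and (geom & ellipses[j]).any() for j in range(n_fruit)
        )
        incomplete = occluded > 0 or overlap
        annotations.append(
            FruitAnnotation(
                fruit_id=i + 1,
                occluded_fraction=occluded,
                overlap=overlap,
                category="incomplete" if incomplete else "complete",
                target=occluded <= NON_TARGET_OCCLUSION,
            )
        )
    fruit_union = np.zeros((H, W), dtype=bool)
    for vis in visible:
        fruit_union |= vis
    soil_visible = soil_geom.copy()
    for geom in ellipses:
        soil_visible &= ~geom
    soil_visible &= ~occluder

    return SynthScene(
        image=image,
        fruit_mask=BinaryMask(fruit_union),
        per_fruit_masks=tuple(BinaryMask(v) for v in visible),
        annotations=tuple(annotations),
        confounder_mask=BinaryMask(soil_visible),
        seed=scene_seed,
    )


def scene_ground_truth(
    scene: SynthScene, include_nontarget: bool = False
) -> tuple[LabelMap, dict[int, str], BinaryMask]:
    """Manual-segmentation stand-in: per-fruit label map plus categories.

    Fruit with no visible pixels are dropped so labels stay contiguous.
    Non-target fruit (occluded beyond the 60% rule) are excluded from the
    label map unless requested; their visible pixels are returned as the
    third element so callers can remove them from predictions before
    scoring, mirroring the protocol in which such fruit are not evaluated.
    """
    H, W = scene.fruit_mask.shape
    label_px = np.zeros((H, W), dtype=np.int32)
    categories: dict[int, str] = {}
    excluded = np.zeros((H, W), dtype=bool)
    next_id = 1
    for mask, ann in zip(scene.per_fruit_masks, scene.annotations):
        if not mask.pixels.any():
            continue
        if not ann.target and not include_nontarget:
            excluded |= mask.pixels
            continue
        label_px[mask.pixels] = next_id
        categories[next_id] = ann.category
        next_id += 1
    return LabelMap(label_px, n_regions=next_id - 1), categories, BinaryMask(excluded)


def annotations_frame(scenes: list[SynthScene]) -> pd.DataFrame:
    """Flat annotation table (one row per fruit) for a list of scenes."""
    rows = []
    for s_idx, scene in enumerate(scenes):
        for ann in scene.annotations:
            rows.append(
                {
                    "scene": s_idx,
                    "fruit_id": ann.fruit_id,
                    "occluded_fraction": ann.occluded_fraction,
                    "overlap": ann.overlap,
                    "category": ann.category,
                    "target": ann.target,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["scene", "fruit_id", "occluded_fraction", "overlap", "category", "target"],
    )


def generate_training_set(
    cfg: SynthConfig | None = None,
    n_scenes: int = 100,
    run_cfg: RunConfig | None = None,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features and labels for the regions of ``n_scenes`` generated scenes.

    Each scene is preprocessed, its regions' texture features extracted, and
    each region tagged -1 (fruit) when the majority of its pixels lie on
    ground-truth fruit, else +1.  Returns (features, labels) tables keyed by
    (scene, region_id).
    """
    if n_scenes < 1:
        raise ValidationError("n_scenes must be >= 1")
    cfg = cfg or SynthConfig()
    run_cfg = run_cfg or RunConfig()
    master = np.random.default_rng(cfg.seed if seed is None else seed)
    scene_seeds = master.integers(0, 2**31, size=n_scenes)
    feat_frames = []
    label_rows = []
    for s_idx, s_seed in enumerate(scene_seeds):
        scene = generate_scene(cfg, seed=int(s_seed))
        pre = preprocess_pipeline(scene.image, run_cfg)
        feats = extract_features(pre, run_cfg)
        df = features_frame(pre, feats, run_cfg)
        df.insert(0, "scene", s_idx)
        feat_frames.append(df)
        for rid in range(1, pre.labels.n_regions + 1):
            region = pre.labels.pixels == rid
            frac = float((region & scene.fruit_mask.pixels).sum() / region.sum())
            label_rows.append(
                {"scene": s_idx, "region_id": rid, "label": -1 if frac > 0.5 else 1}
            )
    features = pd.concat(feat_frames, ignore_index=True) if feat_frames else pd.DataFrame()
    labels = pd.DataFrame(label_rows, columns=["scene", "region_id", "label"])
    return features, labels
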