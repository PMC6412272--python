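"""Region-overlap evaluation of predicted vs. manual fruit masks.

A predicted mask is compared with a manually delineated ground-truth mask
by partitioning the image into four pixel sets: correct detections inside
the manual region (Sic), manual pixels that were missed (Sil, leakage),
detections outside any manual region (Soo, over-segmentation) and the
correctly untouched remainder (Soc).  Three ratios summarize the overlap:

    RP = Sic / (Sic + Soo)        recognition precision
    RS = Sic / (Sic + Sil)        recognition sensitivity
    RE = (Soo + Sil) / (Sic + Sil)  relative error

Per-region reporting attributes every predicted pixel to a manual region —
its own if it lies inside one, otherwise the nearest (Euclidean distance,
ties to the lower region id) — and averages metrics within the complete /
incomplete fruit strata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io_images import BinaryMask, LabelMap, ValidationError

__all__ = [
    "EvalCounts",
    "Metrics",
    "RegionVerdict",
    "overlap_counts",
    "metrics",
    "attribute_predictions",
    "region_verdicts",
    "evaluate_dataset",
    "MIN_MANUAL_REGION_AREA",
]

# manual regions smaller than this many pixels are not evaluated: a human
# annotator does not delineate a few-pixel sliver
MIN_MANUAL_REGION_AREA = 16


@dataclass(frozen=True)
class EvalCounts:
    """Pixel counts of the four overlap categories; they partition the image."""

    s_ic: int  # correct inside the manual region
    s_il: int  # leakage: manual pixels missed
    s_oc: int  # correct outside: neither manual nor detected
    s_oo: int  # over-segmentation: detected outside the manual region

    def __post_init__(self) -> None:
        if min(self.s_ic, self.s_il, self.s_oc, self.s_oo) < 0:
            raise ValidationError("overlap counts must be non-negative")

    @property
    def total(self) -> int:
        return self.s_ic + self.s_il + self.s_oc + self.s_oo


@dataclass(frozen=True)
class Metrics:
    """RP / RS / RE ratios; ``rp_defined`` is False when nothing was detected."""

    rp: float
    rs: float
    re: float
    rp_defined: bool = True


@dataclass(frozen=True)
class RegionVerdict:
    """Counts and metrics for one manual region, with its stratum."""

    manual_region_id: int
    category: str  # "complete" | "incomplete"
    counts: EvalCounts
    metrics: Metrics


def overlap_counts(pred: BinaryMask, manual: BinaryMask) -> EvalCounts:
    """Tally the four overlap categories between prediction and ground truth."""
    if pred.shape != manual.shape:
        raise ValidationError(f"mask shapes differ: {pred.shape} vs {manual.shape}")
    p, m = pred.pixels, manual.pixels
    return EvalCounts(
        s_ic=int(np.count_nonzero(p & m)),
        s_il=int(np.count_nonzero(~p & m)),
        s_oc=int(np.count_nonzero(~p & ~m)),
        s_oo=int(np.count_nonzero(p & ~m)),
    )


def metrics(c: EvalCounts) -> Metrics:
    """RP, RS, RE from the overlap counts.

    Requires a non-empty manual region (Sic + Sil > 0).  When nothing was
    detected at all (Sic + Soo = 0) RP is 0 by convention and flagged.
    """
    denom_manual = c.s_ic + c.s_il
    if denom_manual == 0:
        raise ValidationError("empty manual mask: no ground truth to evaluate")
    denom_pred = c.s_ic + c.s_oo
    if denom_pred == 0:
        rp, rp_defined = 0.0, False
    else:
        rp, rp_defined = c.s_ic / denom_pred, True
    rs = c.s_ic / denom_manual
    re = (c.s_oo + c.s_il) / denom_manual
    return Metrics(rp=rp, rs=rs, re=re, rp_defined=rp_defined)


def attribute_predictions(manual: LabelMap) -> np.ndarray:
    """Assign every pixel to a manual region: its own, else the nearest.

    Nearest by Euclidean distance to the region's support; ties go to the
    lower region id.  Returns an HxW array of region ids (all zero when the
    label map has no regions).
    """
    n = manual.n_regions
    if n == 0:
        return np.zeros(manual.shape, dtype=np.int32)
    dist = np.empty((n,) + manual.shape)
    for rid in range(1, n + 1):
        dist[rid - 1] = ndi.distance_transform_edt(manual.pixels != rid)
    # argmin returns the first (lowest-id) region on ties
    return (np.argmin(dist, axis=0) + 1).astype(np.int32)


def region_verdicts(
    pred: BinaryMask,
    manual: LabelMap,
    categories: dict[int, str],
    min_area: int = MIN_MANUAL_REGION_AREA,
) -> list[RegionVerdict]:
    """Per-region overlap metrics with nearest-region attribution.

    ``categories`` maps each manual region id to "complete" or "incomplete".
    Manual regions smaller than ``min_area`` pixels are skipped.
    """
    if pred.shape != manual.shape:
        raise ValidationError("prediction and manual label map shapes differ")
    for rid in range(1, manual.n_regions + 1):
        if rid not in categories:
            raise ValidationError(f"missing category annotation for manual region {rid}")
        if categories[rid] not in ("complete", "incomplete"):
            raise ValidationError(f"invalid category {categories[rid]!r} for region {rid}")
    assign = attribute_predictions(manual)
    total = pred.pixels.size
    out = []
    for rid in range(1, manual.n_regions + 1):
        support = manual.pixels == rid
        n_manual = int(support.sum())
        if n_manual < min_area:
            continue
        assigned_pred = pred.pixels & (assign == rid)
        s_ic = int(np.count_nonzero(assigned_pred & support))
        s_il = n_manual - int(np.count_nonzero(pred.pixels & support))
        s_oo = int(np.count_nonzero(assigned_pred & ~support))
        counts = EvalCounts(
            s_ic=s_ic, s_il=s_il, s_oo=s_oo, s_oc=total - s_ic - s_il - s_oo
        )
        out.append(
            RegionVerdict(
                manual_region_id=rid,
                category=categories[rid],
                counts=counts,
                metrics=metrics(counts),
            )
        )
    return out


def _stratum_summary(verdicts: list[RegionVerdict], category: str) -> dict:
    vs = [v for v in verdicts if v.category == category]
    if not vs:
        return {"n_regions": 0, "rp": None, "rs": None, "re": None}
    return {
        "n_regions": len(vs),
        "rp": float(np.mean([v.metrics.rp for v in vs])),
        "rs": float(np.mean([v.metrics.rs for v in vs])),
        "re": float(np.mean([v.metrics.re for v in vs])),
    }


def evaluate_dataset(
    items: list[tuple[BinaryMask, LabelMap, dict[int, str]]],
    pooling: str = "region",
    min_area: int = MIN_MANUAL_REGION_AREA,
) -> dict:
    """Stratified report over (prediction, manual label map, categories) pairs.

    With ``pooling="region"`` (default) metrics are unweighted arithmetic
    means over manual regions within each stratum; with ``pooling="image"``
    the overlap counts of each image's regions are pooled per stratum before
    forming ratios, and each image contributes one metric triple.
    """
    if pooling not in ("region", "image"):
        raise ValidationError("pooling must be 'region' or 'image'")
    all_verdicts: list[RegionVerdict] = []
    per_image: list[dict[str, EvalCounts]] = []
    for pred, manual, categories in items:
        verdicts = region_verdicts(pred, manual, categories, min_area=min_area)
        all_verdicts.extend(verdicts)
        pooled: dict[str, EvalCounts] = {}
        for cat in ("complete", "incomplete"):
            vs = [v for v in verdicts if v.category == cat]
            if vs:
                pooled[cat] = EvalCounts(
                    s_ic=sum(v.counts.s_ic for v in vs),
                    s_il=sum(v.counts.s_il for v in vs),
                    s_oc=sum(v.counts.s_oc for v in vs),
                    s_oo=sum(v.counts.s_oo for v in vs),
                )
        per_image.append(pooled)

    report: dict = {"pooling": pooling, "strata": {}}
    if pooling == "region":
        for cat in ("complete", "incomplete"):
            report["strata"][cat] = _stratum_summary(all_verdicts, cat)
        if all_verdicts:
            report["overall"] = {
                "n_regions": len(all_verdicts),
                "rp": float(np.mean([v.metrics.rp for v in all_verdicts])),
                "rs": float(np.mean([v.metrics.rs for v in all_verdicts])),
                "re": float(np.mean([v.metrics.re for v in all_verdicts])),
            }
        else:
            report["overall"] = {"n_regions": 0, "rp": None, "rs": None, "re": None}
    else:
        for cat in ("complete", "incomplete"):
            ms = [metrics(img[cat]) for img in per_image if cat in img]
            n_regions = sum(
                1 for v in all_verdicts if v.category == cat
            )
            if ms:
                report["strata"][cat] = {
                    "n_regions": n_regions,
                    "n_images": len(ms),
                    "rp": float(np.mean([m.rp for m in ms])),
                    "rs": float(np.mean([m.rs for m in ms])),
                    "re": float(np.mean([m.re for m in ms])),
                }
            else:
                report["strata"][cat] = {"n_regions": 0, "n_images": 0,
                                         "rp": None, "rs": None, "re": None}
        report["overall"] = {"n_regions": len(all_verdicts)}
    return report
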