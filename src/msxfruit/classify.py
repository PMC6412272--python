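"""Linear max-margin classification of regions by texture.

The decision function is f(x) = sign(w . x~ + b) where x~ is the
standardized feature vector; the label convention is -1 = fruit region,
+1 = non-fruit region.  The separator is the maximum-margin hyperplane:
a hard margin when the classes are linearly separable, realized as a soft
margin with a large fixed penalty (C = 1e4) so near-separable data remain
tractable.  Features are standardized to zero mean / unit spread before
optimization because contrast and entropy live on very different scales;
the affine parameters are stored in the model so raw-scale prediction is
invariant to rescaling of the training features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io_images import BinaryMask, LabelMap, MsxImage, RunConfig, ValidationError
from .preprocess import PreprocessResult, preprocess_pipeline
from .texture import TextureFeatures, extract_features, features_frame

__all__ = [
    "FRUIT",
    "NON_FRUIT",
    "LinearClassifier",
    "train",
    "predict",
    "classify_regions",
    "assemble_fruit_mask",
    "DetectionResult",
    "detect",
]

FRUIT = -1      # class tag of fruit regions
NON_FRUIT = 1   # class tag of non-fruit regions

PENALTY = 1e4   # margin-violation penalty; effectively hard-margin when separable


@dataclass(frozen=True)
class LinearClassifier:
    """Weights and bias of the max-margin separator on standardized features."""

    weights: tuple[float, ...]
    bias: float
    feature_order: tuple[str, ...]
    scale_mean: tuple[float, ...]
    scale_std: tuple[float, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.feature_order):
            raise ValidationError("weights dimension must match feature dimension")
        if len(self.scale_mean) != len(self.weights) or len(self.scale_std) != len(self.weights):
            raise ValidationError("scaling dimension must match feature dimension")
        if any(s == 0 for s in self.scale_std):
            raise ValidationError("scaling must be invertible (nonzero spreads)")

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - np.asarray(self.scale_mean)) / np.asarray(
            self.scale_std
        )

    def decision(self, x: np.ndarray) -> float:
        """w . x~ + b on the standardized feature vector."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (len(self.weights),):
            raise ValidationError(
                f"feature vector of dimension {x.shape} does not match model "
                f"dimension {len(self.weights)}"
            )
        if not np.all(np.isfinite(x)):
            raise ValidationError("feature vector contains non-finite values")
        return float(np.dot(self.weights, self.standardize(x)) + self.bias)

    def save(self, path: str | Path) -> None:
        data = {
            "feature_order": list(self.feature_order),
            "weights": list(self.weights),
            "bias": self.bias,
            "scale_mean": list(self.scale_mean),
            "scale_std": list(self.scale_std),
            "meta": self.meta,
        }
        Path(path).write_text(json.dumps(data, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "LinearClassifier":
        data = json.loads(Path(path).read_text())
        return cls(
            weights=tuple(data["weights"]),
            bias=float(data["bias"]),
            feature_order=tuple(data["feature_order"]),
            scale_mean=tuple(data["scale_mean"]),
            scale_std=tuple(data["scale_std"]),
            meta=data.get("meta", {}),
        )


def _as_matrix(features, feature_order) -> np.ndarray:
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("features must form an n x d matrix")
    if X.shape[1] != len(feature_order):
        raise ValidationError(
            f"feature dimension {X.shape[1]} does not match feature_order {feature_order}"
        )
    if not np.all(np.isfinite(X)):
        raise ValidationError("features contain non-finite values")
    return X


def train(
    features,
    labels,
    cfg: RunConfig | None = None,
    feature_order: tuple[str, ...] | None = None,
) -> LinearClassifier:
    """Fit the maximum-margin linear separator on standardized features.

    ``features`` is an n x d array ordered like ``feature_order`` (defaults
    to the config's feature set); ``labels`` are -1 / +1 region tags with at
    least one example of each class.  On linearly separable data the fit
    attains 100% training accuracy and every point satisfies the margin
    condition; otherwise the large fixed penalty trades margin violations
    for margin width instead of failing.
    """
    cfg = cfg or RunConfig()
    order = tuple(feature_order) if feature_order is not None else tuple(cfg.feature_set)
    X = _as_matrix(features, order)
    y = np.asarray(labels, dtype=np.int64)
    if y.shape != (X.shape[0],):
        raise ValidationError("labels must match the number of feature rows")
    if not set(np.unique(y)) <= {FRUIT, NON_FRUIT}:
        raise ValidationError("labels must be -1 (fruit) or +1 (non-fruit)")
    if np.unique(y).size < 2:
        raise ValidationError("training requires at least one example of each class")

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std == 0, 1.0, std)  # constant feature: carry through unscaled
    Xs = (X - mean) / std

    # tight tolerance so support vectors sit on the margin to ~1e-6
    svm = SVC(kernel="linear", C=PENALTY, tol=1e-8)
    svm.fit(Xs, y)
    # classes_ is sorted [-1, +1]; decision_function > 0 predicts +1
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    train_pred = np.where(Xs @ w + b > 0, NON_FRUIT, FRUIT)
    accuracy = float((train_pred == y).mean())
    return LinearClassifier(
        weights=tuple(float(v) for v in w),
        bias=b,
        feature_order=order,
        scale_mean=tuple(float(v) for v in mean),
        scale_std=tuple(float(v) for v in std),
        meta={
            "n_train": int(X.shape[0]),
            "n_fruit": int((y == FRUIT).sum()),
            "n_non_fruit": int((y == NON_FRUIT).sum()),
            "train_accuracy": accuracy,
            "penalty": PENALTY,
        },
    )


def predict(model: LinearClassifier, x) -> int:
    """sign(w . x~ + b) mapped to the region tag; sign(0) -> -1 (fruit)."""
    return NON_FRUIT if model.decision(x) > 0 else FRUIT


def classify_regions(
    features: pd.DataFrame | list[TextureFeatures],
    model: LinearClassifier,
) -> pd.DataFrame:
    """Label every region; degenerate regions are non-fruit without evaluation.

    Accepts a features table (as written by the ``features`` CLI subcommand)
    or a list of :class:`TextureFeatures`.  Returns a region_id -> label
    table with the decision values.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_order if c not in features.columns]
        if missing:
            raise ValidationError(f"features table lacks columns: {missing}")
        rows = [
            (int(r.region_id), bool(r.degenerate), tuple(getattr(r, c) for c in model.feature_order))
            for r in features.itertuples(index=False)
        ]
    else:
        rows = [
            (f.region_id, f.degenerate, tuple(getattr(f, c) for c in model.feature_order))
            for f in features
        ]
    out = []
    for region_id, degenerate, x in rows:
        if degenerate:
            out.append({"region_id": region_id, "label": NON_FRUIT, "decision": np.nan})
        else:
            d = model.decision(np.asarray(x))
            out.append({"region_id": region_id, "label": NON_FRUIT if d > 0 else FRUIT,
                        "decision": d})
    return pd.DataFrame(out, columns=["region_id", "label", "decision"])


def assemble_fruit_mask(labels: LabelMap, region_labels: pd.DataFrame) -> BinaryMask:
    """Union of the pixels of all regions tagged -1 (fruit)."""
    fruit_ids = region_labels.loc[region_labels["label"] == FRUIT, "region_id"].to_numpy()
    if fruit_ids.size == 0:
        return BinaryMask(np.zeros(labels.shape, dtype=bool))
    return BinaryMask(np.isin(labels.pixels, fruit_ids))


@dataclass(frozen=True, eq=False)
class DetectionResult:
    """Everything the end-to-end detector produces for one image."""

    preprocess: PreprocessResult
    features: pd.DataFrame
    region_labels: pd.DataFrame
    fruit_mask: BinaryMask


def detect(img: MsxImage, model: LinearClassifier, cfg: RunConfig | None = None) -> DetectionResult:
    """Full pipeline: preprocess -> texture features -> region classification."""
    cfg = cfg or RunConfig()
    pre = preprocess_pipeline(img, cfg)
    feats = extract_features(pre, cfg)
    table = features_frame(pre, feats, cfg)
    region_labels = classify_regions(feats, model)
    fruit_mask = assemble_fruit_mask(pre.labels, region_labels)
    return DetectionResult(
        preprocess=pre, features=table, region_labels=region_labels, fruit_mask=fruit_mask
    )
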