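"""Vessel segmentation: GFP pre-thresholding, random-forest pixel
classification and morphological cleanup.

The classifier follows the published workflow: a default (IsoData intermeans)
threshold binarizes the GFP endothelial channel, then a random forest with
200 trees is trained on sparse scribble labels over the joint feature bank of
the phase-contrast and binarized GFP channels.  Weka's batch size of 100 is a
prediction-batching detail, recorded as provenance only.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, FeatureStack
from .imaging import BinaryMask, CalibratedImage, ValidationError

__all__ = [
    "ScribbleLabels",
    "PixelClassifier",
    "isodata_threshold",
    "default_threshold",
    "train_pixel_classifier",
    "predict_mask",
    "morph_clean",
    "save_classifier",
    "load_classifier",
]

VESSEL = "vessel"
BACKGROUND = "background"

#: 3×3 cross structuring element used by all morphological cleanup
CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class ScribbleLabels:
    """Sparse user scribbles: vessel vs background (spheroid counts as
    background, matching the two-class training scheme)."""

    coordinates: np.ndarray  # (n, 2) row, col
    classes: np.ndarray      # (n,) strings in {vessel, background}
    image_id: str = ""

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=int)
        self.classes = np.asarray(self.classes, dtype=object)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 2:
            raise ValidationError("coordinates must be (n, 2) row/col pairs")
        if len(self.classes) != len(self.coordinates):
            raise ValidationError("classes must parallel coordinates")
        bad = set(self.classes) - {VESSEL, BACKGROUND}
        if bad:
            raise ValidationError(f"unknown scribble classes: {sorted(bad)}")

    def check_within(self, shape: tuple[int, int]) -> None:
        r, c = self.coordinates[:, 0], self.coordinates[:, 1]
        if (r < 0).any() or (c < 0).any() or (r >= shape[0]).any() or (c >= shape[1]).any():
            raise ValidationError("scribble coordinates outside image bounds")

    @classmethod
    def from_masks(
        cls,
        vessel_mask: np.ndarray,
        n_per_class: int,
        rng: np.random.Generator,
        background_mask: np.ndarray | None = None,
        image_id: str = "",
    ) -> "ScribbleLabels":
        """Sample scribbles from a reference mask (used on synthetic truth)."""
        vessel_mask = np.asarray(vessel_mask, dtype=bool)
        bg = ~vessel_mask if background_mask is None else np.asarray(background_mask, bool)
        coords, classes = [], []
        for mask, name in ((vessel_mask, VESSEL), (bg, BACKGROUND)):
            idx = np.flatnonzero(mask.ravel())
            if idx.size == 0:
                raise ValidationError(f"no pixels available for class {name!r}")
            take = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
            rr, cc = np.unravel_index(take, mask.shape)
            coords.append(np.column_stack([rr, cc]))
            classes += [name] * len(rr)
        return cls(np.vstack(coords), np.array(classes, dtype=object), image_id)


@dataclass
class PixelClassifier:
    """Trained random-forest pixel classifier with its feature contract."""

    n_trees: int
    feature_config: FeatureConfig
    random_seed: int
    fitted_model: RandomForestClassifier
    feature_names: list[str]
    training_summary: dict = field(default_factory=dict)
    batch_size: int = 100  # provenance only (Weka prediction batching)

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")


def isodata_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Iterative intermeans (IsoData) threshold.

    Builds an ``n_bins`` histogram over the value range and iterates
    ``t ← (mean below + mean above) / 2`` to its fixed point.  Foreground is
    *strictly above* the returned threshold, matching the ImageJ "default"
    convention used for the GFP channel.
    """
    values = np.asarray(values)
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        raise ValidationError("cannot threshold a constant image")
    hist, edges = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    centers = 0.5 * (edges[:-1] + edges[1:])
    csum = np.cumsum(hist)
    cmass = np.cumsum(hist * centers)
    total, mass = csum[-1], cmass[-1]

    def intermeans(k: int) -> float:
        # threshold between bin k and k+1
        n0 = csum[k]
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            return np.nan
        return 0.5 * (cmass[k] / n0 + (mass - cmass[k]) / n1)

    # start in the middle, iterate on the bin index
    k = n_bins // 2
    for _ in range(n_bins):
        t = intermeans(k)
        if np.isnan(t):
            k += 1 if csum[k] == 0 else -1
            continue
        k_new = int(np.searchsorted(centers, t, side="right") - 1)
        k_new = min(max(k_new, 0), n_bins - 2)
        if k_new == k:
            break
        k = k_new
    t = intermeans(k)
    return float(t)


def default_threshold(img: CalibratedImage) -> BinaryMask:
    """IsoData ("default") threshold of a channel; strictly-above foreground.

    A constant image yields an all-background mask with a warning — there is
    nothing detectable, which for a GFP channel means no vessels.
    """
    values = np.asarray(img.pixels)
    if float(values.min()) == float(values.max()):
        warnings.warn(
            "default_threshold: constant image, returning all-background mask",
            stacklevel=2,
        )
        return BinaryMask(
            np.zeros(values.shape, bool), img.pixel_size_um,
            provenance="default_threshold(constant)",
        )
    t = isodata_threshold(values)
    return BinaryMask(values > t, img.pixel_size_um,
                      provenance=f"default_threshold(t={t:.6g})")


def train_pixel_classifier(
    stack: FeatureStack,
    labels: ScribbleLabels,
    n_trees: int = 200,
    random_seed: int = 0,
    feature_config: FeatureConfig | None = None,
) -> PixelClassifier:
    """Fit the 200-tree random forest on scribbled pixels of a feature stack.

    Same seed and same inputs give identical models and therefore identical
    predicted masks.
    """
    labels.check_within(stack.image_shape)
    present = set(labels.classes)
    if present != {VESSEL, BACKGROUND}:
        raise ValidationError(
            f"training requires both classes, got {sorted(present)}"
        )
    X = stack.samples_at(labels.coordinates[:, 0], labels.coordinates[:, 1])
    y = labels.classes.astype(str)
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=random_seed,
        oob_score=True,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny scribble sets may lack OOB samples
        forest.fit(X, y)
    oob = float(getattr(forest, "oob_score_", np.nan))
    summary = {
        "n_vessel": int((y == VESSEL).sum()),
        "n_background": int((y == BACKGROUND).sum()),
        "oob_accuracy": oob,
        "train_accuracy": float((forest.predict(X) == y).mean()),
    }
    return PixelClassifier(
        n_trees=n_trees,
        feature_config=feature_config or FeatureConfig(),
        random_seed=random_seed,
        fitted_model=forest,
        feature_names=list(stack.names),
        training_summary=summary,
    )


def predict_mask(classifier: PixelClassifier, stack: FeatureStack) -> BinaryMask:
    """Per-pixel majority vote over the forest; returns the vessel mask.

    The stack is matched to the classifier by feature *names* (plane order is
    irrelevant); an exact probability tie (0.5) is resolved to background so
    vessel calls stay conservative.
    """
    if stack.names != classifier.feature_names:
        stack = stack.reordered(classifier.feature_names)
    proba = classifier.fitted_model.predict_proba(stack.as_samples())
    classes = list(classifier.fitted_model.classes_)
    if VESSEL not in classes:
        raise ValidationError("classifier was not trained with a vessel class")
    p_vessel = proba[:, classes.index(VESSEL)]
    mask = (p_vessel > 0.5).reshape(stack.image_shape)
    return BinaryMask(mask, stack.pixel_size_um,
                      provenance=f"predict_mask(n_trees={classifier.n_trees})")


def morph_clean(mask: BinaryMask, n_erosions: int = 1, n_dilations: int = 1) -> BinaryMask:
    """Erosion then dilation with the 3×3 cross element (an opening for the
    default 1+1), removing single-pixel speckle from the classifier output."""
    if n_erosions < 0 or n_dilations < 0:
        raise ValidationError("iteration counts must be >= 0")
    out = mask.pixels
    if n_erosions:
        out = ndimage.binary_erosion(out, structure=CROSS, iterations=n_erosions)
    if n_dilations:
        out = ndimage.binary_dilation(out, structure=CROSS, iterations=n_dilations)
    return BinaryMask(
        out, mask.pixel_size_um,
        provenance=f"{mask.provenance}+morph_clean({n_erosions},{n_dilations})",
    )


_FORMAT_VERSION = 1


def save_classifier(classifier: PixelClassifier, path: str | Path) -> None:
    """Persist the classifier with its feature contract and provenance."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "n_trees": classifier.n_trees,
        "batch_size": classifier.batch_size,
        "random_seed": classifier.random_seed,
        "feature_config": classifier.feature_config.to_dict(),
        "feature_names": classifier.feature_names,
        "training_summary": classifier.training_summary,
        "fitted_model": classifier.fitted_model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_classifier(
    path: str | Path, expect_feature_config: FeatureConfig | None = None
) -> PixelClassifier:
    """Load a persisted classifier; refuse on feature-config mismatch."""
    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValidationError(f"unsupported classifier file version in {path}")
    config = FeatureConfig.from_dict(payload["feature_config"])
    if expect_feature_config is not None and config != expect_feature_config:
        raise ValidationError(
            "classifier feature configuration does not match the requested one"
        )
    return PixelClassifier(
        n_trees=payload["n_trees"],
        feature_config=config,
        random_seed=payload["random_seed"],
        fitted_model=payload["fitted_model"],
        feature_names=list(payload["feature_names"]),
        training_summary=payload["training_summary"],
        batch_size=payload["batch_size"],
    )
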