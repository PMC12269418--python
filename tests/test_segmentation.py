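import numpy as np
import pytest

from mvnquant.features import FeatureConfig, compute_feature_stack
from mvnquant.imaging import BinaryMask, CalibratedImage, ValidationError
from mvnquant.segmentation import (
    ScribbleLabels,
    default_threshold,
    isodata_threshold,
    load_classifier,
    morph_clean,
    predict_mask,
    save_classifier,
    train_pixel_classifier,
)

SMALL_CONFIG = FeatureConfig(families=("gaussian_blur",), sigma_min=1.0, sigma_max=2.0)


def brute_force_isodata(values, n_bins=256):
    """Exhaustive fixed-point search of the intermeans criterion."""
    hist, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    best = None
    for k in range(n_bins - 1):
        n0, n1 = hist[: k + 1].sum(), hist[k + 1:].sum()
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (hist[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (hist[k + 1:] * centers[k + 1:]).sum() / n1
        t = 0.5 * (mu0 + mu1)
        if centers[k] <= t < centers[k + 1]:  # fixed point lands in its own bin
            best = t
            break
    return best


class TestIsoData:
    def test_two_level_image_converges_to_midpoint(self):
        values = np.array([50.0] * 100 + [200.0] * 100)
        assert isodata_threshold(values) == pytest.approx(125.0, abs=1.0)
        img = CalibratedImage(values.reshape(10, 20), "gfp", 1.0)
        mask = default_threshold(img)
        assert mask.pixels.sum() == 100  # the 200-valued pixels

    def test_constant_image_warns_all_background(self):
        img = CalibratedImage(np.full((8, 8), 9.0), "gfp", 1.0)
        with pytest.warns(UserWarning, match="constant"):
            mask = default_threshold(img)
        assert not mask.pixels.any()

    def test_matches_brute_force_fixed_point(self, rng):
        for _ in range(20):
            values = np.concatenate(
                [
                    rng.normal(rng.uniform(20, 80), rng.uniform(2, 15), 400),
                    rng.normal(rng.uniform(120, 240), rng.uniform(2, 25), 300),
                ]
            ).clip(0, 255)
            got = isodata_threshold(values)
            want = brute_force_isodata(values)
            assert want is not None
            assert got == pytest.approx(want, abs=(values.max() - values.min()) / 255)

    def test_foreground_count_matches_exhaustive_count(self, rng):
        values = rng.normal(100, 40, (32, 32)).clip(0, None)
        img = CalibratedImage(values, "gfp", 1.0)
        mask = default_threshold(img)
        t = isodata_threshold(values)
        assert mask.pixels.sum() == (values > t).sum()


@pytest.fixture
def separable_fixture(rng):
    """Vessel stripe at 200±5 over background 50±5 — separable on raw intensity."""
    truth = np.zeros((48, 48), dtype=bool)
    truth[18:30, :] = True
    pixels = np.where(truth, 200.0, 50.0) + rng.normal(0, 5, (48, 48))
    img = CalibratedImage(pixels.clip(0), "phase", 1.0)
    stack = compute_feature_stack([img], SMALL_CONFIG)
    labels = ScribbleLabels.from_masks(truth, 100, rng)
    return stack, labels, truth


class TestClassifier:
    def test_separable_training_is_perfect_and_recovers_truth(self, separable_fixture):
        stack, labels, truth = separable_fixture
        clf = train_pixel_classifier(stack, labels, n_trees=50, random_seed=0,
                                     feature_config=SMALL_CONFIG)
        assert clf.training_summary["train_accuracy"] == 1.0
        assert clf.training_summary["n_vessel"] == 100
        pred = predict_mask(clf, stack)
        iou = (pred.pixels & truth).sum() / (pred.pixels | truth).sum()
        assert iou >= 0.95

    def test_deterministic_given_seed(self, separable_fixture):
        stack, labels, _ = separable_fixture
        masks = [
            predict_mask(
                train_pixel_classifier(stack, labels, n_trees=50, random_seed=11),
                stack,
            ).pixels
            for _ in range(2)
        ]
        assert np.array_equal(*masks)

    def test_single_class_labels_rejected(self, separable_fixture):
        stack, labels, _ = separable_fixture
        bad = ScribbleLabels(labels.coordinates, np.array(["vessel"] * len(labels.classes), dtype=object))
        with pytest.raises(ValidationError, match="both classes"):
            train_pixel_classifier(stack, bad)

    def test_prediction_invariant_to_plane_order(self, separable_fixture, rng):
        stack, labels, _ = separable_fixture
        clf = train_pixel_classifier(stack, labels, n_trees=50, random_seed=0)
        order = rng.permutation(stack.n_features)
        from mvnquant.features import FeatureStack

        shuffled = FeatureStack(
            stack.features[order], [stack.names[i] for i in order],
            stack.source_channels, stack.pixel_size_um,
        )
        assert np.array_equal(predict_mask(clf, stack).pixels,
                              predict_mask(clf, shuffled).pixels)

    def test_mismatched_feature_names_rejected(self, separable_fixture):
        stack, labels, _ = separable_fixture
        clf = train_pixel_classifier(stack, labels, n_trees=10, random_seed=0)
        other = compute_feature_stack(
            [CalibratedImage(np.ones((8, 8)), "gfp", 1.0)], SMALL_CONFIG
        )
        with pytest.raises(ValidationError, match="name sets differ"):
            predict_mask(clf, other)

    def test_persistence_roundtrip_and_config_check(self, separable_fixture, tmp_path):
        stack, labels, _ = separable_fixture
        clf = train_pixel_classifier(stack, labels, n_trees=20, random_seed=3,
                                     feature_config=SMALL_CONFIG)
        save_classifier(clf, tmp_path / "model.pkl")
        back = load_classifier(tmp_path / "model.pkl", SMALL_CONFIG)
        assert np.array_equal(predict_mask(back, stack).pixels,
                              predict_mask(clf, stack).pixels)
        with pytest.raises(ValidationError, match="does not match"):
            load_classifier(tmp_path / "model.pkl", FeatureConfig())


class TestMorphClean:
    def test_removes_isolated_speckle(self):
        m = np.zeros((16, 16), dtype=bool)
        m[8, 8] = True
        out = morph_clean(BinaryMask(m, 1.0), 1, 1)
        assert not out.pixels.any()

    def test_solid_rectangle_area_preserved_up_to_boundary_band(self):
        from scipy import ndimage

        m = np.zeros((40, 40), dtype=bool)
        m[10:30, 5:35] = True
        out = morph_clean(BinaryMask(m, 1.0), 1, 1)
        # set-morphology oracle: opening with the 3x3 cross
        cross = ndimage.generate_binary_structure(2, 1)
        oracle = ndimage.binary_dilation(ndimage.binary_erosion(m, cross), cross)
        assert np.array_equal(out.pixels, oracle)
        assert abs(int(out.pixels.sum()) - int(m.sum())) <= 2 * (20 + 30)

    def test_zero_iterations_is_identity(self, rng):
        m = rng.random((20, 20)) > 0.5
        out = morph_clean(BinaryMask(m, 1.0), 0, 0)
        assert np.array_equal(out.pixels, m)

    def test_anti_extensive_then_extensive(self, rng):
        from scipy import ndimage

        m = rng.random((30, 30)) > 0.4
        mask = BinaryMask(m, 1.0)
        eroded_only = morph_clean(mask, 1, 0)
        assert not (eroded_only.pixels & ~m).any()  # erosion subset of input
        final = morph_clean(mask, 1, 1)
        cross = ndimage.generate_binary_structure(2, 1)
        dilated = ndimage.binary_dilation(m, cross)
        assert not (final.pixels & ~dilated).any()
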