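import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from syntopo.classify import (
    DegenerateClassifierWarning,
    IntensityClassifier,
    classify_cells,
    count_positive_particles,
    fit_intensity_classifier,
    train_pixel_classifier,
)
from syntopo.detect import detect_nuclei, measure_intensity
from syntopo.synth import render_dab_section

CLASS_ORDER = {"low": 0, "medium": 1, "high": 2}

intensity_arrays = hst.lists(
    hst.floats(min_value=0, max_value=1e4, allow_nan=False), min_size=3, max_size=50
).filter(lambda xs: len(set(xs)) > 1)


class TestFitIntensityClassifier:
    def test_textbook_example(self):
        clf = fit_intensity_classifier(np.array([90.0, 100.0, 110.0]))
        assert clf.mu == pytest.approx(100.0)
        assert clf.sd == pytest.approx(10.0)
        assert clf.t_low == pytest.approx(90.0)
        assert clf.t_high == pytest.approx(110.0)

    def test_zero_variance_flags_degenerate(self):
        with pytest.warns(DegenerateClassifierWarning):
            clf = fit_intensity_classifier(np.full(5, 7.0))
        assert clf.mu == 7.0
        assert clf.sd == 0.0
        assert clf.degenerate

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            fit_intensity_classifier(np.array([1.0]))

    def test_sample_sd_uses_n_minus_1(self):
        clf = fit_intensity_classifier(np.array([0.0, 2.0]))
        assert clf.sd == pytest.approx(np.sqrt(2.0))
        assert clf.sd_denominator == "n-1"

    def test_mu_matches_mixture_weighted_mean_on_synth_cells(self, small_section):
        _, _, mixtures, _, truth = small_section
        clf = fit_intensity_classifier(truth.cells["intensity"].to_numpy())
        means = np.array([40.0, 100.0, 180.0])
        counts = truth.cells.groupby("region_id").size()
        expected = np.mean(
            [
                (mixtures[rid].as_array() * means).sum()
                for rid in truth.cells["region_id"]
            ]
        )
        assert clf.mu == pytest.approx(expected, abs=3.0)

    def test_json_roundtrip(self, tmp_path):
        clf = fit_intensity_classifier(np.array([90.0, 100.0, 110.0]))
        p = tmp_path / "clf.json"
        clf.to_json(p)
        again = IntensityClassifier.from_json(p)
        assert again.mu == clf.mu and again.sd == clf.sd
        assert again.t_high == clf.t_high


class TestClassifyCells:
    def clf(self):
        return IntensityClassifier("signal", "nuclear", mu=100.0, sd=10.0, n_train=3)

    def test_low_medium_high_assignment(self):
        labels = self.clf().predict([85.0, 100.0, 115.0])
        assert list(labels) == ["low", "medium", "high"]

    def test_boundaries_are_medium(self):
        labels = self.clf().predict([90.0, 110.0])
        assert list(labels) == ["medium", "medium"]

    def test_degenerate_classifier_all_medium(self):
        clf = IntensityClassifier("signal", "nuclear", mu=5.0, sd=0.0, n_train=9)
        assert list(clf.predict([1.0, 5.0, 9.0])) == ["medium"] * 3

    def test_degenerate_override_flag(self):
        clf = IntensityClassifier("signal", "nuclear", mu=5.0, sd=0.0, n_train=9)
        with pytest.raises(ValueError, match="degenerate"):
            classify_cells(clf, np.array([1.0]), allow_degenerate=False)

    def test_missing_intensity_column_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError, match="missing intensity column"):
            classify_cells(self.clf(), pd.DataFrame({"x": [1.0]}))

    @given(intensity_arrays)
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_partition_every_cell_gets_one_class(self, values):
        values = np.asarray(values)
        clf = fit_intensity_classifier(values)
        labels = clf.predict(values)
        assert len(labels) == len(values)
        assert set(labels) <= {"low", "medium", "high"}

    @given(intensity_arrays, hst.floats(min_value=0.1, max_value=1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_raising_intensity_never_lowers_class(self, values, bump):
        clf = fit_intensity_classifier(np.asarray(values))
        before = clf.predict(values)
        after = clf.predict(np.asarray(values) + bump)
        for b, a in zip(before, after):
            assert CLASS_ORDER[a] >= CLASS_ORDER[b]

    @given(
        intensity_arrays,
        hst.floats(min_value=0.01, max_value=100.0),
        hst.floats(min_value=-1e3, max_value=1e3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance_of_assignments(self, values, a, b):
        values = np.asarray(values)
        base = classify_cells(fit_intensity_classifier(values), values)
        scaled = values * a + b
        rescaled = classify_cells(fit_intensity_classifier(scaled), scaled)
        assert list(base) == list(rescaled)

    def test_true_class_recovery_on_separated_means(self, small_section):
        """With inter-class gaps >= 4 within-class SDs, nearly every cell
        recovers its generating class from its true intensity."""
        _, _, _, _, truth = small_section
        values = truth.cells["intensity"].to_numpy()
        clf = fit_intensity_classifier(values)
        labels = clf.predict(values)
        agree = (labels == truth.cells["true_class"].to_numpy()).mean()
        assert agree >= 0.99

    def test_confusion_diagonal_on_measured_cells(self, small_section):
        """>=80% of detected cells get their true class from measured,
        background-corrected nuclear intensity."""
        from scipy.spatial import cKDTree

        from syntopo.detect import auto_background_rois, subtract_background

        _, _, _, section, truth = small_section
        cells = detect_nuclei(section)
        cells = measure_intensity(cells, section, "signal", "nuclear")
        rois = auto_background_rois(cells, section.shape)
        cells = subtract_background(cells, section, "signal", rois)
        clf = fit_intensity_classifier(cells, "signal", "nuclear", corrected=True)
        cells = classify_cells(clf, cells, corrected=True)
        tree = cKDTree(truth.cells[["x", "y"]].to_numpy())
        d, idx = tree.query(cells.df[["x", "y"]].to_numpy())
        ok = d <= 3
        agree = (
            cells.df.loc[ok, "class"].to_numpy()
            == truth.cells["true_class"].to_numpy()[idx[ok]]
        ).mean()
        assert agree >= 0.80


@pytest.fixture(scope="module")
def dab_training():
    imgs, masks = [], []
    for s in range(3):
        dab, _, _ = render_dab_section(40, 150, size_range_px=(8, 16),
                                       shape=(256, 256), seed=s)
        imgs.append(dab)
        masks.append({"positive": dab < 120, "negative": dab > 200})
    return imgs, masks


class TestPixelClassifier:
    def test_separable_annotations_train_perfectly(self):
        """Dark-vs-bright annotations away from the edge are separable in
        feature space: training accuracy is 100% on the annotated pixels."""
        rng = np.random.default_rng(0)
        img = np.full((64, 64), 220.0) + rng.normal(0, 2, (64, 64))
        img[:, :32] = 60.0 + rng.normal(0, 2, (64, 32))
        pos = np.zeros_like(img, dtype=bool)
        neg = np.zeros_like(img, dtype=bool)
        pos[:, :16] = True
        neg[:, 48:] = True
        clf = train_pixel_classifier([img], [{"positive": pos, "negative": neg}],
                                     scales=(1.0, 2.0))
        prob = clf.predict_proba(img)
        assert (prob[pos] >= 0.5).all()
        assert (prob[neg] < 0.5).all()

    def test_swapped_labels_complement_probabilities(self, dab_training):
        imgs, masks = dab_training
        clf = train_pixel_classifier(imgs, masks, scales=(1.0, 2.0))
        swapped = train_pixel_classifier(
            imgs,
            [{"positive": m["negative"], "negative": m["positive"]} for m in masks],
            scales=(1.0, 2.0),
        )
        p = clf.predict_proba(imgs[1])
        q = swapped.predict_proba(imgs[1])
        np.testing.assert_allclose(p + q, 1.0, atol=1e-5)

    def test_held_out_accuracy(self, dab_training):
        imgs, masks = dab_training
        clf = train_pixel_classifier(imgs, masks, scales=(1.0, 2.0))
        fresh, _, _ = render_dab_section(40, 150, size_range_px=(8, 16),
                                         shape=(256, 256), seed=77)
        prob = clf.predict_proba(fresh)
        truth_mask = fresh < 140
        acc = ((prob >= 0.5) == truth_mask).mean()
        assert acc >= 0.95

    def test_single_class_annotations_rejected(self, dab_training):
        imgs, _ = dab_training
        zeros = np.zeros(imgs[0].shape, dtype=bool)
        with pytest.raises(ValueError, match="both positive and negative"):
            train_pixel_classifier(
                [imgs[0]], [{"positive": imgs[0] < 120, "negative": zeros}]
            )

    def test_untrained_model_rejected(self):
        from syntopo.classify import PixelClassifier

        with pytest.raises(ValueError, match="untrained"):
            count_positive_particles(np.zeros((8, 8)), PixelClassifier())


class TestCountPositiveParticles:
    @staticmethod
    def sharp_classifier(image):
        """Near-pointwise classifier so particle areas come out exactly."""
        return train_pixel_classifier(
            [image], [{"positive": image < 120, "negative": image > 180}],
            scales=(0.1,),
        )

    def exact_area_image(self, areas):
        img = np.full((64, 64), 220.0)
        x = 5
        for a in areas:
            img[5 : 5 + a, x] = 60.0  # vertical bar of exactly a pixels
            x += 5
        return img

    def test_strictly_greater_than_filter(self):
        img = self.exact_area_image([3, 5, 6, 10])
        clf = self.sharp_classifier(img)
        count, kept = count_positive_particles(img, clf, min_size_px=5)
        assert count == 2
        assert kept == [6, 10]

    def test_blank_image_counts_zero(self):
        img = self.exact_area_image([4])
        clf = self.sharp_classifier(img)
        count, kept = count_positive_particles(np.full((32, 32), 220.0), clf)
        assert count == 0 and kept == []

    def test_ground_truth_count_recovered_on_synth_dab(self):
        imgs, masks = [], []
        for s in range(3):
            dab, _, _ = render_dab_section(40, 150, size_range_px=(8, 16),
                                           shape=(256, 256), seed=s)
            imgs.append(dab)
            masks.append({"positive": dab < 120, "negative": dab > 200})
        clf = train_pixel_classifier(imgs, masks, scales=(1.0, 2.0))
        fresh, _, truth = render_dab_section(50, 0, size_range_px=(8, 16),
                                             shape=(512, 512), seed=123)
        count, _ = count_positive_particles(fresh, clf)
        assert count == truth.dab_positive_count

    def test_small_particles_below_filter_count_zero(self):
        imgs, masks = [], []
        for s in range(2):
            dab, _, _ = render_dab_section(40, 0, size_range_px=(8, 16),
                                           shape=(256, 256), seed=s)
            imgs.append(dab)
            masks.append({"positive": dab < 120, "negative": dab > 200})
        clf = train_pixel_classifier(imgs, masks, scales=(0.5,))
        tiny, _, _ = render_dab_section(30, 0, size_range_px=(2, 4),
                                        shape=(256, 256), seed=9)
        count, _ = count_positive_particles(tiny, clf, min_size_px=5)
        assert count == 0
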