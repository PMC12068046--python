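"""Five-shape linear classifier and the PCA normal (penetrance) filter."""

import numpy as np
import pandas as pd
import pytest

from morphoscreen.features import feature_registry
from morphoscreen.shapes import (
    SHAPE_CLASSES,
    NormalModel,
    ShapeModel,
    classify_cells,
    derive_normal_classifier,
    filter_normal,
    train_shape_classifier,
)


def synthetic_features(n_per_class=40, sep=4.0, seed=0, n_features=6):
    """Linearly separable Gaussian blobs, one per shape class."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for k, cls in enumerate(SHAPE_CLASSES):
        centre = np.zeros(n_features)
        centre[k % n_features] = sep
        rows.append(rng.normal(centre, 1.0, size=(n_per_class, n_features)))
        labels += [cls] * n_per_class
    x = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(n_features)])
    return x, np.array(labels)


class TestTrainClassifier:
    def test_separable_blobs_high_holdout_accuracy(self):
        x, y = synthetic_features()
        model = train_shape_classifier(x, y, seed=1)
        assert model.holdout_accuracy >= 0.95

    def test_deterministic_given_seed(self):
        x, y = synthetic_features()
        m1 = train_shape_classifier(x, y, seed=2)
        m2 = train_shape_classifier(x, y, seed=2)
        np.testing.assert_array_equal(m1.coef, m2.coef)
        np.testing.assert_array_equal(m1.intercept, m2.intercept)

    def test_missing_class_rejected(self):
        x, y = synthetic_features()
        keep = y != "fan"
        with pytest.raises(ValueError, match="classes"):
            train_shape_classifier(x[keep], y[keep], seed=0)

    def test_too_few_exemplars_names_class(self):
        x, y = synthetic_features(n_per_class=40)
        drop = np.flatnonzero(y == "spindly")[5:]
        keep = np.ones(len(y), bool)
        keep[drop] = False
        with pytest.raises(ValueError, match="spindly"):
            train_shape_classifier(x[keep], y[keep], seed=0)

    def test_exemplars_get_their_own_label(self):
        x, y = synthetic_features()
        model = train_shape_classifier(x, y, seed=3)
        pred = classify_cells(model, x)
        assert np.mean(pred == y) >= 0.99

    def test_serialization_roundtrip_identical_predictions(self):
        x, y = synthetic_features()
        model = train_shape_classifier(x, y, seed=4)
        clone = ShapeModel.from_json(model.to_json())
        np.testing.assert_array_equal(classify_cells(model, x), classify_cells(clone, x))

    def test_registry_mismatch_rejected(self):
        x, y = synthetic_features()
        model = train_shape_classifier(x, y, seed=5)
        bad = x.rename(columns={"f0": "other"})
        with pytest.raises(ValueError, match="registry"):
            classify_cells(model, bad)


class TestClassifyRenderedCells:
    def test_holdout_accuracy_on_rendered_archetypes(self, labelled_archetype_features):
        df = labelled_archetype_features
        reg = feature_registry()
        model = train_shape_classifier(df[reg], df["true_class"], seed=6)
        assert model.holdout_accuracy >= 0.9

    def test_pure_triangular_well_classified(self, labelled_archetype_features):
        from morphoscreen.synthetic.plate import PlateSpec, WellSpec, generate_plate
        from morphoscreen import imaging, features as feat

        df = labelled_archetype_features
        reg = feature_registry()
        model = train_shape_classifier(df[reg], df["true_class"], seed=7)

        spec = PlateSpec(
            wells=[WellSpec("tri", "t", (0, 0, 1, 0, 0), cells_per_field=25)],
            image_size=640, seed=303,
        )
        images, _ = generate_plate(spec)
        chan = images["tri"][0]
        cells = imaging.segment_cells(chan["dna"], chan["tubulin"])
        bg = {ch: imaging.estimate_background(img, [c.cell_mask for c in cells])
              for ch, img in chan.items()}
        rows = [
            feat.extract_features(c, {k: chan[k] for k in ("dna", "tubulin", "actin")},
                                  pixel_size=0.6, backgrounds=bg)
            for c in cells if not c.is_border
        ]
        pred = classify_cells(model, pd.DataFrame(rows)[reg])
        assert np.mean(pred == "triangular") >= 0.9


class TestNormalModel:
    def test_box_holds_expected_mass_when_populations_identical(self):
        rng = np.random.default_rng(8)
        cols = [f"f{i}" for i in range(5)]
        mock = pd.DataFrame(rng.normal(size=(4000, 5)), columns=cols)
        enriched = pd.DataFrame(rng.normal(size=(4000, 5)), columns=cols)
        model = derive_normal_classifier(mock, enriched, seed=8)
        inside = model.in_box(mock).mean()
        # product of two one-sd normal intervals: 0.6827^2 ~ 0.466
        assert inside == pytest.approx(0.6827**2, abs=0.03)

    def test_same_inputs_same_box(self):
        rng = np.random.default_rng(9)
        cols = [f"f{i}" for i in range(4)]
        mock = pd.DataFrame(rng.normal(size=(300, 4)), columns=cols)
        enriched = pd.DataFrame(rng.normal(1, 1, size=(300, 4)), columns=cols)
        m1 = derive_normal_classifier(mock, enriched, seed=10)
        m2 = derive_normal_classifier(mock, enriched, seed=10)
        np.testing.assert_array_equal(m1.centre, m2.centre)
        np.testing.assert_array_equal(m1.half_width, m2.half_width)

    def test_displaced_cells_called_not_normal(self):
        rng = np.random.default_rng(11)
        cols = [f"f{i}" for i in range(5)]
        mock = pd.DataFrame(rng.normal(size=(2000, 5)), columns=cols)
        shift = np.zeros(5)
        shift[0] = 5.0
        enriched = pd.DataFrame(rng.normal(size=(2000, 5)) + shift, columns=cols)
        model = derive_normal_classifier(mock, enriched, seed=11)
        assert model.predict_normal(enriched).mean() <= 0.01

    def test_single_feature_rejected(self):
        mock = pd.DataFrame({"f0": np.random.default_rng(0).normal(size=50)})
        with pytest.raises(ValueError, match="2 features"):
            derive_normal_classifier(mock, mock.copy(), seed=0)

    def test_serialization_roundtrip(self):
        rng = np.random.default_rng(12)
        cols = [f"f{i}" for i in range(4)]
        mock = pd.DataFrame(rng.normal(size=(200, 4)), columns=cols)
        enriched = pd.DataFrame(rng.normal(2, 1, size=(200, 4)), columns=cols)
        model = derive_normal_classifier(mock, enriched, seed=13)
        clone = NormalModel.from_json(model.to_json())
        np.testing.assert_array_equal(
            model.predict_normal(mock), clone.predict_normal(mock)
        )


class TestFilterNormal:
    def _model(self):
        rng = np.random.default_rng(14)
        cols = [f"f{i}" for i in range(5)]
        mock = pd.DataFrame(rng.normal(size=(1000, 5)), columns=cols)
        shift = np.r_[5.0, np.zeros(4)]
        enriched = pd.DataFrame(rng.normal(size=(1000, 5)) + shift, columns=cols)
        return derive_normal_classifier(mock, enriched, seed=14), cols

    def test_empty_input(self):
        model, cols = self._model()
        empty = pd.DataFrame(columns=cols)
        normal, pheno, frac = filter_normal(empty, model)
        assert len(normal) == 0 and len(pheno) == 0 and np.isnan(frac)

    def test_partition_conserves_cells(self):
        model, cols = self._model()
        rng = np.random.default_rng(15)
        cells = pd.DataFrame(rng.normal(size=(500, 5)), columns=cols)
        normal, pheno, frac = filter_normal(cells, model)
        assert len(normal) + len(pheno) == len(cells)
        assert frac == pytest.approx(len(normal) / len(cells))

    def test_mock_like_higher_normal_fraction_than_shifted(self):
        model, cols = self._model()
        rng = np.random.default_rng(16)
        mock_like = pd.DataFrame(rng.normal(size=(500, 5)), columns=cols)
        shifted = mock_like + np.r_[5.0, np.zeros(4)]
        shifted.columns = cols
        _, _, f_mock = filter_normal(mock_like, model)
        _, _, f_shift = filter_normal(shifted, model)
        assert f_mock > f_shift
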