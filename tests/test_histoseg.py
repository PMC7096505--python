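"""Spectral metrics and per-pixel histology classification."""

import numpy as np
import pytest

from ecmir.histoseg import (HistologyModel, MetricDefinition, TrainingError,
                            classify_pixels, compute_metrics,
                            default_metric_definitions, extract_class_spectra,
                            train_histology_classifier)
from ecmir.hyperio import HyperspectralCube
from ecmir.synthcohort import (SynthCohortConfig, TRUE_CLASS_NAMES,
                               generate_tissue_image)


def _gaussian(axis, center, amp, sigma):
    return amp * np.exp(-0.5 * ((axis.values - center) / sigma) ** 2)


class TestComputeMetrics:
    def test_peak_height_and_location_of_gaussian(self, axis_default):
        y = _gaussian(axis_default, 1656.0, 0.8, 20.0)
        defs = [MetricDefinition("h", "peak_height", 1656.0, 40.0),
                MetricDefinition("loc", "peak_location", 1656.0, 40.0)]
        M, flagged = compute_metrics(y, axis_default, defs)
        assert M[0, 0] == pytest.approx(0.8)
        assert M[0, 1] == 1656.0
        assert not flagged.any()

    def test_band_area_matches_analytic_integral(self, axis_default):
        sigma = 15.0
        y = _gaussian(axis_default, 1400.0, 0.8, sigma)
        defs = [MetricDefinition("a", "band_area", 1400.0, 5 * sigma)]
        M, _ = compute_metrics(y, axis_default, defs)
        assert M[0, 0] == pytest.approx(0.8 * sigma * np.sqrt(2 * np.pi),
                                        rel=0.01)

    def test_ratio_of_equal_heights_is_one(self, axis_default):
        y = (_gaussian(axis_default, 1080.0, 0.5, 10.0)
             + _gaussian(axis_default, 1656.0, 0.5, 10.0))
        defs = [MetricDefinition("a", "peak_height", 1080.0, 30.0),
                MetricDefinition("b", "peak_height", 1656.0, 30.0),
                MetricDefinition("r", "ratio", numerator="a", denominator="b")]
        M, _ = compute_metrics(y, axis_default, defs)
        assert M[0, 2] == pytest.approx(1.0)

    def test_zero_denominator_flags_pixel(self, axis_default):
        y = np.zeros(len(axis_default))
        defs = [MetricDefinition("a", "peak_height", 1080.0, 30.0),
                MetricDefinition("b", "peak_height", 1656.0, 30.0),
                MetricDefinition("r", "ratio", numerator="a", denominator="b")]
        M, flagged = compute_metrics(y, axis_default, defs)
        assert flagged[0]
        assert M[0, 2] == np.inf

    def test_forward_ratio_reference_rejected(self, axis_default):
        defs = [MetricDefinition("r", "ratio", numerator="a", denominator="b"),
                MetricDefinition("a", "peak_height", 1080.0, 30.0),
                MetricDefinition("b", "peak_height", 1656.0, 30.0)]
        with pytest.raises(ValueError):
            compute_metrics(np.zeros(len(axis_default)), axis_default, defs)


class TestTraining:
    def test_symmetric_gaussians_decide_at_midpoint(self):
        """Two unit-variance 1-D classes at 0 and 10 with equal priors:
        posterior crosses 0.5 exactly at 5."""
        defs = [MetricDefinition("m", "peak_height", 1656.0, 20.0)]
        model = HistologyModel(metric_defs=defs, class_names=["a", "b"],
                               means=np.array([[0.0], [10.0]]),
                               covariances=np.array([[[1.0]], [[1.0]]]),
                               priors=np.array([0.5, 0.5]))
        post = model.posteriors(np.array([[5.0]]))
        np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)
        assert model.posteriors(np.array([[4.9]]))[0, 0] > 0.5

    def test_single_class_raises(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(TrainingError):
            train_histology_classifier(
                X, np.array(["only"] * 30),
                [MetricDefinition("a", "peak_height", 1080.0, 30.0),
                 MetricDefinition("b", "peak_height", 1656.0, 30.0)])

    def test_too_few_examples_per_class_raises(self, rng):
        X = rng.normal(size=(4, 3))
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(TrainingError):
            train_histology_classifier(
                X, labels, [MetricDefinition(n, "peak_height", 1080.0, 30.0)
                            for n in "xyz"])

    def test_separable_metrics_classify_perfectly(self, rng):
        """Six well-separated Gaussian clusters in metric space:
        resubstitution accuracy is 100%."""
        centers = np.array([[i * 10.0, -i * 5.0] for i in range(6)])
        X = np.vstack([c + 0.01 * rng.normal(size=(20, 2)) for c in centers])
        labels = np.repeat([f"c{i}" for i in range(6)], 20)
        defs = [MetricDefinition("a", "peak_height", 1080.0, 30.0),
                MetricDefinition("b", "peak_height", 1656.0, 30.0)]
        model = train_histology_classifier(X, labels, defs)
        pred = np.argmax(model.posteriors(X), axis=1)
        assert all(model.class_names[p] == l for p, l in zip(pred, labels))


@pytest.fixture(scope="module")
def trained():
    from ecmir.pipeline import RunConfig, simulate_cohort, \
        train_histology_from_truth
    from ecmir.synthcohort import SynthCohortConfig as SC
    cfg = RunConfig(synth=SC(n_ecm3=2, n_non_ecm3=2, image_shape=(24, 24)),
                    seed=42)
    sim = simulate_cohort(cfg)
    model = train_histology_from_truth(sim.train_cubes, sim.train_maps,
                                       cfg.prep)
    return cfg, sim, model


@pytest.fixture(scope="module")
def segmented():
    cfg = SynthCohortConfig(image_shape=(16, 16))
    rng = np.random.default_rng(9)
    cube, truth = generate_tissue_image(cfg, "ECM3", 0.5, rng)
    # use the ground-truth raster directly as a class map
    from ecmir.histoseg import TissueClassMap
    names = list(TRUE_CLASS_NAMES)
    post = np.zeros(truth.class_map.shape + (len(names),))
    for i in range(len(names)):
        post[truth.class_map == i, i] = 1.0
    cmap = TissueClassMap(labels=truth.class_map, posteriors=post,
                          class_names=names)
    return cube, cmap


class TestClassifyPixels:
    def test_pixel_accuracy_on_noisy_fixture(self, trained):
        """At default noise the classifier recovers ≥ 95% of pixel labels."""
        from ecmir.pipeline import _merged_tissue_label
        from ecmir.specprep import preprocess_cube
        cfg, sim, model = trained
        correct = total = 0
        for cube, tmap in zip(sim.cubes, sim.truth_maps):
            processed, _ = preprocess_cube(cube, cfg.prep)
            cmap = classify_pixels(processed, model)
            truth = np.array([_merged_tissue_label(c)
                              for c in tmap.reshape(-1)])
            pred = np.array([cmap.class_names[i]
                             for i in cmap.labels.reshape(-1)])
            correct += (pred == truth).sum()
            total += truth.size
        assert correct / total >= 0.95

    def test_posteriors_normalized_and_argmax_consistent(self, trained):
        from ecmir.specprep import preprocess_cube
        cfg, sim, model = trained
        processed, _ = preprocess_cube(sim.cubes[0], cfg.prep)
        cmap = classify_pixels(processed, model)
        sums = cmap.posteriors.sum(axis=2)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        np.testing.assert_array_equal(np.argmax(cmap.posteriors, axis=2),
                                      cmap.labels)

    def test_all_zero_cube_is_all_background(self, trained, axis_default):
        cfg, sim, model = trained
        axis = sim.cubes[0].axis
        cube = HyperspectralCube(data=np.zeros((4, 4, len(axis))), axis=axis)
        from ecmir.specprep import preprocess_cube
        processed, _ = preprocess_cube(cube, cfg.prep)
        cmap = classify_pixels(processed, model)
        assert np.all(cmap.labels == 0)
        assert cmap.class_names[0] == "background"

    def test_metric_permutation_leaves_labels_unchanged(self, trained):
        """Re-ordering metric definitions (with matched model columns)
        cannot change the decision."""
        from ecmir.specprep import preprocess_cube
        cfg, sim, model = trained
        perm = np.arange(len(model.metric_defs))[::-1]
        permuted = HistologyModel(
            metric_defs=[model.metric_defs[i] for i in perm
                         if model.metric_defs[i].kind != "ratio"]
            + [model.metric_defs[i] for i in perm
               if model.metric_defs[i].kind == "ratio"],
            class_names=model.class_names,
            means=model.means[:, perm],
            covariances=model.covariances[:, perm][:, :, perm],
            priors=model.priors)
        processed, _ = preprocess_cube(sim.cubes[0], cfg.prep)
        flat = processed.flat_spectra()
        X, _ = compute_metrics(flat, processed.axis, model.metric_defs)
        direct = np.argmax(model.posteriors(X), axis=1)
        permuted_post = permuted.posteriors(X[:, perm])
        np.testing.assert_array_equal(direct,
                                      np.argmax(permuted_post, axis=1))


class TestExtractClassSpectra:
    def test_count_identity(self, segmented):
        cube, cmap = segmented
        n = int(np.sum(cmap.labels == cmap.class_names.index("collagen_ECM3")))
        spectra, coords = extract_class_spectra(cube, cmap, "collagen_ECM3")
        assert spectra.shape[0] == n == coords.shape[0]

    def test_absent_class_returns_empty(self, segmented):
        cube, cmap = segmented
        cmap2 = cmap
        cmap2.labels = np.where(cmap.labels == cmap.class_names.index("blood"),
                                0, cmap.labels)
        spectra, coords = extract_class_spectra(cube, cmap2, "blood")
        assert spectra.shape == (0, cube.shape[2])

    def test_coordinates_roundtrip_bitwise(self, segmented):
        cube, cmap = segmented
        spectra, coords = extract_class_spectra(cube, cmap, "epithelium")
        re_indexed = cube.data[coords[:, 0], coords[:, 1], :]
        np.testing.assert_array_equal(re_indexed, spectra)
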