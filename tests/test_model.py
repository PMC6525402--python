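"""Bayes classifier, feature selection, normalization and model IO."""

import numpy as np
import pytest
from sklearn.base import clone
from sklearn.naive_bayes import GaussianNB

import pcotex as pt
from pcotex.errors import SchemaError, TrainingCoverageError
from pcotex.features import FeatureConfig, FeatureStack
from pcotex.model import (
    MASKED_LABEL,
    N_CLASSES,
    GaussianBayesClassifier,
    SequentialFloatingSelector,
    compute_normalization,
)


def gaussian_samples(rng, means, n=200, scale=1.0):
    """Labelled draws from unit-variance Gaussians at the given mean rows."""
    means = np.atleast_2d(np.asarray(means, dtype=float))
    xs, ys = [], []
    for c, mu in enumerate(means):
        xs.append(rng.normal(mu, scale, size=(n, means.shape[1])))
        ys.append(np.full(n, c))
    return np.concatenate(xs), np.concatenate(ys)


class TestGaussianBayes:
    def test_symmetric_two_class_boundary_at_midpoint(self, rng):
        x, y = gaussian_samples(rng, [[-5.0], [5.0]], n=500)
        clf = GaussianBayesClassifier(priors="uniform").fit(x, y)
        # decision flips within a whisker of the midpoint 0
        assert clf.predict([[-0.2]])[0] == 0
        assert clf.predict([[0.2]])[0] == 1

    def test_empirical_priors_are_frequencies(self, rng):
        x = rng.normal(size=(100, 2))
        y = np.array([0] * 90 + [1] * 10)
        clf = GaussianBayesClassifier(priors="empirical").fit(x, y)
        assert np.allclose(clf.class_prior_, [0.9, 0.1])

    def test_perfect_separation_refit_accuracy(self, rng):
        x, y = gaussian_samples(rng, [[-10.0], [0.0], [10.0]], n=50, scale=0.1)
        clf = GaussianBayesClassifier().fit(x, y)
        assert np.mean(clf.predict(x) == y) == 1.0

    def test_agrees_with_reference_gaussian_nb(self, rng):
        """Independent cross-check against sklearn's GaussianNB on shared
        empirical priors (var_smoothing suppressed)."""
        x, y = gaussian_samples(rng, [[0, 0], [1.5, -1], [-2, 2]], n=150)
        mine = GaussianBayesClassifier(priors="empirical", var_floor=1e-12).fit(x, y)
        ref = GaussianNB(var_smoothing=1e-300).fit(x, y)
        grid = rng.normal(scale=2.0, size=(500, 2))
        assert np.array_equal(mine.predict(grid), ref.predict(grid))
        assert np.allclose(mine.predict_proba(grid), ref.predict_proba(grid))

    def test_parameter_recovery_from_own_gaussians(self):
        rng = np.random.default_rng(77)
        means = np.array([[0.0, 1.0], [2.0, -1.0], [-3.0, 0.5],
                          [1.0, 4.0], [-1.5, -2.0], [4.0, 2.0]])
        variances = np.array([[1.0, 0.5], [2.0, 1.0], [0.3, 0.8],
                              [1.5, 1.5], [0.7, 2.5], [1.0, 1.0]])
        xs, ys = [], []
        for c in range(6):
            xs.append(rng.normal(means[c], np.sqrt(variances[c]), size=(2000, 2)))
            ys.append(np.full(2000, c))
        clf = GaussianBayesClassifier().fit(np.concatenate(xs), np.concatenate(ys))
        assert np.abs(clf.theta_ - means).max() < 0.1
        assert np.abs(clf.var_ / variances - 1.0).max() < 0.2

    def test_needs_two_samples_per_class(self):
        with pytest.raises(TrainingCoverageError):
            GaussianBayesClassifier().fit(np.array([[0.0], [1.0], [2.0]]),
                                          np.array([0, 0, 1]))

    def test_sklearn_protocol(self):
        clf = GaussianBayesClassifier(priors="empirical", var_floor=1e-5)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


class TestPosterior:
    @pytest.fixture
    def model(self, rng):
        means = np.arange(12, dtype=float).reshape(6, 2)
        return pt.fit_bayes(
            np.repeat(means, 5, axis=0) + rng.normal(0, 0.1, size=(30, 2)),
            np.repeat(np.arange(6), 5),
        )

    def test_peaks_at_class_mean(self, model):
        p = model.posterior(model.means[3] * model.norm_scale + model.norm_center)
        assert p.argmax() == 3

    def test_sums_to_one(self, model, rng):
        x = rng.normal(size=(40, 2))
        p = model.posterior(x)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_identical_classes_split_evenly(self):
        x = np.array([[0.0], [0.1], [-0.1]] * 4)
        y = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])
        clf = GaussianBayesClassifier().fit(x[:, :1], y)
        # same samples in both classes -> identical parameters
        probs = clf.predict_proba([[0.05]])[0]
        assert np.allclose(probs, 0.5)


class TestSelection:
    def test_informative_feature_found_first(self, rng):
        n = 120
        y = np.repeat(np.arange(3), n)
        informative = np.concatenate([rng.normal(3 * c, 0.3, n) for c in range(3)])
        x = np.column_stack(
            [rng.normal(size=3 * n), informative, rng.normal(size=3 * n)]
        )
        # brute-force single-feature criterion confirms column 1 is best
        sel = SequentialFloatingSelector(max_features=2, cv=3, random_state=0)
        sel.fit(x, y)
        assert sel.selected_[0] == 1

    def test_max_features_cap(self, rng):
        x, y = gaussian_samples(rng, np.eye(4) * 3, n=60)
        sel = SequentialFloatingSelector(max_features=1, cv=3).fit(x, y)
        assert len(sel.selected_) == 1

    def test_trace_is_non_decreasing(self, rng):
        x, y = gaussian_samples(rng, rng.normal(size=(4, 6)), n=80)
        sel = SequentialFloatingSelector(max_features=5, cv=3).fit(x, y)
        assert all(b >= a for a, b in zip(sel.trace_, sel.trace_[1:]))

    def test_deterministic_given_seed(self, rng):
        x, y = gaussian_samples(rng, rng.normal(size=(4, 8)), n=60)
        a = SequentialFloatingSelector(max_features=4, cv=3, random_state=9).fit(x, y)
        b = SequentialFloatingSelector(max_features=4, cv=3, random_state=9).fit(x, y)
        assert a.selected_ == b.selected_ and a.trace_ == b.trace_

    def test_grouped_selection_keeps_groups_together(self, rng):
        n = 90
        y = np.repeat(np.arange(3), n)
        informative = np.concatenate([rng.normal(3 * c, 0.3, n) for c in range(3)])
        x = np.column_stack([informative, rng.normal(size=(3 * n, 3))])
        sel = SequentialFloatingSelector(
            max_features=1, cv=3, groups=[[0, 2], [1, 3]]
        ).fit(x, y)
        assert sel.selected_groups_ == [(0, 2)]
        assert sel.selected_ == [0, 2]

    def test_too_few_samples_per_class_raises(self):
        x = np.zeros((4, 2))
        y = np.array([0, 0, 1, 1])
        with pytest.raises(TrainingCoverageError):
            SequentialFloatingSelector(cv=3, max_features=1).fit(x, y)


class TestNormalization:
    def _stack(self, rng):
        planes = rng.normal(2.0, 3.0, size=(3, 10, 10))
        return FeatureStack(planes, ("a", "b", "c"))

    def test_self_stats_give_zscores(self, rng):
        stack = self._stack(rng)
        center, scale = compute_normalization(stack.matrix())
        z = pt.normalize_features(stack, center, scale)
        flat = z.matrix()
        assert np.allclose(flat.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(flat.std(axis=0), 1.0, atol=1e-9)

    def test_identity_stats(self, rng):
        stack = self._stack(rng)
        z = pt.normalize_features(stack, np.zeros(3), np.ones(3))
        assert np.array_equal(z.planes, stack.planes)

    def test_constant_plane_floored(self):
        stack = FeatureStack(np.full((1, 5, 5), 0.7), ("a",))
        center, scale = compute_normalization(stack.matrix())
        z = pt.normalize_features(stack, center, scale)
        assert np.all(np.isfinite(z.planes))
        assert np.allclose(z.planes, 0.0, atol=1e-6)

    def test_unknown_feature_name_raises(self, rng):
        stack = self._stack(rng)
        with pytest.raises(SchemaError):
            pt.normalize_features(stack, {"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 1.0})


class TestPredictMap:
    def _model_and_stack(self, rng):
        means = np.linspace(0, 10, 6)[:, None] * np.ones((6, 2))
        x, y = [], []
        for c in range(6):
            x.append(rng.normal(means[c], 0.2, size=(20, 2)))
            y.append(np.full(20, c))
        model = pt.fit_bayes(
            np.concatenate(x), np.concatenate(y), feature_names=("a", "b")
        )
        planes = np.stack([np.full((8, 8), 4.0), np.full((8, 8), 4.0)])
        stack = FeatureStack(planes, ("a", "b"))
        return model, stack

    def test_masked_pixels_get_sentinel(self, rng):
        model, stack = self._model_and_stack(rng)
        mask = pt.AnalysisMask(np.pad(np.ones((4, 4), bool), 2))
        cmap = pt.predict_map(model, stack, mask)
        assert np.all(cmap.labels[~mask.inside] == MASKED_LABEL)
        assert np.all(cmap.labels[mask.inside] == 2)  # nearest mean is 4.0

    def test_tie_broken_toward_lower_class(self):
        x = np.array([[0.0], [0.0], [2.0], [2.0], [4.0], [4.0],
                      [6.0], [6.0], [8.0], [8.0], [10.0], [10.0]])
        y = np.repeat(np.arange(6), 2)
        model = pt.fit_bayes(x + [[0.0]], y, feature_names=("a",))
        # exactly between the class-0 and class-1 means
        stack = FeatureStack(np.full((1, 3, 3), 1.0), ("a",))
        mask = pt.AnalysisMask(np.ones((3, 3), bool))
        cmap = pt.predict_map(model, stack, mask)
        assert np.all(cmap.labels == 0)

    def test_missing_plane_raises(self, rng):
        model, stack = self._model_and_stack(rng)
        stack2 = FeatureStack(stack.planes[:1], ("a",))
        with pytest.raises(SchemaError):
            pt.predict_map(model, stack2, pt.AnalysisMask(np.ones((8, 8), bool)))

    def test_deterministic(self, rng):
        model, stack = self._model_and_stack(rng)
        mask = pt.AnalysisMask(np.ones((8, 8), bool))
        a = pt.predict_map(model, stack, mask)
        b = pt.predict_map(model, stack, mask)
        assert np.array_equal(a.labels, b.labels)


class TestModelIO:
    def test_json_roundtrip(self, rng):
        x, y = gaussian_samples(rng, rng.normal(size=(6, 3)), n=30)
        model = pt.fit_bayes(
            x, y, feature_names=("f0", "f1", "f2"),
            feature_config=FeatureConfig(), metadata={"seed": 3},
        )
        back = pt.TextureModel.from_json(model.to_json())
        assert back.feature_names == model.feature_names
        assert np.allclose(back.means, model.means)
        assert np.allclose(back.variances, model.variances)
        assert back.feature_config == model.feature_config
        assert back.metadata["seed"] == 3

    def test_bad_format_rejected(self):
        with pytest.raises(SchemaError):
            pt.TextureModel.from_json('{"format": "something-else"}')

    def test_missing_class_rejected(self, rng):
        x = rng.normal(size=(20, 2))
        y = np.repeat(np.arange(5), 4)
        with pytest.raises(TrainingCoverageError):
            pt.fit_bayes(x, y)

    def test_priors_must_sum_to_one(self, rng):
        x, y = gaussian_samples(rng, rng.normal(size=(6, 2)), n=10)
        model = pt.fit_bayes(x, y)
        with pytest.raises(ValueError):
            pt.TextureModel(
                feature_names=model.feature_names,
                means=model.means,
                variances=model.variances,
                priors=model.priors * 2,
                norm_center=model.norm_center,
                norm_scale=model.norm_scale,
                feature_config=model.feature_config,
            )
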