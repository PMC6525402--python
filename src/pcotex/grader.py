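"""End-to-end grading estimator: features -> selection -> Bayes -> score.

:class:`PCOGrader` is the scikit-learn-style front end of the package: it is
fitted on labelled images (pixel class maps), selects a feature subset by
SFFS, fits the Gaussian Bayes pixel classifier, and thereafter grades new
images, producing the six-class segmentation and the 0-100 opacification
score.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .errors import TrainingCoverageError
from .features import FeatureConfig, extract_feature_stack
from .image import AnalysisMask, GrayImage, combine_masks, detect_reflex_mask, make_roi_mask
from .model import (
    CLASS_NAMES,
    N_CLASSES,
    ClassMap,
    GaussianBayesClassifier,
    SequentialFloatingSelector,
    TextureModel,
    compute_normalization,
    config_digest,
    predict_map,
)
from .scoring import ClassWeights, PCOScore, aqua_score
from .synthetic import SyntheticScene


def _orientation_groups(names: tuple[str, ...]) -> list[list[int]]:
    """Selection groups: singletons, except Gabor planes grouped across
    orientations per (frequency, statistic) so quartets travel together."""
    groups: list[list[int]] = []
    gabor_key_to_group: dict[tuple[str, str], int] = {}
    for i, n in enumerate(names):
        if n.startswith("gabor_"):
            _, fpart, _, stat = n.split("_")
            key = (fpart, stat)
            if key in gabor_key_to_group:
                groups[gabor_key_to_group[key]].append(i)
                continue
            gabor_key_to_group[key] = len(groups)
        groups.append([i])
    return groups


def _erode_square(mask: np.ndarray, margin: int) -> np.ndarray:
    from scipy.ndimage import binary_erosion

    if margin <= 0:
        return mask
    size = 2 * margin + 1
    return binary_erosion(mask, structure=np.ones((size, size), bool))


def sample_training_pixels(
    stacks: list,
    label_maps: list[np.ndarray],
    masks: list[np.ndarray],
    samples_per_class: int,
    boundary_margin: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified pixel sample drawn from class interiors.

    Pixels within ``boundary_margin`` of a class boundary (or of the mask
    edge) carry mixed-texture windows and are excluded from training.
    """
    per_class_feats: dict[int, list[np.ndarray]] = {c: [] for c in range(N_CLASSES)}
    for stack, labels, mask in zip(stacks, label_maps, masks):
        for c in np.unique(labels[mask]):
            if c < 0:
                continue
            region = (labels == c) & mask
            interior = _erode_square(region, boundary_margin)
            if interior.any():
                per_class_feats[int(c)].append(stack.matrix(interior))
    xs, ys = [], []
    for c in range(N_CLASSES):
        if not per_class_feats[c]:
            raise TrainingCoverageError(
                f"no interior training pixels for class {CLASS_NAMES[c]!r}"
            )
        feats = np.concatenate(per_class_feats[c], axis=0)
        if len(feats) > samples_per_class:
            idx = rng.choice(len(feats), size=samples_per_class, replace=False)
            feats = feats[idx]
        xs.append(feats)
        ys.append(np.full(len(feats), c, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


class PCOGrader(BaseEstimator):
    """Trainable pixelwise opacification grader.

    Parameters
    ----------
    feature_config : FeatureConfig, optional
        Texture-feature parameters (window size, GLCM levels, Gabor bank,
        fractal box sizes).
    roi_diameter : float, optional
        ROI circle diameter in pixels used by :meth:`predict` when no mask
        is supplied; defaults to 85% of the short image side.
    samples_per_class : int
        Training pixels sampled per class (stratified, seeded).
    max_features, cv_folds : SFFS budget and criterion folds.
    priors : {"uniform", "empirical"}
    boundary_margin : int, optional
        Interior erosion margin for training pixels; defaults to half the
        feature window.
    reflex_threshold, reflex_dilation : saturation-exclusion parameters
        applied when grading.
    random_state : int

    Attributes
    ----------
    model_ : TextureModel — the portable trained model.
    selected_features_ : tuple of str
    selection_trace_ : list of float
    classes_ : ndarray of int
    """

    def __init__(
        self,
        feature_config: FeatureConfig | None = None,
        roi_diameter: float | None = None,
        samples_per_class: int = 300,
        max_features: int = 10,
        cv_folds: int = 3,
        priors: str = "uniform",
        var_floor: float = 1e-6,
        boundary_margin: int | None = None,
        reflex_threshold: float = 0.98,
        reflex_dilation: int = 2,
        random_state: int = 0,
    ):
        self.feature_config = feature_config
        self.roi_diameter = roi_diameter
        self.samples_per_class = samples_per_class
        self.max_features = max_features
        self.cv_folds = cv_folds
        self.priors = priors
        self.var_floor = var_floor
        self.boundary_margin = boundary_margin
        self.reflex_threshold = reflex_threshold
        self.reflex_dilation = reflex_dilation
        self.random_state = random_state

    # -- training -------------------------------------------------------
    def fit(self, X, y=None, masks=None) -> "PCOGrader":
        """Fit on labelled images.

        ``X`` is a list of :class:`GrayImage` (or of
        :class:`SyntheticScene`, in which case labels and masks are taken
        from the scenes and ``y`` may be omitted); ``y`` is a list of
        integer label maps with negative values outside the analysis
        region; ``masks`` optionally restricts valid pixels.
        """
        if X and isinstance(X[0], SyntheticScene):
            scenes: list[SyntheticScene] = X
            images = [s.image for s in scenes]
            y = [s.truth_map.labels for s in scenes]
            masks = [s.truth_map.mask.inside for s in scenes]
        else:
            images = list(X)
        if y is None:
            raise ValueError("label maps are required to fit the grader")
        cfg = self.feature_config or FeatureConfig()
        label_maps = [np.asarray(l) for l in y]
        if masks is None:
            masks = [l >= 0 for l in label_maps]
        margin = (
            self.boundary_margin
            if self.boundary_margin is not None
            else cfg.window_size // 2
        )
        rng = np.random.default_rng(self.random_state)
        stacks = [extract_feature_stack(img, cfg) for img in images]
        samples, labels = sample_training_pixels(
            stacks, label_maps, masks, self.samples_per_class, margin, rng
        )
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(N_CLASSES)):
            raise TrainingCoverageError(
                f"training data covers classes {present.tolist()} only"
            )
        names_all = stacks[0].names
        groups = _orientation_groups(names_all)
        center, scale = compute_normalization(samples)
        # tie normalization across orientation quartets so that z-features of
        # a rotated image are an exact permutation of the original's
        for g in groups:
            if len(g) > 1:
                pooled = samples[:, g].ravel()
                center[g] = pooled.mean()
                scale[g] = max(pooled.std(), 1e-8)
        z = (samples - center) / scale
        selector = SequentialFloatingSelector(
            estimator=GaussianBayesClassifier(
                priors=self.priors, var_floor=self.var_floor
            ),
            max_features=self.max_features,
            cv=self.cv_folds,
            random_state=self.random_state,
            groups=groups,
        ).fit(z, labels)
        sel = selector.selected_
        clf = GaussianBayesClassifier(
            priors=self.priors, var_floor=self.var_floor
        ).fit(z[:, sel], labels)
        # tie class parameters across selected quartets (pooled statistics),
        # making the classifier invariant to the quarter-turn permutation
        for g in selector.selected_groups_:
            if len(g) > 1:
                pos = [sel.index(j) for j in g]
                for ci in range(len(clf.classes_)):
                    zc = z[labels == clf.classes_[ci]][:, list(g)].ravel()
                    clf.theta_[ci, pos] = zc.mean()
                    clf.var_[ci, pos] = max(zc.var(), self.var_floor)
        names = tuple(names_all[i] for i in sel)
        self.model_ = TextureModel(
            feature_names=names,
            means=clf.theta_,
            variances=clf.var_,
            priors=clf.class_prior_,
            norm_center=center[sel],
            norm_scale=scale[sel],
            feature_config=cfg,
            metadata={
                "seed": int(self.random_state),
                "config_digest": config_digest(cfg),
                "n_training_pixels": int(len(labels)),
                "selection_trace": [float(v) for v in selector.trace_],
            },
        )
        self.selected_features_ = names
        self.selection_trace_ = selector.trace_
        self.classes_ = np.arange(N_CLASSES)
        return self

    # -- inference ------------------------------------------------------
    def _default_mask(self, img: GrayImage) -> AnalysisMask:
        h, w = img.shape
        diameter = self.roi_diameter or 0.85 * min(h, w)
        if img.mm_per_pixel and self.roi_diameter is None:
            diameter = 4.0 / img.mm_per_pixel  # the 4.0 mm optic disc
        return make_roi_mask((h, w), ((h - 1) / 2.0, (w - 1) / 2.0), diameter)

    def grade(
        self,
        img: GrayImage,
        roi: AnalysisMask | None = None,
        weights: ClassWeights | None = None,
    ) -> tuple[PCOScore, ClassMap]:
        """Segment and score one image.

        Saturated reflex pixels are detected, dilated, and excluded from
        both the segmentation output and the score.
        """
        if not hasattr(self, "model_"):
            raise RuntimeError("grader is not fitted (call fit or load a model)")
        roi = roi or self._default_mask(img)
        reflex = detect_reflex_mask(
            img, self.reflex_threshold, self.reflex_dilation
        )
        mask = combine_masks(roi, reflex)
        stack = extract_feature_stack(img, self.model_.feature_config)
        cmap = predict_map(self.model_, stack, mask)
        return aqua_score(cmap, weights), cmap

    def predict(self, X, masks=None) -> np.ndarray:
        """Scaled (0-100) scores for a list of images or scenes."""
        out = []
        for i, item in enumerate(X):
            img = item.image if isinstance(item, SyntheticScene) else item
            roi = None
            if masks is not None:
                roi = masks[i]
            score, _ = self.grade(img, roi=roi)
            out.append(score.scaled)
        return np.asarray(out)

    # -- model IO -------------------------------------------------------
    def load_model(self, model: TextureModel) -> "PCOGrader":
        self.model_ = model
        self.selected_features_ = model.feature_names
        self.classes_ = np.arange(N_CLASSES)
        return self
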