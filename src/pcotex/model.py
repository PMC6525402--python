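"""Gaussian Bayes pixel classification and wrapper feature selection.

The segmentation engine is a diagonal-covariance Gaussian Bayes classifier
over a small subset of the texture features, the subset being chosen by
sequential forward floating selection (SFFS) with stratified cross-validated
accuracy of the same classifier as the wrapper criterion.

Class labels follow the fixed severity order used throughout the package:

====  ================  ======
index  class             weight
====  ================  ======
0     clear             0.0
1     honeycomb A       0.8
2     honeycomb B       1.0
3     plate             2.0
4     pearl plate       3.0
5     Elschnig pearls   4.0
====  ================  ======
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.model_selection import StratifiedKFold

from .errors import SchemaError, TrainingCoverageError
from .features import FeatureConfig, FeatureStack
from .image import AnalysisMask

MODEL_FORMAT_VERSION = "1"

CLASS_NAMES: tuple[str, ...] = (
    "clear",
    "honeycomb_a",
    "honeycomb_b",
    "plate",
    "pearl_plate",
    "elschnig_pearls",
)
N_CLASSES = len(CLASS_NAMES)

#: sentinel label for pixels outside the analysis mask
MASKED_LABEL = -1


class GaussianBayesClassifier(ClassifierMixin, BaseEstimator):
    """Diagonal-covariance Gaussian Bayes classifier.

    Each class is modelled as an axis-aligned Gaussian (sample mean,
    sample variance floored at ``var_floor``); prediction is the argmax of
    log prior plus summed per-feature log densities, ties resolved toward
    the lowest class index.

    Parameters
    ----------
    priors : {"uniform", "empirical"} or array-like
    var_floor : float
        Lower bound applied to every per-class per-feature variance.
    """

    def __init__(self, priors: str | np.ndarray = "uniform", var_floor: float = 1e-6):
        self.priors = priors
        self.var_floor = var_floor

    def fit(self, X, y) -> "GaussianBayesClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        self.classes_, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise TrainingCoverageError(
                "every present class needs at least 2 training samples"
            )
        n_classes = len(self.classes_)
        self.n_features_in_ = X.shape[1]
        self.theta_ = np.empty((n_classes, self.n_features_in_))
        self.var_ = np.empty((n_classes, self.n_features_in_))
        for i, c in enumerate(self.classes_):
            xc = X[y == c]
            self.theta_[i] = xc.mean(axis=0)
            self.var_[i] = np.maximum(xc.var(axis=0), self.var_floor)
        if isinstance(self.priors, str):
            if self.priors == "uniform":
                self.class_prior_ = np.full(n_classes, 1.0 / n_classes)
            elif self.priors == "empirical":
                self.class_prior_ = counts / counts.sum()
            else:
                raise ValueError(f"unknown priors mode {self.priors!r}")
        else:
            p = np.asarray(self.priors, dtype=np.float64)
            if p.shape != (n_classes,) or not np.isclose(p.sum(), 1.0):
                raise ValueError("explicit priors must match classes and sum to 1")
            self.class_prior_ = p
        return self

    def _joint_log_likelihood(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        jll = np.empty((X.shape[0], len(self.classes_)))
        for i in range(len(self.classes_)):
            d = X - self.theta_[i]
            jll[:, i] = np.log(self.class_prior_[i]) - 0.5 * np.sum(
                np.log(2.0 * np.pi * self.var_[i]) + d * d / self.var_[i], axis=1
            )
        return jll

    def predict(self, X) -> np.ndarray:
        # np.argmax returns the first maximum -> lowest class index on ties
        return self.classes_[np.argmax(self._joint_log_likelihood(X), axis=1)]

    def predict_log_proba(self, X) -> np.ndarray:
        jll = self._joint_log_likelihood(X)
        return jll - logsumexp(jll, axis=1, keepdims=True)

    def predict_proba(self, X) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))


class SequentialFloatingSelector(BaseEstimator):
    """Sequential forward floating feature selection (SFFS).

    Wrapper selection: the criterion of a candidate subset is the mean
    stratified k-fold accuracy of ``estimator`` restricted to that subset.
    Forward steps add the best candidate feature (ties toward the lowest
    feature index) while it improves the criterion; after each inclusion,
    conditional exclusions remove features whose removal beats the best
    subset of the smaller size.  Deterministic given ``random_state``.

    Features may optionally be grouped (``groups`` as a list of column-index
    lists): each group is added or removed as a unit, and ``max_features``
    counts groups.  This is how the grader keeps Gabor orientation quartets
    together so the trained model stays rotation-equivariant.

    Attributes
    ----------
    selected_ : list of int — final subset columns, in order of inclusion.
    selected_groups_ : list of tuple of int — final subset as groups.
    trace_ : list of float — best criterion seen up to each accepted
        forward step (non-decreasing by construction).
    support_ : boolean mask over input features.
    """

    def __init__(
        self,
        estimator: BaseEstimator | None = None,
        max_features: int = 10,
        cv: int = 3,
        random_state: int = 0,
        groups: list[list[int]] | None = None,
    ):
        self.estimator = estimator
        self.max_features = max_features
        self.cv = cv
        self.random_state = random_state
        self.groups = groups

    def _criterion(self, X, y, subset: tuple[int, ...], splits, cache) -> float:
        key = frozenset(subset)
        if key in cache:
            return cache[key]
        est = self.estimator or GaussianBayesClassifier()
        acc = 0.0
        for tr, te in splits:
            m = clone(est).fit(X[np.ix_(tr, list(subset))], y[tr])
            acc += float(np.mean(m.predict(X[np.ix_(te, list(subset))]) == y[te]))
        acc /= len(splits)
        cache[key] = acc
        return acc

    def fit(self, X, y) -> "SequentialFloatingSelector":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        n_features = X.shape[1]
        groups = (
            [tuple(g) for g in self.groups]
            if self.groups is not None
            else [(j,) for j in range(n_features)]
        )
        if not 1 <= self.max_features <= len(groups):
            raise ValueError("max_features must be in [1, n_groups]")
        if self.cv < 2:
            raise ValueError("cv must be >= 2")
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < self.cv:
            raise TrainingCoverageError(
                "each class needs at least `cv` samples for stratified folds"
            )
        skf = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        splits = list(skf.split(X, y))
        cache: dict[frozenset, float] = {}

        def cols(gs: list[tuple[int, ...]]) -> tuple[int, ...]:
            return tuple(j for g in gs for j in g)

        current: list[tuple[int, ...]] = []
        crit_cur = -np.inf
        best_by_size: dict[int, float] = {}
        trace: list[float] = []
        while len(current) < self.max_features:
            cands = [g for g in groups if g not in current]
            scores = [
                self._criterion(X, y, cols(current + [g]), splits, cache)
                for g in cands
            ]
            best = int(np.argmax(scores))  # ties -> lowest group index
            if current and scores[best] <= crit_cur:
                break
            just_added = cands[best]
            current.append(just_added)
            crit_cur = scores[best]
            best_by_size[len(current)] = max(
                best_by_size.get(len(current), -np.inf), crit_cur
            )
            trace.append(max(trace[-1], crit_cur) if trace else crit_cur)
            # conditional exclusion
            while len(current) > 2:
                rem_scores = [
                    self._criterion(
                        X, y, cols([f for f in current if f != g]), splits, cache
                    )
                    for g in current
                ]
                r = int(np.argmax(rem_scores))
                if (
                    current[r] == just_added
                    or rem_scores[r] <= best_by_size.get(len(current) - 1, -np.inf)
                ):
                    break
                current.pop(r)
                crit_cur = max(rem_scores)
                best_by_size[len(current)] = crit_cur
        self.selected_groups_ = current
        self.selected_ = list(cols(current))
        self.trace_ = trace
        self.criterion_ = crit_cur
        self.n_features_in_ = n_features
        self.support_ = np.zeros(n_features, dtype=bool)
        self.support_[self.selected_] = True
        return self

    def get_support(self) -> np.ndarray:
        return self.support_

    def transform(self, X) -> np.ndarray:
        return np.asarray(X)[:, self.selected_]


# ---------------------------------------------------------------------------
# portable trained-model container
# ---------------------------------------------------------------------------

@dataclass
class TextureModel:
    """A trained six-class texture model in a portable form.

    Holds the selected feature names, per-class diagonal Gaussian
    parameters *in normalized feature space*, class priors, and the
    normalization (center, scale) that maps raw features into that space.
    """

    feature_names: tuple[str, ...]
    means: np.ndarray  # (n_classes, k)
    variances: np.ndarray  # (n_classes, k)
    priors: np.ndarray  # (n_classes,)
    norm_center: np.ndarray  # (k,)
    norm_scale: np.ndarray  # (k,)
    feature_config: FeatureConfig
    class_names: tuple[str, ...] = CLASS_NAMES
    metadata: dict = field(default_factory=dict)
    version: str = MODEL_FORMAT_VERSION

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        k = len(self.feature_names)
        n = len(self.class_names)
        self.means = np.asarray(self.means, dtype=np.float64).reshape(n, k)
        self.variances = np.asarray(self.variances, dtype=np.float64).reshape(n, k)
        self.priors = np.asarray(self.priors, dtype=np.float64).reshape(n)
        self.norm_center = np.asarray(self.norm_center, dtype=np.float64).reshape(k)
        self.norm_scale = np.asarray(self.norm_scale, dtype=np.float64).reshape(k)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("class priors must sum to 1")
        if (self.variances <= 0).any() or (self.norm_scale <= 0).any():
            raise ValueError("variances and scales must be positive")

    # -- inference ------------------------------------------------------
    def _log_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        squeeze = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != len(self.feature_names):
            raise SchemaError("feature vector does not cover the selected features")
        z = (x - self.norm_center) / self.norm_scale
        out = np.empty((x.shape[0], len(self.class_names)))
        for i in range(len(self.class_names)):
            d = z - self.means[i]
            out[:, i] = np.log(self.priors[i]) - 0.5 * np.sum(
                np.log(2.0 * np.pi * self.variances[i]) + d * d / self.variances[i],
                axis=1,
            )
        return out[0] if squeeze else out

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Softmax-normalized class probabilities for feature vector(s)."""
        s = self._log_scores(x)
        s = np.atleast_2d(s)
        p = np.exp(s - logsumexp(s, axis=1, keepdims=True))
        return p[0] if np.asarray(x).ndim == 1 else p

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "format": "pcotex-texture-model",
                "version": self.version,
                "class_names": list(self.class_names),
                "feature_names": list(self.feature_names),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "priors": self.priors.tolist(),
                "norm_center": self.norm_center.tolist(),
                "norm_scale": self.norm_scale.tolist(),
                "feature_config": self.feature_config.to_dict(),
                "metadata": self.metadata,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TextureModel":
        d = json.loads(text)
        if d.get("format") != "pcotex-texture-model":
            raise SchemaError("not a texture model file")
        if d.get("version") != MODEL_FORMAT_VERSION:
            raise SchemaError(f"unsupported model version {d.get('version')!r}")
        return cls(
            feature_names=tuple(d["feature_names"]),
            means=np.array(d["means"]),
            variances=np.array(d["variances"]),
            priors=np.array(d["priors"]),
            norm_center=np.array(d["norm_center"]),
            norm_scale=np.array(d["norm_scale"]),
            feature_config=FeatureConfig.from_dict(d["feature_config"]),
            class_names=tuple(d["class_names"]),
            metadata=d.get("metadata", {}),
            version=d["version"],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TextureModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class ClassMap:
    """Per-pixel class labels over the analysis mask.

    ``labels`` holds values in [0, n_classes) on mask-true pixels and the
    sentinel ``MASKED_LABEL`` elsewhere.
    """

    labels: np.ndarray
    mask: AnalysisMask

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=np.int16)
        if lab.shape != self.mask.shape:
            raise ValueError("labels and mask shapes differ")
        inside = self.mask.inside
        if (lab[inside] < 0).any() or (lab[inside] >= N_CLASSES).any():
            raise ValueError("labels on mask-true pixels must be in [0, 6)")
        lab = lab.copy()
        lab[~inside] = MASKED_LABEL
        self.labels = lab

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def class_counts(self) -> np.ndarray:
        inside = self.labels[self.mask.inside]
        return np.bincount(inside, minlength=N_CLASSES).astype(np.int64)


# ---------------------------------------------------------------------------
# functional surface over the estimator classes
# ---------------------------------------------------------------------------

def compute_normalization(
    samples: np.ndarray, scale_floor: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature (center, scale) = (mean, sd) of a training sample matrix."""
    samples = np.asarray(samples, dtype=np.float64)
    center = samples.mean(axis=0)
    scale = np.maximum(samples.std(axis=0), scale_floor)
    return center, scale


def normalize_features(
    stack: FeatureStack,
    center: dict[str, float] | np.ndarray,
    scale: dict[str, float] | np.ndarray,
    scale_floor: float = 1e-8,
) -> FeatureStack:
    """Z-transform every plane with the given per-feature statistics.

    ``center``/``scale`` may be dicts keyed by feature name (missing names
    raise a schema error) or arrays aligned with ``stack.names``.
    """
    if isinstance(center, dict) or isinstance(scale, dict):
        try:
            c = np.array([center[n] for n in stack.names], dtype=np.float64)
            s = np.array([scale[n] for n in stack.names], dtype=np.float64)
        except KeyError as exc:
            raise SchemaError(f"no normalization stats for feature {exc}") from exc
    else:
        c = np.asarray(center, dtype=np.float64)
        s = np.asarray(scale, dtype=np.float64)
        if c.shape != (len(stack.names),) or s.shape != (len(stack.names),):
            raise SchemaError("normalization stats do not cover every plane")
    s = np.maximum(s, scale_floor)
    return FeatureStack((stack.planes - c[:, None, None]) / s[:, None, None],
                        stack.names)


def fit_bayes(
    samples: np.ndarray,
    labels: np.ndarray,
    priors_mode: str = "uniform",
    feature_names: tuple[str, ...] | None = None,
    feature_config: FeatureConfig | None = None,
    norm_center: np.ndarray | None = None,
    norm_scale: np.ndarray | None = None,
    var_floor: float = 1e-6,
    metadata: dict | None = None,
) -> TextureModel:
    """Fit the six-class diagonal Gaussian Bayes model on labelled samples.

    ``samples`` must already be in normalized feature space (or pass the
    normalization stats that produced them for the model record; identity
    is assumed when omitted).  All six classes must be present.
    """
    samples = np.asarray(samples, dtype=np.float64)
    labels = np.asarray(labels)
    present = np.unique(labels)
    if not np.array_equal(present, np.arange(N_CLASSES)):
        raise TrainingCoverageError(
            f"all {N_CLASSES} classes required; got labels {present.tolist()}"
        )
    clf = GaussianBayesClassifier(priors=priors_mode, var_floor=var_floor)
    clf.fit(samples, labels)
    k = samples.shape[1]
    names = tuple(feature_names) if feature_names else tuple(
        f"f{i}" for i in range(k)
    )
    return TextureModel(
        feature_names=names,
        means=clf.theta_,
        variances=clf.var_,
        priors=clf.class_prior_,
        norm_center=np.zeros(k) if norm_center is None else norm_center,
        norm_scale=np.ones(k) if norm_scale is None else norm_scale,
        feature_config=feature_config or FeatureConfig(),
        metadata=metadata or {},
    )


def select_features(
    samples: np.ndarray,
    labels: np.ndarray,
    max_k: int = 10,
    folds: int = 3,
    seed: int = 0,
    priors_mode: str = "uniform",
) -> tuple[list[int], list[float]]:
    """SFFS over feature columns; returns (selected indices, accuracy trace)."""
    sel = SequentialFloatingSelector(
        estimator=GaussianBayesClassifier(priors=priors_mode),
        max_features=max_k,
        cv=folds,
        random_state=seed,
    ).fit(samples, labels)
    return sel.selected_, sel.trace_


def predict_map(model: TextureModel, stack: FeatureStack, mask: AnalysisMask) -> ClassMap:
    """Classify every mask-true pixel; masked pixels get the sentinel label."""
    if stack.image_shape != mask.shape:
        raise ValueError("stack and mask shapes differ")
    sub = stack.select(model.feature_names)  # raises SchemaError when missing
    x = sub.matrix(mask.inside)
    labels = np.full(mask.shape, MASKED_LABEL, dtype=np.int16)
    if len(x):
        scores = model._log_scores(x)
        labels[mask.inside] = np.argmax(scores, axis=1)
    return ClassMap(labels, mask)


def config_digest(cfg: FeatureConfig) -> str:
    """Short stable hash of a feature configuration, for provenance records."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
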