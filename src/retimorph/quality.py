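"""Image quality assessment from global shape features of the vessel map.

An image is usable for vasculometry when enough of the vasculature segments
cleanly; it need not be perfect — an image can be adequate even if only part
of the vascular tree is visible.  Three global shape features summarise the
segmented vessel map:

* ``area`` — fraction of image pixels labelled vessel;
* ``fragmentation`` — connected components per vessel pixel (clean maps are
  one or a few large components; noise and occlusion shatter them);
* ``complexity`` — skeleton pixels per vessel pixel (curvilinear structure is
  skeleton-rich for its area; blobs are not).

A support vector machine with an RBF kernel, selected by k-fold
cross-validation, maps the features to a probability of *inadequate* quality;
that probability is normalised to [0, 1] and flipped into a quality score
(1 = highest quality).  An image is labelled inadequate when its score is
less than or equal to the decision threshold (default 0.48, boundary
inclusive).

The fitted model is serialised to JSON (kernel parameters, support data,
normalisation constants) and round-trips bit-exactly: predictions always go
through the stored arrays, never a live sklearn object.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage import morphology
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .segmentation import LineDetectorConfig, VesselMask, segment_vessels

__all__ = [
    "QualityFeatures",
    "QualityResult",
    "QualityModel",
    "quality_features",
    "fit_quality_classifier",
    "score_image",
    "tabulate_adequacy",
    "DEFAULT_QUALITY_THRESHOLD",
]

DEFAULT_QUALITY_THRESHOLD = 0.48

_C_GRID = (0.1, 1.0, 10.0, 100.0)
_GAMMA_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class QualityFeatures:
    area: float           # vessel fraction of the image, in [0, 1]
    fragmentation: float  # connected components per vessel pixel
    complexity: float     # skeleton pixels per vessel pixel

    def as_array(self) -> np.ndarray:
        return np.array([self.area, self.fragmentation, self.complexity])


@dataclass(frozen=True)
class QualityResult:
    features: QualityFeatures
    p_inadequate: float
    score: float              # 1 - p_inadequate, 1 = highest quality
    label: str                # "adequate" | "inadequate"
    threshold_used: float


def quality_features(mask: VesselMask | np.ndarray) -> QualityFeatures:
    """Global shape features of a binary vessel map (empty map -> all zeros)."""
    data = mask.data if isinstance(mask, VesselMask) else np.asarray(mask, bool)
    n_vessel = int(data.sum())
    if n_vessel == 0:
        return QualityFeatures(0.0, 0.0, 0.0)
    _, n_comp = ndimage.label(data, structure=np.ones((3, 3)))
    skel = morphology.skeletonize(data)
    return QualityFeatures(
        area=n_vessel / data.size,
        fragmentation=n_comp / n_vessel,
        complexity=int(skel.sum()) / n_vessel,
    )


class QualityModel:
    """Frozen RBF-SVM quality classifier.

    Stores the standardisation constants, support vectors, dual coefficients,
    intercept and kernel width, plus the score-normalisation constants fitted
    on the training decision values.  ``p_inadequate`` is a logistic squash of
    the min-max-rescaled decision value, so it lies in [0, 1] for any input
    (positive decision values = inadequate).
    """

    _SQUASH = 8.0  # logistic steepness over the rescaled [-1/2, 1/2] range

    def __init__(self, scaler_mean, scaler_scale, support_vectors, dual_coef,
                 intercept, gamma, score_min, score_max, threshold=DEFAULT_QUALITY_THRESHOLD,
                 cv_params=None):
        self.scaler_mean = np.asarray(scaler_mean, float)
        self.scaler_scale = np.asarray(scaler_scale, float)
        self.support_vectors = np.asarray(support_vectors, float)
        self.dual_coef = np.asarray(dual_coef, float).ravel()
        self.intercept = float(intercept)
        self.gamma = float(gamma)
        self.score_min = float(score_min)
        self.score_max = float(score_max)
        self.threshold = float(threshold)
        self.cv_params = dict(cv_params or {})

    # -- prediction ---------------------------------------------------------
    def decision_value(self, features) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, float))
        z = (x - self.scaler_mean) / self.scaler_scale
        sq = ((z[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.gamma * sq) @ self.dual_coef + self.intercept

    def p_inadequate(self, features) -> np.ndarray:
        d = self.decision_value(features)
        span = self.score_max - self.score_min
        if span <= 0:
            span = 1.0
        u = (d - self.score_min) / span - 0.5
        return 1.0 / (1.0 + np.exp(-self._SQUASH * u))

    def classify(self, features, threshold: float | None = None) -> QualityResult:
        feats = features if isinstance(features, QualityFeatures) else \
            QualityFeatures(*np.asarray(features, float))
        thr = self.threshold if threshold is None else float(threshold)
        p = float(self.p_inadequate(feats.as_array())[0])
        return label_from_probability(feats, p, thr)

    # -- persistence --------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "kind": "retimorph-quality-svm-rbf",
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "score_min": self.score_min,
            "score_max": self.score_max,
            "threshold": self.threshold,
            "cv_params": self.cv_params,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "QualityModel":
        return cls(d["scaler_mean"], d["scaler_scale"], d["support_vectors"],
                   d["dual_coef"], d["intercept"], d["gamma"],
                   d["score_min"], d["score_max"], d.get("threshold", DEFAULT_QUALITY_THRESHOLD),
                   d.get("cv_params"))

    @classmethod
    def load(cls, path) -> "QualityModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def label_from_probability(features: QualityFeatures, p_inadequate: float,
                           threshold: float = DEFAULT_QUALITY_THRESHOLD) -> QualityResult:
    """Flip the inadequate-probability into a quality score and label it.

    ``score = 1 - p_inadequate``; inadequate iff ``score <= threshold``
    (boundary inclusive).
    """
    score = 1.0 - p_inadequate
    label = "inadequate" if score <= threshold else "adequate"
    return QualityResult(features, p_inadequate, score, label, threshold)


def fit_quality_classifier(features, labels, folds: int = 5, seed: int = 0,
                           threshold: float = DEFAULT_QUALITY_THRESHOLD) -> QualityModel:
    """Fit the RBF-SVM quality classifier with k-fold CV model selection.

    ``features`` is (n, 3) (or a list of :class:`QualityFeatures`); ``labels``
    are ``"adequate"`` / ``"inadequate"`` strings (or 0/1 with 1 =
    inadequate).  Both classes must be present.  Hyperparameters (C, gamma)
    are selected over a small logarithmic grid by stratified k-fold CV with a
    seeded fold assignment, so refitting on identical data is deterministic.
    """
    X = np.array([f.as_array() if isinstance(f, QualityFeatures) else np.asarray(f, float)
                  for f in features])
    y = np.array([1 if (l == "inadequate" or l == 1) else 0 for l in labels])
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both quality classes")
    pipe = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf")),
    ])
    grid = {"svm__C": list(_C_GRID), "svm__gamma": list(_GAMMA_GRID)}
    folds = max(2, min(folds, int(np.bincount(y).min())))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(pipe, grid, cv=cv, n_jobs=1)
    search.fit(X, y)
    best = search.best_estimator_
    scaler: StandardScaler = best.named_steps["scale"]
    svm: SVC = best.named_steps["svm"]
    decisions = best.decision_function(X)
    return QualityModel(
        scaler_mean=scaler.mean_, scaler_scale=scaler.scale_,
        support_vectors=svm.support_vectors_, dual_coef=svm.dual_coef_,
        intercept=svm.intercept_[0], gamma=svm._gamma,
        score_min=float(decisions.min()), score_max=float(decisions.max()),
        threshold=threshold,
        cv_params={k: float(v) for k, v in search.best_params_.items()},
    )


QUALITY_WORKING_LONG_SIDE = 256


def score_image(image: np.ndarray, model: QualityModel,
                threshold: float | None = None,
                config: LineDetectorConfig | None = None,
                working_long_side: int | None = QUALITY_WORKING_LONG_SIDE) -> QualityResult:
    """Segment (without post-processing), featurise, classify one image.

    Fragmentation and complexity are per-vessel-pixel quantities and thus
    resolution-dependent, so quality scoring always runs at a fixed working
    resolution (long side 256 px by default) — a trained gate then transfers
    across capture resolutions.
    """
    mask = segment_vessels(image, config, pre=True, post=False,
                           working_long_side=working_long_side)
    feats = quality_features(mask)
    return model.classify(feats, threshold)


def tabulate_adequacy(results) -> dict:
    """Tabulate per-participant counts of adequate images.

    ``results`` is an iterable of ``(participant_id, QualityResult | str)``
    pairs.  Returns counts of participants with exactly 0, 1, 2, and with
    >=1 and >=3 adequate images, plus the participant total.
    """
    per = {}
    for pid, res in results:
        label = res.label if hasattr(res, "label") else str(res)
        per[pid] = per.get(pid, 0) + (1 if label == "adequate" else 0)
    counts = list(per.values())
    return {
        "participants": len(counts),
        "0": sum(1 for c in counts if c == 0),
        "1": sum(1 for c in counts if c == 1),
        "2": sum(1 for c in counts if c == 2),
        ">=1": sum(1 for c in counts if c >= 1),
        ">=3": sum(1 for c in counts if c >= 3),
    }
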