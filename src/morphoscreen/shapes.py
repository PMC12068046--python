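"""Cell-shape classification and the PCA "normal" penetrance filter.

A regularized multinomial logistic (linear) classifier assigns every cell
to one of five reference shapes — spindly, large_round, triangular, fan,
small_round — from its standardized feature vector.  Translocation-ratio
features are deliberately absent from the registry used here.

The normal filter reproduces the penetrance procedure: PCA on the pooled
standardized single-cell features of mock plus shape-enriched
populations; the "normal" region is the axis-aligned box centred on the
mean of (PC1, PC2) with half-width one standard deviation per component;
a binary linear classifier is then trained with mock cells inside the box
as "normal" and everything else as "not normal".  The per-well fraction
of normal cells is the penetrance readout; its depletion (Z <= -1) marks
a shape hit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split

SHAPE_CLASSES = ("spindly", "large_round", "triangular", "fan", "small_round")

__all__ = [
    "SHAPE_CLASSES",
    "ShapeModel",
    "NormalModel",
    "train_shape_classifier",
    "classify_cells",
    "derive_normal_classifier",
    "filter_normal",
]


def _standardize_params(x: np.ndarray):
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


@dataclass
class ShapeModel:
    """Linear five-shape classifier with its standardization and registry."""

    classes: tuple[str, ...]
    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    coef: np.ndarray  # (n_classes, n_features)
    intercept: np.ndarray
    holdout_accuracy: float
    exemplar_counts: dict
    seed: int

    def decision_scores(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.mean) / self.sd
        return z @ self.coef.T + self.intercept

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise ValueError("feature registry mismatch with trained model")
        scores = self.decision_scores(features.to_numpy(dtype=float))
        # ties broken by fixed class order (first max wins)
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.classes),
                "feature_names": self.feature_names,
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept.tolist(),
                "holdout_accuracy": self.holdout_accuracy,
                "exemplar_counts": self.exemplar_counts,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ShapeModel":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            feature_names=d["feature_names"],
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            coef=np.asarray(d["coef"]),
            intercept=np.asarray(d["intercept"]),
            holdout_accuracy=d["holdout_accuracy"],
            exemplar_counts=d["exemplar_counts"],
            seed=d["seed"],
        )


def train_shape_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    min_exemplars: int = 20,
    C: float = 1.0,
    holdout_fraction: float = 0.25,
) -> ShapeModel:
    """Fit the five-shape linear classifier on labelled exemplars.

    Features are standardized, then a multinomial logistic regression
    with L2 regularization (inverse strength ``C``) is fitted; held-out
    accuracy on a stratified ``holdout_fraction`` split is reported and
    the final weights are refitted on all exemplars.
    """
    labels = np.asarray(labels)
    present = set(labels)
    if present != set(SHAPE_CLASSES):
        raise ValueError(
            f"training set must cover exactly the classes {SHAPE_CLASSES}; got {sorted(present)}"
        )
    counts = {c: int(np.sum(labels == c)) for c in SHAPE_CLASSES}
    for c, n in counts.items():
        if n < min_exemplars:
            raise ValueError(f"class {c!r} has {n} exemplars; need >= {min_exemplars}")

    x = features.to_numpy(dtype=float)
    mean, sd = _standardize_params(x)
    z = (x - mean) / sd

    xtr, xte, ytr, yte = train_test_split(
        z, labels, test_size=holdout_fraction, random_state=seed, stratify=labels
    )
    clf = LogisticRegression(C=C, max_iter=2000)
    clf.fit(xtr, ytr)
    acc = float(np.mean(clf.predict(xte) == yte))
    clf.fit(z, labels)

    order = [list(clf.classes_).index(c) for c in SHAPE_CLASSES]
    return ShapeModel(
        classes=SHAPE_CLASSES,
        feature_names=list(features.columns),
        mean=mean,
        sd=sd,
        coef=clf.coef_[order],
        intercept=clf.intercept_[order],
        holdout_accuracy=acc,
        exemplar_counts=counts,
        seed=seed,
    )


def classify_cells(model: ShapeModel, features: pd.DataFrame) -> np.ndarray:
    """Predict one shape label per cell."""
    return model.predict(features)


@dataclass
class NormalModel:
    """PCA box + binary linear classifier defining the "normal" region."""

    feature_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    loadings: np.ndarray  # (2, n_features)
    centre: np.ndarray  # (2,)
    half_width: np.ndarray  # (2,) = 1 SD per PC
    coef: np.ndarray
    intercept: float
    seed: int

    def project(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise ValueError("feature registry mismatch with normal model")
        z = (features.to_numpy(dtype=float) - self.mean) / self.sd
        return z @ self.loadings.T

    def in_box(self, features: pd.DataFrame) -> np.ndarray:
        pc = self.project(features)
        return np.all(np.abs(pc - self.centre) <= self.half_width, axis=1)

    def predict_normal(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.feature_names:
            raise ValueError("feature registry mismatch with normal model")
        z = (features.to_numpy(dtype=float) - self.mean) / self.sd
        return (z @ self.coef + self.intercept) > 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "mean": self.mean.tolist(),
                "sd": self.sd.tolist(),
                "loadings": self.loadings.tolist(),
                "centre": self.centre.tolist(),
                "half_width": self.half_width.tolist(),
                "coef": self.coef.tolist(),
                "intercept": self.intercept,
                "seed": self.seed,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "NormalModel":
        d = json.loads(text)
        return cls(
            feature_names=d["feature_names"],
            mean=np.asarray(d["mean"]),
            sd=np.asarray(d["sd"]),
            loadings=np.asarray(d["loadings"]),
            centre=np.asarray(d["centre"]),
            half_width=np.asarray(d["half_width"]),
            coef=np.asarray(d["coef"]),
            intercept=d["intercept"],
            seed=d["seed"],
        )


def derive_normal_classifier(
    mock_features: pd.DataFrame,
    enriched_features: pd.DataFrame,
    seed: int = 0,
    box_population: str = "pooled",
) -> NormalModel:
    """Derive the PCA normal region and its binary classifier.

    ``enriched_features`` pools cells from wells whose perturbation
    maximally enriches each shape.  ``box_population`` selects which cells
    define the box centre/width: ``"pooled"`` (default), ``"mock"`` or
    ``"enriched"``.
    """
    if list(mock_features.columns) != list(enriched_features.columns):
        raise ValueError("mock and enriched feature registries differ")
    pooled = pd.concat([mock_features, enriched_features], axis=0, ignore_index=True)
    if pooled.shape[1] < 2:
        raise ValueError("need at least 2 features for a 2-component PCA")
    x = pooled.to_numpy(dtype=float)
    mean, sd = _standardize_params(x)
    z = (x - mean) / sd

    pca = PCA(n_components=2, random_state=seed)
    pca.fit(z)
    loadings = pca.components_.copy()
    # sign convention: largest-|loading| entry of each component positive
    for k in range(2):
        j = np.argmax(np.abs(loadings[k]))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]

    pop = {"pooled": pooled, "mock": mock_features, "enriched": enriched_features}[box_population]
    zp = (pop.to_numpy(dtype=float) - mean) / sd
    pcs = zp @ loadings.T
    centre = pcs.mean(axis=0)
    half_width = pcs.std(axis=0, ddof=0)

    z_mock = (mock_features.to_numpy(dtype=float) - mean) / sd
    pc_mock = z_mock @ loadings.T
    inside = np.all(np.abs(pc_mock - centre) <= half_width, axis=1)
    # training set: mock-inside-box = normal, everything else = not normal
    z_enr = (enriched_features.to_numpy(dtype=float) - mean) / sd
    xtrain = np.vstack([z_mock, z_enr])
    ytrain = np.concatenate([inside, np.zeros(len(z_enr), dtype=bool)])
    if ytrain.all() or not ytrain.any():
        raise ValueError("normal training labels degenerate (all one class)")
    clf = LogisticRegression(max_iter=2000, random_state=seed)
    clf.fit(xtrain, ytrain)

    return NormalModel(
        feature_names=list(mock_features.columns),
        mean=mean,
        sd=sd,
        loadings=loadings,
        centre=centre,
        half_width=half_width,
        coef=clf.coef_[0],
        intercept=float(clf.intercept_[0]),
        seed=seed,
    )


def filter_normal(features: pd.DataFrame, model: NormalModel):
    """Partition cells into (normal, phenotypic) and report the normal fraction."""
    if len(features) == 0:
        return features.iloc[:0], features.iloc[:0], float("nan")
    is_normal = model.predict_normal(features)
    normal = features[is_normal]
    phenotypic = features[~is_normal]
    return normal, phenotypic, float(np.mean(is_normal))
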