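"""Descriptor -> PCA -> LDA recognition pipeline and evaluation protocols.

The classifier is deliberately simple: principal component analysis (at
most 200 components, the count chosen by 5-fold cross-validation on the
training set) followed by linear discriminant analysis.  Evaluation runs
under two split protocols used for texture benchmarks:

``sample_holdout``
    leave-one-acquisition-sample-out: train on all but one acquisition
    sample per class, test on the held-out one, over every combination
    (KTH-TIPS-2b style: 4 samples per class -> 4 folds);
``half_half``
    per-class balanced random halves, repeated ``repetitions`` times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .backbones import DualStreamFeaturizer, FeatureCache
from .datasets import LabeledDataset

__all__ = [
    "SplitPlan",
    "make_split_plan",
    "PCALDAClassifier",
    "TextureClassifier",
    "EvalReport",
    "evaluate",
    "fold_seed",
]

DEFAULT_COMPONENT_GRID = (10, 25, 50, 100, 150, 200)
MAX_COMPONENTS = 200


def fold_seed(master_seed: int, index: int) -> int:
    """Per-fold seed from a master seed by a fixed counter scheme."""
    return (int(master_seed) * 100003 + 7919 * int(index) + 1) % (2**31 - 1)


@dataclass
class SplitPlan:
    protocol: str
    folds: list[tuple[np.ndarray, np.ndarray]]
    repetitions: int
    seed: int

    def __post_init__(self) -> None:
        for i, (tr, te) in enumerate(self.folds):
            if len(tr) == 0 or len(te) == 0:
                raise ValueError(f"fold {i}: train and test sets must be non-empty")
            if set(tr) & set(te):
                raise ValueError(f"fold {i}: train and test sets overlap")

    def __len__(self) -> int:
        return len(self.folds)


def make_split_plan(
    ds: LabeledDataset,
    protocol: str = "half_half",
    repetitions: int = 10,
    seed: int = 0,
) -> SplitPlan:
    """Enumerate train/test partitions under a named protocol (deterministic in seed)."""
    labels = ds.labels()
    if protocol == "sample_holdout":
        tags = ds.tags
        if tags is None:
            raise ValueError(
                "sample_holdout protocol needs acquisition-sample tags "
                "(load the dataset with a tag_pattern)"
            )
        folds = []
        for tag in tags:
            test = np.array([i for i, s in enumerate(ds.samples) if s.tag == tag])
            train = np.array([i for i, s in enumerate(ds.samples) if s.tag != tag])
            folds.append((train, test))
        return SplitPlan("sample_holdout", folds, repetitions=len(tags), seed=seed)
    if protocol == "half_half":
        folds = []
        for rep in range(repetitions):
            rng = np.random.default_rng(fold_seed(seed, rep))
            train_idx: list[int] = []
            test_idx: list[int] = []
            for cls in ds.classes:
                members = np.flatnonzero(labels == cls)
                perm = rng.permutation(members)
                half = len(members) // 2
                train_idx.extend(perm[:half])
                test_idx.extend(perm[half:])
            folds.append((np.sort(np.array(train_idx)), np.sort(np.array(test_idx))))
        return SplitPlan("half_half", folds, repetitions=repetitions, seed=seed)
    raise ValueError(f"unknown protocol {protocol!r}")


class PCALDAClassifier(BaseEstimator, ClassifierMixin):
    """PCA (CV-selected component count, capped at 200) followed by LDA.

    The number of principal components is picked from ``candidate_grid``
    (intersected with the rank bound min(n_train - 1, n_features) and the
    200-component cap) by mean ``cv_folds``-fold cross-validated accuracy
    of the downstream LDA, ties broken toward fewer components.  The LDA
    uses the SVD solver, whose tolerance cutoff handles a rank-deficient
    pooled covariance deterministically.

    Attributes (after fit): ``n_components_``, ``pca_``, ``lda_``,
    ``classes_``, ``cv_results_``.
    """

    def __init__(
        self,
        candidate_grid: tuple = DEFAULT_COMPONENT_GRID,
        max_components: int = MAX_COMPONENTS,
        cv_folds: int = 5,
        random_state: int | None = 0,
    ):
        self.candidate_grid = candidate_grid
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _candidates(self, n_samples: int, n_features: int) -> list[int]:
        bound = min(self.max_components, n_samples - 1, n_features)
        cands = sorted({int(c) for c in self.candidate_grid if 1 <= c <= bound})
        return cands or [bound]

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("training data must contain at least 2 classes")
        if counts.min() < 2:
            raise ValueError("every class needs >= 2 training samples")
        candidates = self._candidates(X.shape[0], X.shape[1])
        if len(candidates) > 1:
            n_splits = min(self.cv_folds, counts.min())
            cv = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                 random_state=self.random_state)
            mean_acc = []
            for n_comp in candidates:
                accs = []
                for tr, te in cv.split(X, y):
                    # inner-fold rank can be lower than the outer bound
                    k = min(n_comp, len(tr) - 1, X.shape[1])
                    pca = PCA(n_components=k, svd_solver="full").fit(X[tr])
                    lda = LinearDiscriminantAnalysis(solver="svd")
                    lda.fit(pca.transform(X[tr]), y[tr])
                    accs.append(lda.score(pca.transform(X[te]), y[te]))
                mean_acc.append(float(np.mean(accs)))
            best = int(np.argmax(mean_acc))  # argmax takes the first (fewest) on ties
            self.cv_results_ = {"candidates": candidates, "mean_cv_accuracy": mean_acc}
            n_components = candidates[best]
        else:
            self.cv_results_ = {"candidates": candidates, "mean_cv_accuracy": [None]}
            n_components = candidates[0]
        self.n_components_ = n_components
        self.pca_ = PCA(n_components=n_components, svd_solver="full").fit(X)
        self.lda_ = LinearDiscriminantAnalysis(solver="svd")
        self.lda_.fit(self.pca_.transform(X), y)
        self.classes_ = self.lda_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.predict(self.pca_.transform(np.asarray(X, dtype=np.float64)))

    def decision_function(self, X):
        check_is_fitted(self, "lda_")
        return self.lda_.decision_function(self.pca_.transform(np.asarray(X, dtype=np.float64)))


class TextureClassifier(BaseEstimator, ClassifierMixin):
    """Full pipeline: dual-stream descriptors -> PCA -> LDA, with optional q selection.

    ``fit`` takes a sequence of images (2-D gray or HxWx3 color integer
    arrays) and labels.  If ``q_grid`` is given, the entropic index is
    selected by ``kfold``-fold cross-validation on the training images
    (see :func:`entrotex.selection.sweep_q`); otherwise the fixed ``q``
    is used.

    Attributes (after fit): ``q_``, ``featurizer_``, ``classifier_``,
    ``classes_``, and ``sweep_result_`` when a grid was swept.
    """

    def __init__(
        self,
        q: float = 1.5,
        q_grid: tuple | None = None,
        kfold: int = 5,
        radius: int = 2,
        bin_width: int = 32,
        normalize: bool = True,
        border_mode: str = "reflect",
        q1_mode: str = "bgs_limit",
        backbone: str = "pooled-stats",
        stream: str = "fused",
        candidate_grid: tuple = DEFAULT_COMPONENT_GRID,
        max_components: int = MAX_COMPONENTS,
        cv_folds: int = 5,
        random_state: int | None = 0,
        cache: FeatureCache | None = None,
    ):
        self.q = q
        self.q_grid = q_grid
        self.kfold = kfold
        self.radius = radius
        self.bin_width = bin_width
        self.normalize = normalize
        self.border_mode = border_mode
        self.q1_mode = q1_mode
        self.backbone = backbone
        self.stream = stream
        self.candidate_grid = candidate_grid
        self.max_components = max_components
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.cache = cache

    def _featurizer(self, q: float) -> DualStreamFeaturizer:
        return DualStreamFeaturizer(
            q=q,
            radius=self.radius,
            bin_width=self.bin_width,
            normalize=self.normalize,
            border_mode=self.border_mode,
            q1_mode=self.q1_mode,
            backbone=self.backbone,
            stream=self.stream,
            cache=self.cache,
        ).fit()

    def fit(self, X, y):
        from .selection import sweep_q  # local import to avoid a cycle

        y = np.asarray(y)
        if self.q_grid is not None:
            self.sweep_result_ = sweep_q(
                X,
                y,
                grid=self.q_grid,
                k=self.kfold,
                seed=self.random_state or 0,
                pipeline=self,
            )
            self.q_ = self.sweep_result_.best_q
        else:
            self.q_ = float(self.q)
        self.featurizer_ = self._featurizer(self.q_)
        features = self.featurizer_.transform(X)
        self.classifier_ = PCALDAClassifier(
            candidate_grid=self.candidate_grid,
            max_components=self.max_components,
            cv_folds=self.cv_folds,
            random_state=self.random_state,
        ).fit(features, y)
        self.classes_ = self.classifier_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "classifier_")
        return self.classifier_.predict(self.featurizer_.transform(X))


@dataclass
class EvalReport:
    """Per-fold accuracies, their mean, and the pooled confusion matrix."""

    per_fold_accuracy: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # rows = true class, columns = predicted
    classes: list[str]
    chosen_components: list[int]
    q_used: list[float]
    protocol: str
    seed: int

    def to_json(self) -> str:
        payload = {
            "protocol": self.protocol,
            "seed": self.seed,
            "per_fold_accuracy": self.per_fold_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "classes": self.classes,
            "chosen_components": self.chosen_components,
            "q_used": self.q_used,
            "confusion": self.confusion.tolist(),
        }
        return json.dumps(payload, indent=2)


def evaluate(
    ds: LabeledDataset,
    plan: SplitPlan,
    pipeline: TextureClassifier | None = None,
    cache: FeatureCache | None = None,
) -> EvalReport:
    """Run the pipeline over every fold of a split plan.

    The reducer, classifier and any q selection are fit on each fold's
    training indices only.  A shared feature cache makes repeated folds
    cheap without affecting results.  Any fold failure aborts with the
    fold index in the message.
    """
    if pipeline is None:
        pipeline = TextureClassifier()
    if cache is None:
        cache = pipeline.cache or FeatureCache()
    classes = ds.classes
    class_index = {c: i for i, c in enumerate(classes)}
    images = ds.images()
    labels = ds.labels()
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_fold, components, qs = [], [], []
    for i, (train, test) in enumerate(plan.folds):
        try:
            est = clone(pipeline)
            est.cache = cache
            est.random_state = fold_seed(plan.seed, i)
            est.fit([images[j] for j in train], labels[train])
            pred = est.predict([images[j] for j in test])
        except Exception as exc:
            raise RuntimeError(f"evaluation failed in fold {i} ({plan.protocol}): {exc}") from exc
        truth = labels[test]
        per_fold.append(float(np.mean(pred == truth)))
        components.append(est.classifier_.n_components_)
        qs.append(est.q_)
        for t, p in zip(truth, pred):
            confusion[class_index[t], class_index[p]] += 1
    return EvalReport(
        per_fold_accuracy=per_fold,
        mean_accuracy=float(np.mean(per_fold)),
        confusion=confusion,
        classes=classes,
        chosen_components=components,
        q_used=qs,
        protocol=plan.protocol,
        seed=plan.seed,
    )
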