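"""Selection of the entropic index q by K-fold cross-validation.

q weights rare versus common histogram bins and acts as a regularisation
knob on the entropy stream; the right value depends on the texture
statistics, so it is chosen by sweeping a grid over the full
descriptor -> PCA -> LDA pipeline with K-fold cross-validation on the
training images only.  Ties are broken toward the q closest to 1 (the
additive, least aggressive setting), then toward the smaller q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

__all__ = ["QSweepResult", "sweep_q", "DEFAULT_Q_GRID"]

DEFAULT_Q_GRID = (0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 1.75, 2.0)


@dataclass
class QSweepResult:
    grid: list[float]
    mean_cv_accuracy: list[float]
    sd_cv_accuracy: list[float]
    best_q: float
    k: int
    seed: int

    def as_table(self) -> str:
        lines = ["q\tmean_cv_accuracy\tsd"]
        for q, m, s in zip(self.grid, self.mean_cv_accuracy, self.sd_cv_accuracy):
            lines.append(f"{q:g}\t{m:.6f}\t{s:.6f}")
        return "\n".join(lines)


def sweep_q(
    X,
    y,
    grid=DEFAULT_Q_GRID,
    k: int = 5,
    seed: int = 0,
    pipeline=None,
) -> QSweepResult:
    """Cross-validate the pipeline at each q on training images only.

    ``X`` is a sequence of images, ``y`` their labels; ``pipeline`` is a
    :class:`~entrotex.pipeline.TextureClassifier` (or anything exposing its
    parameters) whose non-q parameters define the pipeline being swept.
    Images are shuffled once into K folds of near-equal size (sizes differ
    by at most one); every q is scored on the same folds.  Descriptors are
    cached per (image, q, stream), so the original-image stream is
    extracted once for the whole sweep.
    """
    from .backbones import FeatureCache
    from .pipeline import PCALDAClassifier, TextureClassifier

    grid = [float(q) for q in grid]
    if not grid:
        raise ValueError("q grid must be non-empty")
    if k < 2:
        raise ValueError("K-fold selection needs K >= 2")
    if pipeline is None:
        pipeline = TextureClassifier()
    y = np.asarray(y)
    images = [np.asarray(img) for img in X]
    cache = pipeline.cache if pipeline.cache is not None else FeatureCache()
    cv = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31 - 1))
    splits = list(cv.split(images))
    means, sds = [], []
    for q in grid:
        featurizer = pipeline._featurizer(q) if hasattr(pipeline, "_featurizer") else None
        if featurizer is None:
            from .backbones import DualStreamFeaturizer

            featurizer = DualStreamFeaturizer(q=q, cache=cache).fit()
        featurizer.cache = cache
        features = featurizer.transform(images)
        accs = []
        for tr, te in splits:
            clf = PCALDAClassifier(
                candidate_grid=getattr(pipeline, "candidate_grid", (10, 25, 50, 100, 150, 200)),
                max_components=getattr(pipeline, "max_components", 200),
                cv_folds=getattr(pipeline, "cv_folds", 5),
                random_state=int(seed) % (2**31 - 1),
            )
            clf.fit(features[tr], y[tr])
            accs.append(float(np.mean(clf.predict(features[te]) == y[te])))
        means.append(float(np.mean(accs)))
        sds.append(float(np.std(accs)))
    best_acc = max(means)
    # argmax with ties broken toward q nearest 1, then toward the smaller q
    tied = [q for q, m in zip(grid, means) if m == best_acc]
    best_q = min(tied, key=lambda q: (abs(q - 1.0), q))
    return QSweepResult(
        grid=grid,
        mean_cv_accuracy=means,
        sd_cv_accuracy=sds,
        best_q=best_q,
        k=k,
        seed=int(seed),
    )
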