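"""Feature fusion, Fisher-score ranking, selection and standardization.

Fusion is serial concatenation: an n-dimensional channel-based vector
followed by an m-dimensional connectivity vector gives an
(n+m)-dimensional fused vector. Each column carries a provenance tag
(``tif:...`` or ``bcf:...``) so the fused matrix can be sliced back into
its sources.

The multiclass Fisher score of feature j is

    F(X_j) = sum_k n_k (mu_kj - mu_j)^2 / sum_k n_k sigma_kj^2

with per-class counts n_k, per-class means mu_kj, per-class population
variances sigma_kj^2 and grand mean mu_j. Higher scores indicate more
between-class scatter relative to within-class scatter; selection keeps
the S highest-scoring features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class FeatureError(ValueError):
    """Raised for inconsistent feature matrices or selection parameters."""


@dataclass
class FeatureMatrix:
    """Epochs-by-features values with provenance tags and class labels."""

    values: np.ndarray
    tags: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.labels = np.asarray(self.labels)
        if np.isnan(self.values).any():
            raise FeatureError("feature matrix contains NaN")
        if len(self.tags) != self.n_features:
            raise FeatureError("tags length does not match feature count")
        if self.labels.shape[0] != self.n_epochs:
            raise FeatureError("labels length does not match epoch count")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def slice_features(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            values=self.values[:, idx],
            tags=[self.tags[i] for i in idx],
            labels=self.labels,
        )

    def with_prefix(self, prefix: str) -> "FeatureMatrix":
        """Features whose tag starts with ``prefix`` (e.g. ``"tif"``)."""
        idx = [i for i, t in enumerate(self.tags) if t.startswith(prefix)]
        return self.slice_features(idx)


def fuse(tif: FeatureMatrix, bcf: FeatureMatrix) -> FeatureMatrix:
    """Serial feature fusion: columns of ``tif`` followed by ``bcf``.

    Both matrices must describe the same epochs in the same order and
    use disjoint tag namespaces.
    """
    if tif.n_epochs != bcf.n_epochs or not np.array_equal(tif.labels, bcf.labels):
        raise FeatureError("feature matrices describe different epochs")
    overlap = set(tif.tags) & set(bcf.tags)
    if overlap:
        raise FeatureError(f"tag namespaces overlap: {sorted(overlap)[:3]}")
    return FeatureMatrix(
        values=np.hstack([tif.values, bcf.values]),
        tags=list(tif.tags) + list(bcf.tags),
        labels=tif.labels,
    )


@dataclass
class FisherScoreVector:
    """Per-feature Fisher scores with the class statistics behind them."""

    scores: np.ndarray
    class_means: dict[str, np.ndarray]
    class_sds: dict[str, np.ndarray]
    class_counts: dict[str, int]
    grand_mean: np.ndarray


def fisher_score(x: FeatureMatrix | np.ndarray, labels=None) -> FisherScoreVector:
    """Multiclass Fisher score per feature.

    Population (divide-by-``n_k``) variances are used consistently with
    the count-weighted numerator. If a feature's pooled within-class
    variance is zero, the score is 0 when the between-class numerator is
    also zero (the feature is constant) and +inf otherwise (a
    zero-variance, class-separating feature is maximally discriminative).
    """
    if isinstance(x, FeatureMatrix):
        values, labels = x.values, x.labels
    else:
        values = np.atleast_2d(np.asarray(x, dtype=float))
        labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise FeatureError("Fisher score needs at least 2 classes")
    means, sds, counts = {}, {}, {}
    numer = np.zeros(values.shape[1])
    denom = np.zeros(values.shape[1])
    grand = values.mean(axis=0)
    for cls in classes:
        sel = values[labels == cls]
        if sel.shape[0] < 2:
            raise FeatureError(f"class {cls!r} has fewer than 2 epochs")
        nk = sel.shape[0]
        mu = sel.mean(axis=0)
        var = sel.var(axis=0)  # population variance
        means[str(cls)], sds[str(cls)], counts[str(cls)] = mu, np.sqrt(var), nk
        numer += nk * (mu - grand) ** 2
        denom += nk * var
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = numer / denom
    scores = np.where(denom == 0, np.where(numer == 0, 0.0, np.inf), scores)
    return FisherScoreVector(
        scores=scores, class_means=means, class_sds=sds,
        class_counts=counts, grand_mean=grand,
    )


def select_top(scores: FisherScoreVector | np.ndarray, s: int) -> np.ndarray:
    """Indices of the ``s`` highest-scoring features, descending.

    Ties are broken by ascending feature index, so the selection is
    deterministic and permutation-equivariant up to the tie rule.
    """
    arr = scores.scores if isinstance(scores, FisherScoreVector) else np.asarray(scores)
    if not 1 <= s <= arr.shape[0]:
        raise FeatureError(f"S={s} outside [1, {arr.shape[0]}]")
    order = np.argsort(-arr, kind="stable")
    return order[:s]


@dataclass
class Standardizer:
    """Per-feature z-scoring state fitted on training data only.

    Features with zero training variance are centred but not scaled.
    """

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, train: np.ndarray) -> "Standardizer":
        train = np.atleast_2d(np.asarray(train, dtype=float))
        mean = train.mean(axis=0)
        sd = train.std(axis=0)
        return cls(mean=mean, scale=np.where(sd == 0, 1.0, sd))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(x, dtype=float)) - self.mean) / self.scale


def standardize(train: FeatureMatrix, apply_to: FeatureMatrix) -> FeatureMatrix:
    """Z-score ``apply_to`` using means and SDs estimated on ``train``."""
    if train.n_features != apply_to.n_features:
        raise FeatureError("feature count mismatch")
    std = Standardizer.fit(train.values)
    return FeatureMatrix(
        values=std.transform(apply_to.values),
        tags=list(apply_to.tags),
        labels=apply_to.labels,
    )


def selection_report(scores: FisherScoreVector, tags: list[str], s: int):
    """(tag, score, rank) table for the selected features, for inspection."""
    import pandas as pd

    idx = select_top(scores, s)
    return pd.DataFrame(
        {
            "rank": np.arange(1, s + 1),
            "tag": [tags[i] for i in idx],
            "score": scores.scores[idx],
        }
    )
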