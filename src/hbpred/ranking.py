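"""Two-class ANOVA F-score feature ranking.

Each feature is scored by a one-way ANOVA between the two classes:
F = (between-group mean square) / (within-group mean square) with
df1 = 1 and df2 = n - 2; for two classes F equals the square of the
pooled-variance two-sample t statistic. p-values come from the upper
tail of the F distribution and are reported raw (no multiple-testing
correction). Features constant across all samples carry no signal and
score F = 0, p = 1 (the 0/0 case); features constant within classes but
differing between them separate perfectly and score F = +inf, p = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import f_classif
from sklearn.utils.validation import check_is_fitted


@dataclass(frozen=True)
class RankedFeature:
    name: str
    f_score: float
    p_value: float
    rank: int


class AnovaRanker(BaseEstimator):
    """Rank features of a two-class matrix by ANOVA F-score.

    Parameters
    ----------
    top_k : int or None
        Number of top features reported by :meth:`top_features`;
        ``None`` reports all.

    Attributes
    ----------
    f_scores_ : ndarray of shape (n_features,)
    p_values_ : ndarray of shape (n_features,)
    ranking_ : ndarray of shape (n_features,)
        Feature indices sorted by descending F; ties keep input
        (canonical) feature order. Constant features rank last.
    feature_names_ : list of str
    """

    def __init__(self, top_k: int | None = 5) -> None:
        self.top_k = top_k

    def fit(self, X, y, feature_names: list[str] | None = None) -> "AnovaRanker":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError(f"expected 2 classes, found {len(classes)}")
        if counts.min() < 2:
            raise ValueError("each class needs at least 2 samples for ANOVA")
        if self.top_k is not None and self.top_k > X.shape[1]:
            raise ValueError(
                f"top_k={self.top_k} exceeds {X.shape[1]} features"
            )
        # degenerate features are handled explicitly below
        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", category=UserWarning, module=r"sklearn\.feature_selection.*"
            )
            f, p = f_classif(X, y)
        # constant features: 0/0 -> no discriminative information
        constant = np.ptp(X, axis=0) == 0
        f = np.where(constant, 0.0, f)
        p = np.where(constant, 1.0, p)
        # perfect separation (within-class variance 0, means differ)
        f = np.where(np.isnan(f), np.inf, f)
        p = np.where(np.isnan(p) & ~constant, 0.0, p)
        self.f_scores_ = f
        self.p_values_ = p
        self.ranking_ = np.argsort(-f, kind="stable")
        self.feature_names_ = (
            list(feature_names)
            if feature_names is not None
            else [f"f{i}" for i in range(X.shape[1])]
        )
        return self

    def top_features(self, k: int | None = None) -> list[RankedFeature]:
        check_is_fitted(self, "f_scores_")
        k = k if k is not None else self.top_k
        order = self.ranking_ if k is None else self.ranking_[:k]
        return [
            RankedFeature(
                name=self.feature_names_[i],
                f_score=float(self.f_scores_[i]),
                p_value=float(self.p_values_[i]),
                rank=r + 1,
            )
            for r, i in enumerate(order)
        ]

    def to_frame(self) -> pd.DataFrame:
        check_is_fitted(self, "f_scores_")
        return pd.DataFrame(
            [rf.__dict__ for rf in self.top_features(k=None)],
            columns=["name", "f_score", "p_value", "rank"],
        )


def anova_rank(
    matrix, labels, top_k: int = 5, feature_names: list[str] | None = None
) -> list[RankedFeature]:
    """Top ``top_k`` features of a two-class matrix by ANOVA F-score.

    Accepts an encoded :class:`pandas.DataFrame` (a ``label`` column, if
    present, is used when ``labels`` is None is not supported — pass labels
    explicitly) or a plain array plus ``feature_names``.
    """
    if isinstance(matrix, pd.DataFrame):
        feature_names = [c for c in matrix.columns if c != "label"]
        matrix = matrix[feature_names].to_numpy(float)
    ranker = AnovaRanker(top_k=top_k).fit(matrix, labels, feature_names=feature_names)
    return ranker.top_features()
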