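"""Density-based outlier screening (local outlier factor).

Screening images form clusters of very different densities in QC-feature
space (replicates, dose series, shared-target compounds), so a global
parametric outlier test is inappropriate.  The local outlier factor
compares each point's local density with its neighbours' and therefore
tolerates between-cluster density variation.  The same screen is reused
at the cell level to tighten each phenotype's training envelope before
one-class SVM fitting.

Features are standardized to zero mean / unit variance internally: QC
features mix units (camera counts, dimensionless slopes, cell counts)
and unscaled Euclidean distance would be dominated by a single column.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.neighbors import LocalOutlierFactor
from sklearn.preprocessing import StandardScaler

from .exceptions import ParameterError
from .io import ImageFeatureTable, logger

__all__ = [
    "lof_scores",
    "flag_outliers",
    "filter_outlier_images",
    "screen_rows",
    "ImageOutlierFilter",
]


def lof_scores(X: np.ndarray, n_neighbors: int = 20) -> np.ndarray:
    """LOF outlyingness scores (larger = more outlying) on standardized X."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if n <= n_neighbors:
        raise ParameterError(
            f"need more rows ({n}) than n_neighbors ({n_neighbors}); "
            "use a smaller n_neighbors"
        )
    Xs = StandardScaler().fit_transform(X)
    lof = LocalOutlierFactor(n_neighbors=n_neighbors)
    lof.fit(Xs)
    # negative_outlier_factor_ is ~ -1 for inliers, very negative for outliers
    return -lof.negative_outlier_factor_


def flag_outliers(
    X: np.ndarray, n_neighbors: int = 20, contamination: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Return (scores, is_outlier) flagging the top-``contamination`` fraction.

    ``contamination=0`` disables flagging.  Score ties at the cut are all
    flagged (conservative removal), so the flagged count is
    round(contamination * n) up to ties.
    """
    if not (0.0 <= contamination < 0.5):
        raise ParameterError(f"contamination must be in [0, 0.5), got {contamination}")
    scores = lof_scores(X, n_neighbors=n_neighbors)
    n = len(scores)
    n_flag = int(round(contamination * n))
    if contamination == 0.0 or n_flag == 0:
        return scores, np.zeros(n, dtype=bool)
    cut = np.sort(scores)[::-1][n_flag - 1]
    return scores, scores >= cut


def filter_outlier_images(
    table: ImageFeatureTable,
    features: list[str] | None = None,
    n_neighbors: int = 20,
    contamination: float = 0.02,
) -> tuple[ImageFeatureTable, pd.DataFrame]:
    """Drop artifact-dominated images before phenotype sampling.

    Returns the inlier table (original row order preserved) and a verdict
    frame with one row per input image (``lof_score``, ``is_outlier``).
    """
    feats = features or table.feature_names
    scores, flagged = flag_outliers(
        table.matrix(feats), n_neighbors=n_neighbors, contamination=contamination
    )
    verdicts = pd.DataFrame(
        {"image_id": table.image_ids, "lof_score": scores, "is_outlier": flagged}
    )
    inliers = ImageFeatureTable(table.frame.loc[~flagged].copy())
    logger.info(
        "filter_outlier_images: flagged %d/%d images (contamination=%g)",
        int(flagged.sum()), len(table), contamination,
    )
    return inliers, verdicts


def screen_rows(
    X: np.ndarray,
    n_neighbors: int = 20,
    contamination: float | None = None,
    score_threshold: float | None = 2.0,
) -> np.ndarray:
    """Boolean keep-mask removing LOF-outlying rows.

    Two modes: pass ``contamination`` to remove the highest-LOF fraction
    (quantile mode), or leave it None to remove rows whose LOF score
    exceeds ``score_threshold`` (score mode, default threshold 2: LOF is
    ~1 for points whose local density matches their neighbours', and a
    score above 2 is the conventional outlier reading).  Score mode
    adapts to the actual contamination instead of assuming a fixed
    fraction.  If the subset is too small for the neighbourhood size,
    screening is skipped with a warning and every row is kept.
    """
    X = np.asarray(X, dtype=float)
    if len(X) <= n_neighbors:
        logger.warning(
            "screen_rows: %d rows <= n_neighbors=%d; screening skipped",
            len(X), n_neighbors,
        )
        return np.ones(len(X), dtype=bool)
    if contamination is not None:
        _, flagged = flag_outliers(
            X, n_neighbors=n_neighbors, contamination=contamination
        )
        return ~flagged
    if score_threshold is None:
        return np.ones(len(X), dtype=bool)
    scores = lof_scores(X, n_neighbors=n_neighbors)
    return scores <= score_threshold


class ImageOutlierFilter(OutlierMixin, BaseEstimator):
    """scikit-learn-style LOF screen over image QC features.

    ``fit_predict`` returns +1 for inliers and -1 for flagged outliers;
    fitted attributes expose the scores (``scores_``, larger = more
    outlying) and the boolean flag vector (``is_outlier_``).
    """

    def __init__(self, n_neighbors: int = 20, contamination: float = 0.02):
        self.n_neighbors = n_neighbors
        self.contamination = contamination

    def fit(self, X, y=None):
        X = X.matrix() if isinstance(X, ImageFeatureTable) else np.asarray(X, float)
        self.scores_, self.is_outlier_ = flag_outliers(
            X, n_neighbors=self.n_neighbors, contamination=self.contamination
        )
        return self

    def fit_predict(self, X, y=None):
        self.fit(X)
        return np.where(self.is_outlier_, -1, 1)

    def _check_fitted(self) -> None:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "is_outlier_")
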