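"""Image-level feature reduction by correlation clustering.

High-content QC measurements are heavily redundant — focus scores track
the standard deviation of pixel intensity, the various intensity
statistics track each other — so before density estimation we cluster
features by absolute correlation and keep one representative per
cluster.  Cell Count is appended afterwards because most QC features
shift with cell count and keeping it explicit lets the sampler separate
count-driven variation from quality-driven variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError
from .io import ImageFeatureTable, logger

#: priority order used to pick cluster representatives; mirrors the QC
#: feature set conventionally retained for screening assays
DEFAULT_PRIORITY = (
    "PowerLogLogSlope",
    "FocusScore",
    "MeanIntensity",
    "Correlation",
    "SNR",
)

DEFAULT_ALWAYS_INCLUDE = ("Cell_Count", "CellCount", "Cell Count")

__all__ = [
    "FeatureClustering",
    "cluster_features",
    "select_features",
    "CorrelatedFeatureReducer",
    "DEFAULT_PRIORITY",
    "DEFAULT_ALWAYS_INCLUDE",
]


@dataclass
class FeatureClustering:
    """Result of average-linkage clustering on distance 1 - |r|."""

    feature_names: list[str]
    linkage_record: np.ndarray
    distance: np.ndarray  # condensed 1 - |r| distances
    cut: float
    clusters: dict[int, list[str]]
    excluded_constant: list[str] = field(default_factory=list)

    def cluster_of(self, name: str) -> int:
        for cid, members in self.clusters.items():
            if name in members:
                return cid
        raise KeyError(name)


def cluster_features(
    table: ImageFeatureTable,
    cut: float = 0.9,
    method: str = "pearson",
) -> FeatureClustering:
    """Group features whose pairwise |correlation| >= ``cut``.

    Average linkage on distance 1 - |r|, cut at height 1 - cut.  Constant
    features cannot carry a correlation and are excluded with a warning.
    """
    if not (0.0 < cut < 1.0):
        raise ParameterError(f"cut must be in (0,1), got {cut}")
    constant = table.constant_features
    names = [c for c in table.feature_names if c not in constant]
    if constant:
        logger.warning("cluster_features: excluding constant features %s", constant)
    if len(names) < 2:
        raise ParameterError("need >= 2 non-constant features to cluster")
    X = table.frame[names]
    corr = X.corr(method=method).to_numpy()
    corr = np.clip(np.nan_to_num(corr, nan=0.0), -1.0, 1.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    flat = fcluster(Z, t=1.0 - cut, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for name, cid in zip(names, flat):
        clusters.setdefault(int(cid), []).append(name)
    return FeatureClustering(
        feature_names=names,
        linkage_record=Z,
        distance=condensed,
        cut=cut,
        clusters=clusters,
        excluded_constant=list(constant),
    )


def select_features(
    clustering: FeatureClustering,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    always_include: Sequence[str] = DEFAULT_ALWAYS_INCLUDE,
) -> list[str]:
    """Pick one representative per cluster, then append ``always_include``.

    Within a cluster the representative is the highest-priority member;
    members absent from the priority list rank after all listed names and
    tie-break alphabetically.  ``always_include`` names (Cell Count by
    default, under its common spellings) are appended when present in the
    table and not already selected.
    """
    if not priority:
        raise ParameterError("priority list must be non-empty")
    rank = {name: i for i, name in enumerate(priority)}

    def sort_key(name: str) -> tuple[int, str]:
        return (rank.get(name, len(priority)), name)

    selected: list[str] = []
    for cid in sorted(clustering.clusters):
        members = clustering.clusters[cid]
        selected.append(min(members, key=sort_key))
    known = set(clustering.feature_names) | set(clustering.excluded_constant)
    for name in always_include:
        if name in known and name not in selected:
            selected.append(name)
    return selected


class CorrelatedFeatureReducer(TransformerMixin, BaseEstimator):
    """Transformer that drops correlation-redundant feature columns.

    Parameters
    ----------
    cut : float, default 0.9
        Absolute-correlation threshold above which two features are
        considered redundant.
    method : {"pearson", "spearman"}, default "pearson"
    priority : sequence of str
        Representative preference order.
    always_include : sequence of str
        Columns appended to the selection when present (default: the
        common Cell Count spellings).
    """

    def __init__(
        self,
        cut: float = 0.9,
        method: str = "pearson",
        priority: Sequence[str] = DEFAULT_PRIORITY,
        always_include: Sequence[str] = DEFAULT_ALWAYS_INCLUDE,
    ):
        self.cut = cut
        self.method = method
        self.priority = priority
        self.always_include = always_include

    def fit(self, X: ImageFeatureTable, y=None):
        table = X if isinstance(X, ImageFeatureTable) else ImageFeatureTable(X.copy())
        self.clustering_ = cluster_features(table, cut=self.cut, method=self.method)
        self.selected_features_ = select_features(
            self.clustering_, priority=self.priority, always_include=self.always_include
        )
        self.n_features_in_ = len(table.feature_names)
        return self

    def transform(self, X: ImageFeatureTable):
        check_is_fitted(self, "selected_features_")
        frame = X.frame if isinstance(X, ImageFeatureTable) else X
        out = frame[self.selected_features_].copy()
        return ImageFeatureTable(out) if isinstance(X, ImageFeatureTable) else out

    def _check_fitted(self) -> None:
        check_is_fitted(self, "selected_features_")
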