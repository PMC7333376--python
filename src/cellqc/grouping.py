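"""Phenotype grouping of sampled images, with a mandatory human veto.

The sampled image subset is clustered in the same QC-feature space used
for sampling.  A plain Gaussian-mixture BIC scan first bounds the number
of groups (n_up); a variational Bayesian mixture with n_up components
then lets weight shrinkage pick the effective number of phenotypes
automatically.  Each effective group exports its most central member
images so a human can veto groups that represent artifacts (unsplittable
clumps, staining defects); vetoed groups contribute no cells to
classifier training.  The veto is mandatory: training with undecided
groups is a hard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import BayesianGaussianMixture, GaussianMixture
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from ._seeds import child_seed
from .exceptions import ParameterError, VerdictError
from .io import ImageFeatureTable, logger

__all__ = [
    "PhenotypeGrouping",
    "estimate_n_up",
    "group_phenotypes",
    "record_verdicts",
    "trainable_groups",
    "PhenotypeGrouper",
    "INCLUDE",
    "EXCLUDE",
    "UNDECIDED",
]

INCLUDE = "include"
EXCLUDE = "exclude"
UNDECIDED = "undecided"


@dataclass
class PhenotypeGrouping:
    """Cluster assignments, representatives and include/exclude verdicts."""

    n_up: int
    assignments: pd.Series  # image_id -> group index
    weights: np.ndarray  # posterior component weights, length n_up
    effective_groups: list[int]
    representatives: dict[int, list[str]]
    verdicts: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.effective_groups:
            self.verdicts.setdefault(g, UNDECIDED)

    @property
    def group_sizes(self) -> dict[int, int]:
        return self.assignments.value_counts().to_dict()

    def images_in(self, group: int) -> list[str]:
        return list(self.assignments.index[self.assignments == group])


def estimate_n_up(
    sampled: ImageFeatureTable,
    k_max: int = 20,
    n_init: int = 5,
    seed: int = 0,
) -> int:
    """Upper-bound the phenotype count via a full-covariance GMM BIC scan.

    Fits mixtures for k = 1..k_max with ``n_init`` restarts each (seeds
    fanned deterministically from ``seed``) and returns the argmin-BIC k.
    Features are standardized internally for numerically stable EM; BIC
    ranking is invariant to this affine change of variables.
    """
    if k_max < 1:
        raise ParameterError(f"k_max must be >= 1, got {k_max}")
    n = len(sampled)
    if n < 2 * k_max:
        raise ParameterError(
            f"need >= {2 * k_max} sampled images for k_max={k_max}, got {n}"
        )
    if k_max == 1:
        return 1
    X = StandardScaler().fit_transform(sampled.matrix())
    bics = []
    for k in range(1, k_max + 1):
        gmm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            reg_covar=1e-6,
            random_state=child_seed(seed, "bic", k),
        )
        gmm.fit(X)
        bics.append(gmm.bic(X))
    best = int(np.argmin(bics)) + 1
    logger.info("estimate_n_up: BIC optimum at k=%d (scan 1..%d)", best, k_max)
    return best


def group_phenotypes(
    sampled: ImageFeatureTable,
    n_up: int,
    seed: int = 0,
    weight_floor: float | None = None,
    min_members: int = 5,
    n_representatives: int = 5,
) -> PhenotypeGrouping:
    """Cluster sampled images with a variational Bayesian mixture.

    ``n_up`` upper-bounds the component count; Dirichlet-process weight
    shrinkage empties superfluous components, and "effective" groups are
    those keeping posterior weight >= ``weight_floor`` (default
    1/(10*n_up)) and >= ``min_members`` assigned images.  Representatives
    are the members closest to the group mean (reproducible inspection
    sheets, unlike random draws).
    """
    if n_up < 1:
        raise ParameterError(f"n_up must be >= 1, got {n_up}")
    if weight_floor is None:
        weight_floor = 1.0 / (10.0 * n_up)
    scaler = StandardScaler()
    X = scaler.fit_transform(sampled.matrix())
    bgmm = BayesianGaussianMixture(
        n_components=n_up,
        covariance_type="full",
        weight_concentration_prior_type="dirichlet_process",
        max_iter=500,
        n_init=3,
        reg_covar=1e-6,
        random_state=child_seed(seed, "bgmm"),
    )
    labels = bgmm.fit_predict(X)
    assignments = pd.Series(labels, index=sampled.image_ids, name="group")
    sizes = assignments.value_counts()
    effective = sorted(
        g for g in range(n_up)
        if bgmm.weights_[g] >= weight_floor and sizes.get(g, 0) >= min_members
    )
    if not effective:
        # degenerate input (e.g. all rows identical): keep the largest group
        effective = [int(sizes.idxmax())]
    representatives: dict[int, list[str]] = {}
    ids = np.asarray(sampled.image_ids)
    raw = sampled.matrix()
    for g in effective:
        members = np.flatnonzero(labels == g)
        center = raw[members].mean(axis=0)
        d = np.linalg.norm(raw[members] - center, axis=1)
        order = members[np.argsort(d, kind="stable")]
        representatives[g] = [str(i) for i in ids[order[:n_representatives]]]
    logger.info(
        "group_phenotypes: %d effective groups of n_up=%d (sizes %s)",
        len(effective), n_up, {g: int(sizes.get(g, 0)) for g in effective},
    )
    return PhenotypeGrouping(
        n_up=n_up,
        assignments=assignments,
        weights=np.asarray(bgmm.weights_),
        effective_groups=effective,
        representatives=representatives,
    )


def record_verdicts(
    grouping: PhenotypeGrouping,
    verdicts: Mapping[int, str] | str | Path,
) -> PhenotypeGrouping:
    """Attach human include/exclude verdicts to a grouping.

    ``verdicts`` is a mapping group-id -> "include"/"exclude", or a path
    to a YAML file with that mapping.  Verdicts for unknown groups are a
    validation error; every effective group must eventually be decided
    before training.
    """
    if not isinstance(verdicts, Mapping):
        with open(verdicts) as fh:
            verdicts = yaml.safe_load(fh) or {}
    for g, v in verdicts.items():
        g = int(g)
        if g not in grouping.effective_groups:
            raise VerdictError(f"verdict for unknown group {g}")
        if v not in (INCLUDE, EXCLUDE):
            raise VerdictError(f"verdict for group {g} must be include/exclude, got {v!r}")
        grouping.verdicts[g] = v
    return grouping


def trainable_groups(grouping: PhenotypeGrouping) -> list[int]:
    """Groups cleared for SVM training; errors if the human step is unfinished."""
    undecided = [g for g in grouping.effective_groups
                 if grouping.verdicts.get(g, UNDECIDED) == UNDECIDED]
    if undecided:
        raise VerdictError(
            f"groups {undecided} are undecided; manual inspection is mandatory "
            "before training"
        )
    included = [g for g in grouping.effective_groups
                if grouping.verdicts[g] == INCLUDE]
    if not included:
        raise VerdictError("no trainable phenotypes: all groups excluded")
    return included


class PhenotypeGrouper(ClusterMixin, BaseEstimator):
    """Estimator combining the BIC scan and the variational grouping.

    Attributes after ``fit``: ``n_up_``, ``grouping_`` (the full
    :class:`PhenotypeGrouping`), ``labels_``.
    """

    def __init__(
        self,
        k_max: int = 20,
        n_init: int = 5,
        min_members: int = 5,
        n_representatives: int = 5,
        weight_floor: float | None = None,
        seed: int = 0,
    ):
        self.k_max = k_max
        self.n_init = n_init
        self.min_members = min_members
        self.n_representatives = n_representatives
        self.weight_floor = weight_floor
        self.seed = seed

    def fit(self, X: ImageFeatureTable, y=None):
        table = X if isinstance(X, ImageFeatureTable) else ImageFeatureTable(X.copy())
        self.n_up_ = estimate_n_up(
            table, k_max=self.k_max, n_init=self.n_init, seed=self.seed
        )
        self.grouping_ = group_phenotypes(
            table,
            self.n_up_,
            seed=self.seed,
            weight_floor=self.weight_floor,
            min_members=self.min_members,
            n_representatives=self.n_representatives,
        )
        self.labels_ = self.grouping_.assignments.to_numpy()
        return self

    def _check_fitted(self) -> None:
        check_is_fitted(self, "grouping_")
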