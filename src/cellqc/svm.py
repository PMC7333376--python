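"""Per-phenotype one-class SVM ensemble for cell-level artifact calls.

One RBF-kernel one-class SVM is trained per included phenotype group, on
that group's cells after a density-based (LOF) screen tightens the
envelope.  nu is kept very small (1e-3 by default) because the sampling
pipeline gives high confidence that the training cells are genuine, so
the classifier should positively identify nearly all of them; gamma
defaults to 1 / D_cell (one over the number of cell descriptors).  At
prediction time an object is an artifact only on unanimous agreement —
it must fall outside the boundary of every phenotype SVM; membership in
any one phenotype suffices for validity.

Each member standardizes descriptors with a scaler fit on its own
group's screened cells: a single RBF gamma across raw heterogeneous
units (pixels, intensities, dimensionless ratios) would be ill-posed,
and per-group scaling matches the one-model-per-phenotype design.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, OutlierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM
from sklearn.utils.validation import check_is_fitted

from .exceptions import ParameterError, SchemaError, VerdictError
from .grouping import PhenotypeGrouping, trainable_groups
from .io import CellFeatureTable, logger
from .outliers import screen_rows

__all__ = [
    "PhenotypeSVM",
    "OneClassSVMEnsemble",
    "collect_training_cells",
    "screen_training_cells",
    "train_ensemble",
    "classify_cells",
]


@dataclass
class PhenotypeSVM:
    """One phenotype's scaler + one-class SVM and its training census."""

    group_id: int
    scaler: StandardScaler
    svm: OneClassSVM
    training_cell_count: int

    #: decision-value slack for boundary support vectors: libsvm leaves
    #: points that lie exactly ON the boundary (f = 0) at ~1e-9 below it;
    #: genuine outliers sit orders of magnitude lower
    BOUNDARY_EPS = 1e-7

    def is_inlier(self, X: np.ndarray) -> np.ndarray:
        d = self.svm.decision_function(self.scaler.transform(X))
        return d >= -self.BOUNDARY_EPS


def collect_training_cells(
    cells: CellFeatureTable, grouping: PhenotypeGrouping
) -> dict[int, pd.DataFrame]:
    """Gather each include-verdicted group's cells (all objects of its images).

    Groups whose images contain no segmented objects (e.g. empty-well
    phenotypes) are dropped with a warning.  Verdicts must be complete.
    """
    included = trainable_groups(grouping)
    out: dict[int, pd.DataFrame] = {}
    for g in included:
        ids = set(grouping.images_in(g))
        sub = cells.frame[cells.frame["image_id"].isin(ids)]
        if len(sub) == 0:
            logger.warning(
                "collect_training_cells: group %d has no cells; dropped", g
            )
            continue
        out[g] = sub.copy()
    if not out:
        raise VerdictError("no included group contributed any cells")
    return out


def screen_training_cells(
    group_cells: pd.DataFrame,
    descriptor_names: Sequence[str],
    n_neighbors: int = 20,
    contamination: float | None = None,
    score_threshold: float | None = 2.0,
) -> pd.DataFrame:
    """LOF-screen one group's cells to tighten its envelope before training.

    By default cells with LOF score > ``score_threshold`` are removed
    (adapts to the actual contamination); pass ``contamination`` to
    remove a fixed top fraction instead.
    """
    X = group_cells[list(descriptor_names)].to_numpy(dtype=float)
    keep = screen_rows(
        X,
        n_neighbors=n_neighbors,
        contamination=contamination,
        score_threshold=score_threshold,
    )
    return group_cells.loc[keep]


class OneClassSVMEnsemble(OutlierMixin, BaseEstimator):
    """Ensemble of per-phenotype one-class SVMs with the unanimity rule.

    Parameters
    ----------
    nu : float, default 1e-3
        Upper bound on the training-error fraction per member.  Small,
        because the sampled training cells are trusted; raising nu
        tightens each boundary.
    gamma : "reciprocal" or float, default "reciprocal"
        RBF kernel coefficient; "reciprocal" uses 1 / D_cell.
    min_train_cells : int, default 50
        Groups with fewer screened cells are dropped (tiny one-class fits
        produce degenerate envelopes).
    screen_neighbors : int, default 20
        Neighbourhood size of the per-group LOF screen.
    screen_lof_threshold : float or None, default 2.0
        Score-mode screen: cells with LOF above this are removed before
        SVM fitting.  Ignored when ``screen_contamination`` is set.
    screen_contamination : float or None, default None
        Quantile-mode screen: remove this top fraction instead.  Set
        both to None (or contamination to 0) to disable screening.

    Each member's scaler is fit on the group's COLLECTED cells (before
    screening) while the SVM support is fit on the screened subset: the
    scale then reflects the group's full observed dispersion while the
    boundary is anchored only on trusted cells.

    ``fit`` accepts either ``(X, y)`` arrays (descriptor matrix + group
    label per training cell) or a :class:`CellFeatureTable` plus a
    verdict-complete :class:`PhenotypeGrouping`.  ``predict`` returns
    +1 (valid) / -1 (artifact).
    """

    def __init__(
        self,
        nu: float = 1e-3,
        gamma: "str | float" = "reciprocal",
        min_train_cells: int = 50,
        screen_neighbors: int = 20,
        screen_lof_threshold: float | None = 2.0,
        screen_contamination: float | None = None,
    ):
        self.nu = nu
        self.gamma = gamma
        self.min_train_cells = min_train_cells
        self.screen_neighbors = screen_neighbors
        self.screen_lof_threshold = screen_lof_threshold
        self.screen_contamination = screen_contamination

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None, descriptor_names: Sequence[str] | None = None):
        if isinstance(X, CellFeatureTable):
            raise ParameterError(
                "pass (descriptor matrix, group labels); use train_ensemble() "
                "for table+grouping input"
            )
        if not (0.0 < self.nu < 1.0):
            raise ParameterError(f"nu must be in (0,1), got {self.nu}")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if len(X) != len(y):
            raise ParameterError("X and group labels differ in length")
        self.descriptor_names_ = (
            list(descriptor_names)
            if descriptor_names is not None
            else [f"d{i}" for i in range(X.shape[1])]
        )
        gamma = (
            1.0 / X.shape[1] if self.gamma == "reciprocal" else float(self.gamma)
        )
        if gamma <= 0:
            raise ParameterError(f"gamma must be positive, got {gamma}")
        self.gamma_ = gamma
        members: list[PhenotypeSVM] = []
        for g in sorted(pd.unique(y)):
            Xg = X[y == g]
            # scale from the collected cells, support from the screened ones
            scaler = StandardScaler().fit(Xg)
            if self.screen_contamination is not None:  # quantile mode
                keep = screen_rows(
                    Xg,
                    n_neighbors=self.screen_neighbors,
                    contamination=self.screen_contamination,
                    score_threshold=None,
                )
            elif self.screen_lof_threshold is not None:  # score mode
                keep = screen_rows(
                    Xg,
                    n_neighbors=self.screen_neighbors,
                    contamination=None,
                    score_threshold=self.screen_lof_threshold,
                )
            else:
                keep = np.ones(len(Xg), dtype=bool)
            Xs = Xg[keep]
            if len(Xs) < self.min_train_cells:
                logger.warning(
                    "ensemble: group %s has %d cells (< %d); dropped",
                    g, len(Xs), self.min_train_cells,
                )
                continue
            # tight solver tolerance: with nu ~ 1e-3 the nu-property (at
            # most a nu-fraction of training points outside) only holds
            # when the dual is solved well past libsvm's 1e-3 default
            svm = OneClassSVM(kernel="rbf", nu=self.nu, gamma=gamma, tol=1e-8)
            svm.fit(scaler.transform(Xs))
            members.append(
                PhenotypeSVM(
                    group_id=int(g), scaler=scaler, svm=svm,
                    training_cell_count=len(Xs),
                )
            )
        if not members:
            raise ParameterError(
                f"no group reached min_train_cells={self.min_train_cells}"
            )
        self.members_ = members
        return self

    # -- prediction --------------------------------------------------------

    def membership(self, X: np.ndarray) -> np.ndarray:
        """Boolean (n_cells, n_members) matrix: member SVM accepts cell."""
        check_is_fitted(self, "members_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.descriptor_names_):
            raise SchemaError(
                f"expected {len(self.descriptor_names_)} descriptors "
                f"({self.descriptor_names_}), got {X.shape[1]}"
            )
        return np.column_stack([m.is_inlier(X) for m in self.members_])

    def predict(self, X: np.ndarray) -> np.ndarray:
        """+1 valid (inside >= 1 boundary), -1 artifact (outside all)."""
        inlier_any = self.membership(X).any(axis=1)
        return np.where(inlier_any, 1, -1)

    def _check_fitted(self) -> None:
        check_is_fitted(self, "members_")


def train_ensemble(
    cells: CellFeatureTable,
    grouping: PhenotypeGrouping,
    nu: float = 1e-3,
    gamma: "str | float" = "reciprocal",
    min_train_cells: int = 50,
    screen_neighbors: int = 20,
    screen_lof_threshold: float | None = 2.0,
    screen_contamination: float | None = None,
) -> OneClassSVMEnsemble:
    """Collect, screen and fit the ensemble from tables + verdicts."""
    per_group = collect_training_cells(cells, grouping)
    frames = []
    labels = []
    for g, df in per_group.items():
        frames.append(df)
        labels.append(np.full(len(df), g))
    X = pd.concat(frames)[cells.descriptor_names].to_numpy(dtype=float)
    y = np.concatenate(labels)
    ens = OneClassSVMEnsemble(
        nu=nu,
        gamma=gamma,
        min_train_cells=min_train_cells,
        screen_neighbors=screen_neighbors,
        screen_lof_threshold=screen_lof_threshold,
        screen_contamination=screen_contamination,
    )
    return ens.fit(X, y, descriptor_names=cells.descriptor_names)


def classify_cells(
    ensemble: OneClassSVMEnsemble,
    cells: CellFeatureTable,
    batch_images: int | None = None,
) -> pd.DataFrame:
    """Label every object valid/artifact under the unanimity rule.

    Returns a frame with image_id, object_id, one ``inlier_<group>``
    column per member, and ``is_artifact``.  ``batch_images`` streams the
    table in chunks of that many images; results are identical to the
    whole-table call (SVM decisions are per-row).
    """
    missing = [d for d in ensemble.descriptor_names_ if d not in cells.descriptor_names]
    extra = [d for d in cells.descriptor_names if d not in ensemble.descriptor_names_]
    if missing or extra:
        raise SchemaError(f"descriptor mismatch: missing={missing} extra={extra}")

    def _verdicts(frame: pd.DataFrame) -> pd.DataFrame:
        X = frame[ensemble.descriptor_names_].to_numpy(dtype=float)
        member_ok = ensemble.membership(X)
        out = frame[["image_id", "object_id"]].copy()
        for j, m in enumerate(ensemble.members_):
            out[f"inlier_{m.group_id}"] = member_ok[:, j]
        out["is_artifact"] = ~member_ok.any(axis=1)
        return out

    if batch_images is None:
        return _verdicts(cells.frame).reset_index(drop=True)
    chunks = []
    all_ids = cells.frame["image_id"].drop_duplicates().tolist()
    for start in range(0, len(all_ids), batch_images):
        ids = set(all_ids[start:start + batch_images])
        chunks.append(_verdicts(cells.frame[cells.frame["image_id"].isin(ids)]))
    return pd.concat(chunks, ignore_index=True)
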