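"""Feature-table, label-mask, config and model input/output.

The canonical interchange format is delimited text (CSV with a header
row), matching the per-image and per-object tables exported by
CellProfiler-style measurement pipelines.  Label masks are single-channel
integer TIFF or PNG images whose nonzero labels equal object ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .exceptions import (
    EmptyInputError,
    InputFormatError,
    ModelPersistenceError,
    StateError,
)

logger = logging.getLogger("cellqc")

#: bumped whenever the persisted-model layout changes incompatibly
MODEL_SCHEMA_VERSION = "cellqc-model-1"

__all__ = [
    "ImageFeatureTable",
    "CellFeatureTable",
    "LabelMask",
    "read_image_features",
    "write_image_features",
    "read_cell_features",
    "write_cell_features",
    "read_label_mask",
    "write_label_mask",
    "persist_model",
    "load_model",
    "MODEL_SCHEMA_VERSION",
]


# ---------------------------------------------------------------------------
# in-memory tables
# ---------------------------------------------------------------------------


@dataclass
class ImageFeatureTable:
    """Per-image QC feature matrix.

    ``frame`` is indexed by a unique string ``image_id`` and contains only
    numeric feature columns (units as produced upstream).  Rows with
    non-finite values must be removed before construction; constant
    columns are permitted but flagged in :attr:`constant_features`.
    """

    frame: pd.DataFrame
    n_dropped: int = 0
    constant_features: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dupes = self.frame.index[self.frame.index.duplicated()].unique()
            raise InputFormatError(
                f"duplicate image_id values: {list(map(str, dupes[:5]))}"
            )
        if len(self.frame) == 0:
            raise EmptyInputError("image feature table has zero rows")
        non_numeric = [
            c for c in self.frame.columns
            if not pd.api.types.is_numeric_dtype(self.frame[c])
        ]
        if non_numeric:
            raise InputFormatError(f"non-numeric feature columns: {non_numeric}")
        if not np.isfinite(self.frame.to_numpy(dtype=float)).all():
            raise InputFormatError("non-finite values present; clean before wrapping")
        self.frame.index = self.frame.index.astype(str)
        self.constant_features = [
            c for c in self.frame.columns if self.frame[c].nunique() <= 1
        ]

    @property
    def image_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.frame.columns)

    def __len__(self) -> int:
        return len(self.frame)

    def matrix(self, features: Sequence[str] | None = None) -> np.ndarray:
        cols = list(features) if features is not None else self.feature_names
        missing = [c for c in cols if c not in self.frame.columns]
        if missing:
            raise InputFormatError(f"unknown feature columns: {missing}")
        return self.frame[cols].to_numpy(dtype=float)

    def subset(self, image_ids: Sequence[str]) -> "ImageFeatureTable":
        ids = [str(i) for i in image_ids]
        missing = set(ids) - set(self.frame.index)
        if missing:
            raise InputFormatError(f"unknown image ids: {sorted(missing)[:5]}")
        return ImageFeatureTable(self.frame.loc[ids].copy())


@dataclass
class CellFeatureTable:
    """Per-object descriptor matrix.

    ``frame`` has columns ``image_id`` (str), ``object_id`` (int >= 1),
    ``area_px`` (positive int) followed by the numeric descriptor columns
    named in :attr:`descriptor_names`.
    """

    frame: pd.DataFrame
    descriptor_names: list[str] = field(default_factory=list)

    ID_COLUMNS = ("image_id", "object_id", "area_px")

    def __post_init__(self) -> None:
        for col in self.ID_COLUMNS:
            if col not in self.frame.columns:
                raise InputFormatError(f"cell table missing required column {col!r}")
        if not self.descriptor_names:
            self.descriptor_names = [
                c for c in self.frame.columns if c not in self.ID_COLUMNS
            ]
        if len(self.descriptor_names) < 1:
            raise InputFormatError("cell table needs >= 1 descriptor column")
        self.frame["image_id"] = self.frame["image_id"].astype(str)
        area = self.frame["area_px"].to_numpy()
        if not np.issubdtype(np.asarray(area).dtype, np.number):
            raise InputFormatError("area_px must be numeric")
        if (area < 1).any() or not np.allclose(area, np.round(area)):
            raise InputFormatError("area_px must be positive integers (pixel counts)")
        self.frame["area_px"] = self.frame["area_px"].astype(np.int64)
        oid = self.frame["object_id"].to_numpy()
        if (oid < 1).any():
            raise InputFormatError("object_id must be >= 1")
        if self.frame.duplicated(subset=["image_id", "object_id"]).any():
            raise InputFormatError("(image_id, object_id) pairs must be unique")
        desc = self.frame[self.descriptor_names]
        non_numeric = [
            c for c in self.descriptor_names
            if not pd.api.types.is_numeric_dtype(desc[c])
        ]
        if non_numeric:
            raise InputFormatError(f"non-numeric descriptor columns: {non_numeric}")
        if not np.isfinite(desc.to_numpy(dtype=float)).all():
            raise InputFormatError("non-finite descriptor values present")

    @property
    def n_descriptors(self) -> int:
        """D_cell, the descriptor count that sets the default RBF gamma."""
        return len(self.descriptor_names)

    def __len__(self) -> int:
        return len(self.frame)

    def descriptors(self) -> np.ndarray:
        return self.frame[self.descriptor_names].to_numpy(dtype=float)

    def for_images(self, image_ids: Sequence[str]) -> "CellFeatureTable":
        ids = {str(i) for i in image_ids}
        sub = self.frame[self.frame["image_id"].isin(ids)].copy()
        if len(sub) == 0:
            raise EmptyInputError("no objects for the requested images")
        return CellFeatureTable(sub, list(self.descriptor_names))


@dataclass
class LabelMask:
    """Integer label image: 0 = background, k >= 1 = object k."""

    image_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise InputFormatError("label mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise InputFormatError("label mask must be integer-typed")
        if (self.labels < 0).any():
            raise InputFormatError("label values must be non-negative")

    @property
    def object_ids(self) -> list[int]:
        vals = np.unique(self.labels)
        return [int(v) for v in vals if v > 0]


# ---------------------------------------------------------------------------
# delimited-text readers/writers
# ---------------------------------------------------------------------------


def read_image_features(path: str | Path, id_column: str = "image_id") -> ImageFeatureTable:
    """Read a per-image CSV into an :class:`ImageFeatureTable`.

    Rows containing non-finite values in any retained numeric column are
    dropped and the drop count logged (dropping, never imputing: the
    downstream density estimators must not see fabricated values).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise InputFormatError(f"id column {id_column!r} not found in {path.name}")
    df = df.set_index(df[id_column].astype(str)).drop(columns=[id_column])
    df.index.name = "image_id"
    if df.index.has_duplicates:
        raise InputFormatError(f"duplicated image ids in {path.name}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise InputFormatError(f"non-numeric feature columns: {non_numeric}")
    finite = np.isfinite(df.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_image_features: dropped %d rows with non-finite values", n_dropped)
    df = df.loc[finite]
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: zero rows remain after cleaning")
    return ImageFeatureTable(df, n_dropped=n_dropped)


def write_image_features(table: ImageFeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index_label="image_id")
    return path


def read_cell_features(
    path: str | Path,
    id_columns: tuple[str, str] = ("image_id", "object_id"),
    area_column: str = "area_px",
) -> CellFeatureTable:
    """Read a per-object CSV into a :class:`CellFeatureTable`."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in (*id_columns, area_column):
        if col not in df.columns:
            raise InputFormatError(f"column {col!r} not found in {path.name}")
    df = df.rename(
        columns={id_columns[0]: "image_id", id_columns[1]: "object_id", area_column: "area_px"}
    )
    finite_cols = [c for c in df.columns if c not in ("image_id",)]
    finite = np.isfinite(df[finite_cols].to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        logger.info("read_cell_features: dropped %d rows with non-finite values", n_dropped)
    df = df.loc[finite]
    if len(df) == 0:
        raise EmptyInputError(f"{path.name}: zero rows remain after cleaning")
    return CellFeatureTable(df.reset_index(drop=True))


def write_cell_features(table: CellFeatureTable, path: str | Path) -> Path:
    path = Path(path)
    table.frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# label masks
# ---------------------------------------------------------------------------


def read_label_mask(path: str | Path, image_id: str | None = None) -> LabelMask:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        labels = tifffile.imread(path)
    else:
        labels = np.asarray(Image.open(path))
    labels = np.asarray(labels)
    if not np.issubdtype(labels.dtype, np.integer):
        raise InputFormatError(f"{path.name}: label mask must be integer-typed")
    return LabelMask(image_id or path.stem, labels.astype(np.int32))


def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    data = mask.labels
    if data.max(initial=0) > np.iinfo(np.uint16).max:
        raise InputFormatError("label values exceed 16-bit range")
    data16 = data.astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data16)
    else:
        Image.fromarray(data16).save(path)
    return path


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def persist_model(model, path: str | Path) -> Path:
    """Serialize a trained model/sampler with an embedded schema version.

    ``load_model(persist_model(m))`` must classify any input identically
    to ``m``.  Persisting an unfitted estimator is a state error.
    """
    check = getattr(model, "_check_fitted", None)
    if check is not None:
        try:
            check()
        except Exception as exc:  # noqa: BLE001 - normalize to StateError
            raise StateError(f"refusing to persist unfitted model: {exc}") from exc
    path = Path(path)
    joblib.dump({"schema_version": MODEL_SCHEMA_VERSION, "payload": model}, path)
    return path


def load_model(path: str | Path):
    path = Path(path)
    try:
        blob = joblib.load(path)
    except Exception as exc:  # noqa: BLE001
        raise ModelPersistenceError(f"cannot read model file {path}: {exc}") from exc
    if not isinstance(blob, dict) or "schema_version" not in blob:
        raise ModelPersistenceError(f"{path} is not a cellqc model file")
    if blob["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelPersistenceError(
            f"model schema {blob['schema_version']!r} incompatible with "
            f"{MODEL_SCHEMA_VERSION!r}"
        )
    return blob["payload"]
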