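"""Image quality readout: AR_cell, gating, reports, mask overlays.

AR_cell is the ratio of artifact-labeled object pixel area to total
segmented object pixel area in one image — a single, phenotype-invariant
quality score.  Images with no segmented objects get an undefined (NaN)
AR_cell, not zero: an empty image carries no evidence of quality, and by
default such images are excluded with an explicit reason code.  The gate
uses a strict ``>`` comparison (an image at exactly the threshold is
kept).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .exceptions import ParameterError, SchemaError
from .io import CellFeatureTable, LabelMask, logger

__all__ = [
    "score_images",
    "gate_images",
    "render_mask",
    "histogram_report",
    "plot_histogram",
    "COLOR_ARTIFACT",
    "COLOR_VALID",
    "COLOR_UNKNOWN",
]

COLOR_ARTIFACT = (0, 255, 0)  # green
COLOR_VALID = (0, 0, 255)  # blue
COLOR_UNKNOWN = (128, 128, 128)  # gray, for labels without a verdict
COLOR_TEXT = (255, 255, 255)  # white annotation


def score_images(
    verdicts: pd.DataFrame,
    cells: CellFeatureTable,
    all_image_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-object verdicts into per-image AR_cell.

    ``verdicts`` must carry image_id/object_id/is_artifact for every
    object, and every key must exist in ``cells`` (the area source).
    ``all_image_ids`` optionally lists images with zero segmented
    objects so they appear with undefined AR_cell.
    """
    required = {"image_id", "object_id", "is_artifact"}
    if not required <= set(verdicts.columns):
        raise SchemaError(f"verdict frame needs columns {sorted(required)}")
    v = verdicts.copy()
    v["image_id"] = v["image_id"].astype(str)
    merged = v.merge(
        cells.frame[["image_id", "object_id", "area_px"]],
        on=["image_id", "object_id"],
        how="left",
        validate="one_to_one",
    )
    if merged["area_px"].isna().any():
        bad = merged.loc[merged["area_px"].isna(), ["image_id", "object_id"]]
        raise SchemaError(
            f"verdicts reference unknown objects, e.g. {bad.head(3).to_dict('records')}"
        )
    merged["artifact_area"] = merged["area_px"].where(merged["is_artifact"], 0)
    per_image = merged.groupby("image_id", sort=True).agg(
        n_objects=("object_id", "size"),
        n_artifacts=("is_artifact", "sum"),
        artifact_area_px=("artifact_area", "sum"),
        total_area_px=("area_px", "sum"),
    )
    if all_image_ids is not None:
        idx = pd.Index([str(i) for i in all_image_ids], name="image_id")
        per_image = per_image.reindex(idx.union(per_image.index, sort=True))
        for col in per_image.columns:
            per_image[col] = per_image[col].fillna(0).astype(np.int64)
    results = per_image.reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        results["ar_cell"] = np.where(
            results["total_area_px"] > 0,
            results["artifact_area_px"] / results["total_area_px"].replace(0, 1),
            np.nan,
        )
    return results


def gate_images(
    results: pd.DataFrame,
    threshold: float = 0.5,
    undefined_policy: str = "exclude",
) -> tuple[list[str], pd.DataFrame]:
    """Split images into kept ids and an excluded frame with reasons.

    Excluded: AR_cell strictly greater than ``threshold``; images with
    undefined AR_cell (no objects) follow ``undefined_policy``
    ("exclude", the default, or "keep").
    """
    if not (0.0 <= threshold <= 1.0):
        raise ParameterError(f"threshold must be in [0,1], got {threshold}")
    if undefined_policy not in ("exclude", "keep"):
        raise ParameterError(f"unknown undefined_policy {undefined_policy!r}")
    ar = results["ar_cell"]
    over = ar > threshold  # NaN compares False
    undefined = ar.isna()
    excluded_mask = over | (undefined if undefined_policy == "exclude" else False)
    excluded = results.loc[excluded_mask, ["image_id", "ar_cell"]].copy()
    excluded["reason"] = np.where(
        excluded["ar_cell"].isna(), "no objects", f"ar_cell > {threshold:g}"
    )
    kept = results.loc[~excluded_mask, "image_id"].tolist()
    return kept, excluded.reset_index(drop=True)


def render_mask(
    mask: LabelMask,
    verdicts: pd.DataFrame,
    ar_cell: float | None = None,
    annotate: bool = True,
) -> np.ndarray:
    """RGB QC overlay: artifacts green, valid cells blue, background black.

    ``verdicts`` holds object_id/is_artifact rows for this image.  Labels
    present in the mask but absent from the verdicts render gray with a
    warning.  The AR_cell percentage (computed from the verdict areas if
    not supplied) is drawn in white in the top-left corner.
    """
    labels = mask.labels
    rgb = np.zeros((*labels.shape, 3), dtype=np.uint8)
    verdict_map = dict(
        zip(verdicts["object_id"].astype(int), verdicts["is_artifact"].astype(bool))
    )
    unknown = []
    for obj in mask.object_ids:
        if obj in verdict_map:
            color = COLOR_ARTIFACT if verdict_map[obj] else COLOR_VALID
        else:
            color = COLOR_UNKNOWN
            unknown.append(obj)
        rgb[labels == obj] = color
    if unknown:
        logger.warning("render_mask[%s]: no verdict for labels %s", mask.image_id, unknown)
    if annotate:
        img = Image.fromarray(rgb)
        draw = ImageDraw.Draw(img)
        if not mask.object_ids:
            text = "0 objects"
        else:
            if ar_cell is None:
                counts = np.bincount(labels.ravel())
                art = sum(
                    counts[o] for o in mask.object_ids if verdict_map.get(o, False)
                )
                tot = sum(counts[o] for o in mask.object_ids)
                ar_cell = art / tot if tot else float("nan")
            text = f"AR {100.0 * ar_cell:.1f}%"
        draw.text((3, 3), text, fill=COLOR_TEXT)
        rgb = np.asarray(img)
    return rgb


def histogram_report(results: pd.DataFrame, bins: int = 20) -> dict:
    """AR_cell histogram plus summary quantiles for QC triage.

    Only images with a defined AR_cell enter the histogram; the report
    states how many were undefined.  Examining this distribution is how
    a threshold gets chosen — long-tailed distributions admit a stringent
    cut at little image cost.
    """
    ar = results["ar_cell"].dropna().to_numpy() if len(results) else np.array([])
    if ar.size == 0:
        return {
            "counts": [], "bin_edges": [], "n_defined": 0,
            "n_undefined": int(len(results)), "quantiles": {},
        }
    counts, edges = np.histogram(ar, bins=bins, range=(0.0, 1.0))
    q = np.quantile(ar, [0.5, 0.9, 0.99])
    return {
        "counts": counts.tolist(),
        "bin_edges": edges.tolist(),
        "n_defined": int(ar.size),
        "n_undefined": int(len(results) - ar.size),
        "quantiles": {"p50": float(q[0]), "p90": float(q[1]), "p99": float(q[2])},
    }


def plot_histogram(results: pd.DataFrame, path: str | Path, bins: int = 20) -> Path:
    """Save the AR_cell histogram as a PNG (matplotlib, Agg backend)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report = histogram_report(results, bins=bins)
    fig, ax = plt.subplots(figsize=(6, 4))
    if report["counts"]:
        edges = np.asarray(report["bin_edges"])
        ax.bar(
            edges[:-1], report["counts"],
            width=np.diff(edges), align="edge", color="#4477aa",
        )
    ax.set_xlabel("AR_cell")
    ax.set_ylabel("images")
    ax.set_title("Artifact-area ratio distribution")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
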