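"""Seeded synthetic assays with exact ground truth.

Two fidelity levels:

* :func:`simulate_feature_tables` emits image- and cell-level feature
  tables directly in feature space — Gaussian phenotype clusters of
  variable density, uniform out-of-cluster artifact images, per-image
  cell populations with far-field artifact objects of known identity and
  heavy-tailed area.  This is the primary test surface: fast and with
  exact labels.
* :func:`simulate_images` + :func:`naive_segment_and_measure` render
  little Gaussian-blob fields, segment them by thresholding and measure
  the same feature families, proving the pixel plumbing end to end.
  They stand in for a real segmentation pipeline in tests only.

Everything is deterministic per seed.  The default assay is a scaled-
down stand-in for a production screen: 1,500 images, five phenotypes
with weights (0.40, 0.30, 0.15, 0.14, 0.01) — one deliberately rare —
2% artifact-dominated outlier images, and a long-tailed per-image
artifact fraction ~ Beta(0.5, 5).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

from ._seeds import child_rng
from .exceptions import InputFormatError, ParameterError
from .io import CellFeatureTable, ImageFeatureTable, LabelMask

__all__ = [
    "PhenotypeSpec",
    "FixtureSpec",
    "GroundTruth",
    "default_spec",
    "simulate_feature_tables",
    "simulate_images",
    "naive_segment_and_measure",
    "auto_verdicts",
    "IMAGE_FEATURES",
    "CELL_DESCRIPTORS",
    "OUTLIER_LABEL",
    "ARTIFACT_LABEL",
]

#: image-level QC features the simulator emits (Cell_Count is the actual
#: emitted object count, so the tables are self-consistent)
IMAGE_FEATURES = [
    "PowerLogLogSlope",
    "FocusScore",
    "MeanIntensity",
    "Correlation",
    "SNR",
    "Cell_Count",
]

#: the concrete 8-descriptor cell feature set (area is both the area_px
#: column and a descriptor, as in CellProfiler object tables)
CELL_DESCRIPTORS = [
    "area",
    "perimeter",
    "eccentricity",
    "solidity",
    "mean_intensity",
    "std_intensity",
    "max_intensity",
    "form_factor",
]

OUTLIER_LABEL = -1  # image planted as out-of-cluster artifact image
ARTIFACT_LABEL = -1  # cell planted as artifact object


@dataclass
class PhenotypeSpec:
    """One planted phenotype: image-feature cluster + cell model."""

    weight: float
    image_mean: np.ndarray  # length 5: the non-count image features
    image_sigma: float  # isotropic cluster scale (controls density)
    cells_per_image: float  # Poisson mean of segmented objects
    cell_mean: np.ndarray  # length 7: the non-area cell descriptors
    cell_sigma: float  # isotropic descriptor scale
    area_log_median: float  # median object area (px), lognormal
    area_log_sigma: float = 0.3


@dataclass
class FixtureSpec:
    """Stated world for one synthetic assay."""

    n_images: int = 1500
    phenotypes: list[PhenotypeSpec] = field(default_factory=list)
    image_outlier_fraction: float = 0.02
    artifact_fraction_beta: tuple[float, float] = (0.5, 5.0)
    outlier_artifact_beta: tuple[float, float] = (5.0, 2.0)
    artifact_min_sep: float = 6.0  # minimum distance (in sigma) to every phenotype
    artifact_max_sep: float = 16.0
    artifact_area_log_median: float = 600.0
    artifact_area_log_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not self.phenotypes:
            raise ParameterError("spec needs >= 1 phenotype")
        w = np.array([p.weight for p in self.phenotypes])
        if not np.isclose(w.sum(), 1.0):
            raise ParameterError(f"phenotype weights must sum to 1, got {w.sum():g}")
        if not (0.0 <= self.image_outlier_fraction < 1.0):
            raise ParameterError("image_outlier_fraction must be in [0,1)")
        if self.artifact_min_sep >= self.artifact_max_sep:
            raise ParameterError(
                "artifact separation band is empty "
                f"({self.artifact_min_sep} >= {self.artifact_max_sep})"
            )


@dataclass
class GroundTruth:
    """Planted labels, exactly consistent with the emitted tables."""

    image_phenotype: pd.Series  # image_id -> phenotype index or OUTLIER_LABEL
    cell_label: pd.Series  # (image_id, object_id) -> phenotype index or ARTIFACT_LABEL
    true_contamination: pd.Series  # image_id -> artifact area fraction (NaN: no objects)

    def artifact_mask(self, cells: CellFeatureTable) -> np.ndarray:
        key = pd.MultiIndex.from_frame(cells.frame[["image_id", "object_id"]])
        return self.cell_label.reindex(key).to_numpy() == ARTIFACT_LABEL


def default_spec(seed: int = 0, n_images: int = 1500) -> FixtureSpec:
    """The default five-phenotype assay (one rare phenotype at 1%).

    Image features carry deliberately heterogeneous units (power-spectrum
    slopes near -2, focus scores of order 0.01, SNR of order 10), as QC
    feature tables do in practice.  That heterogeneity matters to the
    sampler: the pruning radius r = sqrt(sum h_i^2) is isotropic in raw
    units, so large-unit features dominate r and the grid is effectively
    coarse along them — which is what keeps the sampled subset a small
    fraction of the assay, as in production-scale screens.
    """
    # image-feature cluster centres: well separated relative to their
    # sigmas, with deliberately unequal densities
    means = np.array(
        [
            [-1.8, 0.020, 0.30, 0.70, 18.0],
            [-1.0, 0.055, 0.18, 0.45, 10.0],
            [-2.4, 0.012, 0.45, 0.85, 25.0],
            [-0.6, 0.038, 0.08, 0.25, 5.0],
            [-1.5, 0.070, 0.60, 0.60, 30.0],
        ]
    )
    scales = np.array([0.06, 0.10, 0.04, 0.08, 0.05])  # relative densities
    # per-feature natural unit scale (per-column sigma multiplier)
    feat_scale = np.array([1.0, 0.025, 0.20, 0.30, 12.0])
    cell_means = np.array(
        [
            [60.0, 0.55, 0.92, 0.35, 0.08, 0.55, 0.80],
            [75.0, 0.70, 0.88, 0.25, 0.06, 0.40, 0.70],
            [50.0, 0.40, 0.95, 0.50, 0.11, 0.70, 0.88],
            [90.0, 0.80, 0.85, 0.18, 0.05, 0.30, 0.62],
            [65.0, 0.50, 0.90, 0.60, 0.13, 0.85, 0.84],
        ]
    )
    cell_scale = np.array([6.0, 0.05, 0.015, 0.04, 0.012, 0.06, 0.03])
    weights = [0.40, 0.30, 0.15, 0.14, 0.01]
    cpi = [25.0, 22.0, 18.0, 15.0, 20.0]
    areas = [180.0, 240.0, 150.0, 320.0, 200.0]
    phenos = [
        PhenotypeSpec(
            weight=weights[p],
            image_mean=means[p] * 1.0,
            image_sigma=scales[p],
            cells_per_image=cpi[p],
            cell_mean=cell_means[p],
            cell_sigma=1.0,
            area_log_median=areas[p],
        )
        for p in range(5)
    ]
    # stash the per-feature unit scales on the instance:
    spec = FixtureSpec(n_images=n_images, phenotypes=phenos, seed=seed)
    spec._feat_scale = feat_scale  # type: ignore[attr-defined]
    spec._cell_scale = cell_scale  # type: ignore[attr-defined]
    return spec


def _feat_scale(spec: FixtureSpec) -> np.ndarray:
    return getattr(spec, "_feat_scale", np.ones(len(spec.phenotypes[0].image_mean)))


def _cell_scale(spec: FixtureSpec) -> np.ndarray:
    return getattr(spec, "_cell_scale", np.ones(len(spec.phenotypes[0].cell_mean)))


def _draw_artifact_descriptors(
    spec: FixtureSpec, rng: np.random.Generator, n: int
) -> np.ndarray:
    """Far-field artifact descriptors: >= min_sep sigma from every phenotype.

    Drawn as radial offsets in random directions from the global centre
    of the phenotype cell models (standardized units), i.e. a broad
    shell of heterogeneous junk rather than a single artifact cluster.
    """
    scale = _cell_scale(spec)
    means = np.stack([p.cell_mean / scale for p in spec.phenotypes])
    sigmas = np.array([p.cell_sigma for p in spec.phenotypes])
    center = means.mean(axis=0)
    dim = means.shape[1]
    out = np.empty((n, dim))
    filled = 0
    for _ in range(200):
        m = max(n - filled, 1) * 2
        u = rng.normal(size=(m, dim))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        L = rng.uniform(spec.artifact_min_sep + 2.0, spec.artifact_max_sep, size=m)
        cand = center + u * L[:, None]
        d = np.linalg.norm(cand[:, None, :] - means[None, :, :], axis=2) / sigmas[None, :]
        ok = (d >= spec.artifact_min_sep).all(axis=1)
        take = cand[ok][: n - filled]
        out[filled:filled + len(take)] = take
        filled += len(take)
        if filled >= n:
            return out * scale
    raise ParameterError(
        "cannot place artifact descriptors at the requested separation; "
        "widen the separation band or shrink phenotype scales"
    )


def simulate_feature_tables(
    spec: FixtureSpec | None = None, seed: int | None = None
) -> tuple[ImageFeatureTable, CellFeatureTable, GroundTruth]:
    """Emit (image table, cell table, ground truth) for a fixture spec."""
    spec = spec if spec is not None else default_spec()
    if seed is not None:
        new = copy.copy(spec)
        new.seed = seed
        spec = new
    spec.validate()
    rng_assign = child_rng(spec.seed, "assign")
    rng_img = child_rng(spec.seed, "image-features")
    rng_cells = child_rng(spec.seed, "cells")
    n = spec.n_images
    n_out = int(round(spec.image_outlier_fraction * n))
    weights = np.array([p.weight for p in spec.phenotypes])

    pheno_of = rng_assign.choice(len(spec.phenotypes), size=n, p=weights)
    outlier_idx = rng_assign.choice(n, size=n_out, replace=False)
    pheno_of = pheno_of.astype(int)
    pheno_of[outlier_idx] = OUTLIER_LABEL
    image_ids = [f"img_{i:05d}" for i in range(n)]

    fscale = _feat_scale(spec)
    feats = np.empty((n, len(fscale)))
    means = np.stack([p.image_mean for p in spec.phenotypes])
    lo = means.min(axis=0) - 4 * fscale
    hi = means.max(axis=0) + 4 * fscale
    for i in range(n):
        p = pheno_of[i]
        if p == OUTLIER_LABEL:
            feats[i] = rng_img.uniform(lo, hi)
        else:
            ph = spec.phenotypes[p]
            feats[i] = ph.image_mean + rng_img.normal(size=len(fscale)) * ph.image_sigma * fscale

    # cell populations -----------------------------------------------------
    counts = np.zeros(n, dtype=int)
    a_art, b_art = spec.artifact_fraction_beta
    a_out, b_out = spec.outlier_artifact_beta
    cscale = _cell_scale(spec)
    img_col: list[np.ndarray] = []
    obj_col: list[np.ndarray] = []
    area_col: list[np.ndarray] = []
    desc_col: list[np.ndarray] = []
    label_col: list[np.ndarray] = []
    for i in range(n):
        p = pheno_of[i]
        # outlier images borrow a random phenotype's cell model for their
        # residual valid cells but are artifact-dominated
        model_idx = int(p) if p != OUTLIER_LABEL else int(rng_cells.integers(len(spec.phenotypes)))
        model = spec.phenotypes[model_idx]
        n_cells = rng_cells.poisson(model.cells_per_image)
        counts[i] = n_cells
        if n_cells == 0:
            continue
        if p == OUTLIER_LABEL:
            frac = rng_cells.beta(a_out, b_out)
        else:
            frac = rng_cells.beta(a_art, b_art)
        is_art = rng_cells.random(n_cells) < frac
        n_art = int(is_art.sum())
        desc = model.cell_mean + rng_cells.normal(size=(n_cells, len(cscale))) * model.cell_sigma * cscale
        if n_art:
            desc[is_art] = _draw_artifact_descriptors(spec, rng_cells, n_art)
        area = np.maximum(
            1,
            np.round(
                np.exp(
                    np.log(model.area_log_median)
                    + rng_cells.normal(size=n_cells) * model.area_log_sigma
                )
            ),
        ).astype(int)
        if n_art:
            area[is_art] = np.maximum(
                1,
                np.round(
                    np.exp(
                        np.log(spec.artifact_area_log_median)
                        + rng_cells.normal(size=n_art) * spec.artifact_area_log_sigma
                    )
                ),
            ).astype(int)
        img_col.append(np.full(n_cells, image_ids[i]))
        obj_col.append(np.arange(1, n_cells + 1))
        area_col.append(area)
        desc_col.append(desc)
        label_col.append(np.where(is_art, ARTIFACT_LABEL, model_idx))

    img_frame = pd.DataFrame(feats, columns=IMAGE_FEATURES[:-1], index=pd.Index(image_ids, name="image_id"))
    img_frame["Cell_Count"] = counts
    image_table = ImageFeatureTable(img_frame)

    areas = np.concatenate(area_col)
    cell_frame = pd.DataFrame(
        {
            "image_id": np.concatenate(img_col),
            "object_id": np.concatenate(obj_col),
            "area_px": areas,
            "area": areas.astype(float),
        }
    )
    all_desc = np.concatenate(desc_col, axis=0)
    for k, name in enumerate(CELL_DESCRIPTORS[1:]):
        cell_frame[name] = all_desc[:, k]
    cell_table = CellFeatureTable(cell_frame, list(CELL_DESCRIPTORS))

    label_idx = pd.MultiIndex.from_arrays(
        [cell_frame["image_id"], cell_frame["object_id"]],
        names=["image_id", "object_id"],
    )
    cell_label = pd.Series(np.concatenate(label_col), index=label_idx, name="label")

    art = cell_label.to_numpy() == ARTIFACT_LABEL
    cf = cell_frame.assign(is_art=art)
    cf["art_area"] = cf["area_px"].where(cf["is_art"], 0)
    per = cf.groupby("image_id").agg(total=("area_px", "sum"), art=("art_area", "sum"))
    contamination = (per["art"] / per["total"]).reindex(image_ids)
    contamination.name = "true_contamination"

    truth = GroundTruth(
        image_phenotype=pd.Series(pheno_of, index=pd.Index(image_ids, name="image_id")),
        cell_label=cell_label,
        true_contamination=contamination,
    )
    return image_table, cell_table, truth


def auto_verdicts(grouping, truth: GroundTruth) -> dict[int, str]:
    """TEST-ONLY verdicts: include a group iff its majority planted image
    label is a valid phenotype (not an outlier image).

    Stands in for the mandatory human inspection step in CI runs; real
    assays require a human verdict file.
    """
    from .grouping import EXCLUDE, INCLUDE

    verdicts = {}
    for g in grouping.effective_groups:
        members = grouping.images_in(g)
        labels = truth.image_phenotype.reindex(members)
        n_valid = int((labels != OUTLIER_LABEL).sum())
        verdicts[g] = INCLUDE if n_valid > len(members) / 2 else EXCLUDE
    return verdicts


# ---------------------------------------------------------------------------
# pixel-level fixture: blob renderer + naive segmenter
# ---------------------------------------------------------------------------


def _poisson_disc(rng, shape, n, min_dist, margin, max_tries=4000):
    pts: list[tuple[float, float]] = []
    for _ in range(max_tries):
        if len(pts) >= n:
            break
        cand = (
            rng.uniform(margin, shape[0] - margin),
            rng.uniform(margin, shape[1] - margin),
        )
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_dist**2 for p in pts):
            pts.append(cand)
    return pts


def _add_blob(img, cy, cx, radius, amp):
    yy, xx = np.ogrid[: img.shape[0], : img.shape[1]]
    img += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * (radius / 1.5) ** 2)))


def simulate_images(
    n_images: int = 6,
    shape: tuple[int, int] = (192, 192),
    cells_per_image: int = 10,
    cell_radius: float = 6.0,
    artifact_kinds: Sequence[str] = ("saturated", "blur", "clump"),
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], dict[str, LabelMask], pd.DataFrame]:
    """Render Gaussian-blob fields with injected artifacts.

    Returns (images, ground-truth masks, per-object truth frame with
    columns image_id/object_id/kind).  Object kinds: ``cell``,
    ``saturated`` (bright foreign blob), ``clump`` (merged blob pair).
    The ``blur`` artifact is a field-level Gaussian-smoothed region, not
    an object, and is recorded with object_id 0.
    """
    margin = int(3 * cell_radius)
    if shape[0] < 4 * margin or shape[1] < 4 * margin:
        raise ParameterError(f"shape {shape} too small for radius {cell_radius}")
    rng = child_rng(seed, "render")
    images: dict[str, np.ndarray] = {}
    masks: dict[str, LabelMask] = {}
    truth_rows = []
    for i in range(n_images):
        image_id = f"simg_{i:03d}"
        img = np.zeros(shape, float)
        labels = np.zeros(shape, np.int32)
        pts = _poisson_disc(rng, shape, cells_per_image, min_dist=3.2 * cell_radius, margin=margin)
        next_label = 1
        for (cy, cx) in pts:
            r = cell_radius * rng.uniform(0.85, 1.15)
            _add_blob(img, cy, cx, r, amp=rng.uniform(0.45, 0.6))
            yy, xx = np.ogrid[: shape[0], : shape[1]]
            labels[((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2] = next_label
            truth_rows.append({"image_id": image_id, "object_id": next_label, "kind": "cell"})
            next_label += 1
        img += rng.normal(0, 0.012, size=shape)  # camera noise before any blur
        kind = artifact_kinds[i % len(artifact_kinds)] if artifact_kinds else None
        if kind == "saturated":
            cy, cx = rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin)
            r = 2.2 * cell_radius
            _add_blob(img, cy, cx, r, amp=1.5)
            yy, xx = np.ogrid[: shape[0], : shape[1]]
            labels[((yy - cy) ** 2 + (xx - cx) ** 2) <= r**2] = next_label
            truth_rows.append({"image_id": image_id, "object_id": next_label, "kind": "saturated"})
            next_label += 1
        elif kind == "clump":
            cy, cx = rng.uniform(margin, shape[0] - margin), rng.uniform(margin, shape[1] - margin)
            r = cell_radius
            for dy, dx in ((0, 0), (0.9 * r, 0.4 * r), (0.4 * r, 1.1 * r)):
                _add_blob(img, cy + dy, cx + dx, r, amp=0.55)
            yy, xx = np.ogrid[: shape[0], : shape[1]]
            hit = np.zeros(shape, bool)
            for dy, dx in ((0, 0), (0.9 * r, 0.4 * r), (0.4 * r, 1.1 * r)):
                hit |= ((yy - cy - dy) ** 2 + (xx - cx - dx) ** 2) <= r**2
            labels[hit] = next_label
            truth_rows.append({"image_id": image_id, "object_id": next_label, "kind": "clump"})
            next_label += 1
        elif kind == "blur":
            y0 = int(rng.uniform(0, shape[0] // 2))
            x0 = int(rng.uniform(0, shape[1] // 2))
            region = (slice(y0, y0 + shape[0] // 2), slice(x0, x0 + shape[1] // 2))
            img[region] = ndimage.gaussian_filter(img, sigma=4.0)[region]
            truth_rows.append({"image_id": image_id, "object_id": 0, "kind": "blur"})
        images[image_id] = np.clip(img, 0.0, 1.6)
        masks[image_id] = LabelMask(image_id, labels)
    return images, masks, pd.DataFrame(truth_rows)


def _power_loglog_slope(img: np.ndarray) -> float:
    """Slope of the radially averaged log power spectrum vs log frequency."""
    f = np.fft.fftshift(np.fft.fft2(img - img.mean()))
    power = np.abs(f) ** 2
    cy, cx = np.array(power.shape) // 2
    yy, xx = np.indices(power.shape)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2).astype(int)
    maxr = min(cy, cx)
    radial = np.bincount(rr.ravel(), weights=power.ravel())[1:maxr]
    counts = np.bincount(rr.ravel())[1:maxr]
    radial = radial / np.maximum(counts, 1)
    freqs = np.arange(1, maxr)
    good = radial > 0
    if good.sum() < 2:  # blank/constant image: no spectrum to fit
        return 0.0
    slope = np.polyfit(np.log(freqs[good]), np.log(radial[good]), 1)[0]
    return float(slope)


def naive_segment_and_measure(
    images: dict[str, np.ndarray],
    threshold: float = 0.18,
    min_area: int = 12,
) -> tuple[ImageFeatureTable, CellFeatureTable, dict[str, LabelMask]]:
    """Threshold + connected components, then measure both feature levels.

    A deliberately naive stand-in for a real segmentation pipeline; it
    exists so the workflow can be exercised from pixels in tests.
    """
    img_rows = []
    cell_rows = []
    out_masks: dict[str, LabelMask] = {}
    for image_id, img in images.items():
        fg = img > threshold
        labels = measure.label(fg)
        props = [p for p in measure.regionprops(labels, intensity_image=img) if p.area >= min_area]
        relabel = np.zeros_like(labels, dtype=np.int32)
        for new_id, p in enumerate(props, start=1):
            relabel[labels == p.label] = new_id
        out_masks[image_id] = LabelMask(image_id, relabel)
        bg = img[~fg]
        img_rows.append(
            {
                "image_id": image_id,
                "PowerLogLogSlope": _power_loglog_slope(img),
                "FocusScore": float(np.var(ndimage.laplace(img))),
                "MeanIntensity": float(img.mean()),
                "Correlation": (
                    float(np.corrcoef(img[:-1].ravel(), img[1:].ravel())[0, 1])
                    if img.std() > 0
                    else 0.0
                ),
                "SNR": float(img[fg].mean() / bg.std()) if fg.any() and bg.size else 0.0,
                "Cell_Count": len(props),
            }
        )
        for new_id, p in enumerate(props, start=1):
            perim = max(p.perimeter, 1.0)
            cell_rows.append(
                {
                    "image_id": image_id,
                    "object_id": new_id,
                    "area_px": int(p.area),
                    "area": float(p.area),
                    "perimeter": float(perim),
                    "eccentricity": float(p.eccentricity),
                    "solidity": float(p.solidity),
                    "mean_intensity": float(p.intensity_mean),
                    "std_intensity": float(np.std(img[relabel == new_id])),
                    "max_intensity": float(p.intensity_max),
                    "form_factor": float(4 * np.pi * p.area / perim**2),
                }
            )
    img_frame = pd.DataFrame(img_rows).set_index("image_id")
    image_table = ImageFeatureTable(img_frame)
    if not cell_rows:
        raise InputFormatError("naive segmenter found no objects in any image")
    cell_table = CellFeatureTable(pd.DataFrame(cell_rows), list(CELL_DESCRIPTORS))
    return image_table, cell_table, out_masks
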