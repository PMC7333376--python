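"""Shared synthetic fixtures (all generated at test time, seeded)."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from cellqc import ImageFeatureTable
from cellqc.simulate import default_spec, simulate_feature_tables


@pytest.fixture(scope="session")
def default_assay():
    """The default five-phenotype assay (1,500 images) with ground truth."""
    return simulate_feature_tables(default_spec(seed=11))


@pytest.fixture(scope="session")
def small_assay():
    """A 400-image assay for pipeline-level tests that need speed."""
    return simulate_feature_tables(default_spec(seed=23, n_images=400))


def make_gaussian_clusters(
    seed: int,
    centers: np.ndarray,
    n_per: int | list[int],
    sigma: float | list[float] = 1.0,
    prefix: str = "img",
) -> tuple[ImageFeatureTable, np.ndarray]:
    """Isotropic Gaussian blobs in feature space with planted labels."""
    rng = np.random.default_rng(seed)
    centers = np.atleast_2d(np.asarray(centers, float))
    k, d = centers.shape
    n_per = [n_per] * k if np.isscalar(n_per) else list(n_per)
    sigma = [sigma] * k if np.isscalar(sigma) else list(sigma)
    X, labels = [], []
    for c in range(k):
        X.append(centers[c] + sigma[c] * rng.normal(size=(n_per[c], d)))
        labels.append(np.full(n_per[c], c))
    X = np.vstack(X)
    labels = np.concatenate(labels)
    frame = pd.DataFrame(
        X,
        columns=[f"f{j}" for j in range(d)],
        index=pd.Index([f"{prefix}_{i:05d}" for i in range(len(X))], name="image_id"),
    )
    return ImageFeatureTable(frame), labels


@pytest.fixture(scope="session")
def oracle_fixture() -> ImageFeatureTable:
    """The shipped 3-feature grid-oracle fixture (900 images).

    Three Gaussian clusters; the third feature lives on a 10x finer
    natural scale so the iterative grid construction provably loses no
    fully-supported lattice point against the brute-force prune.
    """
    centers = np.array([[0.0, 0.0, 0.0], [10.0, 0.0, 0.5], [0.0, 12.0, -0.6]])
    rng = np.random.default_rng(17)
    X = np.vstack(
        [c + rng.normal(size=(300, 3)) * np.array([1.0, 1.0, 0.1]) for c in centers]
    )
    frame = pd.DataFrame(
        X,
        columns=["f0", "f1", "f2"],
        index=pd.Index([f"w{i:05d}" for i in range(len(X))], name="image_id"),
    )
    return ImageFeatureTable(frame)


def make_clusters_with_outliers(
    seed: int,
    centers: np.ndarray,
    n_per: int | list[int],
    n_outliers: int,
    sigma: float | list[float] = 1.0,
    min_sep: float = 6.0,
) -> tuple[ImageFeatureTable, np.ndarray]:
    """Clusters plus uniform background points kept >= min_sep*sigma away.

    Labels: cluster index for members, -1 for planted outliers.
    """
    table, labels = make_gaussian_clusters(seed, centers, n_per, sigma)
    rng = np.random.default_rng(seed + 1)
    centers = np.atleast_2d(np.asarray(centers, float))
    d = centers.shape[1]
    lo = centers.min(axis=0) - 12.0
    hi = centers.max(axis=0) + 12.0
    sig = np.asarray(sigma if not np.isscalar(sigma) else [sigma] * len(centers))
    out = []
    while len(out) < n_outliers:
        cand = rng.uniform(lo, hi, size=d)
        if all(
            np.linalg.norm(cand - centers[c]) >= min_sep * sig[c]
            for c in range(len(centers))
        ):
            out.append(cand)
    out = np.asarray(out)
    frame = pd.DataFrame(
        np.vstack([table.frame.to_numpy(), out]),
        columns=table.feature_names,
        index=pd.Index(
            list(table.frame.index) + [f"out_{i:04d}" for i in range(n_outliers)],
            name="image_id",
        ),
    )
    return ImageFeatureTable(frame), np.concatenate([labels, np.full(n_outliers, -1)])
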