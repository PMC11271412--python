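"""Patch-feature bag container, toy patch encoder, and spatial-semantic
bag compression.

A :class:`FeatureBag` is the unit of inference: an N x D matrix of
patch-level feature vectors plus the (row, col) patch-grid coordinate of
each patch. Compression averages highly correlated, nearby patches (spatial
radius in patch-grid units, cosine similarity on features) to shrink the
bag before it enters the attention-MIL encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np


@dataclass
class FeatureBag:
    slide_id: str
    features: np.ndarray          # (N, D) float
    coords: np.ndarray            # (N, 2) int grid coords (float after compression)
    patch_um: float = 180.0
    provenance: str = "raw"       # raw | compressed | merged

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        self.coords = np.asarray(self.coords)
        if self.features.ndim != 2 or self.features.shape[0] < 1:
            raise ValueError("features must be a non-empty N x D matrix")
        if self.coords.shape != (self.features.shape[0], 2):
            raise ValueError("coords must align with features (N x 2)")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain non-finite values")

    @property
    def n_patches(self) -> int:
        return self.features.shape[0]

    @property
    def dim(self) -> int:
        return self.features.shape[1]


def toy_encode(
    patches: np.ndarray,
    coords: np.ndarray,
    out_dim: int = 64,
    slide_id: str = "slide",
    patch_um: float = 180.0,
    seed: int = 0,
) -> FeatureBag:
    """Deterministic stand-in featurizer for a frozen patch encoder.

    Each patch (H x W x 3, equal sizes) is mean-pooled to an 8 x 8 grid per
    channel, flattened to 192 values, then passed through a fixed random
    projection (seeded Gaussian) to ``out_dim``.
    """
    patches = np.asarray(patches)
    if patches.ndim != 4 or patches.shape[3] != 3:
        raise ValueError("patches must be (N, H, W, 3)")
    n, h, w, _ = patches.shape
    if h % 8 or w % 8:
        raise ValueError("patch sides must be divisible by 8")
    pooled = (
        patches.astype(np.float64)
        .reshape(n, 8, h // 8, 8, w // 8, 3)
        .mean(axis=(2, 4))
        .reshape(n, 8 * 8 * 3)
    )
    pooled /= 255.0
    rng = np.random.default_rng(seed)
    proj = rng.standard_normal((192, out_dim)) / np.sqrt(192)
    feats = pooled @ proj
    return FeatureBag(
        slide_id=slide_id,
        features=feats.astype(np.float32),
        coords=np.asarray(coords),
        patch_um=patch_um,
        provenance="raw",
    )


def compress_bag(
    bag: FeatureBag, spatial_radius: float = 3.0, cos_min: float = 0.8
) -> FeatureBag:
    """Average highly correlated, nearby patches with a greedy scan.

    Patches are visited in stored (row-major) order. A patch joins the
    first existing cluster whose seed patch lies within ``spatial_radius``
    (Euclidean distance in patch-grid units) and whose current mean feature
    has cosine similarity >= ``cos_min`` with the patch; otherwise it seeds
    a new cluster. Output rows are cluster means at centroid coordinates.

    Zero-norm feature rows are excluded from cosine comparisons and kept as
    singleton clusters.
    """
    feats = bag.features.astype(np.float64)
    coords = bag.coords.astype(np.float64)
    norms = np.linalg.norm(feats, axis=1)
    if (norms == 0).any():
        warnings.warn("zero-norm feature rows kept as singleton clusters")

    seed_coords: list[np.ndarray] = []
    sums: list[np.ndarray] = []
    coord_sums: list[np.ndarray] = []
    counts: list[int] = []
    zero_cluster: list[bool] = []

    for i in range(bag.n_patches):
        x, c = feats[i], coords[i]
        assigned = False
        if norms[i] > 0:
            for j in range(len(sums)):
                if zero_cluster[j]:
                    continue
                if np.linalg.norm(seed_coords[j] - c) > spatial_radius:
                    continue
                mean = sums[j] / counts[j]
                mnorm = np.linalg.norm(mean)
                if mnorm == 0:
                    continue
                cos = float(x @ mean) / (norms[i] * mnorm)
                if cos >= cos_min:
                    sums[j] += x
                    coord_sums[j] += c
                    counts[j] += 1
                    assigned = True
                    break
        if not assigned:
            seed_coords.append(c.copy())
            sums.append(x.copy())
            coord_sums.append(c.copy())
            counts.append(1)
            zero_cluster.append(norms[i] == 0)

    k = np.asarray(counts, dtype=np.float64)
    out_feats = np.stack(sums) / k[:, None]
    out_coords = np.stack(coord_sums) / k[:, None]
    return FeatureBag(
        slide_id=bag.slide_id,
        features=out_feats.astype(bag.features.dtype),
        coords=out_coords,
        patch_um=bag.patch_um,
        provenance="compressed",
    )


def merge_bags(bags: list[FeatureBag]) -> FeatureBag:
    """Concatenate bags into one, offsetting rows so coords never collide."""
    if not bags:
        raise ValueError("need at least one bag")
    dims = {b.dim for b in bags}
    if len(dims) != 1:
        raise ValueError(f"feature dimensions differ across bags: {sorted(dims)}")
    feats = np.concatenate([b.features for b in bags], axis=0)
    coord_parts = []
    row_offset = 0.0
    for b in bags:
        c = b.coords.astype(np.float64).copy()
        c[:, 0] += row_offset
        coord_parts.append(c)
        row_offset += float(b.coords[:, 0].max()) + 2.0
    coords = np.concatenate(coord_parts, axis=0)
    if all(np.issubdtype(b.coords.dtype, np.integer) for b in bags):
        coords = coords.astype(np.int64)
    return FeatureBag(
        slide_id="+".join(b.slide_id for b in bags),
        features=feats,
        coords=coords,
        patch_um=bags[0].patch_um,
        provenance="merged",
    )


def write_bag(bag: FeatureBag, path: str) -> None:
    """Write a bag to HDF5: /features (float32 N x D), /coords (N x 2);
    attrs slide_id, patch_um, provenance."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.features.astype(np.float32))
        f.create_dataset("coords", data=bag.coords)
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["patch_um"] = bag.patch_um
        f.attrs["provenance"] = bag.provenance


def read_bag(path: str) -> FeatureBag:
    with h5py.File(path, "r") as f:
        for member in ("features", "coords"):
            if member not in f:
                raise ValueError(f"bag file {path!r} lacks dataset /{member}")
        for attr in ("slide_id", "patch_um", "provenance"):
            if attr not in f.attrs:
                raise ValueError(f"bag file {path!r} lacks attribute {attr!r}")
        return FeatureBag(
            slide_id=str(f.attrs["slide_id"]),
            features=f["features"][()],
            coords=f["coords"][()],
            patch_um=float(f.attrs["patch_um"]),
            provenance=str(f.attrs["provenance"]),
        )
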