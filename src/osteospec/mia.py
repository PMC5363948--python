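"""Multivariate imaging analysis: K-means and hierarchical segmentation.

Pixel spectra are preprocessed by a declared recipe (any ordered subset of
crop / mask / smooth / baseline / normalize), then clustered:

* K-means: Lloyd iterations with greedy farthest-point seeding from an
  explicit seed, best of ``n_init`` restarts by within-cluster sum of
  squares.
* HCA: Ward-linkage agglomeration on a seeded random subsample of anchor
  pixels (full-linkage cost on every pixel is quadratic); the dendrogram is
  cut at k and remaining pixels join the nearest anchor-cluster centroid.

Labels are relabeled canonically by descending cluster size so maps are
comparable across reruns, and agreement with a ground-truth tissue
template is quantified with the adjusted Rand index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from PIL import Image
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import savgol_filter
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .errors import ParameterError
from .spectral_core import (
    HyperspectralCube,
    SpectralMask,
    WavenumberAxis,
    rubberband_baseline_matrix,
)
from .synthetic_data import TissueTemplate

RecipeStep = Union[str, Tuple[str, Dict]]

#: default recipe: remove the broad background, then unit-norm each pixel
DEFAULT_RECIPE: Sequence[RecipeStep] = ("baseline", "normalize")


@dataclass(frozen=True)
class ClusterMap:
    labels: np.ndarray  # 2-D ints in [0, k)
    k: int
    method: str  # hca | kmeans
    seed: int
    linkage_name: Optional[str] = None
    inertia: Optional[float] = None
    agreement: Optional[float] = None

    def with_agreement(self, truth: TissueTemplate) -> "ClusterMap":
        ari = cluster_agreement(self.labels, truth)
        return ClusterMap(
            self.labels, self.k, self.method, self.seed,
            self.linkage_name, self.inertia, ari,
        )


def _apply_recipe(
    axis: WavenumberAxis, X: np.ndarray, recipe: Sequence[RecipeStep]
) -> Tuple[WavenumberAxis, np.ndarray]:
    """Apply preprocessing steps to a (pixels × channels) matrix."""
    for step in recipe:
        name, kwargs = (step, {}) if isinstance(step, str) else step
        if name == "crop":
            idx = axis.window_indices(kwargs["lo"], kwargs["hi"])
            if idx.size == 0:
                raise ParameterError("crop step retains no channels")
            axis = WavenumberAxis(axis.values[idx])
            X = X[:, idx]
        elif name == "mask":
            mask = kwargs.get("mask", SpectralMask(()))
            keep = np.ones(len(axis), dtype=bool)
            for lo, hi in mask.windows:
                keep &= ~((axis.values >= lo) & (axis.values <= hi))
            if not keep.any():
                raise ParameterError("mask step removes all channels")
            axis = WavenumberAxis(axis.values[keep])
            X = X[:, keep]
        elif name == "smooth":
            X = savgol_filter(
                X, kwargs.get("window_channels", 9), kwargs.get("polyorder", 2), axis=1
            )
        elif name == "baseline":
            X = rubberband_baseline_matrix(axis, X)
        elif name == "normalize":
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            X = X / norms
        else:
            raise ParameterError(f"unknown recipe step {name!r}")
    return axis, X


def _canonical_relabel(flat_labels: np.ndarray, k: int) -> np.ndarray:
    """Relabel so label 0 is the largest cluster, 1 the next, etc.

    Ties in size break by original label index for determinism.
    """
    sizes = np.bincount(flat_labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[flat_labels]


def _farthest_point_centers(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    first = int(rng.integers(len(X)))
    centers = [X[first]]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d2))
        centers.append(X[nxt])
        d2 = np.minimum(d2, np.sum((X - centers[-1]) ** 2, axis=1))
    return np.stack(centers)


def kmeans_segment(
    cube: HyperspectralCube,
    k: int = 4,
    seed: int = 0,
    n_init: int = 4,
    preprocess_recipe: Sequence[RecipeStep] = DEFAULT_RECIPE,
) -> ClusterMap:
    """Lloyd K-means with greedy farthest-point seeding, best of n_init runs."""
    n_pixels = cube.height * cube.width
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > n_pixels:
        raise ParameterError(f"k={k} exceeds pixel count {n_pixels}")
    _, X = _apply_recipe(cube.axis, cube.as_matrix(), preprocess_recipe)
    ss = np.random.SeedSequence(seed)
    best_labels, best_inertia = None, np.inf
    for child in ss.spawn(n_init):
        rng = np.random.default_rng(child)
        centers = _farthest_point_centers(X, k, rng)
        km = KMeans(n_clusters=k, init=centers, n_init=1, algorithm="lloyd", max_iter=300)
        labels = km.fit_predict(X)
        if km.inertia_ < best_inertia:
            best_inertia, best_labels = float(km.inertia_), labels
    flat = _canonical_relabel(best_labels, k)
    return ClusterMap(
        labels=flat.reshape(cube.height, cube.width),
        k=k,
        method="kmeans",
        seed=seed,
        inertia=best_inertia,
    )


def hca_segment(
    cube: HyperspectralCube,
    k: int = 4,
    n_anchor: int = 1000,
    seed: int = 0,
    preprocess_recipe: Sequence[RecipeStep] = DEFAULT_RECIPE,
) -> ClusterMap:
    """Ward-linkage hierarchical segmentation via anchor subsampling."""
    n_pixels = cube.height * cube.width
    if k < 2:
        raise ParameterError("k must be >= 2")
    if n_anchor > n_pixels:
        raise ParameterError(f"n_anchor={n_anchor} exceeds pixel count {n_pixels}")
    if k > n_anchor:
        raise ParameterError("k must be <= n_anchor")
    _, X = _apply_recipe(cube.axis, cube.as_matrix(), preprocess_recipe)
    rng = np.random.default_rng(seed)
    anchor_idx = rng.choice(n_pixels, size=n_anchor, replace=False)
    Z = linkage(X[anchor_idx], method="ward")
    anchor_labels = fcluster(Z, t=k, criterion="maxclust") - 1
    # duplicate anchor spectra can leave some requested clusters empty; park
    # empty centroids at infinity so no pixel is assigned to them
    centroids = np.full((k, X.shape[1]), np.inf)
    for j in range(k):
        members = X[anchor_idx][anchor_labels == j]
        if len(members):
            centroids[j] = members.mean(axis=0)
    flat = np.empty(n_pixels, dtype=int)
    flat[anchor_idx] = anchor_labels
    rest = np.setdiff1d(np.arange(n_pixels), anchor_idx, assume_unique=False)
    if rest.size:
        valid = np.flatnonzero(np.isfinite(centroids).all(axis=1))
        cv = centroids[valid]
        d = (
            np.sum(X[rest] ** 2, axis=1)[:, None]
            - 2.0 * X[rest] @ cv.T
            + np.sum(cv**2, axis=1)[None, :]
        )
        flat[rest] = valid[np.argmin(d, axis=1)]
    flat = _canonical_relabel(flat, k)
    return ClusterMap(
        labels=flat.reshape(cube.height, cube.width),
        k=k,
        method="hca",
        seed=seed,
        linkage_name="ward",
    )


def cluster_agreement(labels: np.ndarray, truth: TissueTemplate) -> float:
    """Adjusted Rand index between a label field and the tissue template."""
    labels = np.asarray(labels)
    if labels.shape != truth.labels.shape:
        raise ParameterError(
            f"label field {labels.shape} does not match template {truth.labels.shape}"
        )
    return float(adjusted_rand_score(truth.labels.ravel(), labels.ravel()))


DEFAULT_PALETTE = (
    (31, 119, 180),
    (255, 127, 14),
    (44, 160, 44),
    (214, 39, 40),
    (148, 103, 189),
    (140, 86, 75),
    (227, 119, 194),
    (127, 127, 127),
)


def false_colour(labels: np.ndarray, palette=DEFAULT_PALETTE, out_path=None) -> np.ndarray:
    """Render a label field as an RGB image, one colour per canonical label."""
    labels = np.asarray(labels)
    k = int(labels.max()) + 1
    if len(palette) < k:
        raise ParameterError(f"palette has {len(palette)} colours; need {k}")
    lut = np.array(palette[:k], dtype=np.uint8)
    rgb = lut[labels]
    if out_path is not None:
        Image.fromarray(rgb, mode="RGB").save(out_path)
    return rgb


def smallest_k_reaching(
    cube: HyperspectralCube,
    truth: TissueTemplate,
    method: str = "hca",
    k_range: Sequence[int] = range(2, 9),
    ari_threshold: float = 0.7,
    seed: int = 0,
    **kwargs,
) -> Tuple[Optional[int], List[Tuple[int, float]]]:
    """Smallest k whose segmentation reaches the ARI threshold vs truth.

    Returns (k or None, full [(k, ari), ...] sweep).
    """
    segment = {"hca": hca_segment, "kmeans": kmeans_segment}[method]
    sweep = []
    answer = None
    for k in k_range:
        cm = segment(cube, k=k, seed=seed, **kwargs)
        ari = cluster_agreement(cm.labels, truth)
        sweep.append((int(k), float(ari)))
        if answer is None and ari >= ari_threshold:
            answer = int(k)
    return answer, sweep
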