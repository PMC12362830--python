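"""Tissue/background separation by spectral k-means clustering.

A vertically sectioned skin specimen occupies only part of the scanned
area; the rest is glass slide and solvent background with its own
chemistry.  Pixels are clustered on binned spectral features (k-means,
k = 15 by default) and the clusters covering tissue are selected either
manually by label or automatically by their mean intensity in an
endogenous marker channel such as choline (m/z 104.107), which is
present throughout viable skin.  Detached specks are then removed by
keeping the largest connected component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from skimage import measure
from sklearn.cluster import KMeans

from .io import IonImage, MSIDataset

__all__ = [
    "FeatureSpec",
    "PixelFeatures",
    "ClusterMap",
    "TissueMask",
    "build_features",
    "cluster_pixels",
    "select_tissue_clusters",
    "crop_outliers",
    "DEFAULT_K",
    "AUTO_MARKER_THRESHOLD",
]

DEFAULT_K = 15
# In auto mode a cluster is kept as tissue when its mean marker
# intensity exceeds this fraction of the best cluster's mean.
AUTO_MARKER_THRESHOLD = 0.25


@dataclass(frozen=True)
class FeatureSpec:
    """How pixel spectra are turned into clustering features.

    Peaks are histogrammed into ``bin_width``-Da bins over
    ``[mz_min, mz_max)``; ``None`` bounds default to the acquired m/z
    range of the dataset.  With ``normalize="per-pixel-sum"`` each
    nonzero pixel vector is divided by its sum, removing overall
    abundance differences so clusters reflect spectral composition.
    """

    mz_min: float | None = None
    mz_max: float | None = None
    bin_width: float = 1.0
    normalize: str = "per-pixel-sum"  # or "none"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if self.mz_min is not None and self.mz_max is not None and self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.normalize not in ("per-pixel-sum", "none"):
            raise ValueError(f"unknown normalization {self.normalize!r}")


@dataclass
class PixelFeatures:
    """Per-pixel feature vectors plus the bin edges that define them."""

    pixels: list[tuple[int, int]]
    matrix: np.ndarray  # (n_pixels, n_bins)
    bin_edges: np.ndarray
    spec: FeatureSpec


@dataclass
class ClusterMap:
    """Per-pixel cluster labels from one k-means run."""

    pixels: list[tuple[int, int]]
    labels: np.ndarray
    k: int
    feature_spec: FeatureSpec
    seed: int

    def label_of(self) -> dict[tuple[int, int], int]:
        return {p: int(l) for p, l in zip(self.pixels, self.labels)}

    def members(self, label: int) -> set[tuple[int, int]]:
        return {p for p, l in zip(self.pixels, self.labels) if l == label}

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"x": [c for c, _ in self.pixels],
             "y": [r for _, r in self.pixels],
             "label": self.labels}
        ).to_csv(path, index=False)

    def to_png(self, path) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        cols = [c for c, _ in self.pixels]
        rows = [r for _, r in self.pixels]
        c0, r0 = min(cols), min(rows)
        img = np.full((max(rows) - r0 + 1, max(cols) - c0 + 1), np.nan)
        for (c, r), l in zip(self.pixels, self.labels):
            img[r - r0, c - c0] = l
        fig, ax = plt.subplots()
        ax.imshow(img, cmap="tab20", interpolation="nearest")
        ax.set_title(f"k-means clusters (k={self.k})")
        ax.set_axis_off()
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


@dataclass
class TissueMask:
    """The selected set of tissue pixels, with selection provenance."""

    pixels: set[tuple[int, int]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.pixels:
            raise ValueError("empty tissue mask")

    def __len__(self) -> int:
        return len(self.pixels)

    def to_csv(self, path) -> None:
        import pandas as pd

        pts = sorted(self.pixels, key=lambda p: (p[1], p[0]))
        pd.DataFrame({"x": [c for c, _ in pts], "y": [r for _, r in pts]}).to_csv(
            path, index=False
        )


def build_features(dataset: MSIDataset, spec: FeatureSpec | None = None) -> PixelFeatures:
    """Bin each pixel's peaks into a fixed-length intensity vector.

    Returns one row per dataset pixel, in a stable (row, col) order.
    Emits a warning when the whole feature matrix is zero (clustering
    would then be degenerate).
    """
    spec = spec or FeatureSpec()
    lo, hi = spec.mz_min, spec.mz_max
    if lo is None or hi is None:
        dlo, dhi = dataset.mz_range()
        lo = dlo if lo is None else lo
        hi = (dhi + spec.bin_width) if hi is None else hi
    n_bins = int(np.ceil((hi - lo) / spec.bin_width))
    if n_bins < 1:
        raise ValueError("feature m/z range is empty")
    edges = lo + spec.bin_width * np.arange(n_bins + 1)

    pixels = sorted(dataset.pixels, key=lambda p: (p[1], p[0]))
    matrix = np.zeros((len(pixels), n_bins))
    for i, p in enumerate(pixels):
        mz, inten = dataset.pixels[p]
        if mz.size == 0:
            continue
        inside = (mz >= lo) & (mz < edges[-1])
        if not np.any(inside):
            continue
        idx = np.minimum(((mz[inside] - lo) / spec.bin_width).astype(int), n_bins - 1)
        np.add.at(matrix[i], idx, inten[inside])

    if spec.normalize == "per-pixel-sum":
        sums = matrix.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        matrix[nz] /= sums[nz]
    if not matrix.any():
        warnings.warn("all-zero feature matrix: clustering will be degenerate")
    return PixelFeatures(pixels, matrix, edges, spec)


def cluster_pixels(features: PixelFeatures, k: int = DEFAULT_K, seed: int = 0) -> ClusterMap:
    """Partition pixels with k-means on spectral features.

    Deterministic for a fixed seed (k-means++ initialisation, 300
    iteration cap, tolerance 1e-4).
    """
    n = len(features.pixels)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of pixels ({n})")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                    tol=1e-4, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate-point convergence chatter
            labels = km.fit_predict(features.matrix)
    return ClusterMap(features.pixels, np.asarray(labels, dtype=int), k,
                      features.spec, seed)


def select_tissue_clusters(
    cluster_map: ClusterMap,
    labels: Sequence[int] | None = None,
    marker: IonImage | None = None,
    threshold: float = AUTO_MARKER_THRESHOLD,
) -> TissueMask:
    """Assemble the tissue mask from chosen clusters.

    Manual mode (``labels`` given) unions the listed clusters.  Auto
    mode (``marker`` given) ranks clusters by mean marker-channel
    intensity and keeps every cluster whose mean exceeds ``threshold``
    times the top cluster's mean — the marker should be an endogenous,
    tissue-wide channel such as choline.
    """
    if labels is None and marker is None:
        raise ValueError("provide either cluster labels (manual) or a marker image (auto)")
    if labels is not None:
        bad = [l for l in labels if not (0 <= l < cluster_map.k)]
        if bad:
            raise ValueError(f"labels out of range [0, {cluster_map.k}): {bad}")
        chosen = set(int(l) for l in labels)
        provenance = f"manual labels {sorted(chosen)}"
    else:
        means = np.full(cluster_map.k, -np.inf)
        for l in range(cluster_map.k):
            vals = [marker.value_at(c, r) for (c, r) in cluster_map.members(l)]
            if vals:
                means[l] = float(np.mean(vals))
        top = means.max()
        if top <= 0:
            raise ValueError("marker channel is empty: cannot auto-select tissue")
        chosen = {l for l in range(cluster_map.k) if means[l] >= threshold * top}
        provenance = f"auto marker m/z {marker.target_mz:g}, threshold {threshold}"
    pixels = {p for p, l in zip(cluster_map.pixels, cluster_map.labels) if l in chosen}
    if not pixels:
        raise ValueError("empty tissue selection")
    return TissueMask(pixels, provenance)


def crop_outliers(
    mask: TissueMask,
    crop_box: tuple[int, int, int, int] | None = None,
) -> TissueMask:
    """Drop detached specks, keeping the largest 8-connected component.

    ``crop_box`` is an optional inclusive ``(col_min, col_max, row_min,
    row_max)`` window applied before the connectivity analysis.
    """
    pixels = mask.pixels
    if crop_box is not None:
        c0, c1, r0, r1 = crop_box
        pixels = {(c, r) for c, r in pixels if c0 <= c <= c1 and r0 <= r <= r1}
        if not pixels:
            raise ValueError("crop box excludes every tissue pixel")
    cols = [c for c, _ in pixels]
    rows = [r for _, r in pixels]
    cmin, rmin = min(cols), min(rows)
    img = np.zeros((max(rows) - rmin + 1, max(cols) - cmin + 1), dtype=bool)
    for c, r in pixels:
        img[r - rmin, c - cmin] = True
    labelled = measure.label(img, connectivity=2)
    counts = np.bincount(labelled.ravel())
    counts[0] = 0
    keep = counts.argmax()
    kept = {(c, r) for c, r in pixels if labelled[r - rmin, c - cmin] == keep}
    return TissueMask(kept, provenance=mask.provenance + " | cropped largest component")
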