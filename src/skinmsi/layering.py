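"""Straightening of the curved tissue band and depth-layer assignment.

A skin section runs as a curved band across the scan.  To divide it
into depth layers of equal width starting at the stratum corneum (SC),
the band is first "straightened" by a linear manipulation of the
depth-axis pixel ordinate Y:

    Y' = (Y - Avg(Y)) / Var(Y),   then   Y' = Y' * 100000

In the default *per-column* mode Avg(Y) is taken separately for each
column of pixels across the band, which removes the band's curvature
(each column is re-centred on the band midline); Var is then taken over
all tissue pixels.  The *global* mode applies the formula verbatim with
Avg and Var over all tissue pixels, which rescales but cannot
straighten a curved band.  Both maps are affine with positive slope
within a column, so pixel ordering along the depth axis is preserved.

The straightened ordinate is then partitioned into a user-chosen number
of layers — 1-D k-means or equal-width bins — indexed from the SC
inwards, and reprojected onto the original tissue shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.cluster import KMeans

from .segmentation import TissueMask

__all__ = [
    "StraightenedTissue",
    "LayerAssignment",
    "DegenerateGeometryError",
    "straighten",
    "assign_layers",
    "reproject",
    "SCALE_FACTOR",
]

SCALE_FACTOR = 100_000.0
Side = Literal["top", "bottom", "left", "right"]


class DegenerateGeometryError(ValueError):
    """Tissue geometry too thin/flat for depth stratification."""


def _rotate(pixels: list[tuple[int, int]], sc_side: Side) -> tuple[np.ndarray, np.ndarray]:
    """Map original (col, row) to (across, depth) with depth 0 at the SC side."""
    cols = np.array([c for c, _ in pixels])
    rows = np.array([r for _, r in pixels])
    if sc_side == "top":
        return cols, rows
    if sc_side == "bottom":
        return cols, rows.max() - rows
    if sc_side == "left":
        return rows, cols
    if sc_side == "right":
        return rows, cols.max() - cols
    raise ValueError(f"unknown sc_side {sc_side!r}")


@dataclass
class StraightenedTissue:
    """Straightened depth ordinate per tissue pixel, with audit parameters."""

    pixels: list[tuple[int, int]]  # original (col, row)
    across: np.ndarray             # coordinate along the band
    depth_px: np.ndarray           # raw depth-axis ordinate after rotation
    y_prime: np.ndarray            # straightened, scaled ordinate
    sc_side: Side
    mode: str
    params: dict


def straighten(
    mask: TissueMask,
    sc_side: Side = "top",
    mode: str = "per-column",
    scale: float = SCALE_FACTOR,
    use_std: bool = False,
) -> StraightenedTissue:
    """Apply the linear depth-axis manipulation to the tissue mask.

    ``mode="per-column"`` centres Y within each across-band column
    before the global variance scaling (straightens curvature);
    ``mode="global"`` centres on the overall mean.  ``use_std``
    switches the divisor from the variance to the standard deviation.
    """
    if mode not in ("per-column", "global"):
        raise ValueError(f"unknown straightening mode {mode!r}")
    pixels = sorted(mask.pixels, key=lambda p: (p[1], p[0]))
    across, depth = _rotate(pixels, sc_side)
    y = depth.astype(float)

    column_means: dict[int, float] = {}
    if mode == "per-column":
        centred = np.empty_like(y)
        for col in np.unique(across):
            sel = across == col
            m = y[sel].mean()
            column_means[int(col)] = float(m)
            centred[sel] = y[sel] - m
    else:
        m = y.mean()
        column_means = {"global": float(m)}  # type: ignore[dict-item]
        centred = y - m

    var = float(np.var(centred))
    if var == 0.0:
        raise DegenerateGeometryError(
            "zero variance of the straightened ordinate (single-row tissue?)"
        )
    divisor = np.sqrt(var) if use_std else var
    y_prime = centred / divisor * scale
    return StraightenedTissue(
        pixels, across, depth, y_prime, sc_side, mode,
        params={"column_means": column_means, "variance": var,
                "use_std": use_std, "scale": scale},
    )


@dataclass
class LayerAssignment:
    """Per-pixel depth-layer index, ordered from the stratum corneum.

    ``widths_um[j]`` is the mean pixel count of layer ``j`` along the
    depth axis (per across-band column) times the pixel size.
    """

    pixels: list[tuple[int, int]]
    layer_index: np.ndarray
    n_layers: int
    widths_um: np.ndarray
    sc_side: Side
    method: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.layer_index)
        present = np.unique(idx)
        if not np.array_equal(present, np.arange(self.n_layers)):
            raise ValueError("layer indices must be contiguous 0..n_layers-1")
        if np.any(self.widths_um <= 0):
            raise ValueError("layer widths must be positive")

    def members(self, layer: int) -> set[tuple[int, int]]:
        return {p for p, l in zip(self.pixels, self.layer_index) if l == layer}

    def width_table(self):
        import pandas as pd

        counts = np.bincount(self.layer_index, minlength=self.n_layers)
        return pd.DataFrame(
            {"layer": np.arange(self.n_layers),
             "mean_width_um": self.widths_um,
             "pixel_count": counts}
        )


def assign_layers(
    st: StraightenedTissue,
    n_layers: int,
    method: str = "kmeans-1d",
    seed: int = 0,
    pixel_size_um: float = 50.0,
) -> LayerAssignment:
    """Partition the straightened ordinate into depth layers.

    ``kmeans-1d`` clusters Y' with k = n_layers (clusters relabelled by
    ascending centre so index 0 touches the SC); ``equal-width-bins``
    splits [min Y', max Y'] into n_layers equal intervals.  Both are
    invariant to affine rescaling of Y', so the verbatim x100000 scale
    step never changes layer membership.
    """
    # Work on a unit-range copy of Y' so membership is exactly invariant
    # to affine rescaling (the verbatim x100000 step must be cosmetic);
    # rounding kills the last-ulp differences such rescaling introduces.
    raw = st.y_prime
    span = raw.max() - raw.min()
    y = np.round((raw - raw.min()) / span, 12) if span > 0 else np.zeros_like(raw)
    n_distinct = np.unique(y).size
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if n_layers > n_distinct:
        raise ValueError(
            f"n_layers={n_layers} exceeds the {n_distinct} distinct straightened ordinates"
        )

    if n_layers == 1:
        idx = np.zeros(y.size, dtype=int)
    elif method == "kmeans-1d":
        # Quantile-based initial centres: on 1-D data k-means++ often
        # sticks in a local optimum with uneven intervals; equal-mass
        # quantiles start at (and keep) the balanced interval solution.
        q = (np.arange(n_layers) + 0.5) / n_layers
        centers = np.quantile(y, q).reshape(-1, 1)
        if np.unique(centers).size == n_layers:
            km = KMeans(n_clusters=n_layers, init=centers, n_init=1,
                        max_iter=300, tol=1e-4)
        else:
            km = KMeans(n_clusters=n_layers, init="k-means++", n_init=10,
                        max_iter=300, tol=1e-4, random_state=seed)
        raw = km.fit_predict(y.reshape(-1, 1))
        order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
        remap = np.empty(n_layers, dtype=int)
        remap[order] = np.arange(n_layers)
        idx = remap[raw]
    elif method == "equal-width-bins":
        idx = np.clip((y * n_layers).astype(int), 0, n_layers - 1)
    else:
        raise ValueError(f"unknown layering method {method!r}")

    widths = np.empty(n_layers)
    for j in range(n_layers):
        sel = idx == j
        cols, counts = np.unique(st.across[sel], return_counts=True)
        widths[j] = counts.mean() * pixel_size_um
    return LayerAssignment(st.pixels, idx, n_layers, widths, st.sc_side, method)


def reproject(
    assignment: LayerAssignment,
    st: StraightenedTissue,
    shape: tuple[int, int] | None = None,
    origin: tuple[int, int] = (0, 0),
    sentinel: int = -1,
) -> np.ndarray:
    """Raster of layer indices over the original grid.

    Background pixels carry ``sentinel``.  The raster regroups exactly
    to the assignment (invertible).
    """
    if assignment.pixels != st.pixels:
        raise ValueError("assignment and straightened tissue cover different pixels")
    if shape is None:
        cmax = max(c for c, _ in assignment.pixels)
        rmax = max(r for _, r in assignment.pixels)
        shape = (rmax - origin[1] + 1, cmax - origin[0] + 1)
    raster = np.full(shape, sentinel, dtype=int)
    c0, r0 = origin
    for (c, r), l in zip(assignment.pixels, assignment.layer_index):
        raster[r - r0, c - c0] = l
    return raster


def layer_raster_png(raster: np.ndarray, path, sentinel: int = -1) -> None:
    """Cyclic-colour layer image with background in black."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    shown = np.ma.masked_where(raster == sentinel, raster)
    cmap = plt.get_cmap("hsv").copy()
    cmap.set_bad("black")
    fig, ax = plt.subplots()
    ax.imshow(shown, cmap=cmap, interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight", facecolor="black")
    plt.close(fig)
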