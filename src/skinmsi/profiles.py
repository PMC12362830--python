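"""Per-layer drug quantification and sum-normalized permeation profiles.

The drug signal in each depth layer is summarised as the arithmetic
mean of the drug-channel ion image over all pixels of the layer
(zero-intensity pixels included), and normalized by sum: the fraction
of layer j is its mean divided by the sum of means over all layers.
The resulting unit-sum profile versus depth is the tool's primary
output and is directly comparable across formulations, skin sources
and timepoints.  A manual region-of-interest (ROI) mode reproduces the
classical workflow of hand-drawn one-pixel-wide (50 um) layers stacked
from the stratum corneum inwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import IonImage
from .layering import LayerAssignment

__all__ = [
    "PermeationProfile",
    "RoiLayerSet",
    "layer_profile",
    "roi_profile",
    "depth_of_detection",
    "compare_profiles",
    "DEFAULT_DETECTION_FLOOR",
]

# A layer "contains" drug when it holds at least this fraction of the
# total normalized signal; operationalises depth-of-permeation claims.
DEFAULT_DETECTION_FLOOR = 0.01


@dataclass
class PermeationProfile:
    """Mean drug intensity and sum-normalized fraction per depth layer.

    ``valid`` is False when the total mean intensity is zero (blank
    section); fractions are then all zero rather than NaN.
    """

    layer: np.ndarray          # 0..n-1 from the stratum corneum
    depth_mid_um: np.ndarray   # cumulative width up to the layer centre
    widths_um: np.ndarray
    mean_intensity: np.ndarray
    fraction: np.ndarray
    valid: bool
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.depth_mid_um) <= 0):
            raise ValueError("depth midpoints must be strictly increasing")
        if np.any(self.fraction < 0):
            raise ValueError("fractions must be non-negative")
        if self.valid and abs(self.fraction.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")

    @property
    def n_layers(self) -> int:
        return self.layer.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"layer": self.layer, "depth_um": self.depth_mid_um,
             "mean_intensity": self.mean_intensity, "fraction": self.fraction}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, path=None, ax=None, label: str | None = None):
        """Fraction-vs-depth line plot (normalized average intensity)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig = None
        if ax is None:
            fig, ax = plt.subplots()
        ax.plot(self.depth_mid_um, self.fraction, marker="o", label=label)
        ax.set_xlabel("depth (µm)")
        ax.set_ylabel("normalized average intensity")
        if label:
            ax.legend()
        if path is not None and fig is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax


def _profile_from_means(
    means: np.ndarray, widths: np.ndarray, provenance: dict
) -> PermeationProfile:
    total = means.sum()
    valid = total > 0
    fraction = means / total if valid else np.zeros_like(means)
    cum = np.concatenate([[0.0], np.cumsum(widths)])
    mids = cum[:-1] + widths / 2.0
    return PermeationProfile(
        layer=np.arange(means.size), depth_mid_um=mids, widths_um=widths,
        mean_intensity=means, fraction=fraction, valid=bool(valid),
        provenance=provenance,
    )


def layer_profile(ion_image: IonImage, layers: LayerAssignment) -> PermeationProfile:
    """Mean drug intensity per automatic layer, normalized by sum.

    The mean is over *all* pixels of the layer, zeros included; the
    result is independent of pixel iteration order and of any global
    intensity scaling of the ion image.
    """
    means = np.empty(layers.n_layers)
    for j in range(layers.n_layers):
        vals = [ion_image.value_at(c, r) for (c, r) in layers.members(j)]
        means[j] = float(np.mean(vals))
    return _profile_from_means(
        means, layers.widths_um,
        provenance={"target_mz": ion_image.target_mz, "tol": ion_image.tol,
                    "n_layers": layers.n_layers, "method": layers.method},
    )


@dataclass
class RoiLayerSet:
    """Ordered manual ROI layers of stated width, starting at the SC."""

    masks: list[set[tuple[int, int]]]
    width_um: float = 50.0

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise ValueError("ROI width must be positive")
        seen: set[tuple[int, int]] = set()
        for i, m in enumerate(self.masks):
            if not m:
                raise ValueError(f"ROI layer {i} is empty")
            overlap = seen & m
            if overlap:
                raise ValueError(f"ROI layers overlap at {sorted(overlap)[:3]}...")
            seen |= m

    @property
    def n_layers(self) -> int:
        return len(self.masks)

    def cumulative_depth_um(self, n: int | None = None) -> float:
        """Depth spanned by the first ``n`` ROI layers (all by default)."""
        n = self.n_layers if n is None else n
        return n * self.width_um

    @classmethod
    def from_assignment(cls, layers: LayerAssignment) -> "RoiLayerSet":
        """Treat reprojected automatic layers as ROIs (uniform nominal width)."""
        masks = [layers.members(j) for j in range(layers.n_layers)]
        return cls(masks, width_um=float(np.mean(layers.widths_um)))


def roi_profile(ion_image: IonImage, rois: RoiLayerSet) -> PermeationProfile:
    """Mean-and-normalize over manual ROI layers (same contract as layer_profile)."""
    means = np.array(
        [float(np.mean([ion_image.value_at(c, r) for (c, r) in m])) for m in rois.masks]
    )
    widths = np.full(rois.n_layers, rois.width_um)
    return _profile_from_means(
        means, widths,
        provenance={"target_mz": ion_image.target_mz, "tol": ion_image.tol,
                    "n_layers": rois.n_layers, "method": "roi"},
    )


def depth_of_detection(
    profile: PermeationProfile, floor: float = DEFAULT_DETECTION_FLOOR
) -> float:
    """Depth (um) of the lower bound of the deepest layer holding >= ``floor``
    of the total normalized signal; 0 when no layer qualifies."""
    if not 0 < floor < 1:
        raise ValueError("floor must be in (0, 1)")
    qualifying = np.nonzero(profile.fraction >= floor)[0]
    if qualifying.size == 0:
        return 0.0
    deepest = qualifying[-1]
    return float(profile.widths_um[: deepest + 1].sum())


def compare_profiles(
    profiles: Sequence[PermeationProfile],
    ids: Sequence[str] | None = None,
    floor: float = DEFAULT_DETECTION_FLOOR,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format comparison table for overlay plotting.

    Returns ``(long, summary)``: the long table has one row per
    (profile id, layer) with depth and fraction; the summary lists each
    profile's depth of detection.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles to compare")
    if ids is None:
        ids = [f"profile_{i}" for i in range(len(profiles))]
    if len(ids) != len(profiles):
        raise ValueError("ids and profiles must have the same length")
    frames = []
    for pid, prof in zip(ids, profiles):
        df = prof.to_frame()
        df.insert(0, "profile_id", pid)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    summary = pd.DataFrame(
        {"profile_id": list(ids),
         "depth_of_detection_um": [depth_of_detection(p, floor) for p in profiles]}
    )
    return long, summary


def plot_comparison(long: pd.DataFrame, path) -> None:
    """Overlay fraction-vs-depth curves, one per profile id."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    for pid, grp in long.groupby("profile_id"):
        ax.plot(grp["depth_um"], grp["fraction"], marker="o", label=str(pid))
    ax.set_xlabel("depth (µm)")
    ax.set_ylabel("normalized average intensity")
    ax.legend()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
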