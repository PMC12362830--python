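"""Data model and I/O for mass spectrometry imaging (MSI) scans.

An MSI scan is a raster of pixels, each carrying a centroided mass
spectrum (m/z, intensity pairs).  Scans are exchanged as plain-text
pixel tables with one row per (x, y, m/z, intensity) record; this is
the export format produced by vendor software when saving an imaging
run as text.  Ion images — the per-pixel summed intensity inside a
narrow m/z window — are the basic visual unit of MSI analysis.

This module also provides exact-mass arithmetic for defining detection
channels from an elemental formula, e.g. protonated terbinafine
[C21H25N + H]+ at m/z 292.206 or the intrinsic choline cation
[C5H14NO]+ at m/z 104.107.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "MSIDataset",
    "IonImage",
    "IonSpecies",
    "PixelTableError",
    "load_pixel_table",
    "write_pixel_table",
    "extract_ion_image",
    "monoisotopic_mz",
    "parse_formula",
]


class PixelTableError(ValueError):
    """Raised when a pixel-table file cannot be parsed."""


# Monoisotopic masses of the most abundant isotope (Da), IUPAC/CODATA.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
    "Si": 27.9769265325,
    "Se": 73.9224764,
    "B": 11.0093054,
    "Li": 7.01600455,
    "Mg": 23.9850417,
    "Ca": 39.96259098,
    "Fe": 55.9349375,
    "Zn": 63.9291422,
    "Cu": 62.9295975,
}

ELECTRON_MASS = 0.000548579909  # Da


@dataclass
class MSIDataset:
    """A grid of pixel spectra with pixel-size metadata.

    Parameters
    ----------
    pixels
        Mapping from integer ``(col, row)`` coordinates to a pair of
        arrays ``(mz, intensity)``.  Within each pixel m/z values are
        strictly ascending and intensities are non-negative.
    pixel_size_um
        Physical edge length of one pixel in micrometres (50 for the
        standard-resolution scans this tool targets).
    source_id
        Free-text provenance tag (file name, specimen id, ...).
    """

    pixels: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]
    pixel_size_um: float = 50.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        clean: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for (c, r), (mz, inten) in self.pixels.items():
            if c < 0 or r < 0:
                raise ValueError(f"negative pixel coordinate ({c}, {r})")
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            if mz.shape != inten.shape:
                raise ValueError(f"pixel ({c}, {r}): mz/intensity length mismatch")
            if mz.size > 1 and not np.all(np.diff(mz) > 0):
                raise ValueError(f"pixel ({c}, {r}): m/z values not strictly ascending")
            if np.any(inten < 0):
                raise ValueError(f"pixel ({c}, {r}): negative intensity")
            clean[(int(c), int(r))] = (mz, inten)
        self.pixels = clean

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def bounding_box(self) -> tuple[int, int, int, int]:
        """(col_min, col_max, row_min, row_max) of observed pixels."""
        if not self.pixels:
            raise ValueError("dataset has no pixels")
        cols = [c for c, _ in self.pixels]
        rows = [r for _, r in self.pixels]
        return min(cols), max(cols), min(rows), max(rows)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_rows, n_cols) of the bounding-box raster."""
        c0, c1, r0, r1 = self.bounding_box
        return r1 - r0 + 1, c1 - c0 + 1

    @property
    def origin(self) -> tuple[int, int]:
        """(col, row) of the bounding-box corner."""
        c0, _, r0, _ = self.bounding_box
        return c0, r0

    def mz_range(self) -> tuple[float, float]:
        """Min and max m/z observed across all pixels with peaks."""
        lo, hi = np.inf, -np.inf
        for mz, _ in self.pixels.values():
            if mz.size:
                lo = min(lo, mz[0])
                hi = max(hi, mz[-1])
        if not np.isfinite(lo):
            raise ValueError("dataset contains no peaks")
        return float(lo), float(hi)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MSIDataset):
            return NotImplemented
        if self.pixel_size_um != other.pixel_size_um:
            return False
        if set(self.pixels) != set(other.pixels):
            return False
        for key, (mz, it) in self.pixels.items():
            omz, oit = other.pixels[key]
            if not (np.allclose(mz, omz) and np.allclose(it, oit)):
                return False
        return True


@dataclass
class IonImage:
    """2-D intensity raster for one m/z window.

    ``values[row, col]`` covers the dataset bounding box; pixels with no
    peak inside the window (or absent from the scan) carry zero.
    """

    values: np.ndarray
    target_mz: float
    tol: float
    tol_mode: str = "da"  # "da" or "ppm"
    origin: tuple[int, int] = (0, 0)  # (col, row) offset of values[0, 0]
    pixel_size_um: float = 50.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("IonImage values must be 2-D")
        if np.any(self.values < 0):
            raise ValueError("IonImage values must be non-negative")

    def value_at(self, col: int, row: int) -> float:
        c0, r0 = self.origin
        return float(self.values[row - r0, col - c0])

    def scaled(self, factor: float) -> "IonImage":
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return IonImage(self.values * factor, self.target_mz, self.tol,
                        self.tol_mode, self.origin, self.pixel_size_um)

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")

    def to_png(self, path: str | Path) -> None:
        """Heat-map export: yellow = max, blue = low, black = absent."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from matplotlib.colors import LinearSegmentedColormap

        cmap = LinearSegmentedColormap.from_list("msi", ["#0000b0", "#00a0ff", "#ffff00"])
        cmap.set_bad("black")
        shown = np.ma.masked_where(self.values <= 0, self.values)
        fig, ax = plt.subplots(figsize=(6, 6 * self.values.shape[0] / max(1, self.values.shape[1])))
        ax.imshow(shown, cmap=cmap, interpolation="nearest")
        ax.set_title(f"m/z {self.target_mz:g}")
        ax.set_axis_off()
        fig.savefig(path, dpi=120, bbox_inches="tight", facecolor="black")
        plt.close(fig)


@dataclass(frozen=True)
class IonSpecies:
    """An ionic species defined by elemental composition, charge and adduct.

    ``adduct`` is ``"protonated"`` for [M + nH]n+ species or
    ``"intrinsic-cation"`` for ions carrying their own charge ([M]+).
    """

    formula: Mapping[str, int]
    charge: int = 1
    adduct: str = "protonated"

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("charge must be nonzero")
        if self.adduct not in ("protonated", "intrinsic-cation"):
            raise ValueError(f"unknown adduct kind {self.adduct!r}")
        for el, n in self.formula.items():
            if n < 1:
                raise ValueError(f"element count must be >= 1, got {el}{n}")


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string like ``"C21H25N"`` into counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        el, n = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(n) if n else 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def monoisotopic_mz(species: IonSpecies) -> float:
    """Theoretical monoisotopic m/z of an ion.

    Computed as (sum of monoisotopic element masses, plus one hydrogen
    per charge for protonated adducts, minus ``charge`` electron
    masses) divided by the absolute charge.
    """
    total = 0.0
    for el, n in species.formula.items():
        try:
            total += MONOISOTOPIC_MASS[el] * n
        except KeyError:
            raise ValueError(f"unknown element symbol {el!r}") from None
    n_charge = abs(species.charge)
    if species.adduct == "protonated":
        total += n_charge * MONOISOTOPIC_MASS["H"]
    total -= species.charge * ELECTRON_MASS
    return total / n_charge


def _detect_delimiter(line: str) -> str | None:
    """Return "," for comma-separated rows, None for whitespace."""
    return "," if "," in line else None


def load_pixel_table(
    path: str | Path,
    pixel_size_um: float = 50.0,
    delimiter: str | None = "auto",
    source_id: str | None = None,
) -> MSIDataset:
    """Load an MSI scan from a plain-text pixel table.

    Each non-header row holds ``x y mz intensity`` separated by the
    given delimiter (auto-detected between comma and whitespace by
    default).  A single leading header line is tolerated.  Duplicate
    (x, y, m/z) records are summed; records whose summed intensity is
    zero are dropped, so pixels whose spectrum is entirely zero do not
    appear in the loaded dataset.
    """
    path = Path(path)
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise PixelTableError(f"no data in {path}")

    accum: dict[tuple[int, int], dict[float, float]] = {}
    start = 0
    first_fields = lines[0].split("," if "," in lines[0] else None)
    try:
        float(first_fields[0])
    except (ValueError, IndexError):
        start = 1  # header line
    if start == len(lines):
        raise PixelTableError(f"no data in {path}")

    for lineno, raw in enumerate(lines[start:], start=start + 1):
        sep = _detect_delimiter(raw) if delimiter == "auto" else delimiter
        fields = raw.split(sep)
        fields = [f for f in fields if f.strip()]
        if len(fields) != 4:
            raise PixelTableError(
                f"{path}: line {lineno}: expected 4 fields (x y mz intensity), got {len(fields)}"
            )
        try:
            x, y = int(float(fields[0])), int(float(fields[1]))
            mz, inten = float(fields[2]), float(fields[3])
        except ValueError:
            raise PixelTableError(f"{path}: line {lineno}: malformed numeric field") from None
        if inten < 0:
            raise PixelTableError(f"{path}: line {lineno}: negative intensity")
        peaks = accum.setdefault((x, y), {})
        peaks[mz] = peaks.get(mz, 0.0) + inten

    pixels: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    for key, peaks in accum.items():
        kept = sorted((m, i) for m, i in peaks.items() if i > 0)
        if not kept:
            continue
        mzs = np.array([m for m, _ in kept])
        its = np.array([i for _, i in kept])
        pixels[key] = (mzs, its)
    if not pixels:
        raise PixelTableError(f"no nonzero records in {path}")
    return MSIDataset(pixels, pixel_size_um=pixel_size_um,
                      source_id=source_id if source_id is not None else path.name)


def write_pixel_table(dataset: MSIDataset, path: str | Path, delimiter: str = "\t") -> None:
    """Write a dataset as a pixel table re-loadable by :func:`load_pixel_table`.

    Rows are emitted sorted by (y, x, m/z).  A pixel with an empty
    spectrum contributes no rows (and is therefore absent after a
    round trip; the text format cannot represent peakless pixels).
    """
    path = Path(path)
    lines = ["x" + delimiter + "y" + delimiter + "mz" + delimiter + "intensity"]
    for (c, r) in sorted(dataset.pixels, key=lambda p: (p[1], p[0])):
        mz, inten = dataset.pixels[(c, r)]
        for m, i in zip(mz, inten):
            lines.append(delimiter.join((str(c), str(r), repr(float(m)), repr(float(i)))))
    path.write_text("\n".join(lines) + "\n")


def extract_ion_image(
    dataset: MSIDataset,
    target_mz: float,
    tol: float = 0.02,
    tol_mode: str = "da",
) -> IonImage:
    """Sum, per pixel, the intensities of peaks within ``tol`` of ``target_mz``.

    ``tol_mode`` selects an absolute window in Da or a relative one in
    ppm.  Pixels without peaks in the window get zero.
    """
    if target_mz <= 0:
        raise ValueError(f"target_mz must be > 0, got {target_mz}")
    if tol <= 0:
        raise ValueError(f"tolerance must be > 0, got {tol}")
    if tol_mode == "da":
        half = tol
    elif tol_mode == "ppm":
        half = target_mz * tol * 1e-6
    else:
        raise ValueError(f"unknown tolerance mode {tol_mode!r}")

    c0, _, r0, _ = dataset.bounding_box
    values = np.zeros(dataset.shape)
    lo, hi = target_mz - half, target_mz + half
    for (c, r), (mz, inten) in dataset.pixels.items():
        i0 = np.searchsorted(mz, lo, side="left")
        i1 = np.searchsorted(mz, hi, side="right")
        if i1 > i0:
            values[r - r0, c - c0] = inten[i0:i1].sum()
    return IonImage(values, target_mz, tol, tol_mode, origin=(c0, r0),
                    pixel_size_um=dataset.pixel_size_um)
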