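"""Trap-layout construction for delimiting-survey grids.

Three grid families are supported, mirroring the designs used in US
delimitation programmes:

* **square banded grids** — an odd number of square cells per side (cells of
  one square mile by default), with trap density set per concentric band of
  cells around the central "core" cell;
* **circular banded grids** — a core disc plus concentric annuli, each with
  its own density, traps on a per-band square lattice clipped to the annulus;
* **perimeter rings** — a single trap-filled annulus with a trap-free
  interior, used for egress (containment) testing.

Layouts are plain collections of trap coordinates plus a per-trap attraction
length ``1/λ`` (metres), serialised as CSV with header ``x_m,y_m,lam_inv_m``.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: side of one square-mile grid cell, metres
MILE_M = 1609.34
#: one square mile in km²
SQ_MILE_KM2 = 2.589988


class GridConfigError(ValueError):
    """Raised for an inconsistent or unsupported grid design."""


class LayoutParseError(ValueError):
    """Raised when a trap-layout file cannot be parsed."""


@dataclass(frozen=True)
class Band:
    """One band of a grid design.

    band_id 1 is the core (central cell or central disc); higher ids are the
    successive rings around it. ``density`` is in traps per km².
    """

    band_id: int
    density: float

    def __post_init__(self) -> None:
        if self.band_id < 1:
            raise GridConfigError(f"band_id must be >= 1, got {self.band_id}")
        if self.density < 0:
            raise GridConfigError(f"band density must be >= 0, got {self.density}")


@dataclass(frozen=True)
class GridDesign:
    """Declarative geometry of a survey grid; compiles to a :class:`TrapLayout`.

    Parameters
    ----------
    shape:
        ``"square"``, ``"circular"`` or ``"perimeter"``.
    bands:
        Per-band densities.  For a square grid band ``b`` is the ring of
        cells at Chebyshev distance ``b - 1`` from the central cell; for a
        circular grid band ``b`` is the annulus between consecutive
        ``band_radii_m``; a perimeter design has exactly one band.
    trap_attractiveness_m:
        The attraction length 1/λ (m) assigned to every trap.
    """

    shape: str
    bands: tuple[Band, ...]
    trap_attractiveness_m: float
    cell_side_m: float = MILE_M          # square grids
    side_cells: int | None = None        # square grids, odd
    band_radii_m: tuple[float, ...] = () # circular grids, outer radii
    perimeter_inner_m: float | None = None
    perimeter_width_m: float | None = None

    def __post_init__(self) -> None:
        if self.trap_attractiveness_m <= 0:
            raise GridConfigError("trap_attractiveness_m must be > 0")
        object.__setattr__(self, "bands", tuple(self.bands))
        ids = [b.band_id for b in self.bands]
        if sorted(ids) != list(range(1, len(ids) + 1)):
            raise GridConfigError(f"band ids must be 1..{len(ids)}, got {ids}")
        if self.shape == "square":
            if self.side_cells is None or self.side_cells < 1 or self.side_cells % 2 == 0:
                raise GridConfigError(
                    f"square grid needs an odd side_cells, got {self.side_cells}")
            need = (self.side_cells + 1) // 2
            if len(self.bands) != need:
                raise GridConfigError(
                    f"square grid of {self.side_cells} cells/side needs {need} bands, "
                    f"got {len(self.bands)} (bands must tile the cell lattice)")
        elif self.shape == "circular":
            radii = tuple(self.band_radii_m)
            if len(radii) != len(self.bands):
                raise GridConfigError("one outer radius per band required")
            if any(r <= 0 for r in radii) or any(
                    b >= a for a, b in zip(radii[1:], radii[:-1])):
                raise GridConfigError(
                    f"band_radii_m must be positive and strictly increasing, got {radii}")
            object.__setattr__(self, "band_radii_m", radii)
        elif self.shape == "perimeter":
            if len(self.bands) != 1:
                raise GridConfigError("perimeter design has exactly one band")
            if self.perimeter_inner_m is None or self.perimeter_inner_m < 0:
                raise GridConfigError("perimeter_inner_m must be >= 0")
            if not self.perimeter_width_m or self.perimeter_width_m <= 0:
                raise GridConfigError("perimeter_width_m must be > 0")
        else:
            raise GridConfigError(f"unknown grid shape {self.shape!r}")

    # -- derived geometry -------------------------------------------------

    def band_cells(self, band_id: int) -> list[tuple[int, int]]:
        """Cell indices (col, row; 0 = centre) of a square-grid band."""
        if self.shape != "square":
            raise GridConfigError("band_cells applies to square grids only")
        half = (self.side_cells - 1) // 2
        ring = band_id - 1
        if ring > half:
            raise GridConfigError(f"band {band_id} outside {self.side_cells}-cell grid")
        return [(i, j) for i in range(-half, half + 1) for j in range(-half, half + 1)
                if max(abs(i), abs(j)) == ring]

    def band_area_km2(self, band_id: int) -> float:
        """Trapped area of one band in km²."""
        band = self._band(band_id)
        if self.shape == "square":
            return len(self.band_cells(band.band_id)) * (self.cell_side_m / 1000.0) ** 2
        if self.shape == "circular":
            r_out = self.band_radii_m[band.band_id - 1] / 1000.0
            r_in = 0.0 if band.band_id == 1 else self.band_radii_m[band.band_id - 2] / 1000.0
            return math.pi * (r_out ** 2 - r_in ** 2)
        r_in = self.perimeter_inner_m / 1000.0
        r_out = r_in + self.perimeter_width_m / 1000.0
        return math.pi * (r_out ** 2 - r_in ** 2)

    def _band(self, band_id: int) -> Band:
        for b in self.bands:
            if b.band_id == band_id:
                return b
        raise GridConfigError(f"no band {band_id} in design")

    def solitary(self, band_id: int) -> "GridDesign":
        """Copy of the design with every band but ``band_id`` set to density 0."""
        keep = self._band(band_id)
        bands = tuple(b if b.band_id == keep.band_id else replace(b, density=0.0)
                      for b in self.bands)
        return replace(self, bands=bands)

    def with_uniform_density(self, density: float) -> "GridDesign":
        bands = tuple(replace(b, density=density) for b in self.bands)
        return replace(self, bands=bands)

    def with_band_density(self, band_id: int, density: float) -> "GridDesign":
        self._band(band_id)
        bands = tuple(replace(b, density=density) if b.band_id == band_id else b
                      for b in self.bands)
        return replace(self, bands=bands)


@dataclass
class TrapLayout:
    """Trap positions (m, grid centre at the origin) with per-trap 1/λ (m)."""

    x: np.ndarray
    y: np.ndarray
    lam_inv: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.lam_inv = np.asarray(self.lam_inv, dtype=float)
        if not (self.x.shape == self.y.shape == self.lam_inv.shape):
            raise ValueError("x, y and lam_inv must have equal length")
        if np.any(self.lam_inv <= 0):
            raise ValueError("all trap attraction lengths must be > 0")

    def __len__(self) -> int:
        return self.x.size

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of trap coordinates."""
        return np.column_stack([self.x, self.y])

    def translated(self, dx: float, dy: float) -> "TrapLayout":
        return TrapLayout(self.x + dx, self.y + dy, self.lam_inv.copy())

    @staticmethod
    def concatenate(layouts: Sequence["TrapLayout"]) -> "TrapLayout":
        if not layouts:
            return TrapLayout(np.empty(0), np.empty(0), np.empty(0))
        return TrapLayout(
            np.concatenate([l.x for l in layouts]),
            np.concatenate([l.y for l in layouts]),
            np.concatenate([l.lam_inv for l in layouts]),
        )


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _near_square_factors(n: int) -> tuple[int, int]:
    """Factor n = k*m with k <= m and k the largest divisor <= sqrt(n)."""
    k = int(math.isqrt(n))
    while k > 1 and n % k:
        k -= 1
    return k, n // k


def _cell_lattice(count: int, side: float) -> np.ndarray:
    """Centred, evenly spaced k×m sub-lattice of `count` points in a cell.

    Points sit at spacing side/k (resp. side/m) with a half-spacing offset
    from the cell edges, so the pattern is centred in the cell.
    """
    if count == 0:
        return np.empty((0, 2))
    k, m = _near_square_factors(count)
    xs = (np.arange(k) + 0.5) * side / k - side / 2.0
    ys = (np.arange(m) + 0.5) * side / m - side / 2.0
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def traps_per_cell(density: float, cell_side_m: float) -> int:
    """Round density × cell area (km²) to the per-cell trap count."""
    area_km2 = (cell_side_m / 1000.0) ** 2
    return int(round(density * area_km2))


def build_square_grid(design: GridDesign) -> TrapLayout:
    """Compile a square banded design into a trap layout.

    Each cell of a band receives ``round(density × cell_area)`` traps placed
    on a centred sub-lattice; band b occupies the ring of cells at Chebyshev
    distance b − 1 from the central core cell.
    """
    if design.shape != "square":
        raise GridConfigError("build_square_grid needs shape='square'")
    side = design.cell_side_m
    pieces: list[np.ndarray] = []
    for band in design.bands:
        count = traps_per_cell(band.density, side)
        if count == 0:
            continue
        pattern = _cell_lattice(count, side)
        for (i, j) in design.band_cells(band.band_id):
            pieces.append(pattern + np.array([i * side, j * side]))
    if not pieces:
        return TrapLayout(np.empty(0), np.empty(0), np.empty(0))
    pts = np.vstack(pieces)
    return TrapLayout(pts[:, 0], pts[:, 1],
                      np.full(len(pts), design.trap_attractiveness_m))


def _annulus_lattice(density: float, r_inner: float, r_outer: float) -> np.ndarray:
    """Square lattice of spacing 1000/sqrt(density) m clipped to an annulus.

    The lattice is centred on the origin (points at half-spacing offsets, so
    no trap sits exactly at the grid centre); a point is kept iff its radius
    lies in [r_inner, r_outer).
    """
    if density <= 0:
        return np.empty((0, 2))
    spacing = 1000.0 / math.sqrt(density)
    n = int(math.ceil(r_outer / spacing)) + 1
    ax = (np.arange(-n, n) + 0.5) * spacing
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    r = np.hypot(gx, gy)
    keep = (r >= r_inner) & (r < r_outer)
    return np.column_stack([gx[keep], gy[keep]])


def build_circular_grid(design: GridDesign) -> TrapLayout:
    """Compile a circular banded design (core disc + annuli) into a layout."""
    if design.shape != "circular":
        raise GridConfigError("build_circular_grid needs shape='circular'")
    pieces = []
    r_in = 0.0
    for band, r_out in zip(design.bands, design.band_radii_m):
        pts = _annulus_lattice(band.density, r_in, r_out)
        if len(pts):
            pieces.append(pts)
        r_in = r_out
    if not pieces:
        return TrapLayout(np.empty(0), np.empty(0), np.empty(0))
    pts = np.vstack(pieces)
    return TrapLayout(pts[:, 0], pts[:, 1],
                      np.full(len(pts), design.trap_attractiveness_m))


def build_perimeter_ring(design: GridDesign) -> TrapLayout:
    """Compile a perimeter (containment) ring; the interior stays trap-free."""
    if design.shape != "perimeter":
        raise GridConfigError("build_perimeter_ring needs shape='perimeter'")
    band = design.bands[0]
    pts = _annulus_lattice(band.density, design.perimeter_inner_m,
                           design.perimeter_inner_m + design.perimeter_width_m)
    if not len(pts):
        return TrapLayout(np.empty(0), np.empty(0), np.empty(0))
    return TrapLayout(pts[:, 0], pts[:, 1],
                      np.full(len(pts), design.trap_attractiveness_m))


def build_layout(design: GridDesign) -> TrapLayout:
    """Dispatch on design.shape."""
    return {
        "square": build_square_grid,
        "circular": build_circular_grid,
        "perimeter": build_perimeter_ring,
    }[design.shape](design)


# ---------------------------------------------------------------------------
# layout file I/O
# ---------------------------------------------------------------------------

_HEADER = ["x_m", "y_m", "lam_inv_m"]


def write_layout(layout: TrapLayout, path: str | Path) -> None:
    """Write a layout as CSV with header ``x_m,y_m,lam_inv_m``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for x, y, li in zip(layout.x, layout.y, layout.lam_inv):
            writer.writerow([repr(float(x)), repr(float(y)), repr(float(li))])


def read_layout(path: str | Path) -> TrapLayout:
    """Read a trap-layout CSV; raises :class:`LayoutParseError` with the
    offending line number on malformed input."""
    xs: list[float] = []
    ys: list[float] = []
    lis: list[float] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise LayoutParseError(f"{path}: empty file, expected header {_HEADER}")
        if [h.strip() for h in header] != _HEADER:
            raise LayoutParseError(f"{path}:1: expected header {_HEADER}, got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise LayoutParseError(f"{path}:{lineno}: expected 3 fields, got {len(row)}")
            try:
                x, y, li = (float(v) for v in row)
            except ValueError:
                raise LayoutParseError(f"{path}:{lineno}: non-numeric field in {row}")
            if li <= 0:
                raise LayoutParseError(f"{path}:{lineno}: lam_inv_m must be > 0, got {li}")
            xs.append(x)
            ys.append(y)
            lis.append(li)
    return TrapLayout(np.array(xs), np.array(ys), np.array(lis))
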