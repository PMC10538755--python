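"""Resistance surfaces and carrying-capacity maps.

A landscape is a rectangular grid of 1 km^2 cells. Each cell carries a habitat
suitability value in [0, 1]; movement resistance is its complement
(``resistance = 1 - habitat``), so resistance 1 is impassable. Carrying
capacity per cell is a step function of habitat suitability (0-24 tortoises
per km^2). Three hypothetical scenario surfaces are supported (uniform
no-barrier, an absolute one-cell-wide linear barrier, and a barrier pierced by
low-capacity culvert cells), plus heterogeneous surfaces built from a habitat
grid degraded by anthropogenic disturbance layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GRID_SIZE = 25  # cells per side for the scenario surfaces
CULVERT_RESISTANCE = 0.7  # habitat 0.3: low probability of use
CULVERT_K = 3  # animals that may occupy or transit a culvert cell per generation

#: multiplicative habitat-degradation factor by disturbance type
CONVERSION_FACTORS = {
    "urban_solar": 1.00,
    "rail_interstate": 0.75,
    "minor_road": 0.25,
    "right_of_way": 0.25,
}

#: per-cell carrying capacity (= seeding density) by density label; the
#: high-density value is the 20 tortoises/km^2 implied by the published
#: initial population size (the habitat-model ceiling of 24 applies to
#: habitat-derived surfaces through the capacity bins)
DENSITY_K = {"low": 3, "moderate": 14, "high": 20}

# carrying-capacity bins: (upper edge of habitat bin, K); bins are half-open on
# the left, closed on the right; habitat exactly 0 maps to K = 0
_K_BIN_EDGES = np.array(
    [0.0, 0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.80, 0.90, 1.00]
)
_K_BIN_VALUES = np.array([0, 1, 1, 3, 6, 9, 12, 15, 18, 21, 24])


def _check_unit(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1) or np.any(~np.isfinite(x)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def apply_conversion(habitat, conversion_factor):
    """Degrade habitat suitability by a disturbance conversion factor.

    Returns ``habitat - habitat * factor``, i.e. multiplication by
    ``(1 - factor)``; a factor of 1 destroys the habitat entirely.
    """
    h = _check_unit(habitat, "habitat")
    f = _check_unit(conversion_factor, "conversion_factor")
    out = h * (1.0 - f)
    return out if out.ndim else float(out)


def resistance_from_habitat(adjusted_habitat):
    """Resistance is the complement of (adjusted) habitat suitability."""
    h = _check_unit(adjusted_habitat, "adjusted_habitat")
    out = 1.0 - h
    return out if out.ndim else float(out)


def carrying_capacity(habitat):
    """Per-cell carrying capacity from binned habitat suitability.

    0 for h = 0; 1 for h in (0, 0.20]; then steps of 3 per 0.10 of habitat up
    to 24 for h in (0.90, 1].
    """
    h = _check_unit(habitat, "habitat")
    arr = np.atleast_1d(h)
    # right-closed bins: index of first edge >= h
    idx = np.searchsorted(_K_BIN_EDGES, arr, side="left")
    k = _K_BIN_VALUES[np.clip(idx, 0, len(_K_BIN_VALUES) - 1)]
    k = np.where(arr == 0.0, 0, k).astype(int)
    return k if np.ndim(h) else int(k[0])


@dataclass
class HabitatGrid:
    """Gridded habitat suitability in [0, 1]; 1 km per cell side by default."""

    values: np.ndarray
    cell_size: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("habitat grid must be 2-D (rectangular)")
        _check_unit(self.values, "habitat values")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]


@dataclass
class DisturbanceLayer:
    """A co-registered disturbance footprint with its conversion factor.

    ``intensity`` is a per-cell value in [0, 1]: 0 = disturbance absent, 1 =
    full-strength disturbance. For minor roads the intensity encodes road
    length in the cell relative to the grid-wide maximum, so the applied
    penalty is at or below the 0.25 maximum.
    """

    kind: str
    intensity: np.ndarray
    conversion_factor: float | None = None

    def __post_init__(self):
        if self.kind not in CONVERSION_FACTORS:
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        self.intensity = _check_unit(self.intensity, "intensity")
        if self.conversion_factor is None:
            self.conversion_factor = CONVERSION_FACTORS[self.kind]

    def effective_factor(self) -> np.ndarray:
        """Per-cell conversion factor (intensity-scaled)."""
        return self.conversion_factor * self.intensity


@dataclass
class ResistanceSurface:
    """Per-cell movement cost in [0, 1] with matching carrying capacities.

    ``culvert_cells`` lists (row, col) indices of low-capacity crossing cells
    embedded in an otherwise impassable barrier; those cells also carry a
    per-generation transit quota equal to their K.
    """

    resistance: np.ndarray
    carrying: np.ndarray
    culvert_cells: list[tuple[int, int]] = field(default_factory=list)
    barrier_col: int | None = None

    def __post_init__(self):
        self.resistance = _check_unit(self.resistance, "resistance")
        self.carrying = np.asarray(self.carrying, dtype=int)
        if self.resistance.shape != self.carrying.shape:
            raise ValueError("resistance and carrying-capacity grids must match")
        if np.any((self.resistance >= 1.0) & (self.carrying > 0)):
            raise ValueError("impassable cells must have K = 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.resistance.shape

    @property
    def habitable(self) -> np.ndarray:
        """Boolean mask of traversable cells (resistance < 1)."""
        return self.resistance < 1.0

    @property
    def total_capacity(self) -> int:
        return int(self.carrying.sum())

    def side_of(self, cols) -> np.ndarray:
        """Group label (0/1) by position relative to the barrier column.

        Without a barrier the grid is split at its central column; cells on
        the barrier column itself (culvert occupants) are grouped with side 0.
        """
        split = self.barrier_col if self.barrier_col is not None else self.shape[1] // 2
        return (np.asarray(cols) > split).astype(int)


def build_scenario_surface(
    scenario: str,
    n_culverts: int = 3,
    density: str = "moderate",
    grid_size: int = GRID_SIZE,
) -> ResistanceSurface:
    """Construct one of the hypothetical scenario surfaces.

    ``no_barrier``: uniform zero resistance. ``barrier``: a one-cell-wide,
    full-length impassable column bisecting the grid. ``culverts``: the
    barrier with ``n_culverts`` evenly spaced passable cells (resistance 0.7,
    K = 3). All non-barrier cells carry K = 3/14/20 for low/moderate/high
    density.
    """
    if density not in DENSITY_K:
        raise ValueError(f"unknown density {density!r}")
    k_cell = DENSITY_K[density]
    resistance = np.zeros((grid_size, grid_size))
    carrying = np.full((grid_size, grid_size), k_cell, dtype=int)

    if scenario == "no_barrier":
        return ResistanceSurface(resistance, carrying)

    barrier_col = grid_size // 2
    resistance[:, barrier_col] = 1.0
    carrying[:, barrier_col] = 0

    if scenario == "barrier":
        return ResistanceSurface(resistance, carrying, barrier_col=barrier_col)

    if scenario == "culverts":
        if n_culverts > grid_size:
            raise ValueError("more culverts than barrier cells")
        if n_culverts < 1:
            raise ValueError("culvert scenario requires at least one culvert")
        # evenly spaced rows along the barrier
        rows = np.linspace(0, grid_size - 1, n_culverts + 2)[1:-1]
        rows = np.round(rows).astype(int)
        culverts = [(int(r), barrier_col) for r in rows]
        for r, c in culverts:
            resistance[r, c] = CULVERT_RESISTANCE
            carrying[r, c] = CULVERT_K
        return ResistanceSurface(
            resistance, carrying, culvert_cells=culverts, barrier_col=barrier_col
        )

    raise ValueError(f"unknown scenario {scenario!r}")


def build_heterogeneous_surface(
    habitat: HabitatGrid, layers: list[DisturbanceLayer]
) -> ResistanceSurface:
    """Degrade a habitat grid by disturbance layers; derive resistance and K.

    Conversions compose multiplicatively (sequentially), which is
    order-independent and keeps values in range:
    ``adjusted = habitat * prod(1 - factor_i)``.
    """
    adjusted = habitat.values.copy()
    for layer in layers:
        if layer.intensity.shape != habitat.values.shape:
            raise ValueError("disturbance layer shape does not match habitat grid")
        adjusted *= 1.0 - layer.effective_factor()
    resistance = 1.0 - adjusted
    carrying = carrying_capacity(adjusted)
    return ResistanceSurface(resistance, carrying)


# ---------------------------------------------------------------------------
# Esri ASCII grid I/O (plain-text, bit-exact round trip via repr formatting)

def write_raster(grid, path) -> None:
    """Write a habitat grid (or any unit-interval grid) as an Esri ASCII raster."""
    values = grid.values if isinstance(grid, HabitatGrid) else np.asarray(grid, float)
    cell = grid.cell_size if isinstance(grid, HabitatGrid) else 1.0
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write("xllcorner 0.0\n")
        fh.write("yllcorner 0.0\n")
        fh.write(f"cellsize {cell!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_raster(path) -> HabitatGrid:
    """Read an Esri ASCII grid of habitat suitability values."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    if "ncols" not in header or "nrows" not in header:
        raise ValueError("missing Esri ASCII header")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid shape does not match header")
    if np.any(values < 0) or np.any(values > 1):
        raise ValueError("habitat values outside [0, 1]")
    return HabitatGrid(values, cell_size=header.get("cellsize", 1.0))
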