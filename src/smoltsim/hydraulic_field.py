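"""Raster river section: per-cell hydraulics and the flow geometry derived from it.

A river section is discretised into square cells (0.5 m median side in the
source CFD grids).  Each wet cell carries the four hydraulic predictors used
throughout the package:

``u``
    longitudinal velocity, m/s, positive downstream;
``v``
    transversal velocity, m/s, positive right-to-left bank;
``w``
    vertical velocity, m/s, positive upward (predictor only — the model is
    a single horizontal plane and no vertical movement is simulated);
``tke``
    turbulent kinetic energy, m²/s².

Dry or out-of-channel cells are explicitly *absent* (all four values NaN)
and are never navigable.

Heading convention
------------------
All headings in this package are mathematical "to" bearings: degrees
counter-clockwise from the +u (downstream) axis, in ``[0, 360)``.  The +v
axis therefore lies at 90°.  Tools that emit meteorological ("from")
directions must be converted before comparison.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

PREDICTOR_NAMES: tuple[str, str, str, str] = ("u", "v", "w", "tke")

FIELD_COLUMNS = ("x_index", "y_index", "u", "v", "w", "tke")


class ScenarioError(ValueError):
    """Raised for malformed field tables, metadata, or region masks."""


def wrap360(angle: float) -> float:
    """Normalise an angle to [0, 360); guards the `x % 360 == 360.0` float edge."""
    a = angle % 360.0
    return 0.0 if a >= 360.0 else a


class HydraulicCell(NamedTuple):
    """Hydraulic state of one raster cell (u, v, w in m/s; tke in m²/s²)."""

    u: float
    v: float
    w: float
    tke: float

    @property
    def is_absent(self) -> bool:
        return any(math.isnan(x) for x in self)


class ResultantFlow(NamedTuple):
    """Horizontal flow vector magnitude and bearing for one cell."""

    speed: float
    heading: float


@dataclass
class FlowScenario:
    """A raster river section with named region masks.

    Arrays are indexed ``(row, col)`` with ``col`` (the table's ``x_index``)
    increasing along +u and ``row`` (``y_index``) increasing along +v.
    Absent cells are NaN in all four hydraulic arrays.

    Parameters
    ----------
    u, v, w, tke
        2-D float arrays of identical shape.
    cell_size
        Cell side length in metres (> 0).
    discharge_q
        Scenario discharge in m³/s (metadata).
    bypass_fraction
        Fraction of discharge routed to the bypass, in [0, 1] (metadata).
    layer_index
        1-based index of the horizontal CFD plane this layer represents
        (plane 2 of 10, counted from the surface, is the conventional
        near-surface migration layer).
    regions
        Name → boolean mask of the grid shape.  ``"intake"`` and
        ``"exit_boundary"`` mark the two terminal regions used for fate
        accounting and must not overlap absent cells.
    """

    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    tke: np.ndarray
    cell_size: float = 0.5
    discharge_q: float | None = None
    bypass_fraction: float | None = None
    layer_index: int = 2
    regions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in (self.u, self.v, self.w, self.tke)]
        self.u, self.v, self.w, self.tke = arrays
        if self.u.ndim != 2 or self.u.size == 0:
            raise ScenarioError("grid must be a non-empty 2-D array")
        for a in arrays[1:]:
            if a.shape != self.u.shape:
                raise ScenarioError("u, v, w, tke arrays must share one shape")
        # a cell is absent iff *all* four values are NaN; partial NaN is invalid
        nan_counts = sum(np.isnan(a).astype(int) for a in arrays)
        if np.any((nan_counts > 0) & (nan_counts < 4)):
            raise ScenarioError("cells must be fully present or fully absent")
        if not self.active.any():
            raise ScenarioError("grid has no active cells")
        with np.errstate(invalid="ignore"):
            if np.any(self.tke < 0):
                raise ScenarioError("tke must be non-negative")
        if not self.cell_size > 0:
            raise ScenarioError("cell_size must be positive")
        if self.bypass_fraction is not None and not 0 <= self.bypass_fraction <= 1:
            raise ScenarioError("bypass_fraction must lie in [0, 1]")
        regions = {}
        for name, mask in self.regions.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.shape:
                raise ScenarioError(f"region {name!r} mask shape {mask.shape} != grid {self.shape}")
            regions[name] = mask
        self.regions = regions
        for name in ("intake", "exit_boundary"):
            mask = self.regions.get(name)
            if mask is not None and np.any(mask & ~self.active):
                raise ScenarioError(f"region {name!r} covers absent cells")

    # -- geometry ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of navigable (wet) cells."""
        return ~np.isnan(self.u)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())

    def in_grid(self, cell: tuple[int, int]) -> bool:
        r, c = cell
        return 0 <= r < self.shape[0] and 0 <= c < self.shape[1]

    def is_active(self, cell: tuple[int, int]) -> bool:
        return self.in_grid(cell) and bool(self.active[cell])

    def hydraulics(self, cell: tuple[int, int]) -> HydraulicCell:
        r, c = cell
        return HydraulicCell(
            float(self.u[r, c]), float(self.v[r, c]), float(self.w[r, c]), float(self.tke[r, c])
        )

    def cell_centre(self, cell: tuple[int, int]) -> tuple[float, float]:
        """Centre of a cell in metres; x along +u (columns), y along +v (rows)."""
        r, c = cell
        return ((c + 0.5) * self.cell_size, (r + 0.5) * self.cell_size)

    def point_to_cell(self, x: float, y: float) -> tuple[int, int] | None:
        """Map a metric position to its containing cell; None if outside or absent."""
        c = int(math.floor(x / self.cell_size))
        r = int(math.floor(y / self.cell_size))
        return (r, c) if self.is_active((r, c)) else None

    def in_region(self, cell: tuple[int, int], name: str) -> bool:
        mask = self.regions.get(name)
        return bool(mask is not None and self.in_grid(cell) and mask[cell])

    def predictor_frame(self) -> pd.DataFrame:
        """Active cells as a tidy frame (row, col, u, v, w, tke)."""
        rows, cols = np.nonzero(self.active)
        return pd.DataFrame(
            {
                "row": rows,
                "col": cols,
                "u": self.u[rows, cols],
                "v": self.v[rows, cols],
                "w": self.w[rows, cols],
                "tke": self.tke[rows, cols],
            }
        )


def resultant_flow(u: float, v: float) -> ResultantFlow:
    """Horizontal resultant of the (u, v) velocity pair.

    Speed is ``sqrt(u² + v²)``; the heading is the bearing of the vector
    (u, v) in degrees counter-clockwise from the +u axis, in [0, 360).
    A zero vector returns heading 0 by convention.
    """
    if not (math.isfinite(u) and math.isfinite(v)):
        raise ScenarioError("resultant_flow requires finite u, v")
    speed = math.hypot(u, v)
    if speed == 0.0:
        return ResultantFlow(0.0, 0.0)
    return ResultantFlow(speed, wrap360(math.degrees(math.atan2(v, u))))


def flow_heading(scenario: FlowScenario, cell: tuple[int, int]) -> float:
    """Bearing of the local resultant flow at ``cell`` (degrees, [0, 360))."""
    if not scenario.in_grid(cell):
        raise ScenarioError(f"cell {cell} outside grid {scenario.shape}")
    hyd = scenario.hydraulics(cell)
    if hyd.is_absent:
        raise ScenarioError(f"cell {cell} is dry/absent: not navigable water")
    return resultant_flow(hyd.u, hyd.v).heading


def flow_heading_grid(scenario: FlowScenario) -> np.ndarray:
    """Per-cell resultant-flow bearing; NaN on absent cells."""
    with np.errstate(invalid="ignore"):
        heading = np.degrees(np.arctan2(scenario.v, scenario.u)) % 360.0
        heading = np.where((scenario.u == 0) & (scenario.v == 0), 0.0, heading)
    heading[~scenario.active] = np.nan
    return heading


# -- I/O -------------------------------------------------------------------


def load_scenario(field_table_path: str | Path, metadata_path: str | Path) -> FlowScenario:
    """Read a scenario from a field-table CSV plus a metadata JSON.

    The table must have columns ``x_index, y_index, u, v, w, tke``; grid
    positions missing from the table become absent cells.  The metadata
    supplies ``cell_size_m``, ``discharge_q``, ``bypass_fraction``,
    ``layer_index`` and ``regions`` (name → list of ``[row, col]`` pairs).
    """
    table = pd.read_csv(field_table_path)
    missing = [c for c in FIELD_COLUMNS if c not in table.columns]
    if missing:
        raise ScenarioError(f"field table lacks columns: {missing}")
    if table.empty:
        raise ScenarioError("field table is empty")
    if table.duplicated(subset=["x_index", "y_index"]).any():
        raise ScenarioError("duplicate (x_index, y_index) pairs in field table")
    xi = table["x_index"].to_numpy(dtype=int)
    yi = table["y_index"].to_numpy(dtype=int)
    if xi.min() < 0 or yi.min() < 0:
        raise ScenarioError("negative cell indices in field table")
    n_rows, n_cols = yi.max() + 1, xi.max() + 1
    arrays = {}
    for name in PREDICTOR_NAMES:
        a = np.full((n_rows, n_cols), np.nan)
        a[yi, xi] = table[name].to_numpy(dtype=float)
        arrays[name] = a

    with open(metadata_path) as fh:
        meta = json.load(fh)
    regions = {}
    for name, cells in meta.get("regions", {}).items():
        mask = np.zeros((n_rows, n_cols), dtype=bool)
        for rc in cells:
            r, c = int(rc[0]), int(rc[1])
            if not (0 <= r < n_rows and 0 <= c < n_cols):
                raise ScenarioError(f"region {name!r} references out-of-range cell ({r}, {c})")
            mask[r, c] = True
        regions[name] = mask
    return FlowScenario(
        u=arrays["u"],
        v=arrays["v"],
        w=arrays["w"],
        tke=arrays["tke"],
        cell_size=float(meta.get("cell_size_m", 0.5)),
        discharge_q=meta.get("discharge_q"),
        bypass_fraction=meta.get("bypass_fraction"),
        layer_index=int(meta.get("layer_index", 2)),
        regions=regions,
    )


def write_scenario(
    scenario: FlowScenario, field_table_path: str | Path, metadata_path: str | Path
) -> None:
    """Write a scenario back to the CSV + JSON pair read by :func:`load_scenario`."""
    rows, cols = np.nonzero(scenario.active)
    table = pd.DataFrame(
        {
            "x_index": cols,
            "y_index": rows,
            "u": scenario.u[rows, cols],
            "v": scenario.v[rows, cols],
            "w": scenario.w[rows, cols],
            "tke": scenario.tke[rows, cols],
        }
    )
    table.to_csv(field_table_path, index=False)
    meta = {
        "cell_size_m": scenario.cell_size,
        "discharge_q": scenario.discharge_q,
        "bypass_fraction": scenario.bypass_fraction,
        "layer_index": scenario.layer_index,
        "regions": {
            name: [[int(r), int(c)] for r, c in zip(*np.nonzero(mask))]
            for name, mask in scenario.regions.items()
        },
    }
    with open(metadata_path, "w") as fh:
        json.dump(meta, fh, indent=1)


def region_mask_from_cells(
    shape: tuple[int, int], cells: Iterable[tuple[int, int]]
) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for r, c in cells:
        mask[r, c] = True
    return mask
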