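"""Synthetic multicolor lineage-tracing datasets.

Emulates the statistical structure of confocal images of mosaically labeled
tumors: a band of tissue between a leading tumor edge and a necrosis
border, sparse founder clones labeled with a finite palette of fluorescent
colors (distinct clones may collide on the same color), clones elongating
preferentially perpendicular to the edge with angular and lateral noise,
and irreversible loss of cells that cross into necrosis.

The generator produces cell tables in the schema the axis analysis
consumes; it does not render images. Growth is discrete placement of cells
along each clone's planted axis plus a per-cycle drift of all cells toward
necrosis (edge proliferation pushing older material centrally), which is
what makes whole-clone loss into necrosis possible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .tableio import CELL_TABLE_COLUMNS, read_cell_table, write_cell_table

__all__ = [
    "TumorGeometry",
    "LinearBand",
    "AnnularBand",
    "SyntheticConfig",
    "make_geometry",
    "seed_clones",
    "grow_clones",
    "export_dataset",
    "import_dataset",
]


class TumorGeometry:
    """Band of viable tumor tissue between the edge and the necrosis curve.

    Subclasses expose, for any planar point: the nearest point on each
    bounding curve, the normalized depth into the band (0 at the edge, 1 at
    necrosis), and the local edge tangent / inward normal unit vectors.
    """

    thickness: float

    def nearest_edge_point(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def nearest_necrosis_point(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def depth(self, p: np.ndarray) -> np.ndarray:
        """Normalized edge->necrosis coordinate; 0 on the edge, 1 at necrosis."""
        raise NotImplementedError

    def edge_tangent(self, p: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def inward_normal(self, p: np.ndarray) -> np.ndarray:
        """Unit vector pointing from the edge toward necrosis at p."""
        raise NotImplementedError

    def arclength(self, p: np.ndarray) -> np.ndarray:
        """Coordinate along the edge direction (for width measurements)."""
        raise NotImplementedError

    @property
    def circumference(self) -> float:
        raise NotImplementedError

    @property
    def area(self) -> float:
        raise NotImplementedError

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "TumorGeometry":
        kind = d.get("kind")
        if kind == "linear":
            return LinearBand(length=d["length"], thickness=d["thickness"])
        if kind == "annular":
            return AnnularBand(r_edge=d["r_edge"], r_necro=d["r_necro"])
        raise ValueError(f"unknown geometry kind {kind!r}")


@dataclass
class LinearBand(TumorGeometry):
    """Straight band: edge along y = 0, necrosis along y = thickness."""

    length: float = 1000.0
    thickness: float = 300.0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.thickness <= 0:
            raise ValueError("length and thickness must be positive")

    def nearest_edge_point(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        out = p.copy()
        out[:, 1] = 0.0
        return np.squeeze(out)

    def nearest_necrosis_point(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        out = p.copy()
        out[:, 1] = self.thickness
        return np.squeeze(out)

    def depth(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return np.squeeze(p[:, 1] / self.thickness)

    def edge_tangent(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return np.squeeze(np.tile([1.0, 0.0], (p.shape[0], 1)))

    def inward_normal(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return np.squeeze(np.tile([0.0, 1.0], (p.shape[0], 1)))

    def arclength(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return np.squeeze(p[:, 0])

    @property
    def circumference(self) -> float:
        return self.length

    @property
    def area(self) -> float:
        return self.length * self.thickness

    def sample_uniform(self, n, rng):
        x = rng.uniform(0.0, self.length, n)
        y = rng.uniform(0.0, self.thickness, n)
        return np.column_stack([x, y])

    def to_dict(self) -> dict:
        return {"kind": "linear", "length": self.length, "thickness": self.thickness}


@dataclass
class AnnularBand(TumorGeometry):
    """Annular band: edge = outer circle, necrosis = inner circle, center origin."""

    r_edge: float = 400.0
    r_necro: float = 150.0

    def __post_init__(self) -> None:
        if self.r_necro <= 0 or self.r_edge <= self.r_necro:
            raise ValueError("need 0 < r_necro < r_edge")

    @property
    def thickness(self) -> float:  # type: ignore[override]
        return self.r_edge - self.r_necro

    def _unit_radial(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        r = np.linalg.norm(p, axis=1, keepdims=True)
        if np.any(r == 0):
            raise ValueError("point at the annulus center has no radial direction")
        return p / r

    def nearest_edge_point(self, p):
        return np.squeeze(self._unit_radial(p) * self.r_edge)

    def nearest_necrosis_point(self, p):
        return np.squeeze(self._unit_radial(p) * self.r_necro)

    def depth(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        r = np.linalg.norm(p, axis=1)
        return np.squeeze((self.r_edge - r) / self.thickness)

    def edge_tangent(self, p):
        u = np.atleast_2d(self._unit_radial(p))
        return np.squeeze(np.column_stack([-u[:, 1], u[:, 0]]))

    def inward_normal(self, p):
        return np.squeeze(-np.atleast_2d(self._unit_radial(p)))

    def arclength(self, p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        theta = np.arctan2(p[:, 1], p[:, 0])
        return np.squeeze(theta * self.r_edge)

    @property
    def circumference(self) -> float:
        return 2.0 * math.pi * self.r_edge

    @property
    def area(self) -> float:
        return math.pi * (self.r_edge**2 - self.r_necro**2)

    def sample_uniform(self, n, rng):
        u = rng.uniform(0.0, 1.0, n)
        r = np.sqrt(u * (self.r_edge**2 - self.r_necro**2) + self.r_necro**2)
        theta = rng.uniform(0.0, 2.0 * math.pi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    def to_dict(self) -> dict:
        return {"kind": "annular", "r_edge": self.r_edge, "r_necro": self.r_necro}


def make_geometry(kind: str, **params) -> TumorGeometry:
    """Construct a tumor band geometry (``linear`` or ``annular``)."""
    if kind == "linear":
        return LinearBand(**params)
    if kind == "annular":
        return AnnularBand(**params)
    raise ValueError(f"unknown geometry kind {kind!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic lineage-tracing generator.

    Defaults emulate the study conditions: sparse mosaic induction yielding
    founder clones of 1-3 cells, a 10-color effective palette (few base
    fluorophores plus mixed colors), clone axes centered on 90 degrees to
    the edge tangent (perpendicular outgrowth toward necrosis) with modest
    angular jitter, cell spacing ~10 um, and a hard loss rule at the
    necrosis curve.
    """

    n_founders: int = 200
    labeling_fraction: float = 0.05
    palette: int = 10
    axis_mean_deg: float = 90.0
    axis_jitter_sd_deg: float = 5.0
    lateral_jitter: float = 2.0  # s.d. of perpendicular cell scatter, coord units
    cell_spacing: float = 10.0  # spacing of successive cells along the axis
    founder_size_min: int = 1
    founder_size_max: int = 3
    cells_per_cycle: int = 1
    drift_per_cycle: float = 5.0  # centripetal displacement of all cells per cycle
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")
        if not 0.0 < self.labeling_fraction <= 1.0:
            raise ValueError("labeling_fraction must be in (0, 1]")
        if self.palette < 1:
            raise ValueError("palette must be >= 1")
        if self.axis_jitter_sd_deg < 0 or self.lateral_jitter < 0:
            raise ValueError("jitter parameters must be >= 0")
        if self.cell_spacing <= 0:
            raise ValueError("cell_spacing must be positive")
        if not 1 <= self.founder_size_min <= self.founder_size_max:
            raise ValueError("need 1 <= founder_size_min <= founder_size_max")
        if self.cells_per_cycle < 1 or self.drift_per_cycle < 0:
            raise ValueError("invalid growth parameters")


def _axis_direction(geometry: TumorGeometry, p: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit growth direction at angle_deg from the local edge tangent, toward necrosis."""
    t = np.asarray(geometry.edge_tangent(p), dtype=float)
    n = np.asarray(geometry.inward_normal(p), dtype=float)
    a = math.radians(angle_deg)
    return math.cos(a) * t + math.sin(a) * n


def _anchor_points(geometry: TumorGeometry, cells: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-clone anchors: E = edge point nearest the clone; N = necrosis point
    nearest E (the local edge->necrosis normal through E)."""
    depths = np.atleast_1d(geometry.depth(cells))
    basal = cells[int(np.argmin(depths))]
    e = np.asarray(geometry.nearest_edge_point(basal), dtype=float)
    n = np.asarray(geometry.nearest_necrosis_point(e), dtype=float)
    return e, n


def _table_from_cells(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS + ["axis_deg"])
    return df


def seed_clones(
    geometry: TumorGeometry,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Cell table at the induction timepoint (timepoint 0).

    Founders are placed uniformly in the band; each founder clone gets a
    color drawn uniformly from the finite palette (so distinct clones can
    share colors, as with a limited set of fluorophores), a planted axis
    angle drawn from N(axis_mean, axis_jitter_sd), and 1-3 cells laid out
    along that axis. The planted angle is carried in the extra column
    ``axis_deg`` (generator ground truth; the analysis ignores it).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    founders = geometry.sample_uniform(config.n_founders, rng)
    colors = rng.integers(0, config.palette, config.n_founders)
    sizes = rng.integers(config.founder_size_min, config.founder_size_max + 1, config.n_founders)
    angles = config.axis_mean_deg + rng.normal(0.0, config.axis_jitter_sd_deg, config.n_founders)
    rows: list[dict] = []
    for cid in range(config.n_founders):
        base = founders[cid]
        u = _axis_direction(geometry, base, angles[cid])
        perp = np.array([-u[1], u[0]])
        cells = []
        for j in range(int(sizes[cid])):
            offset = rng.normal(0.0, config.lateral_jitter) if config.lateral_jitter > 0 else 0.0
            cells.append(base + j * config.cell_spacing * u + offset * perp)
        cells = np.array(cells)
        depths = np.atleast_1d(geometry.depth(cells))
        cells = cells[(depths >= 0.0) & (depths <= 1.0)]
        if cells.shape[0] == 0:
            continue
        e, n = _anchor_points(geometry, cells)
        for c in cells:
            rows.append(
                {
                    "clone_id": cid,
                    "color": int(colors[cid]),
                    "timepoint": 0,
                    "x": c[0],
                    "y": c[1],
                    "edge_x": e[0],
                    "edge_y": e[1],
                    "necro_x": n[0],
                    "necro_y": n[1],
                    "axis_deg": float(angles[cid]),
                }
            )
    return _table_from_cells(rows)


def grow_clones(
    table: pd.DataFrame,
    geometry: TumorGeometry,
    cycles: int,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Advance a cell table by ``cycles`` growth cycles.

    Per cycle every existing cell drifts ``drift_per_cycle`` along the local
    inward normal (older material is pushed toward the center as the edge
    proliferates) and each clone appends ``cells_per_cycle`` cells at its
    tip, continuing along its planted axis with lateral jitter. Cells
    crossing the necrosis curve are removed; a clone whose cells are all
    removed is lost. Per-clone E and N are recomputed from the final
    positions. Labels are heritable and never re-induced, so the clone set
    can only shrink.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    out_tp = (int(table["timepoint"].max()) if len(table) else 0) + cycles
    rows: list[dict] = []
    for clone_id, grp in table.groupby("clone_id", sort=True):
        cells = grp[["x", "y"]].to_numpy(dtype=float)
        angle = float(grp["axis_deg"].iloc[0]) if "axis_deg" in grp else config.axis_mean_deg
        color = grp["color"].iloc[0]
        for _ in range(cycles):
            # centripetal drift of all existing cells
            if config.drift_per_cycle > 0 and cells.shape[0] > 0:
                normals = np.atleast_2d(geometry.inward_normal(cells))
                cells = cells + config.drift_per_cycle * normals
            if cells.shape[0] == 0:
                break
            # tip extension along the planted axis
            depths = np.atleast_1d(geometry.depth(cells))
            tip = cells[int(np.argmax(depths))]
            u = _axis_direction(geometry, tip, angle)
            perp = np.array([-u[1], u[0]])
            new_cells = []
            for j in range(1, config.cells_per_cycle + 1):
                offset = rng.normal(0.0, config.lateral_jitter) if config.lateral_jitter > 0 else 0.0
                new_cells.append(tip + j * config.cell_spacing * u + offset * perp)
            cells = np.vstack([cells, np.array(new_cells)])
            # hard loss at the necrosis curve (and outside the edge)
            depths = np.atleast_1d(geometry.depth(cells))
            cells = cells[(depths >= 0.0) & (depths <= 1.0)]
        if cells.shape[0] == 0:
            continue  # clone lost into necrosis
        e, n = _anchor_points(geometry, cells)
        for c in cells:
            rows.append(
                {
                    "clone_id": clone_id,
                    "color": color,
                    "timepoint": out_tp,
                    "x": c[0],
                    "y": c[1],
                    "edge_x": e[0],
                    "edge_y": e[1],
                    "necro_x": n[0],
                    "necro_y": n[1],
                    "axis_deg": angle,
                }
            )
    return _table_from_cells(rows)


def export_dataset(tables: list[pd.DataFrame] | pd.DataFrame, geometry: TumorGeometry, path) -> None:
    """Write a dataset directory: ``cells.csv`` plus ``geometry.json``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if isinstance(tables, pd.DataFrame):
        table = tables
    else:
        table = pd.concat(list(tables), ignore_index=True) if tables else _table_from_cells([])
    write_cell_table(table, path / "cells.csv")
    (path / "geometry.json").write_text(json.dumps(geometry.to_dict(), indent=2))


def import_dataset(path) -> tuple[pd.DataFrame, TumorGeometry]:
    """Read a dataset directory written by :func:`export_dataset`."""
    path = Path(path)
    table = read_cell_table(path / "cells.csv")
    geometry = TumorGeometry.from_dict(json.loads((path / "geometry.json").read_text()))
    return table, geometry
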