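"""Clone size and clone density statistics over time.

Mirrors the quantification used for the lineage-tracing time courses: mean
clone size (cells per clone) with s.e.m. per timepoint, clones per unit
area overall and in thirds of the edge->necrosis span, a two-sided
two-sample t-test comparing edge vs center densities across replicate
tumors, and the lateral width of edge-contacting clones normalized by the
tumor circumference.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lattice import LatticeState, _edge_run_lengths
from .synthetic import TumorGeometry

__all__ = [
    "RegionPartition",
    "REGIONS",
    "clone_sizes_over_time",
    "clone_density",
    "compare_regions",
    "edge_clone_width",
    "edge_width_from_grid",
]

REGIONS = ("edge", "middle", "center")


@dataclass
class RegionPartition:
    """Thirds of the tumor band along the normalized edge->necrosis depth.

    Depth in [0, 1/3) is the edge third, [1/3, 2/3) the middle, [2/3, 1]
    the center third. Region areas come from the geometry (exact annulus
    areas for annular bands, equal thirds for linear bands).
    """

    geometry: TumorGeometry

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Region label per point ('edge' / 'middle' / 'center')."""
        depth = np.atleast_1d(self.geometry.depth(np.atleast_2d(points)))
        if np.any((depth < -1e-9) | (depth > 1 + 1e-9)):
            raise ValueError("point(s) outside the tumor band")
        idx = np.minimum((np.clip(depth, 0.0, 1.0) * 3).astype(int), 2)
        return np.asarray(REGIONS, dtype=object)[idx]

    def areas(self) -> dict[str, float]:
        geom = self.geometry
        # annular thirds have unequal areas; compute from the band radii
        if hasattr(geom, "r_edge") and hasattr(geom, "r_necro"):
            t = geom.thickness / 3.0
            r0, r1, r2, r3 = (
                geom.r_edge,
                geom.r_edge - t,
                geom.r_edge - 2 * t,
                geom.r_necro,
            )
            ring = lambda a, b: math.pi * (a**2 - b**2)
            out = {"edge": ring(r0, r1), "middle": ring(r1, r2), "center": ring(r2, r3)}
        else:
            out = {r: geom.area / 3.0 for r in REGIONS}
        if any(a <= 0 for a in out.values()):
            raise ValueError("region areas must be positive")
        return out


def clone_sizes_over_time(table: pd.DataFrame) -> pd.DataFrame:
    """Mean clone size with s.e.m. per timepoint.

    Clone size is the number of cells sharing a clone id within one tumor
    or replicate (column ``tumor_id`` if present, else the whole table per
    timepoint); sizes are then pooled across tumors. A timepoint with a
    single clone reports s.e.m. NaN and is flagged.
    """
    if len(table) == 0:
        warnings.warn("empty cell table: no timepoints to summarize", stacklevel=2)
        return pd.DataFrame(columns=["timepoint", "n_clones", "mean_size", "sem_size", "flag"])
    group_cols = ["timepoint", "clone_id"]
    if "tumor_id" in table.columns:
        group_cols.insert(1, "tumor_id")
    sizes = table.groupby(group_cols, sort=True).size().rename("size").reset_index()
    rows = []
    for tp, grp in sizes.groupby("timepoint", sort=True):
        vals = grp["size"].to_numpy(dtype=float)
        sem = float(stats.sem(vals)) if vals.size > 1 else math.nan
        rows.append(
            {
                "timepoint": tp,
                "n_clones": int(vals.size),
                "mean_size": float(vals.mean()),
                "sem_size": sem,
                "flag": "" if vals.size > 1 else "single_observation",
            }
        )
    return pd.DataFrame(rows)


def clone_density(table: pd.DataFrame, partition: RegionPartition) -> pd.DataFrame:
    """Clones per unit area, per region and overall.

    A clone counts in a region if at least one of its cells lies there; a
    clone spanning several regions therefore contributes to each. Grouping
    columns ``timepoint`` and (if present) ``tumor_id`` are respected.
    """
    areas = partition.areas()
    total_area = partition.geometry.area
    work = table.copy()
    work["region"] = partition.assign(work[["x", "y"]].to_numpy(dtype=float))
    group_cols = ["timepoint"] + (["tumor_id"] if "tumor_id" in work.columns else [])
    rows = []
    for keys, grp in work.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        base = dict(zip(group_cols, keys))
        for region in REGIONS:
            count = grp.loc[grp["region"] == region, "clone_id"].nunique()
            rows.append(
                base
                | {
                    "region": region,
                    "clone_count": int(count),
                    "area": areas[region],
                    "density": count / areas[region],
                }
            )
        overall = grp["clone_id"].nunique()
        rows.append(
            base
            | {
                "region": "overall",
                "clone_count": int(overall),
                "area": total_area,
                "density": overall / total_area,
            }
        )
    return pd.DataFrame(rows)


def compare_regions(edge: np.ndarray | list, center: np.ndarray | list) -> dict:
    """Two-sided two-sample t-test on per-tumor densities (edge vs center).

    With fewer than 2 replicates in a group no test is possible and the
    result is flagged. Zero-variance groups are resolved to the closed-form
    limits of the pooled t statistic: equal means give t = 0, p = 1;
    different means give t = +/-inf, p = 0.
    """
    edge = np.asarray(edge, dtype=float)
    center = np.asarray(center, dtype=float)
    if edge.size < 2 or center.size < 2:
        return {
            "t": math.nan,
            "p_value": math.nan,
            "df": math.nan,
            "flag": "too_few_replicates",
        }
    df = edge.size + center.size - 2
    if edge.var(ddof=1) == 0.0 and center.var(ddof=1) == 0.0:
        if edge.mean() == center.mean():
            return {"t": 0.0, "p_value": 1.0, "df": df, "flag": "zero_variance"}
        t = math.inf if edge.mean() > center.mean() else -math.inf
        return {"t": t, "p_value": 0.0, "df": df, "flag": "zero_variance"}
    res = stats.ttest_ind(edge, center, equal_var=True)
    return {"t": float(res.statistic), "p_value": float(res.pvalue), "df": df, "flag": ""}


def edge_clone_width(
    table: pd.DataFrame,
    geometry: TumorGeometry,
    band_width: float | None = None,
    cell_spacing: float | None = None,
) -> pd.DataFrame:
    """Lateral width of edge-contacting clones, absolute and circumference-adjusted.

    Cells within ``band_width`` of the edge curve (default: one cell
    spacing) form the edge band. A clone's width is the extent of its
    edge-band cells along the edge (arclength) direction plus one cell
    spacing (so a single edge cell has width one spacing, and contiguous
    cells tiling the whole edge sum to the full circumference). Adjusted
    width divides by the circumference: the fraction of the edge the clone
    occupies.
    """
    if cell_spacing is None:
        cell_spacing = 1.0
    if band_width is None:
        band_width = cell_spacing
    pts = table[["x", "y"]].to_numpy(dtype=float)
    depth = np.atleast_1d(geometry.depth(np.atleast_2d(pts)))
    dist_to_edge = depth * geometry.thickness
    in_band = dist_to_edge <= band_width
    if not in_band.any():
        warnings.warn("no clones touch the edge band", stacklevel=2)
        return pd.DataFrame(columns=["clone_id", "n_edge_cells", "width", "adjusted_width"])
    sub = table.loc[in_band].copy()
    sub["arclength"] = np.atleast_1d(
        geometry.arclength(sub[["x", "y"]].to_numpy(dtype=float))
    )
    circumference = geometry.circumference
    rows = []
    for clone_id, grp in sub.groupby("clone_id", sort=True):
        s = grp["arclength"].to_numpy(dtype=float)
        width = float(np.ptp(s)) + cell_spacing
        rows.append(
            {
                "clone_id": clone_id,
                "n_edge_cells": int(s.size),
                "width": width,
                "adjusted_width": width / circumference,
            }
        )
    return pd.DataFrame(rows)


def edge_width_from_grid(state: LatticeState) -> float:
    """Mean contiguous bottom-row width (in cells) of edge-contacting clones."""
    return float(_edge_run_lengths(state.grid[0]).mean())
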