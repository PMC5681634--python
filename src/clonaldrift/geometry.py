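"""Clonal-axis analysis of labeled cell positions.

Each clone is a set of cell coordinates together with its nearest point E on
the leading tumor edge and nearest point N on the necrosis border. A rigid
transform (translation + rotation) moves E to the origin and rotates the
E->N direction onto the diagonal x' = y' of the first quadrant, so the local
edge->necrosis axis sits at +45 degrees. An ordinary least-squares line is
then fitted through the transformed cells; with slope m, the axis angle is

    theta = atan(m)            (angle of the fitted line with the x'-axis)
    alpha = theta + 45 deg     (angle relative to the edge tangent)

so a clone growing straight from edge to necrosis has alpha = 90 deg and a
clone lying along the edge has alpha = 0 deg. The 45-degree convention keeps
edge-perpendicular clones (the common case) far from the vertical-slope
singularity of y-on-x regression. Significance of linear alignment is the
two-sided t-test of the correlation coefficient with n - 2 degrees of
freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CloneRecord",
    "TransformedClone",
    "ClonalAxis",
    "DegenerateGeometryError",
    "transform_clone",
    "fit_axis",
    "axis_angle",
    "axis_summary",
    "analyze_cell_table",
]

#: below this relative tolerance of x-variance a fit is treated as vertical
_VAR_TOL = 1e-12
#: 1 - r^2 below this is treated as perfect collinearity
_COLLINEAR_TOL = 1e-12


class DegenerateGeometryError(ValueError):
    """Raised when a clone's edge and necrosis points coincide."""


@dataclass
class CloneRecord:
    """One clone: labeled cell positions plus its edge/necrosis anchor points."""

    clone_id: object
    cells: np.ndarray  # (n, 2) float array of (x, y)
    edge_point: np.ndarray  # E, nearest point on the leading tumor edge
    necro_point: np.ndarray  # N, nearest point on the necrosis border
    color: object = None
    timepoint: object = None

    def __post_init__(self) -> None:
        self.cells = np.atleast_2d(np.asarray(self.cells, dtype=float))
        self.edge_point = np.asarray(self.edge_point, dtype=float)
        self.necro_point = np.asarray(self.necro_point, dtype=float)
        if self.cells.shape[0] < 1 or self.cells.shape[1] != 2:
            raise ValueError("cells must be a non-empty (n, 2) array")

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


@dataclass
class TransformedClone:
    """Clone after the rigid E->origin, E->N -> +45 deg transform."""

    clone_id: object
    cells: np.ndarray  # transformed positions C'
    necro_point: np.ndarray  # N', lies on x' = y' in the first quadrant
    color: object = None
    timepoint: object = None

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]


@dataclass
class ClonalAxis:
    """Fitted clonal axis of one clone."""

    clone_id: object
    n_cells: int
    slope: float
    intercept: float
    p_value: float
    theta_deg: float
    alpha_deg: float
    flag: str = ""
    color: object = None
    timepoint: object = None


def transform_clone(clone: CloneRecord) -> TransformedClone:
    """Rigidly move a clone into the canonical edge/necrosis frame.

    Translates by -E, then rotates so the E->N direction maps onto the
    +45 degree diagonal with N' in the first quadrant (x_N' = y_N' > 0).
    Pairwise distances are preserved exactly (up to floating point).
    """
    v = clone.necro_point - clone.edge_point
    d = float(np.hypot(v[0], v[1]))
    if d == 0.0:
        raise DegenerateGeometryError(
            f"clone {clone.clone_id!r}: edge point equals necrosis point"
        )
    phi = math.pi / 4.0 - math.atan2(v[1], v[0])
    c, s = math.cos(phi), math.sin(phi)
    rot = np.array([[c, -s], [s, c]])
    cells_t = (clone.cells - clone.edge_point) @ rot.T
    necro_t = rot @ v
    return TransformedClone(
        clone_id=clone.clone_id,
        cells=cells_t,
        necro_point=necro_t,
        color=clone.color,
        timepoint=clone.timepoint,
    )


def fit_axis(tc: TransformedClone, min_cells: int = 3) -> ClonalAxis:
    """Least-squares clonal axis through the transformed cell positions.

    Fits y' on x'; the p-value is the two-sided t-test of the linear
    correlation with n - 2 degrees of freedom. Degenerate cases are flagged
    rather than fatal: a vertical point cloud (zero x-variance) is reported
    as theta = 90, alpha = 135 with undefined p; exact collinearity is
    reported with the limiting p = 0.
    """
    n = tc.n_cells
    if n < min_cells:
        raise ValueError(
            f"clone {tc.clone_id!r}: {n} cells < min_cells={min_cells}"
        )
    x = tc.cells[:, 0]
    y = tc.cells[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    syy = float(np.sum((y - y.mean()) ** 2))
    scale = max(sxx, syy, 1.0)
    if sxx / scale < _VAR_TOL:
        return _finish(tc, math.inf, math.nan, math.nan, theta=90.0, flag="vertical")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    if syy / scale < _VAR_TOL:
        # all cells on a horizontal line: slope 0, correlation undefined
        return _finish(tc, 0.0, intercept, math.nan, flag="zero_y_variance")
    r2 = sxy * sxy / (sxx * syy)
    if 1.0 - r2 < _COLLINEAR_TOL:
        return _finish(tc, slope, intercept, 0.0, flag="collinear")
    res = stats.linregress(x, y)
    return _finish(tc, float(res.slope), float(res.intercept), float(res.pvalue))


def _finish(
    tc: TransformedClone,
    slope: float,
    intercept: float,
    p_value: float,
    theta: float | None = None,
    flag: str = "",
) -> ClonalAxis:
    if theta is None:
        theta = math.degrees(math.atan(slope))
    return ClonalAxis(
        clone_id=tc.clone_id,
        n_cells=tc.n_cells,
        slope=slope,
        intercept=intercept,
        p_value=p_value,
        theta_deg=theta,
        alpha_deg=theta + 45.0,
        flag=flag,
        color=tc.color,
        timepoint=tc.timepoint,
    )


def axis_angle(axis: ClonalAxis) -> float:
    """Angle alpha of the clonal axis relative to the edge tangent, degrees."""
    return axis.alpha_deg


def axis_summary(axes: list[ClonalAxis]) -> pd.DataFrame:
    """One row per fitted clone: id, n_cells, slope, p, theta, alpha, flag."""
    cols = [
        "clone_id",
        "color",
        "timepoint",
        "n_cells",
        "slope",
        "intercept",
        "p_value",
        "theta_deg",
        "alpha_deg",
        "flag",
    ]
    if not axes:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([{c: getattr(a, c) for c in cols} for a in axes])


def summarize_angles(axes_table: pd.DataFrame) -> dict:
    """Summary statistics of the fitted axis angles."""
    alpha = axes_table["alpha_deg"].to_numpy(dtype=float)
    alpha = alpha[np.isfinite(alpha)]
    if alpha.size == 0:
        return {"n_clones": 0, "median_alpha_deg": math.nan, "iqr_alpha_deg": math.nan}
    q1, med, q3 = np.percentile(alpha, [25, 50, 75])
    return {
        "n_clones": int(alpha.size),
        "median_alpha_deg": float(med),
        "iqr_alpha_deg": float(q3 - q1),
    }


def clone_records_from_table(table: pd.DataFrame) -> list[CloneRecord]:
    """Group a cell table into CloneRecords (one per distinct clone_id)."""
    records = []
    for clone_id, grp in table.groupby("clone_id", sort=True):
        first = grp.iloc[0]
        records.append(
            CloneRecord(
                clone_id=clone_id,
                cells=grp[["x", "y"]].to_numpy(dtype=float),
                edge_point=np.array([first["edge_x"], first["edge_y"]], dtype=float),
                necro_point=np.array([first["necro_x"], first["necro_y"]], dtype=float),
                color=first.get("color"),
                timepoint=first.get("timepoint"),
            )
        )
    return records


def analyze_cell_table(table: pd.DataFrame, min_cells: int = 3) -> pd.DataFrame:
    """Full pipeline: transform each clone, fit its axis, tabulate.

    Clones with fewer than ``min_cells`` cells (default 3, the smallest n
    giving a one-degree-of-freedom regression) are listed with NaN axis
    fields and flag ``too_few_cells``; degenerate geometry (E = N) is
    flagged ``degenerate_geometry``. Analysis never fails on such clones.
    """
    rows = []
    for clone in clone_records_from_table(table):
        base = {
            "clone_id": clone.clone_id,
            "color": clone.color,
            "timepoint": clone.timepoint,
            "n_cells": clone.n_cells,
        }
        if clone.n_cells < min_cells:
            rows.append(
                base
                | {
                    "slope": math.nan,
                    "intercept": math.nan,
                    "p_value": math.nan,
                    "theta_deg": math.nan,
                    "alpha_deg": math.nan,
                    "flag": "too_few_cells",
                }
            )
            continue
        try:
            tc = transform_clone(clone)
        except DegenerateGeometryError:
            rows.append(
                base
                | {
                    "slope": math.nan,
                    "intercept": math.nan,
                    "p_value": math.nan,
                    "theta_deg": math.nan,
                    "alpha_deg": math.nan,
                    "flag": "degenerate_geometry",
                }
            )
            continue
        axis = fit_axis(tc, min_cells=min_cells)
        rows.append(
            base
            | {
                "slope": axis.slope,
                "intercept": axis.intercept,
                "p_value": axis.p_value,
                "theta_deg": axis.theta_deg,
                "alpha_deg": axis.alpha_deg,
                "flag": axis.flag,
            }
        )
    cols = [
        "clone_id",
        "color",
        "timepoint",
        "n_cells",
        "slope",
        "intercept",
        "p_value",
        "theta_deg",
        "alpha_deg",
        "flag",
    ]
    return pd.DataFrame(rows, columns=cols)
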