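"""Two-dimensional lattice model of neutral clonal competition in a tumor band.

The model represents a cross-section of tumor tissue between the leading
tumor edge (bottom row of the grid) and central tumor necrosis (top row).
Each lattice site holds an integer clone identifier. During one replication
cycle:

* every bottom-row cell divides exactly once, expanding up, left or right
  with configurable probabilities (equal by default) — lateral expansion is
  the mechanism of clonal competition at the edge;
* every other non-top cell divides upward at a reduced rate, either with
  probability ``p_central`` per cycle (default 0.5) or deterministically in
  every ``n_period``-th row;
* a division copies the divider's identifier into the target site and shifts
  the displaced column contents up by one; whatever occupied the top row is
  lost — this simulates irreversible loss of cells into necrosis.

Clones are identified by label, not spatial connectivity. The dynamics are
neutral (no fitness differences), so clone survival is determined purely by
position: clones that lose contact with the edge drift centrally and are
eventually lost, driving the population toward oligoclonality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "LatticeState",
    "SimTrajectory",
    "EnsembleSummary",
    "BoundaryError",
    "init_grid",
    "divide_cell",
    "step_cycle",
    "run_simulation",
    "ensemble_summary",
    "clone_stats_by_region",
    "render_color_grid",
    "harvest_clones",
]

Direction = Literal["up", "left", "right"]


class BoundaryError(ValueError):
    """A lateral division targeted a site outside the grid."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the lattice simulation.

    Defaults reproduce the published setup: a 60x60 grid run for 30
    replication cycles, equal edge expansion probabilities, central
    upward-division probability 0.5, and 100-replicate ensembles.
    """

    width: int = 60
    height: int = 60
    cycles: int = 30
    p_up: float = 1.0 / 3.0
    p_left: float = 1.0 / 3.0
    p_right: float = 1.0 / 3.0
    p_central: float = 0.5
    central_variant: Literal["probabilistic", "every_nth_row"] = "probabilistic"
    n_period: int = 2
    replicates: int = 100
    seed: int = 0
    palette_size: int = 10
    boundary: Literal["reflect", "periodic"] = "reflect"

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError(f"width must be >= 1, got {self.width}")
        if self.height < 2:
            raise ValueError(f"height must be >= 2, got {self.height}")
        if self.cycles < 0:
            raise ValueError(f"cycles must be >= 0, got {self.cycles}")
        probs = (self.p_up, self.p_left, self.p_right)
        if any(p < 0 for p in probs):
            raise ValueError("edge direction probabilities must be >= 0")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(
                f"edge direction probabilities must sum to 1, got {sum(probs)}"
            )
        if not 0.0 <= self.p_central <= 1.0:
            raise ValueError(f"p_central must be in [0, 1], got {self.p_central}")
        if self.central_variant not in ("probabilistic", "every_nth_row"):
            raise ValueError(f"unknown central_variant {self.central_variant!r}")
        if self.n_period < 1:
            raise ValueError(f"n_period must be >= 1, got {self.n_period}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.palette_size < 1:
            raise ValueError(f"palette_size must be >= 1, got {self.palette_size}")
        if self.boundary not in ("reflect", "periodic"):
            raise ValueError(f"unknown boundary {self.boundary!r}")


@dataclass
class LatticeState:
    """Grid of clone identifiers.

    ``grid[row, col]`` with row 0 = bottom = leading tumor edge and
    row ``height - 1`` = top = border to central necrosis.
    """

    grid: np.ndarray
    cycle: int = 0

    @property
    def height(self) -> int:
        return self.grid.shape[0]

    @property
    def width(self) -> int:
        return self.grid.shape[1]

    def copy(self) -> "LatticeState":
        return LatticeState(grid=self.grid.copy(), cycle=self.cycle)

    def clone_ids(self) -> np.ndarray:
        return np.unique(self.grid)

    def clone_sizes(self) -> np.ndarray:
        """Sizes of all distinct clones, ordered by identifier."""
        return np.unique(self.grid, return_counts=True)[1]

    @property
    def clone_count(self) -> int:
        return int(np.unique(self.grid).size)


def init_grid(config: SimConfig, rng: np.random.Generator | None = None) -> LatticeState:
    """Seed a fresh grid: identifiers 1..W*H, each exactly once, shuffled.

    Every site starts as its own single-cell clone, mirroring maximal
    polyclonality at the moment of label induction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.width * config.height
    ids = rng.permutation(np.arange(1, n + 1, dtype=np.int32))
    grid = ids.reshape(config.height, config.width)
    return LatticeState(grid=grid, cycle=0)


def _shift_column_up(grid: np.ndarray, col: int, from_row: int) -> None:
    # contents at from_row..top-1 move up one; old top row content discarded
    grid[from_row + 1 :, col] = grid[from_row:-1, col]


def _divide_inplace(
    grid: np.ndarray, col: int, row: int, direction: Direction, boundary: str
) -> None:
    height, width = grid.shape
    if direction == "up":
        if row == height - 1:
            # the copy would land in necrosis immediately; nothing changes
            return
        _shift_column_up(grid, col, row + 1)
        grid[row + 1, col] = grid[row, col]
        return
    step = -1 if direction == "left" else 1
    target = col + step
    if target < 0 or target >= width:
        if boundary == "periodic":
            target %= width
        else:
            raise BoundaryError(
                f"lateral division from column {col} direction {direction!r} "
                f"leaves a width-{width} grid"
            )
    _shift_column_up(grid, target, row)
    grid[row, target] = grid[row, col]


def divide_cell(
    state: LatticeState,
    col: int,
    row: int,
    direction: Direction,
    boundary: str = "reflect",
) -> LatticeState:
    """Apply one cell division and return the resulting state.

    The divider's identifier is copied into the target site; the target's
    previous content and everything above it in that column shift up one
    row, and the former top-row content is discarded (loss into necrosis).
    Total cell count is unchanged.
    """
    if not (0 <= row < state.height and 0 <= col < state.width):
        raise IndexError(f"cell ({col}, {row}) outside {state.width}x{state.height} grid")
    new = state.copy()
    _divide_inplace(new.grid, col, row, direction, boundary)
    return new


def _edge_division_order(rng: np.random.Generator, width: int) -> np.ndarray:
    return rng.permutation(width)


def step_cycle(
    state: LatticeState, config: SimConfig, rng: np.random.Generator
) -> LatticeState:
    """Advance the lattice by one replication cycle.

    Non-edge divisions are processed first, top row downward, so that a cell
    copied upward within the cycle does not divide again. Bottom-row cells
    then each divide once, in a seeded random column order, with direction
    drawn from the configured probabilities; at a lateral wall the
    probabilities renormalize over the available directions (reflecting
    boundary) or the target wraps (periodic).
    """
    new = state.copy()
    grid = new.grid
    height, width = grid.shape

    # central divisions: rows height-2 .. 1 (top row abuts necrosis, never divides)
    if config.central_variant == "probabilistic":
        for r in range(height - 2, 0, -1):
            mask = rng.random(width) < config.p_central
            if mask.any():
                grid[r + 2 :, mask] = grid[r + 1 : -1, mask]
                grid[r + 1, mask] = grid[r, mask]
    else:  # every_nth_row: eligibility alternates with cycle parity
        for r in range(height - 2, 0, -1):
            if r % config.n_period == state.cycle % config.n_period:
                grid[r + 2 :, :] = grid[r + 1 : -1, :]
                grid[r + 1, :] = grid[r, :]

    # edge divisions: every bottom-row cell divides exactly once
    p_up, p_left, p_right = config.p_up, config.p_left, config.p_right
    for col in _edge_division_order(rng, width):
        if config.boundary == "reflect":
            w_l = p_left if col > 0 else 0.0
            w_r = p_right if col < width - 1 else 0.0
        else:
            w_l, w_r = p_left, p_right
        total = p_up + w_l + w_r
        if total <= 0.0:
            continue  # no admissible direction (e.g. p_up=0 in a single column)
        u = rng.random() * total
        if u < p_up:
            direction: Direction = "up"
        elif u < p_up + w_l:
            direction = "left"
        else:
            direction = "right"
        _divide_inplace(grid, int(col), 0, direction, config.boundary)

    new.cycle = state.cycle + 1
    return new


def _thirds_bounds(height: int) -> tuple[int, int]:
    """Row index bounds splitting the grid into edge/middle/center thirds.

    Returns (edge_end, center_start): edge third = rows [0, edge_end),
    center third = rows [center_start, height). When the height is not
    divisible by 3 the extra rows go to the middle third, keeping the edge
    and center thirds symmetric.
    """
    q = height // 3
    return q, height - q


def clone_stats_by_region(state: LatticeState) -> dict:
    """Clone counts and sizes, overall and within edge/middle/center thirds.

    A clone is counted in a third if at least one of its cells lies there
    (distinct identifiers, not connected components).
    """
    grid = state.grid
    edge_end, center_start = _thirds_bounds(state.height)
    sizes = state.clone_sizes()
    return {
        "clones_total": int(np.unique(grid).size),
        "clones_edge_third": int(np.unique(grid[:edge_end]).size),
        "clones_mid_third": int(np.unique(grid[edge_end:center_start]).size),
        "clones_center_third": int(np.unique(grid[center_start:]).size),
        "mean_clone_size": float(sizes.mean()),
        "clone_sizes": sizes,
    }


def _edge_run_lengths(bottom_row: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of identical identifiers along the bottom row."""
    if bottom_row.size == 0:
        return np.array([], dtype=int)
    breaks = np.flatnonzero(np.diff(bottom_row) != 0)
    edges = np.concatenate(([0], breaks + 1, [bottom_row.size]))
    return np.diff(edges)


@dataclass
class SimTrajectory:
    """Per-cycle statistics of one simulation run."""

    config: SimConfig
    records: list[dict] = field(default_factory=list)
    snapshots: list[np.ndarray] = field(default_factory=list)
    final_state: LatticeState | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{k: v for k, v in rec.items() if k != "clone_sizes"} for rec in self.records]
        return pd.DataFrame(rows)

    def clone_sizes_at(self, cycle: int) -> np.ndarray:
        return self.records[cycle]["clone_sizes"]


def _record_cycle(state: LatticeState) -> dict:
    rec = clone_stats_by_region(state)
    rec["cycle"] = state.cycle
    rec["total_cells"] = int(rec["clone_sizes"].sum())
    rec["mean_edge_width"] = float(_edge_run_lengths(state.grid[0]).mean())
    return rec


def run_simulation(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    keep_snapshots: bool = False,
) -> SimTrajectory:
    """Run one replicate for ``config.cycles`` cycles from a fresh grid.

    Fully reproducible: the same (config, seed) yields bit-identical
    trajectories. Statistics are recorded at cycle 0 and after every cycle.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = init_grid(config, rng)
    traj = SimTrajectory(config=config)
    traj.records.append(_record_cycle(state))
    if keep_snapshots:
        traj.snapshots.append(state.grid.copy())
    for _ in range(config.cycles):
        state = step_cycle(state, config, rng)
        traj.records.append(_record_cycle(state))
        if keep_snapshots:
            traj.snapshots.append(state.grid.copy())
    traj.final_state = state
    return traj


@dataclass
class EnsembleSummary:
    """Replicate-wise and aggregated per-cycle statistics of an ensemble."""

    config: SimConfig
    per_replicate: pd.DataFrame  # tidy: cycle, replicate, statistics
    final_states: list[LatticeState]

    def aggregate(self) -> pd.DataFrame:
        """Per-cycle mean and standard deviation across replicates."""
        stats = [
            "clones_total",
            "clones_edge_third",
            "clones_mid_third",
            "clones_center_third",
            "mean_clone_size",
            "mean_edge_width",
        ]
        grouped = self.per_replicate.groupby("cycle")[stats]
        mean = grouped.mean().add_suffix("_mean")
        sd = grouped.std(ddof=1).add_suffix("_sd")
        return pd.concat([mean, sd], axis=1).reset_index()


def replicate_rngs(seed: int, replicates: int) -> list[np.random.Generator]:
    """Independent per-replicate generators derived from one master seed."""
    return [np.random.default_rng(ss) for ss in np.random.SeedSequence(seed).spawn(replicates)]


def ensemble_summary(config: SimConfig) -> EnsembleSummary:
    """Run ``config.replicates`` independent simulations and collect statistics.

    Replicate r uses a sub-seed derived deterministically from the master
    seed, so the whole ensemble is reproducible from (config, seed).
    """
    frames = []
    finals: list[LatticeState] = []
    for rep, rng in enumerate(replicate_rngs(config.seed, config.replicates)):
        traj = run_simulation(config, rng=rng)
        df = traj.to_frame()
        df.insert(1, "replicate", rep)
        frames.append(df)
        finals.append(traj.final_state)
    return EnsembleSummary(
        config=config,
        per_replicate=pd.concat(frames, ignore_index=True),
        final_states=finals,
    )


def render_color_grid(state: LatticeState, palette_size: int = 10) -> np.ndarray:
    """Map identifiers to a finite color palette: color = id mod palette_size."""
    if palette_size < 1:
        raise ValueError(f"palette_size must be >= 1, got {palette_size}")
    return state.grid % palette_size


def harvest_clones(state: LatticeState, min_cells: int = 5):
    """Extract clones from a grid as cell-position records for axis analysis.

    Cell positions are (col, row) in lattice units. For each clone the edge
    point E is the bottom-row point nearest the clone (mean column of its
    lowest cells, row 0) and the necrosis point N is the top-row point
    nearest the clone (mean column of its highest cells, row height-1).
    Clones with fewer than ``min_cells`` cells are omitted.
    """
    from .geometry import CloneRecord  # local import to avoid cycle at import time

    rows, cols = np.nonzero(np.ones_like(state.grid))
    ids = state.grid[rows, cols]
    order = np.argsort(ids, kind="stable")
    ids, rows, cols = ids[order], rows[order], cols[order]
    clones = []
    top = state.height - 1
    for clone_id in np.unique(ids):
        sel = ids == clone_id
        if sel.sum() < min_cells:
            continue
        r, c = rows[sel], cols[sel]
        cells = np.column_stack([c, r]).astype(float)
        e_col = float(c[r == r.min()].mean())
        n_col = float(c[r == r.max()].mean())
        clones.append(
            CloneRecord(
                clone_id=int(clone_id),
                cells=cells,
                edge_point=np.array([e_col, 0.0]),
                necro_point=np.array([n_col, float(top)]),
                color=int(clone_id) % 10,
                timepoint=state.cycle,
            )
        )
    return clones
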