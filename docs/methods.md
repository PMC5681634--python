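# Methods

## Lattice model of clonal competition

The simulator represents a radial strip of tumor tissue as a W×H grid of
integer clone labels; row 0 is the leading tumor edge, the top row abuts
central necrosis. The model is neutral — all clones follow identical rules —
and purely positional. Defaults are the published setup: W = H = 60, 30
replication cycles, 100-replicate ensembles.

Per cycle, two division phases run in a fixed order:

1. **Central divisions.** Every cell in rows 1..H−2 divides upward with
   probability `p_central` (default 0.5) per cycle. Rows are processed from
   the top down, so a copy placed upward within a cycle never divides again
   in the same cycle; this guarantees at most one division per cell per
   cycle. The alternative `every_nth_row` variant replaces the Bernoulli
   draw with a deterministic schedule: all cells in rows with
   `row mod n_period == cycle mod n_period` divide. The parity alternates
   across cycles; whether a fixed or alternating schedule is intended by
   the original description is not recoverable, and the alternating choice
   avoids permanently silent rows. Top-row cells never divide: their copy
   would land in necrosis immediately and is unobservable.
2. **Edge divisions.** Every bottom-row cell divides exactly once, in a
   seeded random column order (a fixed sweep direction would bias lateral
   competition). The direction is drawn from {up, left, right} with
   configurable probabilities, equal by default.

A division copies the divider's label into the target site; the target's
previous content and everything above it in that column shift up one row,
and the old top-row content is discarded (loss into necrosis). Cell count
is therefore conserved exactly, and the set of labels can only shrink.

**Lateral boundaries.** Default is reflecting: a corner edge cell
renormalizes its direction probabilities over its admissible directions
(e.g. {up, right} with probability ½ each at the left wall). A tumor
cross-section has no wrap-around, but a periodic option exists behind
`boundary="periodic"` for sensitivity checks. With W = 1 and `p_up = 0` an
edge cell has no admissible direction and simply does not divide.

**Thirds.** Region statistics split rows into edge/middle/center thirds;
when H is not divisible by 3 the extra rows go to the middle third so the
edge and center thirds stay symmetric. A clone is counted in a third if at
least one of its cells lies there — membership is by distinct label, not
connected component.

**Reproducibility.** One master seed; replicate r draws its generator from
`SeedSequence(master).spawn(replicates)[r]`, so ensembles are bit-identical
across runs and replicates are statistically independent.

## Clonal-axis analysis

Each clone carries its cell positions, a nearest edge point E and a nearest
necrosis point N. The transform is rigid: translate by −E, then rotate so
the E→N direction lands on the +45° diagonal with N′ in the first quadrant.
Of the two rotations that put N′ on x′ = y′, the first-quadrant one makes
"toward necrosis" the +45° direction, so edge-perpendicular clones get
α = 90° and stay far from the vertical-slope singularity of y-on-x
regression. OLS of y′ on x′ gives slope m; θ = tan⁻¹(m) and α = θ + 45°,
with the correlation t-test (n−2 df) as the significance of linear
alignment.

Numerical edge cases are flagged, never fatal:

- fewer than `min_cells` cells (default 3, the smallest n with a positive
  df): tabulated without an axis, flag `too_few_cells`;
- zero x′-variance (vertical point cloud): θ = 90°, α = 135°, p undefined,
  flag `vertical` — preserves the full angular range;
- exact collinearity: p reported as its limiting value 0, flag `collinear`;
- zero y′-variance: m = 0, correlation undefined, flag `zero_y_variance`;
- E = N: flag `degenerate_geometry`.

For clones harvested from simulation grids, E is the bottom-row point
nearest the clone (mean column of its lowest cells, row 0) and N the
top-row point nearest the clone (mean column of its highest cells, top
row); ties across columns resolve to the mean, which is deterministic and
symmetric.

## Clone size, density and edge width

Clone size is cells per label within one tumor/replicate; per-timepoint
means carry the s.e.m. (flagged undefined for a single clone). Density is
distinct clones per unit region area, with regions defined as thirds of the
normalized edge→necrosis depth (exact annulus areas for annular bands);
a clone spanning several regions counts once in each. Edge-vs-center
comparisons use the standard two-sided pooled t-test; zero-variance groups
are resolved to the closed-form limits (equal means: t = 0, p = 1;
different means: t = ±∞, p = 0) instead of returning NaN.

Edge clone width takes the cells within one cell spacing of the edge curve
(configurable band), measures each clone's extent along the edge arclength
direction plus one cell spacing — so a lone edge cell has width one spacing
and contiguous clones tile the circumference exactly — and divides by the
circumference. The adjusted width is dimensionless and scale-invariant.

## Synthetic lineage-tracing generator

The generator emulates the statistical structure the analysis assumes, not
images: a tumor band (parallel lines or a concentric annulus) between an
edge curve and a necrosis curve; sparse mosaic induction (founder clones of
1–3 cells placed uniformly in the band); a finite color palette (default
10, standing for a few base fluorophores plus their mixed-integration
colors) with colors drawn uniformly per clone so distinct neighboring
clones can collide on a color; and per-clone axis angles drawn from
N(axis_mean, axis_jitter_sd) with default mean 90° — perpendicular
outgrowth toward necrosis.

Growth is discrete cell placement, not reaction–diffusion: per cycle every
existing cell is advected a fixed drift (default 0.5 cell spacings) along
the local inward normal — the edge proliferates and pushes older material
centrally — and each clone appends cells at its tip along its planted axis
with perpendicular Gaussian jitter. Cells crossing the necrosis curve are
removed; a clone whose cells are all removed is lost. The drift is what
makes whole-clone loss possible at all: with tip growth alone, founder
cells would be immortal. Labels are heritable and never re-induced, so the
clone set is non-increasing across timepoints.

Per-clone anchors are recomputed from the final positions: E is the edge
point nearest the clone, and N is the necrosis point nearest E — i.e. E→N
is the local edge→necrosis normal through E. Taking N nearest to the
*clone* instead would tilt E→N along any obliquely grown clone and bias
every fitted angle toward 90°; anchoring N through E keeps the planted
angle recoverable without bias (exactly, for the linear band).

Default scales: cell spacing 10 (arbitrary planar units, think µm), band
thickness 300, lateral jitter 2, one new cell per clone per cycle. These
give clones of ~10–15 cells after ~12 cycles spanning a realistic fraction
of the band.

What the generator does **not** emulate: real segmentation noise, clone
fragmentation and merging of same-color neighbors, curved/irregular edge
geometry beyond the annulus, induction kinetics, or in-vivo growth-rate
time courses (growth is linear in cycle count, not exponential). Passing
tests therefore demonstrate correctness of the geometry/statistics
pipeline under the stated assumptions, not robustness to imaging artifacts.

## Problem sizes

The default ensemble (60×60, 30 cycles, 100 replicates) and the exact
2×2 enumeration check (10⁵ runs) run in seconds. Parameter-recovery runs
use 250 founder clones grown for 12 cycles in an 8000×300 band, yielding
well over 100 clones of ≥ 10 cells per setting. The acceptance script uses
24 replicates of the default simulation (~200 clones of ≥ 5 cells).

## Known limitations

- Clone identity is by label; fragmented same-label regions are one clone.
- The update order within a cycle (central first, edge in random order) is
  a design choice; other orders satisfy the same invariants but differ in
  detail.
- The every-Nth-row variant's phase convention is an assumption (see above).
- In-vivo absolute clone sizes and densities are not reproduced — only
  relative and temporal patterns are meaningful at this scale.
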