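# Methods

This note documents the model implemented by `fftdock`, the choices made
where the design was genuinely open, and what the test fixtures do and do
not exercise.

## Model overview

`fftdock` performs exhaustive rigid-body docking by grid correlation.  The
receptor is voxelized once into a complex score grid `R(v)` over the cubic
grid space V (edge = N/2 voxels); for each of n_θ ligand orientations the
rotated ligand is voxelized into `L(v)` and the score of every integer
translation **t** is obtained at once as

    S(t) = Re Σ_{v∈V} R(v)* · L(v+t) = Re IFFT[ FFT[R]* ⊙ FFT[L] ](t).

The conjugated form is used consistently in both the FFT path and the
direct-sum oracle; for the real-valued single-term grids it reduces to the
plain correlation sum.  Favorable scores are positive: the best pose
maximizes S.

### Grid geometry

* `edge = ceil((largest receptor extent + 2·max vdW radius)/pitch) + 2·margin`,
  `N = 2·edge`.  The factor-two zero padding guarantees the circular
  correlation returned by the FFT equals the aperiodic sum for every
  translation with components in ±(edge−1); translations at the wrap
  boundary are never reported.
* The receptor is centered in V by the grid origin; the ligand is
  recentered (centroid to the center of V) before voxelization and must fit
  V entirely at every orientation, else the run aborts with a grid-overflow
  diagnostic.
* Voxel membership uses the voxel center point; voxels are half-open boxes
  `[origin + i·pitch, origin + (i+1)·pitch)`.
* Default pitch **1.2 Å** (configurable).  For typical 150–250 residue
  chains this lands the FFT size near the conventional N ≈ 128.

### Score channels

Three channels are packed into one complex grid per body so the whole
score needs a single complex FFT per rotation:

| channel | receptor | ligand |
| --- | --- | --- |
| shape | `core_value` (−45) inside any atom's vdW sphere; `surface_value` (+1) on the unoccupied shell within `surface_thickness` (2) voxels (Chebyshev dilation) of an occupied voxel | binary occupancy |
| electrostatics | −Σ_i q_i / max(d/pitch, 1), per-voxel total clamped to ±`elec_clamp` (10) | Σ_i q_i over voxels inside atom i's vdW sphere |
| desolvation | atom-overlap (burial) count capped at `desolv_cap` (4) | occupancy (shared with the shape channel) |

Packing: `R = (w_shape·shape + w_desolv·desolv) + i·(w_elec·elec)`,
`L = occupancy + i·charge`.  Then
`Re Σ R*·L(v+t) = w_shape·S_shape + w_desolv·S_desolv + w_elec·S_elec`
identically — the decomposition is asserted against independently computed
single-term correlations in the tests.  All weights live on the receptor
side so every product term carries its weight exactly once.

Notes on these choices:

* The electrostatic receptor grid is the **negated** potential so that
  opposite-charge attraction raises S with the default `w_elec = +1`,
  keeping the maximize-S convention uniform across terms.
* The ligand electrostatic channel carries charge (accumulated over the
  atom spheres), while the receptor carries the potential.  Correlating a
  potential with a potential would not produce an interaction-energy-like
  term, and only the charge-mask form makes the packed decomposition
  exact.
* The shape constants follow the soft-core/surface-shell family of
  pairwise shape scores; the electrostatic functional form is a simplified
  clamped distance-weighted potential and the desolvation term a capped
  burial count.  These are configurable stand-ins with sensible defaults,
  not reproductions of any published parameter set, and scores are not
  comparable numerically to other docking programs.
* Grids are stored in single-precision complex (`complex64`) — the
  reference storage precision — while FFTs and accumulations run in double
  precision.  Test tolerances (1e-6 relative on toy grids) reflect the
  single-precision storage.

### Rotational sampling

Orientations are enumerated on a ZYZ Euler grid with uniform step θ
(α, γ ∈ [0°, 360°), β ∈ [0°, 180°]) in lexicographic order, converted to
matrices, and deduplicated keeping first occurrences.  The grid
over-counts at the β poles, so e.g. the 90° grid's 48 triples reduce to
the 24 rotations of the cube group.  Deduplication is implemented as
6-decimal rounding of matrix entries (equivalent to a 1e-6 Frobenius
tolerance for any step ≥ 0.5°, where distinct grid matrices differ by
≥ 1e-2 per entry).

The deduplicated 15° grid contains 6384 unique rotations.  The shipped
default keeps the **first 3600** in deterministic order — the conventional
default rotation count for this class of docking tools — and records the
truncation on the returned set and in the log.  The default set is defined
by this package; no claim is made that it coincides with any other
program's angle set.  Externally supplied angle files (3-column degrees)
can replace the built-in grid.

Rotations are applied about the ligand centroid (the rotation origin is
otherwise arbitrary for a translation-searched score; the centroid keeps
the recentered ligand maximally inside V).

### Search, ranking, determinism

For each rotation the maximal in-bounds translation is recorded
(`best_per_rotation`); ties break by the lexicographically smallest signed
(tz, ty, tx).  The overall ranking sorts by score descending, then
rotation index, then (tz, ty, tx); `top_k` (default 2000) decoys are
reported.  A run evaluates exactly n_θ × N³ candidate poses, reuses the
conjugated receptor spectrum across all rotations, and is bit-reproducible
for a fixed configuration — the resolved configuration is echoed into
every result file.

### Memory planner

Angle-parallel execution on a memory-limited accelerator needs, per
thread, the FFT input and output arrays: 2 × 8 bytes × N³ = **16·N³
bytes**.  `max_fft_size(budget, threads)` returns the real-valued bound
`(budget/threads/16)^(1/3)` and the largest integer N that fits; an 8 GB
budget gives 127.7 → N ≤ 127 at 240 threads and 202.7 → N ≤ 202 at 60
threads.  `usable_threads` inverts the formula.  This is a formula-only
model: real per-thread footprints are larger (FFT workspace, program
state), so the predicted thread counts are upper bounds, and no attempt is
made to model the additional overheads.

### Profiler

`dock` times the nine canonical stages (P1 initialization, P2 receptor
voxelization, P3 receptor FFT, P4 ligand rotation & voxelization, P5
ligand FFT, P6 convolution, P7 inverse FFT, P8 best-solution
identification, P9 post-processing); P4–P8 accumulate over the rotation
loop.  `profile_run` emits seconds and percentages (percentages sum to 100
up to rounding).  Timings are reported, never asserted against any
external measurement — they are hardware-dependent.

## Synthetic fixtures

`make_synthetic_structure(n, extent, seed)` places n atoms uniformly in an
`extent³` Å cube with radii in [1.0, 2.0] Å and charges in [−1, 1] e,
bit-reproducibly.  This emulates the size and parameter ranges of small
rigid bodies (3–50 pseudo-atoms) but none of the chemistry of real
proteins: no bonded geometry, no residue composition, no correlated charge
placement.  Tests passing on these fixtures validate the *numerics* —
grid geometry, correlation identities, determinism — not predictive
docking accuracy on real complexes.

`make_complementary_pair()` builds a deliberately solvable recognition
problem: a two-layer receptor plate whose top layer has an L-shaped
notch, and the matching 3-atom L-shaped plug (1 Å radii, no charges).
At 1 Å pitch the receptor yields edge 6 (N = 12), small enough that the
O(N⁶)-per-rotation brute-force enumeration over all 24 rotations of the
90° set and all 11³ translations runs in seconds, providing a full
independent check of the end-to-end pipeline.  The plug is self-symmetric
under its in-plane arm swap, so two rotation indices produce bit-identical
ligand grids; that exact tie resolves identically (by rotation index) in
the FFT path and the brute-force path, while every geometrically distinct
pose scores well below the seated optimum (gap ≥ 4 score units), keeping
the comparison robust to floating-point noise.

## Numerical and degenerate-input choices

* Sphere membership uses `d² ≤ r² + 1e-12` to make exactly-on-surface
  voxel centers deterministic.
* `determine_grid` subtracts 1e-9 before the ceiling so exact-integer
  extents do not round up spuriously.
* Structures must contain ≥ 1 atom; zero-rotation runs are allowed
  (loop stages report 0 in the profile) to support degenerate-run
  diagnostics.
* Orthonormality of rotation matrices is checked to 1e-8 on application;
  improper rotations (det −1) are rejected.
* PDB coordinates are written at the format's 1e-3 Å precision, which
  bounds the read/write roundtrip error asserted in tests.  Only the first
  MODEL is read, alternate locations resolve to the first conformer,
  hydrogens and HETATM records are skipped by default (flags to include):
  heavy atoms dominate shape at ≥ 1 Å pitches, and rigid docking uses one
  conformer.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic
fixtures at small grid sizes — random complex grids at edge 2 (N = 4) for
the correlation identities, edge ≤ 8 for voxelization oracles, and the
edge-6 pocket pair with the 24-rotation set for end-to-end recovery —
chosen so the full brute-force cross-checks stay exhaustive.  The default
configuration (15° step, 3600 rotations, pitch 1.2 Å) is exercised where
its cost is trivial (rotation-set generation, memory planning); a
full-size default docking run on real ~200-residue chains (N ≈ 128,
3600 rotations) works through the same code paths but is not part of the
test suite.

## Known limitations

* Purely rigid-body: no flexibility, refinement, clustering, or
  re-ranking of decoys; no interface-RMSD evaluation against native
  complexes.
* The score parameterization is a configurable stand-in (see above);
  absolute scores have no physical units beyond "grid overlap units".
* Serial execution only; the angle loop is the natural parallel seam
  (one rotation per worker) and the FFT/voxelize stages are pluggable,
  but no accelerator or multi-process backend is included — the planner
  only *models* such execution.
* mmCIF input is not supported; no structure preparation beyond parsing.
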