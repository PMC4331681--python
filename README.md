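# fftdock

FFT-based exhaustive rigid-body protein–protein docking, with a brute-force
scoring oracle, an accelerator memory planner, and a per-stage profiler.

## The problem and who this is for

Rigid-body docking asks: given the structures of two proteins (a fixed
*receptor* and a mobile *ligand*), which relative orientation and placement
of the ligand best complements the receptor surface?  Grid-correlation
(Katchalski-Katzir-style) docking answers by discretizing both proteins
onto a 3-D voxel grid and scoring **every** pose on a dense rotational ×
translational sample.  `fftdock` is a compact, fully tested Python
implementation of that scheme for method developers, teachers, and anyone
who wants a transparent reference with an honest brute-force oracle next to
the fast path.

## The score and the algorithm

Both proteins are voxelized into complex grids `R(v)` and `L(v)` over the
cubic grid space `V` (edge `N/2` voxels, FFT size `N = 2 × edge`).  The
docking score of a pose at integer translation **t** is the conjugated
cross-correlation

```
S(t) = Re Σ_{v∈V} R(v)* · L(v+t)
     = Re IFFT[ FFT[R]* ⊙ FFT[L] ](t)
```

Direct evaluation of the sum over all t costs O(N⁶); the FFT route costs
O(N³ log N).  Both paths are implemented — `correlate` (FFT) and
`direct_score` (direct sum) — and are tested to agree at every translation.

Three score channels ride in one complex FFT per rotation:

* **shape complementarity** — receptor: +1 on a thin surface shell, −45
  inside atoms (soft-core pairwise shape scoring); ligand: binary occupancy
  within the van der Waals radius of any atom;
* **electrostatics** — receptor: clamped distance-weighted potential;
  ligand: per-voxel cumulative atomic charge;
* **desolvation** — receptor: capped atom-burial count; ligand: occupancy.

The packing `R = (w_shape·shape + w_desolv·desolv) + i·(w_elec·elec)`,
`L = occupancy + i·charge` makes the real part of the conjugated
correlation exactly the weighted sum of the three single-term scores.

Ligand orientations are sampled exhaustively on a deduplicated ZYZ
Euler-angle grid; the default set contains **n_θ = 3600** rotations (15°
grid, first 3600 unique matrices in deterministic order).  For each
rotation the best-scoring translation is recorded, so a run evaluates
n_θ × N³ candidate poses and reports one decoy per rotation plus a ranked
top-k list.

The search follows the canonical nine-stage decomposition of FFT docking
codes — initialization (P1), receptor voxelization (P2), receptor FFT
(P3), then per rotation: ligand rotation & voxelization (P4), ligand FFT
(P5), convolution (P6), inverse FFT (P7), best-solution identification
(P8) — and post-processing (P9).  `profile_run` reports seconds and
percentages per stage.

The `planner` module models angle-parallel execution on memory-limited
accelerators: each thread needs the FFT input and output arrays,
`16·N³` bytes of single-precision complex storage, so an 8 GB budget with
240 threads caps the FFT size at N = 127 (real-valued bound 127.7), while
60 threads allow N up to 202 (bound 202.7).

## Worked example

Generate the built-in shape-complementary pocket/plug pair and dock with a
scaled-down 90° rotational sample (24 rotations) and shape-only weights:

```sh
python -c "from fftdock import make_complementary_pair, write_pdb
r, l = make_complementary_pair(); write_pdb(r, 'rec.pdb'); write_pdb(l, 'lig.pdb')"
fftdock dock rec.pdb lig.pdb --pitch 1.0 --margin 0 --rotation-step 90 \
        --w-elec 0 --w-desolv 0 --top-k 5 --out decoys.tsv
```

The log reports the grid (`edge 8, FFT size 16`), the pose count
(`24 × 16³ = 98304`), and the stage profile.  `decoys.tsv` embeds the full
resolved configuration in `#` header lines, then the ranked decoys:

```
rank	rotation_index	alpha	beta	gamma	tx	ty	tz	score
1	0	0.000	0.000	0.000	2	2	-3	40.000000
2	9	0.000	180.000	90.000	2	2	-3	40.000000
3	2	0.000	0.000	180.000	1	3	-3	30.000000
```

Rank 1 is the plug seated in the receptor's L-shaped notch: rotation
(α, β, γ) = (0°, 0°, 0°) and translation t = (2, 2, −3) voxels, score 40
(forty ligand voxels on the +1 surface shell, none inside an atom core).
Rank 2 is the same physical pose reached through the plug's own in-plane
symmetry.  `--write-ligands 1` additionally writes the transformed ligand
PDB for visual inspection.

The memory planner:

```sh
$ fftdock plan --budget 8e9 --threads 240
budget_bytes	8000000000.0
n_threads	240
fft_size	127
per_thread_bytes	32774128
max_n_real	127.71823873225881
max_n	127
usable_threads	240
```

## Layout

| module | contents |
| --- | --- |
| `fftdock.structures` | PDB I/O, atom parameters, synthetic rigid bodies |
| `fftdock.rotations` | Euler-grid rotation sets, rigid application |
| `fftdock.voxelizer` | grid geometry, score channels, complex packing |
| `fftdock.fft_search` | FFT correlation, direct-sum oracle, `dock` |
| `fftdock.planner` | 16·N³ memory model, pose accounting, profiler |
| `fftdock.cli` | `fftdock dock / plan / synth / rotations-export` |

See `docs/methods.md` for the model details, parameter defaults, and known
limitations.
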