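# Methods

`crowdhop` simulates crowded many-protein systems by combining two layers
that are usually separate: exhaustive rigid-body docking, which maps the
pairwise intermolecular energy landscape once, and Markov-chain Monte
Carlo, which then propagates the whole system through that landscape for
very long effective times.  This note records the model, its assumptions,
the tunable parameters, and the numerical choices made where the design
was genuinely open.

## The model

### Energy landscape from pairwise docking

Each ordered pair of protein types (ligand moving onto receptor) is docked
exhaustively once.  The receptor is rasterized on a cubic grid (step 3.5 Å
by default) as a step-function approximation of a Lennard-Jones contact
potential: occupied cells with at least one empty 6-neighbor form a
one-cell attractive surface layer scored +1, deeper occupied cells form a
repulsive core scored −ρ (ρ = 9 by default).  The ligand is an occupancy
indicator (+1).  The score of a relative placement is the overlap
correlation of the two grids, evaluated for all translations at once by
FFT; rotations are sampled on a deterministic quasi-uniform covering of
SO(3) (super-Fibonacci spiral on the quaternion sphere; identity at index
0) with a nominal covering radius of 10° by default.  The top K = 30 000
positive-score placements per ordered pair are kept, ranked.  A pose's
energy is its negated score, so docked states are negative-energy minima
and the fully unbound (monomeric) state sits at zero — the docking score
is the only energy in the model; there is no electrostatics, solvent, or
flexibility.

Occupancy uses a uniform 1.7 Å atom radius smeared by half a grid step.
Low-resolution rigid docking is insensitive to per-element radii, and the
half-step smear keeps thin features connected on the coarse lattice.  A
cell containing an atom is always marked occupied even if no cell center
falls inside the atom sphere, so arbitrarily coarse grids still rasterize
every atom.

Exactness: FFT correlation of integer-valued grids is rounded back to
integers (the float error is orders of magnitude below 0.5 for any
realistic grid), and a non-integral ρ is handled by correlating the
surface and core indicator channels separately.  The FFT route is
verified against direct summation in the tests.

### Minima-hopping Monte Carlo

The system is a cubic periodic box (500 Å reference size) holding rigid
copies of each type, with equal copy counts per type chosen to reach a
target volume fraction V (molecular volumes from a voxelized
union-of-spheres estimator: van der Waals radii, 1.4 Å water probe, 1 Å
voxels anchored at the world origin).  The initial state places copies on
a cubic lattice in random order with uniform random orientations and a
±half-lattice-step jitter, without any collision check; residual overlaps
are eliminated by the first accepted moves.

A sweep ("step") gives every copy one move attempt in a fresh random
permutation.  A move takes the chosen ligand to a pose drawn uniformly
from the pose table of a receptor drawn uniformly from its neighborhood
— copies whose center lies within r_lig + r_rec + 50 Å (minimum image),
using the bounding radius of each type so no stored pose can fall outside
the shell.  Because the proposal probability is 1/(N·K) with N the local
receptor count, and N differs between departure and arrival states, the
Metropolis rule carries the normalization needed for detailed balance:

    P(i→j) = min{ 1, exp[−(E_j − E_i)/T] · N_i / N_j }

with T a temperature-like scaling factor in docking-score units.
ΔE = E_j − E_i is just the new match energy minus the energy of the match
the ligand abandons, maintained incrementally and cross-checked against a
full bond-graph recomputation in the tests.  A move is also rejected if
any Cα of the relocated ligand comes within 8 Å (minimum image) of any
Cα of any copy other than the new receptor; the new receptor is exempt
because genuine docked interfaces at 3.5 Å resolution legitimately have
cross-interface Cα pairs below 8 Å and the pose itself defines that
contact.  Isolated ligands (no neighbors) consume their attempt as a
rejection, keeping the per-sweep attempt count fixed at n.

Each copy owns at most one outgoing match (the one it formed when it last
moved as a ligand); clusters arise through shared receptors and incoming
bonds.  When a ligand moves away, its incoming bonds persist until those
partners move themselves — the model does not force detachment, which is
also what lets "monomers" (copies with no bonds at all) appear transiently.

### Time

All transitions share a constant Kramers/Arrhenius prefactor (the model
assumes no extra barriers between minima and equal well curvatures), so
rates are proportional to acceptance probabilities and every sweep
advances physical time by the same amount.  That amount is calibrated by
matching the simulated diffusion coefficient of a reference protein to an
external value: the bundled reference is an MD diffusion coefficient of
3.5 Å²/ns for a small protein at physiological crowding, divided by 3
because that MD value is known to run three times faster than experiment.
The reference configuration (500 Å box, V = 0.3) yields 20 ns per sweep,
the package default.

## Observables

- **Energy / shift / acceptance** per sweep: mean per-copy energy (each
  match counts toward both partners), mean accepted displacement length,
  accepted fraction of attempts.
- **MSD and diffusion.**  Mean squared displacement on unwrapped
  coordinates relative to a reference sweep (default 100, excluding the
  off-lattice relaxation of the initial grid).  D = slope/6 with the
  slope fit through the origin over lags between 10% and 50% of the
  series (our choice; it avoids the reference transient and the noisy
  tail, where few independent displacement blocks remain).  A quality
  flag marks saturating or poorly linear MSD.  A time-origin-averaged
  estimator (`msd_time_averaged`) is also provided: averaging over all
  origins is the standard variance reduction when a quantitative D is
  needed from a single run, and it is what the quantitative tests use.
- **Cohen–Turnbull fit.**  D(V) = D₀ exp[−γV/(1−V)], fit both by
  nonlinear least squares and by linear regression of ln D on V/(1−V)
  (the latter seeds and cross-checks the former).
- **Clusters.**  Connected components of the undirected bond graph.  The
  aggregation number N_c averages components of size ≥ 2; monomers are
  reported separately (and a variant including them is also computed,
  since either convention appears in the aggregation literature).
- **Residence time.**  A pair episode starts when a ligand docks onto a
  receptor and ends when it moves to a *different* receptor; re-docking
  the same partner with a new pose keeps the pair alive.  Episodes still
  open at the end of a run are right-censored: excluded from the mean and
  counted, which is unbiased for the completed-episode mean.
- **Melting curve.**  Terminal-window means of smoothed (100-sweep boxcar)
  energy/shift/MSD/acceptance per temperature over a decade grid
  T ∈ {1, 10, 10², 10³, 10⁴}.  The melting point is the zero crossing of
  the second divided difference of the *shift* versus log₁₀T (shift is
  the most direct mobility readout); a symmetric sigmoid on the decade
  grid yields its center exactly.  Degenerate (flat) curves return no
  inflection; multiple curvature sign changes lower the confidence flag.
- **Size dependence.**  Slowdown D_max/D per type, fit exponentially in
  residue count N and linearly in N^(1/3) (an Einstein–Stokes radius
  proxy for globules).

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| grid step | 3.5 | Å | docking resolution (intermediate, unbound regime) |
| ρ (core repulsion) | 9.0 | — | core/surface weight in the step potential |
| rotation spacing | 10 | ° | SO(3) covering radius of the pose search |
| K (poses/pair) | 30 000 | — | breadth of the sampled minima set |
| box | 500 | Å | periodic box edge |
| V | 0.10–0.30 | — | protein volume fraction |
| T | 100 | score units | melting point of the score landscape |
| neighbor margin | 50 | Å | receptor shell beyond touching distance |
| collision cutoff | 8 | Å | minimal Cα–Cα distance between non-partners |
| MSD reference | 100 | sweeps | excludes initial relaxation |
| ns per sweep | 20 | ns | calibrated time unit |

## Synthetic structures

The fixture generator emulates globular proteins as compact self-avoiding
Cα walks: 3.8 Å virtual bonds, 3.6 Å exclusion between non-bonded Cα,
confined to a sphere of radius 3.15·N^(1/3) Å (≈130 Å³ per residue, the
empirical packing of real globules), plus three pseudo side-chain carbon
atoms per residue at 1.6 Å.  They reproduce the features the pipeline
depends on — compact shape, N^(1/3) radius scaling, realistic volume per
residue, a parsable PDB representation — and none it doesn't: no
secondary structure, no sequence, no chemically meaningful surfaces.
Tests passing on synthetic globules therefore validate the machinery
(grids, sampling, detailed balance, bookkeeping, estimators), not the
biology of any particular complex; score scales on real proteins are
larger and interface-specific.

Toy scenarios make the chain's stationary law exact: `two_state` (two
molecules, poses at −100/−50, occupancy ratio e^{50/T}), `frozen_pair`
(a −10 000 minimum that freezes at low T), and `uniform_walk`
(equal-energy poses, collisions off).  The `uniform_walk` hop set is
antipodally symmetric — without that, docked clusters, whose orientations
homogenize because a docked ligand inherits the receptor frame, acquire a
net drift and the MSD turns ballistic — and hops span a good fraction of
the neighbor shell so that, in a dense crowd, consecutive hops land in
statistically fresh neighborhoods.  In that regime the dynamics is an
ideal random walk and D matches ⟨δ²⟩/6 per sweep; in sparse or
short-hop regimes the crowd tethers its members and hop–hop
anticorrelation depresses D below the ideal value, which is genuine model
behavior rather than an artifact.

## Numerical choices and degenerate inputs

- Equal copy shares round the remainder to the first types in input
  order (deterministic).
- The volume voxel lattice is world-anchored, making the estimate
  monotone under atom addition and exactly additive for voxel-aligned
  disjoint unions.
- Pose ties are broken by (rotation index, lexicographic translation);
  pose tables are strictly sorted by descending score.
- Minimum-image components map to (−box/2, box/2] with the tie assigned
  to +box/2.
- N_i is counted before the move, N_j at the proposed placement with all
  other copies unmoved; the new receptor is always within its own shell,
  so N_j ≥ 1 and the acceptance ratio is always defined.
- Neighbor queries use a vectorized all-pairs minimum-image scan up to
  1024 copies (faster than any cell structure at that size in Python) and
  a 27-stencil uniform-grid cell list beyond; both routes are exposed and
  cross-checked.
- Empty pose tables yield a warning and a null proposal (counted as a
  rejected attempt); an all-HETATM PDB is a parse error; residues without
  a Cα are excluded from the trace but keep their atoms.
- Runs are bit-reproducible: one master seed, subsystem streams derived
  through `SeedSequence`, and HDF5 outputs written without timestamps.

## Known limitations

- Rigid bodies, score-only energetics: no electrostatics, solvation,
  flexibility, or real binding affinities.
- The minima-hopping approximation requires crowding; in dilute systems
  most attempts find no neighbor and the dynamics stalls by construction.
- Coarse rotation sampling (needed to keep test and example runtimes in
  seconds) quantizes the pose landscape; pairwise docking symmetry
  (A→B vs B→A best scores) only converges at spacings ≤ 20°.
- Cluster statistics at small copy numbers are dominated by a few
  components and fluctuate strongly between sweeps; terminal-window
  averages are reported for that reason.
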