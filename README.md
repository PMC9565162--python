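# crowdhop

Docking-based minima-hopping Monte Carlo simulation of crowded protein
systems.

## What this is for

Atomistic molecular dynamics reaches microseconds on cell-scale protein
systems; rigid-body docking searches the full 6D pose space of a protein
pair in seconds but has no time axis.  `crowdhop` joins the two: it
precomputes, for every ordered pair of protein types, a ranked library of
rigid-body docking poses by FFT grid correlation, and then propagates a
periodic box crowded with protein copies by hopping directly between
those docked minima under a Metropolis criterion.  Because the sampler
skips the high-energy unbound intermediates, effective trajectory times
of hundreds of microseconds are reachable on one CPU core, while the
underlying representation stays atomic.  It is aimed at people studying
macromolecular crowding: diffusion slowdown with concentration and size,
transient cluster formation, and docking-bond residence times.

## The model in brief

The pose score is the classic step-function (Katchalski-Katzir style)
grid correlation: receptor surface layer +1, receptor core −ρ, ligand
occupancy +1, all translations scored at once by FFT, rotations on a
quasi-uniform SO(3) covering (10° nominal).  Pose energy = −score, so
docked states are negative minima and monomers sit at zero.  A Monte
Carlo sweep gives every copy one attempt to re-dock onto a random
neighbor at a random stored pose, accepted with

    P(i→j) = min{ 1, exp[−(E_j − E_i)/T] · N_i/N_j }

where N_m counts the available receptors in state m — the normalization
that keeps detailed balance under a variable-size move set.  Moves
placing any Cα within 8 Å of a non-partner are rejected.  Each sweep
advances time by a constant calibrated against reference diffusion data
(20 ns at the default calibration).  Observables include per-type MSD and
Einstein-relation diffusion coefficients, the Cohen–Turnbull free-volume
fit D(V) = D₀·exp[−γV/(1−V)], aggregation numbers from the bond graph,
residence times, and melting curves over a temperature scan.

See `docs/methods.md` for the full model description and parameter table.

## Worked example

Generate two synthetic globules, dock them, run 200 sweeps at volume
fraction 0.2, and analyze:

```sh
crowdhop fixtures --n 40 --seed 1 --out pdbs/a.pdb
crowdhop fixtures --n 60 --seed 2 --out pdbs/b.pdb
crowdhop dock --pdb-dir pdbs --spacing 45 --topk 2000 --out lib.h5
cat > sim.yaml <<EOF
box: 140.0
target_fraction: 0.2
temperature: 100.0
steps: 200
msd_reference_step: 50
ns_per_step: 1.0
seed: 7
EOF
crowdhop run --pdb-dir pdbs --config sim.yaml --lib lib.h5 --out traj.h5
crowdhop analyze --traj traj.h5 --out report/
```

The `run` step prints:

```
config hash 3512e3697290ad07; 200 steps at T=100.0, V=0.2
final acceptance 0.112, mean energy -24.49
wrote traj.h5
```

and `report/summary.json` contains (abridged):

```json
{
  "copies": 89,
  "n_c": 44.5,
  "monomer_fraction": 0.0,
  "residence_time_ns": 8.06,
  "diffusion": [
    {"type": "a", "d_A2_per_step": 77.96, "r_squared": 0.981},
    {"type": "b", "d_A2_per_step": 53.26, "r_squared": 0.981}
  ]
}
```

Read: at 20% volume fraction about 11% of attempted re-docking moves are
accepted (mostly collision-limited at this density); each copy
participates in matches worth −24 score units on average; the smaller
protein diffuses faster than the larger one (Å²/sweep here, since the
demo sets 1 ns per sweep; a real calibration rescales that).  The mean
cluster size of 44.5 says the bond graph of this tiny demo box has
percolated into one large cluster — with 40–60-residue globules the
50 Å neighbor margin spans most of a 140 Å box, so nearly everyone is
everyone's neighbor.  Larger boxes (and larger proteins) localize the
clusters.  The temperature scan (`crowdhop scan-temperature`) produces
the melting table and locates the freeze-to-melt inflection.

The same pipeline is available as a library; the docking, system,
engine, and observables layers are plain functions over NumPy arrays
(`crowdhop.build_library`, `crowdhop.run_simulation`, `crowdhop.msd`,
...).

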