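"""Minima-hopping Metropolis Monte Carlo engine.

The system hops directly between docked states: a move takes one copy
(the ligand) to a randomly drawn precomputed docking pose on a randomly
drawn neighboring copy (the receptor), skipping the high-energy unbound
intermediates.  Because the number of available receptors differs between
the departure and arrival states, the Metropolis criterion carries a
proposal-normalization factor to preserve detailed balance:

    P(i -> j) = min{ 1, exp[-(E_j - E_i)/T] * N_i / N_j }

where N_m counts the receptors available from state m and T is a
temperature-like scaling factor in docking-score units.  All transitions
share a constant Kramers prefactor, so every simulation step advances
physical time by the same calibrated amount regardless of acceptance.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import yaml

from . import observables as _obs
from .structures import plan_copies
from .system import SystemState, init_state, neighbors

__all__ = [
    "SimulationConfig",
    "MoveProposal",
    "TimeModel",
    "Trajectory",
    "acceptance_probability",
    "propose_move",
    "collision_check",
    "apply_move",
    "run_step",
    "run_simulation",
]

_EXP_CLIP = 700.0


@dataclass
class SimulationConfig:
    """Parameters of one simulation run.

    ``temperature`` is a scaling factor in docking-score units, not
    Kelvin.  ``ns_per_step`` is the physical duration assigned to one
    sweep, calibrated against reference diffusion data (20 ns by
    default).  ``cluster_interval`` controls how often the per-step
    cluster statistics are computed (0 disables them).
    """

    box: float = 500.0
    target_fraction: float = 0.3
    temperature: float = 100.0
    steps: int = 1000
    neighbor_margin: float = 50.0
    collision_cutoff: float = 8.0
    top_k: int = 30_000
    msd_reference_step: int = 100
    smoothing_window: int = 100
    ns_per_step: float = 20.0
    seed: int = 0
    cluster_interval: int = 1

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.steps < 0:
            raise ValueError("steps must be non-negative")
        if self.neighbor_margin < 0 or self.box <= 0:
            raise ValueError("box and neighbor margin must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass(frozen=True)
class TimeModel:
    """Constant-prefactor rate model: every step lasts the same time."""

    ns_per_step: float = 20.0

    def __post_init__(self):
        if self.ns_per_step <= 0:
            raise ValueError("step duration must be positive")

    def steps_to_ns(self, steps) -> float:
        return steps * self.ns_per_step


class MoveProposal:
    """A proposed ligand move with everything the acceptance rule needs."""

    __slots__ = ("ligand", "receptor", "pose_index", "new_rot", "new_pos",
                 "displacement", "e_new", "e_old", "E_i", "E_j", "N_i", "N_j")

    def __init__(self, ligand, receptor, pose_index, new_rot, new_pos,
                 displacement, e_new, e_old, E_i, E_j, N_i, N_j):
        self.ligand = ligand
        self.receptor = receptor
        self.pose_index = pose_index
        self.new_rot = new_rot
        self.new_pos = new_pos
        self.displacement = displacement
        self.e_new = e_new
        self.e_old = e_old
        self.E_i = E_i
        self.E_j = E_j
        self.N_i = N_i
        self.N_j = N_j


def acceptance_probability(e_i: float, e_j: float, temperature: float,
                           n_i: int, n_j: int) -> float:
    """Normalized Metropolis acceptance probability.

    ``min(1, exp(-(E_j - E_i)/T) * N_i/N_j)`` — the move-count ratio
    compensates for asymmetric proposal probabilities (1/N_m per
    receptor) so the chain satisfies detailed balance.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if n_i < 1 or n_j < 1:
        raise ValueError("move counts must be >= 1 for a valid proposal")
    arg = -(e_j - e_i) / temperature
    p = math.exp(min(arg, _EXP_CLIP)) * (n_i / n_j)
    return min(1.0, p)


def propose_move(state: SystemState, ligand: int, library,
                 rng: np.random.Generator) -> MoveProposal | None:
    """Draw a receptor and a pose for one ligand.

    The receptor is uniform over the ligand's current neighbors, the pose
    uniform over the stored table for that ordered type pair.  Returns
    ``None`` when the ligand is isolated or the pair's table is empty
    (counted as a rejected attempt by the caller).
    """
    nb = neighbors(state, ligand)
    n_i = len(nb)
    if n_i == 0:
        return None
    receptor = int(nb[rng.integers(n_i)])
    table = library.table(int(state.types[ligand]), int(state.types[receptor]))
    if len(table) == 0:
        warnings.warn(
            f"empty pose table for type pair "
            f"({state.types[ligand]}, {state.types[receptor]})")
        return None
    k = int(rng.integers(len(table)))

    rot_r = state.rot[receptor]
    pose_rot = library.rotations.matrices[table.rot_index[k]]
    new_rot = rot_r @ pose_rot
    new_pos = state.pos[receptor] + rot_r @ table.disp[k]
    new_pos -= state.box * np.floor(new_pos * state.inv_box)

    disp = new_pos - state.pos[ligand]
    disp -= state.box * np.rint(disp * state.inv_box)

    n_j = len(neighbors(state, ligand, position=new_pos))
    e_new = -float(table.score[k])
    e_old = float(state.out_energy[ligand])
    E_i = state.total_energy
    return MoveProposal(
        ligand=ligand, receptor=receptor, pose_index=k,
        new_rot=new_rot, new_pos=new_pos, displacement=disp,
        e_new=e_new, e_old=e_old,
        E_i=E_i, E_j=E_i + e_new - e_old, N_i=n_i, N_j=n_j)


def collision_check(state: SystemState, proposal: MoveProposal) -> bool:
    """True when the proposed placement is collision free.

    A move collides when any C-alpha of the relocated ligand falls within
    the cutoff (minimum image) of any C-alpha of any copy other than the
    new receptor — the docking pose itself defines the sanctioned contact
    with the receptor.  A non-positive cutoff disables the check.
    """
    cutoff = state.collision_cutoff
    if cutoff <= 0:
        return True
    i = proposal.ligand
    t = int(state.types[i])
    p = proposal.new_pos
    if state.cells is not None:
        cand = state.cells.query(p)
    else:
        cand = np.arange(state.n)
    d = state.pos[cand] - p
    d -= state.box * np.rint(d * state.inv_box)
    d2 = np.einsum("ij,ij->i", d, d)
    mask = (d2 < state.coll_cut2[t][cand]) & (cand != i) & \
           (cand != proposal.receptor)
    cand = cand[mask]
    if len(cand) == 0:
        return True
    lig_ca = p + state.ca_templates[t] @ proposal.new_rot.T
    cut2 = cutoff * cutoff
    order = np.argsort(d2[mask])
    for c in cand[order]:
        diff = lig_ca[:, None, :] - state.ca_world[c][None, :, :]
        diff -= state.box * np.rint(diff * state.inv_box)
        if np.min(np.einsum("ijk,ijk->ij", diff, diff)) < cut2:
            return False
    return True


def apply_move(state: SystemState, proposal: MoveProposal) -> None:
    """Commit an accepted move with incremental bookkeeping.

    The ligand's outgoing match is replaced: its energy and the energies
    of the old and new receptors are updated by the match energies only.
    Incoming bonds to the ligand are left untouched — partners keep their
    match until they themselves move.
    """
    i = proposal.ligand
    old_rec = int(state.out_rec[i])
    e_old = proposal.e_old
    e_new = proposal.e_new

    state.energy[i] += e_new - e_old
    if old_rec >= 0:
        state.energy[old_rec] -= e_old
        state.in_deg[old_rec] -= 1
    state.energy[proposal.receptor] += e_new
    state.in_deg[proposal.receptor] += 1
    state.total_energy += e_new - e_old

    state.bond_events.append((state.step, i, old_rec, proposal.receptor))
    state.out_rec[i] = proposal.receptor
    state.out_pose[i] = proposal.pose_index
    state.out_energy[i] = e_new

    state.unwrapped[i] += proposal.displacement
    state.pos[i] = proposal.new_pos
    state.rot[i] = proposal.new_rot
    state.ca_world[i] = proposal.new_pos + \
        state.ca_templates[int(state.types[i])] @ proposal.new_rot.T
    if state.cells is not None:
        state.cells.move(i, proposal.new_pos)


def run_step(state: SystemState, library, config: SimulationConfig,
             rng: np.random.Generator) -> dict:
    """One sweep: every copy attempts exactly one move, in random order."""
    n = state.n
    order = rng.permutation(n)
    accepted = 0
    shift_sum = 0.0
    temperature = config.temperature
    for i in order:
        prop = propose_move(state, int(i), library, rng)
        if prop is None:
            continue
        p = acceptance_probability(prop.E_i, prop.E_j, temperature,
                                   prop.N_i, prop.N_j)
        if p < 1.0 and rng.random() >= p:
            continue
        if not collision_check(state, prop):
            continue
        apply_move(state, prop)
        accepted += 1
        shift_sum += math.sqrt(float(prop.displacement @ prop.displacement))
    state.step += 1
    return {
        "attempts": n,
        "accepted": accepted,
        "acceptance_rate": accepted / n,
        "shift": shift_sum / n,
        "energy": float(state.energy.mean()),
    }


@dataclass
class Trajectory:
    """Recorded simulation output.

    ``unwrapped[k]`` holds the unwrapped copy centers after step ``k``
    (row 0 is the initial state); ``bond_rec``/``bond_pose`` snapshot the
    bond graph the same way.  Scalar series have one entry per step.
    ``n_c`` is NaN for steps where cluster statistics were not computed.
    """

    unwrapped: np.ndarray          # (S+1, n, 3)
    bond_rec: np.ndarray           # (S+1, n)
    bond_pose: np.ndarray          # (S+1, n)
    energy: np.ndarray             # (S,)
    shift: np.ndarray              # (S,)
    acceptance: np.ndarray         # (S,)
    monomer_fraction: np.ndarray   # (S,)
    n_c: np.ndarray                # (S,)
    bond_events: np.ndarray        # (E, 4): step, ligand, old rec, new rec
    types: np.ndarray              # (n,)
    type_ids: list
    type_n_residues: np.ndarray
    type_radii: np.ndarray
    config: SimulationConfig
    final_state: SystemState | None = field(default=None, repr=False)

    @property
    def n_steps(self) -> int:
        return len(self.energy)

    @property
    def n_copies(self) -> int:
        return len(self.types)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["config"] = json.dumps(self.config.to_dict())
            f.attrs["config_hash"] = self.config.hash()
            f.attrs["type_ids"] = [str(s) for s in self.type_ids]
            for name in ("unwrapped", "bond_rec", "bond_pose", "energy",
                         "shift", "acceptance", "monomer_fraction", "n_c",
                         "bond_events", "types", "type_n_residues",
                         "type_radii"):
                f.create_dataset(name, data=getattr(self, name),
                                 track_times=False)

    @classmethod
    def load(cls, path) -> "Trajectory":
        with h5py.File(path, "r") as f:
            config = SimulationConfig(**json.loads(f.attrs["config"]))
            data = {name: f[name][...] for name in
                    ("unwrapped", "bond_rec", "bond_pose", "energy", "shift",
                     "acceptance", "monomer_fraction", "n_c", "bond_events",
                     "types", "type_n_residues", "type_radii")}
            type_ids = [str(s) for s in f.attrs["type_ids"]]
        return cls(config=config, type_ids=type_ids, **data)


def run_simulation(config: SimulationConfig, proteins, library,
                   plan=None, state: SystemState | None = None,
                   progress=None) -> Trajectory:
    """Run a full simulation and record per-step observables.

    When no ``state`` is given, a copy-count plan for the configured
    volume fraction is built and the initial lattice state generated from
    a seed stream derived from ``config.seed``; the run itself uses an
    independent stream, so runs are bit-reproducible per seed.
    ``progress(step, stats)`` is invoked after every step when given.
    """
    ss = np.random.SeedSequence(config.seed)
    init_ss, run_ss = ss.spawn(2)
    if state is None:
        if plan is None:
            plan = plan_copies(proteins, config.box, config.target_fraction)
        state = init_state(plan, proteins,
                           rng=np.random.default_rng(init_ss),
                           neighbor_margin=config.neighbor_margin,
                           collision_cutoff=config.collision_cutoff)
    rng = np.random.default_rng(run_ss)

    n = state.n
    steps = config.steps
    unwrapped = np.zeros((steps + 1, n, 3))
    bond_rec = np.full((steps + 1, n), -1, dtype=np.int32)
    bond_pose = np.full((steps + 1, n), -1, dtype=np.int32)
    energy = np.zeros(steps)
    shift = np.zeros(steps)
    acceptance = np.zeros(steps)
    monomer = np.zeros(steps)
    n_c = np.full(steps, np.nan)

    unwrapped[0] = state.unwrapped
    bond_rec[0] = state.out_rec
    bond_pose[0] = state.out_pose

    for s in range(steps):
        stats = run_step(state, library, config, rng)
        energy[s] = stats["energy"]
        shift[s] = stats["shift"]
        acceptance[s] = stats["acceptance_rate"]
        monomer[s] = float(
            np.mean((state.out_rec < 0) & (state.in_deg == 0)))
        if config.cluster_interval and (s + 1) % config.cluster_interval == 0:
            n_c[s] = _obs.cluster_stats(state.out_rec).n_c
        unwrapped[s + 1] = state.unwrapped
        bond_rec[s + 1] = state.out_rec
        bond_pose[s + 1] = state.out_pose
        if progress is not None:
            progress(s + 1, stats)

    events = (np.array(state.bond_events, dtype=np.int64)
              if state.bond_events else np.empty((0, 4), dtype=np.int64))
    return Trajectory(
        unwrapped=unwrapped, bond_rec=bond_rec, bond_pose=bond_pose,
        energy=energy, shift=shift, acceptance=acceptance,
        monomer_fraction=monomer, n_c=n_c, bond_events=events,
        types=state.types.copy(),
        type_ids=[p.id for p in state.proteins],
        type_n_residues=np.array([p.n_residues for p in state.proteins]),
        type_radii=np.array([p.radius for p in state.proteins]),
        config=config, final_state=state)
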