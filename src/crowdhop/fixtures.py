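"""Synthetic protein structures and hand-built toy systems.

Real crowding studies start from PDB structures; this module generates
stand-ins so the whole pipeline runs hermetically.  Synthetic globules
are compact self-avoiding C-alpha traces (3.8 A virtual bonds) with
pseudo side-chain atoms, whose radius scales like N^(1/3) as for real
globular proteins.  Toy scenarios provide enumerable systems with
hand-written pose libraries, small enough that the stationary
distribution of the Monte Carlo chain is known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

from .docking import PoseLibrary, PoseTable, RotationSet
from .engine import SimulationConfig
from .structures import CopyCountPlan, Protein, protein_volume
from .system import SystemState

__all__ = [
    "SyntheticSpec",
    "ToyScenario",
    "synthetic_protein",
    "synthetic_pdb",
    "build_toy_scenario",
    "fetch_pdb",
]

CA_BOND = 3.8          # virtual C-alpha bond length, Angstrom
MIN_CA_DIST = 3.6      # self-avoidance cutoff between non-bonded C-alphas
#: Empirical globule radius prefactor: ~130 A^3 per residue packed into a
#: sphere gives R ~ 3.15 * N^(1/3).
RADIUS_PREFACTOR = 3.15


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic protein-like structure."""

    n_residues: int
    shape: str = "globule"       # "globule" | "rod"
    seed: int = 0
    atoms_per_residue: int = 4   # CA plus pseudo side-chain atoms

    def __post_init__(self):
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if self.shape not in ("globule", "rod"):
            raise ValueError("shape must be 'globule' or 'rod'")
        if self.atoms_per_residue < 1:
            raise ValueError("need at least the C-alpha per residue")


def _walk(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Compact self-avoiding C-alpha walk; None on dead end."""
    n = spec.n_residues
    r_target = RADIUS_PREFACTOR * n ** (1.0 / 3.0)
    pts = np.zeros((n, 3))
    pts[0] = rng.uniform(-1, 1, 3)
    for k in range(1, n):
        prev = pts[k - 1]
        for _ in range(300):
            u = rng.normal(size=3)
            if spec.shape == "globule":
                u = u - 0.85 * prev / r_target
            else:
                u = u + np.array([0.0, 0.0, 1.2])
            u /= np.linalg.norm(u)
            cand = prev + CA_BOND * u
            if spec.shape == "globule":
                if np.linalg.norm(cand) > r_target:
                    continue
            elif np.linalg.norm(cand[:2]) > 8.0:
                continue
            if k > 1:
                d = np.linalg.norm(pts[:k - 1] - cand, axis=1)
                if d.min() < MIN_CA_DIST:
                    continue
            pts[k] = cand
            break
        else:
            return None
    return pts


_SIDE_NAMES = ["CB", "CG", "CD", "CE", "CZ", "CH"]


def synthetic_protein(spec: SyntheticSpec, with_volume: bool = True) -> Protein:
    """Generate a synthetic protein, deterministic under the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    trace = None
    for _ in range(60):
        trace = _walk(spec, rng)
        if trace is not None:
            break
    if trace is None:
        raise RuntimeError(
            f"self-avoiding walk failed for n={spec.n_residues}")

    coords, elements, names, resid = [], [], [], []
    for k, ca in enumerate(trace):
        coords.append(ca)
        elements.append("C")
        names.append("CA")
        resid.append(k)
        for s in range(spec.atoms_per_residue - 1):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            coords.append(ca + 1.6 * u)
            elements.append("C")
            names.append(_SIDE_NAMES[s % len(_SIDE_NAMES)])
            resid.append(k)

    p = Protein(
        id=f"syn{spec.n_residues}s{spec.seed}"
           + ("r" if spec.shape == "rod" else ""),
        atom_coords=np.array(coords),
        atom_elements=elements,
        atom_names=names,
        atom_resid=np.array(resid, dtype=int),
        calphas=trace,
    )
    if with_volume:
        p = p.with_volume(protein_volume(p))
    return p


def synthetic_pdb(spec: SyntheticSpec) -> str:
    """The same synthetic structure as PDB-format text."""
    p = synthetic_protein(spec, with_volume=False)
    st = gemmi.Structure()
    st.name = p.id
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    res = None
    last = -1
    for k in range(len(p.atom_coords)):
        ir = int(p.atom_resid[k])
        if ir != last:
            if res is not None:
                chain.add_residue(res)
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(ir + 1, " ")
            res.het_flag = "A"
            last = ir
        atom = gemmi.Atom()
        atom.name = p.atom_names[k]
        atom.element = gemmi.Element(p.atom_elements[k])
        atom.pos = gemmi.Position(*p.atom_coords[k])
        atom.occ = 1.0
        atom.b_iso = 0.0
        res.add_atom(atom)
    chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


# --------------------------------------------------------------------------
# toy scenarios

@dataclass
class ToyScenario:
    """A hand-built enumerable system with a known stationary law."""

    name: str
    proteins: list
    library: PoseLibrary
    config: SimulationConfig
    state: SystemState
    pose_energies: np.ndarray
    description: str = ""
    plan: CopyCountPlan | None = field(default=None)

    def boltzmann_weights(self, temperature: float) -> np.ndarray:
        """Normalized stationary weights over the single-ligand pose states."""
        w = np.exp(-self.pose_energies / temperature)
        return w / w.sum()


def _toy_protein(tag: str, scale: float = 1.0) -> Protein:
    # small tetrahedral CA cage, radius ~2.3 * scale
    verts = np.array([
        [0.0, 0.0, 0.0],
        [3.8, 0.0, 0.0],
        [1.9, 3.29, 0.0],
        [1.9, 1.10, 3.10],
    ]) * scale
    return Protein(
        id=tag,
        atom_coords=verts,
        atom_elements=["C"] * 4,
        atom_names=["CA"] * 4,
        atom_resid=np.arange(4),
        calphas=verts,
    ).with_volume(protein_volume(Protein(
        id=tag, atom_coords=verts, atom_elements=["C"] * 4,
        atom_names=["CA"] * 4, atom_resid=np.arange(4), calphas=verts)))


def _identity_rotations() -> RotationSet:
    return RotationSet(quats=np.array([[0.0, 0.0, 0.0, 1.0]]),
                       matrices=np.eye(3)[None, :, :], spacing=90.0)


def _hand_library(n_types: int, disps, scores) -> PoseLibrary:
    disps = np.asarray(disps, dtype=float)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="stable")
    table = PoseTable(
        rot_index=np.zeros(len(scores), dtype=np.int32),
        trans=np.zeros((len(scores), 3), dtype=np.int32),
        score=scores[order],
        disp=disps[order],
    )
    pairs = {(i, j): table for i in range(n_types) for j in range(n_types)}
    return PoseLibrary(rotations=_identity_rotations(), pairs=pairs,
                       ids=[f"toy{t}" for t in range(n_types)],
                       params={"hand_built": True})


def build_toy_scenario(name: str, temperature: float = 100.0,
                       seed: int = 0, n_copies: int = 100,
                       box: float = 120.0) -> ToyScenario:
    """Build one of the named toy systems.

    ``two_state``: two molecules, two poses with energies -100 and -50;
    the stationary pose-occupancy ratio is exp(50/T) exactly.
    ``uniform_walk``: ``n_copies`` molecules with an equal-energy pose
    library and collisions disabled, so the dynamics is a pure random
    walk between docking sites.
    ``frozen_pair``: one deep minimum at -10000 next to a shallow -50
    one; at low temperature the system freezes into the deep pose.
    """
    if name == "two_state":
        p = _toy_protein("toy0")
        lib = _hand_library(1, disps=[[10.0, 0, 0], [0, 10.0, 0]],
                            scores=[100.0, 50.0])
        pose_e = -lib.table(0, 0).score
        cfg = SimulationConfig(
            box=120.0, target_fraction=0.1, temperature=temperature,
            steps=0, seed=seed, cluster_interval=0, msd_reference_step=0)
        state = SystemState(
            [p], [0, 0],
            pos=np.array([[30.0, 30.0, 30.0], [50.0, 30.0, 30.0]]),
            rot=np.stack([np.eye(3)] * 2), box=cfg.box,
            collision_cutoff=cfg.collision_cutoff)
        return ToyScenario(
            name=name, proteins=[p], library=lib, config=cfg, state=state,
            pose_energies=pose_e,
            description="two molecules, two poses: exact Boltzmann ratio")

    if name == "uniform_walk":
        p = _toy_protein("toy0")
        rng = np.random.default_rng(12345)   # library geometry, not dynamics
        u = rng.normal(size=(16, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        # antipodal pairs: the hop set is exactly zero-mean, otherwise
        # docked clusters (whose orientations homogenize) drift ballistically.
        # Hops span a good fraction of the neighbor shell so that in a dense
        # crowd consecutive hops land in fresh neighborhoods and decorrelate,
        # making the dynamics an ideal random walk.
        u = np.vstack([u, -u])
        lib = _hand_library(1, disps=40.0 * u, scores=np.full(32, 10.0))
        pose_e = -lib.table(0, 0).score
        m = int(np.ceil(n_copies ** (1 / 3)))
        plan = CopyCountPlan(
            counts=(n_copies,), lattice_step=box / m,
            realized_fraction=n_copies * p.volume / box ** 3,
            box=box, target_fraction=n_copies * p.volume / box ** 3)
        cfg = SimulationConfig(
            box=box, target_fraction=plan.target_fraction,
            temperature=temperature, steps=0, seed=seed,
            collision_cutoff=0.0, cluster_interval=0)
        from .system import init_state
        state = init_state(plan, [p], rng=np.random.default_rng(seed),
                           collision_cutoff=0.0)
        return ToyScenario(
            name=name, proteins=[p], library=lib, config=cfg, state=state,
            pose_energies=pose_e, plan=plan,
            description="equal-energy poses, collisions off: random walk")

    if name == "frozen_pair":
        p = _toy_protein("toy0")
        lib = _hand_library(1, disps=[[10.0, 0, 0], [0, 10.0, 0]],
                            scores=[10_000.0, 50.0])
        pose_e = -lib.table(0, 0).score
        cfg = SimulationConfig(
            box=120.0, target_fraction=0.1, temperature=temperature,
            steps=0, seed=seed, cluster_interval=0, msd_reference_step=0)
        state = SystemState(
            [p], [0, 0],
            pos=np.array([[30.0, 30.0, 30.0], [50.0, 30.0, 30.0]]),
            rot=np.stack([np.eye(3)] * 2), box=cfg.box,
            collision_cutoff=cfg.collision_cutoff)
        return ToyScenario(
            name=name, proteins=[p], library=lib, config=cfg, state=state,
            pose_energies=pose_e,
            description="deep -10000 minimum: frozen at low temperature")

    raise ValueError(f"unknown toy scenario: {name!r}")


def fetch_pdb(code: str, dest_dir=".") -> str:
    """Download a PDB entry from RCSB (convenience only; never required).

    Returns the path of the written file.  All tests and examples run on
    synthetic structures; this helper exists for users who want to
    reproduce runs on real proteins.
    """
    import urllib.request
    from pathlib import Path

    code = code.lower()
    url = f"https://files.rcsb.org/download/{code}.pdb"
    dest = Path(dest_dir) / f"{code}.pdb"
    with urllib.request.urlopen(url, timeout=60) as r:
        dest.write_bytes(r.read())
    return str(dest)
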