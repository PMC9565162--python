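"""Periodic-box system state: placement, wrapping, neighbor search.

The simulated system is a cubic box with periodic boundary conditions
holding rigid copies of a few protein types.  Each copy carries a
rotation matrix, a wrapped position, an unwrapped position (for mean
squared displacement), and its current docking bond.  The initial state
tiles the box with a cubic lattice, assigns copies to random sites with
uniform random orientations and a sub-lattice jitter, and applies no
collision check: residual overlaps are resolved by the first Monte Carlo
moves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

__all__ = [
    "MoleculeState",
    "SystemState",
    "CellList",
    "min_image",
    "wrap_positions",
    "init_state",
    "neighbors",
    "write_snapshot_pdb",
]

DEFAULT_NEIGHBOR_MARGIN = 50.0

# below this copy count a vectorized all-pairs scan beats a cell list
BRUTE_FORCE_LIMIT = 1024


def min_image(d, box: float):
    """Map displacement components into the interval (-box/2, box/2].

    The boundary convention assigns exactly +box/2 to the tie.
    """
    d = np.asarray(d, dtype=float)
    return d - box * np.ceil(d / box - 0.5)


def wrap_positions(pos, box: float):
    """Wrap absolute positions into [0, box)."""
    return np.mod(pos, box)


@dataclass(frozen=True)
class MoleculeState:
    """Read-only snapshot of one molecular copy."""

    copy_id: int
    type_id: int
    rotation: np.ndarray
    position: np.ndarray          # wrapped, [0, box)
    unwrapped: np.ndarray
    bond_receptor: int            # -1 when this copy owns no docking match
    bond_pose: int
    energy: float


class CellList:
    """Uniform-grid spatial index over wrapped positions.

    Cells are at least ``cutoff`` wide so any pair within ``cutoff`` lies
    in adjacent cells.  Falls back to "all candidates" when the box holds
    fewer than 3 cells per side, where the 27-cell stencil would not be
    smaller than the whole box.
    """

    def __init__(self, box: float, cutoff: float, positions: np.ndarray):
        self.box = float(box)
        self.m = max(1, int(box // cutoff))
        self.degenerate = self.m < 3
        self.cell_width = box / self.m
        n = len(positions)
        self.cells = {}
        self.cell_of = np.zeros(n, dtype=np.int64)
        if not self.degenerate:
            for i, p in enumerate(positions):
                c = self._key(p)
                self.cell_of[i] = c
                self.cells.setdefault(c, []).append(i)
        self.n = n
        # precomputed 27-stencil offsets in flat key space
        r = np.array([-1, 0, 1])
        self._stencil = np.stack(np.meshgrid(r, r, r, indexing="ij"),
                                 axis=-1).reshape(-1, 3)

    def _key(self, p) -> int:
        ix = np.minimum((np.asarray(p) / self.cell_width).astype(int), self.m - 1)
        return int(ix[0] * self.m * self.m + ix[1] * self.m + ix[2])

    def query(self, p) -> np.ndarray:
        """Indices of all copies in the 27 cells around point ``p``."""
        if self.degenerate:
            return np.arange(self.n)
        ix = np.minimum((np.asarray(p) / self.cell_width).astype(int), self.m - 1)
        out = []
        for off in self._stencil:
            c = (ix + off) % self.m
            key = int(c[0] * self.m * self.m + c[1] * self.m + c[2])
            got = self.cells.get(key)
            if got:
                out.extend(got)
        return np.array(out, dtype=np.int64)

    def move(self, i: int, new_pos) -> None:
        if self.degenerate:
            return
        new_key = self._key(new_pos)
        old_key = int(self.cell_of[i])
        if new_key != old_key:
            self.cells[old_key].remove(i)
            self.cells.setdefault(new_key, []).append(i)
            self.cell_of[i] = new_key


class SystemState:
    """Mutable state of all copies in the periodic box.

    Holds flat per-copy arrays (types, rotation matrices, wrapped and
    unwrapped positions, per-copy energies) plus the directed bond graph:
    every copy owns at most one outgoing docking match (``out_rec``) and
    any number of incoming ones (counted by ``in_deg``).  Per-copy energy
    is the sum of the energies of all matches the copy participates in,
    so the per-copy energies double count each bond.
    """

    def __init__(self, proteins, types, pos, rot, box,
                 neighbor_margin: float = DEFAULT_NEIGHBOR_MARGIN,
                 collision_cutoff: float = 8.0,
                 unwrapped=None):
        n = len(types)
        self.proteins = list(proteins)
        self.types = np.asarray(types, dtype=np.int32)
        self.pos = np.asarray(pos, dtype=float).copy()
        self.rot = np.asarray(rot, dtype=float).copy()
        self.box = float(box)
        self.inv_box = 1.0 / self.box
        self.neighbor_margin = float(neighbor_margin)
        self.collision_cutoff = float(collision_cutoff)
        self.unwrapped = (self.pos.copy() if unwrapped is None
                          else np.asarray(unwrapped, dtype=float).copy())
        self.energy = np.zeros(n)
        self.out_rec = np.full(n, -1, dtype=np.int32)
        self.out_pose = np.full(n, -1, dtype=np.int32)
        self.out_energy = np.zeros(n)
        self.in_deg = np.zeros(n, dtype=np.int32)
        self.total_energy = 0.0
        self.step = 0
        self.bond_events = []

        type_radii = np.array([p.radius for p in self.proteins])
        self.radii = type_radii[self.types]
        ntypes = len(self.proteins)
        # per-ligand-type squared neighbor cutoffs against every copy
        self.pair_cut2 = np.stack([
            (type_radii[t] + self.radii + self.neighbor_margin) ** 2
            for t in range(ntypes)])
        self.coll_cut2 = np.stack([
            (type_radii[t] + self.radii + max(self.collision_cutoff, 0.0)) ** 2
            for t in range(ntypes)])
        self.ca_templates = [p.calphas_centered() for p in self.proteins]
        self.ca_world = [
            self.pos[i] + self.ca_templates[self.types[i]] @ self.rot[i].T
            for i in range(n)]
        max_cut = float(np.sqrt(self.pair_cut2.max()))
        if n > BRUTE_FORCE_LIMIT:
            self.cells = CellList(self.box, max_cut, self.pos)
        else:
            self.cells = None

    @property
    def n(self) -> int:
        return len(self.types)

    def molecule(self, i: int) -> MoleculeState:
        return MoleculeState(
            copy_id=i, type_id=int(self.types[i]),
            rotation=self.rot[i].copy(), position=self.pos[i].copy(),
            unwrapped=self.unwrapped[i].copy(),
            bond_receptor=int(self.out_rec[i]), bond_pose=int(self.out_pose[i]),
            energy=float(self.energy[i]))

    def recompute_energies(self):
        """Per-copy energies recomputed from the bond graph (oracle path)."""
        e = np.zeros(self.n)
        for i in range(self.n):
            j = self.out_rec[i]
            if j >= 0:
                e[i] += self.out_energy[i]
                e[j] += self.out_energy[i]
        return e


def init_state(plan, proteins, seed: int = 0,
               neighbor_margin: float = DEFAULT_NEIGHBOR_MARGIN,
               collision_cutoff: float = 8.0,
               rng: np.random.Generator | None = None) -> SystemState:
    """Build the initial state from a copy-count plan.

    Copies are assigned to random distinct sites of the cubic lattice,
    given uniform random orientations (normalized Gaussian quaternions)
    and a uniform jitter within half a lattice step per axis.  No
    collision check is applied; overlaps anneal out during early MC.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    box = plan.box
    total = plan.total
    m = math.ceil(total ** (1 / 3) - 1e-9)
    if total > m ** 3:
        raise ValueError("more copies than lattice sites")
    lstep = box / m

    sites = rng.choice(m ** 3, size=total, replace=False)
    ix = np.stack(np.unravel_index(sites, (m, m, m)), axis=1)
    centers = (ix + 0.5) * lstep
    jitter = rng.uniform(-lstep / 2, lstep / 2, size=(total, 3))
    pos = wrap_positions(centers + jitter, box)

    q = rng.normal(size=(total, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    from scipy.spatial.transform import Rotation
    rot = Rotation.from_quat(q).as_matrix()

    types = np.repeat(np.arange(len(plan.counts), dtype=np.int32), plan.counts)
    return SystemState(proteins, types, pos, rot, box,
                       neighbor_margin=neighbor_margin,
                       collision_cutoff=collision_cutoff)


def neighbors(state: SystemState, i: int, position=None,
              method: str = "auto") -> np.ndarray:
    """Copies within the docking neighborhood of copy ``i``.

    Copy ``j`` is a neighbor when the minimum-image center distance is
    below ``r_i + r_j + margin``.  ``position`` overrides the query point
    (used to count moves available from a proposed placement).  ``method``
    selects the candidate search: ``"cells"`` forces the cell list,
    ``"brute"`` the all-pairs scan, ``"auto"`` picks by system size.
    """
    t = int(state.types[i])
    p = state.pos[i] if position is None else np.asarray(position, float)
    cut2 = state.pair_cut2[t]
    use_cells = (method == "cells" or
                 (method == "auto" and state.cells is not None))
    if use_cells:
        cells = state.cells
        if cells is None:
            cells = CellList(state.box, float(np.sqrt(state.pair_cut2.max())),
                             state.pos)
        cand = cells.query(p)
        d = state.pos[cand] - p
        d -= state.box * np.rint(d * state.inv_box)
        d2 = np.einsum("ij,ij->i", d, d)
        mask = (d2 < cut2[cand]) & (cand != i)
        return np.sort(cand[mask])
    d = state.pos - p
    d -= state.box * np.rint(d * state.inv_box)
    d2 = np.einsum("ij,ij->i", d, d)
    mask = d2 < cut2
    mask[i] = False
    return np.flatnonzero(mask)


_CHAIN_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


def write_snapshot_pdb(state: SystemState, path) -> None:
    """Export the current state as a PDB snapshot (CA trace per copy).

    Copies become separate chains (names recycled through an alphabet)
    with the copy index in the segment id, which is enough for quick
    visual inspection of the box.
    """
    st = gemmi.Structure()
    st.name = "snapshot"
    model = gemmi.Model("1")
    for i in range(state.n):
        chain = gemmi.Chain(_CHAIN_ALPHABET[i % len(_CHAIN_ALPHABET)])
        t = int(state.types[i])
        ca = state.pos[i] + state.ca_templates[t] @ state.rot[i].T
        for k, xyz in enumerate(ca):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(k + 1, " ")
            res.het_flag = "A"
            res.segment = str(i)
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
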