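"""Protein structure input and geometry.

Reads rigid protein structures from PDB files and derives the geometric
quantities that the docking and simulation layers consume: the ordered
C-alpha trace, the geometric center, a bounding radius, and an estimated
molecular volume.  Also plans how many copies of each protein type are
needed to reach a target volume fraction inside a cubic periodic box.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Protein",
    "CopyCountPlan",
    "read_pdb",
    "protein_volume",
    "plan_copies",
    "protein_summary",
]

#: Van der Waals radii (Angstrom) used by the voxel volume estimator.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
    "SE": 1.90,
}
DEFAULT_VDW = 1.70

#: Water-probe inflation (Angstrom) applied to atom spheres when voxelizing.
DEFAULT_PROBE = 1.4


@dataclass(frozen=True)
class Protein:
    """A rigid protein: coordinates plus derived geometry.

    Attributes
    ----------
    id : str
        Short name, typically the PDB code or a synthetic label.
    atom_coords : (A, 3) float array
        Coordinates of all heavy atoms, Angstrom.
    atom_elements : list of str
        Element symbol per atom.
    atom_names : list of str
        Atom name per atom (``CA``, ``CB``, ...).
    atom_resid : (A,) int array
        Residue index per atom (consecutive over chains).
    calphas : (N, 3) float array
        Ordered C-alpha trace, Angstrom.
    center : (3,) float array
        Geometric center of all atoms.
    radius : float
        Maximum center-to-atom distance: a bounding radius, used by the
        docking neighbor rule so no pose can fall outside the search shell.
    volume : float
        Estimated molecular volume, Angstrom^3 (voxelized union of spheres).
    """

    id: str
    atom_coords: np.ndarray
    atom_elements: list
    atom_names: list
    atom_resid: np.ndarray
    calphas: np.ndarray
    center: np.ndarray = field(default=None)
    radius: float = field(default=None)
    volume: float = field(default=None)

    def __post_init__(self):
        coords = np.asarray(self.atom_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) == 0:
            raise ValueError("atom_coords must be a non-empty (A, 3) array")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite atom coordinates")
        object.__setattr__(self, "atom_coords", coords)
        object.__setattr__(self, "calphas", np.asarray(self.calphas, dtype=float))
        center = coords.mean(axis=0)
        if self.center is None:
            object.__setattr__(self, "center", center)
        radius = float(np.linalg.norm(coords - self.center, axis=1).max())
        if self.radius is None:
            object.__setattr__(self, "radius", radius)

    @property
    def n_residues(self) -> int:
        return len(self.calphas)

    @property
    def atoms(self):
        """Atom records as (residue index, name, element, xyz) tuples."""
        return [
            (int(self.atom_resid[k]), self.atom_names[k], self.atom_elements[k],
             tuple(self.atom_coords[k]))
            for k in range(len(self.atom_coords))
        ]

    def with_volume(self, volume: float) -> "Protein":
        return Protein(
            id=self.id,
            atom_coords=self.atom_coords,
            atom_elements=self.atom_elements,
            atom_names=self.atom_names,
            atom_resid=self.atom_resid,
            calphas=self.calphas,
            center=self.center,
            radius=self.radius,
            volume=volume,
        )

    def calphas_centered(self) -> np.ndarray:
        """C-alpha trace relative to the geometric center."""
        return self.calphas - self.center


def read_pdb(path, id: str | None = None, with_volume: bool = True,
             voxel: float = 1.0) -> Protein:
    """Read a protein from a PDB file.

    Uses the first model; all chains are concatenated into one rigid
    molecule.  HETATM records (ligands, waters) and hydrogens are dropped;
    alternate conformations are resolved to the first one.  Residues
    lacking a C-alpha are excluded from the trace (with a warning) but
    their atoms still contribute to the center/radius/volume.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.remove_alternative_conformations()
    st.remove_hydrogens()
    st.remove_ligands_and_waters()
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]

    coords, elements, names, resid = [], [], [], []
    calphas = []
    ires = 0
    for chain in model:
        for res in chain:
            if res.het_flag == "H":
                continue
            ca = None
            got_atom = False
            for atom in res:
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name.upper())
                names.append(atom.name)
                resid.append(ires)
                got_atom = True
                if atom.name == "CA":
                    ca = [atom.pos.x, atom.pos.y, atom.pos.z]
            if not got_atom:
                continue
            if ca is None:
                warnings.warn(
                    f"{path.name}: residue {chain.name}/{res.seqid.num} "
                    f"({res.name}) has no CA; excluded from the trace")
            else:
                calphas.append(ca)
            ires += 1

    if not coords:
        raise ValueError(f"{path}: no ATOM records")

    p = Protein(
        id=id or path.stem,
        atom_coords=np.array(coords, dtype=float),
        atom_elements=elements,
        atom_names=names,
        atom_resid=np.array(resid, dtype=int),
        calphas=np.array(calphas, dtype=float).reshape(-1, 3),
    )
    if with_volume:
        p = p.with_volume(protein_volume(p, voxel=voxel))
    return p


def protein_volume(p: Protein, voxel: float = 1.0, probe: float = DEFAULT_PROBE,
                   radii=None) -> float:
    """Molecular volume by voxelized union of atom spheres, Angstrom^3.

    Counts voxels whose center lies within ``vdW radius + probe`` of any
    atom.  The voxel lattice is anchored at the world origin (centers at
    ``(k + 1/2) * voxel``), which makes the estimate deterministic and
    monotone under addition of atoms, and exactly additive for disjoint
    copies shifted by whole voxels.

    ``radii`` may be a scalar (uniform radius for all atoms) or a mapping
    from element symbol to radius; default is a van der Waals table.
    """
    if voxel <= 0:
        raise ValueError("voxel must be positive")
    coords = p.atom_coords
    if np.isscalar(radii) and radii is not None:
        r = np.full(len(coords), float(radii))
    else:
        table = VDW_RADII if radii is None else radii
        r = np.array([table.get(e, DEFAULT_VDW) for e in p.atom_elements])
    r = r + probe

    span = (coords.max(axis=0) + r.max()) - (coords.min(axis=0) - r.max())
    if voxel > span.max():
        raise ValueError(
            f"voxel {voxel} exceeds protein extent {span.max():.2f}: "
            "degenerate volume estimate")

    lo = np.floor((coords.min(axis=0) - r.max()) / voxel).astype(int) - 1
    hi = np.ceil((coords.max(axis=0) + r.max()) / voxel).astype(int) + 1
    dims = hi - lo
    occ = np.zeros(dims, dtype=bool)
    for (x, y, z), rad in zip(coords, r):
        # index window of voxels possibly inside this sphere
        i0 = np.floor((np.array([x, y, z]) - rad) / voxel).astype(int)
        i1 = np.ceil((np.array([x, y, z]) + rad) / voxel).astype(int)
        ax = [np.arange(i0[k], i1[k] + 1) for k in range(3)]
        cx = (ax[0] + 0.5) * voxel - x
        cy = (ax[1] + 0.5) * voxel - y
        cz = (ax[2] + 0.5) * voxel - z
        d2 = cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
        sl = tuple(slice(i0[k] - lo[k], i1[k] + 1 - lo[k]) for k in range(3))
        occ[sl] |= d2 <= rad * rad
    return float(occ.sum()) * voxel ** 3


@dataclass(frozen=True)
class CopyCountPlan:
    """Copy counts per protein type for a target volume fraction."""

    counts: tuple            # copies per type, aligned with the input order
    lattice_step: float      # placement lattice step, Angstrom
    realized_fraction: float
    box: float
    target_fraction: float

    @property
    def total(self) -> int:
        return int(sum(self.counts))


def plan_copies(proteins, box: float, target_v: float) -> CopyCountPlan:
    """Plan copy counts so the box reaches a target volume fraction.

    The total count is ``round(V * box^3 / mean type volume)``, split into
    equal shares per type (remainder assigned to the first types in input
    order), and the placement lattice step is chosen so a cubic grid holds
    all copies.
    """
    if not 0 < target_v < 0.74:
        raise ValueError("target volume fraction must be in (0, 0.74)")
    vols = [p.volume for p in proteins]
    if any(v is None or v <= 0 for v in vols):
        raise ValueError("all proteins need a positive volume estimate")
    max_diam = 2 * max(p.radius for p in proteins)
    if box <= 2 * max_diam:
        raise ValueError(
            f"box {box} must exceed twice the largest protein diameter "
            f"({max_diam:.1f})")

    k = len(proteins)
    mean_vol = float(np.mean(vols))
    total = int(round(target_v * box ** 3 / mean_vol))
    if total < 1:
        raise ValueError("target volume fraction yields zero copies")
    base, rem = divmod(total, k)
    counts = tuple(base + (1 if i < rem else 0) for i in range(k))
    m = math.ceil(total ** (1 / 3) - 1e-9)
    lattice_step = box / m
    realized = float(sum(c * v for c, v in zip(counts, vols)) / box ** 3)
    return CopyCountPlan(
        counts=counts,
        lattice_step=lattice_step,
        realized_fraction=realized,
        box=float(box),
        target_fraction=float(target_v),
    )


def protein_summary(proteins) -> pd.DataFrame:
    """Per-protein table (id, n_residues, radius, volume)."""
    return pd.DataFrame(
        {
            "id": [p.id for p in proteins],
            "n_residues": [p.n_residues for p in proteins],
            "radius": [p.radius for p in proteins],
            "volume": [p.volume for p in proteins],
        }
    )
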