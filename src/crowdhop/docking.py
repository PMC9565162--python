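"""Rigid-body pose library generation by FFT correlation docking.

For every ordered (ligand, receptor) pair of protein types a ranked
library of rigid-body docking poses is precomputed once and then sampled
during the Monte Carlo run.  Scoring follows the classic grid-correlation
scheme: the receptor is rasterized with a thin attractive surface layer
(+1) over a repulsive core (-rho), the ligand as an occupancy indicator
(+1), and the score of a relative translation is the overlap correlation,
evaluated for all translations at once with an FFT.  This is a
step-function approximation of a Lennard-Jones contact potential: surface
contact is rewarded, core interpenetration is penalized.  Pose energies
are the negated scores, so docked states are negative-energy minima and
the unbound state sits at zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

__all__ = [
    "RotationSet",
    "ScoreGrid",
    "Pose",
    "PoseTable",
    "PoseLibrary",
    "build_rotation_set",
    "rasterize",
    "correlate",
    "dock_pair",
    "build_library",
    "pose_to_transform",
    "transform_to_pose",
]

# Default docking parameters: intermediate-resolution regime for unbound
# docking (coarse 3.5 A grid, strong core repulsion, ~10 degree rotations).
DEFAULT_STEP = 3.5
DEFAULT_RHO = 9.0
DEFAULT_SPACING = 10.0
DEFAULT_TOP_K = 30_000
DEFAULT_PER_ROTATION = 50

#: Uniform occupancy radius for rasterization (Angstrom, before grid smear).
ATOM_RADIUS = 1.7

# Super-Fibonacci spiral constants (quasi-uniform points on S^3).
_PHI = math.sqrt(2.0)
_PSI = 1.533751168755204288118041
# Oversampling factor relating requested covering radius to sample count;
# calibrated so the empirical covering radius stays below the nominal
# spacing for spacings between 10 and 90 degrees.
_COVER_FACTOR = 3.8


@dataclass(frozen=True)
class RotationSet:
    """Deterministic quasi-uniform sampling of SO(3).

    ``matrices[0]`` is always the identity.  ``spacing`` is the nominal
    covering radius in degrees: every rotation is within ``spacing`` of
    some member (relative-rotation angle).
    """

    quats: np.ndarray       # (M, 4) unit quaternions, scalar-last
    matrices: np.ndarray    # (M, 3, 3)
    spacing: float          # nominal covering radius, degrees

    def __len__(self) -> int:
        return len(self.quats)


def _super_fibonacci(n: int) -> np.ndarray:
    s = np.arange(n) + 0.5
    t = s / n
    d = 2 * np.pi * s
    r = np.sqrt(t)
    big_r = np.sqrt(1.0 - t)
    alpha = d / _PHI
    beta = d / _PSI
    return np.stack(
        [r * np.sin(alpha), r * np.cos(alpha),
         big_r * np.sin(beta), big_r * np.cos(beta)], axis=1)


def build_rotation_set(spacing: float = DEFAULT_SPACING) -> RotationSet:
    """Build a covering of SO(3) with nominal angular spacing in degrees.

    Uses a super-Fibonacci spiral on the quaternion 3-sphere, which is
    deterministic and close to uniform under the Haar measure.  The number
    of samples is chosen from the Haar volume of a geodesic ball of radius
    ``spacing`` with a fixed oversampling factor, and the identity is
    prepended at index 0.
    """
    if not 0 < spacing <= 90:
        raise ValueError("spacing must be in (0, 90] degrees")
    delta = math.radians(spacing)
    # fraction of SO(3) within angle delta of a rotation: (delta - sin delta)/pi
    n = int(math.ceil(_COVER_FACTOR * math.pi / (delta - math.sin(delta))))
    quats = np.vstack([np.array([[0.0, 0.0, 0.0, 1.0]]), _super_fibonacci(n)])
    matrices = Rotation.from_quat(quats).as_matrix()
    matrices[0] = np.eye(3)
    return RotationSet(quats=quats, matrices=matrices, spacing=float(spacing))


@dataclass(frozen=True)
class ScoreGrid:
    """Rasterized molecule on a cubic grid.

    ``origin`` is the position (Angstrom, in the molecule's center frame)
    of the center of cell (0, 0, 0).  Receptor grids hold +1 on the
    one-cell surface layer and ``-rho`` in the core; ligand grids hold +1
    on occupied cells.  A one-cell empty boundary layer is guaranteed.
    """

    origin: np.ndarray
    step: float
    values: np.ndarray
    role: str


def _occupancy(coords: np.ndarray, step: float, radius: float):
    lo = np.floor((coords.min(axis=0) - radius) / step).astype(int) - 1
    hi = np.ceil((coords.max(axis=0) + radius) / step).astype(int) + 1
    dims = hi - lo + 1
    occ = np.zeros(dims, dtype=bool)
    for x, y, z in coords:
        i0 = np.floor((np.array([x, y, z]) - radius) / step).astype(int)
        i1 = np.ceil((np.array([x, y, z]) + radius) / step).astype(int)
        ax = [np.arange(i0[k], i1[k] + 1) for k in range(3)]
        cx = (ax[0] + 0.5) * step - x
        cy = (ax[1] + 0.5) * step - y
        cz = (ax[2] + 0.5) * step - z
        d2 = cx[:, None, None] ** 2 + cy[None, :, None] ** 2 + cz[None, None, :] ** 2
        sl = tuple(slice(i0[k] - lo[k], i1[k] + 1 - lo[k]) for k in range(3))
        occ[sl] |= d2 <= radius * radius
    # the cell holding each atom is always occupied, so a very coarse grid
    # still rasterizes to at least one cell per atom
    own = np.floor(coords / step).astype(int) - lo
    occ[own[:, 0], own[:, 1], own[:, 2]] = True
    origin = (lo + 0.5) * step
    return occ, origin


def rasterize(p, rot: np.ndarray, step: float = DEFAULT_STEP,
              role: str = "ligand", rho: float = DEFAULT_RHO) -> ScoreGrid:
    """Rasterize a rotated protein onto a score grid.

    The protein is rotated about its geometric center.  Occupied cells are
    those whose center lies within ``ATOM_RADIUS + step/2`` of any atom
    (the half-step smear compensates for the coarse lattice).  For the
    receptor role, occupied cells with at least one empty 6-neighbor form
    the +1 surface layer; deeper occupied cells get ``-rho``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if role not in ("receptor", "ligand"):
        raise ValueError("role must be 'receptor' or 'ligand'")
    if role == "receptor" and rho <= 0:
        raise ValueError("rho must be positive")
    coords = (np.asarray(rot, dtype=float) @ (p.atom_coords - p.center).T).T
    occ, origin = _occupancy(coords, step, ATOM_RADIUS + step / 2.0)
    if not occ.any():
        raise ValueError("rasterization produced no occupied cells")

    if role == "ligand":
        values = occ.astype(np.float64)
    else:
        empty = ~occ
        surface = np.zeros_like(occ)
        for axis in range(3):
            for shift in (1, -1):
                surface |= occ & np.roll(empty, shift, axis=axis)
        # boundary layer is empty by construction, so np.roll wraparound
        # never marks spurious surface
        core = occ & ~surface
        values = surface.astype(np.float64) - rho * core.astype(np.float64)
    return ScoreGrid(origin=origin, step=float(step), values=values, role=role)


def _is_integral(a: np.ndarray) -> bool:
    return bool(np.array_equal(a, np.rint(a)))


def correlate(receptor: ScoreGrid, ligand: ScoreGrid) -> np.ndarray:
    """Correlation score for every integer translation of the ligand grid.

    Returns the full linear (zero-padded) cross-correlation ``c`` with
    ``c[k] = sum_x rec[x] * lig[x - t]`` where ``t = k - (lig_dims - 1)``.
    When both grids are integer-valued the FFT result is rounded back to
    exact integers; when the receptor holds a non-integral ``-rho`` the
    surface and core channels are correlated separately so each channel
    stays exact.
    """
    if abs(receptor.step - ligand.step) > 1e-12:
        raise ValueError("incompatible grid steps")
    rec = receptor.values.astype(np.float64)
    lig = ligand.values.astype(np.float64)
    if _is_integral(lig):
        if _is_integral(rec):
            return np.rint(signal.correlate(rec, lig, mode="full", method="fft"))
        pos = np.clip(rec, 0.0, None)
        neg = np.clip(-rec, 0.0, None)
        pos_m = pos.max() if pos.max() > 0 else 1.0
        neg_m = neg.max() if neg.max() > 0 else 1.0
        if _is_integral(pos / pos_m) and _is_integral(neg / neg_m):
            cp = np.rint(signal.correlate(pos / pos_m, lig, "full", "fft"))
            cn = np.rint(signal.correlate(neg / neg_m, lig, "full", "fft"))
            return pos_m * cp - neg_m * cn
    return signal.correlate(rec, lig, mode="full", method="fft")


@dataclass(frozen=True)
class Pose:
    """A single docking pose of a ligand relative to a receptor frame."""

    rot_index: int
    trans: tuple          # integer grid translation (3,)
    score: float
    disp: tuple           # ligand-center displacement, Angstrom, pair frame

    @property
    def energy(self) -> float:
        return -self.score


@dataclass
class PoseTable:
    """Ranked docking poses for one ordered (ligand, receptor) pair."""

    rot_index: np.ndarray   # (K,) int
    trans: np.ndarray       # (K, 3) int
    score: np.ndarray       # (K,) float, descending
    disp: np.ndarray        # (K, 3) float, Angstrom

    def __len__(self) -> int:
        return len(self.score)

    @property
    def energy(self) -> np.ndarray:
        return -self.score

    def pose(self, k: int) -> Pose:
        return Pose(
            rot_index=int(self.rot_index[k]),
            trans=tuple(int(v) for v in self.trans[k]),
            score=float(self.score[k]),
            disp=tuple(float(v) for v in self.disp[k]),
        )


def dock_pair(ligand, receptor, step: float = DEFAULT_STEP,
              rho: float = DEFAULT_RHO, spacing: float = DEFAULT_SPACING,
              top_k: int = DEFAULT_TOP_K,
              per_rotation: int = DEFAULT_PER_ROTATION,
              rotations: RotationSet | None = None) -> PoseTable:
    """Full rigid-body docking of ``ligand`` onto ``receptor``.

    The receptor is rasterized once in its own frame; for each ligand
    rotation the FFT correlation is evaluated over all translations, the
    best ``per_rotation`` positive-score candidates are kept, and the
    global top ``top_k`` are merged.  Ties are broken by (rotation index,
    lexicographic translation) for reproducibility.
    """
    if rotations is None:
        rotations = build_rotation_set(spacing)
    rec_grid = rasterize(receptor, np.eye(3), step, "receptor", rho)
    chunks = []
    for ri, rot in enumerate(rotations.matrices):
        lig_grid = rasterize(ligand, rot, step, "ligand", rho)
        chunks.append(_top_candidates(rec_grid, lig_grid, ri, per_rotation))
    return _merge_candidates(chunks, top_k, ligand.id, receptor.id)


def _top_candidates(rec_grid: ScoreGrid, lig_grid: ScoreGrid, ri: int,
                    per_rotation: int):
    c = correlate(rec_grid, lig_grid)
    flat = c.ravel()
    n_keep = min(per_rotation, flat.size)
    if n_keep < flat.size:
        idx = np.argpartition(-flat, n_keep - 1)[:n_keep]
    else:
        idx = np.arange(flat.size)
    scores = flat[idx]
    pos = scores > 0
    idx, scores = idx[pos], scores[pos]
    t = np.stack(np.unravel_index(idx, c.shape), axis=1) - (
        np.array(lig_grid.values.shape) - 1)
    disp = rec_grid.origin - lig_grid.origin + rec_grid.step * t
    return (np.full(len(idx), ri, dtype=np.int32), t.astype(np.int32),
            scores.astype(np.float64), disp.astype(np.float64))


def _merge_candidates(chunks, top_k, lig_id, rec_id) -> PoseTable:
    ri = np.concatenate([c[0] for c in chunks]) if chunks else np.empty(0, np.int32)
    if len(ri) == 0:
        warnings.warn(f"no positive-score docking pose for {lig_id}->{rec_id}")
        return PoseTable(
            rot_index=np.empty(0, np.int32), trans=np.empty((0, 3), np.int32),
            score=np.empty(0), disp=np.empty((0, 3)))
    tr = np.concatenate([c[1] for c in chunks])
    sc = np.concatenate([c[2] for c in chunks])
    dp = np.concatenate([c[3] for c in chunks])
    order = np.lexsort((tr[:, 2], tr[:, 1], tr[:, 0], ri, -sc))[:top_k]
    return PoseTable(rot_index=ri[order], trans=tr[order],
                     score=sc[order], disp=dp[order])


@dataclass
class PoseLibrary:
    """Ranked pose tables for all ordered pairs of protein types.

    ``pairs[(i, j)]`` holds the poses of type ``i`` as the moving ligand
    docked onto type ``j`` as the receptor; all ``n^2`` ordered pairs are
    present.
    """

    rotations: RotationSet
    pairs: dict                      # (lig_type, rec_type) -> PoseTable
    ids: list                        # type index -> protein id
    params: dict = field(default_factory=dict)

    def table(self, lig_type: int, rec_type: int) -> PoseTable:
        return self.pairs[(lig_type, rec_type)]

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["ids"] = [str(s) for s in self.ids]
            f.attrs["spacing"] = self.rotations.spacing
            for key, val in self.params.items():
                f.attrs[key] = val
            f.create_dataset("rotations/quats", data=self.rotations.quats,
                             track_times=False)
            g = f.create_group("pairs")
            for (i, j), t in self.pairs.items():
                gp = g.create_group(f"{i}__{j}")
                for nm, arr in (("rot_index", t.rot_index),
                                ("trans", t.trans), ("score", t.score),
                                ("disp", t.disp)):
                    gp.create_dataset(nm, data=arr, track_times=False)

    @classmethod
    def load(cls, path) -> "PoseLibrary":
        with h5py.File(path, "r") as f:
            quats = f["rotations/quats"][...]
            spacing = float(f.attrs["spacing"])
            ids = [str(s) for s in f.attrs["ids"]]
            params = {k: f.attrs[k] for k in f.attrs if k not in ("ids", "spacing")}
            matrices = Rotation.from_quat(quats).as_matrix()
            matrices[0] = np.eye(3)
            rotations = RotationSet(quats=quats, matrices=matrices,
                                    spacing=spacing)
            pairs = {}
            for name, gp in f["pairs"].items():
                i, j = (int(v) for v in name.split("__"))
                pairs[(i, j)] = PoseTable(
                    rot_index=gp["rot_index"][...], trans=gp["trans"][...],
                    score=gp["score"][...], disp=gp["disp"][...])
        return cls(rotations=rotations, pairs=pairs, ids=ids, params=params)


def build_library(proteins, step: float = DEFAULT_STEP, rho: float = DEFAULT_RHO,
                  spacing: float = DEFAULT_SPACING, top_k: int = DEFAULT_TOP_K,
                  per_rotation: int = DEFAULT_PER_ROTATION,
                  progress=None) -> PoseLibrary:
    """Dock all ordered pairs of protein types into one pose library.

    Each ligand rotation is rasterized once and correlated against every
    receptor grid, so the cost scales as O(types * rotations) raster
    operations plus O(types^2 * rotations) FFTs.
    """
    rotations = build_rotation_set(spacing)
    rec_grids = {j: rasterize(p, np.eye(3), step, "receptor", rho)
                 for j, p in enumerate(proteins)}
    candidates = {(i, j): [] for i in range(len(proteins))
                  for j in range(len(proteins))}
    for i, lig in enumerate(proteins):
        for ri, rot in enumerate(rotations.matrices):
            lig_grid = rasterize(lig, rot, step, "ligand", rho)
            for j in range(len(proteins)):
                candidates[(i, j)].append(
                    _top_candidates(rec_grids[j], lig_grid, ri, per_rotation))
            if progress is not None:
                progress(i, ri)
    pairs = {
        key: _merge_candidates(chunks, top_k, proteins[key[0]].id,
                               proteins[key[1]].id)
        for key, chunks in candidates.items()
    }
    return PoseLibrary(
        rotations=rotations, pairs=pairs, ids=[p.id for p in proteins],
        params={"step": step, "rho": rho, "top_k": top_k,
                "per_rotation": per_rotation})


def pose_to_transform(pose, rotations: RotationSet, receptor_rot: np.ndarray,
                      receptor_pos: np.ndarray):
    """World placement of a docked ligand given the receptor placement.

    Returns ``(world_rot, world_pos)`` where the ligand's atoms sit at
    ``world_pos + world_rot @ (atom - ligand.center)``.
    """
    pose_rot = rotations.matrices[pose.rot_index]
    disp = np.asarray(pose.disp, dtype=float)
    world_rot = receptor_rot @ pose_rot
    world_pos = np.asarray(receptor_pos, dtype=float) + receptor_rot @ disp
    return world_rot, world_pos


def transform_to_pose(world_rot: np.ndarray, world_pos: np.ndarray,
                      receptor_rot: np.ndarray, receptor_pos: np.ndarray):
    """Inverse of :func:`pose_to_transform`: recover the pair-frame pose.

    Returns ``(pair_rot, disp)``.
    """
    pair_rot = receptor_rot.T @ world_rot
    disp = receptor_rot.T @ (np.asarray(world_pos, float) -
                             np.asarray(receptor_pos, float))
    return pair_rot, disp
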