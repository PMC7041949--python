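"""Structure and trajectory metrics for the β11-12 linker analyses.

Implements the geometric read-outs used to compare simulation frames against
the resting and desensitized reference conformations of the channel's
extracellular domain: local Kabsch superposition, RMSD time series over a
residue selection (canonically the Cα atoms of linker residues 409-420),
per-residue RMSF, a two-reference RMSD state plane, side-chain χ1-χ3
dihedrals, and atom-pair distance series with a hydrogen-bond-distance
threshold report.

PDB reading and writing (including multi-model trajectories, with the
highest-occupancy altloc kept) is delegated to biotite; a plain whitespace
coordinate table (frame, atom index, x, y, z) is also accepted for
trajectories.  All metrics operate on unwrapped, whole molecules; no
periodicity handling is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "StructureFrame",
    "Trajectory",
    "Selection",
    "read_pdb",
    "write_pdb",
    "read_trajectory_pdb",
    "read_coordinate_table",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "state_plane",
    "chi_dihedrals",
    "dihedral_angle",
    "atom_distance_series",
]

# Side-chain chi dihedral atom windows (heavy-atom definitions, IUPAC order).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "NE")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "OE1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"), ("CB", "CG", "CD", "CE")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"), ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "VAL": [("N", "CA", "CB", "CG1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
}


@dataclass
class StructureFrame:
    chain_id: np.ndarray  # str per atom
    res_id: np.ndarray  # int per atom
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray  # (n_atoms, 3) in Angstrom

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        n = self.coord.shape[0]
        for arr in (self.chain_id, self.res_id, self.res_name, self.atom_name, self.element):
            if len(arr) != n:
                raise ValueError("atom annotation arrays must match coordinate count")
        keys = list(zip(self.chain_id, self.res_id, self.atom_name))
        if len(set(keys)) != n:
            raise ValueError("(chain, residue, atom name) must be unique per frame")

    @property
    def n_atoms(self) -> int:
        return self.coord.shape[0]

    def atom_index(self, chain: str, res_id: int, atom_name: str) -> int:
        mask = (
            (self.chain_id == chain) & (self.res_id == res_id) & (self.atom_name == atom_name)
        )
        hits = np.flatnonzero(mask)
        if hits.size != 1:
            raise KeyError(f"atom {chain}/{res_id}/{atom_name} not found")
        return int(hits[0])


@dataclass
class Trajectory:
    frames: list[StructureFrame]
    frame_interval: float = 0.02  # ns (5 ps snapshots, every 4th used)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if fr.n_atoms != ref.n_atoms or not np.array_equal(fr.atom_name, ref.atom_name):
                raise ValueError("frames must be congruent in atom ordering")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def strided(self, stride: int) -> "Trajectory":
        return Trajectory(self.frames[::stride], self.frame_interval * stride)


@dataclass
class Selection:
    chains: tuple[str, ...] | None = None
    res_range: tuple[int, int] | None = None  # inclusive bounds
    atom_names: tuple[str, ...] | None = None

    def mask(self, frame: StructureFrame) -> np.ndarray:
        m = np.ones(frame.n_atoms, dtype=bool)
        if self.chains is not None:
            m &= np.isin(frame.chain_id, self.chains)
        if self.res_range is not None:
            lo, hi = self.res_range
            m &= (frame.res_id >= lo) & (frame.res_id <= hi)
        if self.atom_names is not None:
            m &= np.isin(frame.atom_name, self.atom_names)
        if not m.any():
            raise ValueError(f"selection {self} resolves to no atoms")
        return m

    @classmethod
    def parse(cls, text: str) -> "Selection":
        """Parse 'chain:resstart-resend:atomname' (any field may be '*')."""
        chain_s, res_s, atom_s = (text.split(":") + ["*", "*"])[:3]
        chains = None if chain_s in ("*", "") else tuple(chain_s.split(","))
        res_range = None
        if res_s not in ("*", ""):
            lo, _, hi = res_s.partition("-")
            res_range = (int(lo), int(hi or lo))
        atoms = None if atom_s in ("*", "") else tuple(atom_s.split(","))
        return cls(chains=chains, res_range=res_range, atom_names=atoms)


# ---------------------------------------------------------------------------
# PDB / coordinate-table I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _frame_from_atoms(atoms) -> StructureFrame:
    return StructureFrame(
        chain_id=np.asarray(atoms.chain_id, dtype="U4"),
        res_id=np.asarray(atoms.res_id, dtype=int),
        res_name=np.asarray(atoms.res_name, dtype="U4"),
        atom_name=np.asarray(atoms.atom_name, dtype="U5"),
        element=np.asarray(atoms.element, dtype="U2"),
        coord=np.asarray(atoms.coord, dtype=float),
    )


def _load_pdb(path: str | Path):
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return PDBFile.read(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: malformed PDB ({exc})") from exc


def read_pdb(path: str | Path, model: int = 1) -> StructureFrame:
    """Read one model from a PDB file, keeping the highest-occupancy altloc."""
    pdb = _load_pdb(path)
    try:
        atoms = pdb.get_structure(model=model, altloc="occupancy")
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse ATOM records ({exc})") from exc
    if atoms.array_length() == 0:
        raise ValueError(f"{path}: no ATOM records")
    return _frame_from_atoms(atoms)


def read_trajectory_pdb(path: str | Path, frame_interval: float = 0.02) -> Trajectory:
    """Read a multi-model PDB as a trajectory."""
    pdb = _load_pdb(path)
    stack = pdb.get_structure(altloc="occupancy")
    frames = []
    template = None
    for k in range(stack.stack_depth()):
        atoms = stack[k]
        fr = _frame_from_atoms(atoms)
        if template is None:
            template = fr
        frames.append(fr)
    return Trajectory(frames=frames, frame_interval=frame_interval)


def write_pdb(frame: StructureFrame, path: str | Path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    atoms = struc.AtomArray(frame.n_atoms)
    atoms.chain_id = frame.chain_id
    atoms.res_id = frame.res_id
    atoms.res_name = frame.res_name
    atoms.atom_name = frame.atom_name
    atoms.element = frame.element
    atoms.coord = frame.coord.astype(np.float32)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_coordinate_table(
    path: str | Path,
    template: StructureFrame,
    frame_interval: float = 0.02,
) -> Trajectory:
    """Read a whitespace table of (frame, atom_index, x, y, z) rows onto a
    template frame's atom annotations."""
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] != 5:
        raise ValueError("coordinate table must have 5 columns: frame idx x y z")
    frames = []
    for f in np.unique(data[:, 0].astype(int)):
        rows = data[data[:, 0].astype(int) == f]
        order = np.argsort(rows[:, 1])
        coords = rows[order, 2:5]
        if coords.shape[0] != template.n_atoms:
            raise ValueError(f"frame {f}: {coords.shape[0]} atoms, template has {template.n_atoms}")
        frames.append(
            StructureFrame(
                chain_id=template.chain_id, res_id=template.res_id,
                res_name=template.res_name, atom_name=template.atom_name,
                element=template.element, coord=coords,
            )
        )
    return Trajectory(frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# Superposition and deviation metrics
# ---------------------------------------------------------------------------

def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (proper rotation only).

    Returns (rotation, translation, rmsd) such that
    ``mobile @ rotation.T + translation`` best fits ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need matching coordinate sets of >= 3 atoms")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    A = mobile - mc
    B = reference - rc
    s = np.linalg.svd(B, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) coordinate set")
    H = A.T @ B
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = A @ R.T + rc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_series(
    traj: Trajectory,
    reference: StructureFrame,
    fit_selection: Selection,
    measure_selection: Selection | None = None,
) -> np.ndarray:
    """Per-frame RMSD to a reference: superpose on ``fit_selection``, measure
    over ``measure_selection`` (defaults to the fit selection — the local
    alignment used for linker analyses)."""
    measure_selection = measure_selection or fit_selection
    fit_ref = reference.coord[fit_selection.mask(reference)]
    meas_mask_ref = measure_selection.mask(reference)
    out = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        fit_mob = fr.coord[fit_selection.mask(fr)]
        if fit_mob.shape != fit_ref.shape:
            raise ValueError(f"frame {k}: fit selection atom count mismatch")
        R, t, _ = kabsch_superpose(fit_mob, fit_ref)
        moved = fr.coord[measure_selection.mask(fr)] @ R.T + t
        ref_meas = reference.coord[meas_mask_ref]
        if moved.shape != ref_meas.shape:
            raise ValueError(f"frame {k}: measure selection atom count mismatch")
        out[k] = math.sqrt(np.mean(np.sum((moved - ref_meas) ** 2, axis=1)))
    return out


def rmsf(traj: Trajectory, selection: Selection, superpose: bool = True) -> dict:
    """Root-mean-square fluctuation of selected atoms about their
    time-averaged positions, after per-frame superposition of the selection
    onto the first frame (disable with ``superpose=False`` when frames are
    already aligned).  Returns per-atom values plus a per-residue map taking
    each residue's Cα value where present."""
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    ref = traj.frames[0]
    mask = selection.mask(ref)
    coords = np.empty((traj.n_frames, int(mask.sum()), 3))
    ref_sel = ref.coord[mask]
    for k, fr in enumerate(traj.frames):
        sel = fr.coord[selection.mask(fr)]
        if superpose and k > 0:
            R, t, _ = kabsch_superpose(sel, ref_sel)
            sel = sel @ R.T + t
        coords[k] = sel
    mean_pos = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean_pos) ** 2, axis=2), axis=0))
    per_residue: dict[tuple[str, int], float] = {}
    chains = ref.chain_id[mask]
    resids = ref.res_id[mask]
    names = ref.atom_name[mask]
    for c, r, nm, v in zip(chains, resids, names, per_atom):
        if nm == "CA":
            per_residue[(str(c), int(r))] = float(v)
    return {"per_atom": per_atom, "per_residue": per_residue}


def state_plane(
    traj: Trajectory,
    reference_a: StructureFrame,
    reference_b: StructureFrame,
    selection: Selection,
) -> np.ndarray:
    """Per-frame (RMSD to reference_a, RMSD to reference_b) pairs, sharing the
    local superposition rule of ``rmsd_series``."""
    ra = rmsd_series(traj, reference_a, selection)
    rb = rmsd_series(traj, reference_b, selection)
    return np.column_stack([ra, rb])


# ---------------------------------------------------------------------------
# Dihedrals and distances
# ---------------------------------------------------------------------------

def dihedral_angle(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, p4: np.ndarray) -> float:
    """Signed torsion in degrees in (-180, 180], IUPAC sign convention."""
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    b3 = np.asarray(p4, float) - np.asarray(p3, float)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(n1 @ n2)
    y = float(np.cross(n1, n2) @ (b2 / np.linalg.norm(b2)))
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang == -180.0 else ang


def chi_dihedrals(frame: StructureFrame, chain: str, res_id: int) -> tuple[float, ...]:
    """χ1..χk side-chain dihedrals (degrees) for one residue, as defined for
    its residue type; raises naming the first missing atom."""
    mask = (frame.chain_id == chain) & (frame.res_id == res_id)
    if not mask.any():
        raise KeyError(f"residue {chain}/{res_id} not found")
    res_name = str(frame.res_name[mask][0])
    windows = CHI_ATOMS.get(res_name)
    if windows is None:
        raise ValueError(f"no chi definition for residue type {res_name}")
    angles = []
    for window in windows:
        coords = []
        for atom in window:
            try:
                coords.append(frame.coord[frame.atom_index(chain, res_id, atom)])
            except KeyError:
                raise ValueError(
                    f"residue {chain}/{res_id} ({res_name}) is missing atom {atom}"
                ) from None
        angles.append(dihedral_angle(*coords))
    return tuple(angles)


def atom_distance_series(
    traj: Trajectory,
    atom_a: tuple[str, int, str],
    atom_b: tuple[str, int, str],
    cutoff: float = 3.5,
) -> dict:
    """Euclidean distance per frame between two named atoms, plus the
    fraction of frames at or below ``cutoff`` (default hydrogen-bond 3.5 Å)."""
    dists = np.empty(traj.n_frames)
    for k, fr in enumerate(traj.frames):
        try:
            ia = fr.atom_index(*atom_a)
            ib = fr.atom_index(*atom_b)
        except KeyError as exc:
            raise KeyError(f"frame {k}: {exc}") from exc
        dists[k] = np.linalg.norm(fr.coord[ia] - fr.coord[ib])
    return {"distance": dists, "fraction_within_cutoff": float(np.mean(dists <= cutoff))}
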