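"""Trajectory container, atom-selection mini-language, and file IO.

Coordinates are stored in Å, times in ns, masses in Da.  File reading and
writing (PDB topology / multi-model PDB / DCD / XTC) goes through
MDAnalysis; the container itself is a plain set of numpy arrays so that
synthetic trajectories can be built directly in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..sasa import vdw_radius

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HSD", "HSE", "HSP", "HID", "HIE", "HIP", "CYX", "MSE",
}
SOLVENT_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "NA", "CL", "K", "NA+", "CL-"}
_BACKBONE_NAMES = {"N", "CA", "C"}
_MAINCHAIN_NAMES = {"N", "CA", "C", "O", "OXT", "OT1", "OT2"}

_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "P": 30.974, "S": 32.06, "CL": 35.45, "BR": 79.904, "I": 126.904,
    "NA": 22.990, "K": 39.098, "MG": 24.305, "ZN": 65.38, "FE": 55.845,
}


def element_mass(element: str) -> float:
    return _MASSES.get(element.strip().upper(), 12.011)


@dataclass
class Trajectory:
    """Time-ordered frames of labelled atom coordinates.

    Attributes
    ----------
    names, elements, resnames, chains : (n_atoms,) object arrays
    resids : (n_atoms,) int array
    masses, radii : (n_atoms,) float arrays, Da and Å
    times : (n_frames,) float array, ns, strictly increasing
    coords : (n_frames, n_atoms, 3) float array, Å
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    masses: np.ndarray
    radii: np.ndarray
    times: np.ndarray
    coords: np.ndarray
    chains: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for attr in ("names", "elements", "resids", "resnames", "masses",
                     "radii", "times"):
            setattr(self, attr, np.asarray(getattr(self, attr)))
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.names)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (n, 3):
            raise ValueError("coords must be (n_frames, n_atoms, 3)")
        if len(self.times) != len(self.coords):
            raise ValueError("one time per frame required")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")
        if self.chains is None:
            self.chains = np.array(["A"] * n, dtype=object)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    # ------------------------------------------------------------ selection

    def _clause_mask(self, clause: str) -> np.ndarray:
        clause = clause.strip()
        if clause.startswith("not "):
            return ~self._clause_mask(clause[4:])
        is_protein = np.isin(self.resnames, list(PROTEIN_RESNAMES))
        if clause == "all":
            return np.ones(self.n_atoms, dtype=bool)
        if clause == "protein":
            return is_protein
        if clause == "ligand":
            return ~is_protein & ~np.isin(self.resnames, list(SOLVENT_RESNAMES))
        if clause == "backbone":
            return is_protein & np.isin(self.names, list(_BACKBONE_NAMES))
        if clause == "mainchain":
            return is_protein & np.isin(self.names, list(_MAINCHAIN_NAMES))
        if clause == "sidechain":
            return is_protein & ~np.isin(self.names, list(_MAINCHAIN_NAMES))
        if clause == "calpha":
            return is_protein & (self.names == "CA")
        if clause.startswith("resid "):
            spec = clause[6:].strip()
            if ":" in spec:
                lo, hi = (int(x) for x in spec.split(":"))
                return (self.resids >= lo) & (self.resids <= hi)
            wanted = [int(x) for x in spec.split(",")]
            return np.isin(self.resids, wanted)
        if clause.startswith("name "):
            wanted = [x.strip() for x in clause[5:].split(",")]
            return np.isin(self.names, wanted)
        raise ValueError(f"unknown selection clause: {clause!r}")

    def select(self, expr: str) -> np.ndarray:
        """Atom indices matching an ``and``-joined clause expression, e.g.
        ``"protein and backbone"`` or ``"resid 3:7 and name CA"``."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expr.split(" and "):
            mask &= self._clause_mask(clause)
        return np.flatnonzero(mask)


@dataclass
class HbondPair:
    """Donor/acceptor atom indices (heavy atoms) with an optional
    hydrogen index and a human-readable label."""

    donor: int
    acceptor: int
    hydrogen: Optional[int] = None
    label: str = ""

    def validate(self, traj: Trajectory) -> None:
        for idx in (self.donor, self.acceptor) + (
            (self.hydrogen,) if self.hydrogen is not None else ()
        ):
            if not 0 <= idx < traj.n_atoms:
                raise IndexError(f"atom id {idx} out of range")
        if self.donor == self.acceptor:
            raise ValueError("donor and acceptor must differ")


@dataclass
class TorsionSpec:
    """Four ordered atom indices defining a dihedral, plus a label."""

    atoms: tuple[int, int, int, int]
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.atoms)) != 4:
            raise ValueError("torsion needs four distinct atoms")


# ------------------------------------------------------------------ IO


def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("CL", "BR", "NA", "MG",
                                                       "ZN", "FE"):
        return stripped[:2].capitalize()
    return stripped[:1].upper() if stripped else "C"


def read_trajectory(topology_path, coords_path=None) -> Trajectory:
    """Load a trajectory via MDAnalysis.

    ``topology_path`` is a PDB; ``coords_path`` may be a multi-model PDB,
    DCD or XTC (omitted = use the topology's own frames).  Times are taken
    from the reader (ps) and converted to ns; a reader without time
    information falls back to a 1-ns-per-frame ramp.
    """
    import MDAnalysis as mda

    args = (str(topology_path),) if coords_path is None else (
        str(topology_path), str(coords_path))
    u = mda.Universe(*args)
    n = len(u.atoms)
    names = np.array([a.name for a in u.atoms], dtype=object)
    try:
        elements = np.array([a.element if a.element else _guess_element(a.name)
                             for a in u.atoms], dtype=object)
    except mda.exceptions.NoDataError:
        elements = np.array([_guess_element(nm) for nm in names], dtype=object)
    masses = np.array([element_mass(e) for e in elements])
    radii = np.array([vdw_radius(e) for e in elements])
    resids = np.array([a.resid for a in u.atoms])
    resnames = np.array([a.resname for a in u.atoms], dtype=object)
    coords, times = [], []
    for ts in u.trajectory:
        if len(ts.positions) != n:
            raise ValueError("atom-count mismatch between topology and frames")
        coords.append(ts.positions.copy())
        times.append(ts.time / 1000.0)  # ps -> ns
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        times = np.arange(len(coords), dtype=float)
    return Trajectory(names=names, elements=elements, resids=resids,
                      resnames=resnames, masses=masses, radii=radii,
                      times=times, coords=np.array(coords))


def _to_universe(traj: Trajectory):
    import MDAnalysis as mda

    resid_keys = list(dict.fromkeys(zip(traj.resids, traj.resnames)))
    res_index = {key: i for i, key in enumerate(resid_keys)}
    atom_resindex = np.array([res_index[(rid, rn)]
                              for rid, rn in zip(traj.resids, traj.resnames)])
    u = mda.Universe.empty(traj.n_atoms, n_residues=len(resid_keys),
                           atom_resindex=atom_resindex, trajectory=True)
    u.add_TopologyAttr("names", [str(x) for x in traj.names])
    u.add_TopologyAttr("elements", [str(x) for x in traj.elements])
    u.add_TopologyAttr("masses", traj.masses)
    u.add_TopologyAttr("resids", [int(k[0]) for k in resid_keys])
    u.add_TopologyAttr("resnames", [str(k[1]) for k in resid_keys])
    return u


def write_pdb(traj: Trajectory, path) -> None:
    """Write all frames as a multi-model PDB."""
    import MDAnalysis as mda

    u = _to_universe(traj)
    with mda.Writer(str(path), n_atoms=traj.n_atoms, multiframe=True) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            w.write(u.atoms)


def write_dcd(traj: Trajectory, path) -> None:
    """Write frame coordinates as a DCD (pair with a PDB topology)."""
    import MDAnalysis as mda

    u = _to_universe(traj)
    with mda.Writer(str(path), n_atoms=traj.n_atoms) as w:
        for frame in traj.coords:
            u.atoms.positions = frame
            w.write(u.atoms)
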