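"""Small-molecule parsing and the ten GFA-selected molecular descriptors.

Molecules are represented as RDKit ``Mol`` objects (RDKit's default
aromaticity model is used throughout; descriptor counts depend on it).
The descriptor set combines electrotopological-state (E-state) counts and
sums, ring/connectivity topology, polar surface areas and a shadow length:

* ``ES_Count_aaCH`` / ``ES_Sum_aaCH`` — aromatic CH atoms (two aromatic
  neighbours, one hydrogen): count, and sum of their E-state indices.
* ``ES_Count_sOH`` — hydroxyl oxygens; ``ES_Sum_sssN`` — E-state sum over
  nitrogens with three single bonds.
* ``Num_Rings6`` — six-membered rings in the SSSR.
* ``Molecular_PolarSurfaceArea`` — Ertl fragment-based 2D TPSA (Å²).
* ``CHI_2`` — second-order simple connectivity index.
* ``Jurs_TPSA`` — 3D polar solvent-accessible surface area (N, O and their
  attached hydrogens; 1.4 Å probe), a surface-based counterpart of TPSA.
* ``Minimized_Energy`` — caller-supplied forcefield energy (kcal/mol); the
  pipeline treats it as an injectable numeric feature and never computes it.
* ``Shadow_Ylength`` — molecular extent (including vdW radii) along the
  second principal axis of the coordinate covariance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors as RDDescriptors

from .sasa import shrake_rupley, vdw_radius

log = logging.getLogger(__name__)

#: Canonical descriptor order used in tables and serialized models.
DESCRIPTOR_NAMES = [
    "ES_Count_aaCH",
    "ES_Count_sOH",
    "ES_Sum_aaCH",
    "ES_Sum_sssN",
    "Num_Rings6",
    "Molecular_PolarSurfaceArea",
    "CHI_2",
    "Jurs_TPSA",
    "Minimized_Energy",
    "Shadow_Ylength",
]

# principal quantum number per period, indexed by atomic number ranges
_PERIOD_EDGES = [2, 10, 18, 36, 54, 86, 118]


class Requires3DError(ValueError):
    """A 3D descriptor was requested for a molecule without coordinates."""


class EmptyInputError(ValueError):
    """No parseable molecule records were found."""


@dataclass
class DescriptorVector:
    """The ten named descriptors for one molecule.

    ``Jurs_TPSA``/``Shadow_Ylength`` are ``None`` when no 3D coordinates
    were available; ``Minimized_Energy`` is ``None`` unless supplied.
    """

    ES_Count_aaCH: int = 0
    ES_Count_sOH: int = 0
    ES_Sum_aaCH: float = 0.0
    ES_Sum_sssN: float = 0.0
    Num_Rings6: int = 0
    Molecular_PolarSurfaceArea: float = 0.0
    CHI_2: float = 0.0
    Jurs_TPSA: Optional[float] = None
    Minimized_Energy: Optional[float] = None
    Shadow_Ylength: Optional[float] = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


def read_molecules(path, fmt: str) -> list[Chem.Mol]:
    """Read molecules from a SMILES (one per line, optional tab-separated
    name) or SDF V2000 file.  Unparseable records are skipped with a
    warning; an input yielding zero molecules raises :class:`EmptyInputError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    mols: list[Chem.Mol] = []
    skipped = 0
    if fmt == "smiles":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            mol = Chem.MolFromSmiles(parts[0])
            if mol is None:
                skipped += 1
                log.warning("skipping unparseable SMILES at line %d", lineno)
                continue
            name = parts[1] if len(parts) > 1 else f"mol{len(mols) + 1}"
            mol.SetProp("_Name", name)
            mols.append(mol)
    elif fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
        for i, mol in enumerate(supplier):
            if mol is None:
                skipped += 1
                log.warning("skipping unparseable SDF record %d", i + 1)
                continue
            mols.append(mol)
    else:
        raise ValueError(f"unrecognized format: {fmt!r} (expected smiles|sdf)")
    if skipped:
        log.warning("%d record(s) skipped", skipped)
    if not mols:
        raise EmptyInputError(f"no parseable records in {path}")
    return mols


def _principal_quantum_number(atomic_num: int) -> int:
    for period, edge in enumerate(_PERIOD_EDGES, start=1):
        if atomic_num <= edge:
            return period
    return 7


_BOND_CODE_ORDER = {"a": 0, "d": 1, "t": 2, "s": 3}


def estate_atom_types(mol: Chem.Mol) -> list[str]:
    """Assign a Kier–Hall E-state atom-type string to every heavy atom.

    The label concatenates one letter per heavy-atom bond (``s`` single,
    ``d`` double, ``t`` triple, ``a`` aromatic, aromatics/multiples first),
    the element symbol, and the attached-hydrogen count — e.g. ``aaCH``,
    ``sOH``, ``sssN``, ``dO``.  Atoms whose valence cannot be encoded are
    labelled ``"other"`` rather than raising.
    """
    labels = []
    for atom in mol.GetAtoms():
        try:
            codes = []
            for bond in atom.GetBonds():
                if bond.GetIsAromatic():
                    codes.append("a")
                else:
                    order = bond.GetBondTypeAsDouble()
                    codes.append({1.0: "s", 2.0: "d", 3.0: "t"}[order])
            codes.sort(key=_BOND_CODE_ORDER.__getitem__)
            n_h = atom.GetTotalNumHs()
            h_part = "" if n_h == 0 else ("H" if n_h == 1 else f"H{n_h}")
            labels.append("".join(codes) + atom.GetSymbol() + h_part)
        except KeyError:
            labels.append("other")
    return labels


def estate_indices(mol: Chem.Mol) -> np.ndarray:
    """Kier–Hall electrotopological state index per heavy atom.

    ``S_i = I_i + sum_j (I_i - I_j) / d_ij**2`` with the intrinsic state
    ``I = ((2/N)**2 * dv + 1) / d`` (``N`` principal quantum number, ``dv``
    valence electrons minus attached H, ``d`` heavy-atom degree) and
    ``d_ij`` = graph distance + 1.  A single-heavy-atom molecule has its
    degree clamped to 1 so that ``S = I``.
    """
    n = mol.GetNumAtoms()
    intrinsic = np.empty(n)
    for atom in mol.GetAtoms():
        nv = Chem.GetPeriodicTable().GetNOuterElecs(atom.GetAtomicNum())
        dv = nv - atom.GetTotalNumHs()
        delta = atom.GetDegree()
        if delta == 0:
            log.warning("isolated heavy atom: clamping connectivity to 1")
            delta = 1
        pqn = _principal_quantum_number(atom.GetAtomicNum())
        intrinsic[atom.GetIdx()] = ((2.0 / pqn) ** 2 * dv + 1.0) / delta
    if n == 1:
        return intrinsic.copy()
    dist = Chem.GetDistanceMatrix(mol) + 1.0
    np.fill_diagonal(dist, np.inf)
    diff = intrinsic[:, None] - intrinsic[None, :]
    return intrinsic + (diff / dist**2).sum(axis=1)


def chi2_index(mol: Chem.Mol) -> float:
    """Second-order simple connectivity index: sum over 2-edge paths
    ``i-j-k`` of ``(delta_i * delta_j * delta_k) ** -0.5`` with heavy-atom
    degrees ``delta``."""
    total = 0.0
    for atom in mol.GetAtoms():
        dj = atom.GetDegree()
        if dj < 2:
            continue
        neighbors = [nb for nb in atom.GetNeighbors()]
        for a, b in itertools.combinations(neighbors, 2):
            total += (a.GetDegree() * dj * b.GetDegree()) ** -0.5
    return total


def _coords_and_radii(mol: Chem.Mol) -> tuple[np.ndarray, np.ndarray]:
    conf = mol.GetConformer()
    coords = conf.GetPositions()
    radii = np.array([vdw_radius(a.GetSymbol()) for a in mol.GetAtoms()])
    return coords, radii


def shadow_ylength(mol: Chem.Mol) -> float:
    """Extent of the molecule (vdW spheres included) along the second
    principal axis, with axes ordered by descending coordinate variance."""
    coords, radii = _coords_and_radii(mol)
    centered = coords - coords.mean(axis=0)
    if len(coords) == 1:
        return 2.0 * radii[0]
    cov = np.cov(centered.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    y_axis = eigvecs[:, order[1]]
    proj = centered @ y_axis
    return float((proj + radii).max() - (proj - radii).min())


def jurs_tpsa(mol: Chem.Mol, probe: float = 1.4, n_points: int = 960) -> float:
    """3D polar solvent-accessible surface area (Å²): the SASA summed over
    N and O atoms and hydrogens bonded to them."""
    coords, radii = _coords_and_radii(mol)
    areas = shrake_rupley(coords, radii, probe=probe, n_points=n_points)
    polar = np.zeros(len(areas), dtype=bool)
    for atom in mol.GetAtoms():
        sym = atom.GetSymbol()
        if sym in ("N", "O"):
            polar[atom.GetIdx()] = True
        elif sym == "H":
            if any(nb.GetSymbol() in ("N", "O") for nb in atom.GetNeighbors()):
                polar[atom.GetIdx()] = True
    return float(areas[polar].sum())


def compute_descriptors(
    mol: Chem.Mol,
    energy: Optional[float] = None,
    require_3d: bool = False,
) -> DescriptorVector:
    """Compute the full descriptor vector for one molecule.

    3D descriptors (``Jurs_TPSA``, ``Shadow_Ylength``) are left ``None``
    when the molecule carries no conformer; pass ``require_3d=True`` to
    turn that into a :class:`Requires3DError` instead.
    """
    types = estate_atom_types(mol)
    svals = estate_indices(mol)
    aa_ch = [i for i, t in enumerate(types) if t == "aaCH"]
    s_oh = [i for i, t in enumerate(types) if t == "sOH"]
    sss_n = [i for i, t in enumerate(types) if t == "sssN"]

    num_rings6 = sum(1 for ring in Chem.GetSSSR(mol) if len(ring) == 6)

    has_3d = mol.GetNumConformers() > 0
    if require_3d and not has_3d:
        raise Requires3DError(
            "Jurs_TPSA/Shadow_Ylength need 3D coordinates; none present"
        )

    return DescriptorVector(
        ES_Count_aaCH=len(aa_ch),
        ES_Count_sOH=len(s_oh),
        ES_Sum_aaCH=float(svals[aa_ch].sum()) if aa_ch else 0.0,
        ES_Sum_sssN=float(svals[sss_n].sum()) if sss_n else 0.0,
        Num_Rings6=num_rings6,
        Molecular_PolarSurfaceArea=float(RDDescriptors.TPSA(mol)),
        CHI_2=chi2_index(mol),
        Jurs_TPSA=jurs_tpsa(mol) if has_3d else None,
        Minimized_Energy=energy,
        Shadow_Ylength=shadow_ylength(mol) if has_3d else None,
    )


def descriptor_table(
    mols: list[Chem.Mol], energies: Optional[list[float]] = None
) -> pd.DataFrame:
    """One row per molecule, columns exactly the ten descriptor names,
    indexed by molecule name."""
    rows, names = [], []
    for i, mol in enumerate(mols):
        energy = energies[i] if energies is not None else None
        rows.append(compute_descriptors(mol, energy=energy).as_dict())
        names.append(mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i + 1}")
    return pd.DataFrame(rows, index=pd.Index(names, name="name"))[DESCRIPTOR_NAMES]
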