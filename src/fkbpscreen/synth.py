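"""Synthetic inputs with planted ground truth for every pipeline stage.

The QSAR generator emulates the study design used for the activity
models: a 37-row descriptor/activity table randomly split 30/7 into
train/test, with pIC50 an exact linear function of a few active
descriptors plus Gaussian noise.  The trajectory generator produces toy
systems with planted hydrogen-bond occupancy, a scripted torsion, and
isotropic positional jitter.  All generators are pure functions of their
seed, and every generated artifact is accompanied by a ground-truth
record.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .chem import DESCRIPTOR_NAMES
from .gfa import TrainingTable
from .screen import CandidateRecord
from .traj.core import Trajectory, HbondPair, TorsionSpec
from .traj.dssp import _assign_frame, _backbone_index, _hbond_matrix
from .sasa import vdw_radius
from .traj.core import element_mass

# plausible physical sampling ranges per descriptor family
_DEFAULT_RANGES = {
    "ES_Count_aaCH": (0, 10), "ES_Count_sOH": (0, 6),
    "ES_Sum_aaCH": (0.0, 20.0), "ES_Sum_sssN": (0.0, 10.0),
    "Num_Rings6": (0, 6),
    "Molecular_PolarSurfaceArea": (0.0, 200.0), "CHI_2": (0.0, 15.0),
    "Jurs_TPSA": (0.0, 200.0), "Minimized_Energy": (-100.0, 0.0),
    "Shadow_Ylength": (2.0, 20.0),
}
_COUNT_DESCRIPTORS = {"ES_Count_aaCH", "ES_Count_sOH", "Num_Rings6"}


# ------------------------------------------------------------ QSAR tables


@dataclass
class PlantedQsarSpec:
    """Planted linear descriptor–activity relationship."""

    n_rows: int = 37
    n_train: int = 30
    n_test: int = 7
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "ES_Count_aaCH": 0.8,
        "Molecular_PolarSurfaceArea": 0.02,
        "CHI_2": -0.5,
    })
    intercept: float = 5.0
    sigma: float = 0.1
    ranges: dict[str, tuple] = field(default_factory=lambda: dict(_DEFAULT_RANGES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_train + self.n_test != self.n_rows:
            raise ValueError("split sizes must sum to n_rows")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        unknown = set(self.coefficients) - set(DESCRIPTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown descriptors: {sorted(unknown)}")


def gen_qsar_table(spec: PlantedQsarSpec) -> tuple[TrainingTable, dict]:
    """Draw descriptors uniformly in their ranges, compute
    ``pIC50 = intercept + sum(beta * d) + N(0, sigma)``, and split
    randomly into train/test.  Returns the table plus the ground truth."""
    rng = np.random.default_rng(spec.seed)
    cols = {}
    for name in DESCRIPTOR_NAMES:
        lo, hi = spec.ranges[name]
        if name in _COUNT_DESCRIPTORS:
            cols[name] = rng.integers(lo, hi + 1, size=spec.n_rows).astype(float)
        else:
            cols[name] = rng.uniform(lo, hi, size=spec.n_rows)
    df = pd.DataFrame(cols, index=pd.Index(
        [f"synth-{i + 1:03d}" for i in range(spec.n_rows)], name="name"))
    signal = np.full(spec.n_rows, spec.intercept)
    for name, beta in spec.coefficients.items():
        signal += beta * df[name].to_numpy()
    noise = rng.normal(0.0, spec.sigma, size=spec.n_rows) if spec.sigma else 0.0
    df["pIC50"] = signal + noise
    split = np.array(["train"] * spec.n_train + ["test"] * spec.n_test)
    df["split"] = rng.permutation(split)
    table = TrainingTable(df, list(DESCRIPTOR_NAMES))
    truth = {
        "intercept": spec.intercept,
        "coefficients": dict(spec.coefficients),
        "sigma": spec.sigma,
        "seed": spec.seed,
        "n_train": spec.n_train,
        "n_test": spec.n_test,
    }
    return table, truth


def write_qsar_table(table: TrainingTable, truth: dict, out_dir) -> None:
    """CSV plus its ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.data.to_csv(out / "qsar_table.csv")
    (out / "qsar_table.truth.json").write_text(json.dumps(truth, indent=2))


# ------------------------------------------------------------ score tables


def gen_score_table(n: int, seed: int = 0) -> tuple[list[CandidateRecord], dict]:
    """Random screening-score table with a designated control.

    Candidate dock scores straddle the control's so the dock gate is
    exercised in both directions.  (The printed FKBP52 table is available
    separately via :func:`fkbpscreen.screen.bundled_score_table`.)
    """
    rng = np.random.default_rng(seed)
    control_dock = float(rng.uniform(55.0, 65.0))
    records = []
    for i in range(n):
        records.append(CandidateRecord(
            name=f"synth-cand-{i + 1:02d}",
            svm_pred=float(rng.uniform(4.5, 5.5)),
            mlr_pred=float(rng.uniform(5.0, 9.0)),
            bn_pred=float(rng.uniform(5.0, 8.0)),
            dock_score=float(rng.uniform(50.0, 90.0)),
        ))
    control = CandidateRecord(name="synth-control", svm_pred=5.1,
                              mlr_pred=6.2, bn_pred=5.3,
                              dock_score=control_dock, is_control=True)
    truth = {"seed": seed, "n": n, "control_dock": control_dock}
    return records + [control], truth


# ------------------------------------------------------------ trajectories


@dataclass
class PlantedTrajSpec:
    """Toy trajectory with planted observables.

    A rigid scatter of ``n_base`` atoms gets isotropic Gaussian jitter of
    ``jitter_sigma`` Å per frame; one designated atom pair sits at 3.0 Å
    (inside the 2.3–3.2 Å H-bond window) in a planted fraction of frames
    and at 5.0 Å otherwise; four extra atoms trace ``torsion_schedule``
    (degrees per frame, default constant -90°).
    """

    n_frames: int = 100
    n_base: int = 10
    jitter_sigma: float = 0.1
    hbond_fraction: float = 0.5
    torsion_schedule: Optional[np.ndarray] = None
    dt_ns: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.hbond_fraction <= 1.0:
            raise ValueError("hbond_fraction must be in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.n_base < 4:
            raise ValueError("need at least 4 base atoms")


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement: position D at distance ``r``
    from C, angle B-C-D ``theta``, dihedral A-B-C-D ``phi``."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        -r * np.sin(theta) * np.sin(phi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_trajectory(spec: PlantedTrajSpec) -> tuple[Trajectory, dict]:
    """Build the planted toy trajectory plus its ground-truth record."""
    rng = np.random.default_rng(spec.seed)
    nb = spec.n_base
    base = rng.uniform(-5.0, 5.0, size=(nb, 3))
    # H-bond pair: donor fixed, acceptor along +x at a scheduled distance
    donor = np.array([20.0, 0.0, 0.0])
    n_in = int(round(spec.hbond_fraction * spec.n_frames))
    in_window = np.zeros(spec.n_frames, dtype=bool)
    in_window[:n_in] = True
    hb_dist = np.where(in_window, 3.0, 5.0)
    # torsion quartet on its own offset plane
    off = np.array([0.0, 20.0, 0.0])
    t0 = off + np.array([0.0, 0.0, 0.0])
    t1 = off + np.array([1.5, 0.0, 0.0])
    t2 = off + np.array([2.2, 1.3, 0.0])
    schedule = (np.full(spec.n_frames, -90.0)
                if spec.torsion_schedule is None
                else np.asarray(spec.torsion_schedule, dtype=float))
    if len(schedule) != spec.n_frames:
        raise ValueError("torsion schedule length must equal n_frames")

    n_atoms = nb + 2 + 4
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        jitter = rng.normal(0.0, spec.jitter_sigma, size=(nb, 3)) \
            if spec.jitter_sigma > 0 else 0.0
        coords[f, :nb] = base + jitter
        coords[f, nb] = donor
        coords[f, nb + 1] = donor + np.array([hb_dist[f], 0.0, 0.0])
        coords[f, nb + 2] = t0
        coords[f, nb + 3] = t1
        coords[f, nb + 4] = t2
        coords[f, nb + 5] = _place_atom(t0, t1, t2, 1.5, 109.5, schedule[f])

    names = np.array([f"C{i + 1}" for i in range(nb)]
                     + ["OD", "OA", "T1", "T2", "T3", "T4"], dtype=object)
    elements = np.array(["C"] * nb + ["O", "O", "C", "C", "C", "C"],
                        dtype=object)
    # resid 1 = rigid jittered base, 2 = H-bond pair, 3 = torsion quartet,
    # so e.g. "resid 1" selects the base scatter alone
    resids = np.array([1] * nb + [2, 2, 3, 3, 3, 3])
    traj = Trajectory(
        names=names, elements=elements,
        resids=resids,
        resnames=np.array(["TOY"] * n_atoms, dtype=object),
        masses=np.array([element_mass(e) for e in elements]),
        radii=np.array([vdw_radius(e) for e in elements]),
        times=spec.dt_ns * np.arange(spec.n_frames),
        coords=coords,
    )
    truth = {
        "seed": spec.seed,
        "jitter_sigma": spec.jitter_sigma,
        "hbond_pair": HbondPair(donor=nb, acceptor=nb + 1, label="planted"),
        "hbond_fraction_planted": spec.hbond_fraction,
        "hbond_fraction_realized": n_in / spec.n_frames,
        "torsion": TorsionSpec(atoms=(nb + 2, nb + 3, nb + 4, nb + 5),
                               label="planted"),
        "torsion_schedule": schedule,
        "base_atoms": list(range(nb)),
    }
    return traj, truth


# ------------------------------------------------------------ SS fixtures

# ideal backbone geometry (lengths Å, angles deg)
_BB = {"n_ca": 1.458, "ca_c": 1.525, "c_n": 1.329, "c_o": 1.231,
       "n_ca_c": 111.2, "ca_c_n": 116.2, "c_n_ca": 121.7, "ca_c_o": 120.5}


def _build_chain(n_res: int, phi: float, psi: float,
                 omega: float = 180.0) -> np.ndarray:
    """Poly-alanine backbone (N, CA, C, O per residue) with uniform
    torsions; returns (n_res * 4, 3) coordinates."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.radians(180.0 - _BB["n_ca_c"])
    c = ca + _BB["ca_c"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    coords = []
    for r in range(n_res):
        if r > 0:
            n = _place_atom(prev[0], prev[1], prev[2],
                            _BB["c_n"], _BB["ca_c_n"], psi)
            ca = _place_atom(prev[1], prev[2], n,
                             _BB["n_ca"], _BB["c_n_ca"], omega)
            c = _place_atom(prev[2], n, ca, _BB["ca_c"], _BB["n_ca_c"], phi)
        prev = (n, ca, c)
        coords.append([n, ca, c, None])  # O placed once the next N is known
    out = []
    for r in range(n_res):
        n, ca, c, _ = coords[r]
        if r + 1 < n_res:
            n_next = coords[r + 1][0]
            o = _place_atom(n_next, ca, c, _BB["c_o"], _BB["ca_c_o"], 180.0)
        else:
            o = _place_atom(n, ca, c, _BB["c_o"], _BB["ca_c_o"], psi + 180.0)
        out.extend([n, ca, c, o])
    return np.asarray(out)


def _chain_trajectory(coords: np.ndarray, resid_start: int = 1) -> Trajectory:
    n_res = len(coords) // 4
    names = np.array(["N", "CA", "C", "O"] * n_res, dtype=object)
    elements = np.array(["N", "C", "C", "O"] * n_res, dtype=object)
    resids = np.repeat(np.arange(resid_start, resid_start + n_res), 4)
    return Trajectory(
        names=names, elements=elements, resids=resids,
        resnames=np.array(["ALA"] * (4 * n_res), dtype=object),
        masses=np.array([element_mass(e) for e in elements]),
        radii=np.array([vdw_radius(e) for e in elements]),
        times=np.array([0.0]),
        coords=coords[None, :, :],
    )


def _pair_strands(strand: np.ndarray, n_res: int) -> np.ndarray:
    """Place a second, antiparallel copy of ``strand`` so that the two
    form inter-strand backbone H-bonds.  The rigid placement (flip axis
    and offset) is chosen by maximizing the Kabsch–Sander H-bond count
    over a deterministic coarse-then-fine grid."""
    residues = _backbone_index(_chain_trajectory(
        np.vstack([strand, strand + 100.0])))
    flip = np.diag([-1.0, -1.0, 1.0])  # reverse the chain direction
    flipped = strand @ flip.T

    def sheet_quality(offset: np.ndarray) -> tuple[int, int]:
        both = np.vstack([strand, flipped + offset])
        hb = _hbond_matrix(both, residues)
        labels = _assign_frame(both, residues)
        n_bridge = int((labels == "E").sum())
        n_hb = int(hb[:n_res, n_res:].sum() + hb[n_res:, :n_res].sum())
        return n_bridge, n_hb

    # coarse register/separation scan, then greedy local refinement
    best_off, best_q = None, (-1, -1)
    for dx in np.arange(8.0, 17.01, 0.5):
        for dy in np.arange(3.0, 8.01, 0.5):
            for dz in np.arange(-1.0, 1.01, 0.5):
                off = np.array([dx, dy, dz])
                q = sheet_quality(off)
                if q > best_q:
                    best_off, best_q = off, q
    for step in (0.25, 0.1):
        improved = True
        while improved:
            improved = False
            for delta in step * np.array(
                    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                     [0, 0, 1], [0, 0, -1]], dtype=float):
                q = sheet_quality(best_off + delta)
                if q > best_q:
                    best_off, best_q = best_off + delta, q
                    improved = True
    return np.vstack([strand, flipped + best_off])


def gen_ss_fixtures() -> dict[str, Trajectory]:
    """Ideal secondary-structure fixtures as single-frame trajectories:

    * ``helix`` — 12-residue poly-alanine α-helix (φ=−57°, ψ=−47°);
    * ``sheet`` — two 8-residue antiparallel strands (φ=−139°, ψ=135°)
      paired to form inter-strand H-bonds;
    * ``extended`` — 12-residue fully extended chain (φ=ψ=180°).
    """
    helix = _build_chain(12, phi=-57.0, psi=-47.0)
    strand = _build_chain(8, phi=-139.0, psi=135.0)  # ideal antiparallel
    sheet = _pair_strands(strand, 8)
    extended = _build_chain(12, phi=180.0, psi=180.0)
    return {
        "helix": _chain_trajectory(helix),
        "sheet": _chain_trajectory(sheet),
        "extended": _chain_trajectory(extended),
    }
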