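"""Kabsch–Sander secondary-structure assignment.

Backbone N–H···O=C hydrogen bonds are detected from the electrostatic
energy

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332  kcal/mol

with a bond assigned when E < -0.5 kcal/mol.  Amide hydrogens missing
from the topology are imputed 1.0 Å from N along the direction of the
previous residue's C→O vector reversed.  Classes (priority order):

* ``H`` — α-helix: two consecutive n→n+4 turn H-bonds (3₁₀/π folded in);
* ``E`` — β-sheet: parallel or antiparallel bridge patterns, |i−j| > 2;
* ``T`` — n→n+3/4/5 turn without helix;
* ``S`` — bend: Cα chain direction change > 70° over i±2;
* ``C`` — everything else (including residues with missing backbone atoms).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import PROTEIN_RESNAMES, Trajectory

log = logging.getLogger(__name__)

SS_CLASSES = ("H", "E", "T", "S", "C")
_Q = 0.084 * 332.0       # kcal/mol·Å, Kabsch–Sander coupling constant
_E_CUTOFF = -0.5         # kcal/mol
_MIN_DIST = 0.5          # Å; guard against coordinate pathologies


@dataclass
class SsTimeline:
    """Per-frame, per-residue class labels and per-class fraction series."""

    times: np.ndarray
    resids: np.ndarray
    labels: np.ndarray                 # (n_frames, n_residues) of SS_CLASSES
    fractions: dict[str, np.ndarray]   # class -> (n_frames,) fraction

    def fraction_summary(self) -> dict[str, float]:
        return {c: float(series.mean()) for c, series in self.fractions.items()}


def _backbone_index(traj: Trajectory):
    """Per protein residue, the N/CA/C/O (and H if present) atom indices."""
    residues = []
    order = {}
    for i in range(traj.n_atoms):
        if traj.resnames[i] not in PROTEIN_RESNAMES:
            continue
        key = (traj.chains[i], int(traj.resids[i]))
        if key not in order:
            order[key] = {"resid": int(traj.resids[i]),
                          "resname": traj.resnames[i]}
            residues.append(order[key])
        name = traj.names[i]
        if name in ("N", "CA", "C", "O", "H", "HN"):
            order[key]["H" if name == "HN" else name] = i
    return residues


def _hbond_matrix(coords: np.ndarray, residues: list[dict]) -> np.ndarray:
    """hb[d, a]: backbone NH of residue d donates to CO of residue a."""
    nres = len(residues)
    n_pos = np.full((nres, 3), np.nan)
    h_pos = np.full((nres, 3), np.nan)
    c_pos = np.full((nres, 3), np.nan)
    o_pos = np.full((nres, 3), np.nan)
    for r, res in enumerate(residues):
        if "N" in res:
            n_pos[r] = coords[res["N"]]
        if "C" in res:
            c_pos[r] = coords[res["C"]]
        if "O" in res:
            o_pos[r] = coords[res["O"]]
        if "H" in res:
            h_pos[r] = coords[res["H"]]
        elif ("N" in res and r > 0 and res["resname"] != "PRO"
              and "C" in residues[r - 1] and "O" in residues[r - 1]):
            co = c_pos[r - 1] - o_pos[r - 1]
            h_pos[r] = n_pos[r] + co / np.linalg.norm(co)
    hb = np.zeros((nres, nres), dtype=bool)
    for d in range(nres):
        if np.isnan(n_pos[d]).any() or np.isnan(h_pos[d]).any():
            continue
        for a in range(nres):
            if a == d or abs(a - d) < 2:
                continue
            if np.isnan(c_pos[a]).any() or np.isnan(o_pos[a]).any():
                continue
            r_on = np.linalg.norm(o_pos[a] - n_pos[d])
            if r_on > 5.2:  # beyond any plausible backbone H-bond
                continue
            r_ch = np.linalg.norm(c_pos[a] - h_pos[d])
            r_oh = np.linalg.norm(o_pos[a] - h_pos[d])
            r_cn = np.linalg.norm(c_pos[a] - n_pos[d])
            if min(r_on, r_ch, r_oh, r_cn) < _MIN_DIST:
                continue
            energy = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hb[d, a] = energy < _E_CUTOFF
    return hb


def _assign_frame(coords: np.ndarray, residues: list[dict]) -> np.ndarray:
    nres = len(residues)
    hb = _hbond_matrix(coords, residues)
    labels = np.full(nres, "C", dtype=object)

    def turn(n: int, i: int) -> bool:
        return i + n < nres and hb[i + n, i]

    # bends first (lowest priority; later classes overwrite)
    for i in range(2, nres - 2):
        res_set = (residues[i - 2], residues[i], residues[i + 2])
        if any("CA" not in r for r in res_set):
            continue
        v1 = coords[residues[i]["CA"]] - coords[residues[i - 2]["CA"]]
        v2 = coords[residues[i + 2]["CA"]] - coords[residues[i]["CA"]]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom == 0:
            continue
        ang = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1.0, 1.0)))
        if ang > 70.0:
            labels[i] = "S"

    # turns: residues spanned by an n->n+3/4/5 H-bond
    for i in range(nres):
        for n in (3, 4, 5):
            if turn(n, i):
                labels[i + 1:i + n] = "T"

    # bridges / sheets
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            parallel = (hb[j, i - 1] and hb[i + 1, j]) or \
                       (hb[i, j - 1] and hb[j + 1, i])
            antiparallel = (hb[j, i] and hb[i, j]) or \
                           (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if parallel or antiparallel:
                labels[i] = labels[j] = "E"

    # helices: two consecutive 4-turns cover residues i..i+3
    for i in range(1, nres):
        if turn(4, i - 1) and turn(4, i):
            labels[i:i + 4] = "H"

    for i, res in enumerate(residues):
        if any(k not in res for k in ("N", "CA", "C", "O")):
            labels[i] = "C"
    return labels


def secondary_structure(traj: Trajectory) -> SsTimeline:
    """Assign per-residue secondary structure for every frame and report
    per-class fraction series (fractions sum to 1 per frame)."""
    residues = _backbone_index(traj)
    if not residues:
        raise ValueError("no protein residues in trajectory")
    incomplete = sum(1 for r in residues
                     if any(k not in r for k in ("N", "CA", "C", "O")))
    if incomplete:
        log.warning("%d residue(s) missing backbone atoms; classed C",
                    incomplete)
    nres = len(residues)
    labels = np.empty((traj.n_frames, nres), dtype=object)
    for f in range(traj.n_frames):
        labels[f] = _assign_frame(traj.coords[f], residues)
    fractions = {
        c: (labels == c).sum(axis=1) / nres for c in SS_CLASSES
    }
    return SsTimeline(times=traj.times.copy(),
                      resids=np.array([r["resid"] for r in residues]),
                      labels=labels, fractions=fractions)
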