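"""Per-frame and whole-trajectory statistics.

All superpositions use the Kabsch least-squares algorithm with the proper-
rotation (det = +1) correction; RMSD is coordinate-only (unweighted) by
default, with a mass-weighted variant available where it matters (radius
of gyration is always mass-weighted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ..sasa import shrake_rupley
from .core import HbondPair, TorsionSpec, Trajectory

log = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    """Fewer than three non-collinear atoms in a superposition selection."""


# ------------------------------------------------------------ superposition


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           weights: Optional[np.ndarray] = None
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``mobile @ R.T + t`` the fitted
    coordinates and ``rmsd`` the post-fit RMSD over the input atoms
    (weighted if ``weights`` given).  The rotation is always proper.
    """
    p = np.asarray(mobile, dtype=float)
    q = np.asarray(reference, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("need matching (n, 3) coordinate arrays")
    if len(p) < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    w = np.ones(len(p)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    pc = p - (w[:, None] * p).sum(axis=0)
    qc = q - (w[:, None] * q).sum(axis=0)
    if np.linalg.matrix_rank(pc, tol=1e-8) < 2:
        raise DegenerateGeometryError("selection is collinear")
    h = (w[:, None] * pc).T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = (w[:, None] * q).sum(axis=0) - rot @ (w[:, None] * p).sum(axis=0)
    fitted = p @ rot.T + t
    rmsd = float(np.sqrt((w * ((fitted - q) ** 2).sum(axis=1)).sum()))
    return rot, t, rmsd


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: Optional[np.ndarray] = None,
              weights: Optional[np.ndarray] = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit ``mobile`` onto ``reference`` using ``selection`` (atom index
    array; default all atoms); RMSD is reported over the selection."""
    if selection is not None:
        sel_w = None if weights is None else weights[selection]
        return kabsch(mobile[selection], reference[selection], sel_w)
    return kabsch(mobile, reference, weights)


# ------------------------------------------------------------ RMSD / RMSF


def rmsd_series(traj: Trajectory, fit_selection: str = "protein",
                measure_selection: Optional[str] = None,
                mass_weighted: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
    """RMSD versus the first frame.

    Each frame is rigidly fitted on ``fit_selection`` and the deviation
    measured on ``measure_selection`` (default: same as fit) — so ligand
    RMSD is obtained by fitting on the protein and measuring the ligand.
    """
    fit_idx = traj.select(fit_selection)
    meas_idx = (fit_idx if measure_selection is None
                else traj.select(measure_selection))
    if len(meas_idx) == 0:
        raise ValueError("empty measure selection")
    ref = traj.coords[0]
    weights = traj.masses if mass_weighted else None
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, t, _ = superpose(traj.coords[f], ref, fit_idx, weights)
        fitted = traj.coords[f][meas_idx] @ rot.T + t
        diff2 = ((fitted - ref[meas_idx]) ** 2).sum(axis=1)
        if mass_weighted:
            w = traj.masses[meas_idx] / traj.masses[meas_idx].sum()
            out[f] = np.sqrt((w * diff2).sum())
        else:
            out[f] = np.sqrt(diff2.mean())
    return traj.times.copy(), out


def rmsf(traj: Trajectory, selection: str = "protein",
         by_residue: bool = False, n_iter: int = 2, align: bool = True
         ) -> tuple[np.ndarray, np.ndarray]:
    """Root-mean-square fluctuation about the mean structure.

    Frames are superposed onto the (iteratively refined) average
    structure of the selection first (``align=False`` skips the fit for
    pre-aligned trajectories).  Returns ``(ids, values)`` — atom indices,
    or residue ids with per-residue atom averaging when ``by_residue``.
    A single-frame trajectory yields zeros.
    """
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    if traj.n_frames == 1:
        log.warning("single frame: RMSF is identically zero")
        vals = np.zeros(len(idx))
    else:
        frames = traj.coords[:, idx, :].copy()
        mean = frames[0]
        for _ in range(n_iter if align else 0):
            fitted = np.empty_like(frames)
            for f in range(len(frames)):
                rot, t, _ = kabsch(frames[f], mean)
                fitted[f] = frames[f] @ rot.T + t
            mean = fitted.mean(axis=0)
            frames = fitted
        mean = frames.mean(axis=0)
        vals = np.sqrt(((frames - mean) ** 2).sum(axis=2).mean(axis=0))
    if not by_residue:
        return idx, vals
    resids = traj.resids[idx]
    uniq = np.unique(resids)
    per_res = np.array([vals[resids == r].mean() for r in uniq])
    return uniq, per_res


# ------------------------------------------------------------ Rg / SASA


@dataclass
class RgResult:
    times: np.ndarray     # ns
    values: np.ndarray    # nm
    average: float
    maximum: float


def radius_of_gyration(traj: Trajectory, selection: str = "protein") -> RgResult:
    """Mass-weighted radius of gyration per frame, reported in nm."""
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    m = traj.masses[idx]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        r = traj.coords[f][idx]
        com = (m[:, None] * r).sum(axis=0) / m.sum()
        out[f] = np.sqrt((m * ((r - com) ** 2).sum(axis=1)).sum() / m.sum())
    values_nm = out / 10.0
    return RgResult(traj.times.copy(), values_nm,
                    float(values_nm.mean()), float(values_nm.max()))


def sasa_series(traj: Trajectory, selection: str = "all",
                probe: float = 1.4, n_points: int = 960
                ) -> tuple[np.ndarray, np.ndarray]:
    """Total solvent-accessible surface area per frame (nm²) over the
    selection (Shrake–Rupley, 1.4 Å probe by default)."""
    idx = traj.select(selection)
    if len(idx) == 0:
        raise ValueError("empty selection")
    totals = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        areas = shrake_rupley(traj.coords[f][idx], traj.radii[idx],
                              probe=probe, n_points=n_points)
        totals[f] = areas.sum() / 100.0  # Å² -> nm²
    return traj.times.copy(), totals


# ------------------------------------------------------------ H-bonds


def hbond_series(traj: Trajectory, pairs: Sequence[HbondPair],
                 use_hydrogen: bool = False) -> dict[str, np.ndarray]:
    """Per-pair donor–acceptor distance series (Å); ``use_hydrogen``
    switches to hydrogen–acceptor distances where a hydrogen is given."""
    out = {}
    for pair in pairs:
        pair.validate(traj)
        a = pair.acceptor
        d = (pair.hydrogen if use_hydrogen and pair.hydrogen is not None
             else pair.donor)
        delta = traj.coords[:, d, :] - traj.coords[:, a, :]
        label = pair.label or f"{d}-{a}"
        out[label] = np.sqrt((delta ** 2).sum(axis=1))
    return out


def hbond_occupancy(distances: np.ndarray, lo: float = 2.3,
                    hi: float = 3.2) -> float:
    """Percentage of frames with ``lo <= d <= hi`` (the optimal H-bond
    window, 2.3–3.2 Å by default)."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValueError("empty distance series")
    return float(100.0 * ((d >= lo) & (d <= hi)).mean())


# ------------------------------------------------------------ torsions


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees, in (-180, 180]; NaN when the
    middle bond is collinear with either flank."""
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        return np.nan
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = n1 @ n2
    y = m1 @ n2
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if ang == -180.0 else float(ang)


@dataclass
class TorsionResult:
    times: np.ndarray
    raw: np.ndarray        # X: signed angle, (-180, 180]
    unwrapped: np.ndarray  # Y: X + 360 where X < 0, so Y in [0, 360)
    delta: np.ndarray      # Z: Y[i+1] - Y[i], length n_frames - 1


def torsion_series(traj: Trajectory, spec: TorsionSpec) -> TorsionResult:
    """Dihedral series with the X/Y/Z decomposition: raw signed angle X,
    the non-negative rewrap Y (= X, or X + 360 when X < 0), and the
    frame-to-frame change Z of Y.  Frames with an undefined dihedral
    (collinear middle bond) carry NaN."""
    i, j, k, l = spec.atoms
    x = np.array([
        dihedral(traj.coords[f, i], traj.coords[f, j],
                 traj.coords[f, k], traj.coords[f, l])
        for f in range(traj.n_frames)
    ])
    if np.isnan(x).any():
        log.warning("torsion %s undefined in %d frame(s)",
                    spec.label or spec.atoms, int(np.isnan(x).sum()))
    y = np.where(x < 0, x + 360.0, x)
    return TorsionResult(traj.times.copy(), x, y, np.diff(y))


# ------------------------------------------------------------ clustering


@dataclass
class ClusterResult:
    clusters: list[dict]        # {center, members, center_time}, largest first
    representative: int         # frame index (within the full trajectory)
    representative_time: float  # ns


def cluster_frames(traj: Trajectory, cutoff: float = 1.0,
                   selection: str = "all",
                   window: Optional[tuple[float, float]] = None
                   ) -> ClusterResult:
    """GROMOS conformational clustering over a time window.

    Builds the pairwise superposed-RMSD matrix over the window's frames,
    then repeatedly takes the frame with the most neighbours within
    ``cutoff`` Å as a cluster centre and removes the cluster.  The
    representative conformation is the centre of the largest cluster.
    """
    idx = traj.select(selection)
    if window is None:
        frame_ids = np.arange(traj.n_frames)
    else:
        lo, hi = window
        frame_ids = np.flatnonzero((traj.times >= lo) & (traj.times <= hi))
    if len(frame_ids) == 0:
        raise ValueError("empty time window")
    coords = traj.coords[np.ix_(frame_ids, idx)]
    nf = len(frame_ids)
    dist = np.zeros((nf, nf))
    for a in range(nf):
        for b in range(a + 1, nf):
            _, _, r = kabsch(coords[b], coords[a])
            dist[a, b] = dist[b, a] = r
    remaining = list(range(nf))
    clusters = []
    while remaining:
        sub = np.array(remaining)
        counts = (dist[np.ix_(sub, sub)] <= cutoff).sum(axis=1)
        center = sub[int(np.argmax(counts))]  # ties -> earliest frame
        members = [f for f in remaining if dist[center, f] <= cutoff]
        clusters.append({
            "center": int(frame_ids[center]),
            "members": [int(frame_ids[m]) for m in members],
            "center_time": float(traj.times[frame_ids[center]]),
        })
        remaining = [f for f in remaining if f not in members]
    clusters.sort(key=lambda c: (-len(c["members"]), c["center"]))
    rep = clusters[0]["center"]
    return ClusterResult(clusters, rep, float(traj.times[rep]))
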