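"""Shrake–Rupley solvent-accessible surface area.

Each atom is expanded by the probe radius (1.4 Å water by default) and
covered with a quasi-uniform Fibonacci point lattice; a point counts as
exposed iff it lies outside every neighbouring expanded sphere.  The
per-atom area is the exposed fraction of ``4*pi*(r_vdw + probe)**2``.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

# Bondi vdW radii, Å
_VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98,
    "NA": 2.27, "K": 2.75, "MG": 1.73, "ZN": 1.39, "FE": 1.94,
}
_DEFAULT_RADIUS = 1.70


def vdw_radius(element: str) -> float:
    """Bondi vdW radius for an element symbol; carbon-like 1.70 Å fallback."""
    r = _VDW_RADII.get(element.strip().upper())
    if r is None:
        log.warning("no vdW radius for element %r; using %.2f Å",
                    element, _DEFAULT_RADIUS)
        return _DEFAULT_RADIUS
    return r


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors (golden-spiral lattice)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom accessible surface area (Å²).

    Parameters
    ----------
    coords : (n, 3) positions in Å.
    radii : (n,) vdW radii in Å.
    probe : probe sphere radius, Å.
    n_points : lattice points per atom; accuracy ~ O(1/n_points).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("coords must be (n, 3)")
    if np.any(radii <= 0):
        raise ValueError("vdW radii must be strictly positive")
    n = len(coords)
    expanded = radii + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * expanded.max()
    areas = np.empty(n)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > expanded[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * expanded[i] ** 2
    return areas
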