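"""Numerical solvent-accessible surface area (Shrake–Rupley).

Deterministic Fibonacci sphere lattice; per-atom areas in Å².
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    if n <= 0:
        raise ValueError("sphere-point count must be positive")
    k = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = 2.0 * np.pi * k / phi
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
    occluder_coords: np.ndarray | None = None,
    occluder_radii: np.ndarray | None = None,
) -> np.ndarray:
    """Per-atom SASA for ``coords``/``radii``.

    ``occluder_coords`` adds extra atoms that block solvent but whose own
    area is not reported (used for the with/without-ligand comparison).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.size == 0:
        raise ValueError("empty structure")
    if probe_radius < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points <= 0:
        raise ValueError("sphere-point count must be positive")

    unit = sphere_points(n_points)

    if occluder_coords is not None and len(occluder_coords) > 0:
        all_coords = np.vstack([coords, np.asarray(occluder_coords, dtype=float)])
        all_radii = np.concatenate([radii, np.asarray(occluder_radii, dtype=float)])
    else:
        all_coords = coords
        all_radii = radii

    extended = all_radii + probe_radius
    tree = cKDTree(all_coords)
    max_ext = float(extended.max())

    areas = np.zeros(len(coords))
    for i in range(len(coords)):
        r_i = radii[i] + probe_radius
        pts = coords[i] + unit * r_i
        neighbors = tree.query_ball_point(coords[i], r_i + max_ext)
        neighbors = [j for j in neighbors if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum(
                "ij,ij->i", pts - all_coords[j], pts - all_coords[j]
            )
            accessible &= d2 > extended[j] ** 2
        areas[i] = 4.0 * np.pi * r_i * r_i * accessible.mean()
    return areas
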