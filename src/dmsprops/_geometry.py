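"""Internal 3D geometry utilities: dihedral measurement and manipulation.

Coordinates are in angstroms, angles in radians unless a function name says
degrees.  Dihedral sign convention follows IUPAC (looking down the j->k bond,
positive = clockwise rotation of l relative to i).
"""

from __future__ import annotations

import numpy as np


def measure_dihedral(coords: np.ndarray, i: int, j: int, k: int, l: int) -> float:
    """Dihedral angle (radians, in (-pi, pi]) defined by atoms i-j-k-l."""
    b1 = coords[j] - coords[i]
    b2 = coords[k] - coords[j]
    b3 = coords[l] - coords[k]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    return float(np.arctan2(y, x))


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix about a (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ux, uy, uz = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1.0 - c
    return np.array(
        [
            [c + ux * ux * cc, ux * uy * cc - uz * s, ux * uz * cc + uy * s],
            [uy * ux * cc + uz * s, c + uy * uy * cc, uy * uz * cc - ux * s],
            [uz * ux * cc - uy * s, uz * uy * cc + ux * s, c + uz * uz * cc],
        ]
    )


def bond_partition(n_atoms: int, bonds: list[tuple[int, int]], j: int, k: int) -> np.ndarray:
    """Atom indices on the k-side of bond (j, k) when that bond is removed.

    Breadth-first search over the bond graph; assumes (j, k) is a bridge
    (true for acyclic molecules), otherwise the rotation would tear a ring.
    """
    adj: list[list[int]] = [[] for _ in range(n_atoms)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    seen = np.zeros(n_atoms, dtype=bool)
    seen[j] = True  # wall off the j side
    seen[k] = True
    stack = [k]
    tail = [k]
    while stack:
        cur = stack.pop()
        for nb in adj[cur]:
            if not seen[nb]:
                seen[nb] = True
                stack.append(nb)
                tail.append(nb)
    if j in tail:
        raise ValueError(f"bond ({j}, {k}) lies in a ring; cannot rotate about it")
    return np.array(sorted(tail), dtype=int)


def set_dihedral(
    coords: np.ndarray,
    bonds: list[tuple[int, int]],
    dihedral: tuple[int, int, int, int],
    target: float,
) -> np.ndarray:
    """Return coords with dihedral i-j-k-l rotated to ``target`` (radians).

    The rigid tail on the k-side of the j-k bond is rotated; all other
    dihedral angles in an acyclic molecule are unaffected.
    """
    i, j, k, l = dihedral
    current = measure_dihedral(coords, i, j, k, l)
    delta = target - current
    if abs(delta) < 1e-15:
        return coords.copy()
    # rotating the tail by +angle about the j->k axis decreases the
    # IUPAC-signed dihedral, hence the minus sign
    axis = coords[k] - coords[j]
    rot = rotation_matrix(axis, -delta)
    tail = bond_partition(coords.shape[0], bonds, j, k)
    out = coords.copy()
    out[tail] = (out[tail] - coords[k]) @ rot.T + coords[k]
    return out


def chain_coords(
    n: int,
    bond_length: float = 1.52,
    bond_angle_deg: float = 111.0,
    dihedrals_deg: np.ndarray | None = None,
) -> np.ndarray:
    """Cartesian coordinates of an n-atom chain from internal coordinates.

    Uses sequential placement (NeRF): atom ``i`` is positioned relative to
    atoms ``i-1, i-2, i-3`` at the given bond length, bond angle, and
    dihedral.  ``dihedrals_deg`` must have length ``max(n - 3, 0)``;
    defaults to all-anti (180 degrees).
    """
    if n < 1:
        raise ValueError("need at least one atom")
    if dihedrals_deg is None:
        dihedrals_deg = np.full(max(n - 3, 0), 180.0)
    dihedrals_deg = np.asarray(dihedrals_deg, dtype=float)
    if dihedrals_deg.size != max(n - 3, 0):
        raise ValueError(f"expected {max(n - 3, 0)} dihedrals, got {dihedrals_deg.size}")

    theta = np.deg2rad(bond_angle_deg)
    coords = np.zeros((n, 3))
    if n >= 2:
        coords[1] = [bond_length, 0.0, 0.0]
    if n >= 3:
        coords[2] = coords[1] + bond_length * np.array(
            [-np.cos(theta), np.sin(theta), 0.0]
        )
    for idx in range(3, n):
        phi = np.deg2rad(dihedrals_deg[idx - 3])
        a, b, c = coords[idx - 3], coords[idx - 2], coords[idx - 1]
        bc = c - b
        bc /= np.linalg.norm(bc)
        ab = b - a
        normal = np.cross(ab, bc)
        normal /= np.linalg.norm(normal)
        m = np.cross(normal, bc)
        # local displacement for bond length r, angle theta, dihedral phi;
        # the minus on the normal component makes the placed dihedral match
        # the IUPAC sign returned by measure_dihedral
        d_local = bond_length * np.array(
            [-np.cos(theta), np.sin(theta) * np.cos(phi), -np.sin(theta) * np.sin(phi)]
        )
        coords[idx] = c + d_local[0] * bc + d_local[1] * m + d_local[2] * normal
    return coords
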