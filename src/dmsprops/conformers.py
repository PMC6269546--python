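"""Torsional conformer search on a classical toy potential.

The search operates purely in dihedral space: bond lengths and angles are
frozen, and the energy is a reduced force field —

* 12-6 Lennard-Jones between atom pairs separated by three or more bonds
  (1-4 interactions scaled by 0.5),
* Coulomb interaction of the carried partial charges over the same pairs,
* a three-term cosine torsion potential on every rotatable dihedral.

Basin hopping alternates a random distortion of every rotatable dihedral
(at most ``max_dihedral_step`` degrees each), local minimization, and
Metropolis acceptance on the minimized energies.  Distinct minima are
collected with a joint energy / dihedral-RMSD uniqueness test.  The whole
machinery is a desk-scale stand-in for conformer searches that refine
their minima with quantum chemistry; an export hook writes XYZ frames for
such external refinement.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from ._geometry import bond_partition, measure_dihedral, set_dihedral
from .records import BHConfig, Minimum, Structure

__all__ = [
    "StructureOverlapError",
    "LJ_PARAMS",
    "TORSION_TERMS",
    "COULOMB_K",
    "enumerate_protomers",
    "toy_potential",
    "local_minimize",
    "basin_hop",
    "dihedral_rmsd",
]


class StructureOverlapError(ValueError):
    """Raised when two atoms coincide and the pair energy would overflow."""


#: per-element Lennard-Jones sigma (A) and epsilon (kJ/mol)
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (2.50, 0.12),
    "C": (3.40, 0.36),
    "N": (3.25, 0.30),
    "O": (3.00, 0.25),
    "S": (3.60, 0.40),
    "F": (2.95, 0.25),
    "Cl": (3.45, 0.30),
}

#: cosine torsion series: (V_n kJ/mol, n, gamma_n rad); 3-fold dominant
#: with small 1- and 2-fold corrections.  The 3-fold barrier is set high
#: enough that the staggered wells survive the Coulomb tilt of a +1 ion.
TORSION_TERMS: list[tuple[float, int, float]] = [
    (0.8, 1, 0.0),
    (0.4, 2, np.pi),
    (5.0, 3, 0.0),
]

#: Coulomb constant, kJ mol^-1 A e^-2
COULOMB_K = 1389.35458

#: 1-4 nonbonded scaling
SCALE_14 = 0.5

_MIN_PAIR_DISTANCE = 1e-6


# --------------------------------------------------------------------------
# Pair bookkeeping
# --------------------------------------------------------------------------

def _bond_distances(n: int, bonds: list[tuple[int, int]]) -> np.ndarray:
    """All-pairs bond-graph distances (BFS; inf when disconnected)."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for a, b in bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        queue = [src]
        while queue:
            nxt: list[int] = []
            for cur in queue:
                for nb in adj[cur]:
                    if dist[src, nb] == np.inf:
                        dist[src, nb] = dist[src, cur] + 1
                        nxt.append(nb)
            queue = nxt
    return dist


def _nonbonded_pairs(structure: Structure) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(i, j, weight) arrays of pairs with >= 3 bonds between them."""
    n = structure.n_atoms
    d = _bond_distances(n, structure.bonds)
    ii, jj = np.triu_indices(n, k=1)
    keep = d[ii, jj] >= 3
    ii, jj = ii[keep], jj[keep]
    w = np.where(d[ii, jj] == 3, SCALE_14, 1.0)
    return ii, jj, w


# --------------------------------------------------------------------------
# Energy and gradient
# --------------------------------------------------------------------------

def _pair_energy_forces(structure: Structure) -> tuple[float, np.ndarray]:
    """Nonbonded (LJ + Coulomb) energy and cartesian gradient."""
    ii, jj, w = _nonbonded_pairs(structure)
    grad = np.zeros_like(structure.coords)
    if ii.size == 0:
        return 0.0, grad
    coords = structure.coords
    rij = coords[jj] - coords[ii]
    r = np.linalg.norm(rij, axis=1)
    if np.any(r < _MIN_PAIR_DISTANCE):
        k = int(np.argmin(r))
        raise StructureOverlapError(
            f"atoms {ii[k]} and {jj[k]} coincide (r={r[k]:.2e} A); "
            "pair energy would overflow"
        )
    try:
        sig = np.array([LJ_PARAMS[e][0] for e in structure.elements])
        eps = np.array([LJ_PARAMS[e][1] for e in structure.elements])
    except KeyError as exc:
        raise KeyError(f"no Lennard-Jones parameters for element {exc.args[0]!r}") from None
    sig_ij = 0.5 * (sig[ii] + sig[jj])
    eps_ij = np.sqrt(eps[ii] * eps[jj])
    sr6 = (sig_ij / r) ** 6
    e_lj = 4.0 * eps_ij * (sr6**2 - sr6)
    q = structure.charges
    e_coul = COULOMB_K * q[ii] * q[jj] / r
    energy = float(np.sum(w * (e_lj + e_coul)))
    # dE/dr for each pair
    dedr = w * (4.0 * eps_ij * (-12.0 * sr6**2 + 6.0 * sr6) / r - COULOMB_K * q[ii] * q[jj] / r**2)
    fvec = (dedr / r)[:, None] * rij  # gradient contribution on atom j
    np.add.at(grad, jj, fvec)
    np.add.at(grad, ii, -fvec)
    return energy, grad


def _torsion_energy_grad(theta: np.ndarray) -> tuple[float, np.ndarray]:
    energy = 0.0
    grad = np.zeros_like(theta)
    for v_n, n, gamma in TORSION_TERMS:
        energy += float(np.sum(0.5 * v_n * (1.0 + np.cos(n * theta - gamma))))
        grad += -0.5 * v_n * n * np.sin(n * theta - gamma)
    return energy, grad


def current_dihedrals(structure: Structure) -> np.ndarray:
    """Current rotatable dihedral angles (radians)."""
    return np.array(
        [measure_dihedral(structure.coords, *d) for d in structure.rotatable_dihedrals]
    )


def toy_potential(structure: Structure) -> tuple[float, np.ndarray]:
    """Energy (kJ/mol) and analytic gradient w.r.t. the rotatable dihedrals.

    The cartesian nonbonded gradient is mapped into dihedral space through
    the rotation generator of each dihedral's tail: rotating the tail of
    bond (j, k) moves atom m by ``b_hat x (r_m - r_k)`` per radian.
    """
    e_nb, g_cart = _pair_energy_forces(structure)
    theta = current_dihedrals(structure)
    e_t, g_t = _torsion_energy_grad(theta)
    grad = g_t.copy()
    coords = structure.coords
    for idx, (i, j, k, l) in enumerate(structure.rotatable_dihedrals):
        axis = coords[k] - coords[j]
        axis = axis / np.linalg.norm(axis)
        tail = bond_partition(structure.n_atoms, structure.bonds, j, k)
        # d r_m / d theta = -(b_hat x (r_m - r_k)): a unit increase of the
        # IUPAC dihedral is a -1 rad rotation of the tail about j->k
        disp = -np.cross(np.broadcast_to(axis, (tail.size, 3)), coords[tail] - coords[k])
        grad[idx] += float(np.sum(g_cart[tail] * disp))
    return e_nb + e_t, grad


def _with_dihedrals(structure: Structure, theta: np.ndarray) -> Structure:
    out = structure.copy()
    for d, t in zip(structure.rotatable_dihedrals, theta):
        out.coords = set_dihedral(out.coords, out.bonds, d, float(t))
    return out


# --------------------------------------------------------------------------
# Local minimization
# --------------------------------------------------------------------------

def local_minimize(
    structure: Structure,
    potential=toy_potential,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> Minimum:
    """L-BFGS minimization in dihedral coordinates.

    Returns a :class:`Minimum` whose ``converged`` flag reflects whether
    the gradient max-norm dropped below ``tol`` (kJ/mol/rad); the energy
    never exceeds the input energy.  A structure without rotatable
    dihedrals is returned unchanged with its energy evaluated.
    """
    e0, _ = potential(structure)
    if not structure.rotatable_dihedrals:
        return Minimum(structure.copy(), energy=e0, converged=True, grad_norm=0.0)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        return potential(_with_dihedrals(structure, theta))

    theta0 = current_dihedrals(structure)
    res = _scipy_minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": tol * 0.1, "ftol": 1e-12},
    )
    final = _with_dihedrals(structure, res.x)
    energy, grad = potential(final)
    if energy > e0:  # never return worse than the input
        final, energy, grad = structure.copy(), e0, potential(structure)[1]
    gnorm = float(np.max(np.abs(grad))) if np.size(grad) else 0.0
    return Minimum(final, energy=float(energy), converged=bool(gnorm < tol), grad_norm=gnorm)


# --------------------------------------------------------------------------
# Uniqueness and basin hopping
# --------------------------------------------------------------------------

def dihedral_rmsd(theta1: np.ndarray, theta2: np.ndarray) -> float:
    """Circular RMSD between two dihedral vectors, degrees."""
    diff = np.rad2deg(np.angle(np.exp(1j * (np.asarray(theta1) - np.asarray(theta2)))))
    return float(np.sqrt(np.mean(diff**2))) if np.size(diff) else 0.0


def _is_duplicate(
    energy: float, theta: np.ndarray, stored: list[tuple[float, np.ndarray]], config: BHConfig
) -> bool:
    for e_s, t_s in stored:
        if abs(energy - e_s) <= config.energy_tol and dihedral_rmsd(theta, t_s) <= config.rmsd_tol:
            return True
    return False


def basin_hop(
    structure: Structure,
    config: BHConfig,
    potential=toy_potential,
) -> list[Minimum]:
    """Basin-hopping search over the torsional energy surface.

    Each step perturbs every rotatable dihedral of the *running geometry*
    by an independent uniform draw in ``[-max_dihedral_step,
    +max_dihedral_step]`` degrees (or a single randomly chosen dihedral
    when ``perturb_all`` is off), locally minimizes a copy to identify the
    basin, and Metropolis-accepts the move on the minimized energies at
    ``metropolis_kT``.  Because the walk itself accumulates the raw
    distortions (only the acceptance rule sees the minimized energies), a
    small per-step distortion can still diffuse across torsional barriers
    — with a 5-degree cap a walk that restarted from each basin floor
    could never leave the first well.

    A minimized geometry is stored as a new distinct minimum unless it
    matches a stored one in both energy (within ``energy_tol``) and
    dihedral RMSD (within ``rmsd_tol``).  Deterministic for a fixed seed;
    the result is sorted by energy.
    """
    rng = np.random.default_rng(config.seed)
    start = local_minimize(structure, potential)
    if not structure.rotatable_dihedrals:
        return [start]

    minima: list[Minimum] = [start]
    stored: list[tuple[float, np.ndarray]] = [
        (start.energy, current_dihedrals(start.structure))
    ]
    walk_theta = current_dihedrals(structure)
    cur_basin_energy = start.energy
    max_step = np.deg2rad(config.max_dihedral_step)
    n_dih = len(structure.rotatable_dihedrals)

    for step in range(1, config.n_steps + 1):
        if config.perturb_all:
            trial_theta = walk_theta + rng.uniform(-max_step, max_step, size=n_dih)
        else:
            trial_theta = walk_theta.copy()
            k = int(rng.integers(n_dih))
            trial_theta[k] += rng.uniform(-max_step, max_step)
        m = local_minimize(_with_dihedrals(structure, trial_theta), potential)
        m.found_at_step = step
        m_theta = current_dihedrals(m.structure)
        if not _is_duplicate(m.energy, m_theta, stored, config):
            minima.append(m)
            stored.append((m.energy, m_theta))
        # Metropolis on minimized (basin-floor) energies
        de = m.energy - cur_basin_energy
        if de <= 0 or (
            config.metropolis_kT > 0 and rng.random() < np.exp(-de / config.metropolis_kT)
        ):
            walk_theta, cur_basin_energy = trial_theta, m.energy
    minima.sort(key=lambda m: m.energy)
    return minima


# --------------------------------------------------------------------------
# Protomers
# --------------------------------------------------------------------------

def enumerate_protomers(
    structure: Structure, candidate_sites: list[int]
) -> list[Structure]:
    """One protonated structure per candidate heteroatom site.

    The proton is placed 1.0 A from the site, pointing away from the
    molecular centroid.  Charge bookkeeping: the new hydrogen carries
    +0.5 e and the protonation site gains +0.5 e, incrementing the total
    charge by one.  Tautomer enumeration is not performed.
    """
    if not candidate_sites:
        raise ValueError("candidate_sites must not be empty")
    for site in candidate_sites:
        if not (0 <= site < structure.n_atoms):
            raise ValueError(f"candidate site {site} out of range")
        if structure.elements[site] not in ("N", "O", "S"):
            raise ValueError(
                f"site {site} is {structure.elements[site]!r}; protonation "
                "sites must be heteroatoms (N, O, S)"
            )
    centroid = structure.coords.mean(axis=0)
    out: list[Structure] = []
    for site in candidate_sites:
        direction = structure.coords[site] - centroid
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        h_pos = structure.coords[site] + direction
        charges = np.append(structure.charges.copy(), 0.5)
        charges[site] += 0.5
        out.append(
            Structure(
                elements=list(structure.elements) + ["H"],
                coords=np.vstack([structure.coords, h_pos]),
                charges=charges,
                bonds=list(structure.bonds) + [(site, structure.n_atoms)],
                rotatable_dihedrals=list(structure.rotatable_dihedrals),
                total_charge=structure.total_charge + 1,
                molecule_id=f"{structure.molecule_id}_H{site}",
            )
        )
    return out
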