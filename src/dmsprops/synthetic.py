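"""Synthetic DMS datasets with known ground truth.

This module emulates the statistical structure of a differential mobility
spectrometry (DMS) screening database — dispersion curves of type A
(strong clustering), B (weak clustering with a turn-around), C (hard
sphere) and "complex" character, Gaussian ionogram peaks, toy 3D
structures, and condensed-phase property labels that are noisy monotone
functions of the curve parameters and of molecular size — so that every
downstream stage (peak fitting, classification, featurization, random
forest evaluation) can be tested without an instrument.

Dispersion-curve family
-----------------------
With ``u = SV / sv_max`` the noiseless optimal compensation voltage is

    CV(SV) = amplitude_c * u**3
             - a_eff * u**p * exp(-(p/q) * (SV / turn_sv)**q)

with fixed damping exponent ``q = 4`` and ``a_eff`` the temperature-scaled
clustering amplitude.  The positive cubic term is the conventional leading
odd-power (hard-sphere) expansion of differential mobility; the damped
power term models clustering that collapses at high field.  The ``p/q``
factor in the exponent places the minimum of the clustering term exactly
at ``SV = turn_sv`` regardless of ``p``, so ``turn_sv`` is the type-B
turn-around of the clustering component.  Type A pins ``turn_sv = sv_max``
(no interior turn-around); type C has ``amplitude_a = 0``.  "Complex"
curves add a sinusoidal modulation that produces multiple reversals.

Raising ``temperature_C`` shrinks the clustering amplitude
exponentially, ``a_eff = amplitude_a * exp(-(T - 150) / 300)``, reflecting
the weaker ion-solvent cluster binding at elevated gas temperature.
"""

from __future__ import annotations

import numpy as np

from ._geometry import chain_coords
from .records import (
    Behavior,
    Conditions,
    CurveParams,
    DispersionCurve,
    GroundTruth,
    Ionogram,
    MoleculeRecord,
    Structure,
)

__all__ = [
    "DAMPING_EXPONENT_Q",
    "TEMP_REF_C",
    "TEMP_SCALE_C",
    "PROPERTY_LINKS",
    "DEFAULT_NOISE_SD",
    "DEFAULT_MISSING_RATES",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_SV_GRID",
    "dispersion_cv",
    "temperature_factor",
    "simulate_dispersion",
    "simulate_ionograms",
    "sample_curve_params",
    "property_value",
    "true_ccs_value",
    "generate_toy_structure",
    "generate_dataset",
]

# --------------------------------------------------------------------------
# Curve-family constants
# --------------------------------------------------------------------------

#: fixed damping exponent q of the clustering term
DAMPING_EXPONENT_Q = 4.0
#: reference gas temperature (deg C) at which a_eff equals amplitude_a
TEMP_REF_C = 150.0
#: e-folding temperature scale (deg C) of the clustering amplitude
TEMP_SCALE_C = 300.0
#: relative amplitude of the sinusoidal modulation used for "complex" curves
COMPLEX_MODULATION = 0.55

#: measured SV grid of the default synthetic campaign (V)
DEFAULT_SV_GRID = np.arange(250.0, 4000.0 + 1, 250.0)

# --------------------------------------------------------------------------
# Property link functions
# --------------------------------------------------------------------------
# Each condensed-phase label is an affine function of the clustering
# depth D (V) — the negative CV excursion of the noiseless curve, the
# direct signature of the ion-solvent interaction strength — the
# turn-around voltage t (V), and the reciprocal collision cross section
# (via 1000/CCS, scaled 1/A^2):
#
#   g(D, t, ccs) = b0 + bd * D + bt * t + bc * (1000 / ccs)
#
# The depth, not the raw clustering amplitude, is the sampled latent (see
# sample_curve_params), so it is statistically independent of the
# hard-sphere amplitude and of the turn-around.  Coefficients were chosen
# from a variance budget so that, at the default noise level, the
# curve-derived terms explain most of the permeability variance while the
# CCS term contributes a measurable independent share — DMS-only features
# give a strong but imperfect fit, adding CCS closes most of the gap, and
# CCS alone explains little.
PROPERTY_LINKS: dict[str, dict[str, float]] = {
    "pkb": {"b0": 3.5, "bd": 0.55, "bt": 0.0006, "bc": 0.0},
    "logd": {"b0": -1.2, "bd": 0.30, "bt": -0.0006, "bc": 0.0},
    "epsa": {"b0": 30.0, "bd": 5.0, "bt": 0.012, "bc": 0.0},
    "permeability": {"b0": 16.0, "bd": -0.45, "bt": 0.0005, "bc": 0.30},
}

#: per-label Gaussian noise (property units) at noise_scale = 1.  The
#: "ccs" entry is *relative* (lognormal log-sd): molecule-to-molecule CCS
#: variation is proportional to molecular size.
DEFAULT_NOISE_SD: dict[str, float] = {
    "pkb": 0.12,
    "logd": 0.10,
    "epsa": 2.0,
    "permeability": 0.10,
    "ccs": 0.20,
}

#: default fraction of molecules missing each label, mimicking a screening
#: database where pKb / EPSA / logD are known only for subsets
DEFAULT_MISSING_RATES: dict[str, float] = {
    "pkb": 37.0 / 89.0,
    "epsa": 46.0 / 89.0,
    "logd": 55.0 / 89.0,
    "permeability": 0.0,
    "ccs": 0.0,
}

#: CCS link: ccs = (120 + 24 * amplitude_c) * exp(sd_rel * z)  (A^2).
#: The hard-sphere term is the size proxy visible in the dispersion
#: curve; the lognormal factor is molecular-size information NOT encoded
#: in the curve.
CCS_BASE = 120.0
CCS_PER_AMPLITUDE_C = 24.0

# --------------------------------------------------------------------------
# Topology classes
# --------------------------------------------------------------------------
# Ten classes patterned on a small-molecule screening campaign: two
# quinoline-derivative families, four intramolecular-hydrogen-bond (IMHB)
# topologies, and four covalent-reactive-group (CRG) motifs.  Each class
# carries a behavior-type distribution, a baseline clustering amplitude,
# and a heavy-atom size range.

_CLASS_SPECS: dict[str, dict] = {
    "quinoline": dict(count=10, behaviors={"A": 0.6, "B": 0.4}, a_base=8.0, size=(10, 18)),
    "quinolinol": dict(count=22, behaviors={"A": 0.4, "B": 0.6}, a_base=6.5, size=(11, 20)),
    "imhb_a": dict(count=9, behaviors={"B": 0.7, "A": 0.2, "complex": 0.1}, a_base=5.5, size=(20, 34)),
    "imhb_b": dict(count=8, behaviors={"B": 0.7, "A": 0.3}, a_base=6.0, size=(22, 36)),
    "imhb_c": dict(count=8, behaviors={"B": 0.6, "C": 0.2, "complex": 0.2}, a_base=4.5, size=(24, 40)),
    "imhb_d": dict(count=8, behaviors={"B": 0.7, "A": 0.3}, a_base=6.0, size=(20, 34)),
    "crg_i": dict(count=6, behaviors={"A": 0.4, "B": 0.4, "C": 0.2}, a_base=4.0, size=(8, 14)),
    "crg_ii": dict(count=6, behaviors={"B": 0.6, "C": 0.4}, a_base=3.5, size=(10, 16)),
    "crg_iii": dict(count=6, behaviors={"C": 0.6, "B": 0.4}, a_base=3.0, size=(10, 16)),
    "crg_iv": dict(count=6, behaviors={"A": 0.3, "B": 0.5, "C": 0.2}, a_base=4.5, size=(12, 18)),
}

DEFAULT_CLASS_MIX: dict[str, float] = {
    name: spec["count"] / 89.0 for name, spec in _CLASS_SPECS.items()
}


# --------------------------------------------------------------------------
# Curve evaluation
# --------------------------------------------------------------------------

def temperature_factor(temperature_C: float) -> float:
    """Multiplier applied to the clustering amplitude at gas temperature T."""
    return float(np.exp(-(temperature_C - TEMP_REF_C) / TEMP_SCALE_C))


def dispersion_cv(params: CurveParams, sv: np.ndarray) -> np.ndarray:
    """Noiseless optimal CV of the curve family at the given SV values (V)."""
    sv = np.asarray(sv, dtype=float)
    u = sv / params.sv_max
    q = DAMPING_EXPONENT_Q
    p = params.shape_p
    a_eff = params.amplitude_a * temperature_factor(params.temperature_C)
    damping = np.exp(-(p / q) * (sv / params.turn_sv) ** q)
    cv = params.amplitude_c * u**3 - a_eff * u**p * damping
    if params.behavior is Behavior.COMPLEX:
        mod = COMPLEX_MODULATION * (params.amplitude_a + params.amplitude_c + 3.0)
        cv = cv + mod * u * np.sin(3.0 * np.pi * u)
    return cv


def _peak_sigma_profile(sv: np.ndarray) -> np.ndarray:
    # CV-peak width grows mildly with SV (broader peaks at high field)
    return 0.25 + 7.5e-5 * np.asarray(sv, dtype=float)


def simulate_dispersion(
    params: CurveParams,
    sv_grid: np.ndarray,
    noise_sd_cv: float = 0.0,
    seed: int = 0,
    molecule_id: str = "synthetic",
) -> DispersionCurve:
    """Sample a dispersion curve on ``sv_grid`` with additive CV noise.

    Deterministic for a fixed seed.  The noiseless values follow
    :func:`dispersion_cv`; ``noise_sd_cv`` (V) is the standard deviation of
    i.i.d. Gaussian measurement noise on each optimal-CV value.
    """
    sv_grid = np.asarray(sv_grid, dtype=float)
    if sv_grid.size == 0:
        raise ValueError("sv_grid must not be empty")
    if np.any(sv_grid < 0) or not np.all(np.diff(sv_grid) > 0):
        raise ValueError("sv_grid must be nonnegative and strictly increasing")
    if noise_sd_cv < 0:
        raise ValueError(f"noise_sd_cv must be >= 0, got {noise_sd_cv}")
    rng = np.random.default_rng(seed)
    cv = dispersion_cv(params, sv_grid)
    if noise_sd_cv > 0:
        cv = cv + rng.normal(0.0, noise_sd_cv, size=sv_grid.size)
    conditions = Conditions(
        temperature_C=params.temperature_C,
        modifier="methanol",
        modifier_mole_pct=params.modifier_mole_pct,
    )
    return DispersionCurve(
        molecule_id=molecule_id,
        conditions=conditions,
        sv=sv_grid,
        cv=cv,
        sigma=_peak_sigma_profile(sv_grid),
    )


def simulate_ionograms(
    curve: DispersionCurve,
    cv_window: tuple[float, float],
    cv_step: float,
    peak_sigma: float,
    noise_frac: float = 0.0,
    seed: int = 0,
    amplitude: float = 100.0,
) -> list[Ionogram]:
    """One ionogram (intensity vs CV) per SV point of ``curve``.

    Each scan is a Gaussian of width ``peak_sigma`` centered at that SV's
    optimal CV, with multiplicative intensity noise of relative scale
    ``noise_frac``.  Deterministic for a fixed seed.
    """
    if cv_step <= 0:
        raise ValueError("cv_step must be positive")
    if peak_sigma <= 0:
        raise ValueError("peak_sigma must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    lo, hi = cv_window
    if lo >= hi:
        raise ValueError("cv_window must be an increasing (low, high) pair")
    for sv_i, cv_i in zip(curve.sv, curve.cv):
        if not (lo <= cv_i <= hi):
            raise ValueError(
                f"cv_window ({lo}, {hi}) excludes the CV peak at SV={sv_i:g} V "
                f"(CV_opt={cv_i:.3f} V)"
            )
    rng = np.random.default_rng(seed)
    cv_axis = np.arange(lo, hi + 0.5 * cv_step, cv_step)
    out: list[Ionogram] = []
    for sv_i, cv_i in zip(curve.sv, curve.cv):
        signal = amplitude * np.exp(-((cv_axis - cv_i) ** 2) / (2.0 * peak_sigma**2))
        if noise_frac > 0:
            signal = signal * (1.0 + noise_frac * rng.normal(size=cv_axis.size))
        signal = np.clip(signal, 0.0, None)
        out.append(
            Ionogram(molecule_id=curve.molecule_id, sv=float(sv_i), cv=cv_axis, intensity=signal)
        )
    return out


# --------------------------------------------------------------------------
# Parameter sampling and labels
# --------------------------------------------------------------------------

def sample_curve_params(
    behavior: Behavior | str,
    rng: np.random.Generator,
    a_base: float = 5.5,
    n_heavy: int | None = None,
    temperature_C: float = 150.0,
    modifier_mole_pct: float = 1.5,
    sv_max: float = 4000.0,
) -> CurveParams:
    """Draw one realistic parameter set of the requested behavior type.

    The sampled latent is the clustering *depth* D — the negative CV
    excursion the curve will display — drawn around the class baseline
    ``a_base``; the raw clustering amplitude is then solved from D, the
    turn-around and the hard-sphere amplitude.  Sampling the depth (rather
    than the amplitude) keeps the physically meaningful clustering
    strength statistically independent of molecular size, and guarantees
    every type-B curve a discernible turn-around (depth >= 1.5 V).
    """
    behavior = Behavior(behavior)
    if n_heavy is None:
        n_heavy = int(rng.integers(10, 36))
    # hard-sphere amplitude scales with molecular size
    amp_c = max(0.2, 0.1 * n_heavy + rng.uniform(-0.3, 0.3))
    depth = max(1.0, a_base + rng.uniform(-1.5, 1.5))
    # campaign-wide family constant: per-molecule identity lives in the
    # depth, hard-sphere amplitude and turn-around, not in the exponent
    shape_p = 1.8
    damp_min = np.exp(-shape_p / DAMPING_EXPONENT_Q)
    if behavior is Behavior.A:
        amp_c = 0.0
        turn = sv_max
        amp_a = depth / damp_min  # excursion D reached at sv_max
    elif behavior is Behavior.C:
        amp_a = 0.0
        turn = sv_max
    else:  # B or complex
        depth = max(depth, 1.5)
        turn = rng.uniform(1800.0, 3200.0)
        u_t = turn / sv_max
        amp_a = (depth + amp_c * u_t**3) / (u_t**shape_p * damp_min)
    return CurveParams(
        behavior=behavior,
        amplitude_a=amp_a,
        amplitude_c=amp_c,
        turn_sv=turn,
        shape_p=shape_p,
        temperature_C=temperature_C,
        modifier_mole_pct=modifier_mole_pct,
        sv_max=sv_max,
    )


def true_ccs_value(params: CurveParams, noise_sd_rel: float, rng: np.random.Generator) -> float:
    """Collision cross section (A^2): affine in the hard-sphere amplitude
    times a lognormal factor of molecule-specific size variation not
    encoded in the dispersion curve (``noise_sd_rel`` is its log-sd)."""
    ccs = CCS_BASE + CCS_PER_AMPLITUDE_C * params.amplitude_c
    if noise_sd_rel > 0:
        ccs *= float(np.exp(rng.normal(0.0, noise_sd_rel)))
    return float(ccs)


def excursion_depth(params: CurveParams) -> float:
    """Clustering depth D (V): the negative CV excursion of the curve.

    Evaluated analytically at the clustering-term minimum (``turn_sv``,
    which is ``sv_max`` for types A and C); zero for pure hard-sphere
    curves.  This is the quantity the property links are keyed on.
    """
    if params.amplitude_a == 0:
        return 0.0
    u_t = params.turn_sv / params.sv_max
    damp_min = np.exp(-params.shape_p / DAMPING_EXPONENT_Q)
    a_eff = params.amplitude_a * temperature_factor(params.temperature_C)
    return float(a_eff * u_t**params.shape_p * damp_min - params.amplitude_c * u_t**3)


def property_value(name: str, params: CurveParams, ccs: float) -> float:
    """Noiseless label g(D, t, ccs) for one property (documented link)."""
    link = PROPERTY_LINKS[name]
    return float(
        link["b0"]
        + link["bd"] * excursion_depth(params)
        + link["bt"] * params.turn_sv
        + link["bc"] * (1000.0 / ccs)
    )


# --------------------------------------------------------------------------
# Toy structures
# --------------------------------------------------------------------------

def generate_toy_structure(
    n_heavy_atoms: int,
    n_rotatable: int,
    seed: int = 0,
    molecule_id: str = "toy",
) -> Structure:
    """Chemically naive but geometrically valid chain structure.

    Heavy atoms form a single chain with fixed bond length (1.52 A) and
    bond angle (111 deg).  The first ``n_rotatable`` backbone dihedrals are
    flagged rotatable; the rest stay frozen at their initial values.
    Per-atom partial charges are positive and sum to exactly +1 (the
    protonated species probed in positive-mode DMS).
    """
    if n_heavy_atoms < 1:
        raise ValueError("n_heavy_atoms must be >= 1")
    max_rot = max(n_heavy_atoms - 3, 0)
    if n_rotatable < 0 or n_rotatable > max_rot:
        raise ValueError(
            f"n_rotatable={n_rotatable} impossible for a {n_heavy_atoms}-atom "
            f"chain (at most {max_rot})"
        )
    rng = np.random.default_rng(seed)
    elements = ["C"]
    for _ in range(n_heavy_atoms - 1):
        elements.append(str(rng.choice(["C", "C", "C", "N", "O"])))
    # rejection-sample backbone dihedrals: gauche runs can fold the chain
    # onto itself, which would put atoms inside each other's cores
    ii, jj = np.triu_indices(n_heavy_atoms, k=3)  # pairs 1-4 and beyond
    for _attempt in range(200):
        dihedral_values = rng.choice([60.0, 180.0, -60.0], size=max_rot)
        coords = chain_coords(n_heavy_atoms, dihedrals_deg=dihedral_values)
        if ii.size == 0:
            break
        dist = np.linalg.norm(coords[ii] - coords[jj], axis=1)
        if dist.min() >= 2.0:
            break
    else:
        dihedral_values = np.full(max_rot, 180.0)  # all-anti never clashes
        coords = chain_coords(n_heavy_atoms, dihedrals_deg=dihedral_values)
    # mixed-sign partial charges (as a charge-partition scheme would give),
    # shifted so the protonated species carries exactly +1
    charges = rng.normal(0.0, 0.25, size=n_heavy_atoms)
    charges += (1.0 - charges.sum()) / n_heavy_atoms
    charges[-1] = 1.0 - charges[:-1].sum()  # exact +1 total
    bonds = [(i, i + 1) for i in range(n_heavy_atoms - 1)]
    rotatable = [(i, i + 1, i + 2, i + 3) for i in range(n_rotatable)]
    return Structure(
        elements=elements,
        coords=coords,
        charges=charges,
        bonds=bonds,
        rotatable_dihedrals=rotatable,
        total_charge=1,
        molecule_id=molecule_id,
    )


# --------------------------------------------------------------------------
# Full datasets
# --------------------------------------------------------------------------

def _allocate_counts(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n molecules across classes."""
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    raw = {k: n * f for k, f in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def generate_dataset(
    n_molecules: int,
    class_mix: dict[str, float] | None = None,
    seed: int = 0,
    noise_scale: float = 1.0,
    missing_rates: dict[str, float] | None = None,
    sv_grid: np.ndarray | None = None,
    noise_sd_cv: float = 0.15,
    temperatures_C: tuple[float, ...] = (150.0,),
) -> tuple[list[MoleculeRecord], list[GroundTruth]]:
    """Generate a complete synthetic screening dataset.

    Parameters
    ----------
    n_molecules
        Number of molecules (>= 2).
    class_mix
        Topology-class fractions (default: the ten-class mix of the
        default campaign).  Unknown class names fall back to generic
        mid-range parameters.
    noise_scale
        Multiplier on every stochastic noise amplitude: the per-label
        noise standard deviations and the CV measurement noise alike.  At
        0 every label is an exact function of the curve parameters and
        the curves are noiseless — the configuration used for
        parameter-recovery tests, where the signal must be fully
        recoverable.
    missing_rates
        Per-property probability that a molecule's label is absent.
    temperatures_C
        Gas temperatures at which dispersion curves are recorded.  The
        default single condition (150 C, 1.5% methanol) is used for the
        feature pipeline; extra temperatures attach additional curves via
        ``MoleculeRecord`` duplication and are provided for
        temperature-sweep studies without any fidelity claim.

    Returns
    -------
    (records, truths)
        Molecule records (curve, labels, toy structure) and the matching
        ground truths for recovery tests.
    """
    if n_molecules < 2:
        raise ValueError("n_molecules must be >= 2")
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    rates = dict(DEFAULT_MISSING_RATES)
    if missing_rates is not None:
        rates.update(missing_rates)
    if sv_grid is None:
        sv_grid = DEFAULT_SV_GRID
    counts = _allocate_counts(n_molecules, mix)
    rng = np.random.default_rng(seed)

    records: list[MoleculeRecord] = []
    truths: list[GroundTruth] = []
    idx = 0
    for cls in sorted(counts):
        spec = _CLASS_SPECS.get(
            cls, dict(behaviors={"A": 0.3, "B": 0.5, "C": 0.2}, a_base=5.0, size=(10, 30))
        )
        behaviors = list(spec["behaviors"].items())
        names = [b for b, _ in behaviors]
        probs = np.array([w for _, w in behaviors], dtype=float)
        probs /= probs.sum()
        lo, hi = spec["size"]
        for _ in range(counts[cls]):
            idx += 1
            mol_id = f"M{idx:03d}"
            behavior = Behavior(str(rng.choice(names, p=probs)))
            n_heavy = int(rng.integers(lo, hi + 1))
            params = sample_curve_params(
                behavior,
                rng,
                a_base=spec["a_base"],
                n_heavy=n_heavy,
                temperature_C=temperatures_C[0],
            )
            noise_sd = {k: v * noise_scale for k, v in DEFAULT_NOISE_SD.items()}
            ccs = true_ccs_value(params, noise_sd["ccs"], rng)
            labels: dict[str, float] = {"ccs": ccs}
            for prop in PROPERTY_LINKS:
                val = property_value(prop, params, ccs)
                if noise_sd[prop] > 0:
                    val += rng.normal(0.0, noise_sd[prop])
                labels[prop] = val
            truth = GroundTruth(
                molecule_id=mol_id,
                curve_params=params,
                true_ccs=ccs,
                property_map={k: v for k, v in labels.items() if k != "ccs"},
                noise_sd=noise_sd,
            )
            observed = {
                k: v for k, v in labels.items() if rng.random() >= rates.get(k, 0.0)
            }
            curve = simulate_dispersion(
                params,
                sv_grid,
                noise_sd_cv=noise_sd_cv * noise_scale,
                seed=int(rng.integers(0, 2**31 - 1)),
                molecule_id=mol_id,
            )
            n_rot = min(max(n_heavy - 3, 0), 4)
            structure = generate_toy_structure(
                n_heavy, n_rot, seed=int(rng.integers(0, 2**31 - 1)), molecule_id=mol_id
            )
            records.append(
                MoleculeRecord(
                    molecule_id=mol_id,
                    topology_class=cls,
                    properties=observed,
                    curve=curve,
                    structure=structure,
                )
            )
            truths.append(truth)
    return records, truths
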