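"""Core data containers shared across the pipeline.

The central measurement object is the :class:`DispersionCurve` — the per-ion
relationship between separation voltage (SV) and the optimal compensation
voltage (CV) under fixed gas conditions.  Raw signal arrives as
:class:`Ionogram` scans (intensity versus CV at a fixed SV); downstream
stages attach behavior classifications, feature vectors and property labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Behavior",
    "Conditions",
    "Ionogram",
    "PeakFit",
    "DispersionCurve",
    "BehaviorCall",
    "CurveParams",
    "GroundTruth",
    "Structure",
    "Minimum",
    "BHConfig",
    "MoleculeRecord",
    "FeatureVector",
    "FeatureMatrix",
    "RadiusTable",
    "CCSResult",
    "RFConfig",
    "LOOResult",
    "LearningCurve",
]


class Behavior(str, Enum):
    """Dispersion-plot archetypes.

    ``A``: strong clustering — CV grows increasingly negative with SV.
    ``B``: weak clustering — negative CV excursion followed by a turn-around.
    ``C``: hard-sphere — CV grows increasingly positive with SV.
    ``COMPLEX``: none of the above (multiple reversals).
    """

    A = "A"
    B = "B"
    C = "C"
    COMPLEX = "complex"


@dataclass(frozen=True)
class Conditions:
    """Gas conditions under which a dispersion curve was recorded."""

    temperature_C: float = 150.0
    modifier: str = "methanol"
    modifier_mole_pct: float = 1.5


@dataclass
class Ionogram:
    """One CV scan at fixed SV: ion intensity versus compensation voltage."""

    molecule_id: str
    sv: float
    cv: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.cv = np.asarray(self.cv, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.cv.size != self.intensity.size:
            raise ValueError("cv and intensity must have equal length")
        if self.cv.size < 5:
            raise ValueError(
                f"ionogram for {self.molecule_id!r} at SV={self.sv} has "
                f"{self.cv.size} points; at least 5 required"
            )
        if not np.all(np.diff(self.cv) > 0):
            raise ValueError(
                f"ionogram for {self.molecule_id!r} at SV={self.sv}: "
                "cv values must be strictly increasing"
            )
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and nonnegative")


@dataclass
class PeakFit:
    """Gaussian-plus-baseline fit of a single ionogram peak."""

    cv_opt: float
    sigma: float
    amplitude: float
    baseline: float
    rmse: float
    converged: bool
    message: str = ""


@dataclass
class DispersionCurve:
    """Ordered (SV, optimal CV, CV-peak sigma) series for one molecule."""

    molecule_id: str
    conditions: Conditions
    sv: np.ndarray
    cv: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.sv = np.asarray(self.sv, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.sv.size == self.cv.size == self.sigma.size):
            raise ValueError("sv, cv and sigma must have equal length")
        if self.sv.size and not np.all(np.diff(self.sv) > 0):
            dup = self.sv[np.flatnonzero(np.diff(self.sv) <= 0)]
            raise ValueError(
                f"dispersion curve {self.molecule_id!r}: sv must be strictly "
                f"increasing (violation near SV={dup[0]:g} V)"
            )

    def __len__(self) -> int:
        return int(self.sv.size)


@dataclass
class BehaviorCall:
    """Classification of a dispersion curve into the A/B/C/complex taxonomy."""

    behavior: Behavior
    turn_sv: float | None
    confidence: float

    def __post_init__(self) -> None:
        if (self.behavior is Behavior.B) != (self.turn_sv is not None):
            raise ValueError("turn_sv must be present iff behavior is B")


@dataclass
class CurveParams:
    """Parameters of the synthetic dispersion-curve family.

    ``amplitude_a`` (V) controls the depth of the negative, clustering-driven
    CV excursion; ``amplitude_c`` (V) the positive hard-sphere cubic term;
    ``turn_sv`` (V) the SV at which a type-B curve turns around; ``shape_p``
    the low-field power of the clustering term.  Raising ``temperature_C``
    weakens clustering (smaller effective ``amplitude_a``).
    """

    behavior: Behavior
    amplitude_a: float
    amplitude_c: float
    turn_sv: float
    shape_p: float = 1.8
    temperature_C: float = 150.0
    modifier_mole_pct: float = 1.5
    sv_max: float = 4000.0

    def __post_init__(self) -> None:
        self.behavior = Behavior(self.behavior)
        if self.amplitude_a < 0 or self.amplitude_c < 0:
            raise ValueError("amplitudes must be nonnegative")
        if not (0 < self.turn_sv <= self.sv_max):
            raise ValueError("turn_sv must lie in (0, sv_max]")
        if self.shape_p < 1:
            raise ValueError("shape_p must be >= 1")
        if self.behavior is Behavior.A and self.amplitude_c != 0:
            raise ValueError("type A requires amplitude_c = 0")
        if self.behavior is Behavior.C and self.amplitude_a != 0:
            raise ValueError("type C requires amplitude_a = 0")
        # Monotone decrease up to sv_max requires the damping minimum at the
        # high-SV boundary; the generator pins turn_sv there for type A.
        if self.behavior is Behavior.A and self.turn_sv != self.sv_max:
            raise ValueError("type A requires turn_sv = sv_max (no turn-around)")


@dataclass
class GroundTruth:
    """Generator-side truth for one synthetic molecule, kept for recovery tests."""

    molecule_id: str
    curve_params: CurveParams
    true_ccs: float
    property_map: dict[str, float]
    noise_sd: dict[str, float]


@dataclass
class Structure:
    """A 3D structure with per-atom partial charges and rotatable dihedrals."""

    elements: list[str]
    coords: np.ndarray
    charges: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    rotatable_dihedrals: list[tuple[int, int, int, int]] = field(default_factory=list)
    total_charge: int = 0
    molecule_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.elements)
        if self.coords.shape[0] != n or self.charges.size != n:
            raise ValueError("elements, coords and charges must agree in length")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) references a missing atom")
        if abs(float(self.charges.sum()) - self.total_charge) > 1e-6:
            raise ValueError(
                f"charges sum to {self.charges.sum():.8f}, expected "
                f"total_charge={self.total_charge}"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "Structure":
        return Structure(
            elements=list(self.elements),
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            bonds=list(self.bonds),
            rotatable_dihedrals=list(self.rotatable_dihedrals),
            total_charge=self.total_charge,
            molecule_id=self.molecule_id,
        )


@dataclass
class Minimum:
    """A local minimum on the torsional potential-energy surface."""

    structure: Structure
    energy: float
    found_at_step: int = 0
    converged: bool = True
    grad_norm: float = 0.0


@dataclass
class BHConfig:
    """Basin-hopping settings.

    Defaults follow the search protocol used for drug-candidate conformer
    sampling: ~20,000 perturbation steps with every rotatable dihedral
    distorted by at most 5 degrees per step, Metropolis acceptance at a
    thermal energy of 2.5 kJ/mol (about 300 K), and uniqueness judged by
    energy (0.1 kJ/mol) together with dihedral-space RMSD (10 degrees).
    """

    n_steps: int = 20000
    max_dihedral_step: float = 5.0
    metropolis_kT: float = 2.5
    energy_tol: float = 0.1
    rmsd_tol: float = 10.0
    seed: int = 0
    perturb_all: bool = True

    def __post_init__(self) -> None:
        if self.n_steps < 1 or self.max_dihedral_step <= 0:
            raise ValueError("n_steps and max_dihedral_step must be positive")
        if self.max_dihedral_step > 180:
            raise ValueError("max_dihedral_step must be <= 180 degrees")
        if self.metropolis_kT < 0 or self.energy_tol <= 0 or self.rmsd_tol <= 0:
            raise ValueError("metropolis_kT, energy_tol, rmsd_tol must be positive")


@dataclass
class MoleculeRecord:
    """One molecule: identity, topology class, labels and measured data."""

    molecule_id: str
    topology_class: str
    properties: dict[str, float]
    curve: DispersionCurve | None = None
    structure: Structure | None = None


@dataclass
class FeatureVector:
    """A dispersion curve resampled onto the shared SV grid."""

    molecule_id: str
    grid: np.ndarray
    cv_values: np.ndarray
    coverage: np.ndarray  # True where the grid point falls inside measured SV
    ccs: float | None = None


@dataclass
class FeatureMatrix:
    """Feature rows plus one named label column, ready for regression."""

    ids: list[str]
    grid: np.ndarray
    matrix: np.ndarray
    labels: np.ndarray
    property_name: str
    include_ccs: bool
    feature_names: list[str] = field(default_factory=list)

    @property
    def n_molecules(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class RadiusTable:
    """Hard-sphere collision radii per element plus the buffer-gas probe radius."""

    radii: dict[str, float]
    probe_radius: float
    name: str = "default-N2"

    def effective_radius(self, element: str) -> float:
        try:
            r = self.radii[element]
        except KeyError:
            raise KeyError(
                f"no collision radius for element {element!r} in table "
                f"{self.name!r}"
            ) from None
        return r + self.probe_radius


@dataclass
class CCSResult:
    """Monte-Carlo projection-approximation collision cross section."""

    ccs: float
    mc_standard_error: float
    n_orientations: int
    n_samples_per_orientation: int
    seed: int


@dataclass
class RFConfig:
    """Random-forest settings: 500 trees, bootstrap resampling, fixed seed."""

    n_trees: int = 500
    seed: int = 0
    max_features: float | str = 1.0
    min_samples_leaf: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class LOOResult:
    """Leave-one-out predictions and summary metrics for one property."""

    property_name: str
    ids: list[str]
    true: np.ndarray
    predicted: np.ndarray
    r2: float
    r2_cod: float
    mae: float
    mean_abs_pct_error: float | None


@dataclass
class LearningCurve:
    """Mean/sd of train and test MAE across repeated fractional splits."""

    property_name: str
    fractions: list[float]
    repeats: int
    test_mae_mean: np.ndarray
    test_mae_sd: np.ndarray
    train_mae_mean: np.ndarray
    train_mae_sd: np.ndarray
    n_splits: int


def as_float_array(values: Sequence[float]) -> np.ndarray:
    return np.asarray(values, dtype=float)
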