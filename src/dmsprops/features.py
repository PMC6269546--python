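"""Fixed-length feature vectors from dispersion curves.

Each molecule's dispersion curve is resampled onto a dataset-wide SV grid
by linear interpolation (nearest-value hold outside the measured range,
with a coverage mask marking extrapolated points).  Per-property feature
matrices pair those rows with one label column, optionally augmented with
the molecule's collision cross section.
"""

from __future__ import annotations

import numpy as np

from .records import DispersionCurve, FeatureMatrix, FeatureVector, MoleculeRecord

__all__ = ["DEFAULT_GRID", "interpolate_to_grid", "build_feature_matrix"]

#: default shared SV grid: 0-4000 V in 250 V steps (17 features)
DEFAULT_GRID = np.arange(0.0, 4000.0 + 1, 250.0)

#: labels the pipeline knows how to regress
KNOWN_PROPERTIES = ("ccs", "pkb", "logd", "epsa", "permeability")


def interpolate_to_grid(curve: DispersionCurve, grid: np.ndarray) -> FeatureVector:
    """Resample one dispersion curve onto ``grid``.

    Inside the measured SV range the CV is linearly interpolated; outside
    it, the nearest measured CV is held constant and the point is flagged
    False in the coverage mask.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be non-empty and strictly increasing")
    if len(curve) < 2:
        raise ValueError(
            f"curve {curve.molecule_id!r} has {len(curve)} point(s); "
            "interpolation requires at least 2"
        )
    cv_values = np.interp(grid, curve.sv, curve.cv)  # np.interp holds endpoints
    coverage = (grid >= curve.sv[0]) & (grid <= curve.sv[-1])
    return FeatureVector(
        molecule_id=curve.molecule_id, grid=grid, cv_values=cv_values, coverage=coverage
    )


def build_feature_matrix(
    records: list[MoleculeRecord],
    property_name: str,
    grid: np.ndarray | None = None,
    include_ccs: bool = False,
    ccs_only: bool = False,
    include_sigma: bool = False,
) -> FeatureMatrix:
    """Assemble the regression matrix for one named property.

    Rows are sorted by molecule_id (deterministic regardless of input
    order); molecules missing the label are dropped for this property
    only.  ``include_ccs`` appends the CCS descriptor column;
    ``ccs_only`` keeps nothing but that column (the negative-control
    feature set).  Predicting the ``"ccs"`` label itself with the CCS
    column among the features is rejected as label leakage.

    ``include_sigma`` additionally appends the per-grid-point CV-peak
    widths (off by default: only SV/CV data enter the standard model).
    """
    if property_name not in KNOWN_PROPERTIES:
        raise ValueError(
            f"unknown property {property_name!r}; expected one of {KNOWN_PROPERTIES}"
        )
    if property_name == "ccs" and (include_ccs or ccs_only):
        raise ValueError(
            "refusing to use the CCS descriptor as a feature when predicting "
            "the ccs label (label leakage)"
        )
    if ccs_only:
        include_ccs = True
    if grid is None:
        grid = DEFAULT_GRID
    grid = np.asarray(grid, dtype=float)

    rows: list[np.ndarray] = []
    labels: list[float] = []
    ids: list[str] = []
    for rec in sorted(records, key=lambda r: r.molecule_id):
        if property_name not in rec.properties or rec.curve is None:
            continue
        if include_ccs and "ccs" not in rec.properties:
            continue
        fv = interpolate_to_grid(rec.curve, grid)
        parts = [] if ccs_only else [fv.cv_values]
        if include_sigma and not ccs_only:
            parts.append(np.interp(grid, rec.curve.sv, rec.curve.sigma))
        if include_ccs:
            parts.append(np.array([rec.properties["ccs"]]))
        row = np.concatenate(parts)
        if not np.all(np.isfinite(row)):
            raise ValueError(f"non-finite feature values for {rec.molecule_id!r}")
        rows.append(row)
        labels.append(rec.properties[property_name])
        ids.append(rec.molecule_id)
    if len(rows) < 2:
        raise ValueError(
            f"only {len(rows)} record(s) carry a {property_name!r} label; need >= 2"
        )
    names: list[str] = []
    if not ccs_only:
        names += [f"cv_at_sv_{int(s)}" for s in grid]
        if include_sigma:
            names += [f"sigma_at_sv_{int(s)}" for s in grid]
    if include_ccs:
        names.append("ccs")
    return FeatureMatrix(
        ids=ids,
        grid=grid,
        matrix=np.vstack(rows),
        labels=np.asarray(labels, dtype=float),
        property_name=property_name,
        include_ccs=include_ccs,
        feature_names=names,
    )
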