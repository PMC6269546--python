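"""Readers and writers for the pipeline's file formats.

All tabular interchange is plain CSV (UTF-8, header row, '.' decimal):

* ionograms:  ``molecule_id, sv_V, cv_V, intensity``
* dispersion: ``molecule_id, temperature_C, modifier, modifier_mole_pct,
  sv_V, cv_V, cv_sigma_V``
* properties: ``molecule_id, class, ccs_A2, pkb, logd, epsa, permeability``
  (blank cells = missing labels)

Structures travel as extended XYZ: the per-atom line carries
``element x y z charge`` and the comment line records the total charge
(and, for conformer frames, the energy).  Ground truths and feature-matrix
metadata are JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    Behavior,
    Conditions,
    CurveParams,
    DispersionCurve,
    FeatureMatrix,
    GroundTruth,
    Ionogram,
    LearningCurve,
    LOOResult,
    MoleculeRecord,
    Structure,
)

__all__ = [
    "write_ionogram_csv", "read_ionogram_csv",
    "write_dispersion_csv", "read_dispersion_csv",
    "write_property_table", "read_property_table",
    "write_xyz", "read_xyz",
    "write_ground_truth_json", "read_ground_truth_json",
    "write_feature_matrix", "read_feature_matrix",
    "write_loo_csv", "write_learning_curve_csv",
    "file_sha256",
]

PROPERTY_COLUMNS = ["ccs", "pkb", "logd", "epsa", "permeability"]
_PROP_TO_COL = {"ccs": "ccs_A2", "pkb": "pkb", "logd": "logd", "epsa": "epsa",
                "permeability": "permeability"}


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --------------------------------------------------------------------------
# Ionograms
# --------------------------------------------------------------------------

def write_ionogram_csv(ionograms: list[Ionogram], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"molecule_id": ig.molecule_id, "sv_V": ig.sv, "cv_V": ig.cv,
             "intensity": ig.intensity}
        )
        for ig in ionograms
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_ionogram_csv(path: str | Path) -> list[Ionogram]:
    df = pd.read_csv(path)
    expected = {"molecule_id", "sv_V", "cv_V", "intensity"}
    if set(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {sorted(df.columns)}"
        )
    out: list[Ionogram] = []
    for (mid, sv), grp in df.groupby(["molecule_id", "sv_V"], sort=True):
        cv = grp["cv_V"].to_numpy(dtype=float)
        if not np.all(np.diff(cv) > 0):
            raise ValueError(
                f"{path}: scan {mid!r} at SV={sv} has non-increasing cv values"
            )
        out.append(
            Ionogram(molecule_id=str(mid), sv=float(sv), cv=cv,
                     intensity=grp["intensity"].to_numpy(dtype=float))
        )
    return out


# --------------------------------------------------------------------------
# Dispersion curves
# --------------------------------------------------------------------------

def write_dispersion_csv(curves: list[DispersionCurve], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "molecule_id": c.molecule_id,
                "temperature_C": c.conditions.temperature_C,
                "modifier": c.conditions.modifier,
                "modifier_mole_pct": c.conditions.modifier_mole_pct,
                "sv_V": c.sv, "cv_V": c.cv, "cv_sigma_V": c.sigma,
            }
        )
        for c in curves
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_dispersion_csv(path: str | Path) -> list[DispersionCurve]:
    df = pd.read_csv(path)
    expected = {"molecule_id", "temperature_C", "modifier", "modifier_mole_pct",
                "sv_V", "cv_V", "cv_sigma_V"}
    if set(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {sorted(df.columns)}"
        )
    out: list[DispersionCurve] = []
    keys = ["molecule_id", "temperature_C", "modifier", "modifier_mole_pct"]
    for (mid, temp, mod, pct), grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("sv_V")
        out.append(
            DispersionCurve(
                molecule_id=str(mid),
                conditions=Conditions(float(temp), str(mod), float(pct)),
                sv=grp["sv_V"].to_numpy(dtype=float),
                cv=grp["cv_V"].to_numpy(dtype=float),
                sigma=grp["cv_sigma_V"].to_numpy(dtype=float),
            )
        )
    return out


# --------------------------------------------------------------------------
# Property tables
# --------------------------------------------------------------------------

def write_property_table(records: list[MoleculeRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        row: dict = {"molecule_id": rec.molecule_id, "class": rec.topology_class}
        for prop, col in _PROP_TO_COL.items():
            row[col] = rec.properties.get(prop, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_property_table(path: str | Path) -> list[MoleculeRecord]:
    """Typed molecule-record stubs from a property CSV (no curves attached)."""
    df = pd.read_csv(path, dtype={"molecule_id": str, "class": str})
    expected = {"molecule_id", "class"} | set(_PROP_TO_COL.values())
    if set(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {sorted(expected)}, got {sorted(df.columns)}"
        )
    dup = df["molecule_id"][df["molecule_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate molecule_id {dup.iloc[0]!r}")
    records: list[MoleculeRecord] = []
    for idx, row in df.iterrows():
        props: dict[str, float] = {}
        for prop, col in _PROP_TO_COL.items():
            cell = row[col]
            if pd.isna(cell):
                continue
            try:
                props[prop] = float(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: row {idx + 2}: non-numeric value {cell!r} in "
                    f"column {col!r}"
                ) from None
        records.append(
            MoleculeRecord(
                molecule_id=str(row["molecule_id"]),
                topology_class=str(row["class"]),
                properties=props,
            )
        )
    return records


# --------------------------------------------------------------------------
# Extended XYZ
# --------------------------------------------------------------------------

def write_xyz(structures: list[Structure], path: str | Path,
              energies: list[float] | None = None) -> None:
    lines: list[str] = []
    for fi, s in enumerate(structures):
        lines.append(str(s.n_atoms))
        comment = f"molecule_id={s.molecule_id or 'frame%d' % fi} total_charge={s.total_charge}"
        if energies is not None:
            comment += f" energy_kJ_mol={energies[fi]:.6f}"
        lines.append(comment)
        for el, (x, y, z), q in zip(s.elements, s.coords, s.charges):
            lines.append(f"{el} {x:.8f} {y:.8f} {z:.8f} {q:.8f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_xyz(path: str | Path) -> list[Structure]:
    """Parse (multi-frame) extended XYZ with per-atom charges."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    structures: list[Structure] = []
    pos = 0
    while pos < len(text):
        if not text[pos].strip():
            pos += 1
            continue
        try:
            n = int(text[pos].strip())
        except ValueError:
            raise ValueError(f"{path}: line {pos + 1}: expected an atom count") from None
        comment = text[pos + 1] if pos + 1 < len(text) else ""
        meta = dict(
            tok.split("=", 1) for tok in comment.split() if "=" in tok
        )
        body = text[pos + 2 : pos + 2 + n]
        if len(body) < n:
            raise ValueError(f"{path}: frame starting line {pos + 1}: "
                             f"declared {n} atoms but found {len(body)}")
        elements, coords, charges = [], [], []
        for ln in body:
            parts = ln.split()
            if len(parts) < 5:
                raise ValueError(f"{path}: malformed atom line {ln!r} "
                                 "(need element x y z charge)")
            elements.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
            charges.append(float(parts[4]))
        total = int(meta.get("total_charge", round(sum(charges))))
        bonds = [(i, i + 1) for i in range(n - 1)]  # chain assumption
        structures.append(
            Structure(
                elements=elements, coords=np.array(coords),
                charges=np.array(charges), bonds=bonds,
                total_charge=total, molecule_id=meta.get("molecule_id", ""),
            )
        )
        pos += 2 + n
    return structures


# --------------------------------------------------------------------------
# Ground truth and feature matrices
# --------------------------------------------------------------------------

def write_ground_truth_json(truths: list[GroundTruth], path: str | Path) -> None:
    payload = []
    for t in truths:
        d = dataclasses.asdict(t)
        d["curve_params"]["behavior"] = t.curve_params.behavior.value
        payload.append(d)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def read_ground_truth_json(path: str | Path) -> list[GroundTruth]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    out = []
    for d in payload:
        cp = d["curve_params"]
        cp["behavior"] = Behavior(cp["behavior"])
        out.append(
            GroundTruth(
                molecule_id=d["molecule_id"],
                curve_params=CurveParams(**cp),
                true_ccs=d["true_ccs"],
                property_map=d["property_map"],
                noise_sd=d["noise_sd"],
            )
        )
    return out


def write_feature_matrix(fm: FeatureMatrix, csv_path: str | Path,
                         sidecar_path: str | Path | None = None,
                         provenance: dict | None = None) -> None:
    df = pd.DataFrame(fm.matrix, columns=fm.feature_names)
    df.insert(0, "molecule_id", fm.ids)
    df["label"] = fm.labels
    df.to_csv(csv_path, index=False)
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    meta = {
        "property": fm.property_name,
        "include_ccs": fm.include_ccs,
        "grid_V": list(map(float, fm.grid)),
        "feature_names": fm.feature_names,
        "n_molecules": fm.n_molecules,
        "provenance": provenance or {},
    }
    Path(sidecar_path).write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_feature_matrix(csv_path: str | Path,
                        sidecar_path: str | Path | None = None) -> FeatureMatrix:
    if sidecar_path is None:
        sidecar_path = Path(csv_path).with_suffix(".json")
    meta = json.loads(Path(sidecar_path).read_text(encoding="utf-8"))
    df = pd.read_csv(csv_path)
    feats = meta["feature_names"]
    return FeatureMatrix(
        ids=[str(v) for v in df["molecule_id"]],
        grid=np.array(meta["grid_V"], dtype=float),
        matrix=df[feats].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=float),
        property_name=meta["property"],
        include_ccs=bool(meta["include_ccs"]),
        feature_names=list(feats),
    )


# --------------------------------------------------------------------------
# Result tables
# --------------------------------------------------------------------------

def write_loo_csv(result: LOOResult, path: str | Path) -> None:
    pd.DataFrame(
        {"molecule_id": result.ids, "true": result.true, "predicted": result.predicted}
    ).to_csv(path, index=False)
    summary = {
        "property": result.property_name,
        "r2_pearson_sq": result.r2,
        "r2_coefficient_of_determination": result.r2_cod,
        "mae": result.mae,
        "mean_abs_pct_error": result.mean_abs_pct_error,
        "n": len(result.ids),
    }
    Path(path).with_suffix(".json").write_text(json.dumps(summary, indent=1),
                                               encoding="utf-8")


def write_learning_curve_csv(lc: LearningCurve, path: str | Path) -> None:
    pd.DataFrame(
        {
            "fraction": lc.fractions,
            "test_mae_mean": lc.test_mae_mean,
            "test_mae_sd": lc.test_mae_sd,
            "train_mae_mean": lc.train_mae_mean,
            "train_mae_sd": lc.train_mae_sd,
        }
    ).to_csv(path, index=False)
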