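"""File formats: NIfTI images/masks, CSV curves and manifests, JSON plans,
YAML NTCP models."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .evaluate import NTCPModel
from .optimize import Plan
from .phantoms import ImageGrid, StructureSet
from .physics import Beam, CalibrationCurve
from .scenarios import Scenario

__all__ = [
    "save_image", "load_image",
    "save_structures", "load_structures",
    "write_cohort_manifest",
    "save_curve", "load_curve",
    "save_plan", "load_plan",
    "save_ntcp_models", "load_ntcp_models",
]


def _affine(image: ImageGrid) -> np.ndarray:
    aff = np.eye(4)
    for a in range(image.ndim):
        aff[a, a] = image.spacing[a]
        aff[a, 3] = image.origin[a]
    return aff


def save_image(image: ImageGrid, path: Path) -> None:
    """Write an image as single-channel NIfTI (2-D grids get a singleton z)."""
    data = image.values
    if data.ndim == 2:
        data = data[:, :, None]
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(image)), str(path))


def load_image(path: Path) -> ImageGrid:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    aff = img.affine
    if data.ndim == 3 and data.shape[2] == 1:
        data = data[:, :, 0]
    nd = data.ndim
    spacing = tuple(float(aff[a, a]) for a in range(nd))
    origin = tuple(float(aff[a, 3]) for a in range(nd))
    return ImageGrid(data, spacing, origin)


def save_structures(structures: StructureSet, directory: Path, image: ImageGrid) -> None:
    """One NIfTI label volume per mask, named after the structure."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in structures.items():
        data = mask.astype(np.uint8)
        if data.ndim == 2:
            data = data[:, :, None]
        nib.save(nib.Nifti1Image(data, _affine(image)), str(directory / f"{name}.nii.gz"))


def load_structures(directory: Path) -> StructureSet:
    directory = Path(directory)

    def read(name: str) -> np.ndarray:
        arr = np.asanyarray(nib.load(str(directory / f"{name}.nii.gz")).dataobj)
        if arr.ndim == 3 and arr.shape[2] == 1:
            arr = arr[:, :, 0]
        return arr.astype(bool)

    oars = {}
    for f in sorted(directory.glob("oar_*.nii.gz")):
        oars[f.name[len("oar_"):-len(".nii.gz")]] = read(f.name[: -len(".nii.gz")])
    avoidance = None
    if (directory / "avoidance.nii.gz").exists():
        avoidance = read("avoidance")
    return StructureSet(
        external=read("external"),
        ctv_high=read("ctv_high"),
        ctv_low=read("ctv_low"),
        oars=oars,
        avoidance=avoidance,
    )


def write_cohort_manifest(
    rows: Sequence[Dict[str, object]], path: Path
) -> pd.DataFrame:
    """CSV listing phantom id, seed and file paths for a generated cohort."""
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def save_curve(curve: CalibrationCurve, path: Path) -> None:
    np.savetxt(path, np.column_stack([curve.hu, curve.rsp]),
               delimiter=",", header="hu,rsp", comments="")


def load_curve(path: Path) -> CalibrationCurve:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return CalibrationCurve(arr[:, 0], arr[:, 1])


def save_plan(plan: Plan, path: Path) -> None:
    payload = {
        "weights": plan.weights.tolist(),
        "beams": [
            {
                "angle_deg": b.angle_deg,
                "lateral": b.lateral.tolist(),
                "nominal_range": b.nominal_range.tolist(),
                "lateral_sigma": b.lateral_sigma,
            }
            for b in plan.beams
        ],
        "scenarios": [
            {"shift": list(s.shift), "density_scale": s.density_scale, "label": s.label}
            for s in plan.scenarios
        ],
        "srs": plan.srs,
        "rrs": plan.rrs,
        "label": plan.label,
        "feasible": plan.feasible,
        "diagnostics": _jsonable(plan.diagnostics),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_plan(path: Path) -> Plan:
    payload = json.loads(Path(path).read_text())
    beams = [
        Beam(b["angle_deg"], np.array(b["lateral"]), np.array(b["nominal_range"]),
             b["lateral_sigma"])
        for b in payload["beams"]
    ]
    scenarios = [
        Scenario(tuple(s["shift"]), s["density_scale"], s["label"])
        for s in payload["scenarios"]
    ]
    return Plan(
        weights=np.array(payload["weights"]),
        beams=beams,
        scenarios=scenarios,
        srs=payload["srs"],
        rrs=payload["rrs"],
        label=payload.get("label", ""),
        feasible=payload.get("feasible", True),
        diagnostics=payload.get("diagnostics", {}),
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def save_ntcp_models(models: Sequence[NTCPModel], path: Path) -> None:
    payload = [
        {"name": m.name, "intercept": m.intercept, "coefficients": dict(m.coefficients)}
        for m in models
    ]
    Path(path).write_text(yaml.safe_dump(payload))


def load_ntcp_models(path: Path) -> List[NTCPModel]:
    payload = yaml.safe_load(Path(path).read_text())
    return [
        NTCPModel(m["name"], float(m["intercept"]),
                  {k: float(v) for k, v in m["coefficients"].items()})
        for m in payload
    ]
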