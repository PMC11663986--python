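"""File interchange: NIfTI volumes, CSV tables, YAML study configuration."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .contours import MarginSpec, StructureMask
from .dosimetry import DoseGrid

__all__ = [
    "save_mask",
    "load_mask",
    "save_dose",
    "load_dose",
    "margins_to_csv",
    "margins_from_csv",
    "jsonable",
    "config_hash",
    "write_json",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_mask(mask: StructureMask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))


def load_mask(path, structure_name: str = "") -> StructureMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    name = structure_name or Path(path).name.split(".")[0]
    return StructureMask(np.asanyarray(img.dataobj) > 0, spacing, name)


def save_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.spacing))
    img.header["descrip"] = f"nfx={dose.n_fractions}".encode()
    nib.save(img, str(path))


def load_dose(path, n_fractions: int | None = None) -> DoseGrid:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if n_fractions is None:
        descrip = bytes(img.header["descrip"]).decode(errors="ignore")
        if "nfx=" not in descrip:
            raise ValueError("n_fractions not stored in header; pass it explicitly")
        n_fractions = int(descrip.split("nfx=")[1].split("\x00")[0])
    return DoseGrid(np.asanyarray(img.dataobj).astype(float), spacing, n_fractions)


def margins_to_csv(margins: dict[str, MarginSpec], path) -> None:
    rows = [
        {
            "structure": m.structure_name,
            "msd_mm": m.msd_mm,
            "sd_mm": m.sd_mm,
            "expand_mm": m.expand_margin_mm,
            "contract_mm": m.contract_margin_mm,
            "policy": m.policy,
        }
        for m in margins.values()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def margins_from_csv(path) -> dict[str, MarginSpec]:
    df = pd.read_csv(path)
    out = {}
    for _, r in df.iterrows():
        out[str(r["structure"])] = MarginSpec(
            structure_name=str(r["structure"]),
            msd_mm=float(r["msd_mm"]),
            sd_mm=float(r["sd_mm"]),
            expand_margin_mm=float(r["expand_mm"]),
            contract_margin_mm=float(r["contract_mm"]),
            policy=str(r.get("policy", "symmetric")),
        )
    return out


def jsonable(obj):
    """Recursively convert dataclasses / numpy / tuple-keyed dicts to JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {
            (k if isinstance(k, str) else "x".join(str(v) for v in np.atleast_1d(k))):
                jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return {str(k): jsonable(v) for k, v in obj.items()}
    return obj


def config_hash(obj) -> str:
    """Content hash of a configuration object (stage caching key)."""
    payload = json.dumps(jsonable(obj), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(jsonable(obj), sort_keys=True, indent=1))
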