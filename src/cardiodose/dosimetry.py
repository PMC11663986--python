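"""EQD2 conversion and DVH feature extraction (Dmean, D0.1cc).

Planned physical dose is converted voxel-wise to the equivalent dose in
2 Gy fractions (EQD2) under the linear-quadratic model before any DVH
summary is computed; for heterogeneous dose this order differs from
converting DVH points post hoc, and the voxel-wise order is the one used
here (switchable, see :func:`dose_metrics`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import StructureMask

logger = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "AlphaBetaMap",
    "DoseMetrics",
    "eqd2",
    "dose_metrics",
    "build_feature_table",
    "resample_nearest",
    "CARDIAC_STRUCTURES",
    "LUNG_STRUCTURES",
    "ALL_STRUCTURES",
    "standard_alpha_beta",
    "all3_alpha_beta",
]

#: Whole heart and cardiac substructures (α/β = 2 Gy in the standard scenario).
CARDIAC_STRUCTURES = ("LA", "LV", "RA", "RV", "aorta", "SVC", "IVC", "PA", "WH")
#: Other organs at risk carried through the analysis (α/β = 3 Gy).
LUNG_STRUCTURES = ("LL", "RL")
ALL_STRUCTURES = CARDIAC_STRUCTURES + LUNG_STRUCTURES


@dataclass
class DoseGrid:
    """Total physical dose per voxel (Gy) plus the fractionation context."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    n_fractions: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("dose grid must be 3D")
        if (self.values < 0).any():
            raise ValueError("dose values must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.n_fractions = int(self.n_fractions)
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass
class AlphaBetaMap:
    """Per-structure α/β ratio (Gy) for the linear-quadratic conversion."""

    ratios: dict[str, float]
    scenario: str = "standard"

    def __post_init__(self) -> None:
        for name, ab in self.ratios.items():
            if ab <= 0:
                raise ValueError(f"alpha/beta for {name!r} must be > 0")

    def __getitem__(self, structure: str) -> float:
        return self.ratios[structure]


def standard_alpha_beta() -> AlphaBetaMap:
    """α/β of 2 Gy for the whole heart and cardiac substructures, 3 Gy else."""
    ratios = {s: 2.0 for s in CARDIAC_STRUCTURES}
    ratios.update({s: 3.0 for s in LUNG_STRUCTURES})
    return AlphaBetaMap(ratios, scenario="standard")


def all3_alpha_beta() -> AlphaBetaMap:
    """Robustness scenario: α/β of 3 Gy for every structure."""
    return AlphaBetaMap({s: 3.0 for s in ALL_STRUCTURES}, scenario="all3")


@dataclass
class DoseMetrics:
    """DVH summary for one structure under one contour/α-β variation."""

    structure_name: str
    d_mean: float
    d_0p1cc: float
    variation: str = "original"
    alpha_beta_scenario: str = "standard"
    sub_volume_flag: bool = False
    missing: bool = False


def eqd2(total_dose, n_fractions: int, alpha_beta: float):
    """Equivalent dose in 2 Gy fractions.

    EQD2 = D · (d + α/β) / (2 + α/β) with fraction dose d = D / n, applied
    element-wise, so a voxel receiving exactly 2 Gy per fraction is a fixed
    point of the conversion.
    """
    if alpha_beta <= 0:
        raise ValueError("alpha/beta must be > 0")
    n = int(n_fractions)
    if n < 1:
        raise ValueError("n_fractions must be >= 1")
    D = np.asarray(total_dose, dtype=float)
    if (D < 0).any():
        raise ValueError("dose must be non-negative")
    d = D / n
    out = D * (d + alpha_beta) / (2.0 + alpha_beta)
    if np.isscalar(total_dose) or np.ndim(total_dose) == 0:
        return float(out)
    return out


def dose_metrics(
    dose: DoseGrid,
    mask: StructureMask,
    alpha_beta: float,
    *,
    volume_cc: float = 0.1,
    variation: str = "original",
    alpha_beta_scenario: str = "standard",
) -> DoseMetrics:
    """Extract Dmean and D0.1cc (in EQD2 Gy) for one structure.

    The dose grid is converted voxel-wise to EQD2, then Dmean is the mean
    over mask voxels and D0.1cc is the dose to the hottest 0.1 cc: mask
    voxels are sorted by descending EQD2 and voxel volumes accumulated
    until ``volume_cc`` is reached; the value at the crossing voxel is
    reported without interpolation (sub-voxel interpolation would be false
    precision at 3 mm slices).

    An empty mask yields a missing-value result with a warning; a mask
    smaller than ``volume_cc`` reports its minimum EQD2, flagged.
    """
    if dose.values.shape != mask.voxels.shape:
        raise ValueError("dose grid and mask are on different lattices")
    if mask.is_empty():
        logger.warning("empty mask %r: dose features set to missing", mask.structure_name)
        return DoseMetrics(mask.structure_name, float("nan"), float("nan"),
                           variation, alpha_beta_scenario, missing=True)
    vals = eqd2(dose.values[mask.voxels], dose.n_fractions, alpha_beta)
    d_mean = float(vals.mean())
    vox_cc = mask.voxel_volume_mm3 / 1000.0
    order = np.sort(vals)[::-1]
    cum_cc = vox_cc * np.arange(1, order.size + 1)
    sub = cum_cc[-1] < volume_cc
    if sub:
        d01 = float(order[-1])
    else:
        idx = int(np.searchsorted(cum_cc, volume_cc))
        d01 = float(order[idx])
    return DoseMetrics(mask.structure_name, d_mean, d01, variation,
                       alpha_beta_scenario, sub_volume_flag=sub)


def build_feature_table(
    patient_ids,
    masks_per_patient,
    doses_per_patient,
    alpha_beta: AlphaBetaMap,
    *,
    variation: str = "original",
    structures=ALL_STRUCTURES,
) -> pd.DataFrame:
    """Assemble the per-patient dose-feature table for one model variation.

    One row per patient; columns ``<structure>_mean_eqd2`` and
    ``<structure>_max_eqd2`` (the latter being D0.1cc, the surrogate for
    the maximum dose).  Missing masks propagate NaN; the modelling stage
    applies the missing-data rule.
    """
    rows = []
    for pid, masks, dose in zip(patient_ids, masks_per_patient, doses_per_patient):
        row: dict[str, object] = {"id": pid}
        for s in structures:
            if s not in masks:
                raise KeyError(f"patient {pid}: mask for structure {s!r} missing")
            m = masks[s]
            if m.voxels.shape != dose.values.shape:
                raise ValueError(f"patient {pid}: dose/mask lattice mismatch for {s!r}")
            dm = dose_metrics(dose, m, alpha_beta[s], variation=variation,
                              alpha_beta_scenario=alpha_beta.scenario)
            row[f"{s}_mean_eqd2"] = dm.d_mean
            row[f"{s}_max_eqd2"] = dm.d_0p1cc
        rows.append(row)
    return pd.DataFrame(rows).set_index("id")


def resample_nearest(values: np.ndarray, src_spacing, dst_shape, dst_spacing) -> np.ndarray:
    """Nearest-neighbour resampling of a grid onto a different lattice.

    Utility only: the core pipeline assumes dose grids are already on the
    mask lattice.
    """
    src = np.asarray(values)
    coords = [
        np.clip(
            np.round((np.arange(n) + 0.5) * d / s - 0.5).astype(int), 0, src.shape[ax] - 1
        )
        for ax, (n, d, s) in enumerate(zip(dst_shape, dst_spacing, src_spacing))
    ]
    return src[np.ix_(*coords)]
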