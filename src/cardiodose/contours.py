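"""Segmentation-agreement metrics and signed-margin contour perturbation.

Delineation uncertainty of auto-contoured cardiac substructures is
propagated into dosimetry by expanding or contracting each binary mask by a
physical margin derived from the contour-evaluation statistics (mean surface
distance and its standard deviation).  All distances are Euclidean in
physical millimetres on the anisotropic voxel lattice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "StructureMask",
    "MarginSpec",
    "SegMetrics",
    "dice",
    "surface_distances",
    "perturb_mask",
    "margins_from_metrics",
    "qualify_structure",
]


@dataclass
class StructureMask:
    """Binary voxel mask of one anatomical structure.

    Parameters
    ----------
    voxels : ndarray of bool, shape (nx, ny, nz)
        Structure occupancy on the voxel lattice.
    spacing : tuple of 3 floats
        Voxel spacing in mm per axis; anisotropy is supported.
    structure_name : str
        Label, e.g. ``"LA"`` for the left atrium.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    structure_name: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be a 3D lattice")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive floats (mm)")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def volume_cc(self) -> float:
        """Structure volume in cubic centimetres."""
        return float(self.voxels.sum()) * self.voxel_volume_mm3 / 1000.0

    def is_empty(self) -> bool:
        return not bool(self.voxels.any())


@dataclass
class MarginSpec:
    """Expansion/contraction margins for one structure, in mm."""

    structure_name: str
    msd_mm: float
    sd_mm: float
    expand_margin_mm: float
    contract_margin_mm: float
    policy: str = "symmetric"

    def __post_init__(self) -> None:
        for field in ("msd_mm", "sd_mm", "expand_margin_mm", "contract_margin_mm"):
            if getattr(self, field) < 0:
                raise ValueError(f"{field} must be non-negative")


@dataclass
class SegMetrics:
    """Agreement between an automatic and a reference segmentation.

    ``msd_sd_mm`` is the standard deviation of the mean surface distance
    over the evaluation set; it sizes the contour-uncertainty margins.
    """

    dsc: float
    hd95_mm: float
    msd_mm: float
    msd_sd_mm: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dsc <= 1.0:
            raise ValueError("dsc must lie in [0, 1]")
        if self.hd95_mm < 0 or self.msd_mm < 0 or self.msd_sd_mm < 0:
            raise ValueError("surface distances must be non-negative")


def _check_same_lattice(a: StructureMask, b: StructureMask) -> None:
    if a.voxels.shape != b.voxels.shape:
        raise ValueError("masks are on different lattices")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError("masks have different voxel spacings")


def dice(a: StructureMask, b: StructureMask) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Symmetric in its arguments.  Raises if both masks are empty (0/0 is
    undefined, not zero).
    """
    _check_same_lattice(a, b)
    na, nb = int(a.voxels.sum()), int(b.voxels.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: mask minus its 6-connected erosion.

    ``border_value=0`` makes voxels touching the array edge boundary voxels,
    which is the convention documented for the surface metrics.
    """
    struct = ndimage.generate_binary_structure(3, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def surface_distances(a: StructureMask, b: StructureMask) -> tuple[float, float]:
    """Mean surface distance and 95th-percentile Hausdorff distance in mm.

    Boundary voxels are extracted by 6-connectivity erosion difference.
    The MSD is the mean of the two directed mean boundary distances
    (A→B and B→A); HD95 is the 95th percentile of the pooled symmetric
    boundary-distance set.  Both depend on these conventions, which are the
    ones used throughout the package.

    Returns
    -------
    (msd_mm, hd95_mm)
    """
    _check_same_lattice(a, b)
    if a.is_empty() or b.is_empty():
        raise ValueError("surface distances undefined for an empty mask")
    surf_a = _boundary(a.voxels)
    surf_b = _boundary(b.voxels)
    # distance of every voxel to the nearest boundary voxel of the other mask
    dt_to_b = ndimage.distance_transform_edt(~surf_b, sampling=a.spacing)
    dt_to_a = ndimage.distance_transform_edt(~surf_a, sampling=a.spacing)
    d_ab = dt_to_b[surf_a]
    d_ba = dt_to_a[surf_b]
    msd = 0.5 * (float(d_ab.mean()) + float(d_ba.mean()))
    pooled = np.concatenate([d_ab, d_ba])
    hd95 = float(np.percentile(pooled, 95))
    return msd, hd95


def perturb_mask(mask: StructureMask, signed_margin_mm: float) -> StructureMask:
    """Expand (positive margin) or contract (negative margin) a mask.

    Uses the exact Euclidean distance transform with anisotropic sampling:
    expansion by m keeps all voxels within distance m of the original mask;
    contraction by m keeps the voxels whose distance to the complement
    exceeds m.  Consequently ``contract(m) ⊆ original ⊆ expand(m)``.

    A contraction that empties the mask returns an empty mask with a logged
    warning; downstream dosimetry treats its features as missing.
    """
    m = float(signed_margin_mm)
    extent = min(s * n for s, n in zip(mask.spacing, mask.voxels.shape))
    if abs(m) >= extent:
        raise ValueError(f"|margin| {abs(m)} mm exceeds grid extent {extent} mm")
    if m == 0.0:
        out = mask.voxels.copy()
    elif m > 0:
        dt = ndimage.distance_transform_edt(~mask.voxels, sampling=mask.spacing)
        out = mask.voxels | (dt <= m)
    else:
        if mask.is_empty():
            raise ValueError("cannot contract an empty mask")
        dt_in = ndimage.distance_transform_edt(mask.voxels, sampling=mask.spacing)
        out = dt_in > -m
        if not out.any():
            logger.warning(
                "contraction by %.2f mm emptied structure %r",
                -m,
                mask.structure_name,
            )
            warnings.warn(
                f"contraction emptied structure {mask.structure_name!r}",
                stacklevel=2,
            )
    return StructureMask(out, mask.spacing, mask.structure_name)


def margins_from_metrics(metrics: SegMetrics, structure_name: str = "",
                         policy: str = "symmetric") -> MarginSpec:
    """Derive perturbation margins from contour-evaluation metrics.

    The default ``symmetric`` policy applies the same magnitude
    MSD + 2·SD outward (expansion) and inward (contraction).  The
    ``asymmetric`` alternative contracts by max(0, MSD − 2·SD) instead,
    which can degenerate to zero when the SD is large; the choice is a
    configuration switch rather than a silent decision.
    """
    expand = metrics.msd_mm + 2.0 * metrics.msd_sd_mm
    if policy == "symmetric":
        contract = expand
    elif policy == "asymmetric":
        contract = max(0.0, metrics.msd_mm - 2.0 * metrics.msd_sd_mm)
    else:
        raise ValueError(f"unknown margin policy {policy!r}")
    return MarginSpec(
        structure_name=structure_name,
        msd_mm=metrics.msd_mm,
        sd_mm=metrics.msd_sd_mm,
        expand_margin_mm=expand,
        contract_margin_mm=contract,
        policy=policy,
    )


def qualify_structure(metrics: SegMetrics) -> bool:
    """Inclusion rule for auto-contoured structures.

    A structure qualifies for dosimetric analysis when its Dice score is
    strictly above 0.80 and its mean surface distance strictly below 2 mm.
    """
    return metrics.dsc > 0.80 and metrics.msd_mm < 2.0
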