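"""Synthetic lung-SBRT cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of early-stage lung cancer patients treated with
hypofractionated stereotactic radiotherapy, a stylized thoracic phantom
(spheres/ellipsoids/tubes for the four cardiac chambers, great vessels,
whole heart and lungs), a spatially coherent dose distribution falling off
from the planning target volume (PTV), and survival times drawn from a
proportional-hazards model in which one chosen substructure's mean EQD2 is
the true dose driver.  Every stage is deterministic given the master seed;
patients draw from per-patient substreams so that changing the cohort size
does not reshuffle earlier patients.

Two levels of fidelity are provided: :func:`generate_cohort` builds the
full voxel phantom per patient (geometry, masks, dose grid, dose features,
survival), while :func:`generate_feature_cohort` samples the dose-feature
table directly from the same latent-distance model without rasterizing
anything — orders of magnitude faster, used for calibration experiments
that need hundreds of replicate cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .contours import StructureMask
from .dosimetry import (
    ALL_STRUCTURES,
    LUNG_STRUCTURES,
    DoseGrid,
    dose_metrics,
    eqd2,
    standard_alpha_beta,
)
from .exceptions import ConfigurationError, DataError, GeometryError

__all__ = [
    "CohortSpec",
    "HazardSpec",
    "CensoringSpec",
    "CovariateSpec",
    "PatientRecord",
    "PhantomGeometry",
    "generate_cohort",
    "generate_feature_cohort",
    "recovery_hazard",
    "rasterize_masks",
    "generate_dose_grid",
    "simulate_survival",
    "cohort_to_frame",
    "PATHOLOGY_LEVELS",
    "FRACTIONATION_MIX",
]

PATHOLOGY_LEVELS = ("squamous", "adeno", "proven", "unknown")

#: Default fractionation mix: the four SBRT schedules of the emulated cohort
#: (3x18, 5x12, 8x7.5 and 12x5 Gy) at their observed relative frequencies.
FRACTIONATION_MIX = {
    (3, 18.0): 176 / 725,
    (5, 12.0): 368 / 725,
    (8, 7.5): 140 / 725,
    (12, 5.0): 41 / 725,
}


@dataclass
class CovariateSpec:
    """Marginal distributions of the baseline covariates.

    Defaults reproduce the covariate mix of the emulated cohort: 56.4%
    male, median age 74 (range 37-92), 76.6% stage 1, 43.0% left-sided,
    pathology squamous/adeno/proven/unknown at 8.6/12.1/73.7/5.6%, and a
    log-normal PTV volume with median about 20 cc.
    """

    sex_male_prop: float = 0.564
    age_mean: float = 73.0
    age_sd: float = 9.5
    age_range: tuple[float, float] = (37.0, 92.0)
    stage1_prop: float = 0.766
    laterality_left_prop: float = 0.430
    pathology_props: dict[str, float] = field(
        default_factory=lambda: {
            "squamous": 0.086, "adeno": 0.121, "proven": 0.737, "unknown": 0.056
        }
    )
    log_ptv_mean: float = math.log(20.4)
    log_ptv_sd: float = 0.95
    ptv_cc_range: tuple[float, float] = (1.9, 150.0)
    # GTV volume as a Beta-distributed fraction of the PTV volume
    gtv_ratio_ab: tuple[float, float] = (4.8, 5.2)


@dataclass
class HazardSpec:
    """Ground-truth proportional-hazards model.

    Event times follow a Weibull baseline (shape, scale in days) scaled by
    exp(linear predictor).  ``driver_feature`` names the dose feature that
    carries the designed effect; its coefficient is a per-Gy log hazard
    ratio on the EQD2 scale.  Coefficients apply to covariates centred at
    ``reference_values`` (zero where absent), so the baseline scale retains
    its interpretation as the survival of a typical patient.
    """

    baseline_shape: float = 1.1
    baseline_scale_days: float = 2200.0
    log_hazard_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "LA_mean_eqd2": math.log(1.05),
            "age": 0.025,
            "sex_M": 0.20,
            "log_ptv": 0.35,
            "pathology_squamous": 0.25,
            "pathology_adeno": 0.10,
            "pathology_unknown": 0.05,
        }
    )
    reference_values: dict[str, float] = field(
        default_factory=lambda: {
            "LA_mean_eqd2": 4.0,
            "age": 73.0,
            "sex_M": 0.56,
            "log_ptv": math.log(20.4),
        }
    )
    driver_feature: str = "LA_mean_eqd2"

    def validate(self) -> None:
        if self.baseline_shape <= 0 or self.baseline_scale_days <= 0:
            raise ConfigurationError("hazard baseline shape and scale must be > 0")
        if self.driver_feature not in self.log_hazard_coefficients:
            raise ConfigurationError(
                f"driver_feature {self.driver_feature!r} has no coefficient"
            )


@dataclass
class CensoringSpec:
    """Administrative horizon plus independent exponential random censoring."""

    horizon_days: float = 3650.0
    random_rate_per_day: float = 1.0 / 6000.0

    def validate(self) -> None:
        if self.horizon_days < 0:
            raise ConfigurationError("censoring horizon_days must be >= 0")
        if self.random_rate_per_day < 0:
            raise ConfigurationError("censoring random_rate_per_day must be >= 0")


@dataclass
class CohortSpec:
    """Full specification of a synthetic cohort."""

    n_patients: int = 730
    seed: int = 0
    grid_shape: tuple[int, int, int] = (84, 84, 40)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    fractionation_mix: dict[tuple[int, float], float] = field(
        default_factory=lambda: dict(FRACTIONATION_MIX)
    )
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    hazard: HazardSpec = field(default_factory=HazardSpec)
    censoring: CensoringSpec = field(default_factory=CensoringSpec)
    dose_falloff_mm: float = 20.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive on every axis")
        if len(self.grid_shape) != 3 or any(n < 4 for n in self.grid_shape):
            raise ConfigurationError("grid_shape must be three ints >= 4")
        if self.dose_falloff_mm <= 0:
            raise ConfigurationError("dose_falloff_mm must be > 0")
        for name, probs in (
            ("fractionation_mix", list(self.fractionation_mix.values())),
            ("pathology_props", list(self.covariates.pathology_props.values())),
        ):
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} probabilities must sum to 1")
            if any(p < 0 for p in probs):
                raise ConfigurationError(f"{name} probabilities must be >= 0")
        self.hazard.validate()
        self.censoring.validate()


@dataclass
class PatientRecord:
    """Covariates, fractionation and outcome for one synthetic patient."""

    id: str
    sex: str
    age: float
    stage: int
    laterality: str
    gtv_cc: float
    ptv_cc: float
    pathology: str
    n_fractions: int
    dose_per_fraction: float
    survival_days: float
    event: int
    dist_heart_ptv_cc: float
    dist_heart_ptv_inplane: float
    dist_heart_gtv_cc: float
    dist_heart_gtv_inplane: float


@dataclass
class PhantomGeometry:
    """Analytic placement of every structure for one patient (mm units).

    The four chambers are ellipsoids around a (jittered) heart centre, the
    great vessels are vertical tubes, the whole heart (WH) is the union of
    the chambers with the intracardiac vessel segments, and the lungs are
    large ellipsoids with the WH carved out.  Stylized rather than
    anatomical: downstream stages consume only masks and dose values.
    """

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    heart_center: tuple[float, float, float]
    chamber_offsets: dict[str, tuple[float, float, float]]
    chamber_radii: dict[str, tuple[float, float, float]]
    vessel_xy: dict[str, tuple[float, float]]
    vessel_z: dict[str, tuple[float, float]]
    vessel_radius: float
    wh_capture_radius: float
    lung_centers: dict[str, tuple[float, float, float]]
    lung_radii: tuple[float, float, float]
    ptv_center: tuple[float, float, float]
    ptv_radii: tuple[float, float, float]
    gtv_radii: tuple[float, float, float]

    @property
    def ptv_radius(self) -> float:
        return max(self.ptv_radii)


_CHAMBER_OFFSETS = {
    "LA": (17.0, 17.0, 0.0),
    "LV": (17.0, -17.0, 0.0),
    "RA": (-17.0, 17.0, 0.0),
    "RV": (-17.0, -17.0, 0.0),
}
_VESSEL_XY = {
    "aorta": (5.0, 26.0),
    "SVC": (-21.0, 18.0),
    "IVC": (-21.0, 16.0),
    "PA": (-3.0, -26.0),
}


def _patient_rng(seed: int, index: int) -> np.random.Generator:
    """Per-patient substream: independent of cohort size and of other patients."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _radius_from_cc(volume_cc: float) -> float:
    return (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def _sample_geometry(rng: np.random.Generator, spec: CohortSpec,
                     laterality: str, ptv_cc: float, gtv_cc: float) -> PhantomGeometry:
    extent = tuple(n * s for n, s in zip(spec.grid_shape, spec.spacing))
    # canonical layout is drawn for a 180 x 180 x 132 mm grid and rescaled
    fx, fy, fz = extent[0] / 180.0, extent[1] / 180.0, extent[2] / 132.0
    scale = min(fx, fy, fz)
    jitter = rng.uniform(-4.0, 4.0, size=3) * scale
    hc = np.array([80.0 * fx + jitter[0], 98.0 * fy + jitter[1], 62.0 * fz + jitter[2]])

    lung_z = 0.5 * extent[2]
    lungs = {
        "LL": (46.0 * fx, 94.0 * fy, lung_z),
        "RL": (134.0 * fx, 94.0 * fy, lung_z),
    }
    lung_cx = lungs["LL"][0] if laterality == "left" else lungs["RL"][0]
    # hearts vary in size across patients; chambers vary a little on top
    heart_size = rng.uniform(0.85, 1.25)
    chamber_radii = {
        name: tuple(r * heart_size * rng.uniform(0.90, 1.08) * scale
                    for r in (15.0, 15.0, 17.0))
        for name in _CHAMBER_OFFSETS
    }
    # ellipsoidal target with random aspect, volume preserved; targets too
    # large for a (small) grid are clamped so the sphere always fits
    ax = rng.uniform(0.75, 1.35, size=3)
    ax /= ax.prod() ** (1.0 / 3.0)
    max_r = (min(extent) / 2.0 - 4.0) / float(ax.max())
    if max_r <= 2.0:
        raise GeometryError("grid too small to hold any target volume")
    max_cc = 4.0 / 3.0 * math.pi * max_r**3 / 1000.0
    if ptv_cc > max_cc:
        gtv_cc *= max_cc / ptv_cc
        ptv_cc = max_cc
    ptv_r = _radius_from_cc(ptv_cc)
    gtv_r = _radius_from_cc(gtv_cc)
    ptv_radii = tuple(ptv_r * a for a in ax)
    gtv_radii = tuple(gtv_r * a for a in ax)
    ptv_r = max(ptv_radii)
    center = np.array([
        lung_cx + rng.uniform(-18.0, 18.0) * scale,
        94.0 * fy + rng.uniform(-40.0, 40.0) * scale,
        lung_z + rng.uniform(-40.0, 40.0) * scale,
    ])
    # surface gap between PTV and the heart envelope, emulating the target
    # cohort's distance distribution (closest targets abut the heart)
    gap = rng.uniform(-4.0, 34.0) * scale
    heart_extent = 42.0 * scale
    vec = center - hc
    norm = float(np.linalg.norm(vec))
    if norm < 1e-6:
        vec, norm = np.array([1.0, 0.0, 0.0]), 1.0
    needed = heart_extent + ptv_r + gap
    if norm < needed:
        center = hc + vec / norm * needed
    lo = np.array([ptv_r + 1.0] * 3)
    hi = np.array(extent) - (ptv_r + 1.0)
    if (lo > hi).any():
        raise GeometryError("PTV too large for the grid extent")
    center = np.clip(center, lo, hi)

    return PhantomGeometry(
        grid_shape=tuple(spec.grid_shape),
        spacing=tuple(spec.spacing),
        heart_center=tuple(float(c) for c in hc),
        chamber_offsets={k: tuple(np.array(v) * heart_size * scale)
                         for k, v in _CHAMBER_OFFSETS.items()},
        chamber_radii=chamber_radii,
        vessel_xy={k: (v[0] * scale, v[1] * scale) for k, v in _VESSEL_XY.items()},
        vessel_z={
            "aorta": (hc[2] + 8.0 * scale, min(extent[2] - 3.0, hc[2] + 56.0 * scale)),
            "SVC": (hc[2] + 10.0 * scale, min(extent[2] - 3.0, hc[2] + 52.0 * scale)),
            "IVC": (max(3.0, hc[2] - 50.0 * scale), hc[2] - 10.0 * scale),
            "PA": (hc[2] + 6.0 * scale, min(extent[2] - 3.0, hc[2] + 44.0 * scale)),
        },
        vessel_radius=7.5 * heart_size * scale,
        wh_capture_radius=40.0 * heart_size * scale,
        lung_centers=lungs,
        lung_radii=(30.0 * scale, 48.0 * scale, min(52.0 * scale, 0.45 * extent[2])),
        ptv_center=tuple(float(c) for c in center),
        ptv_radii=tuple(float(r) for r in ptv_radii),
        gtv_radii=tuple(float(r) for r in gtv_radii),
    )


def _coord_grids(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(coords, center, radii) -> np.ndarray:
    X, Y, Z = coords
    return (
        ((X - center[0]) / radii[0]) ** 2
        + ((Y - center[1]) / radii[1]) ** 2
        + ((Z - center[2]) / radii[2]) ** 2
    ) <= 1.0


def _tube(coords, xy, radius, z_range) -> np.ndarray:
    X, Y, Z = coords
    return (
        (((X - xy[0]) / radius) ** 2 + ((Y - xy[1]) / radius) ** 2 <= 1.0)
        & (Z >= z_range[0])
        & (Z <= z_range[1])
    )


def rasterize_masks(geometry: PhantomGeometry,
                    structures=None) -> dict[str, StructureMask]:
    """Rasterize the phantom onto the voxel lattice.

    Returns masks for the four chambers, the great vessels, the whole heart
    (union of chambers and intracardiac vessel segments), the two lungs
    (with the heart carved out so lungs and WH are disjoint) and the PTV
    and GTV target structures.  A structure that rasterizes to zero voxels
    raises :class:`GeometryError` (the documented degenerate-size rule).

    Parameters
    ----------
    structures : iterable of str, optional
        Restrict output to these structure names (dependencies such as the
        chambers for WH are computed regardless).
    """
    shape, spacing = geometry.grid_shape, geometry.spacing
    coords = _coord_grids(shape, spacing)
    hc = np.array(geometry.heart_center)

    chambers = {
        name: _ellipsoid(coords, hc + np.array(off), geometry.chamber_radii[name])
        for name, off in geometry.chamber_offsets.items()
    }
    vessels = {
        name: _tube(
            coords,
            (hc[0] + geometry.vessel_xy[name][0], hc[1] + geometry.vessel_xy[name][1]),
            geometry.vessel_radius,
            geometry.vessel_z[name],
        )
        for name in geometry.vessel_xy
    }
    heart_ball = _ellipsoid(coords, hc, (geometry.wh_capture_radius,) * 3)
    wh = np.zeros(shape, dtype=bool)
    for m in chambers.values():
        wh |= m
    for m in vessels.values():
        wh |= m & heart_ball

    ptv = _ellipsoid(coords, geometry.ptv_center, geometry.ptv_radii)
    gtv = _ellipsoid(coords, geometry.ptv_center, geometry.gtv_radii)
    # lung OAR masks exclude the heart and the treatment target, as in the
    # clinical lungs-minus-target dosimetric structure
    lungs = {
        name: _ellipsoid(coords, c, geometry.lung_radii) & ~wh & ~ptv
        for name, c in geometry.lung_centers.items()
    }

    voxel_masks = {**chambers, **vessels, "WH": wh, **lungs, "PTV": ptv, "GTV": gtv}
    wanted = list(voxel_masks) if structures is None else list(structures)
    out = {}
    for name in wanted:
        vox = voxel_masks[name]
        if not vox.any():
            raise GeometryError(f"structure {name!r} rasterizes to zero voxels")
        out[name] = StructureMask(vox, spacing, name)
    return out


def generate_dose_grid(geometry: PhantomGeometry, prescription: float,
                       falloff_mm: float, n_fractions: int,
                       ptv_mask: StructureMask | None = None) -> DoseGrid:
    """SBRT-like dose surrogate: prescription inside the PTV, isotropic
    exponential falloff with the Euclidean distance from the PTV surface."""
    if prescription <= 0:
        raise ConfigurationError("prescription must be > 0")
    if falloff_mm <= 0:
        raise ConfigurationError("falloff_mm must be > 0")
    if ptv_mask is None:
        ptv_mask = rasterize_masks(geometry, structures=["PTV"])["PTV"]
    dt = ndimage.distance_transform_edt(~ptv_mask.voxels, sampling=geometry.spacing)
    dose = prescription * np.exp(-dt / falloff_mm)
    dose[ptv_mask.voxels] = prescription
    return DoseGrid(dose, geometry.spacing, n_fractions)


def _surface_gap(target: StructureMask, wh: StructureMask):
    """Signed nearest-approach between a target structure and the heart,
    split into craniocaudal (axis 2) and in-plane components (mm)."""
    dt, inds = ndimage.distance_transform_edt(
        ~wh.voxels, sampling=wh.spacing, return_indices=True
    )
    tvox = np.argwhere(target.voxels)
    d = dt[tuple(tvox.T)]
    k = int(np.argmin(d))
    if d[k] == 0.0:
        return 0.0, 0.0
    src = tvox[k]
    dst = inds[:, src[0], src[1], src[2]]
    delta = (src - dst) * np.array(wh.spacing)
    return float(delta[2]), float(math.hypot(delta[0], delta[1]))


def _dose_feature_names(hazard: HazardSpec) -> list[str]:
    return [
        name for name in hazard.log_hazard_coefficients
        if name.endswith("_mean_eqd2") or name.endswith("_max_eqd2")
    ]


def _draw_covariates(rng: np.random.Generator, cov: CovariateSpec,
                     mix: dict[tuple[int, float], float]) -> dict:
    sex = "M" if rng.random() < cov.sex_male_prop else "F"
    age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), *cov.age_range))
    stage = 1 if rng.random() < cov.stage1_prop else 2
    laterality = "left" if rng.random() < cov.laterality_left_prop else "right"
    pathology = PATHOLOGY_LEVELS[
        rng.choice(len(PATHOLOGY_LEVELS), p=[cov.pathology_props[p] for p in PATHOLOGY_LEVELS])
    ]
    ptv_cc = float(np.clip(math.exp(rng.normal(cov.log_ptv_mean, cov.log_ptv_sd)),
                           *cov.ptv_cc_range))
    gtv_cc = float(ptv_cc * rng.beta(*cov.gtv_ratio_ab))
    schemes = list(mix)
    scheme = schemes[rng.choice(len(schemes), p=[mix[s] for s in schemes])]
    return dict(sex=sex, age=age, stage=stage, laterality=laterality,
                pathology=pathology, ptv_cc=ptv_cc, gtv_cc=gtv_cc,
                n_fractions=scheme[0], dose_per_fraction=scheme[1])


def _covariate_features(c: dict) -> dict[str, float]:
    feats = {
        "age": c["age"],
        "sex_M": 1.0 if c["sex"] == "M" else 0.0,
        "log_ptv": math.log(c["ptv_cc"]),
        "stage_2": 1.0 if c["stage"] == 2 else 0.0,
        "laterality_left": 1.0 if c["laterality"] == "left" else 0.0,
    }
    for lvl in PATHOLOGY_LEVELS:
        if lvl != "proven":  # largest category is the reference level
            feats[f"pathology_{lvl}"] = 1.0 if c["pathology"] == lvl else 0.0
    return feats


def simulate_survival(features: pd.DataFrame, hazard: HazardSpec,
                      censoring: CensoringSpec, seed: int) -> pd.DataFrame:
    """Draw (survival_days, event) per patient under the ground-truth model.

    Event times come from the Weibull baseline accelerated by
    exp(linear predictor); the observed time is the minimum of the event
    time, the administrative horizon and an exponential random-censoring
    time.  Each patient uses an independent substream of ``seed`` keyed by
    row position.
    """
    hazard.validate()
    censoring.validate()
    for feat in hazard.log_hazard_coefficients:
        if feat not in features.columns:
            raise DataError(f"feature {feat!r} missing from feature table")
        bad = features.index[features[feat].isna()]
        if len(bad):
            raise DataError(f"patient {bad[0]!r}: feature {feat!r} is missing")
    lp = np.zeros(len(features))
    for feat, beta in hazard.log_hazard_coefficients.items():
        ref = hazard.reference_values.get(feat, 0.0)
        lp += beta * (features[feat].to_numpy(dtype=float) - ref)
    out_t = np.empty(len(features))
    out_e = np.empty(len(features), dtype=int)
    for i in range(len(features)):
        rng = _patient_rng(seed, i)
        u = rng.random()
        t_event = hazard.baseline_scale_days * (
            -math.log(1.0 - u) / math.exp(lp[i])
        ) ** (1.0 / hazard.baseline_shape)
        t_cens = censoring.horizon_days
        if censoring.random_rate_per_day > 0:
            t_cens = min(t_cens, rng.exponential(1.0 / censoring.random_rate_per_day))
        out_t[i] = min(t_event, t_cens)
        out_e[i] = int(t_event <= t_cens)
    return pd.DataFrame(
        {"survival_days": out_t, "event": out_e}, index=features.index
    )


def generate_cohort(spec: CohortSpec):
    """Generate a full synthetic cohort with voxel phantoms.

    Per patient: draw covariates, place the phantom, compute target-heart
    distances and the dose features named in the hazard specification from
    the rasterized masks and the dose grid (original contours, standard
    α/β), then draw survival from the proportional-hazards ground truth.

    Returns
    -------
    (records, geometries)
        ``records`` is a list of :class:`PatientRecord`; ``geometries`` the
        matching list of :class:`PhantomGeometry` so downstream stages can
        re-rasterize the masks deterministically.
    """
    spec.validate()
    ab = standard_alpha_beta()
    dose_feats = _dose_feature_names(spec.hazard)
    dose_structs = sorted({f.rsplit("_", 2)[0] for f in dose_feats})
    records: list[PatientRecord] = []
    geometries: list[PhantomGeometry] = []
    feature_rows = []
    for i in range(spec.n_patients):
        rng = _patient_rng(spec.seed, i)
        cov = _draw_covariates(rng, spec.covariates, spec.fractionation_mix)
        geom = _sample_geometry(rng, spec, cov["laterality"], cov["ptv_cc"], cov["gtv_cc"])
        need = sorted(set(dose_structs) | {"WH", "PTV", "GTV"})
        masks = rasterize_masks(geom, structures=need)
        rx = cov["n_fractions"] * cov["dose_per_fraction"]
        dose = generate_dose_grid(geom, rx, spec.dose_falloff_mm,
                                  cov["n_fractions"], ptv_mask=masks["PTV"])
        cc_p, ip_p = _surface_gap(masks["PTV"], masks["WH"])
        cc_g, ip_g = _surface_gap(masks["GTV"], masks["WH"])
        feats = _covariate_features(cov)
        for f in dose_feats:
            struct, kind, _ = f.rsplit("_", 2)
            dm = dose_metrics(dose, masks[struct], ab[struct])
            feats[f] = dm.d_mean if kind == "mean" else dm.d_0p1cc
        feature_rows.append(feats)
        records.append(PatientRecord(
            id=f"P{i:05d}", sex=cov["sex"], age=cov["age"], stage=cov["stage"],
            laterality=cov["laterality"], gtv_cc=cov["gtv_cc"], ptv_cc=cov["ptv_cc"],
            pathology=cov["pathology"], n_fractions=cov["n_fractions"],
            dose_per_fraction=cov["dose_per_fraction"],
            survival_days=0.0, event=0,
            dist_heart_ptv_cc=cc_p, dist_heart_ptv_inplane=ip_p,
            dist_heart_gtv_cc=cc_g, dist_heart_gtv_inplane=ip_g,
        ))
        geometries.append(geom)
    features = pd.DataFrame(feature_rows, index=[r.id for r in records])
    surv = simulate_survival(features, spec.hazard, spec.censoring,
                             seed=spec.seed + 1_000_003)
    for rec, (_, row) in zip(records, surv.iterrows()):
        rec.survival_days = float(max(row["survival_days"], 0.0))
        rec.event = int(row["event"])
    return records, geometries


def cohort_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    """Cohort table with one row per patient (column dictionary in docs)."""
    df = pd.DataFrame([vars(r) for r in records]).set_index("id")
    return df


# ---------------------------------------------------------------------------
# feature-level generator (no voxel phantom)


def recovery_hazard(driver: str = "LA_mean_eqd2") -> HazardSpec:
    """Ground truth for parameter-recovery benchmarks.

    The driver carries the designed per-Gy effect (HR 1.05/Gy EQD2) and is
    the sole dose-linked term; the remaining coefficients act on covariates
    that do not determine dose (age, sex, pathology), so the driver is
    identifiable from the dose features — a volume or distance effect
    would leak into every dose feature and make the dose-only models an
    ill-posed recovery target for any method.
    """
    return HazardSpec(
        log_hazard_coefficients={
            driver: math.log(1.05), "age": 0.02, "sex_M": 0.20,
            "pathology_squamous": 0.25,
        },
        reference_values={driver: 4.0, "age": 73.0, "sex_M": 0.56},
        driver_feature=driver,
    )


#: mm offset of each structure's nearest surface beyond the latent
#: target-heart gap (lungs sit closer to the target than the heart does)
_STRUCT_OFFSETS = {s: o for s, o in zip(
    ALL_STRUCTURES, (0.0, 4.0, 7.0, 9.0, 12.0, 15.0, 18.0, 14.0, -2.0, -6.0, -8.0)
)}


def _feature_latents(prng, c, structures, falloff_mm):
    """Latent per-structure dose state for one patient.

    Two latent distances per structure decouple the two DVH features the
    way treatment plans do: D0.1cc follows the nearest-approach distance
    (plus a hot-spot factor), Dmean the bulk-averaging depth beyond it.
    """
    rx = c["n_fractions"] * c["dose_per_fraction"]
    # latent target-heart surface gap: gamma with median ~29 mm and a
    # small abutting fraction, emulating the cohort's distance table
    d0 = prng.gamma(3.0, 11.0)
    out = {}
    for s in structures:
        d_near = max(0.0, d0 + _STRUCT_OFFSETS.get(s, 0.0) + prng.normal(0.0, 3.0))
        depth = prng.uniform(4.0, 28.0)
        het_max = math.exp(prng.normal(0.0, 0.15))
        het_mean = math.exp(prng.normal(0.0, 0.10))
        out[s] = (rx, d_near, depth, het_max, het_mean)
    return out


def _latents_to_features(latents, n_fx, falloff_mm, margin_mm, ab_cardiac):
    """Physical dose from the latent distances, then EQD2 per feature.

    ``margin_mm`` shifts the structure surface outward (positive, expanded
    contours: nearer to the target and deeper) or inward (negative).
    """
    feats = {}
    for s, (rx, d_near, depth, het_max, het_mean) in latents.items():
        dn = max(0.0, d_near - margin_mm)
        db = dn + max(2.0, depth + margin_mm)
        max_phys = min(rx, rx * math.exp(-dn / falloff_mm) * het_max)
        mean_phys = min(max_phys, rx * math.exp(-db / falloff_mm) * het_mean)
        ab = ab_cardiac if s not in LUNG_STRUCTURES else 3.0
        feats[f"{s}_mean_eqd2"] = eqd2(mean_phys, n_fx, ab)
        feats[f"{s}_max_eqd2"] = eqd2(max_phys, n_fx, ab)
    return feats


def generate_feature_cohort(
    n_patients: int,
    seed: int,
    hazard: HazardSpec | None = None,
    censoring: CensoringSpec | None = None,
    covariates: CovariateSpec | None = None,
    structures=ALL_STRUCTURES,
    falloff_mm: float = 20.0,
    margin_mm: float = 2.0,
    return_variants: bool = False,
):
    """Sample the dose-feature table directly from a latent-distance model.

    Each patient has a latent target-heart gap; each structure's
    nearest-approach and bulk-averaging distances derive from it, and the
    two DVH features follow the exponential falloff with independent
    hot-spot/heterogeneity factors.  This adds the plan-heterogeneity
    decorrelation between Dmean and D0.1cc that the idealized voxel
    phantom's isotropic kernel cannot produce, while preserving the
    inter-structure correlation — and it runs in milliseconds, which makes
    many-replicate calibration experiments feasible.

    With ``return_variants`` the function also returns the four model
    variation feature tables (expanded/contracted contours emulated by a
    ±``margin_mm`` shift of the latent distances; the all-3 Gy α/β
    scenario by reconverting the same physical dose), keyed like the
    study pipeline: ``(variation, alpha_beta_scenario)``.

    Returns the cohort frame (covariates, original/standard dose features,
    ``survival_days``/``event``), plus the variant dict when requested.
    """
    hazard = hazard if hazard is not None else HazardSpec()
    censoring = censoring if censoring is not None else CensoringSpec()
    cov = covariates if covariates is not None else CovariateSpec()
    rows = []
    variant_rows: dict[tuple[str, str], list] = {
        ("original", "standard"): [], ("expanded", "standard"): [],
        ("contracted", "standard"): [], ("original", "all3"): [],
    }
    variant_args = {
        ("original", "standard"): (0.0, 2.0),
        ("expanded", "standard"): (margin_mm, 2.0),
        ("contracted", "standard"): (-margin_mm, 2.0),
        ("original", "all3"): (0.0, 3.0),
    }
    for i in range(n_patients):
        prng = _patient_rng(seed, i)
        c = _draw_covariates(prng, cov, FRACTIONATION_MIX)
        latents = _feature_latents(prng, c, structures, falloff_mm)
        per_variant = {
            v: _latents_to_features(latents, c["n_fractions"], falloff_mm, m, ab)
            for v, (m, ab) in variant_args.items()
        }
        feats = dict(per_variant[("original", "standard")])
        feats.update(_covariate_features(c))
        feats.update({k: c[k] for k in ("sex", "age", "stage", "laterality",
                                        "pathology", "ptv_cc", "gtv_cc",
                                        "n_fractions", "dose_per_fraction")})
        rows.append(feats)
        for v in variant_rows:
            variant_rows[v].append(per_variant[v])
    index = [f"P{i:05d}" for i in range(n_patients)]
    df = pd.DataFrame(rows, index=index)
    surv = simulate_survival(df, hazard, censoring, seed=seed + 1_000_003)
    cohort = pd.concat([df, surv], axis=1)
    cohort.index.name = "id"
    if not return_variants:
        return cohort
    variants = {v: pd.DataFrame(r, index=index) for v, r in variant_rows.items()}
    for t in variants.values():
        t.index.name = "id"
    return cohort, variants
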