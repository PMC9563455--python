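"""Seeded phantom prostates and paired PET-1/PET-2 cohorts.

Each phantom is an ellipsoidal gland at a low background SUV containing a
focal tumor whose uptake decays as a clipped Gaussian from the configured
peak — the simplest profile whose relative-threshold iso-volumes can be
checked analytically.  The Gaussian width is chosen so the 45%-of-max
iso-surface sits at the configured tumor radius; the 20% iso-surface then
lies at ``radius * sqrt(ln(0.2)/ln(0.45))``, so zone-1 and zone-2 are
non-empty by construction.  A multiplicative correlated "lump" field
roughens the uptake, additive Gaussian noise (truncated at zero) is applied
last.

Group structure is injected twice, independently:

* on PET-1 texture/geometry (the prediction setting: features are
  pre-treatment), via per-group tumor radius, lump amplitude and a rim-
  cooling factor that lowers the peripheral background floor;
* on PET-1 -> PET-2 dynamics, via per-group reduction-ratio targets for
  SUVmax and MTV (SUVmean follows SUVmax; TL is their composite).

Responder-vs-non-responder differences are oriented so the planted feature
manifest matches the published direction pattern: responders have smaller,
rougher tumors (lower glcm_idmn/idn/imc1, glrlm_rln, gldm_dn,
shape_MeshVolume; higher ngtdm_Contrast; higher surface-to-volume ratio in
zones 1-2, lower in zone 3; higher zone-3 sphericity), a smaller zone-2
shell (lower shape_MinorAxisLength, higher gldm_sdlgle) and a cooler gland
rim (lower zone-3 interpolated minimum SUV).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import CohortTooSmallError, InfeasibleResponseTargetError
from .imaging import PETVolume, ROIMask

ZONE1_ISO_FRACTION = 0.45  # iso-contour the tumor radius is calibrated to

__all__ = [
    "GroupEffects",
    "SyntheticCohortConfig",
    "PhantomSpec",
    "PatientRecord",
    "make_phantom",
    "apply_response",
    "make_cohort",
    "make_sphere_lesion",
    "PLANTED_FEATURES",
]

# planted feature -> (zone, direction of responders relative to non-responders)
PLANTED_FEATURES: List[Tuple[str, int, str]] = [
    ("glcm_idmn", 1, "responders_lower"),
    ("glcm_idn", 1, "responders_lower"),
    ("glcm_imc1", 1, "responders_lower"),
    ("ngtdm_Contrast", 1, "responders_higher"),
    ("glrlm_rln", 1, "responders_lower"),
    ("gldm_dn", 1, "responders_lower"),
    ("shape_MeshVolume", 1, "responders_lower"),
    ("shape_SurfaceVolumeRatio", 1, "responders_higher"),
    ("gldm_sdlgle", 2, "responders_higher"),
    ("shape_MinorAxisLength", 2, "responders_lower"),
    ("shape_SurfaceVolumeRatio", 2, "responders_higher"),
    ("shape_Sphericity", 3, "responders_higher"),
    ("diagnostics_Mask-interpolated_Minimum", 3, "responders_lower"),
    ("shape_SurfaceVolumeRatio", 3, "responders_lower"),
]


@dataclass(frozen=True)
class GroupEffects:
    """Per-group generator settings (one instance per response group)."""

    tumor_radius_mm: float          # 45%-iso radius of the uptake profile
    texture_amp: float              # lump-field amplitude (fraction of local uptake)
    rim_cool: float                 # background falloff toward the gland rim
    rr_suvmax_range: Tuple[float, float]  # true reduction-ratio draw, percent
    rr_mtv_range: Tuple[float, float]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study-scale defaults: 35 patients, 73% responders, desk-size grids."""

    n_patients: int = 35
    responder_fraction: float = 0.73
    shape: Tuple[int, int, int] = (64, 64, 48)
    spacing: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    prostate_semiaxes_mm: Tuple[float, float, float] = (25.0, 20.0, 20.0)
    tumor_offset_mm: Tuple[float, float, float] = (6.0, 4.0, 0.0)
    peak_suv: float = 12.0
    peak_jitter_sd: float = 0.10        # lognormal sd on the per-patient peak
    radius_jitter_sd: float = 0.08      # lognormal sd on the per-patient radius
    background_suv: float = 1.2
    ambient_suv: float = 0.3            # outside the gland
    noise_sd_fraction: float = 0.05     # of background SUV
    blob_sigma_mm: float = 3.0          # correlation length of the lump field
    responders: GroupEffects = field(
        default_factory=lambda: GroupEffects(
            tumor_radius_mm=7.0,
            texture_amp=0.35,
            rim_cool=0.45,
            rr_suvmax_range=(40.0, 60.0),
            rr_mtv_range=(40.0, 65.0),
        )
    )
    non_responders: GroupEffects = field(
        default_factory=lambda: GroupEffects(
            tumor_radius_mm=10.0,
            texture_amp=0.10,
            rim_cool=0.20,
            rr_suvmax_range=(-5.0, 15.0),
            rr_mtv_range=(-5.0, 15.0),
        )
    )
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if min(self.prostate_semiaxes_mm) <= 0 or min(self.spacing) <= 0:
            raise ValueError("geometry must be positive")
        for g in (self.responders, self.non_responders):
            if g.tumor_radius_mm >= min(self.prostate_semiaxes_mm):
                raise ValueError("tumor larger than the prostate")

    @classmethod
    def null(cls, seed: int = 0, **kwargs) -> "SyntheticCohortConfig":
        """A cohort with no planted group differences anywhere.

        Both groups share one set of generator parameters and every
        patient's reduction ratios are drawn from one wide range spanning
        the 30% decision threshold, so the four per-parameter labelings
        carry no information about any image feature.
        """
        shared = GroupEffects(
            tumor_radius_mm=8.5,
            texture_amp=0.20,
            rim_cool=0.30,
            rr_suvmax_range=(0.0, 60.0),
            rr_mtv_range=(0.0, 60.0),
        )
        return cls(responders=shared, non_responders=shared, seed=seed, **kwargs)


@dataclass(frozen=True)
class PhantomSpec:
    """Everything needed to re-render one patient's uptake deterministically."""

    shape: Tuple[int, int, int]
    spacing: Tuple[float, float, float]
    prostate_center_mm: Tuple[float, float, float]
    prostate_semiaxes_mm: Tuple[float, float, float]
    tumor_center_mm: Tuple[float, float, float]
    peak_suv: float
    sigma_mm: float                  # Gaussian falloff width
    texture_amp: float
    blob_sigma_mm: float
    background_suv: float
    ambient_suv: float
    rim_cool: float
    noise_sd: float
    structure_seed: int              # lump field
    noise_seed: int                  # additive noise


@dataclass(frozen=True)
class PatientRecord:
    patient_id: int
    pet1: PETVolume
    pet2: PETVolume
    prostate_mask: ROIMask
    true_group: str                  # "responder" | "non_responder"
    true_rr: Dict[str, float]        # per-parameter targets, percent
    spec: PhantomSpec


def _grids(spec: PhantomSpec):
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    return X, Y, Z


def _render(spec: PhantomSpec, peak_scale: float = 1.0, radius_scale: float = 1.0):
    """Render the noiseless uptake field and the gland mask."""
    X, Y, Z = _grids(spec)
    pc = spec.prostate_center_mm
    sa = spec.prostate_semiaxes_mm
    rho2 = (
        ((X - pc[0]) / sa[0]) ** 2
        + ((Y - pc[1]) / sa[1]) ** 2
        + ((Z - pc[2]) / sa[2]) ** 2
    )
    gland = rho2 <= 1.0
    background = np.where(
        gland, spec.background_suv * (1.0 - spec.rim_cool * rho2), spec.ambient_suv
    )
    tc = spec.tumor_center_mm
    r2 = (X - tc[0]) ** 2 + (Y - tc[1]) ** 2 + (Z - tc[2]) ** 2
    sigma = spec.sigma_mm * radius_scale
    kernel = np.exp(-r2 / (2.0 * sigma ** 2))
    if spec.texture_amp > 0:
        rng = np.random.default_rng(spec.structure_seed)
        raw = rng.standard_normal(spec.shape)
        blob = ndimage.gaussian_filter(raw, sigma=[spec.blob_sigma_mm / s for s in spec.spacing])
        blob = (blob - blob.mean()) / blob.std()
        if radius_scale != 1.0:
            # shrink the lump pattern with the tumor so the follow-up lesion
            # is an exact spatial scaling and iso-volumes scale as k^3
            idx_c = [tc[a] / spec.spacing[a] for a in range(3)]
            coords = np.meshgrid(
                *[
                    (np.arange(n) - c) / radius_scale + c
                    for n, c in zip(spec.shape, idx_c)
                ],
                indexing="ij",
            )
            blob = ndimage.map_coordinates(blob, coords, order=1, mode="nearest")
        lumps = np.clip(1.0 + spec.texture_amp * blob, 0.05, None)
    else:
        lumps = 1.0
    tumor = peak_scale * spec.peak_suv * kernel * lumps
    return np.maximum(background, tumor), gland


def _finish(field: np.ndarray, spec: PhantomSpec, noise_seed: int) -> PETVolume:
    rng = np.random.default_rng(noise_seed)
    noisy = field + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return PETVolume(np.clip(noisy, 0.0, None), spec.spacing, (0.0, 0.0, 0.0))


def sigma_for_radius(radius_mm: float, fraction: float = ZONE1_ISO_FRACTION) -> float:
    """Gaussian width whose ``fraction``-of-peak iso-surface sits at ``radius_mm``."""
    return radius_mm / np.sqrt(2.0 * np.log(1.0 / fraction))


def make_phantom(spec: PhantomSpec) -> Tuple[PETVolume, ROIMask]:
    """Render the baseline (PET-1) volume and the gland mask."""
    field, gland = _render(spec)
    vol = _finish(field, spec, spec.noise_seed)
    mask = ROIMask(gland, spec.spacing, (0.0, 0.0, 0.0),
                   lesion_class="prostate_gland", label="prostate")
    return vol, mask


def apply_response(
    spec: PhantomSpec, rr_targets: Dict[str, float], noise_seed: Optional[int] = None
) -> PETVolume:
    """Render the follow-up (PET-2) volume for given true reduction ratios.

    The tumor peak is scaled by ``1 - rr_SUVmax/100`` and the iso-radius by
    ``(1 - rr_MTV/100)^(1/3)``; relative thresholding then reproduces the
    targets up to noise.  Targets must leave the scaled 45% threshold above
    the background floor, otherwise the metabolic volume is no longer
    delineable and the target is infeasible.
    """
    rr_max = rr_targets.get("SUVmax", 0.0)
    rr_mtv = rr_targets.get("MTV", 0.0)
    if rr_max >= 100.0 or rr_mtv >= 100.0:
        raise InfeasibleResponseTargetError("intensity/volume reductions must stay below 100%")
    s = 1.0 - rr_max / 100.0
    k = (1.0 - rr_mtv / 100.0) ** (1.0 / 3.0)
    if s * spec.peak_suv * ZONE1_ISO_FRACTION <= spec.background_suv + 3.0 * spec.noise_sd:
        raise InfeasibleResponseTargetError(
            "scaled tumor sinks into the background; reduce the SUVmax target"
        )

    def _mtv_voxels(field, gland):
        ref = field[gland].max()
        return int((gland & (field >= ZONE1_ISO_FRACTION * ref)).sum())

    # correct the analytic radius scale for voxelization: match the
    # noiselessly delineated volume ratio to the target within half a voxel
    base_field, gland = _render(spec)
    target_ratio = 1.0 - rr_mtv / 100.0
    n1 = _mtv_voxels(base_field, gland)
    field, _ = _render(spec, peak_scale=s, radius_scale=k)
    for _ in range(3):
        ratio = _mtv_voxels(field, gland) / n1
        if abs(ratio - target_ratio) * n1 <= 0.5 or ratio <= 0:
            break
        k *= (target_ratio / ratio) ** (1.0 / 3.0)
        field, _ = _render(spec, peak_scale=s, radius_scale=k)
    seed = spec.noise_seed + 1 if noise_seed is None else noise_seed
    return _finish(field, spec, seed)


def _derived_rr(rr_max: float, rr_mtv: float) -> Dict[str, float]:
    # SUVmean tracks SUVmax (the profile shape is preserved); TL compounds.
    return {
        "SUVmax": rr_max,
        "SUVmean": rr_max,
        "MTV": rr_mtv,
        "TL": 100.0 * (1.0 - (1.0 - rr_max / 100.0) * (1.0 - rr_mtv / 100.0)),
    }


def make_cohort(config: SyntheticCohortConfig) -> Tuple[List[PatientRecord], Dict]:
    """Generate the paired cohort plus a manifest of the planted truth."""
    if config.n_patients < 6:
        raise CohortTooSmallError("screening needs at least 6 patients")
    root = np.random.SeedSequence(config.seed)
    group_seq, *patient_seqs = root.spawn(config.n_patients + 1)
    group_rng = np.random.default_rng(group_seq)
    is_responder = group_rng.random(config.n_patients) < config.responder_fraction

    center = tuple((n - 1) * s / 2.0 for n, s in zip(config.shape, config.spacing))
    tumor_center = tuple(c + o for c, o in zip(center, config.tumor_offset_mm))

    records: List[PatientRecord] = []
    for pid, (resp, seq) in enumerate(zip(is_responder, patient_seqs)):
        rng = np.random.default_rng(seq)
        eff = config.responders if resp else config.non_responders
        radius = eff.tumor_radius_mm * np.exp(rng.normal(0.0, config.radius_jitter_sd))
        radius = min(radius, 0.9 * min(config.prostate_semiaxes_mm))
        peak = config.peak_suv * np.exp(rng.normal(0.0, config.peak_jitter_sd))
        struct_seed, noise_seed = rng.integers(0, 2 ** 31 - 1, size=2)
        spec = PhantomSpec(
            shape=config.shape,
            spacing=config.spacing,
            prostate_center_mm=center,
            prostate_semiaxes_mm=config.prostate_semiaxes_mm,
            tumor_center_mm=tumor_center,
            peak_suv=float(peak),
            sigma_mm=float(sigma_for_radius(radius)),
            texture_amp=eff.texture_amp,
            blob_sigma_mm=config.blob_sigma_mm,
            background_suv=config.background_suv,
            ambient_suv=config.ambient_suv,
            rim_cool=eff.rim_cool,
            noise_sd=config.noise_sd_fraction * config.background_suv,
            structure_seed=int(struct_seed),
            noise_seed=int(noise_seed),
        )
        pet1, gland = make_phantom(spec)
        rr_max = float(rng.uniform(*eff.rr_suvmax_range))
        rr_mtv = float(rng.uniform(*eff.rr_mtv_range))
        true_rr = _derived_rr(rr_max, rr_mtv)
        pet2 = apply_response(spec, true_rr)
        records.append(
            PatientRecord(
                patient_id=pid,
                pet1=pet1,
                pet2=pet2,
                prostate_mask=gland,
                true_group="responder" if resp else "non_responder",
                true_rr=true_rr,
                spec=spec,
            )
        )

    null_cohort = config.responders == config.non_responders
    manifest = {
        "n_patients": config.n_patients,
        "seed": config.seed,
        "n_responders": int(is_responder.sum()),
        "planted_features": []
        if null_cohort
        else [
            {"feature": f, "zone": z, "direction": d} for f, z, d in PLANTED_FEATURES
        ],
    }
    return records, manifest


def make_sphere_lesion(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_mm: Tuple[float, float, float],
    radius_mm: float,
    peak_suv: float,
    background_suv: float = 0.5,
    lesion_class: str = "lymph_node",
    noise_sd: float = 0.05,
    seed: int = 0,
) -> Tuple[PETVolume, ROIMask]:
    """A plain hot sphere in its own volume, for multi-lesion aggregation tests."""
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r2 = (X - center_mm[0]) ** 2 + (Y - center_mm[1]) ** 2 + (Z - center_mm[2]) ** 2
    inside = r2 <= radius_mm ** 2
    field = np.where(inside, peak_suv, background_suv)
    rng = np.random.default_rng(seed)
    vol = PETVolume(
        np.clip(field + rng.normal(0, noise_sd, shape), 0, None), spacing, (0, 0, 0)
    )
    return vol, ROIMask(inside, spacing, (0, 0, 0), lesion_class=lesion_class)
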