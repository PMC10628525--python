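"""Synthetic longitudinal DCE cohort generator.

Produces fully synthetic subjects with the statistical structure the
analysis assumes: a roughly ellipsoidal enhancing tumor that shrinks and
de-enhances over BL -> C2 -> C4 (more strongly for responders), a
low-enhancement peritumoral shell, spatially correlated texture, additive
Gaussian noise, and simulated second-reader / repeat segmentations with
controlled boundary perturbation.  The whole cohort is a pure function of
its configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .core import NON_PCR, PCR, TIMEPOINTS, ImageVolume, RoiMask, SubjectRecord, TimepointData

#: Relative amplitude of the multiplicative texture field.
TEXTURE_REL_SD = 0.2
#: Enhancement of the peritumoral shell relative to the tumor core.
SHELL_REL_ENHANCEMENT = 0.2
#: Outward scale factor of the low-enhancement shell ellipsoid.
SHELL_SCALE = 1.5


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``decline_pcr`` / ``decline_nonpcr`` are per-time-point multiplicative
    enhancement factors (BL, C2, C4), each in [0, 1.5]; tumor radii shrink
    with the cube root of the same factor.
    """

    n_pcr: int = 10
    n_nonpcr: int = 10
    image_shape: Tuple[int, int, int] = (32, 32, 32)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range_mm: Tuple[float, float] = (6.0, 9.0)
    enhancement_bl: float = 100.0
    decline_pcr: Tuple[float, float, float] = (1.0, 0.5, 0.1)
    decline_nonpcr: Tuple[float, float, float] = (1.0, 0.9, 0.8)
    noise_sd: float = 2.0
    texture_corr_length_mm: float = 2.0
    reader_perturb_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pcr < 1 or self.n_nonpcr < 1:
            raise ValueError("n_pcr and n_nonpcr must both be >= 1")
        for name in ("decline_pcr", "decline_nonpcr"):
            factors = getattr(self, name)
            if len(factors) != 3 or any(not (0 <= f <= 1.5) for f in factors):
                raise ValueError(f"{name} must be 3 factors in [0, 1.5], got {factors}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        lo, hi = self.tumor_radius_range_mm
        if not (0 < lo <= hi):
            raise ValueError(f"invalid tumor_radius_range_mm {self.tumor_radius_range_mm}")

    def decline(self, response: str) -> Tuple[float, float, float]:
        return self.decline_pcr if response == PCR else self.decline_nonpcr


def _ellipsoid_mask(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_mm: np.ndarray,
    radii_mm: np.ndarray,
) -> np.ndarray:
    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    with np.errstate(divide="ignore"):
        r2 = (
            ((zz - center_mm[0]) / radii_mm[0]) ** 2
            + ((yy - center_mm[1]) / radii_mm[1]) ** 2
            + ((xx - center_mm[2]) / radii_mm[2]) ** 2
        )
    return r2 <= 1.0


def _texture_field(
    rng: np.random.Generator,
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    corr_length_mm: float,
) -> np.ndarray:
    """Unit-mean multiplicative texture: smoothed, standardized white noise."""
    noise = rng.standard_normal(shape)
    if corr_length_mm > 0:
        sigma = [corr_length_mm / s for s in spacing]
        noise = ndimage.gaussian_filter(noise, sigma=sigma)
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return np.clip(1.0 + TEXTURE_REL_SD * noise, 0.05, None)


def subject_seed_for(config_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from the cohort seed."""
    return int(np.random.SeedSequence((config_seed, index)).generate_state(1)[0])


def generate_subject(config: CohortConfig, response: str, subject_seed: int) -> SubjectRecord:
    """Generate one subject; deterministic given (config, response, seed)."""
    if response not in (PCR, NON_PCR):
        raise ValueError(f"unknown response label {response!r}")
    rng = np.random.default_rng(subject_seed)
    shape = tuple(config.image_shape)
    spacing = tuple(config.spacing_mm)
    extent_mm = np.array([(n - 1) * s for n, s in zip(shape, spacing)])

    base_radius = rng.uniform(*config.tumor_radius_range_mm)
    radii_bl = base_radius * rng.uniform(0.85, 1.15, size=3)
    for ax in range(3):
        if 2 * radii_bl[ax] >= extent_mm[ax]:
            raise ValueError(
                f"tumor diameter {2 * radii_bl[ax]:.1f} mm exceeds image extent "
                f"{extent_mm[ax]:.1f} mm along axis {ax}"
            )
    max_jitter = np.minimum(0.1 * extent_mm, (extent_mm - 2 * radii_bl) / 2 * 0.5)
    center_mm = extent_mm / 2 + rng.uniform(-1, 1, size=3) * max_jitter

    texture = _texture_field(rng, shape, spacing, config.texture_corr_length_mm)
    factors = config.decline(response)

    timepoints: Dict[str, TimepointData] = {}
    prev_effective: Optional[RoiMask] = None
    for tp, factor in zip(TIMEPOINTS, factors):
        if factor > 0:
            radii = radii_bl * factor ** (1.0 / 3.0)
            tumor = _ellipsoid_mask(shape, spacing, center_mm, radii)
            shell = _ellipsoid_mask(shape, spacing, center_mm, radii * SHELL_SCALE) & ~tumor
        else:
            tumor = np.zeros(shape, dtype=bool)
            shell = np.zeros(shape, dtype=bool)
        enh = config.enhancement_bl * factor
        data = np.zeros(shape)
        data[tumor] = enh * texture[tumor]
        data[shell] = SHELL_REL_ENHANCEMENT * enh * texture[shell]
        if config.noise_sd > 0:
            data = data + rng.normal(0.0, config.noise_sd, size=shape)

        volume = ImageVolume(data, spacing)
        tumor_mask = RoiMask(tumor)
        bed = prev_effective if tumor_mask.is_empty() else None
        td = TimepointData(volume, tumor_mask, bed_mask=bed)
        timepoints[tp] = td
        prev_effective = td.effective_mask()

    record = SubjectRecord(
        subject_id=f"S{subject_seed & 0xFFFFFFFF:08x}",
        response=response,
        timepoints=timepoints,
        meta={"radii_bl_mm": radii_bl.tolist(), "center_mm": center_mm.tolist()},
    )

    if config.reader_perturb_mm > 0:
        reader2: Dict[str, RoiMask] = {}
        repeat: Dict[str, RoiMask] = {}
        for k, tp in enumerate(TIMEPOINTS):
            eff = timepoints[tp].effective_mask()
            reader2[tp] = perturb_mask(
                eff, spacing, config.reader_perturb_mm, subject_seed + 1000 + k
            )
            repeat[tp] = perturb_mask(
                eff, spacing, config.reader_perturb_mm / 2.0, subject_seed + 2000 + k
            )
        record.reader2_masks = reader2
        record.reader1_repeat_masks = repeat
    return record


def generate_cohort(config: CohortConfig) -> List[SubjectRecord]:
    """Generate n_pcr + n_nonpcr subjects with deterministic per-subject seeds."""
    cohort: List[SubjectRecord] = []
    labels = [PCR] * config.n_pcr + [NON_PCR] * config.n_nonpcr
    for idx, label in enumerate(labels):
        rec = generate_subject(config, label, subject_seed_for(config.seed, idx))
        rec.subject_id = f"S{idx:04d}"
        cohort.append(rec)
    return cohort


def perturb_mask(
    mask: RoiMask,
    spacing: Tuple[float, float, float],
    magnitude_mm: float,
    seed: int,
) -> RoiMask:
    """Randomly jitter a mask boundary by at most ``magnitude_mm`` (physical).

    The symmetric difference with the input is confined to the shell of
    voxels within ``magnitude_mm`` of the input boundary (verified by
    distance transform).  Magnitude 0 returns the input unchanged; an empty
    input is returned unchanged with a warning.
    """
    if magnitude_mm < 0:
        raise ValueError("magnitude_mm must be >= 0")
    if mask.is_empty():
        warnings.warn("perturb_mask: empty input mask returned unchanged", stacklevel=2)
        return mask
    if magnitude_mm == 0:
        return mask

    spacing = tuple(float(s) for s in spacing)
    m = mask.data
    d_out = ndimage.distance_transform_edt(~m, sampling=spacing)
    d_in = ndimage.distance_transform_edt(m, sampling=spacing)
    signed = np.where(m, -d_in, d_out)  # < 0 inside, > 0 outside

    rng = np.random.default_rng(seed)
    field = rng.standard_normal(m.shape)
    field = ndimage.gaussian_filter(field, sigma=[2.0 * magnitude_mm / s for s in spacing])
    sd = field.std()
    if sd > 0:
        field = field / sd
    threshold = np.clip(magnitude_mm * field, -magnitude_mm, magnitude_mm)
    return RoiMask(signed <= threshold)
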