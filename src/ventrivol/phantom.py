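"""Synthetic cranial-ultrasound phantoms with ground-truth ventricle masks.

The phantoms emulate the features of neonatal transfontanellar 3D
ultrasound that the segmentation pipeline depends on: dark quasi-ellipsoidal
(optionally tortuous) lateral-ventricle cavities inside a brighter
speckle-textured parenchyma, a bright cranial shell, an exactly-zero
exterior (outside the acquisition footprint), an optional periventricular
cyst, and day-over-day cavity growth or post-drainage shrinkage mimicking
post-haemorrhagic ventricular dilatation.  They make no claim to acoustic
realism; what matters downstream is the contrast ordering
cavity < parenchyma < shell, the multiplicative speckle, and exact
knowledge of the true cavity volume.

Default geometry: a 64 x 96 x 96 grid at 0.5 mm isotropic pitch (desk
scale; same anatomy-to-grid proportions as clinical volumes) with two
mirrored bent-ellipsoid cavities of roughly 2.8 cm^3 each -- a clearly
dilated ventricular system.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .volume_io import BRAIN, VENTRICLE, LabelVolume, USVolume


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head volume.

    ``ventricle_axes_mm`` gives per-side ellipsoid semi-axes (sagittal,
    axial, coronal) in mm.  ``tortuosity`` bends each cavity centreline
    sinusoidally in the coronal direction; 0 gives plain ellipsoids.
    ``speckle_sigma`` is the log-scale of the multiplicative log-normal
    speckle; 0 disables noise entirely.
    """

    grid_dims: tuple[int, int, int] = (64, 96, 96)
    voxel_size_mm: float = 0.5
    # semi-axes chosen to leave growth headroom inside the brain ellipsoid,
    # so multi-day dilatation schedules are not distorted by clipping
    ventricle_axes_mm: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (5.0, 12.0, 7.0),
        (5.0, 12.0, 7.0),
    )
    tortuosity: float = 0.3
    cavity_intensity_mean: float = 30.0
    brain_intensity_mean: float = 120.0
    shell_intensity_mean: float = 220.0
    speckle_sigma: float = 0.05
    cyst: Optional[tuple[tuple[float, float, float], float]] = None  # (centre vox, r mm)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.cavity_intensity_mean < self.brain_intensity_mean
            < self.shell_intensity_mean <= 255
        ):
            raise ValueError("intensity means must satisfy cavity < brain < shell")
        if self.speckle_sigma < 0 or self.tortuosity < 0:
            raise ValueError("speckle_sigma and tortuosity must be >= 0")


@dataclass
class TrajectorySpec:
    """A temporal series of phantoms with multiplicative volume growth.

    ``growth_per_day`` multiplies each side's cavity volume per day; after
    ``intervention_day`` (CSF drainage) it is replaced by ``shrink_per_day``.
    """

    base: PhantomSpec = field(default_factory=PhantomSpec)
    n_days: int = 5
    growth_per_day: float = 1.1
    intervention_day: Optional[int] = None
    shrink_per_day: float = 0.8

    def __post_init__(self) -> None:
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.growth_per_day <= 0 or self.shrink_per_day <= 0:
            raise ValueError("volume factors must be > 0")
        if self.intervention_day is not None and not (
            0 <= self.intervention_day < self.n_days
        ):
            raise ValueError("intervention_day must lie inside the series")


def _head_masks(spec: PhantomSpec):
    """Return boolean (brain_interior, shell, cavity_left, cavity_right, cyst)."""
    ns, na, nc = spec.grid_dims
    s, a, c = np.meshgrid(
        np.arange(ns), np.arange(na), np.arange(nc), indexing="ij"
    )
    cs, ca, cc = (ns - 1) / 2, (na - 1) / 2, (nc - 1) / 2
    # outer skull ellipsoid and inner brain ellipsoid (shell thickness ~8%)
    outer = (
        ((s - cs) / (0.48 * ns)) ** 2
        + ((a - ca) / (0.48 * na)) ** 2
        + ((c - cc) / (0.48 * nc)) ** 2
    ) <= 1.0
    inner = (
        ((s - cs) / (0.40 * ns)) ** 2
        + ((a - ca) / (0.40 * na)) ** 2
        + ((c - cc) / (0.40 * nc)) ** 2
    ) <= 1.0
    shell = outer & ~inner

    cavities = []
    vox = spec.voxel_size_mm
    for side, axes in zip((-1, +1), spec.ventricle_axes_mm):
        rs, ra, rc = (ax / vox for ax in axes)  # semi-axes in voxels
        # cavity centre offset laterally from the mid-sagittal plane
        c0s = cs + side * max(rs + 2.0, 0.14 * ns)
        c0a, c0c = ca, cc
        # sinusoidal coronal bend along the axial (long) direction
        bend = spec.tortuosity * rc * np.sin(np.pi * (a - c0a) / (2.0 * ra))
        cav = (
            ((s - c0s) / rs) ** 2
            + ((a - c0a) / ra) ** 2
            + ((c - c0c - bend) / rc) ** 2
        ) <= 1.0
        clipped = cav & inner
        if cav.sum() and (cav.sum() - clipped.sum()) / cav.sum() > 0.02:
            import warnings

            warnings.warn(
                "cavity clipped by the brain ellipsoid by more than 2%: "
                "volume schedules will be distorted"
            )
        cavities.append(clipped)

    cyst = np.zeros_like(inner)
    if spec.cyst is not None:
        (ks, ka, kc), r_mm = spec.cyst
        r = r_mm / vox
        cyst = (((s - ks) ** 2 + (a - ka) ** 2 + (c - kc) ** 2) <= r**2) & inner

    for cav in cavities:
        if cav.any() and not (cav <= inner).all():  # pragma: no cover
            raise ValueError("cavity extends outside the brain")
    return inner, shell, cavities[0], cavities[1], cyst


def generate_phantom(spec: PhantomSpec) -> tuple[USVolume, LabelVolume]:
    """Generate one phantom volume and its exact 3-class label.

    Deterministic for a fixed ``spec.seed``.  The label marks cavity and
    cyst voxels as ventricle, everything else inside the outer shell as
    brain, and the exterior as background.  True per-side volumes in cm^3
    (voxel count x voxel volume) are stored in ``label.meta``.
    """
    inner, shell, cav_l, cav_r, cyst = _head_masks(spec)
    if not cav_l.any() or not cav_r.any():
        raise ValueError("cavity empty: axes too small for the grid")

    intens = np.zeros(spec.grid_dims, dtype=np.float64)
    intens[inner] = spec.brain_intensity_mean
    intens[shell] = spec.shell_intensity_mean
    ventricle = cav_l | cav_r | cyst
    intens[ventricle] = spec.cavity_intensity_mean

    if spec.speckle_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.lognormal(
            mean=-spec.speckle_sigma**2 / 2.0,
            sigma=spec.speckle_sigma,
            size=spec.grid_dims,
        )
        intens *= noise
    voxels = np.clip(np.round(intens), 0, 255).astype(np.uint8)
    # interior voxels must stay non-zero so "exactly black" stays exterior-only
    interior = inner | shell
    voxels[interior & (voxels == 0)] = 1

    labels = np.zeros(spec.grid_dims, dtype=np.uint8)
    labels[interior] = BRAIN
    labels[ventricle] = VENTRICLE

    vv = spec.voxel_size_mm**3 / 1000.0
    meta = {
        "true_volume_cm3": {
            "left": float(cav_l.sum() * vv),
            "right": float(cav_r.sum() * vv),
            "total": float(ventricle.sum() * vv),
        },
        "spec_seed": spec.seed,
    }
    vol = USVolume(voxels=voxels, voxel_size_mm=spec.voxel_size_mm)
    lab = LabelVolume(labels=labels, voxel_size_mm=spec.voxel_size_mm, meta=meta)
    return vol, lab


def generate_trajectory(spec: TrajectorySpec) -> list[tuple[USVolume, LabelVolume]]:
    """Generate a temporal series following the multiplicative schedule.

    Day ``d`` scales each side's target volume by the cumulative product of
    the daily factors (growth before the intervention, shrinkage after);
    ellipsoid semi-axes scale by the cube root of the volume factor.
    """
    out = []
    factor = 1.0
    for day in range(spec.n_days):
        if day > 0:
            if spec.intervention_day is not None and day > spec.intervention_day:
                factor *= spec.shrink_per_day
            else:
                factor *= spec.growth_per_day
        lin = factor ** (1.0 / 3.0)
        axes = tuple(
            tuple(ax * lin for ax in side) for side in spec.base.ventricle_axes_mm
        )
        day_spec = replace(
            spec.base, ventricle_axes_mm=axes, seed=spec.base.seed + day
        )
        vol, lab = generate_phantom(day_spec)
        vol.acquisition_index = day
        lab.acquisition_index = day
        lab.meta["schedule_factor"] = factor
        out.append((vol, lab))
    return out


def degrade_wall(
    volume: USVolume,
    label: LabelVolume,
    fraction: float,
    seed: int = 0,
    brain_mean: float = 120.0,
) -> USVolume:
    """Blur a fraction of the cavity wall up to parenchymal intensity.

    Picks a random ``fraction`` of the cavity boundary voxels (cavity voxels
    with at least one 6-neighbour outside the cavity) and raises their
    intensity to ``brain_mean``, emulating ill-defined ventricular walls
    that defeat intensity thresholding.  Labels are left untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    mask = label.ventricle_mask()
    from scipy import ndimage

    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(3, 1))
    boundary = np.argwhere(mask & ~eroded)
    voxels = volume.voxels.copy()
    if fraction > 0 and len(boundary):
        rng = np.random.default_rng(seed)
        n = int(round(fraction * len(boundary)))
        pick = boundary[rng.choice(len(boundary), size=n, replace=False)]
        voxels[pick[:, 0], pick[:, 1], pick[:, 2]] = np.uint8(
            np.clip(round(brain_mean), 0, 255)
        )
    return USVolume(
        voxels=voxels,
        voxel_size_mm=volume.voxel_size_mm,
        patient_id=volume.patient_id,
        acquisition_index=volume.acquisition_index,
    )


def auto_roi(label: LabelVolume, margin: int = 2):
    """Sagittal ROI spanning the true cavities plus a margin (half-open).

    Stands in for the narrow rectangular regions of interest that are drawn
    manually on a coronal view of clinical volumes.
    """
    from .dataset import SagittalROI

    idx = np.where(label.ventricle_mask().any(axis=(1, 2)))[0]
    if len(idx) == 0:
        raise ValueError("label contains no ventricle voxels")
    first = max(0, int(idx[0]) - margin)
    last = min(label.shape[0], int(idx[-1]) + 1 + margin)
    return SagittalROI(first=first, last=last)
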