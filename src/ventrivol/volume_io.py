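"""Volumetric I/O and grid primitives.

Cranial 3D ultrasound volumes are stored as NRRD files holding an 8-bit
intensity grid with isotropic voxel spacing.  This module fixes the axis
convention used throughout the package and provides the slicing, padding
and median-filtering primitives every downstream stage builds on.

Axis convention
---------------
axis 0 : sagittal index (left -> right)
axis 1 : axial (superior -> inferior) -- rows of a sagittal slice
axis 2 : coronal (anterior -> posterior) -- columns of a sagittal slice

All indexing is 0-based.  A sagittal slice extracted at index ``s`` is a
2D array of shape ``(axial extent, coronal extent)``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import SimpleITK as sitk
from scipy import ndimage
from skimage.transform import resize as _sk_resize

log = logging.getLogger(__name__)

#: Canvas size of the network input, pixels (height, width).
CANVAS: tuple[int, int] = (200, 200)

#: Metadata key carried by label NRRDs.
LABEL_MAP_KEY = "label_map"
LABEL_MAP_VALUE = "0:background,1:brain,2:ventricle"

# Integer class codes for the 3-class semantic labelling.
BACKGROUND, BRAIN, VENTRICLE = 0, 1, 2


class VolumeFormatError(ValueError):
    """Raised when an NRRD file violates the expected conventions."""


@dataclass
class USVolume:
    """A 3D ultrasound intensity grid with calibrated isotropic voxels.

    Parameters
    ----------
    voxels : ndarray, uint8, shape (S, A, C)
        Intensity grid in [0, 255] following the package axis convention.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    patient_id : str
        Opaque identifier.
    acquisition_index : int
        Ordinal position within a temporal series (day index).
    """

    voxels: np.ndarray
    voxel_size_mm: float
    patient_id: str = ""
    acquisition_index: int = 0
    axis_order: str = "sagittal-axial-coronal"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3D grid, got {self.voxels.ndim} dimensions"
            )
        if min(self.voxels.shape) < 8:
            raise VolumeFormatError(
                f"all dimensions must be >= 8, got {self.voxels.shape}"
            )
        if not self.voxel_size_mm > 0:
            raise VolumeFormatError("voxel_size_mm must be positive")
        if self.voxels.min() < 0 or self.voxels.max() > 255:
            raise VolumeFormatError("intensities must lie in [0, 255]")
        self.voxels = self.voxels.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of a single voxel in cm^3."""
        return self.voxel_size_mm**3 / 1000.0


@dataclass
class LabelVolume:
    """A 3-class semantic label grid aligned with a :class:`USVolume`.

    Values are 0 (background), 1 (brain / non-ventricle), 2 (ventricle).
    Binary ventricle masks are stored with values {0, 2} so the ventricle
    code is stable across binary and 3-class uses; :meth:`ventricle_mask`
    is the canonical boolean accessor.
    """

    labels: np.ndarray
    voxel_size_mm: float
    patient_id: str = ""
    acquisition_index: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise VolumeFormatError("label grid must be 3D")
        bad = set(np.unique(self.labels)) - {0, 1, 2}
        if bad:
            raise VolumeFormatError(f"label values outside {{0,1,2}}: {sorted(bad)}")
        self.labels = self.labels.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def ventricle_mask(self) -> np.ndarray:
        return self.labels == VENTRICLE


@dataclass
class PadInfo:
    """Geometry needed to invert the resize-and-pad preprocessing."""

    pad_offsets: tuple[int, int]  # (top, left) on the canvas
    scale_factor: float  # original_size / resized_size, 1.0 if no resize
    original_shape: tuple[int, int]


@dataclass
class SliceStack:
    """An ordered stack of 2D sagittal images from one volume."""

    slices: list[np.ndarray]
    origin_volume: Optional[USVolume] = None
    pad_info: Optional[PadInfo] = None

    def __len__(self) -> int:
        return len(self.slices)


def read_nrrd(path: str | os.PathLike) -> USVolume:
    """Read a 3D NRRD file into a :class:`USVolume`.

    Spacing must be isotropic to within 1% relative tolerance.  Intensities
    stored outside [0, 255] (e.g. float or 16-bit data) are min-max rescaled
    to [0, 255] and the rescale is logged.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - message from ITK
        raise VolumeFormatError(f"malformed NRRD header: {exc}") from exc
    if img.GetDimension() != 3:
        raise VolumeFormatError(
            f"field 'dimension': expected 3, got {img.GetDimension()}"
        )
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    if np.any(spacing <= 0):
        raise VolumeFormatError(f"field 'spacings': non-positive spacing {spacing}")
    if (spacing.max() - spacing.min()) / spacing.min() > 0.01:
        raise VolumeFormatError(
            f"field 'spacings': anisotropic spacing {tuple(spacing)} "
            "(relative tolerance 1%)"
        )
    arr = sitk.GetArrayFromImage(img)
    if arr.dtype != np.uint8:
        lo, hi = float(arr.min()), float(arr.max())
        if lo < 0 or hi > 255:
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            arr = np.round((arr.astype(np.float64) - lo) * scale)
            log.info("rescaled intensities from [%g, %g] to [0, 255]", lo, hi)
        arr = arr.astype(np.uint8)
    return USVolume(voxels=arr, voxel_size_mm=float(spacing[0]))


def read_label_nrrd(path: str | os.PathLike) -> LabelVolume:
    """Read a 3-class label NRRD (values restricted to {0, 1, 2})."""
    vol = _read_raw(path)
    arr, spacing = vol
    return LabelVolume(labels=arr, voxel_size_mm=spacing)


def _read_raw(path) -> tuple[np.ndarray, float]:
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise VolumeFormatError("field 'dimension': expected 3")
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    return sitk.GetArrayFromImage(img), float(spacing[0])


def write_nrrd(volume: USVolume | LabelVolume, path: str | os.PathLike) -> str:
    """Write a volume (or label volume) to NRRD; round-trips exactly."""
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"directory does not exist: {parent}")
    if isinstance(volume, LabelVolume):
        arr = volume.labels
    else:
        arr = volume.voxels
    img = sitk.GetImageFromArray(arr.astype(np.uint8))
    s = float(volume.voxel_size_mm)
    img.SetSpacing((s, s, s))
    if isinstance(volume, LabelVolume):
        img.SetMetaData(LABEL_MAP_KEY, LABEL_MAP_VALUE)
    sitk.WriteImage(img, str(path), useCompression=False)
    return str(path)


def extract_sagittal(volume: USVolume, index: int) -> np.ndarray:
    """Return the sagittal slice at ``index`` as a read-only 2D view."""
    extent = volume.voxels.shape[0]
    if not 0 <= index < extent:
        raise IndexError(f"sagittal index {index} out of range [0, {extent})")
    view = volume.voxels[index]
    view.flags.writeable = False
    return view


def pad_to_canvas(
    image: np.ndarray, canvas: tuple[int, int] = CANVAS, *, is_label: bool = False
) -> tuple[np.ndarray, PadInfo]:
    """Centre ``image`` on a zero-valued canvas, downscaling if oversized.

    Images larger than the canvas in either dimension are first uniformly
    downscaled by ``max(H, W) / canvas`` (linear interpolation for
    intensities, nearest-neighbour for labels) and the factor recorded in
    :class:`PadInfo` so the operation is invertible by :func:`unpad`.
    Centring splits any odd border difference with the extra pixel on the
    bottom/right.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    ch, cw = canvas
    scale = 1.0
    resized = image
    if h > ch or w > cw:
        scale = max(h / ch, w / cw)
        new_h, new_w = int(round(h / scale)), int(round(w / scale))
        resized = _resize2d(image, (new_h, new_w), is_label=is_label)
        h, w = new_h, new_w
    top = (ch - h) // 2
    left = (cw - w) // 2
    out_shape = (ch, cw) + image.shape[2:]
    out = np.zeros(out_shape, dtype=image.dtype)
    out[top : top + h, left : left + w] = resized
    return out, PadInfo((top, left), scale, image.shape[:2])


def unpad(padded: np.ndarray, info: PadInfo, *, is_label: bool = False) -> np.ndarray:
    """Invert :func:`pad_to_canvas` exactly (up to resize interpolation)."""
    oh, ow = info.original_shape
    if info.scale_factor == 1.0:
        top, left = info.pad_offsets
        return padded[top : top + oh, left : left + ow].copy()
    rh = int(round(oh / info.scale_factor))
    rw = int(round(ow / info.scale_factor))
    top, left = info.pad_offsets
    crop = padded[top : top + rh, left : left + rw]
    return _resize2d(crop, (oh, ow), is_label=is_label)


def _resize2d(image: np.ndarray, shape: tuple[int, int], *, is_label: bool):
    order = 0 if is_label else 1
    out = _sk_resize(
        image.astype(float),
        shape + image.shape[2:],
        order=order,
        preserve_range=True,
        anti_aliasing=False,
    )
    if is_label:
        return out.astype(image.dtype)
    return np.round(out).astype(image.dtype) if image.dtype.kind in "ui" else out


def median_filter_stack(stack: SliceStack) -> SliceStack:
    """Apply a [1, 3, 3] median filter: per-slice 3x3 spatial median.

    Kernel depth 1 means no cross-slice mixing.  Borders are handled by
    edge replication so exactly-zero padding borders stay exactly zero.
    """
    if len(stack.slices) < 1:
        raise ValueError("stack must contain at least one slice")
    filtered = [
        ndimage.median_filter(s, size=(3, 3), mode="nearest") for s in stack.slices
    ]
    return SliceStack(filtered, stack.origin_volume, stack.pad_info)


def median_filter_image(image: np.ndarray) -> np.ndarray:
    """3x3 spatial median of a single 2D (or per-channel 2D+C) image."""
    if image.ndim == 2:
        return ndimage.median_filter(image, size=(3, 3), mode="nearest")
    return np.stack(
        [
            ndimage.median_filter(image[..., c], size=(3, 3), mode="nearest")
            for c in range(image.shape[-1])
        ],
        axis=-1,
    )


def median_filter_3d(volume: USVolume, kernel: int = 3) -> USVolume:
    """Full 3D median filter with an odd cubic kernel (edge replication)."""
    if kernel % 2 == 0 or kernel < 3:
        raise ValueError(f"kernel must be odd and >= 3, got {kernel}")
    out = ndimage.median_filter(volume.voxels, size=kernel, mode="nearest")
    return USVolume(
        voxels=out,
        voxel_size_mm=volume.voxel_size_mm,
        patient_id=volume.patient_id,
        acquisition_index=volume.acquisition_index,
    )
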