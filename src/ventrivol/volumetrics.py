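"""3D reconstruction of per-slice segmentations and voxel-counting volumetry.

Per-slice class maps are mapped back to native slice geometry (inverting
the resize-and-pad preprocessing), stacked into a binary 3D volume, split
into 26-connected blobs, and each blob's volume is the voxel count times
the calibrated voxel volume.  Left/right assignment uses the blob
centroid's position relative to the mid-sagittal plane; blobs that
straddle the midline are split by the plane into per-side contributions.
Agreement between two binary volumes is quantified with the 3D Dice
similarity coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .dataset import SagittalROI, SliceLabel, ThickSlice, build_thick_slices
from .volume_io import VENTRICLE, LabelVolume, USVolume, unpad

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class VentricleMeasurement:
    """One (patient, day, side, method) -> volume record."""

    patient_id: str
    acquisition_index: int
    side: str  # "left" | "right" | "total"
    method: str  # "manual" | "auto"
    volume_cm3: float

    def __post_init__(self):
        if self.volume_cm3 < 0:
            raise ValueError("volume_cm3 must be >= 0")
        if self.side not in ("left", "right", "total"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class SegmentationMetrics:
    iou_2d_mean: float
    dsc_3d: float
    n_intersection: int
    n_a: int
    n_b: int


def stack_predictions(
    slices: Sequence[SliceLabel], origin: USVolume, roi: SagittalROI
) -> LabelVolume:
    """Stack per-slice ventricle maps into a binary volume on the origin grid.

    Each slice label is cropped/rescaled back to native sagittal-slice
    geometry using its recorded pad offsets and scale factor, then placed
    at its sagittal index; indices outside the ROI stay zero.
    """
    if len(slices) != len(roi.indices()):
        raise ValueError(
            f"{len(slices)} slices do not cover ROI of {len(roi.indices())} indices"
        )
    out = np.zeros(origin.shape, dtype=np.uint8)
    for sl, s in zip(slices, roi.indices()):
        if sl.pad_info is None:
            raise ValueError(f"slice at index {s} lacks pad/scale metadata")
        native = unpad(sl.pixels, sl.pad_info, is_label=True)
        if native.shape != origin.shape[1:]:
            raise ValueError(
                f"inverted slice shape {native.shape} does not match grid "
                f"{origin.shape[1:]}"
            )
        out[s][native == VENTRICLE] = VENTRICLE
    return LabelVolume(
        labels=out,
        voxel_size_mm=origin.voxel_size_mm,
        patient_id=origin.patient_id,
        acquisition_index=origin.acquisition_index,
    )


def measure_volumes(
    binary: LabelVolume,
    voxel_size_mm: float | None = None,
    method: str = "auto",
    midline: Optional[float] = None,
) -> list[VentricleMeasurement]:
    """Per-side and total ventricular volumes by blob voxel counting.

    Volume of each 26-connected blob = voxel count x voxel_size_mm^3 / 1000
    (cm^3).  A blob belongs to the side of its centroid relative to the
    mid-sagittal plane; straddling blobs are split by the plane and
    contribute to both sides.  Always returns left, right and total
    records (zero volume on empty input).
    """
    vs = voxel_size_mm if voxel_size_mm is not None else binary.voxel_size_mm
    values = set(np.unique(binary.labels))
    # a {0,1} binary mask is foreground=1; otherwise use the ventricle class
    mask = binary.labels > 0 if values <= {0, 1} else binary.ventricle_mask()
    mid = midline if midline is not None else binary.shape[0] / 2.0
    vv = vs**3 / 1000.0
    lab, n = ndimage.label(mask, structure=_STRUCT_26)
    left = right = 0.0
    for i in range(1, n + 1):
        coords_s = np.nonzero(lab == i)[0]
        lo, hi = coords_s.min(), coords_s.max()
        if hi < mid:  # wholly on the left of the plane
            left += len(coords_s) * vv
        elif lo >= mid:
            right += len(coords_s) * vv
        else:  # straddles the midline: split by the plane
            left += int((coords_s < mid).sum()) * vv
            right += int((coords_s >= mid).sum()) * vv
    total = float(mask.sum()) * vv
    mk = lambda side, v: VentricleMeasurement(
        binary.patient_id, binary.acquisition_index, side, method, v
    )
    return [mk("left", left), mk("right", right), mk("total", total)]


def dsc_3d(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray) -> float:
    """3D Dice coefficient 2|A&B| / (|A|+|B|); both-empty -> 1.0."""
    ma = a.ventricle_mask() if isinstance(a, LabelVolume) else np.asarray(a, bool)
    mb = b.ventricle_mask() if isinstance(b, LabelVolume) else np.asarray(b, bool)
    if ma.shape != mb.shape:
        raise ValueError(f"shape mismatch {ma.shape} vs {mb.shape}")
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def iou_3d(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray) -> float:
    """3D Jaccard index |A&B| / |A|B|; both-empty -> 1.0."""
    ma = a.ventricle_mask() if isinstance(a, LabelVolume) else np.asarray(a, bool)
    mb = b.ventricle_mask() if isinstance(b, LabelVolume) else np.asarray(b, bool)
    union = int((ma | mb).sum())
    if union == 0:
        return 1.0
    return int((ma & mb).sum()) / union


def dsc_from_iou(iou: float) -> float:
    """Convert a Jaccard index to a Dice coefficient: 2*IoU / (1 + IoU)."""
    if not 0.0 <= iou <= 1.0:
        raise ValueError(f"IoU must lie in [0, 1], got {iou}")
    return 2.0 * iou / (1.0 + iou)


def segment_volume(
    model,
    volume: USVolume,
    roi: SagittalROI,
    reference: Optional[LabelVolume] = None,
) -> tuple[LabelVolume, list[VentricleMeasurement], Optional[SegmentationMetrics]]:
    """Full inference path: thick slices -> per-slice prediction -> 3D volume.

    Returns the reconstructed binary label volume, the per-side volume
    measurements, and overlap metrics against ``reference`` when given.
    """
    thick = build_thick_slices(volume, roi)
    preds = model.predict_batch(thick)
    seg = stack_predictions(preds, volume, roi)
    measurements = measure_volumes(seg, method="auto")
    metrics = None
    if reference is not None:
        from .model import evaluate_slices  # local import to avoid cycle

        dsc = dsc_3d(seg, reference)
        ious = []
        ref_mask = reference.ventricle_mask()
        for pred, s in zip(preds, roi.indices()):
            a = unpad(pred.pixels, pred.pad_info, is_label=True) == VENTRICLE
            b = ref_mask[s]
            if not a.any() and not b.any():
                continue
            ious.append(int((a & b).sum()) / int((a | b).sum()))
        metrics = SegmentationMetrics(
            iou_2d_mean=float(np.mean(ious)) if ious else float("nan"),
            dsc_3d=dsc,
            n_intersection=int((seg.ventricle_mask() & ref_mask).sum()),
            n_a=int(seg.ventricle_mask().sum()),
            n_b=int(ref_mask.sum()),
        )
    return seg, measurements, metrics
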