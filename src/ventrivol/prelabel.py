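"""Semi-automatic threshold-based pre-labelling of the ventricles.

Bootstraps ground truth in three steps: (1) 3D median filtering for noise
reduction; (2) an iterative global threshold scan over the volume
histogram, segmenting dark (CSF-filled) voxels and classifying the
resulting 26-connected blobs by geometric criteria at every step;
(3) keeping the largest threshold before the accepted dark region "leaks"
into the parenchyma.  On volumes with ill-defined ventricular walls the
recovered volume is systematically an underestimate -- the method is a
starting proposal, not a final segmentation.

Exactly-zero voxels lie outside the acquisition footprint and are never
candidates; they belong to the background class by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import BACKGROUND, BRAIN, VENTRICLE, LabelVolume, USVolume, median_filter_3d

log = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BlobCriteria:
    """Geometric acceptance criteria for candidate ventricle blobs.

    min/max volume in cm^3; ``max_elongation`` bounds the ratio of largest
    to smallest principal extent; ``max_centrality`` bounds the distance of
    a blob centroid from the volume centre as a fraction of the grid
    half-diagonal.
    """

    min_volume_cm3: float = 0.5
    max_volume_cm3: float = 80.0
    max_elongation: float = 15.0
    max_centrality: float = 0.6

    def __post_init__(self) -> None:
        if not 0 < self.min_volume_cm3 < self.max_volume_cm3:
            raise ValueError("need 0 < min_volume_cm3 < max_volume_cm3")
        if self.max_elongation <= 0 or self.max_centrality <= 0:
            raise ValueError("bounds must be positive")


@dataclass
class PrelabelResult:
    """Outcome of the iterative threshold search."""

    threshold: int
    label: LabelVolume
    empty: bool  # no blob ever passed the criteria


def _blob_properties(coords: np.ndarray, voxel_size_mm: float, centre: np.ndarray,
                     half_diag: float) -> tuple[float, float, float]:
    """(volume cm3, elongation, centrality) of a blob from voxel coords."""
    volume = len(coords) * voxel_size_mm**3 / 1000.0
    centroid = coords.mean(axis=0)
    centrality = float(np.linalg.norm(centroid - centre) / half_diag)
    centred = coords - centroid
    if len(coords) == 1:
        return volume, 1.0, centrality
    # principal extents: span of coordinates projected on covariance axes
    cov = np.cov(centred.T)
    _, vecs = np.linalg.eigh(cov)
    proj = centred @ vecs
    extents = proj.max(axis=0) - proj.min(axis=0) + 1.0  # +1 voxel width
    elongation = float(extents.max() / extents.min())
    return volume, elongation, centrality


def classify_blobs(
    label: LabelVolume, criteria: BlobCriteria, voxel_size_mm: float | None = None
) -> LabelVolume:
    """Keep only 26-connected components passing every criterion.

    Input is treated as a binary ventricle mask; rejected components are
    zeroed.  Properties are computed from voxel coordinates and the
    calibrated voxel size.
    """
    vs = voxel_size_mm if voxel_size_mm is not None else label.voxel_size_mm
    values = set(np.unique(label.labels))
    # a {0,1} binary mask is foreground=1; otherwise use the ventricle class
    mask = label.labels > 0 if values <= {0, 1} else label.ventricle_mask()
    kept = _classify_mask(mask, criteria, vs, label.shape)
    out = np.where(kept, VENTRICLE, 0).astype(np.uint8)
    return LabelVolume(
        labels=out,
        voxel_size_mm=vs,
        patient_id=label.patient_id,
        acquisition_index=label.acquisition_index,
    )


def _classify_mask(
    mask: np.ndarray, criteria: BlobCriteria, voxel_size_mm: float, shape
) -> np.ndarray:
    """Boolean mask of voxels in accepted blobs."""
    lab, n = ndimage.label(mask, structure=_STRUCT_26)
    if n == 0:
        return np.zeros(shape, dtype=bool)
    centre = (np.asarray(shape) - 1) / 2.0
    half_diag = float(np.linalg.norm(centre))
    kept = np.zeros(shape, dtype=bool)
    objects = ndimage.find_objects(lab)
    for i, sl in enumerate(objects, start=1):
        sub = lab[sl] == i
        coords = np.argwhere(sub) + np.array([s.start for s in sl])
        vol, elong, cent = _blob_properties(
            coords.astype(float), voxel_size_mm, centre, half_diag
        )
        if (
            criteria.min_volume_cm3 <= vol <= criteria.max_volume_cm3
            and elong <= criteria.max_elongation
            and cent <= criteria.max_centrality
        ):
            kept[sl] |= sub
    return kept


def iterative_threshold(
    volume: USVolume,
    criteria: BlobCriteria | None = None,
    leak_factor: float = 2.0,
    plateau_tol: float = 1.005,
    min_plateau: int = 5,
    _filtered_hint: bool = True,
) -> PrelabelResult:
    """Search the intensity histogram for the best dark-region threshold.

    Scans every integer threshold ``t`` in ascending order; at each step
    the candidate set is ``0 < v < t`` (strictly positive, so the exterior
    never participates), its 26-connected blobs are classified by
    ``criteria``, and the accepted voxel count is tracked.  Steps where
    the candidate histogram count does not change are skipped (identical
    candidate set).

    Stopping rule.  The accepted-count curve has a characteristic shape:
    a fill-in ramp while the cavity submerges, a long plateau once it is
    complete, then a growth resumption when the dark region leaks into
    the parenchyma.  A step is *quiescent* when the accepted count grew
    by at most ``plateau_tol`` since the previous distinct step (the
    first accepted step counts as quiescent); a *leak* is declared when
    the count exceeds ``leak_factor`` times the count at the latest
    quiescent step.  The result is the threshold and label of that
    quiescent step -- the top of the plateau just before the leak.  On
    noise-free two-mode volumes the leak is a single abrupt jump and the
    rule degenerates to "largest step before the jump".

    Two guards reject non-segmentations: the scan only runs up to the
    maximum intensity present (a constant volume has no sub-threshold
    voxels at any candidate threshold), and a quiescent reference that
    survived fewer than ``min_plateau`` integer thresholds before the
    leak is treated as a transient percolation artefact (pure noise),
    not a cavity.  ``empty=True`` if no stable blob is ever found.
    """
    criteria = criteria or BlobCriteria()
    if not _filtered_hint:
        log.warning("iterative_threshold called on an unfiltered volume")
    v = volume.voxels
    vs = volume.voxel_size_mm
    shape = v.shape
    hist = np.bincount(v.ravel(), minlength=256)

    prev_count = 0
    ref_count = 0  # accepted count at the latest quiescent step
    ref_mask = None
    ref_t = 0
    cum = 0  # candidate voxels strictly below t, excluding exact zeros
    last_cum = -1
    for t in range(1, int(v.max()) + 1):
        cum += int(hist[t - 1]) if t - 1 > 0 else 0
        if cum == last_cum:
            continue  # histogram unchanged: identical candidate set
        last_cum = cum
        if cum == 0:
            continue
        cand = (v > 0) & (v < t)
        kept = _classify_mask(cand, criteria, vs, shape)
        count = int(kept.sum())
        if count == 0:
            continue
        if ref_count > 0 and count > leak_factor * ref_count:
            if t - ref_t < min_plateau:  # transient blob, not a cavity
                ref_count, ref_mask = 0, None
                prev_count = count
                continue
            return _result(ref_t, ref_mask, volume, empty=False)
        if prev_count == 0 or count <= plateau_tol * prev_count:
            ref_count, ref_mask, ref_t = count, kept, t
        prev_count = count
    # a "cavity" covering most of the imaged volume is a flood, not a
    # segmentation: the ventricles are a dark minority region
    n_positive = int((v > 0).sum())
    if ref_mask is not None and ref_count > 0.5 * n_positive:
        ref_mask = None
    if ref_mask is None:
        empty_label = LabelVolume(
            labels=np.zeros(shape, dtype=np.uint8), voxel_size_mm=vs,
            patient_id=volume.patient_id, acquisition_index=volume.acquisition_index,
        )
        return PrelabelResult(threshold=0, label=empty_label, empty=True)
    return _result(ref_t, ref_mask, volume, empty=False)


def _result(t, mask, volume, empty) -> PrelabelResult:
    lab = LabelVolume(
        labels=np.where(mask, VENTRICLE, 0).astype(np.uint8),
        voxel_size_mm=volume.voxel_size_mm,
        patient_id=volume.patient_id,
        acquisition_index=volume.acquisition_index,
    )
    return PrelabelResult(threshold=t, label=lab, empty=empty)


def prelabel_volume(
    volume: USVolume,
    criteria: BlobCriteria | None = None,
    kernel: int = 3,
    leak_factor: float = 2.0,
) -> PrelabelResult:
    """Full pre-labelling pipeline: median filter, threshold scan, 3-class map.

    The returned label partitions the grid: background where the *input*
    volume is exactly zero, ventricle on accepted blobs, brain elsewhere
    (ventricle assignment wins on conflicts).
    """
    filtered = median_filter_3d(volume, kernel=kernel)
    res = iterative_threshold(filtered, criteria, leak_factor=leak_factor)
    three = np.full(volume.shape, BRAIN, dtype=np.uint8)
    three[volume.voxels == 0] = BACKGROUND
    three[res.label.ventricle_mask()] = VENTRICLE
    label = LabelVolume(
        labels=three,
        voxel_size_mm=volume.voxel_size_mm,
        patient_id=volume.patient_id,
        acquisition_index=volume.acquisition_index,
        meta={"threshold": res.threshold, "empty": res.empty},
    )
    return PrelabelResult(threshold=res.threshold, label=label, empty=res.empty)
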