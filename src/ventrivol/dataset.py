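"""2.5D training-corpus construction.

A 2D network segments a 3D volume one sagittal plane at a time; to give it
limited volumetric context each training image is a *thickened slice*: a
3-channel 200x200 image whose channels R/G/B hold the sagittal slices
s-1, s, s+1.  Labels for a thickened slice are the pixelwise OR of the
three corresponding ventricle masks, then rebalanced into three classes:
ventricle, background (pixels that are exactly black -- the zero padding
and the exterior of the acquisition footprint), and brain (everything
else).  Class imbalance is countered with median-frequency weighting of
the cross-entropy loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import (
    BACKGROUND,
    BRAIN,
    CANVAS,
    VENTRICLE,
    LabelVolume,
    PadInfo,
    USVolume,
    extract_sagittal,
    median_filter_image,
    pad_to_canvas,
)


@dataclass
class SagittalROI:
    """Half-open range [first, last) of sagittal indices to segment.

    Emulates the narrow rectangular region of interest drawn on a coronal
    view to exclude slices with no ventricle content.
    """

    first: int
    last: int

    def __post_init__(self) -> None:
        if not 0 <= self.first < self.last:
            raise ValueError(f"invalid ROI [{self.first}, {self.last})")

    def indices(self) -> range:
        return range(self.first, self.last)


@dataclass
class ThickSlice:
    """A 200x200x3 network input centred on sagittal index ``centre_index``."""

    pixels: np.ndarray  # (200, 200, 3) uint8
    centre_index: int
    source_id: str = ""
    pad_info: Optional[PadInfo] = None

    def __post_init__(self) -> None:
        if self.pixels.shape[:2] != CANVAS or self.pixels.shape[2] != 3:
            raise ValueError(f"ThickSlice must be {CANVAS}+(3,), got {self.pixels.shape}")


@dataclass
class SliceLabel:
    """A 200x200 class map over {background, brain, ventricle}."""

    pixels: np.ndarray  # (200, 200) uint8
    centre_index: int
    source_id: str = ""
    pad_info: Optional[PadInfo] = None

    def __post_init__(self) -> None:
        if self.pixels.shape != CANVAS:
            raise ValueError(f"SliceLabel must be {CANVAS}, got {self.pixels.shape}")
        bad = set(np.unique(self.pixels)) - {BACKGROUND, BRAIN, VENTRICLE}
        if bad:
            raise ValueError(f"label values outside the class set: {sorted(bad)}")


@dataclass
class ClassWeights:
    """Median-frequency class weights alpha_c = m_p / p_c."""

    alpha: dict[int, float]
    frequencies: dict[int, float]
    median_frequency: float


def preprocess_slice(image: np.ndarray, *, is_label: bool = False):
    """resize-if-oversized -> centre-pad to 200x200 -> (images only) 3x3 median."""
    padded, info = pad_to_canvas(image, is_label=is_label)
    if not is_label:
        padded = median_filter_image(padded)
    return padded, info


def build_thick_slices(volume: USVolume, roi: SagittalROI) -> list[ThickSlice]:
    """One ThickSlice per ROI sagittal index, ordered by index.

    Neighbour slices s-1 / s+1 are taken with edge replication at the
    ROI (and volume) boundary, so every ROI slice yields a sample; each
    channel goes through the identical resize -> pad -> 3x3 median
    preprocessing.
    """
    extent = volume.shape[0]
    if roi.last > extent:
        raise ValueError(f"ROI [{roi.first}, {roi.last}) exceeds sagittal extent {extent}")
    out = []
    for s in roi.indices():
        chans = []
        info = None
        for ds in (-1, 0, 1):
            idx = int(np.clip(s + ds, roi.first, roi.last - 1))
            img = np.asarray(extract_sagittal(volume, idx))
            proc, info = preprocess_slice(img)
            chans.append(proc)
        pixels = np.stack(chans, axis=-1).astype(np.uint8)
        out.append(
            ThickSlice(
                pixels=pixels,
                centre_index=s,
                source_id=f"{volume.patient_id}:{volume.acquisition_index}",
                pad_info=info,
            )
        )
    return out


def compress_labels(masks: Sequence[np.ndarray]) -> np.ndarray:
    """Pixelwise OR of three consecutive binary ventricle masks."""
    if len(masks) != 3:
        raise ValueError("expected exactly three consecutive masks")
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"mask dimensions differ: {shapes}")
    out = np.zeros(masks[0].shape, dtype=bool)
    for m in masks:
        out |= m.astype(bool)
    return out


def rebalance_classes(image: ThickSlice, binary_label: np.ndarray) -> SliceLabel:
    """3-class map with precedence ventricle > background > brain.

    Ventricle where the (OR-compressed) mask is set; background where all
    three image channels are exactly zero and the mask is not set; brain
    elsewhere.
    """
    if binary_label.shape != CANVAS:
        raise ValueError("label and canvas dims differ")
    out = np.full(CANVAS, BRAIN, dtype=np.uint8)
    black = (image.pixels == 0).all(axis=-1)
    out[black] = BACKGROUND
    out[binary_label.astype(bool)] = VENTRICLE
    return SliceLabel(
        pixels=out,
        centre_index=image.centre_index,
        source_id=image.source_id,
        pad_info=image.pad_info,
    )


def build_slice_labels(
    label_volume: LabelVolume, roi: SagittalROI, thick: Sequence[ThickSlice]
) -> list[SliceLabel]:
    """Thickened, OR-compressed, rebalanced labels matching ``thick``.

    Each sagittal ventricle mask goes through the same geometric
    preprocessing as the images (nearest-neighbour resize, centre pad,
    no median filter), then the three neighbours are OR-compressed and
    rebalanced against the corresponding thick slice.
    """
    extent = label_volume.shape[0]
    mask3d = label_volume.ventricle_mask()
    out = []
    for ts in thick:
        masks = []
        for ds in (-1, 0, 1):
            idx = int(np.clip(ts.centre_index + ds, roi.first, roi.last - 1))
            proc, _ = preprocess_slice(mask3d[idx].astype(np.uint8), is_label=True)
            masks.append(proc)
        out.append(rebalance_classes(ts, compress_labels(masks)))
    return out


def compute_class_weights(labels: Sequence[SliceLabel]) -> ClassWeights:
    """Median-frequency balancing over a label corpus.

    p_c = (pixels of class c over all labels) / (total pixels of the
    labels in which c appears at least once); m_p = median of the p_c of
    the classes present; alpha_c = m_p / p_c.  Classes absent from the
    whole corpus are omitted (their weight is undefined).
    """
    if not labels:
        raise ValueError("need at least one label")
    classes = (BACKGROUND, BRAIN, VENTRICLE)
    npix = {c: 0 for c in classes}
    denom = {c: 0 for c in classes}
    per_label = CANVAS[0] * CANVAS[1]
    for lab in labels:
        counts = np.bincount(lab.pixels.ravel(), minlength=3)
        for c in classes:
            if counts[c] > 0:
                npix[c] += int(counts[c])
                denom[c] += per_label
    freqs = {c: npix[c] / denom[c] for c in classes if denom[c] > 0}
    if len(freqs) < len(classes):
        import warnings

        missing = sorted(set(classes) - set(freqs))
        warnings.warn(f"classes absent from corpus, weights omitted: {missing}")
    m_p = float(np.median(list(freqs.values())))
    alpha = {c: m_p / p for c, p in freqs.items()}
    return ClassWeights(alpha=alpha, frequencies=freqs, median_frequency=m_p)


def split_train_test(
    items: Sequence, ratio: float = 0.75, seed: int = 0, group_key=None
) -> tuple[list, list]:
    """Shuffled disjoint train/test split with sizes floor(ratio*n) / rest.

    ``group_key`` optionally maps an item to a group id (e.g. its source
    volume); groups are then assigned whole to one side, with the train
    side grown greedily until it reaches floor(ratio*n) items.
    """
    items = list(items)
    n = len(items)
    if n < 4:
        raise ValueError("need at least 4 items to split")
    rng = np.random.default_rng(seed)
    n_train = int(np.floor(ratio * n))
    if group_key is None:
        perm = rng.permutation(n)
        train = [items[i] for i in perm[:n_train]]
        test = [items[i] for i in perm[n_train:]]
        return train, test
    groups: dict = {}
    for it in items:
        groups.setdefault(group_key(it), []).append(it)
    keys = list(groups)
    order = rng.permutation(len(keys))
    train, test = [], []
    for k in order:
        bucket = groups[keys[k]]
        (train if len(train) + len(bucket) <= n_train else test).extend(bucket)
    return train, test


@dataclass
class AffineParams:
    """One augmentation draw: translation px, rotation deg, scale, shear deg."""

    tx: float
    ty: float
    rotation_deg: float
    scale: float
    shear_x_deg: float
    shear_y_deg: float


def augmentation_sample(rng: np.random.Generator | int) -> AffineParams:
    """Independent uniform draws within the augmentation ranges.

    Translation +-20 px in x and y, rotation +-30 degrees, scale in
    [0.8, 1.2], shear +-20 degrees in x and y.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return AffineParams(
        tx=float(rng.uniform(-20, 20)),
        ty=float(rng.uniform(-20, 20)),
        rotation_deg=float(rng.uniform(-30, 30)),
        scale=float(rng.uniform(0.8, 1.2)),
        shear_x_deg=float(rng.uniform(-20, 20)),
        shear_y_deg=float(rng.uniform(-20, 20)),
    )


def _affine_matrix(p: AffineParams, centre: tuple[float, float]) -> np.ndarray:
    """Output->input pixel map (row, col homogeneous), pivoting at centre."""
    th = np.deg2rad(p.rotation_deg)
    shx = np.tan(np.deg2rad(p.shear_x_deg))
    shy = np.tan(np.deg2rad(p.shear_y_deg))
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    shear = np.array([[1.0, shx], [shy, 1.0]])
    fwd = p.scale * rot @ shear  # forward (input->output) linear part
    inv = np.linalg.inv(fwd)
    cy, cx = centre
    c = np.array([cy, cx])
    t = np.array([p.ty, p.tx])
    # forward: out = fwd @ (in - c) + c + t  =>  in = inv @ (out - c - t) + c
    offset = c - inv @ (c + t)
    return inv, offset


def apply_augmentation(
    image: ThickSlice, label: SliceLabel, params: AffineParams
) -> tuple[ThickSlice, SliceLabel]:
    """Apply one affine draw identically to image and label.

    Images use linear interpolation, labels nearest-neighbour (so no
    interpolated class values appear); pixels mapped from outside the
    canvas are filled with zeros, hence background class.
    """
    centre = ((CANVAS[0] - 1) / 2.0, (CANVAS[1] - 1) / 2.0)
    inv, offset = _affine_matrix(params, centre)
    chans = [
        ndimage.affine_transform(
            image.pixels[..., c].astype(np.float32), inv, offset=offset,
            order=1, mode="constant", cval=0.0,
        )
        for c in range(3)
    ]
    img = np.clip(np.round(np.stack(chans, axis=-1)), 0, 255).astype(np.uint8)
    lab = ndimage.affine_transform(
        label.pixels, inv, offset=offset, order=0, mode="constant", cval=BACKGROUND
    ).astype(np.uint8)
    # pixels pushed to exact black must be background unless ventricle there
    lab[(img == 0).all(axis=-1) & (lab != VENTRICLE)] = BACKGROUND
    return (
        ThickSlice(img, image.centre_index, image.source_id, image.pad_info),
        SliceLabel(lab, label.centre_index, label.source_id, label.pad_info),
    )


@dataclass
class SliceDataset:
    """Paired thick slices and labels with a train/test split."""

    train_images: list[ThickSlice]
    train_labels: list[SliceLabel]
    test_images: list[ThickSlice]
    test_labels: list[SliceLabel]
    class_weights: ClassWeights = None  # computed on the training split only

    def __post_init__(self):
        if self.class_weights is None and self.train_labels:
            self.class_weights = compute_class_weights(self.train_labels)


def build_dataset(
    volumes: Sequence[USVolume],
    labels: Sequence[LabelVolume],
    rois: Sequence[SagittalROI],
    ratio: float = 0.75,
    seed: int = 0,
) -> SliceDataset:
    """End-to-end corpus build: thick slices, labels, per-slice split, weights."""
    pairs: list[tuple[ThickSlice, SliceLabel]] = []
    for vol, lab, roi in zip(volumes, labels, rois):
        thick = build_thick_slices(vol, roi)
        slabs = build_slice_labels(lab, roi, thick)
        pairs.extend(zip(thick, slabs))
    train, test = split_train_test(pairs, ratio=ratio, seed=seed)
    return SliceDataset(
        train_images=[p[0] for p in train],
        train_labels=[p[1] for p in train],
        test_images=[p[0] for p in test],
        test_labels=[p[1] for p in test],
    )
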