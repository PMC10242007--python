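"""From 3D scans to the 2D two-channel slice records the classifier consumes.

The pipeline mirrors slice-based tumor classification practice: from each
patient, the five slices with the largest tumor cross-section are taken from
each of the three anatomical views (axial, sagittal, coronal) — 15 records per
patient; pixels outside the tumor mask are attenuated to 1/3 of their value to
focus learning on the lesion while keeping context; slices are resized to a
square grid (128x128 by default, 32x32 in the test preset) and min-max
normalized to [0, 1] per slice and channel.  Training-time augmentation is a
horizontal flip (p=0.5) plus a small rotation (|angle| <= 10 degrees) and is
never applied to test slices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from .synthetic import PatientScan, MODALITIES

__all__ = [
    "VIEWS", "SliceRecord", "SliceDataset", "extract_tumor_slices",
    "attenuate_outside_mask", "resize_normalize", "augment",
    "preprocess_scan", "preprocess_cohort",
]

#: view name -> volume axis sliced over
VIEWS = {"axial": 0, "sagittal": 1, "coronal": 2}

ATTENUATION = 1.0 / 3.0


@dataclass
class SliceRecord:
    patient_id: str
    view: str
    slice_index: int
    image: np.ndarray            # (2, H, W), channel order (FLAIR, T1ce)
    label: int
    mask: np.ndarray | None = None   # in-plane tumor mask; dropped after resize

    def __post_init__(self):
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {sorted(VIEWS)}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if self.image.ndim != 3 or self.image.shape[0] != 2:
            raise ValueError("image must be (2, H, W)")
        if self.slice_index < 0:
            raise ValueError("slice_index must be nonnegative")


def extract_tumor_slices(scan: PatientScan,
                         n_per_view: int = 5) -> list[SliceRecord]:
    """Select, per view, the ``n_per_view`` slices with the largest tumor
    cross-sectional area (ties broken by lower slice index).

    Returns 3 * n_per_view records at native in-plane resolution, each
    carrying its 2D mask for downstream attenuation.
    """
    mask = scan.mask.astype(bool)
    records = []
    for view, axis in VIEWS.items():
        other = tuple(a for a in range(3) if a != axis)
        areas = mask.sum(axis=other)
        n_nonzero = int((areas > 0).sum())
        if n_nonzero < n_per_view:
            raise ValueError(
                f"patient {scan.patient_id}: only {n_nonzero} tumor-bearing "
                f"slices along the {view} axis, need {n_per_view}")
        order = np.argsort(-areas, kind="stable")[:n_per_view]
        for idx in order:
            idx = int(idx)
            image = np.stack([np.take(scan.volumes[m], idx, axis=axis)
                              for m in MODALITIES])
            records.append(SliceRecord(
                patient_id=scan.patient_id, view=view, slice_index=idx,
                image=image, label=scan.label,
                mask=np.take(mask, idx, axis=axis)))
    return records


def attenuate_outside_mask(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Multiply pixels outside the tumor mask by 1/3; inside unchanged.

    ``image`` may be (H, W) or (C, H, W); ``mask`` is (H, W).
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[-2:] != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} "
                         "are not co-shaped")
    return np.where(mask, image, ATTENUATION * image)


def resize_normalize(image: np.ndarray, out_size: int = 128) -> np.ndarray:
    """Resize to (out_size, out_size) and min-max normalize to [0, 1].

    Operates per channel for (C, H, W) input.  A constant channel maps to
    all zeros (the degenerate rule for a flat slice).
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("empty image")
    single = image.ndim == 2
    if single:
        image = image[None]
    out = np.empty((image.shape[0], out_size, out_size))
    for c, chan in enumerate(image):
        if chan.shape != (out_size, out_size):
            chan = _sk_resize(chan, (out_size, out_size), order=1,
                              preserve_range=True, anti_aliasing=None)
        lo, hi = chan.min(), chan.max()
        out[c] = (chan - lo) / (hi - lo) if hi > lo else np.zeros_like(chan)
    return out[0] if single else out


def augment(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Online training augmentation: horizontal flip (p=0.5) then rotation by
    an angle uniform in [-10, +10] degrees (bilinear, zero padding).

    Output is clipped back to [0, 1].  Never applied to test slices.
    """
    image = np.asarray(image, dtype=np.float64)
    if rng.random() < 0.5:
        image = image[..., ::-1]
    angle = rng.uniform(-10.0, 10.0)
    if angle != 0.0:
        axes = (-2, -1)
        image = ndimage.rotate(image, angle, axes=axes, reshape=False,
                               order=1, mode="constant", cval=0.0)
    return np.clip(image, 0.0, 1.0)


def preprocess_scan(scan: PatientScan, n_per_view: int = 5,
                    out_size: int = 128) -> list[SliceRecord]:
    """Full per-patient pipeline: extract -> attenuate -> resize+normalize."""
    out = []
    for rec in extract_tumor_slices(scan, n_per_view=n_per_view):
        img = attenuate_outside_mask(rec.image, rec.mask)
        img = resize_normalize(img, out_size=out_size)
        out.append(SliceRecord(patient_id=rec.patient_id, view=rec.view,
                               slice_index=rec.slice_index, image=img,
                               label=rec.label, mask=None))
    return out


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class SliceDataset:
    """Arrays-of-slices container used by the trainers.

    images: (N, 2, H, W) float; labels: (N,) int; provenance columns keep the
    slice-to-patient mapping needed for scan-level voting.
    """

    images: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    views: np.ndarray
    slice_indices: np.ndarray

    def __post_init__(self):
        n = len(self.images)
        for arr in (self.labels, self.patient_ids, self.views,
                    self.slice_indices):
            if len(arr) != n:
                raise ValueError("all dataset columns must have equal length")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_patients(self) -> int:
        return len(np.unique(self.patient_ids))

    @classmethod
    def from_records(cls, records: list[SliceRecord]) -> "SliceDataset":
        if not records:
            raise ValueError("no slice records")
        return cls(
            images=np.stack([r.image for r in records]).astype(np.float64),
            labels=np.array([r.label for r in records], dtype=np.int64),
            patient_ids=np.array([r.patient_id for r in records], dtype=object),
            views=np.array([r.view for r in records], dtype=object),
            slice_indices=np.array([r.slice_index for r in records],
                                   dtype=np.int64))

    def subset(self, idx) -> "SliceDataset":
        return SliceDataset(self.images[idx], self.labels[idx],
                            self.patient_ids[idx], self.views[idx],
                            self.slice_indices[idx])

    def replace_images(self, images: np.ndarray) -> "SliceDataset":
        """New dataset with mapped images; labels/metadata untouched."""
        if images.shape != self.images.shape:
            raise ValueError("mapped images must keep shape")
        return SliceDataset(images, self.labels.copy(),
                            self.patient_ids.copy(), self.views.copy(),
                            self.slice_indices.copy())

    # -- persistence -------------------------------------------------------
    def to_hdf5(self, path) -> None:
        path = Path(path)
        sdt = h5py.string_dtype()
        with h5py.File(path, "w") as f:
            f.create_dataset("images", data=self.images.astype(np.float32))
            f.create_dataset("labels", data=self.labels)
            f.create_dataset("patient_id",
                             data=self.patient_ids.astype(object), dtype=sdt)
            f.create_dataset("view", data=self.views.astype(object), dtype=sdt)
            f.create_dataset("slice_index", data=self.slice_indices)
        pd.DataFrame({
            "patient_id": self.patient_ids, "view": self.views,
            "slice_index": self.slice_indices, "label": self.labels,
        }).to_csv(path.with_suffix(".csv"), index=False)

    @classmethod
    def from_hdf5(cls, path) -> "SliceDataset":
        with h5py.File(path, "r") as f:
            return cls(
                images=f["images"][()].astype(np.float64),
                labels=f["labels"][()],
                patient_ids=np.array([s.decode() if isinstance(s, bytes)
                                      else s for s in f["patient_id"][()]],
                                     dtype=object),
                views=np.array([s.decode() if isinstance(s, bytes) else s
                                for s in f["view"][()]], dtype=object),
                slice_indices=f["slice_index"][()])


def preprocess_cohort(scans, n_per_view: int = 5,
                      out_size: int = 128) -> SliceDataset:
    """Preprocess a list of scans into one SliceDataset."""
    records = []
    for scan in scans:
        records.extend(preprocess_scan(scan, n_per_view=n_per_view,
                                       out_size=out_size))
    return SliceDataset.from_records(records)
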