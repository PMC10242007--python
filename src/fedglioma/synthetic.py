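"""Deterministic synthetic multi-site MRI cohorts.

Real multi-hospital glioma cohorts combine three statistical features the
federated scheme must cope with: per-site class imbalance (e.g. 55/112 vs
68/08 patients per class), a learnable lesion signal that differs between
classes, and a site-level intensity domain shift caused by different scanners
and acquisition settings.  This module generates small 3D two-modality
"scans" with exactly that structure:

* each patient has one FLAIR-like and one T1ce-like nonnegative volume plus a
  binary spherical tumor mask guaranteed to span at least
  :data:`MIN_TUMOR_SLICES` slices along every axis;
* the lesion carries class-dependent texture — classes differ in mean lesion
  intensity and in texture granularity, so a simple intensity summary already
  separates them (the "learnable signal" contract);
* the FLAIR-analogue shows the full lesion while the T1ce-analogue emphasizes
  the lesion rim, so two-stream fusion sees complementary information;
* a per-site monotone intensity transform v -> gain * v**gamma + offset plus
  voxel noise emulates scanner-induced domain shift.

Everything is driven by ``numpy`` Generators seeded from the site spec, so a
given (spec, seed) is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "MIN_TUMOR_SLICES", "MODALITIES", "ClassSignal", "DomainShift",
    "SiteSpec", "PatientScan", "generate_site", "apply_domain_shift",
    "split_patients", "write_site", "read_site",
]

#: every generated tumor mask spans at least this many slices per axis, so
#: that five tumor-bearing slices can be extracted from each of the 3 views
MIN_TUMOR_SLICES = 5

MODALITIES = ("FLAIR", "T1ce")


@dataclass(frozen=True)
class ClassSignal:
    """Per-class lesion appearance: (class0, class1) parameter pairs."""

    lesion_mean: tuple = (0.3, 0.75)     # mean lesion intensity
    texture_freq: tuple = (0.15, 0.35)   # spatial frequency of lesion texture
    texture_amp: float = 0.05

    def __post_init__(self):
        if abs(self.lesion_mean[1] - self.lesion_mean[0]) <= 0:
            raise ValueError("class signal requires nonzero mean separation")


@dataclass(frozen=True)
class DomainShift:
    """Monotone intensity transform v -> gain * v**gamma + offset."""

    gain: float = 1.0
    offset: float = 0.0
    gamma_exponent: float = 1.0

    def __post_init__(self):
        if self.gain <= 0 or self.gamma_exponent <= 0:
            raise ValueError("gain and gamma_exponent must be positive")


@dataclass(frozen=True)
class SiteSpec:
    site_id: str
    n_class0: int
    n_class1: int
    volume_shape: tuple = (32, 32, 32)
    lesion_radius_range: tuple = (4, 6)
    class_signal: ClassSignal = field(default_factory=ClassSignal)
    domain_shift: DomainShift = field(default_factory=DomainShift)
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_class0 + self.n_class1 < 2:
            raise ValueError("a site needs at least two patients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        rmin, rmax = self.lesion_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("invalid lesion_radius_range")
        if 2 * rmin + 1 < MIN_TUMOR_SLICES:
            raise ValueError(
                f"lesion_radius_range {self.lesion_radius_range} cannot "
                f"guarantee {MIN_TUMOR_SLICES} tumor slices per axis "
                f"(smallest lesion spans {2 * rmin + 1})")
        if min(self.volume_shape) < 2 * rmax + 3:
            raise ValueError(
                f"volume_shape {self.volume_shape} too small to host a "
                f"radius-{rmax} lesion with the "
                f"{MIN_TUMOR_SLICES}-slices-per-axis guarantee")


@dataclass
class PatientScan:
    """One patient: two co-registered modality volumes + binary tumor mask."""

    patient_id: str
    site_id: str
    label: int
    volumes: dict
    mask: np.ndarray

    def __post_init__(self):
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if set(self.volumes) != set(MODALITIES):
            raise ValueError(f"volumes must contain exactly {MODALITIES}")
        self.mask = np.asarray(self.mask)
        for m, v in self.volumes.items():
            if v.shape != self.mask.shape:
                raise ValueError(f"{m} volume shape differs from mask shape")
            if np.any(v < 0):
                raise ValueError(f"{m} volume must be nonnegative")

    def mask_slices_per_axis(self) -> tuple:
        """Number of mask-bearing slices along each of the three axes."""
        m = self.mask.astype(bool)
        return tuple(int(np.any(m, axis=tuple(a for a in range(3) if a != ax))
                         .sum()) for ax in range(3))


def _smooth_noise(rng, shape, freq):
    """Zero-mean, unit-std smoothed noise field; freq sets granularity."""
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=1.0 / max(freq, 1e-3))
    sd = sm.std()
    return (sm - sm.mean()) / (sd if sd > 0 else 1.0)


def _generate_scan(rng, spec: SiteSpec, patient_id: str,
                   label: int) -> PatientScan:
    shape = spec.volume_shape
    rmin, rmax = spec.lesion_radius_range
    r = int(rng.integers(rmin, rmax + 1))
    center = np.array([rng.integers(r + 1, s - r - 1) for s in shape])
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    dist = np.sqrt(sum((g - c) ** 2.0 for g, c in zip(grids, center)))
    mask = dist <= r

    sig = spec.class_signal
    mean_c = sig.lesion_mean[label]
    freq_c = sig.texture_freq[label]
    texture = _smooth_noise(rng, shape, freq_c)
    # second, correlated texture for the T1ce-analogue
    texture2 = 0.7 * texture + 0.3 * _smooth_noise(rng, shape, freq_c)

    background = 0.15 + 0.03 * _smooth_noise(rng, shape, 0.2)
    flair = np.where(mask, mean_c + sig.texture_amp * texture, background)
    # T1ce: contrast enhancement concentrated at the lesion rim
    rim = np.exp(-((r - dist) / 2.0) ** 2)
    t1ce = np.where(mask,
                    mean_c * (0.35 + 0.65 * rim)
                    + 0.75 * sig.texture_amp * texture2,
                    0.8 * background)
    volumes = {}
    for name, vol in (("FLAIR", flair), ("T1ce", t1ce)):
        noisy = vol + rng.normal(0.0, spec.noise_sd, shape)
        volumes[name] = np.clip(noisy, 0.0, None)
    scan = PatientScan(patient_id=patient_id, site_id=spec.site_id,
                       label=label, volumes=volumes, mask=mask)
    if min(scan.mask_slices_per_axis()) < MIN_TUMOR_SLICES:
        raise RuntimeError(  # unreachable under SiteSpec validation
            "generated mask violates the slice-per-axis guarantee")
    return scan


def generate_site(spec: SiteSpec) -> list[PatientScan]:
    """Generate all patients of one site; deterministic for a given spec."""
    rng = np.random.default_rng(spec.seed)
    labels = [0] * spec.n_class0 + [1] * spec.n_class1
    scans = []
    for idx, label in enumerate(labels):
        pid = f"{spec.site_id}-p{idx:03d}"
        scan = _generate_scan(rng, spec, pid, label)
        scan = apply_domain_shift(scan, spec.domain_shift, noise_sd=0.0,
                                  seed=0)
        scans.append(scan)
    return scans


def apply_domain_shift(scan: PatientScan, shift: DomainShift,
                       noise_sd: float = 0.0, seed: int = 0,
                       v_max: float = 2.0) -> PatientScan:
    """Scanner-shift analogue: v -> clip(gain * v**gamma + offset + eps, 0, v_max).

    eps ~ Normal(0, noise_sd^2) per voxel; mask and label are untouched.
    ``v_max`` caps pathological offsets; at 2.0 it is inert for the intensity
    ranges the generator produces.
    """
    if isinstance(shift, (tuple, list)):
        shift = DomainShift(*shift)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    volumes = {}
    for m, v in scan.volumes.items():
        out = shift.gain * np.power(v, shift.gamma_exponent) + shift.offset
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd, v.shape)
        volumes[m] = np.clip(out, 0.0, v_max)
    return PatientScan(patient_id=scan.patient_id, site_id=scan.site_id,
                       label=scan.label, volumes=volumes,
                       mask=scan.mask.copy())


def split_patients(scans: list[PatientScan], train_fraction: float = 0.8,
                   seed: int = 0):
    """Stratified patient-wise train/test split.

    Per class, round(train_fraction * n) patients go to training; the split is
    disjoint by construction (no patient's scan can appear in both sets) and
    deterministic for a given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class = {0: [], 1: []}
    for s in scans:
        by_class[s.label].append(s)
    if not by_class[0] or not by_class[1]:
        raise ValueError("need at least one patient per class")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for label in (0, 1):
        group = by_class[label]
        order = rng.permutation(len(group))
        n_train = int(np.floor(train_fraction * len(group) + 0.5))
        for rank, idx in enumerate(order):
            (train if rank < n_train else test).append(group[idx])
    return train, test


# ---------------------------------------------------------------------------
# NIfTI persistence
# ---------------------------------------------------------------------------

def write_site(scans: list[PatientScan], out_dir) -> Path:
    """Write one NIfTI file per modality plus mask, and a CSV manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    affine = np.eye(4)
    for scan in scans:
        files = {}
        for m in MODALITIES:
            fname = f"{scan.patient_id}_{m.lower()}.nii.gz"
            nib.save(nib.Nifti1Image(
                scan.volumes[m].astype(np.float32), affine),
                out_dir / fname)
            files[m.lower()] = fname
        mname = f"{scan.patient_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(scan.mask.astype(np.uint8), affine),
                 out_dir / mname)
        rows.append({"patient_id": scan.patient_id, "site_id": scan.site_id,
                     "label": scan.label, "flair": files["flair"],
                     "t1ce": files["t1ce"], "mask": mname})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_site(site_dir) -> list[PatientScan]:
    """Load a site written by :func:`write_site` (or any matching layout)."""
    site_dir = Path(site_dir)
    manifest = pd.read_csv(site_dir / "manifest.csv")
    scans = []
    for _, row in manifest.iterrows():
        volumes = {
            "FLAIR": np.asarray(
                nib.load(site_dir / row["flair"]).get_fdata(), dtype=np.float64),
            "T1ce": np.asarray(
                nib.load(site_dir / row["t1ce"]).get_fdata(), dtype=np.float64),
        }
        mask = np.asarray(
            nib.load(site_dir / row["mask"]).get_fdata()) > 0.5
        scans.append(PatientScan(patient_id=str(row["patient_id"]),
                                 site_id=str(row["site_id"]),
                                 label=int(row["label"]),
                                 volumes=volumes, mask=mask))
    return scans
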