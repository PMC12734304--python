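"""Synthetic NIfTI brain-phantom cohorts with a controllable class effect.

Each phantom is an ellipsoidal "brain" of smoothed random texture inside a
single-channel volume, normalised to [0, 1].  The two classes differ only by
an atrophy-like mean-intensity reduction — a factor ``(1 - effect_size)`` —
inside a fixed subregion of the axial ``signal_slab``, mimicking the localized
structural alterations that volumetric classifiers are trained to detect.
Axial slices are indexed 0-based, inferior to superior; slab and occlusion
windows are half-open intervals.

Randomness: one master seed; each sample is drawn from an independent
substream indexed by ``draw``, so cohort generation is order-independent and
the voxel grid is a pure function of ``(seed, draw, label)``.  The texture and
noise streams do not depend on the label, so at ``effect_size = 0`` the two
class-conditional distributions are identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import List, Sequence, Tuple

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class Volume:
    """A single-channel 3D intensity grid with voxel spacing and class label."""

    data: np.ndarray                      # (D, H, W) float32 in [0, 1]
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: int = 0
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(f"volume must be 3D with positive dims, got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite intensities")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class PhantomSpec:
    """Generative parameters of the phantom cohort.

    Defaults mirror the preprocessed scans the network targets: 73 axial
    slices (in-plane 96 x 96 is a configurable stand-in), a disease signal in
    slices [20, 40), and mild texture/noise so the class effect dominates.
    """

    shape: Tuple[int, int, int] = (73, 96, 96)      # (D, H, W)
    effect_size: float = 0.4
    signal_slab: Tuple[int, int] = (20, 40)         # half-open axial interval
    noise_sd: float = 0.02
    smoothing_sigma: float = 1.5                    # voxels
    seed: int = 0
    base_intensity: float = 0.7
    texture_sd: float = 0.08

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s < 1 for s in self.shape):
            raise ValueError(f"shape must be positive, got {self.shape}")
        lo, hi = (int(v) for v in self.signal_slab)
        if not (0 <= lo < hi <= self.shape[0]):
            raise ValueError(
                f"signal_slab {self.signal_slab} must be a non-empty half-open "
                f"interval inside [0, {self.shape[0]})")
        self.signal_slab = (lo, hi)
        if self.effect_size < 0:
            raise ValueError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_sd and smoothing_sigma must be >= 0")


def brain_mask(spec: PhantomSpec) -> np.ndarray:
    """Ellipsoidal brain support centred in the volume."""
    d, h, w = spec.shape
    zz, yy, xx = np.ogrid[:d, :h, :w]
    cz, cy, cx = (d - 1) / 2, (h - 1) / 2, (w - 1) / 2
    rz, ry, rx = 0.46 * d, 0.42 * h, 0.42 * w
    return (((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2
            + ((xx - cx) / rx) ** 2) <= 1.0


def signal_region_mask(spec: PhantomSpec) -> np.ndarray:
    """The fixed subregion carrying the class signal.

    The central half of the in-plane extent, restricted to the signal slab
    and to the brain mask.
    """
    d, h, w = spec.shape
    region = np.zeros(spec.shape, dtype=bool)
    lo, hi = spec.signal_slab
    region[lo:hi, h // 4: 3 * h // 4, w // 4: 3 * w // 4] = True
    return region & brain_mask(spec)


def generate_phantom(label: int, spec: PhantomSpec, draw: int = 0) -> Volume:
    """One reproducible phantom volume for class ``label``.

    The disease class (label 1) has the signal-region mean intensity reduced
    by the factor ``(1 - effect_size)``; texture and additive noise are shared
    between labels for the same ``(seed, draw)``.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    if draw < 0:
        raise ValueError(f"draw must be >= 0, got {draw}")
    rng = np.random.default_rng([spec.seed, draw])
    mask = brain_mask(spec)
    texture = rng.normal(0.0, 1.0, size=spec.shape)
    if spec.smoothing_sigma > 0:
        texture = ndimage.gaussian_filter(texture, spec.smoothing_sigma)
        sd = texture.std()
        if sd > 0:
            texture /= sd
    vol = np.where(mask, spec.base_intensity + spec.texture_sd * texture, 0.0)
    if label == 1 and spec.effect_size > 0:
        region = signal_region_mask(spec)
        vol = np.where(region, vol * (1.0 - spec.effect_size), vol)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    vol = np.clip(vol, 0.0, 1.0).astype(np.float32)
    return Volume(data=vol, label=label, subject_id=f"sub-{spec.seed}-{draw:04d}")


def generate_cohort(spec: PhantomSpec, n_per_class: int) -> List[Volume]:
    """``n_per_class`` phantoms per class; a pure function of (spec, n_per_class)."""
    vols = []
    for draw in range(n_per_class):
        for label in (0, 1):
            v = generate_phantom(label, spec, draw=2 * draw + label)
            vols.append(v)
    return vols


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment_gaussian_noise(v: Volume, sd: float, seed: int) -> Volume:
    """Independent zero-mean Gaussian perturbation per voxel, re-clipped to [0,1]."""
    if sd < 0:
        raise ValueError(f"noise sd must be >= 0, got {sd}")
    if sd == 0:
        return v
    rng = np.random.default_rng(seed)
    data = np.clip(v.data + rng.normal(0.0, sd, size=v.data.shape), 0.0, 1.0)
    return replace(v, data=data.astype(np.float32))


def augment_gamma(v: Volume, gamma: float) -> Volume:
    """Monotone intensity remap ``x -> x**gamma`` (intensities must be in [0,1])."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    if v.data.min() < 0 or v.data.max() > 1:
        raise ValueError("gamma correction requires intensities in [0, 1]")
    return replace(v, data=np.power(v.data, gamma, dtype=np.float32))


# ---------------------------------------------------------------------------
# cohort manifest and class balancing
# ---------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """Records of (subject_id, label, path); one subject may own several volumes."""

    records: pd.DataFrame  # columns: subject_id, label, path

    def __post_init__(self):
        required = ["subject_id", "label", "path"]
        missing = [c for c in required if c not in self.records.columns]
        if missing:
            raise ValueError(f"manifest missing columns {missing}")
        if self.records["path"].duplicated().any():
            dup = self.records["path"][self.records["path"].duplicated()].iloc[0]
            raise ValueError(f"duplicate file path in manifest: {dup}")
        bad = set(self.records["label"]) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")

    def __len__(self):
        return len(self.records)

    @property
    def labels(self) -> np.ndarray:
        return self.records["label"].to_numpy(dtype=int)

    @property
    def subjects(self) -> np.ndarray:
        return self.records["subject_id"].to_numpy(dtype=object)


def oversample_balance(labels, seed: int) -> np.ndarray:
    """Indices equalising class counts by resampling the minority class.

    Majority records appear exactly once; every minority record appears at
    least once, with the shortfall filled by seeded sampling with replacement.
    Accepts a CohortManifest or a label sequence.
    """
    if isinstance(labels, CohortManifest):
        labels = labels.labels
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("oversampling needs both classes present")
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    out = []
    for cls in classes:
        idx = np.nonzero(labels == cls)[0]
        out.append(idx)
        shortfall = n_max - idx.size
        if shortfall > 0:
            out.append(rng.choice(idx, size=shortfall, replace=True))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def write_cohort(volumes: Sequence[Volume], directory) -> CohortManifest:
    """Write volumes as float32 .nii.gz plus a CSV manifest; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, v in enumerate(volumes):
        name = f"{v.subject_id or f'sub-{i:04d}'}_label{v.label}_{i:04d}.nii.gz"
        path = directory / name
        affine = np.diag([*v.spacing, 1.0])
        nib.save(nib.Nifti1Image(v.data.astype(np.float32), affine), str(path))
        rows.append({"subject_id": v.subject_id or f"sub-{i:04d}",
                     "label": int(v.label), "path": name})
    manifest = CohortManifest(pd.DataFrame(rows, columns=["subject_id", "label", "path"]))
    manifest.records.to_csv(directory / MANIFEST_NAME, index=False)
    return manifest


def read_cohort(directory) -> Tuple[List[Volume], CohortManifest]:
    """Load a written cohort; raises per-record errors naming missing files."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        warnings.warn(f"no {MANIFEST_NAME} in {directory}; returning empty cohort")
        empty = CohortManifest(pd.DataFrame(columns=["subject_id", "label", "path"]))
        return [], empty
    manifest = CohortManifest(pd.read_csv(manifest_path))
    volumes = []
    for rec in manifest.records.itertuples(index=False):
        path = directory / rec.path
        if not path.exists():
            raise FileNotFoundError(f"manifest references missing file: {path}")
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        volumes.append(Volume(data=data, spacing=spacing, label=int(rec.label),
                              subject_id=str(rec.subject_id)))
    return volumes, manifest
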