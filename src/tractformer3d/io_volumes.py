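"""Reading, writing and spatial conditioning of 4D peak and label volumes.

Peak volumes hold fiber-orientation peaks: nine channels per voxel, three
principal directions times three vector components, packed peak-major
(p1x, p1y, p1z, p2x, ...). Label volumes hold one binary channel per tract;
channels are independent, so a voxel may belong to several tracts.

Volumes are stored as 4D NIfTI (gzip handled transparently by nibabel):
peaks as 32-bit float, labels as 8-bit unsigned integers. All geometry in
this package is computed in voxel space; the affine is carried through I/O
and crop/pad but never used in computation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

N_PEAK_CHANNELS = 9

__all__ = [
    "PeakVolume", "TractLabelVolume", "VolumeDimensionError",
    "ChannelCountError", "NonBinaryLabelError", "read_peak_volume",
    "write_peak_volume", "read_label_volume", "write_label_volume",
    "read_label_stack", "crop_or_pad",
]


class VolumeDimensionError(ValueError):
    """The on-disk image is not a 4D volume."""


class ChannelCountError(ValueError):
    """The 4th dimension does not match the expected channel count."""


class NonBinaryLabelError(ValueError):
    """Label data contains values other than 0 and 1."""


@dataclass
class PeakVolume:
    """Rank-4 grid H x W x D x 9 of peak-vector components (channels last)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 4:
            raise VolumeDimensionError(
                f"peak volume must be 4D, got {self.data.ndim}D")
        if self.data.shape[3] != N_PEAK_CHANNELS:
            raise ChannelCountError(
                f"expected {N_PEAK_CHANNELS} peak channels, got {self.data.shape[3]}")
        if not np.isfinite(self.data).all():
            raise ValueError("peak volume contains non-finite values")
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class TractLabelVolume:
    """Rank-4 binary grid H x W x D x T, one channel per tract."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 4:
            raise VolumeDimensionError(
                f"label volume must be 4D, got {arr.ndim}D")
        if not np.isin(arr, (0, 1)).all():
            raise NonBinaryLabelError("label volume must contain only 0 and 1")
        self.data = arr.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_tracts(self) -> int:
        return self.data.shape[3]


def _load_4d(path: str | Path) -> tuple[np.ndarray, tuple, np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise VolumeDimensionError(
            f"{path.name}: expected a 4D volume, got {data.ndim}D")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine, dtype=np.float64)


def read_peak_volume(path: str | Path) -> PeakVolume:
    """Read a 9-channel fiber-orientation-peak volume from a 4D NIfTI file."""
    data, spacing, affine = _load_4d(path)
    if data.shape[3] != N_PEAK_CHANNELS:
        raise ChannelCountError(
            f"{Path(path).name}: expected {N_PEAK_CHANNELS} peak channels, "
            f"got {data.shape[3]}")
    return PeakVolume(np.asarray(data, dtype=np.float32), spacing, affine)


def write_peak_volume(volume: PeakVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    img.header.set_zooms(tuple(volume.spacing) + (1.0,))
    nib.save(img, str(path))


def read_label_volume(path: str | Path) -> TractLabelVolume:
    """Read a multi-label tract mask volume (any tract count) from NIfTI."""
    data, spacing, affine = _load_4d(path)
    return TractLabelVolume(data, spacing, affine)


def write_label_volume(labels: TractLabelVolume, path: str | Path) -> None:
    """Write a binary multi-label volume with 8-bit integer storage."""
    if not np.isin(labels.data, (0, 1)).all():
        raise NonBinaryLabelError("refusing to write non-binary label data")
    img = nib.Nifti1Image(labels.data.astype(np.uint8), labels.affine)
    img.header.set_zooms(tuple(labels.spacing) + (1.0,))
    nib.save(img, str(path))


def read_label_stack(paths: list[str | Path]) -> TractLabelVolume:
    """Stack T separate 3D binary masks, in filename-sorted order, into one
    multi-label volume (a common ground-truth layout for tract masks)."""
    if not paths:
        raise ValueError("no label files given")
    ordered = sorted(Path(p) for p in paths)
    vols = []
    spacing, affine = None, None
    for p in ordered:
        if not p.exists():
            raise FileNotFoundError(f"label file not found: {p}")
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise VolumeDimensionError(f"{p.name}: expected 3D mask, got {arr.ndim}D")
        vols.append(arr)
        if spacing is None:
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            affine = np.asarray(img.affine, dtype=np.float64)
    return TractLabelVolume(np.stack(vols, axis=-1), spacing, affine)


def _axis_window(n: int, target: int, center: float) -> tuple[int, int, int, int]:
    """Return (src_lo, src_hi, dst_lo, dst_hi) for one axis."""
    if target <= n:  # crop
        start = int(round(center - target / 2.0))
        start = min(max(start, 0), n - target)
        return start, start + target, 0, target
    lo = (target - n) // 2  # pad, symmetric (extra voxel goes high)
    return 0, n, lo, lo + n


def crop_or_pad(volume, target_dims: tuple[int, int, int]):
    """Center-crop and/or zero-pad a volume to the target spatial dims.

    Cropping is centered on the bounding box of nonzero voxels when one
    exists, else on the volume center. The affine translation is updated so
    voxel-to-world coordinates of retained voxels are unchanged. A crop that
    discards nonzero voxels proceeds but emits a warning.
    """
    target_dims = tuple(int(t) for t in target_dims)
    if len(target_dims) != 3 or any(t <= 0 for t in target_dims):
        raise ValueError(f"target dims must be 3 positive integers, got {target_dims}")
    data = volume.data
    shape = data.shape[:3]
    fg = np.any(data != 0, axis=3)
    if fg.any():
        centers = [(idx.min() + idx.max() + 1) / 2.0 for idx in np.nonzero(fg)]
    else:
        centers = [n / 2.0 for n in shape]
    windows = [_axis_window(n, t, c) for n, t, c in zip(shape, target_dims, centers)]
    out = np.zeros(target_dims + (data.shape[3],), dtype=data.dtype)
    src = tuple(slice(w[0], w[1]) for w in windows)
    dst = tuple(slice(w[2], w[3]) for w in windows)
    out[dst] = data[src]
    if fg.any() and np.count_nonzero(np.any(out != 0, axis=3)) < np.count_nonzero(fg):
        warnings.warn("crop_or_pad discarded nonzero voxels", stacklevel=2)
    # voxel offset of the output origin in input voxel coordinates
    offset = np.array([w[0] - w[2] for w in windows], dtype=np.float64)
    affine = volume.affine.copy()
    affine[:3, 3] = affine[:3, 3] + affine[:3, :3] @ offset
    return replace(volume, data=out, affine=affine)
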