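"""Synthetic fiber-crossing phantoms.

The generator emulates the input regime of peak-based tract segmentation:
tubular, curving, mutually crossing tracts whose voxelwise peak vectors
follow the local tract tangent. Each tract is a smooth cubic-spline curve
through randomly placed control points, swept with a constant tube radius.
At each voxel the tangents of up to three covering tracts are written into
the three peak slots (peak-major packing, ascending tract index), scaled by
a common amplitude; Gaussian perturbation is added to foreground peak
components. Background voxels carry exactly zero peaks, mirroring the brain
mask of the real pipeline. Ground-truth labels record *all* covering tracts,
so labels and peaks can disagree in more-than-threefold crossings, as they
do in real data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.spatial import cKDTree

from .io_volumes import PeakVolume, TractLabelVolume

__all__ = ["PhantomSpec", "TractCurve", "Phantom", "sample_tract_curve",
           "rasterize_tract", "generate_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic volume.

    dims: grid size in voxels. n_tracts: number of tubes. radius_range:
    min/max tube radius in voxels (uniformly sampled per tract).
    noise_sigma: SD of the additive Gaussian perturbation on foreground peak
    components. amplitude: peak magnitude scale (peaks are unit tangents
    times amplitude before noise).
    """

    dims: tuple[int, int, int] = (32, 32, 32)
    n_tracts: int = 6
    control_points_per_curve: int = 5
    radius_range: tuple[float, float] = (1.5, 3.0)
    noise_sigma: float = 0.05
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_tracts < 1:
            raise ValueError("n_tracts must be >= 1")
        if self.control_points_per_curve < 4:
            raise ValueError("control_points_per_curve must be >= 4")
        if self.radius_range[0] < 1.0:
            raise ValueError("minimum tube radius must be >= 1 voxel")
        if self.radius_range[1] < self.radius_range[0]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


class TractCurve:
    """A composite cubic curve through control points, with a tube radius.

    The curve is the natural cubic spline interpolating the control points
    (a chain of cubic segments, smooth and with cheap analytic tangents).
    """

    def __init__(self, control_points: np.ndarray, radius: float):
        pts = np.asarray(control_points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
            raise ValueError("need at least 4 control points of dimension 3")
        self.control_points = pts
        self.radius = float(radius)
        t = np.arange(pts.shape[0], dtype=np.float64)
        self._spline = CubicSpline(t, pts, axis=0)
        self._tmax = float(t[-1])

    def sample(self, max_spacing: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
        """Return (points, unit tangents) along the discretized curve with
        arc spacing no larger than ``max_spacing`` voxels."""
        # coarse pass to estimate arc length, then uniform refinement
        t0 = np.linspace(0.0, self._tmax, 8 * self.control_points.shape[0])
        seg = np.linalg.norm(np.diff(self._spline(t0), axis=0), axis=1)
        length = float(seg.sum())
        n = max(int(np.ceil(length / max_spacing)) + 1, 2)
        t = np.linspace(0.0, self._tmax, n)
        pts = self._spline(t)
        tan = self._spline(t, 1)
        norms = np.linalg.norm(tan, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return pts, tan / norms


def sample_tract_curve(spec: PhantomSpec, rng: np.random.Generator) -> TractCurve:
    """Draw one random tube: radius uniform in radius_range, control points
    uniform inside the volume with a margin of the sampled radius."""
    radius = float(rng.uniform(*spec.radius_range))
    lo = radius
    his = [d - 1 - radius for d in spec.dims]
    if any(hi < lo for hi in his):
        raise ValueError(
            f"dims {spec.dims} too small for tube radius {radius:.2f}")
    pts = np.column_stack([
        rng.uniform(lo, hi, size=spec.control_points_per_curve) for hi in his])
    return TractCurve(pts, radius)


def rasterize_tract(curve: TractCurve, radius: float,
                    dims: Sequence[int]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelize a tube around the curve.

    A voxel is set iff its center lies within ``radius`` of the discretized
    curve polyline. Returns (binary mask, tangent field); the tangent at a
    set voxel is the curve's unit tangent at the nearest curve sample.
    """
    dims = tuple(int(d) for d in dims)
    pts, tans = curve.sample(max_spacing=0.25)
    tree = cKDTree(pts)
    # restrict the query to the tube's bounding box
    lo = np.maximum(np.floor(pts.min(axis=0) - radius - 1), 0).astype(int)
    hi = np.minimum(np.ceil(pts.max(axis=0) + radius + 1) + 1,
                    dims).astype(int)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    vox = np.stack([g.ravel() for g in grids], axis=1)
    mask = np.zeros(dims, dtype=bool)
    tangent = np.zeros(dims + (3,), dtype=np.float32)
    if vox.size == 0:
        return mask, tangent
    dist, idx = tree.query(vox.astype(np.float64), workers=1)
    inside = dist <= radius
    vi = vox[inside]
    mask[vi[:, 0], vi[:, 1], vi[:, 2]] = True
    tangent[vi[:, 0], vi[:, 1], vi[:, 2]] = tans[idx[inside]]
    return mask, tangent


@dataclass
class Phantom:
    """A synthetic peak volume with its paired ground truth and provenance."""

    peaks: PeakVolume
    labels: TractLabelVolume
    curves: list[TractCurve] = field(default_factory=list)

    def provenance(self) -> dict:
        return {
            "curves": [
                {"control_points": c.control_points.tolist(), "radius": c.radius}
                for c in self.curves
            ],
        }


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one phantom volume deterministically from ``spec.seed``.

    Peak slots are filled in ascending tract-index order; a voxel covered by
    more than three tracts keeps the three lowest tract indices in its peak
    slots while its label channels record every covering tract.
    """
    rng = np.random.default_rng(spec.seed)
    dims = tuple(int(d) for d in spec.dims)
    labels = np.zeros(dims + (spec.n_tracts,), dtype=np.uint8)
    peaks = np.zeros(dims + (9,), dtype=np.float32)
    slot_count = np.zeros(dims, dtype=np.int8)
    curves = []
    for t in range(spec.n_tracts):
        curve = sample_tract_curve(spec, rng)
        curves.append(curve)
        mask, tangent = rasterize_tract(curve, curve.radius, dims)
        labels[..., t][mask] = 1
        free = mask & (slot_count < 3)
        slots = slot_count[free]
        vi = np.nonzero(free)
        vecs = tangent[free] * spec.amplitude
        for s in range(3):
            sel = slots == s
            if sel.any():
                peaks[vi[0][sel], vi[1][sel], vi[2][sel], 3 * s:3 * s + 3] = vecs[sel]
        slot_count[free] += 1
    if spec.noise_sigma > 0:
        fg = labels.any(axis=-1)
        noise = rng.normal(0.0, spec.noise_sigma,
                           size=(int(fg.sum()), 9)).astype(np.float32)
        peaks[fg] += noise
    return Phantom(
        peaks=PeakVolume(peaks),
        labels=TractLabelVolume(labels),
        curves=curves,
    )
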