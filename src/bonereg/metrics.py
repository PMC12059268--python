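"""Overlap, surface-distance, and intensity evaluation metrics.

DSC (Dice similarity coefficient), MSD (symmetric mean surface distance, mm)
and MSE (mean squared intensity error, HU²) are the three numbers used to
judge a registration: DSC/MSD compare the fixed bone mask with the
nearest-neighbor-resampled moving bone mask, MSE compares voxel intensities
over an evaluation region.

The "surface" of a mask is its set of 6-connectivity boundary voxels at
voxel centers (a true voxel 6-adjacent to a false or outside voxel); volume
edges count as outside, so masks touching the edge still have a surface
there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume import GeometryError, ParameterError


class UndefinedSurfaceError(ParameterError):
    """A surface metric was requested for an empty mask."""


def surface_points(mask):
    """World coordinates (mm) of the 6-connectivity boundary voxels."""
    if not mask.data.any():
        raise UndefinedSurfaceError("empty mask has no surface")
    # erode with the 6-neighborhood; border_value=0 makes volume edges surface
    interior = ndimage.binary_erosion(
        mask.data, structure=ndimage.generate_binary_structure(3, 1),
        border_value=0,
    )
    boundary = mask.data & ~interior
    return mask.index_to_world(np.argwhere(boundary).astype(float))


def dsc(x, y):
    """Dice similarity coefficient ``2|X∩Y| / (|X|+|Y|)``; both empty -> 1."""
    if x.shape != y.shape or not x.same_grid(y):
        raise GeometryError("masks must share a grid")
    nx, ny = int(x.data.sum()), int(y.data.sum())
    if nx + ny == 0:
        return 1.0
    inter = int((x.data & y.data).sum())
    return 2.0 * inter / (nx + ny)


def msd(x, y):
    """Symmetric mean surface distance in mm.

    ``(Σ_p d(p, S') + Σ_p' d(p', S)) / (nS + nS')`` over the two surface
    point sets, with nearest-neighbor Euclidean distances in physical space.
    """
    if x.shape != y.shape or not x.same_grid(y):
        raise GeometryError("masks must share a grid")
    sx, sy = surface_points(x), surface_points(y)
    dx = cKDTree(sy).query(sx, k=1)[0]
    dy = cKDTree(sx).query(sy, k=1)[0]
    return float((dx.sum() + dy.sum()) / (len(sx) + len(sy)))


def mse(fixed, registered, region=None):
    """Mean squared intensity difference (HU²) over ``region``."""
    if fixed.shape != registered.shape or not fixed.same_grid(registered):
        raise GeometryError("images must share a grid")
    if region is None:
        sel = np.ones(fixed.shape, dtype=bool)
    else:
        if region.shape != fixed.shape:
            raise GeometryError("region must share the image grid")
        sel = region.data
        if not sel.any():
            raise ParameterError("empty evaluation region")
    d = fixed.data[sel].astype(np.float64) - registered.data[sel].astype(np.float64)
    return float(d @ d / d.size)


@dataclass
class MetricReport:
    """Mean ± sample SD of DSC, MSD, MSE per bone across cases."""

    per_bone: dict = field(default_factory=dict)  # bone -> {metric: (mean, sd, n)}
    grand: dict = field(default_factory=dict)     # metric -> (mean, sd, n)

    def to_dict(self):
        return {"per_bone": self.per_bone, "grand": self.grand}


def _mean_sd(vals):
    v = np.asarray(vals, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return mean, sd, len(v)


def summarize(reports):
    """Aggregate per-bone metric dicts into a :class:`MetricReport`.

    ``reports`` is an iterable of dicts with keys ``bone``, ``dsc``, ``msd``,
    ``mse``.  SD uses the n-1 denominator; single-case bones report SD 0
    with n = 1.
    """
    reports = list(reports)
    if not reports:
        raise ParameterError("need at least one report")
    out = MetricReport()
    bones = sorted({r["bone"] for r in reports})
    for bone in bones:
        sel = [r for r in reports if r["bone"] == bone]
        out.per_bone[bone] = {
            m: _mean_sd([r[m] for r in sel]) for m in ("dsc", "msd", "mse")
        }
    for m in ("dsc", "msd", "mse"):
        out.grand[m] = _mean_sd([r[m] for r in reports])
    return out
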