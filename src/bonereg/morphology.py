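"""Binary-mask operations: slice-wise dilation, components, boxes, masking.

The registration pipeline never needs general mathematical morphology — only
the handful of mask operations used to build metric masks (slice-wise
circular dilation), resolve bone instances (largest connected components),
and crop around a bone (bounding boxes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import GeometryError, ImageVolume, LabelMap, ParameterError


class EmptyMaskError(ParameterError):
    pass


@dataclass
class BinaryMask:
    """3D boolean mask sharing the grid of a companion image."""

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data).astype(bool)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)

    @classmethod
    def from_volume(cls, vol, data=None):
        d = vol.data.astype(bool) if data is None else data
        return cls(d, vol.spacing, vol.origin, vol.direction)

    @property
    def shape(self):
        return self.data.shape

    def count(self):
        return int(self.data.sum())

    def index_to_world(self, idx):
        return ImageVolume.index_to_world(self, idx)

    def world_to_index(self, pts):
        return ImageVolume.world_to_index(self, pts)

    def same_grid(self, other, atol=1e-6):
        return ImageVolume.same_grid(self, other, atol=atol)

    def centroid_world(self):
        """Centroid (mm) of the true voxels."""
        if not self.data.any():
            raise EmptyMaskError("empty mask has no centroid")
        idx = np.argwhere(self.data)
        return self.index_to_world(idx.mean(axis=0))


@dataclass(frozen=True)
class BoundingBox:
    """Inclusive voxel-index box [lower, upper]."""

    lower: tuple
    upper: tuple

    def __post_init__(self):
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if np.any(lo > up):
            raise ParameterError(f"invalid box: lower {lo} > upper {up}")

    @property
    def shape(self):
        return tuple(np.asarray(self.upper) - np.asarray(self.lower) + 1)


def disk_offsets(radius):
    """Integer offsets of the discrete disk {(dx,dy): dx²+dy² ≤ r²}."""
    r = int(radius)
    dx, dy = np.meshgrid(np.arange(-r, r + 1), np.arange(-r, r + 1), indexing="ij")
    keep = dx * dx + dy * dy <= r * r
    return dx[keep], dy[keep]


def dilate_slicewise(mask, radius):
    """Dilate each axial (axis-2) slice with a circular kernel of ``radius``.

    Slices are dilated independently — the structuring element is flat along
    the third axis, so no voxel couples across slices.  The disk is the
    standard discrete ball {(dx,dy): dx²+dy² ≤ r²}, center included.
    """
    if radius < 0:
        raise ParameterError("dilation radius must be >= 0")
    r = int(radius)
    if r == 0 or not mask.data.any():
        return BinaryMask(mask.data.copy(), mask.spacing, mask.origin, mask.direction)
    # Equivalent to binary dilation with the disk, via a slice-wise distance
    # transform: a voxel is set iff some true voxel of its own slice lies
    # within Euclidean distance r.  The huge z sampling decouples slices.
    d2 = ndimage.distance_transform_edt(
        ~mask.data, sampling=(1.0, 1.0, 1e12), return_distances=True
    )
    out = d2 <= r
    return BinaryMask(out, mask.spacing, mask.origin, mask.direction)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def connected_components(data, connectivity=26):
    """Label 26-connected components; returns (labels, sizes sorted spec)."""
    structure = _CONN26 if connectivity == 26 else None
    return ndimage.label(data, structure=structure)


def keep_largest_components(labels, k=2):
    """Keep only the ``k`` largest 26-connected components of each label.

    Mirrors the segmentation post-processing that retains the two largest
    components per bone label (one per leg).  Ties at rank ``k`` are broken
    toward the component whose minimum linear voxel index is smallest, which
    is deterministic and independent of the labeling implementation.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    out = np.zeros_like(labels.data)
    for lab in np.unique(labels.data):
        if lab == 0:
            continue
        comp, n = connected_components(labels.data == lab)
        if n <= k:
            out[comp > 0] = lab
            continue
        sizes = ndimage.sum_labels(np.ones_like(comp), comp, index=np.arange(1, n + 1))
        # tie-break: smaller minimum linear index wins
        flat = comp.ravel()
        first = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.flatnonzero(flat)
        np.minimum.at(first, flat[nz], nz)
        order = sorted(range(1, n + 1), key=lambda c: (-sizes[c - 1], first[c]))
        keep = set(order[:k])
        sel = np.isin(comp, list(keep))
        out[sel] = lab
    return LabelMap(
        out, labels.spacing, labels.origin, labels.direction,
        label_names=dict(labels.label_names),
    )


def bounding_box(mask, padding=0):
    """Tightest box around the true voxels, expanded by ``padding`` voxels.

    The expanded box is clamped to the array extent.
    """
    if not mask.data.any():
        raise EmptyMaskError("cannot bound an empty mask")
    idx = np.argwhere(mask.data)
    lower = np.maximum(idx.min(axis=0) - padding, 0)
    upper = np.minimum(idx.max(axis=0) + padding, np.array(mask.shape) - 1)
    return BoundingBox(tuple(int(v) for v in lower), tuple(int(v) for v in upper))


def zero_outside_mask(img, mask):
    """Set voxels outside ``mask`` to 0 HU; leaves the rest untouched."""
    if img.shape != mask.shape or not img.same_grid(mask):
        raise GeometryError("image and mask must share a grid")
    out = np.where(mask.data, img.data, 0.0).astype(img.data.dtype)
    return img.with_data(out)


def crop_mask(mask, box):
    """Crop a BinaryMask to an inclusive index box (clamped), updating origin."""
    lower = np.maximum(np.asarray(box.lower, dtype=int), 0)
    upper = np.minimum(np.asarray(box.upper, dtype=int), np.array(mask.shape) - 1)
    if np.any(lower > upper):
        raise ParameterError(f"empty crop box {box}")
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(lower, upper))
    new_origin = mask.index_to_world(lower)
    return BinaryMask(mask.data[sl].copy(), mask.spacing, new_origin, mask.direction)
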