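"""Image volumes, grid geometry, file I/O, and resampling.

The data model is deliberately small: a 3D scalar grid (:class:`ImageVolume`)
or integer grid (:class:`LabelMap`) together with its physical geometry —
per-axis spacing in mm, an origin in mm, and a 3x3 orthonormal direction
matrix.  Voxel indices are 0-based ``(i, j, k)`` with axis 2 the axial
(superior-inferior) direction for the lower-limb phantoms; world coordinates
follow the usual medical-imaging convention

    world = origin + direction @ (spacing * index).

Resampling supports the three interpolators the registration pipeline needs:
nearest neighbor (for label maps), trilinear (during metric evaluation), and
Lanczos windowed sinc (for the final high-quality resampling of CT images).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates


class BoneregError(Exception):
    """Base class for errors raised by this package."""


class GeometryError(BoneregError):
    """Inconsistent or invalid grid geometry."""


class FormatError(BoneregError):
    """Unsupported or malformed image file."""


class ParameterError(BoneregError):
    """Invalid parameter value."""


_SUPPORTED_EXT = (".nii", ".nii.gz", ".mhd", ".mha")


def _check_geometry(data, spacing, origin, direction):
    if data.ndim != 3:
        raise FormatError(f"expected 3D data, got {data.ndim}D")
    spacing = np.asarray(spacing, dtype=float)
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    if spacing.shape != (3,) or origin.shape != (3,) or direction.shape != (3, 3):
        raise GeometryError("spacing/origin must be 3-vectors, direction 3x3")
    if np.any(spacing <= 0):
        raise GeometryError(f"spacing must be positive, got {spacing}")
    if not np.allclose(direction @ direction.T, np.eye(3), atol=1e-6):
        raise GeometryError("direction matrix must be orthonormal")
    return spacing, origin, direction


@dataclass
class ImageVolume:
    """A 3D scalar image (Hounsfield units) with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values in HU.  Stored as float32 unless already floating.
    spacing : array-like of 3 floats
        Voxel size in mm along each index axis.
    origin : array-like of 3 floats
        World position (mm) of voxel (0, 0, 0).
    direction : (3, 3) array-like
        Orthonormal matrix mapping index axes to world axes.
    """

    data: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(np.float32)
        self.spacing, self.origin, self.direction = _check_geometry(
            self.data, self.spacing, self.origin, self.direction
        )
        if not np.all(np.isfinite(self.data)):
            raise FormatError("image contains non-finite values")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def index_to_world(self, idx):
        """Map (possibly fractional) voxel indices to world mm.

        ``idx`` has shape (..., 3); returns the same shape.
        """
        idx = np.asarray(idx, dtype=float)
        return (self.direction @ (idx * self.spacing)[..., None])[..., 0] + self.origin

    def world_to_index(self, pts):
        """Map world points (mm) to continuous voxel indices."""
        pts = np.asarray(pts, dtype=float)
        return (self.direction.T @ (pts - self.origin)[..., None])[..., 0] / self.spacing

    def grid_world_points(self):
        """World coordinates of every voxel center, shape (nx, ny, nz, 3)."""
        idx = np.stack(
            np.meshgrid(*[np.arange(n) for n in self.shape], indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)

    def same_grid(self, other, atol=1e-6):
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    def with_data(self, data):
        """Same geometry, new voxel values."""
        return replace(self, data=np.asarray(data))


@dataclass
class LabelMap(ImageVolume):
    """Integer-valued volume; 0 is background, labels name bone types."""

    label_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise FormatError("label map requires integer values")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise FormatError("label values must be non-negative")
        self.spacing, self.origin, self.direction = _check_geometry(
            self.data, self.spacing, self.origin, self.direction
        )


@dataclass(frozen=True)
class Interpolator:
    """Interpolation scheme: 'nearest', 'linear', or 'lanczos_windowed_sinc'.

    ``lanczos_radius`` is the window half-width in voxels (3 lobes by
    default, the common choice; small enough relative to the 3 mm slice
    spacing of the target data).
    """

    kind: str = "linear"
    lanczos_radius: int = 3

    def __post_init__(self):
        if self.kind not in ("nearest", "linear", "lanczos_windowed_sinc"):
            raise ParameterError(f"unknown interpolator {self.kind!r}")
        if self.lanczos_radius < 1:
            raise ParameterError("lanczos radius must be >= 1")


NEAREST = Interpolator("nearest")
LINEAR = Interpolator("linear")
LANCZOS = Interpolator("lanczos_windowed_sinc")

#: Out-of-domain fill: air for CT images, background for label maps.
AIR_HU = -1024.0


# -- file I/O ---------------------------------------------------------------

def _sitk():
    import SimpleITK as sitk

    return sitk


def load_volume(path):
    """Load a NIfTI or MetaImage file as :class:`ImageVolume` or :class:`LabelMap`.

    Files with an integer pixel type are returned as :class:`LabelMap`;
    anything else as :class:`ImageVolume`.  Geometry round-trips exactly
    through :func:`save_volume`.
    """
    sitk = _sitk()
    path = os.fspath(path)
    if not any(path.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(f"unsupported file extension: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # sitk raises RuntimeError
        raise FormatError(f"cannot read {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected 3D image, got {img.GetDimension()}D")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(np.transpose(arr, (2, 1, 0)))
    spacing = np.array(img.GetSpacing())
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(3, 3)
    if np.issubdtype(data.dtype, np.integer):
        return LabelMap(data, spacing, origin, direction)
    return ImageVolume(data, spacing, origin, direction)


def save_volume(vol, path):
    """Write a volume to NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha)."""
    sitk = _sitk()
    path = os.fspath(path)
    if not any(path.endswith(e) for e in _SUPPORTED_EXT):
        raise FormatError(f"unsupported file extension: {path}")
    data = vol.data
    if isinstance(vol, LabelMap):
        data = data.astype(np.uint8 if data.max() < 256 else np.int32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    img.SetDirection(tuple(float(d) for d in vol.direction.ravel()))
    sitk.WriteImage(img, path)


# -- intensity ---------------------------------------------------------------

def rescale_intensity(img, lo=-500.0, hi=3000.0):
    """Affinely map HU range [lo, hi] to [0, 1], clipping outside values."""
    if hi <= lo:
        raise ParameterError(f"need hi > lo, got [{lo}, {hi}]")
    out = np.clip((img.data - lo) / (hi - lo), 0.0, 1.0)
    return img.with_data(out.astype(np.float32))


# -- resampling --------------------------------------------------------------

try:  # fused affine + interpolation kernel for whole-grid resampling
    from numba import njit as _njit

    @_njit(cache=True)
    def _affine_sample_kernel(data, M, v, out, order, a, fill):
        nx, ny, nz = data.shape
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                for k in range(out.shape[2]):
                    x = M[0, 0] * i + M[0, 1] * j + M[0, 2] * k + v[0]
                    y = M[1, 0] * i + M[1, 1] * j + M[1, 2] * k + v[1]
                    z = M[2, 0] * i + M[2, 1] * j + M[2, 2] * k + v[2]
                    if (x < 0.0 or x > nx - 1 or y < 0.0 or y > ny - 1
                            or z < 0.0 or z > nz - 1):
                        out[i, j, k] = fill
                        continue
                    if order == 0:
                        out[i, j, k] = data[
                            int(np.floor(x + 0.5)), int(np.floor(y + 0.5)),
                            int(np.floor(z + 0.5))]
                    elif order == 1:
                        ix = min(int(x), nx - 2)
                        iy = min(int(y), ny - 2)
                        iz = min(int(z), nz - 2)
                        fx = x - ix
                        fy = y - iy
                        fz = z - iz
                        c00 = data[ix, iy, iz] * (1 - fx) + data[ix + 1, iy, iz] * fx
                        c10 = data[ix, iy + 1, iz] * (1 - fx) + data[ix + 1, iy + 1, iz] * fx
                        c01 = data[ix, iy, iz + 1] * (1 - fx) + data[ix + 1, iy, iz + 1] * fx
                        c11 = data[ix, iy + 1, iz + 1] * (1 - fx) + data[ix + 1, iy + 1, iz + 1] * fx
                        out[i, j, k] = ((c00 * (1 - fy) + c10 * fy) * (1 - fz)
                                        + (c01 * (1 - fy) + c11 * fy) * fz)
                    else:  # Lanczos windowed sinc, window half-width a
                        bx = int(np.floor(x))
                        by = int(np.floor(y))
                        bz = int(np.floor(z))
                        wx = np.empty(2 * a)
                        wy = np.empty(2 * a)
                        wz = np.empty(2 * a)
                        sx = sy = sz = 0.0
                        for t in range(2 * a):
                            off = t + 1 - a
                            d = off - (x - bx)
                            if d == 0.0:
                                wx[t] = 1.0
                            elif abs(d) >= a:
                                wx[t] = 0.0
                            else:
                                pd = np.pi * d
                                wx[t] = (np.sin(pd) / pd) * (np.sin(pd / a) / (pd / a))
                            d = off - (y - by)
                            if d == 0.0:
                                wy[t] = 1.0
                            elif abs(d) >= a:
                                wy[t] = 0.0
                            else:
                                pd = np.pi * d
                                wy[t] = (np.sin(pd) / pd) * (np.sin(pd / a) / (pd / a))
                            d = off - (z - bz)
                            if d == 0.0:
                                wz[t] = 1.0
                            elif abs(d) >= a:
                                wz[t] = 0.0
                            else:
                                pd = np.pi * d
                                wz[t] = (np.sin(pd) / pd) * (np.sin(pd / a) / (pd / a))
                            sx += wx[t]
                            sy += wy[t]
                            sz += wz[t]
                        acc = 0.0
                        for ti in range(2 * a):
                            gi = min(max(bx + ti + 1 - a, 0), nx - 1)
                            for tj in range(2 * a):
                                gj = min(max(by + tj + 1 - a, 0), ny - 1)
                                wij = wx[ti] * wy[tj]
                                for tk in range(2 * a):
                                    gk = min(max(bz + tk + 1 - a, 0), nz - 1)
                                    acc += wij * wz[tk] * data[gi, gj, gk]
                        out[i, j, k] = acc / (sx * sy * sz)

except ImportError:  # pragma: no cover
    _affine_sample_kernel = None

def _lanczos_kernel(t, a):
    """Normalized sinc window: L(t) = sinc(t)·sinc(t/a) for |t| < a."""
    out = np.where(np.abs(t) < a, np.sinc(t) * np.sinc(t / a), 0.0)
    return out


def _resample_lanczos(data, coords, a, default_value):
    """Separable Lanczos interpolation at continuous index ``coords`` (3, n).

    Per-axis weights are normalized to sum to one so constant regions are
    reproduced exactly; taps falling past the array edge replicate the edge
    sample, while query points outside the grid return ``default_value``.
    """
    n = coords.shape[1]
    shape = data.shape
    inside = np.ones(n, dtype=bool)
    for ax in range(3):
        inside &= (coords[ax] >= 0) & (coords[ax] <= shape[ax] - 1)
    base = np.floor(coords).astype(np.int64)
    frac = coords - base
    taps = np.arange(1 - a, a + 1)  # 2a taps per axis
    w = []
    for ax in range(3):
        wa = _lanczos_kernel(taps[:, None] - frac[ax][None, :], a)
        wa /= wa.sum(axis=0, keepdims=True)
        w.append(wa)
    acc = np.zeros(n, dtype=np.float64)
    flat = data.ravel()
    stride = np.array([shape[1] * shape[2], shape[2], 1], dtype=np.int64)
    idx_ax = [
        np.clip(base[ax][None, :] + taps[:, None], 0, shape[ax] - 1) for ax in range(3)
    ]
    for ti in range(2 * a):
        ix = idx_ax[0][ti] * stride[0]
        wx = w[0][ti]
        for tj in range(2 * a):
            ixy = ix + idx_ax[1][tj] * stride[1]
            wxy = wx * w[1][tj]
            for tk in range(2 * a):
                acc += (wxy * w[2][tk]) * flat[ixy + idx_ax[2][tk] * stride[2]]
    acc[~inside] = default_value
    return acc


def interpolate_at_indices(vol, coords, interp, default_value):
    """Sample ``vol`` at continuous index coordinates ``coords`` (3, n)."""
    if interp.kind == "lanczos_windowed_sinc":
        return _resample_lanczos(
            vol.data.astype(np.float64), coords, interp.lanczos_radius, default_value
        )
    order = 0 if interp.kind == "nearest" else 1
    return map_coordinates(
        vol.data.astype(np.float64) if order else vol.data,
        coords,
        order=order,
        mode="grid-constant" if order == 0 else "constant",
        cval=default_value,
        prefilter=False,
    )


def sample_at_world(vol, pts, interp, default_value):
    """Sample ``vol`` at world points (n, 3) mm."""
    coords = np.ascontiguousarray(vol.world_to_index(pts).T)
    return interpolate_at_indices(vol, coords, interp, default_value)


def resample(moving, reference, transform=None, interp=LINEAR, default_value=None):
    """Resample ``moving`` onto the grid of ``reference`` under a rigid map.

    ``transform`` maps FIXED (reference) physical points to MOVING physical
    points; values are "pulled" onto the reference grid.  Points landing
    outside the moving extent receive ``default_value`` (air for images,
    0 for label maps).  Label maps are always resampled nearest-neighbor.
    """
    if default_value is None:
        default_value = 0.0 if isinstance(moving, LabelMap) else AIR_HU
    if isinstance(moving, LabelMap):
        interp = NEAREST
    if _affine_sample_kernel is not None:
        # fold reference-grid -> world -> rigid map -> moving-index into one
        # affine map and sample in a single pass
        A_ref = reference.direction * reference.spacing[None, :]
        if transform is None:
            R, shift = np.eye(3), np.zeros(3)
        else:
            R = transform.rotation.as_matrix()
            shift = transform.center + transform.translation - R @ transform.center
        A_mv = moving.direction.T / moving.spacing[:, None]
        M = A_mv @ R @ A_ref
        v = A_mv @ (R @ reference.origin + shift - moving.origin)
        order = {"nearest": 0, "linear": 1, "lanczos_windowed_sinc": 2}[interp.kind]
        out_data = np.empty(reference.shape, dtype=np.float64)
        _affine_sample_kernel(
            np.ascontiguousarray(moving.data), M, v, out_data, order,
            interp.lanczos_radius, float(default_value),
        )
    else:
        pts = reference.grid_world_points().reshape(-1, 3)
        if transform is not None:
            pts = transform.apply(pts)
        vals = sample_at_world(moving, pts, interp, default_value)
        out_data = vals.reshape(reference.shape)
    if isinstance(moving, LabelMap):
        out = LabelMap(
            out_data.astype(moving.data.dtype),
            reference.spacing,
            reference.origin,
            reference.direction,
            label_names=dict(moving.label_names),
        )
    else:
        dtype = np.float64 if moving.data.dtype == np.float64 else np.float32
        out = ImageVolume(
            out_data.astype(dtype),
            reference.spacing,
            reference.origin,
            reference.direction,
        )
    return out


def crop(vol, box):
    """Extract the inclusive index bounding ``box``, preserving world geometry.

    The box is clamped to the array extent (dilation near volume edges can
    push boxes out of bounds); an empty clamped box is an error.  The output
    origin is the world position of the box's lower corner, so physical
    coordinates of retained voxels are unchanged.
    """
    lower = np.maximum(np.asarray(box.lower, dtype=int), 0)
    upper = np.minimum(np.asarray(box.upper, dtype=int), np.array(vol.shape) - 1)
    if np.any(lower > upper):
        raise ParameterError(f"empty crop box {box}")
    sl = tuple(slice(lo, hi + 1) for lo, hi in zip(lower, upper))
    new_origin = vol.index_to_world(lower)
    if isinstance(vol, LabelMap):
        return LabelMap(
            vol.data[sl].copy(), vol.spacing, new_origin, vol.direction,
            label_names=dict(vol.label_names),
        )
    return ImageVolume(vol.data[sl].copy(), vol.spacing, new_origin, vol.direction)
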