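"""Shared fixtures: small synthetic volumes and brute-force oracle helpers.

Oracles here are deliberately naive (per-voxel loops, exhaustive scans,
flood fill) so they stay independent of the vectorized implementations they
check.
"""

import numpy as np
import pytest

from bonereg.morphology import BinaryMask
from bonereg.phantom import (
    BoneGeometry,
    FocalChange,
    HUModel,
    PhantomSpec,
    generate,
)
from bonereg.registration import RigidTransform
from bonereg.volume import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_volume(rng, shape=(16, 16, 16), spacing=(0.9, 0.9, 3.0)):
    """Smooth random image so interpolation comparisons are well-conditioned."""
    from scipy.ndimage import gaussian_filter

    data = gaussian_filter(rng.normal(size=shape), 1.5) * 500.0
    return ImageVolume(data.astype(np.float64), np.asarray(spacing),
                       rng.uniform(-10, 10, 3), np.eye(3))


def random_rigid(rng, center=(5.0, 5.0, 10.0), max_deg=15.0, max_mm=5.0):
    from scipy.spatial.transform import Rotation

    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(0, max_deg))
    return RigidTransform(Rotation.from_rotvec(axis * ang),
                          rng.uniform(-max_mm, max_mm, 3),
                          np.asarray(center, float))


def brute_force_trilinear(vol, pts, default):
    """Per-point trilinear interpolation written as an explicit loop."""
    out = np.empty(len(pts))
    nx, ny, nz = vol.shape
    for n, p in enumerate(pts):
        c = vol.world_to_index(p)
        if np.any(c < 0) or c[0] > nx - 1 or c[1] > ny - 1 or c[2] > nz - 1:
            out[n] = default
            continue
        i, j, k = (min(int(np.floor(c[a])), s - 2)
                   for a, s in zip(range(3), vol.shape))
        fx, fy, fz = c - (i, j, k)
        v = 0.0
        for di in (0, 1):
            for dj in (0, 1):
                for dk in (0, 1):
                    w = ((fx if di else 1 - fx) * (fy if dj else 1 - fy)
                         * (fz if dk else 1 - fz))
                    v += w * float(vol.data[i + di, j + dj, k + dk])
        out[n] = v
    return out


def brute_force_dilate(data, radius):
    """Slice-wise disk dilation, one output pixel at a time."""
    out = np.zeros_like(data, dtype=bool)
    r = int(radius)
    nx, ny, nz = data.shape
    offs = [(dx, dy) for dx in range(-r, r + 1) for dy in range(-r, r + 1)
            if dx * dx + dy * dy <= r * r]
    for z in range(nz):
        src = data[:, :, z]
        for x in range(nx):
            for y in range(ny):
                for dx, dy in offs:
                    u, v = x + dx, y + dy
                    if 0 <= u < nx and 0 <= v < ny and src[u, v]:
                        out[x, y, z] = True
                        break
    return out


def flood_fill_components(data):
    """26-connected component labels via explicit BFS."""
    lab = np.zeros(data.shape, dtype=int)
    cur = 0
    for start in zip(*np.nonzero(data)):
        if lab[start]:
            continue
        cur += 1
        stack = [start]
        lab[start] = cur
        while stack:
            x, y, z = stack.pop()
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        u, v, w = x + dx, y + dy, z + dz
                        if (0 <= u < data.shape[0] and 0 <= v < data.shape[1]
                                and 0 <= w < data.shape[2]
                                and data[u, v, w] and not lab[u, v, w]):
                            lab[u, v, w] = cur
                            stack.append((u, v, w))
    return lab, cur


def surface_voxels_bruteforce(data):
    """6-connectivity boundary voxels; outside the grid counts as background."""
    out = []
    nx, ny, nz = data.shape
    for x, y, z in zip(*np.nonzero(data)):
        for dx, dy, dz in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            u, v, w = x + dx, y + dy, z + dz
            if not (0 <= u < nx and 0 <= v < ny and 0 <= w < nz) or not data[u, v, w]:
                out.append((x, y, z))
                break
    return np.array(out, dtype=float)


def single_bone_spec(seed=0, motion=None, noise_sd=20.0, with_lesion=False,
                     axis="z"):
    """A compact one-bone phantom for unit tests.

    ``axis='x'`` lays the capsule horizontally, which breaks its rotational
    symmetry about the volume's axial direction so in-plane rotations are
    observable.
    """
    if axis == "z":
        bone = BoneGeometry("bone", 1, (21.0, 21.0, 24.0), (21.0, 21.0, 96.0),
                            9.0, 3.0)
        shape = (48, 48, 40)
    else:
        bone = BoneGeometry("bone", 1, (15.0, 32.0, 45.0), (93.0, 32.0, 45.0),
                            9.0, 3.0)
        shape = (120, 72, 30)
    lesions = ()
    if with_lesion:
        # off-axis so a control sphere mirrored through the axis is disjoint
        lesions = (FocalChange("bone", (25.5, 21.0, 60.0), 4.0, -400.0),)
    return PhantomSpec(
        shape=shape, bones=(bone,),
        motions={} if motion is None else {"bone": motion},
        hu=HUModel(noise_sd=noise_sd), lesions=lesions, seed=seed,
    )


@pytest.fixture(scope="session")
def small_bone_pair():
    """Noise-on single-bone pair with a known modest motion."""
    from scipy.spatial.transform import Rotation

    motion = RigidTransform(Rotation.from_euler("xyz", [0.02, -0.03, 0.04]),
                            np.array([3.0, -2.0, 4.0]),
                            np.array([21.0, 21.0, 60.0]))
    return generate(single_bone_spec(seed=5, motion=motion)), motion


def bone_mask(labels, label=1):
    return BinaryMask.from_volume(labels, labels.data == label)
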