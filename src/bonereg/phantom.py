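"""Synthetic paired pre/post lower-limb CT phantoms with ground truth.

Long bones are modeled as capsules (cylinders with spherical caps): a
cortical shell at cortical-bone HU around a marrow interior, embedded in a
soft-tissue envelope with air outside.  The post-change volume is generated
analytically in its own frame — bone geometry is carried through a per-bone
rigid motion rather than resampling the pre volume — so registration tests
recover a true geometric motion, not a shared interpolation artifact.
Osteolytic lesions (focal HU decrements) and marrow infiltrate (HU
increments) are carved into the post volume only, and their ground-truth
masks are recorded on both grids.

Default grid: 160x160x120 voxels at 0.9 x 0.9 x 3.0 mm — in-plane and axial
spacings representative of whole-body low-dose CT reconstructions, at a
desk-scale single-leg field of view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .morphology import BinaryMask
from .registration import RigidTransform
from .volume import ImageVolume, LabelMap, ParameterError

log = logging.getLogger("bonereg")

LABEL_NAMES = {1: "femur", 2: "tibia", 3: "fibula"}


@dataclass(frozen=True)
class BoneGeometry:
    """A bowed capsule bone.

    The axis is a shallow arc from ``end_a`` to ``end_b`` with sagitta
    ``bow`` (mm) along ``bow_direction``; long-bone shafts bow by several
    millimetres, and the bow is what makes rotation about the shaft axis
    observable to an intensity metric (a perfectly straight tube is
    rotationally symmetric and its axial twist could never be recovered).
    """

    name: str
    label: int
    end_a: tuple
    end_b: tuple
    radius: float         # outer radius, mm
    cortex: float         # cortical shell thickness, mm
    bow: float = 0.0      # arc sagitta, mm
    bow_direction: tuple = (0.0, 1.0, 0.0)

    def centroid(self):
        return (np.asarray(self.end_a) + np.asarray(self.end_b)) / 2.0

    def axis_nodes(self, n=9):
        """Polyline nodes of the bowed axis (pre frame)."""
        a, b = np.asarray(self.end_a, float), np.asarray(self.end_b, float)
        d = np.asarray(self.bow_direction, float)
        d = d / np.linalg.norm(d)
        t = np.linspace(0.0, 1.0, n)[:, None]
        return a + t * (b - a) + self.bow * np.sin(np.pi * t) * d


@dataclass(frozen=True)
class FocalChange:
    """A spherical HU change in a host bone: lesions carve density out
    (``delta_hu`` < 0), infiltrate adds it (``delta_hu`` > 0)."""

    bone: str
    center: tuple   # mm, pre frame
    radius: float   # mm
    delta_hu: float


@dataclass(frozen=True)
class HUModel:
    """CT value palette (HU), scanner PSF, and noise SD.

    Defaults are representative CT values: dense cortical bone +1200,
    fatty marrow -60, soft tissue +40, air -1024, with 20 HU Gaussian noise
    everywhere (typical low-dose CT noise magnitude).  ``psf_sigma`` is the
    Gaussian point-spread applied to the noiseless geometry on each grid
    (mm): reconstruction-kernel blur in-plane and the slice sensitivity
    profile axially.  Without it the phantom would have infinitely sharp
    edges no scanner produces, and intensity metrics would be dominated by
    grid-phase aliasing instead of alignment.
    """

    cortex: float = 1200.0
    marrow: float = -60.0
    soft_tissue: float = 40.0
    air: float = -1024.0
    noise_sd: float = 20.0
    psf_sigma: tuple = (0.8, 0.8, 2.0)


@dataclass
class PhantomSpec:
    """Declarative description of one pre/post phantom pair."""

    shape: tuple = (160, 160, 120)
    spacing: tuple = (0.9, 0.9, 3.0)
    bones: tuple = ()
    hu: HUModel = field(default_factory=HUModel)
    motions: dict = field(default_factory=dict)   # bone name -> RigidTransform
    lesions: tuple = ()
    infiltrates: tuple = ()
    global_motion: RigidTransform = None
    soft_margin: float = 15.0   # soft-tissue envelope beyond each bone, mm
    seed: int = 0

    def __post_init__(self):
        sp = np.asarray(self.spacing, float)
        if not (np.all(sp[:2] > 0.5) and np.all(sp[:2] < 1.5) and 1.0 < sp[2] < 5.0):
            # loose envelope around whole-body LDCT reconstruction spacings
            raise ParameterError(f"implausible CT spacing {self.spacing}")


@dataclass
class PhantomPair:
    """Generated pre/post volumes, labels, and ground truth."""

    pre: ImageVolume
    pre_labels: LabelMap
    post: ImageVolume
    post_labels: LabelMap
    transforms: dict                  # bone name -> RigidTransform (pre -> post)
    lesion_masks_pre: list            # list of (FocalChange, BinaryMask)
    lesion_masks_post: list
    infiltrate_masks_pre: list
    infiltrate_masks_post: list
    spec: PhantomSpec


def _segment_distance(pts, a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    ab = b - a
    t = np.clip(((pts - a) @ ab) / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(pts - a - t[:, None] * ab, axis=1)


def _polyline_distance(pts, nodes):
    d = _segment_distance(pts, nodes[0], nodes[1])
    for i in range(1, len(nodes) - 1):
        np.minimum(d, _segment_distance(pts, nodes[i], nodes[i + 1]), out=d)
    return d


def _slab(shape, spacing, a, b, reach):
    """Index slab (slices) covering a capsule of radius ``reach`` around
    segment ab, clamped to the grid, plus the slab's world points."""
    lo = np.floor((np.minimum(a, b) - reach) / spacing).astype(int)
    hi = np.ceil((np.maximum(a, b) + reach) / spacing).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape) - 1)
    sl = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
    axes = [np.arange(l, h + 1) * s for l, h, s in zip(lo, hi, spacing)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    return sl, pts


def _rasterize(shape, spacing, bones, transforms, hu, soft_margin):
    """Labels, HU values and cortex/soft masks on the full grid.

    Each capsule's distance field is only evaluated inside its bounding
    slab — everything else is air by construction.
    """
    labels = np.zeros(shape, dtype=np.int32)
    soft = np.zeros(shape, dtype=bool)
    cortex = np.zeros(shape, dtype=bool)
    for bone in bones:
        T = transforms.get(bone.name) if transforms else None
        nodes = bone.axis_nodes()
        if T is not None:
            nodes = T.apply(nodes)
        lo_n, hi_n = nodes.min(axis=0), nodes.max(axis=0)
        sl, pts = _slab(shape, spacing, lo_n, hi_n, bone.radius + soft_margin)
        d = _polyline_distance(pts, nodes).reshape(labels[sl].shape)
        inside = d <= bone.radius
        if np.any(labels[sl][inside] != 0):
            raise ParameterError(f"bone {bone.name} overlaps another bone")
        lab_view = labels[sl]
        lab_view[inside] = bone.label
        cortex[sl] |= inside & (d > bone.radius - bone.cortex)
        soft[sl] |= d <= bone.radius + soft_margin
    values = np.full(shape, hu.air, dtype=np.float64)
    values[soft] = hu.soft_tissue
    values[labels > 0] = hu.marrow
    values[cortex] = hu.cortex
    return labels, values


def generate(spec):
    """Generate a :class:`PhantomPair` from a :class:`PhantomSpec`.

    The pre volume has no lesions or infiltrate; the post volume is the
    analytically moved geometry with focal changes carved in, and each time
    point gets an independent noise realization under the spec seed.
    """
    shape = tuple(spec.shape)
    spacing = np.asarray(spec.spacing, float)

    motions = {}
    for bone in spec.bones:
        local = spec.motions.get(bone.name, RigidTransform.identity(bone.centroid()))
        motions[bone.name] = (
            spec.global_motion.compose(local) if spec.global_motion else local
        )

    pre_lab, pre_hu = _rasterize(shape, spacing, spec.bones, None, spec.hu,
                                 spec.soft_margin)
    post_lab, post_hu = _rasterize(shape, spacing, spec.bones, motions, spec.hu,
                                   spec.soft_margin)

    geom = dict(spacing=spacing, origin=np.zeros(3), direction=np.eye(3))
    by_name = {b.name: b for b in spec.bones}

    def spheres(changes, apply_motion):
        masks = []
        for ch in changes:
            host = by_name[ch.bone]
            c = np.asarray(ch.center, float)
            lab = post_lab if apply_motion else pre_lab
            if apply_motion:
                c = motions[ch.bone].apply(c)
            sl, pts = _slab(shape, spacing, c, c, ch.radius)
            sel = np.zeros(shape, dtype=bool)
            sel[sl] = (
                (np.linalg.norm(pts - c, axis=1) <= ch.radius).reshape(lab[sl].shape)
                & (lab[sl] == host.label)
            )
            if not sel.any():
                raise ParameterError(f"focal change misses its host bone: {ch}")
            masks.append((ch, BinaryMask(sel, **geom)))
        return masks

    lesions_pre = spheres(spec.lesions, apply_motion=False)
    lesions_post = spheres(spec.lesions, apply_motion=True)
    infil_pre = spheres(spec.infiltrates, apply_motion=False)
    infil_post = spheres(spec.infiltrates, apply_motion=True)

    for ch, mask in lesions_post + infil_post:
        post_hu[mask.data] += ch.delta_hu

    if any(s > 0 for s in spec.hu.psf_sigma):
        from scipy.ndimage import gaussian_filter

        sig_vox = np.asarray(spec.hu.psf_sigma, float) / spacing
        pre_hu = gaussian_filter(pre_hu, sigma=sig_vox)
        post_hu = gaussian_filter(post_hu, sigma=sig_vox)

    rng = np.random.default_rng(spec.seed)
    if spec.hu.noise_sd > 0:
        pre_hu = pre_hu + rng.normal(0.0, spec.hu.noise_sd, pre_hu.shape)
        post_hu = post_hu + rng.normal(0.0, spec.hu.noise_sd, post_hu.shape)

    names = {b.label: b.name.split("_")[0] for b in spec.bones}
    return PhantomPair(
        pre=ImageVolume(pre_hu.reshape(shape).astype(np.float32), **geom),
        pre_labels=LabelMap(pre_lab.reshape(shape), label_names=names, **geom),
        post=ImageVolume(post_hu.reshape(shape).astype(np.float32), **geom),
        post_labels=LabelMap(post_lab.reshape(shape), label_names=names, **geom),
        transforms=motions,
        lesion_masks_pre=lesions_pre,
        lesion_masks_post=lesions_post,
        infiltrate_masks_pre=infil_pre,
        infiltrate_masks_post=infil_post,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Single-leg layout on the default 144 x 144 x 360 mm field of view:
#: femur-like shaft above, tibia-like and thin fibula-like shafts below,
#: with clearances sized so the randomized motions cannot collide bones.
DEFAULT_BONES = (
    BoneGeometry("femur", 1, (72.0, 72.0, 220.0), (72.0, 72.0, 325.0), 14.0, 4.0,
                 bow=6.0),
    BoneGeometry("tibia", 2, (50.0, 72.0, 30.0), (50.0, 72.0, 150.0), 11.0, 4.0,
                 bow=4.0),
    BoneGeometry("fibula", 3, (98.0, 72.0, 30.0), (98.0, 72.0, 150.0), 5.0, 2.0,
                 bow=3.0),
)

#: One osteolytic lesion at the femoral cortex/marrow interface (400 HU
#: density drop) and one marrow infiltrate (+100 HU), the phenomenology the
#: difference images are meant to surface.
DEFAULT_LESIONS = (FocalChange("femur", (81.0, 72.0, 270.0), 5.0, -400.0),)
DEFAULT_INFILTRATES = (FocalChange("femur", (72.0, 72.0, 300.0), 6.0, +100.0),)


def random_rigid_motion(rng, center, max_rotation_deg=10.0,
                        max_inplane_mm=7.0, max_axial_mm=15.0):
    """Random per-bone motion: rotation up to ``max_rotation_deg`` about a
    uniform random axis through ``center``, in-plane translation components
    uniform within ±``max_inplane_mm`` and axial within ±``max_axial_mm``
    (total translation norm stays below 20 mm — between-visit repositioning
    of a scanned leg moves mostly along the table axis)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    t = np.array([
        rng.uniform(-max_inplane_mm, max_inplane_mm),
        rng.uniform(-max_inplane_mm, max_inplane_mm),
        rng.uniform(-max_axial_mm, max_axial_mm),
    ])
    return RigidTransform(Rotation.from_rotvec(axis * angle), t,
                          np.asarray(center, float))


def default_spec(seed=0, with_changes=True, motions=None, shape=(160, 160, 120)):
    """The default single-leg phantom pair under randomized motions.

    Motions are redrawn (deterministically under ``seed``) in the rare event
    a draw would collide two bones.
    """
    rng = np.random.default_rng(seed)
    for _attempt in range(20):
        m = motions or {
            b.name: random_rigid_motion(rng, b.centroid()) for b in DEFAULT_BONES
        }
        spec = PhantomSpec(
            shape=shape,
            bones=DEFAULT_BONES,
            motions=m,
            lesions=DEFAULT_LESIONS if with_changes else (),
            infiltrates=DEFAULT_INFILTRATES if with_changes else (),
            seed=seed,
        )
        try:
            _check_disjoint(spec)
            return spec
        except ParameterError:
            if motions is not None:
                raise
            log.warning("phantom seed %d: redrawing colliding motions", seed)
    raise ParameterError(f"could not draw non-colliding motions for seed {seed}")


def _check_disjoint(spec):
    """Cheap analytic collision check on the moved capsule axes."""
    moved = []
    for b in spec.bones:
        T = spec.motions.get(b.name, RigidTransform.identity(b.centroid()))
        moved.append((b, T.apply(b.axis_nodes(n=64))))
    for i in range(len(moved)):
        for j in range(i + 1, len(moved)):
            bi, ni = moved[i]
            bj, nj = moved[j]
            d = _polyline_distance(ni, nj).min()
            if d <= bi.radius + bj.radius:
                raise ParameterError(f"bones {bi.name}/{bj.name} collide (d={d:.1f})")


def default_suite(n_seeds, base_seed=0, **kwargs):
    """The seeded phantom suite: ``n_seeds`` independent pairs."""
    if n_seeds < 1:
        raise ParameterError("need at least one seed")
    return [generate(default_spec(seed=base_seed + i, **kwargs))
            for i in range(n_seeds)]


def mirror_through_axis(bone, point):
    """Reflect a world point through a bone's axis line (for placing control
    regions on the intact side of the cortex)."""
    a = np.asarray(bone.end_a, float)
    b = np.asarray(bone.end_b, float)
    u = (b - a) / np.linalg.norm(b - a)
    p = np.asarray(point, float)
    radial = (p - a) - ((p - a) @ u) * u
    return p - 2.0 * radial


def two_leg_spec(seed=0, shape=(160, 96, 60), motions=None, with_changes=False):
    """A compact six-bone (two-leg) phantom for exercising instance
    splitting and per-patient orchestration.  Left/right bones of a type
    share a label and are separate connected components, as in a real label
    map."""
    bones = []
    for side, xc in (("right", 38.0), ("left", 106.0)):
        bones += [
            BoneGeometry(f"femur_{side}", 1, (xc, 43.0, 105.0), (xc, 43.0, 160.0),
                         13.0, 4.0, bow=4.0),
            BoneGeometry(f"tibia_{side}", 2, (xc - 16.0, 43.0, 15.0),
                         (xc - 16.0, 43.0, 70.0), 10.0, 3.5, bow=3.0),
            BoneGeometry(f"fibula_{side}", 3, (xc + 20.0, 43.0, 15.0),
                         (xc + 20.0, 43.0, 70.0), 5.0, 2.0, bow=2.0),
        ]
    rng = np.random.default_rng(seed)
    if motions is None:
        motions = {
            b.name: random_rigid_motion(rng, b.centroid(), max_rotation_deg=2.0,
                                        max_inplane_mm=2.0, max_axial_mm=4.0)
            for b in bones
        }
    lesions = (FocalChange("femur_left", (112.0, 43.0, 130.0), 5.0, -400.0),) \
        if with_changes else ()
    spec = PhantomSpec(shape=shape, bones=tuple(bones), motions=motions,
                       lesions=lesions, seed=seed)
    _check_disjoint(spec)
    return spec
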