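"""6-DOF rigid registration engine.

Implements the machinery of an intensity-based rigid registration between two
CT volumes: rigid transform algebra (versor or Euler parameterization around
a fixed rotation center), a masked mean-squares metric evaluated at sampled
fixed-image points, regular and random point samplers, a Gaussian
smooth-then-subsample multiresolution pyramid, parameter weighting from
physical shifts, and two optimizers — a Powell direction-set method with
Brent line minimization and a step-capped gradient descent.

Transform convention: a :class:`RigidTransform` maps FIXED physical points to
MOVING physical points, so resampling "pulls" moving values onto the fixed
grid and the recovered transform composes directly with a second-stage
refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .morphology import BinaryMask, EmptyMaskError
from .volume import (
    LANCZOS,
    LINEAR,
    ImageVolume,
    Interpolator,
    ParameterError,
    interpolate_at_indices,
)


class OptimizationError(Exception):
    """Objective became non-finite or diverged during the search."""


try:  # fused transform + trilinear + SSD kernel for the optimizer hot loop
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _ssd_kernel(data, pts, A, b, fvals, fill):
        nx, ny, nz = data.shape
        acc = 0.0
        for i in range(pts.shape[0]):
            x = A[0, 0] * pts[i, 0] + A[0, 1] * pts[i, 1] + A[0, 2] * pts[i, 2] + b[0]
            y = A[1, 0] * pts[i, 0] + A[1, 1] * pts[i, 1] + A[1, 2] * pts[i, 2] + b[1]
            z = A[2, 0] * pts[i, 0] + A[2, 1] * pts[i, 1] + A[2, 2] * pts[i, 2] + b[2]
            if x < 0.0 or x > nx - 1 or y < 0.0 or y > ny - 1 or z < 0.0 or z > nz - 1:
                v = fill
            else:
                ix = int(x)
                iy = int(y)
                iz = int(z)
                if ix > nx - 2:
                    ix = nx - 2
                if iy > ny - 2:
                    iy = ny - 2
                if iz > nz - 2:
                    iz = nz - 2
                fx = x - ix
                fy = y - iy
                fz = z - iz
                c00 = data[ix, iy, iz] * (1 - fx) + data[ix + 1, iy, iz] * fx
                c10 = data[ix, iy + 1, iz] * (1 - fx) + data[ix + 1, iy + 1, iz] * fx
                c01 = data[ix, iy, iz + 1] * (1 - fx) + data[ix + 1, iy, iz + 1] * fx
                c11 = data[ix, iy + 1, iz + 1] * (1 - fx) + data[ix + 1, iy + 1, iz + 1] * fx
                v = (c00 * (1 - fy) + c10 * fy) * (1 - fz) + (c01 * (1 - fy) + c11 * fy) * fz
            d = fvals[i] - v
            acc += d * d
        return acc / pts.shape[0]

except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _ssd_kernel = None


# =====================================================================
# Rigid transforms
# =====================================================================

@dataclass
class RigidTransform:
    """Rigid map ``T(x) = R (x - c) + c + t`` from fixed to moving space.

    ``rotation`` is a :class:`scipy.spatial.transform.Rotation`; ``center``
    is the rotation center in mm (typically the metric-mask centroid, which
    decouples the rotation and translation parameters).
    """

    rotation: Rotation = field(default_factory=Rotation.identity)
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.translation = np.asarray(self.translation, dtype=float)
        self.center = np.asarray(self.center, dtype=float)

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)):
        return cls(Rotation.identity(), np.zeros(3), np.asarray(center, float))

    def apply(self, pts):
        """Apply to world points, shape (..., 3)."""
        pts = np.asarray(pts, dtype=float)
        return (pts - self.center) @ self.rotation.as_matrix().T + (
            self.center + self.translation
        )

    def matrix(self):
        """4x4 homogeneous matrix."""
        R = self.rotation.as_matrix()
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = self.center + self.translation - R @ self.center
        return m

    def compose(self, other):
        """``self ∘ other``: the map x -> self(other(x))."""
        R1, R2 = self.rotation.as_matrix(), other.rotation.as_matrix()
        R = R1 @ R2
        c = other.center
        t = R1 @ (c + other.translation - self.center) + self.center + self.translation - c
        return RigidTransform(Rotation.from_matrix(R), t, c)

    def inverse(self):
        Rinv = self.rotation.inv()
        return RigidTransform(Rinv, -Rinv.apply(self.translation), self.center)

    def recenter(self, new_center):
        """Re-express the same spatial map around a different rotation center."""
        c = np.asarray(new_center, float)
        R = self.rotation.as_matrix()
        t = R @ (c - self.center) - c + self.center + self.translation
        return RigidTransform(self.rotation, t, c)

    # -- parameter vectors ------------------------------------------------
    def parameters(self, parameterization="versor"):
        """6-vector: 3 rotation parameters + 3 translation components (mm)."""
        if parameterization == "versor":
            q = self.rotation.as_quat()  # (x, y, z, w)
            if q[3] < 0:
                q = -q
            rot = q[:3]
        elif parameterization == "euler":
            rot = self.rotation.as_euler("xyz")
        else:
            raise ParameterError(f"unknown parameterization {parameterization!r}")
        return np.concatenate([rot, self.translation])

    @classmethod
    def from_parameters(cls, params, center, parameterization="versor"):
        params = np.asarray(params, dtype=float)
        if parameterization == "versor":
            v = params[:3]
            n2 = v @ v
            if n2 >= 1.0:
                q = np.concatenate([v / math.sqrt(n2), [0.0]])
            else:
                q = np.concatenate([v, [math.sqrt(1.0 - n2)]])
            rot = Rotation.from_quat(q)
        elif parameterization == "euler":
            rot = Rotation.from_euler("xyz", params[:3])
        else:
            raise ParameterError(f"unknown parameterization {parameterization!r}")
        return cls(rot, params[3:6].copy(), np.asarray(center, float))

    def rotation_angle_deg(self):
        return float(np.degrees(np.linalg.norm(self.rotation.as_rotvec())))

    # -- serialization ----------------------------------------------------
    def to_tfm(self, path):
        """Write an ITK-compatible plain-text .tfm transform file."""
        R = self.rotation.as_matrix()
        params = " ".join(f"{v:.17g}" for v in np.r_[R.ravel(), self.translation])
        fixed = " ".join(f"{v:.17g}" for v in self.center)
        with open(path, "w") as fh:
            fh.write(
                "#Insight Transform File V1.0\n"
                "#Transform 0\n"
                "Transform: AffineTransform_double_3_3\n"
                f"Parameters: {params}\n"
                f"FixedParameters: {fixed}\n"
            )

    @classmethod
    def from_tfm(cls, path):
        params = fixed = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("Parameters:"):
                    params = np.array([float(v) for v in line.split(":")[1].split()])
                elif line.startswith("FixedParameters:"):
                    fixed = np.array([float(v) for v in line.split(":")[1].split()])
        if params is None or fixed is None:
            raise ParameterError(f"not a transform file: {path}")
        R = params[:9].reshape(3, 3)
        return cls(Rotation.from_matrix(R), params[9:12], fixed)


# =====================================================================
# Samplers and metric
# =====================================================================

@dataclass
class SamplePointSet:
    """Physical metric sample points (mm) drawn from a mask's true voxels."""

    points: np.ndarray  # (n, 3) mm

    def __len__(self):
        return len(self.points)


def sample_points(mask, strategy="regular", fraction=1.0, seed=0):
    """Draw metric sample points from the true voxels of ``mask``.

    ``regular`` keeps every ceil(1/fraction)-th true voxel in linear (C) scan
    order; ``random`` draws floor(fraction*n) voxels uniformly without
    replacement under ``seed``.  Points are voxel centers in world mm.
    """
    if not (0.0 < fraction <= 1.0):
        raise ParameterError(f"sampling fraction must be in (0, 1], got {fraction}")
    idx = np.argwhere(mask.data)  # C-order == linear scan order
    if len(idx) == 0:
        raise EmptyMaskError("cannot sample from an empty mask")
    if fraction >= 1.0:
        sel = idx
    elif strategy == "regular":
        sel = idx[:: int(math.ceil(1.0 / fraction))]
    elif strategy == "random":
        rng = np.random.default_rng(seed)
        take = max(1, int(math.floor(fraction * len(idx))))
        sel = idx[np.sort(rng.choice(len(idx), size=take, replace=False))]
    else:
        raise ParameterError(f"unknown sampling strategy {strategy!r}")
    return SamplePointSet(mask.index_to_world(sel.astype(float)))


def mean_squares_metric(fixed, moving, transform, pts, interp=LINEAR,
                        default_value=0.0):
    """Masked mean-squares metric (HU²) at sample points ``pts``.

    ``(1/n) Σ (fixed(p) - moving(T(p)))²``; points mapping outside the moving
    extent contribute with ``default_value`` (the pipeline zeroes soft tissue,
    so background level 0 is the natural fill during optimization).
    """
    if len(pts) == 0:
        raise ParameterError("empty sample point set")
    from .volume import sample_at_world

    f = sample_at_world(fixed, pts.points, interp, default_value)
    m = sample_at_world(moving, transform.apply(pts.points), interp, default_value)
    d = f - m
    return float(d @ d / len(d))


# =====================================================================
# Pyramid
# =====================================================================

@dataclass(frozen=True)
class PyramidSchedule:
    """Coarse-to-fine schedule: shrink factors, smoothing sigmas (voxels of
    the full-resolution grid), per-level sampling fraction, per-level
    iteration caps."""

    shrink_factors: tuple = (4, 2, 2, 1)
    smoothing_sigmas: tuple = (4, 2, 2, 1)
    sampling_fraction: tuple = (1.0,)
    iterations: tuple = None

    def __post_init__(self):
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ParameterError("shrink and sigma lists must have equal length")
        if any(s < 1 for s in self.shrink_factors):
            raise ParameterError("shrink factors must be >= 1")
        if any(s < 0 for s in self.smoothing_sigmas):
            raise ParameterError("smoothing sigmas must be >= 0")

    @property
    def n_levels(self):
        return len(self.shrink_factors)

    def fraction_at(self, level):
        f = self.sampling_fraction
        return f[level] if len(f) == self.n_levels else f[0]

    def iterations_at(self, level, default):
        if self.iterations is None:
            return default
        it = self.iterations
        return it[level] if len(it) == self.n_levels else it[0]


def build_pyramid(img, mask, schedule):
    """Per-level (image, mask) pairs: Gaussian-smooth the image with the
    level's sigma (image only, full-resolution voxel units), then subsample
    every s-th voxel with spacing multiplied by s.  The world position of
    voxel (0,0,0) is preserved; masks are subsampled nearest-neighbor and
    never smoothed."""
    if any(s > min(img.shape) for s in schedule.shrink_factors):
        raise ParameterError("shrink factor exceeds a volume dimension")
    levels = []
    for s, sig in zip(schedule.shrink_factors, schedule.smoothing_sigmas):
        data = ndimage.gaussian_filter(img.data, sigma=sig) if sig > 0 else img.data
        sub = data[::s, ::s, ::s]
        lvl_img = ImageVolume(sub.copy(), img.spacing * s, img.origin, img.direction)
        lvl_mask = None
        if mask is not None:
            lvl_mask = BinaryMask(
                mask.data[::s, ::s, ::s].copy(), mask.spacing * s, mask.origin,
                mask.direction,
            )
        levels.append((lvl_img, lvl_mask))
    return levels


# =====================================================================
# Parameter scaling
# =====================================================================

def scales_from_physical_shift(transform, pts, delta=1e-4,
                               parameterization="versor"):
    """Squared physical shift per unit parameter change, per parameter.

    For parameter i, perturb by ``delta`` and take the maximum displacement
    over the sample points; ``scale_i = (shift_i / delta)²``.  Optimizer
    steps are then taken in the rescaled space ``parameter_i * sqrt(scale_i)``
    so a unit step moves every parameter by a comparable physical distance.
    Degenerate parameters (zero shift) are floored at scale 1.
    """
    if len(pts) == 0:
        raise ParameterError("empty sample point set")
    p = np.asarray(pts.points, dtype=float)
    base = transform.apply(p)
    params = transform.parameters(parameterization)
    scales = np.ones(6)
    for i in range(6):
        pp = params.copy()
        pp[i] += delta
        Tp = RigidTransform.from_parameters(pp, transform.center, parameterization)
        shift = np.max(np.linalg.norm(Tp.apply(p) - base, axis=1))
        scales[i] = max((shift / delta) ** 2, 1.0)
    return scales


# =====================================================================
# Optimizers
# =====================================================================

def _scaled(objective, scales):
    root = np.sqrt(np.asarray(scales, dtype=float))

    def f(y):
        v = objective(y / root)
        if not np.isfinite(v):
            raise OptimizationError("objective is non-finite during search")
        return v

    return f, root


def powell_optimize(objective, x0, scales=None, max_iterations=5000,
                    max_line_iterations=500, step_length=1.0,
                    step_tolerance=1e-8, value_tolerance=1e-8,
                    callback=None):
    """Powell direction-set minimization with Brent line searches.

    Runs in the rescaled parameter space defined by ``scales`` (so a unit
    step is a comparable physical shift for every parameter).  Terminates on
    the iteration cap, on the displacement of a full sweep dropping below
    ``step_tolerance``, or on relative value improvement below
    ``value_tolerance``.  Exact (one sweep) for convex quadratics.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    if scales is None:
        scales = np.ones(n)
    f, root = _scaled(objective, scales)
    y = x0 * root
    directions = [np.eye(n)[i] for i in range(n)]
    fval = f(y)
    if callback:
        callback(fval)
    for _ in range(int(max_iterations)):
        y_start, f_start = y.copy(), fval
        biggest_drop, drop_idx = 0.0, 0
        for i, d in enumerate(directions):
            def f1d(alpha, d=d, y=y, f0=fval):
                if alpha == 0.0:
                    return f0
                return f(y + alpha * d)

            alpha, fmin, *_ = optimize.brent(
                f1d, brack=(0.0, step_length), maxiter=int(max_line_iterations),
                full_output=True, tol=1e-8,
            )
            if fmin < fval:
                if fval - fmin > biggest_drop:
                    biggest_drop, drop_idx = fval - fmin, i
                y = y + alpha * d
                fval = fmin
        if callback:
            callback(fval)
        disp = y - y_start
        step = np.linalg.norm(disp)
        # Powell direction replacement (Numerical-Recipes criterion)
        if step > 0:
            f_ext = f(y_start + 2.0 * disp)
            if f_ext < f_start:
                df = f_start - fval
                t = (
                    2.0 * (f_start - 2.0 * fval + f_ext)
                    * (f_start - fval - biggest_drop) ** 2
                    - biggest_drop * (f_start - f_ext) ** 2
                )
                if t < 0:
                    dn = disp / step

                    def f1d(alpha, d=dn, y=y, f0=fval):
                        if alpha == 0.0:
                            return f0
                        return f(y + alpha * d)

                    alpha, fmin, *_ = optimize.brent(
                        f1d, brack=(0.0, step_length),
                        maxiter=int(max_line_iterations), full_output=True,
                        tol=1e-8,
                    )
                    if fmin < fval:
                        y = y + alpha * dn
                        fval = fmin
                    directions[drop_idx] = directions[-1]
                    directions[-1] = dn
        if step <= step_tolerance:
            break
        if 2.0 * (f_start - fval) <= value_tolerance * (abs(f_start) + abs(fval) + 1e-300):
            break
    return y / root, fval


def _window_slope(values, window):
    """Least-squares slope of the trailing window, relative to its mean
    magnitude (an HU²-scale objective never reaches an absolute 1e-6 slope,
    so the convergence threshold is applied to the relative profile)."""
    if len(values) < window:
        return None
    v = np.asarray(values[-window:], dtype=float)
    x = np.arange(window, dtype=float)
    x -= x.mean()
    slope = float((x @ (v - v.mean())) / (x @ x))
    return slope / (abs(v.mean()) + 1e-12)


def gradient_descent_optimize(objective, x0, scales=None, learning_rate=0.1,
                              iterations=1500, convergence_min_value=1e-6,
                              convergence_window=10, max_step=None,
                              relative_step_floor=1e-5, grad_h=1e-4,
                              callback=None):
    """Scaled-space gradient descent with regular-step relaxation.

    The plain update is ``y <- y - learning_rate * grad`` (central finite
    differences with spacing ``grad_h`` in scaled units).  When ``max_step``
    is set, each update's norm is capped at the current step bound; a step
    that fails to decrease the objective is reverted and the bound halved,
    so the iterate settles geometrically below the cap instead of
    oscillating at it.  With ``learning_rate=None`` every accepted step
    moves exactly the current bound along the negative gradient.
    Convergence: the step bound falls below ``relative_step_floor`` times
    ``max_step``, or the least-squares slope of the last
    ``convergence_window`` metric values has magnitude below
    ``convergence_min_value``.  Divergence (value growing 10x over the run)
    aborts with a diagnostic.
    """
    x0 = np.asarray(x0, dtype=float)
    n = len(x0)
    if scales is None:
        scales = np.ones(n)
    f, root = _scaled(objective, scales)
    y = x0 * root
    fval = f(y)
    trace = [fval]
    if callback:
        callback(fval)
    cap = max_step
    for _ in range(int(iterations)):
        g = np.empty(n)
        for i in range(n):
            e = np.zeros(n)
            e[i] = grad_h
            g[i] = (f(y + e) - f(y - e)) / (2.0 * grad_h)
        gn = np.linalg.norm(g)
        if gn == 0.0:
            break
        if learning_rate is None:
            step = -(g / gn) * cap
        else:
            step = -learning_rate * g
            if cap is not None and np.linalg.norm(step) > cap:
                step *= cap / np.linalg.norm(step)
        y_new = y + step
        f_new = f(y_new)
        if cap is not None and f_new >= fval:
            cap *= 0.5  # reverted step: relax the bound
        else:
            y, fval = y_new, f_new
        trace.append(fval)
        if callback:
            callback(fval)
        if fval > 10.0 * trace[0] and fval > 10.0 * min(trace):
            raise OptimizationError("gradient descent diverging")
        if cap is not None and max_step is not None and cap < relative_step_floor * max_step:
            break
        if len(trace) > convergence_window:
            slope = _window_slope(trace, convergence_window)
            if slope is not None and abs(slope) < convergence_min_value:
                break
    return y / root, fval


# =====================================================================
# Configuration and the multiresolution driver
# =====================================================================

@dataclass(frozen=True)
class RegistrationConfig:
    """Full parameterization of one registration run.

    Presets :data:`INITIAL`, :data:`FINAL`, and :data:`BASELINE` mirror the
    three configurations the pipeline uses: the Powell-driven whole-volume
    first phase, the gradient-descent cropped refinement, and the
    single-level gradient-descent reference run.
    """

    parameterization: str = "versor"
    sampler: str = "regular"
    pyramid: PyramidSchedule = PyramidSchedule()
    optimizer: str = "powell"
    optimizer_params: tuple = ()  # tuple of (key, value) pairs; hashable
    final_interpolator: Interpolator = LANCZOS
    metric_fill: float = 0.0
    seed: int = 0

    def opt_params(self):
        return dict(self.optimizer_params)


INITIAL = RegistrationConfig(
    parameterization="versor",
    sampler="regular",
    pyramid=PyramidSchedule(
        shrink_factors=(4, 2, 2, 1),
        smoothing_sigmas=(4, 2, 2, 1),
        sampling_fraction=(0.25, 0.50, 0.75, 1.00),
    ),
    optimizer="powell",
    optimizer_params=(
        ("max_iterations", 5000),
        ("max_line_iterations", 500),
        ("step_length", 1.0),
        ("step_tolerance", 1e-8),
        ("value_tolerance", 1e-8),
    ),
    final_interpolator=LANCZOS,
)

FINAL = RegistrationConfig(
    parameterization="versor",
    sampler="regular",
    pyramid=PyramidSchedule(
        shrink_factors=(8, 4, 2, 1),
        smoothing_sigmas=(3, 2, 1, 0),
        sampling_fraction=(0.35,),
        iterations=(1000, 500, 250, 100),
    ),
    optimizer="gradient_descent",
    optimizer_params=(
        ("learning_rate", None),  # pure maximum-step steps
        ("max_step", 0.1),
        ("convergence_min_value", 1e-6),
        ("convergence_window", 10),
    ),
    final_interpolator=LANCZOS,
)

BASELINE = RegistrationConfig(
    parameterization="euler",
    sampler="random",
    pyramid=PyramidSchedule(
        shrink_factors=(1,), smoothing_sigmas=(0,), sampling_fraction=(0.1,),
        iterations=(1500,),
    ),
    optimizer="gradient_descent",
    optimizer_params=(
        ("learning_rate", 0.1),
        ("max_step", 1.0),  # stabilizes plain descent on an HU² objective
        ("convergence_min_value", 1e-6),
        ("convergence_window", 10),
    ),
    final_interpolator=LINEAR,
)

PRESETS = {"initial": INITIAL, "final": FINAL, "baseline": BASELINE}


@dataclass
class RegistrationReport:
    """Per-level convergence traces and final metric values."""

    levels: list = field(default_factory=list)  # dicts per level
    final_metric: float = float("nan")

    def to_dict(self):
        return {"levels": self.levels, "final_metric": self.final_metric}


def register(fixed, moving, metric_mask, config=INITIAL, T0=None):
    """Multiresolution rigid registration of ``moving`` onto ``fixed``.

    The rotation center is the metric-mask centroid (mm) and is fixed for
    the whole run; each pyramid level is warm-started from the previous
    level's result.  The driver never returns a transform worse than its
    initialization: the start and end parameters are compared under the
    finest-level metric and the better one is kept (coarse levels of an
    already-converged initialization can otherwise wander within their
    smoothed, subsampled objective).  Returns ``(transform, report)``.
    """
    center = metric_mask.centroid_world()
    if T0 is None:
        T = RigidTransform.identity(center)
    else:
        T = T0.recenter(center)
    params = T.parameters(config.parameterization)

    levels = build_pyramid(fixed, metric_mask, config.pyramid)
    moving_levels = build_pyramid(moving, None, config.pyramid)

    # parameter weights from the full-resolution mask support
    all_pts = sample_points(metric_mask, "regular",
                            min(1.0, 5000.0 / max(metric_mask.count(), 1)),
                            seed=config.seed)
    scales = scales_from_physical_shift(
        RigidTransform.from_parameters(params, center, config.parameterization),
        all_pts, parameterization=config.parameterization,
    )

    report = RegistrationReport()
    for lvl, ((fx_img, fx_mask), (mv_img, _)) in enumerate(zip(levels, moving_levels)):
        if not fx_mask.data.any():
            raise EmptyMaskError(
                f"metric mask collapsed at pyramid level {lvl} "
                f"(shrink {config.pyramid.shrink_factors[lvl]})"
            )
        pts = sample_points(
            fx_mask, config.sampler, config.pyramid.fraction_at(lvl),
            seed=config.seed + lvl,
        )
        p = pts.points
        fvals = fx_img.data[tuple(
            np.round(fx_mask.world_to_index(p)).astype(int).T
        )].astype(np.float64)
        mv_data = np.ascontiguousarray(mv_img.data, dtype=np.float32)
        A0 = (mv_img.direction.T / mv_img.spacing[:, None])
        b0 = -A0 @ mv_img.origin
        fill = float(config.metric_fill)
        n_pts = len(p)
        p = np.ascontiguousarray(p)

        def objective(par):
            Tl = RigidTransform.from_parameters(par, center, config.parameterization)
            R = Tl.rotation.as_matrix()
            A = A0 @ R
            b = A0 @ (Tl.center + Tl.translation - R @ Tl.center) + b0
            if _ssd_kernel is not None:
                return _ssd_kernel(mv_data, p, A, b, fvals, fill)
            coords = (p @ A.T + b).T
            mvals = ndimage.map_coordinates(
                mv_data, coords, order=1, mode="constant", cval=fill,
                prefilter=False,
            )
            d = fvals - mvals
            return float(d @ d) / n_pts

        trace = []
        opts = config.opt_params()
        if config.optimizer == "powell":
            opts["max_iterations"] = config.pyramid.iterations_at(
                lvl, opts.get("max_iterations", 5000))
            params, fval = powell_optimize(
                objective, params, scales=scales, callback=trace.append, **opts)
        elif config.optimizer == "gradient_descent":
            opts["iterations"] = config.pyramid.iterations_at(
                lvl, opts.pop("iterations", 1500))
            params, fval = gradient_descent_optimize(
                objective, params, scales=scales, callback=trace.append, **opts)
        else:
            raise ParameterError(f"unknown optimizer {config.optimizer!r}")
        report.levels.append({
            "level": lvl,
            "shrink": int(config.pyramid.shrink_factors[lvl]),
            "n_points": int(n_pts),
            "initial_metric": float(trace[0]) if trace else None,
            "final_metric": float(fval),
            "trace": [float(v) for v in trace],
        })
        report.final_metric = float(fval)

    p0 = T.parameters(config.parameterization)
    if not np.array_equal(p0, params):
        f_start = objective(p0)  # finest-level metric at the initialization
        if f_start < report.final_metric:
            params = p0
            report.final_metric = float(f_start)
            report.levels[-1]["kept_initialization"] = True

    return RigidTransform.from_parameters(params, center, config.parameterization), report
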