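"""Per-bone two-phase registration orchestration and temporal subtraction.

Each bone is registered individually, post-change (moving) onto pre-change
(fixed).  The full pipeline is two-phase: a whole-volume multiresolution
Powell registration on soft-tissue-zeroed images with a radius-8 slice-wise
dilated metric mask, then a crop to the bounding box of the radius-20
dilated fixed mask and a gradient-descent refinement on the crops.  A
one-phase variant stops after phase 1, and a single-level gradient-descent
baseline serves as a reference.  Temporal subtraction (pre minus registered
post) on the crop grid yields the difference image: density loss (osteolytic
lesions) shows bright, density gain (marrow infiltrate) dark.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import metrics
from .morphology import (
    BinaryMask,
    bounding_box,
    crop_mask,
    dilate_slicewise,
    keep_largest_components,
    connected_components,
)
from .registration import BASELINE, FINAL, INITIAL, RigidTransform, register
from .volume import LANCZOS, LINEAR, LabelMap, ParameterError, crop, resample
from .morphology import zero_outside_mask

log = logging.getLogger("bonereg")

#: dilation radii (voxels) for the metric mask and the cropping mask
METRIC_DILATION_RADIUS = 8
CROP_DILATION_RADIUS = 20


class InstanceResolutionError(ParameterError):
    """A bone label did not resolve into exactly two instances."""


@dataclass
class BoneCase:
    """One bone's registration inputs: fixed = pre-change, moving = post."""

    bone: str
    fixed_image: object
    fixed_mask: BinaryMask
    moving_image: object
    moving_mask: BinaryMask

    def __post_init__(self):
        if not (self.fixed_mask.data.any() and self.moving_mask.data.any()):
            raise ParameterError(f"bone {self.bone}: empty mask")


@dataclass
class BoneResult:
    """Everything one bone-wise registration produces."""

    bone: str
    method: str
    transform: RigidTransform            # total fixed->moving map
    phase_transforms: list               # [T1] or [T1, T2]
    reports: list                        # RegistrationReport per phase
    difference: object                   # ImageVolume on the crop grid
    registered_crop: object              # registered moving image on crop grid
    fixed_crop: object
    crop_box: object
    registered_mask: BinaryMask          # moving mask resampled to fixed grid
    dsc: float = float("nan")
    msd: float = float("nan")
    mse: float = float("nan")
    diverged: bool = False

    def metric_dict(self):
        return {"bone": self.bone, "dsc": self.dsc, "msd": self.msd,
                "mse": self.mse}

    def to_dict(self):
        return {
            "bone": self.bone,
            "method": self.method,
            "transform_matrix": self.transform.matrix().tolist(),
            "transform_center": self.transform.center.tolist(),
            "phase_parameters": [
                t.parameters("versor").tolist() for t in self.phase_transforms
            ],
            "reports": [r.to_dict() for r in self.reports],
            "dsc": self.dsc,
            "msd": self.msd,
            "mse": self.mse,
            "diverged": self.diverged,
        }


def split_left_right(labels, flip=False):
    """Resolve each bone label into left/right instance masks.

    After largest-component filtering each label must have exactly two
    26-connected components; the one with the smaller mean world
    x-coordinate is "right" in radiological convention (set ``flip`` to
    invert for the opposite patient orientation).
    """
    out = {}
    for lab in sorted(np.unique(labels.data)):
        if lab == 0:
            continue
        comp, n = connected_components(labels.data == lab)
        if n != 2:
            raise InstanceResolutionError(
                f"label {lab}: expected 2 components, found {n}")
        masks, mean_x = [], []
        for c in (1, 2):
            m = BinaryMask(comp == c, labels.spacing, labels.origin,
                           labels.direction)
            masks.append(m)
            mean_x.append(m.centroid_world()[0])
        right_idx = int(np.argmax(mean_x)) if flip else int(np.argmin(mean_x))
        name = labels.label_names.get(int(lab), f"label{lab}")
        out[name] = {
            "right": masks[right_idx],
            "left": masks[1 - right_idx],
        }
    return out


def _masked_inputs(case):
    fixed_z = zero_outside_mask(case.fixed_image, case.fixed_mask)
    moving_z = zero_outside_mask(case.moving_image, case.moving_mask)
    metric_mask = dilate_slicewise(case.fixed_mask, METRIC_DILATION_RADIUS)
    box = bounding_box(dilate_slicewise(case.fixed_mask, CROP_DILATION_RADIUS))
    return fixed_z, moving_z, metric_mask, box


def _evaluate(case, result, metric_mask_crop):
    """DSC/MSD on full-grid masks, MSE over the dilated mask on the crop."""
    moving_lab = LabelMap(case.moving_mask.data.astype(np.uint8),
                          case.moving_mask.spacing, case.moving_mask.origin,
                          case.moving_mask.direction)
    reg_lab = resample(moving_lab, case.fixed_image, result.transform)
    reg_mask = BinaryMask.from_volume(reg_lab)
    result.registered_mask = reg_mask
    result.dsc = metrics.dsc(case.fixed_mask, reg_mask)
    result.msd = (metrics.msd(case.fixed_mask, reg_mask)
                  if reg_mask.data.any() else float("inf"))
    result.mse = metrics.mse(result.fixed_crop, result.registered_crop,
                             metric_mask_crop)
    return result


def register_bone_one_phase(case, seed=0, config=INITIAL):
    """Phase 1 only: whole-volume registration, Lanczos resampling, and the
    difference computed on the radius-20 crop for comparability with the
    two-phase result."""
    fixed_z, moving_z, metric_mask, box = _masked_inputs(case)
    T1, rep1 = register(fixed_z, moving_z, metric_mask,
                        replace(config, seed=seed))
    fixed_crop = crop(fixed_z, box)
    m1 = resample(moving_z, fixed_crop, T1, config.final_interpolator,
                  default_value=0.0)
    diff = fixed_crop.with_data(fixed_crop.data - m1.data)
    result = BoneResult(
        bone=case.bone, method="one_phase", transform=T1,
        phase_transforms=[T1], reports=[rep1], difference=diff,
        registered_crop=m1, fixed_crop=fixed_crop, crop_box=box,
        registered_mask=None,
    )
    return _evaluate(case, result, crop_mask(metric_mask, box))


def register_bone_two_phase(case, seed=0, from_one_phase=None):
    """The full pipeline: phase 1 as above, then a cropped refinement.

    Phase 2 registers the original (soft-tissue-zeroed) moving volume onto
    the radius-20 crop of the fixed volume with the gradient-descent
    configuration, warm-started at the phase-1 transform; the refined map is
    the total transform and the moving image is resampled once, with the
    Lanczos interpolator, onto the crop grid.  Refining the already-
    resampled phase-1 output instead (sequential resampling) turned out to
    bias the refinement: interpolating a once-resampled image is exact on
    its own lattice and increasingly smoothed off it, which carves spurious
    minima into the mean-squares profile and drags an already-converged
    registration off the true alignment.  Masks are likewise transformed
    once, nearest-neighbor, under the total transform.

    ``from_one_phase`` may supply an existing
    :func:`register_bone_one_phase` result (same case and seed) whose
    phase-1 transform is reused verbatim.
    """
    fixed_z, moving_z, metric_mask, box = _masked_inputs(case)
    if from_one_phase is not None:
        T1 = from_one_phase.transform
        rep1 = from_one_phase.reports[0]
        fixed_crop = from_one_phase.fixed_crop
    else:
        T1, rep1 = register(fixed_z, moving_z, metric_mask,
                            replace(INITIAL, seed=seed))
        fixed_crop = crop(fixed_z, box)
    metric_crop = crop_mask(metric_mask, box)
    T_total, rep2 = register(fixed_crop, moving_z, metric_crop,
                             replace(FINAL, seed=seed), T0=T1)
    # divergence check at like-for-like conditions: phase 2's finest level
    # start (the phase-1 alignment) vs its end
    p2_start = rep2.levels[-1]["initial_metric"]
    diverged = bool(p2_start and rep2.final_metric > 10.0 * p2_start)
    if diverged:
        log.warning("bone %s: phase-2 metric %.1f exceeds 10x its start %.1f",
                    case.bone, rep2.final_metric, p2_start)
    m2 = resample(moving_z, fixed_crop, T_total, FINAL.final_interpolator,
                  default_value=0.0)
    diff = fixed_crop.with_data(fixed_crop.data - m2.data)
    result = BoneResult(
        bone=case.bone, method="two_phase", transform=T_total,
        phase_transforms=[T1, T_total], reports=[rep1, rep2], difference=diff,
        registered_crop=m2, fixed_crop=fixed_crop, crop_box=box,
        registered_mask=None, diverged=diverged,
    )
    return _evaluate(case, result, metric_crop)


def register_bone_baseline(case, seed=0):
    """Single-level gradient-descent reference registration: random 10%
    sampling on the radius-8 dilated mask, no cropping, linear final
    resampling; the difference is still reported on the radius-20 crop so
    the three methods are directly comparable."""
    fixed_z, moving_z, metric_mask, box = _masked_inputs(case)
    T1, rep1 = register(fixed_z, moving_z, metric_mask,
                        replace(BASELINE, seed=seed))
    fixed_crop = crop(fixed_z, box)
    m1 = resample(moving_z, fixed_crop, T1, BASELINE.final_interpolator,
                  default_value=0.0)
    diff = fixed_crop.with_data(fixed_crop.data - m1.data)
    result = BoneResult(
        bone=case.bone, method="baseline", transform=T1,
        phase_transforms=[T1], reports=[rep1], difference=diff,
        registered_crop=m1, fixed_crop=fixed_crop, crop_box=box,
        registered_mask=None,
    )
    return _evaluate(case, result, crop_mask(metric_mask, box))


_METHODS = {
    "two_phase": register_bone_two_phase,
    "one_phase": register_bone_one_phase,
    "baseline": register_bone_baseline,
}


def coronal_mip(difference):
    """Coronal maximum-intensity projection (max along the
    anterior-posterior axis, axis 1) of a difference image."""
    return difference.data.max(axis=1)


def make_bone_cases(pre, post, pre_labels, post_labels, flip=False):
    """Resolve the six bone instances of a patient into BoneCases."""
    pre_inst = split_left_right(keep_largest_components(pre_labels, 2), flip)
    post_inst = split_left_right(keep_largest_components(post_labels, 2), flip)
    cases = []
    for bone_type in sorted(pre_inst):
        for side in ("left", "right"):
            name = f"{bone_type}_{side}"
            if bone_type not in post_inst:
                log.warning("bone %s missing in post labels; skipped", name)
                continue
            cases.append(BoneCase(
                bone=name,
                fixed_image=pre, fixed_mask=pre_inst[bone_type][side],
                moving_image=post, moving_mask=post_inst[bone_type][side],
            ))
    return cases


def run_patient(pre, post, pre_labels, post_labels, method="two_phase",
                seed=0, flip=False):
    """Run one patient: six bones processed independently.

    Returns ``(results, summary)`` where ``results`` is a list of
    :class:`BoneResult` (with difference images and coronal MIPs available
    per bone) and ``summary`` a :class:`metrics.MetricReport`.
    Missing bone instances are skipped with a logged warning.
    """
    if method not in _METHODS:
        raise ParameterError(f"unknown method {method!r}")
    results = []
    for case in make_bone_cases(pre, post, pre_labels, post_labels, flip):
        try:
            results.append(_METHODS[method](case, seed=seed))
        except ParameterError as exc:
            log.warning("bone %s failed: %s", case.bone, exc)
    if not results:
        raise ParameterError("no bone produced a result")
    summary = metrics.summarize([r.metric_dict() for r in results])
    return results, summary


def write_report(results, summary, path):
    """Emit the per-run JSON report (transforms, traces, metrics)."""
    payload = {
        "bones": [r.to_dict() for r in results],
        "summary": summary.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload
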