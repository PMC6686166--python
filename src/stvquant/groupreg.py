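"""Pairwise and groupwise nonrigid registration; mean reference frame.

The training stage of the pipeline needs (i) a mean reference frame — the
common coordinate space obtained by groupwise registration of the training
images — and (ii) one deformation field per subject mapping reference-frame
coordinates to that subject's coordinates.  Training masks are warped into
the reference frame and averaged into a probabilistic "mean 3-D mask" that
loosely delimits where synovitis occurs.

Pairwise registration is built on SimpleITK's registration framework: a
translation stage followed by a B-spline free-form deformation, mean-squared
intensity similarity, and a two-level multiresolution pyramid.  The coarse
control-point spacing of the B-spline grid acts as the smoothness
regularizer keeping the Jacobian positive at the deformation magnitudes the
cohort generator produces.  The groupwise scheme is the standard iterative
reference-based one: register everyone to the current reference, re-centre
the fields to zero mean displacement so the reference does not drift, and
update the reference as the mean of the warped images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volio import GridSpec, Mask, Volume, mask_like, resample_to_grid


@dataclass(frozen=True)
class RegistrationParams:
    """Knobs of the pairwise registration.

    mesh_size: B-spline control-point mesh (interior nodes per axis).
    shrink / smooth: multiresolution schedule (coarse to fine).
    """

    mesh_size: tuple[int, int, int] = (5, 5, 2)
    shrink: tuple[int, ...] = (4, 2)
    smooth: tuple[float, ...] = (1.0, 0.5)
    translation_iters: int = 50
    bspline_iters: int = 30
    bspline_max_evals: int = 60
    normalize: bool = True


@dataclass
class DeformationField:
    """Dense displacement field in mm on the reference grid.

    ``disp[i, j, k]`` is the physical offset added to the world coordinates
    of reference voxel (i, j, k) to land in the subject image (the resampling
    convention: reference frame -> subject).
    """

    disp: np.ndarray  # (nx, ny, nz, 3), mm
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    converged: bool = True

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]  # type: ignore[return-value]

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt(np.sum(self.disp ** 2, axis=-1))

    def jacobian_determinant(self) -> np.ndarray:
        """det(I + grad d) on the reference grid; > 0 everywhere for a
        locally invertible (diffeomorphic) field."""
        grads = np.empty(self.shape + (3, 3))
        for c in range(3):
            g = np.gradient(self.disp[..., c], *self.spacing, edge_order=1)
            for k in range(3):
                grads[..., c, k] = g[k]
        jac = grads + np.eye(3)
        return np.linalg.det(jac)


def identity_field(shape: tuple[int, int, int],
                   spacing: tuple[float, float, float],
                   origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> DeformationField:
    return DeformationField(np.zeros(tuple(shape) + (3,)), spacing, origin)


def translation_field(shape, spacing, shift_mm,
                      origin=(0.0, 0.0, 0.0)) -> DeformationField:
    disp = np.zeros(tuple(shape) + (3,))
    disp[...] = np.asarray(shift_mm, dtype=float)
    return DeformationField(disp, tuple(spacing), tuple(origin))


@dataclass
class MeanModelFrame:
    """Groupwise mean image, mean mask and per-subject deformation fields."""

    mean_image: Volume
    mean_mask: Mask  # probabilistic
    fields: list[DeformationField] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mean_mask.kind != "probabilistic":
            raise ValueError("mean_mask must be probabilistic")


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def _to_sitk(vol: Volume) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    return img


def _normalized(vol: Volume) -> Volume:
    sd = vol.data.std()
    if sd == 0:
        return vol.with_data(vol.data - vol.data.mean())
    return vol.with_data((vol.data - vol.data.mean()) / sd)


def _field_from_transform(tx: sitk.Transform, ref: Volume) -> np.ndarray:
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(_to_sitk(ref))
    filt.SetOutputPixelType(sitk.sitkVectorFloat64)
    f = filt.Execute(tx)
    arr = sitk.GetArrayFromImage(f)  # (z, y, x, 3) with components (x, y, z)
    return np.ascontiguousarray(arr.transpose(2, 1, 0, 3))


def register_pair(moving: Volume, fixed: Volume,
                  params: RegistrationParams | None = None) -> DeformationField:
    """Nonrigid registration of ``moving`` onto ``fixed``.

    Returns the field mapping fixed-frame (reference) coordinates into the
    moving image, i.e. the transform used to resample ``moving`` onto the
    fixed grid.  Translation is recovered first, then a B-spline free-form
    deformation on top, both under a mean-squares similarity with a
    multiresolution schedule.  If an optimizer fails, the best field found so
    far is returned with ``converged=False`` and a warning.
    """
    params = params or RegistrationParams()
    if params.normalize:
        moving_n, fixed_n = _normalized(moving), _normalized(fixed)
    else:
        moving_n, fixed_n = moving, fixed
    f_img = sitk.Cast(_to_sitk(fixed_n), sitk.sitkFloat64)
    m_img = sitk.Cast(_to_sitk(moving_n), sitk.sitkFloat64)

    converged = True
    # stage 1: translation
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMeanSquares()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4,
        numberOfIterations=params.translation_iters)
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetInitialTransform(sitk.TranslationTransform(3), inPlace=False)
    reg.SetShrinkFactorsPerLevel(list(params.shrink))
    reg.SetSmoothingSigmasPerLevel(list(params.smooth))
    try:
        t_tx = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # pragma: no cover - optimizer failure path
        warnings.warn(f"translation stage failed ({exc}); using identity")
        t_tx = sitk.TranslationTransform(3)
        converged = False

    # stage 2: B-spline FFD on top of the recovered translation
    bspline = sitk.BSplineTransformInitializer(f_img, list(params.mesh_size))
    reg2 = sitk.ImageRegistrationMethod()
    reg2.SetMetricAsMeanSquares()
    reg2.SetInterpolator(sitk.sitkLinear)
    reg2.SetOptimizerAsLBFGSB(
        gradientConvergenceTolerance=1e-7,
        numberOfIterations=params.bspline_iters,
        maximumNumberOfFunctionEvaluations=params.bspline_max_evals)
    reg2.SetMovingInitialTransform(t_tx)
    reg2.SetInitialTransform(bspline, inPlace=True)
    reg2.SetShrinkFactorsPerLevel(list(params.shrink))
    reg2.SetSmoothingSigmasPerLevel(list(params.smooth))
    try:
        reg2.Execute(f_img, m_img)
        total = sitk.CompositeTransform([t_tx, bspline])
    except RuntimeError as exc:  # pragma: no cover
        warnings.warn(f"B-spline stage failed ({exc}); returning translation only")
        total = t_tx
        converged = False

    disp = _field_from_transform(total, fixed)
    return DeformationField(disp, fixed.spacing, fixed.origin, converged=converged)


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------

def _pullback(data: np.ndarray, field: DeformationField, order: int) -> np.ndarray:
    """Sample ``data`` (on the subject grid) at reference + displacement."""
    idx = np.indices(field.shape).astype(np.float64)
    coords = [idx[k] + field.disp[..., k] / field.spacing[k] for k in range(3)]
    return ndimage.map_coordinates(data, np.stack(coords), order=order, mode="nearest")


def invert_field(field: DeformationField, n_iter: int = 20) -> DeformationField:
    """Numerical inverse by fixed-point iteration: e(x) = -d(x + e(x))."""
    e = -field.disp.copy()
    idx = np.indices(field.shape).astype(np.float64)
    for _ in range(n_iter):
        coords = [idx[k] + e[..., k] / field.spacing[k] for k in range(3)]
        stacked = np.stack(coords)
        sampled = np.stack(
            [ndimage.map_coordinates(field.disp[..., c], stacked, order=1,
                                     mode="nearest") for c in range(3)], axis=-1)
        e = -sampled
    return DeformationField(e, field.spacing, field.origin, field.converged)


def warp_volume(vol: Volume, field: DeformationField) -> Volume:
    """Warp a subject image into the reference frame (linear pullback)."""
    out = _pullback(vol.data, field, order=1)
    return Volume(out, field.spacing, field.origin, vol.slice_axis)


def warp_mask(mask: Mask, field: DeformationField,
              direction: str = "to_reference") -> Mask:
    """Warp a mask through the field.

    ``to_reference``: the mask lives on the subject grid and is pulled back
    into the reference frame.  ``to_subject``: the mask lives in the
    reference frame and is carried onto the subject grid via the numerically
    inverted field.  Binary masks use nearest-neighbour interpolation (ties
    broken by scipy's round-half-away-from-centre indexing), probabilistic
    masks linear with clamping to [0, 1].
    """
    if direction not in ("to_reference", "to_subject"):
        raise ValueError(f"unknown direction {direction!r}")
    if mask.shape != field.shape:
        raise ValueError(
            f"mask grid {mask.shape} does not match field grid {field.shape} "
            f"for direction {direction}")
    f = field if direction == "to_reference" else invert_field(field)
    order = 0 if mask.kind == "binary" else 1
    out = _pullback(mask.data, f, order=order)
    out = np.clip(out, 0.0, 1.0)
    if mask.kind == "binary":
        out = np.rint(out)
    return Mask(out, f.spacing, f.origin, mask.slice_axis, mask.kind)


# ---------------------------------------------------------------------------
# Groupwise mean frame
# ---------------------------------------------------------------------------

def _median_intensity_index(images: list[Volume]) -> int:
    means = np.array([im.data.mean() for im in images])
    return int(np.argmin(np.abs(means - np.median(means))))


def build_mean_frame(images: list[Volume], masks: list[Mask],
                     iterations: int = 3,
                     params: RegistrationParams | None = None) -> MeanModelFrame:
    """Iterative reference-based groupwise registration.

    Starts from the intensity-median subject, alternates (register all ->
    re-centre fields to zero mean displacement -> reference = mean of warped
    images), then averages the warped training masks into the probabilistic
    mean 3-D mask.
    """
    if len(images) < 2:
        raise ValueError("groupwise registration needs at least 2 subjects")
    if len(images) != len(masks):
        raise ValueError("each image needs a paired mask")
    for im, mk in zip(images, masks):
        if not im.same_grid(mk):
            raise ValueError("image/mask grid mismatch in training set")

    ref_idx = _median_intensity_index(images)
    ref_grid = GridSpec(images[ref_idx].shape, images[ref_idx].spacing,
                        images[ref_idx].origin)
    images = [im if im.same_grid(images[ref_idx])
              else resample_to_grid(im, ref_grid, "linear") for im in images]
    reference = images[ref_idx]

    fields: list[DeformationField] = []
    for _ in range(max(1, iterations)):
        fields = [register_pair(im, reference, params) for im in images]
        mean_disp = np.mean([f.disp for f in fields], axis=0)
        fields = [DeformationField(f.disp - mean_disp, f.spacing, f.origin,
                                   f.converged) for f in fields]
        warped = [warp_volume(im, f) for im, f in zip(images, fields)]
        reference = Volume(np.mean([w.data for w in warped], axis=0),
                           reference.spacing, reference.origin,
                           reference.slice_axis)

    warped_masks = [warp_mask(mk, f, "to_reference")
                    for mk, f in zip(masks, fields)]
    mean_mask_data = np.clip(np.mean([w.data for w in warped_masks], axis=0),
                             0.0, 1.0)
    mean_mask = mask_like(reference, mean_mask_data, kind="probabilistic")
    return MeanModelFrame(mean_image=reference, mean_mask=mean_mask,
                          fields=fields)


def binarize_mean_mask(prob: Mask, tau: float = 0.25) -> Mask:
    """Keep voxels whose mean occupancy across the cohort is >= ``tau``."""
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if prob.kind != "probabilistic":
        raise ValueError("binarize_mean_mask expects a probabilistic mask")
    return prob.with_data((prob.data >= tau).astype(np.float64), kind="binary")
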