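"""Statistical appearance model: training, search, and mask propagation.

The model couples a *shape* PCA over the vectorized groupwise deformation
fields with an *appearance* PCA over reference-frame intensities (each
training sample intensity-normalized to zero mean / unit variance, so the
model is insensitive to scanner scale).  Fitting a new image estimates the
nonrigid mapping from the mean reference frame to the target: a coarse
exhaustive translation search provides the pose initialization (guarding
against the gross mask-displacement failure mode), followed by simplex
refinement of the pose and bounded coordinate descent over the shape
coefficients, minimizing the fraction of normalized intensity variance the
appearance subspace cannot explain.  The fitted field then carries the
binarized mean synovitis mask onto the target, deliberately over-covering:
the mask is a loose region of interest for the thresholding step, not a
segmentation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize

from .groupreg import (DeformationField, MeanModelFrame, binarize_mean_mask,
                       warp_mask, warp_volume)
from .volio import (GridSpec, Mask, Volume, read_mask, read_volume,
                    resample_mask_to_grid, write_mask, write_volume)

_EIG_TOL = 1e-10  # relative eigenvalue floor: below this a mode is noise


@dataclass
class AppearanceModel:
    """Trained shape + appearance PCA around the mean reference frame."""

    frame: MeanModelFrame
    shape_mean: np.ndarray        # (3N,) mm
    shape_components: np.ndarray  # (m, 3N), orthonormal rows
    shape_sd: np.ndarray          # (m,) per-mode SD in training set
    app_mean: np.ndarray          # (N,)
    app_components: np.ndarray    # (q, N), orthonormal rows
    app_sd: np.ndarray            # (q,)
    var_frac: float
    n_train: int

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.frame.mean_image.shape

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.frame.mean_image.spacing

    @property
    def n_shape_modes(self) -> int:
        return self.shape_components.shape[0]


def _pca(samples: np.ndarray, var_frac: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA keeping the smallest number of modes explaining >= var_frac.

    Returns (mean, components (m, dim), per-mode SD)."""
    n = samples.shape[0]
    mean = samples.mean(axis=0)
    centered = samples - mean
    # economy SVD: at most n-1 non-trivial modes
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    lam = s ** 2 / (n - 1)
    total = lam.sum()
    if total <= 0 or lam[0] < _EIG_TOL:
        return mean, np.zeros((0, samples.shape[1])), np.zeros(0)
    keep = lam > _EIG_TOL * lam[0]
    lam, vt = lam[keep], vt[keep]
    cum = np.cumsum(lam) / total
    m = int(np.searchsorted(cum, var_frac - 1e-12) + 1)
    m = min(m, len(lam))
    return mean, vt[:m], np.sqrt(lam[:m])


def train_aam(frame: MeanModelFrame, images: list[Volume],
              var_frac: float = 0.95) -> AppearanceModel:
    """Train shape/appearance PCA from the groupwise frame and its images.

    Shape samples are the vectorized per-subject deformation fields;
    appearance samples are the training images warped into the reference
    frame and normalized to zero mean / unit variance.
    """
    if not 0 < var_frac <= 1:
        raise ValueError("var_frac must be in (0, 1]")
    if len(images) < 3:
        raise ValueError("training an appearance model needs at least 3 subjects")
    if len(images) != len(frame.fields):
        raise ValueError("one deformation field per training image is required")

    shape_samples = np.stack([f.disp.ravel() for f in frame.fields])
    s_mean, s_comp, s_sd = _pca(shape_samples, var_frac)

    app_samples = []
    for im, f in zip(images, frame.fields):
        warped = warp_volume(im, f).data.ravel()
        sd = warped.std()
        app_samples.append((warped - warped.mean()) / (sd if sd > 0 else 1.0))
    a_mean, a_comp, a_sd = _pca(np.stack(app_samples), var_frac)

    return AppearanceModel(frame=frame, shape_mean=s_mean, shape_components=s_comp,
                           shape_sd=s_sd, app_mean=a_mean, app_components=a_comp,
                           app_sd=a_sd, var_frac=var_frac, n_train=len(images))


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchParams:
    """Pose/shape search configuration.

    The coarse translation grid spans +-``coarse_extent_frac`` of the field
    of view in-plane (step ``coarse_step_vox`` voxels) and +-``coarse_z_vox``
    slices through-plane, evaluated on a stride-subsampled grid.
    """

    coarse_extent_frac: float = 0.25
    coarse_step_vox: int = 2
    coarse_z_vox: int = 2
    coarse_stride: int = 2
    sweeps: int = 2
    clamp_sd: float = 3.0


class _Objective:
    """Normalized model-synthesis residual for a fixed target volume."""

    def __init__(self, model: AppearanceModel, target: Volume):
        self.model = model
        self.target = target
        shape = model.grid_shape
        self.ref_world = [model.frame.mean_image.origin[k]
                          + model.spacing[k] * np.indices(shape)[k].astype(float)
                          for k in range(3)]
        self.mean_disp = model.shape_mean.reshape(shape + (3,))
        self.modes = [c.reshape(shape + (3,)) for c in model.shape_components]
        self.app_mean = model.app_mean.reshape(shape)
        self.app_comp = model.app_components  # (q, N)

    def residual(self, t: np.ndarray, b: np.ndarray, stride: int = 1) -> float:
        sl = (slice(None, None, stride),) * 2 + (slice(None),)
        disp = self.mean_disp[sl].copy()
        for bj, mode in zip(b, self.modes):
            if bj != 0.0:
                disp = disp + bj * mode[sl]
        tg = self.target
        coords = [(self.ref_world[k][sl] + disp[..., k] + t[k] - tg.origin[k])
                  / tg.spacing[k] for k in range(3)]
        g = ndimage.map_coordinates(tg.data, np.stack(coords), order=1,
                                    mode="nearest")
        sd = g.std()
        gn = ((g - g.mean()) / (sd if sd > 0 else 1.0)).ravel()
        if stride == 1:
            r = gn - self.app_mean.ravel()
            a = self.app_comp @ r if self.app_comp.size else np.zeros(0)
        else:
            mu = self.app_mean[sl[:2] + (slice(None),)].ravel()
            r = gn - mu
            if self.app_comp.size:
                q = self.app_comp.reshape((-1,) + self.model.grid_shape)
                comp = q[(slice(None),) + sl[:2] + (slice(None),)].reshape(len(q), -1)
                # subsampled rows are not orthonormal; plain projection suffices
                # for ranking candidate poses
                a = comp @ r
            else:
                a = np.zeros(0)
        return float((r @ r - a @ a) / r.size)


def fit_aam(model: AppearanceModel, target: Volume,
            params: SearchParams | None = None) -> tuple[DeformationField, float]:
    """Search ``target`` for the mapping from the reference frame onto it.

    Returns the fitted deformation field (pose translation folded in) and the
    final residual as a fraction of normalized intensity variance, for
    quality control.  The search is deterministic.
    """
    params = params or SearchParams()
    obj = _Objective(model, target)
    shape = model.grid_shape
    sp = np.asarray(model.spacing)

    # coarse exhaustive translation search (pose initialization)
    ext = [max(params.coarse_step_vox,
               int(round(params.coarse_extent_frac * shape[k]))) for k in range(2)]
    cand = []
    zs = range(-params.coarse_z_vox, params.coarse_z_vox + 1)
    for ix in range(-ext[0], ext[0] + 1, params.coarse_step_vox):
        for iy in range(-ext[1], ext[1] + 1, params.coarse_step_vox):
            for iz in zs:
                cand.append((ix * sp[0], iy * sp[1], iz * sp[2]))
    b0 = np.zeros(model.n_shape_modes)
    scores = [obj.residual(np.asarray(t), b0, stride=params.coarse_stride)
              for t in cand]
    t = np.asarray(cand[int(np.argmin(scores))], dtype=float)

    converged = True
    try:
        res = optimize.minimize(lambda tt: obj.residual(tt, b0), t,
                                method="Nelder-Mead",
                                options={"xatol": 0.05, "fatol": 1e-9,
                                         "maxiter": 200})
        t = res.x
        # bounded coordinate descent over shape coefficients, re-refining pose
        b = b0.copy()
        for _ in range(params.sweeps):
            for j in range(model.n_shape_modes):
                lim = params.clamp_sd * model.shape_sd[j]
                if lim <= 0:
                    continue
                r1 = optimize.minimize_scalar(
                    lambda bj: obj.residual(t, _with(b, j, bj)),
                    bounds=(-lim, lim), method="bounded",
                    options={"xatol": 1e-3 * lim})
                b[j] = r1.x
            res = optimize.minimize(lambda tt: obj.residual(tt, b), t,
                                    method="Nelder-Mead",
                                    options={"xatol": 0.05, "fatol": 1e-9,
                                             "maxiter": 100})
            t = res.x
    except Exception:  # pragma: no cover - optimizer failure path
        b = b0
        converged = False

    disp = obj.mean_disp.copy()
    for bj, mode in zip(b, obj.modes):
        disp = disp + bj * mode
    disp = disp + t
    field = DeformationField(disp, model.spacing,
                             model.frame.mean_image.origin, converged=converged)
    return field, obj.residual(t, b)


def _with(b: np.ndarray, j: int, v: float) -> np.ndarray:
    out = b.copy()
    out[j] = v
    return out


def propagate_mask(model: AppearanceModel, field: DeformationField,
                   target: Volume, tau: float = 0.25,
                   dilate_voxels: int = 1) -> Mask:
    """Carry the binarized mean synovitis mask onto ``target``'s grid.

    ``dilate_voxels`` applies an in-plane morphological dilation before
    warping, keeping the propagated region deliberately loose (it is a
    region of interest for thresholding, not a segmentation); set 0 to
    disable.
    """
    if field.shape != model.grid_shape:
        raise ValueError("field does not live on the model reference grid")
    binary = binarize_mean_mask(model.frame.mean_mask, tau)
    data = binary.data.astype(bool)
    if dilate_voxels > 0:
        struct = ndimage.generate_binary_structure(2, 2)[..., None]  # in-plane
        data = ndimage.binary_dilation(data, structure=struct,
                                       iterations=dilate_voxels)
    loose = binary.with_data(data.astype(np.float64))
    warped = warp_mask(loose, field, direction="to_subject")
    if warped.same_grid(target):
        out = warped
    else:
        out = resample_mask_to_grid(
            warped, GridSpec(target.shape, target.spacing, target.origin))
    return Mask(out.data, target.spacing, target.origin, target.slice_axis,
                "binary")


# ---------------------------------------------------------------------------
# Model directory persistence
# ---------------------------------------------------------------------------

def save_model(model: AppearanceModel, directory: str | Path) -> None:
    """Write the model as NIfTI images + npz arrays + a JSON manifest."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(model.frame.mean_image, d / "mean_image.nii.gz")
    write_mask(model.frame.mean_mask, d / "mean_mask.nii.gz")
    np.savez_compressed(
        d / "model.npz",
        fields=np.stack([f.disp for f in model.frame.fields]),
        shape_mean=model.shape_mean, shape_components=model.shape_components,
        shape_sd=model.shape_sd, app_mean=model.app_mean,
        app_components=model.app_components, app_sd=model.app_sd)
    manifest = {
        "format": "stvquant-aam-v1",
        "grid": list(model.grid_shape),
        "spacing": list(model.spacing),
        "var_frac": model.var_frac,
        "n_train": model.n_train,
        "n_shape_modes": int(model.n_shape_modes),
        "n_appearance_modes": int(model.app_components.shape[0]),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_model(directory: str | Path) -> AppearanceModel:
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    if manifest.get("format") != "stvquant-aam-v1":
        raise ValueError(f"{d}: not a model directory")
    mean_image = read_volume(d / "mean_image.nii.gz")
    mean_mask = read_mask(d / "mean_mask.nii.gz", kind="probabilistic")
    arrs = np.load(d / "model.npz")
    fields = [DeformationField(f, mean_image.spacing, mean_image.origin)
              for f in arrs["fields"]]
    frame = MeanModelFrame(mean_image=mean_image, mean_mask=mean_mask,
                           fields=fields)
    return AppearanceModel(
        frame=frame, shape_mean=arrs["shape_mean"],
        shape_components=arrs["shape_components"], shape_sd=arrs["shape_sd"],
        app_mean=arrs["app_mean"], app_components=arrs["app_components"],
        app_sd=arrs["app_sd"], var_frac=float(manifest["var_frac"]),
        n_train=int(manifest["n_train"]))
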