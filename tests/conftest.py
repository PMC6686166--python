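"""Shared fixtures: phantoms, textured volumes, and a hand-built model.

The expensive groupwise training run lives in the end-to-end tests only;
unit tests of the appearance model use a small frame assembled directly
from known deformation fields, which exercises the same code paths without
registration cost.
"""

import numpy as np
import pytest
from scipy import ndimage

from stvquant import (DeformationField, MeanModelFrame, PhantomSpec, Volume,
                      generate_phantom, mask_like, train_aam)
from stvquant.phantom import random_displacement, warp_arrays


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def base_phantom(phantom_spec):
    return generate_phantom(phantom_spec)


@pytest.fixture(scope="session")
def textured_volume() -> Volume:
    """Smoothed-noise image with intensity gradients everywhere, so that a
    deformation is observable at every voxel (unlike the piecewise-constant
    phantom, whose flat regions carry no registration signal)."""
    rng = np.random.default_rng(7)
    spec = PhantomSpec()
    tex = ndimage.gaussian_filter(rng.standard_normal(spec.grid), (2, 2, 0.7))
    tex = (tex - tex.mean()) / tex.std() * 100 + 500
    return Volume(tex, spec.spacing)


def make_synthetic_model(n_subjects: int = 6, warp_sigma: float = 1.0,
                         seed: int = 5, var_frac: float = 0.95):
    """A trained appearance model assembled from *known* deformation fields.

    Each subject is the base phantom pulled back through an independent
    smooth random field; those generating fields (re-centred to zero mean)
    play the role the groupwise registration output would play.  Returns
    (model, images, generating fields, ground-truth masks).
    """
    spec = PhantomSpec(seed=seed, warp_sigma=warp_sigma)
    base, base_mask, _ = generate_phantom(spec)
    rng_children = np.random.SeedSequence((seed, 99)).spawn(n_subjects)
    disps, images, masks = [], [], []
    for child in rng_children:
        rng = np.random.default_rng(child)
        d = random_displacement(spec.grid, spec.spacing, warp_sigma,
                                spec.warp_smooth_vox, rng)
        img = warp_arrays(base.data, d, spec.spacing, order=1)
        gt = warp_arrays(base_mask.data, d, spec.spacing, order=0)
        img = img + rng.standard_normal(spec.grid) * 5.0
        images.append(Volume(img, spec.spacing))
        masks.append(mask_like(base, gt, kind="binary"))
        # subject(x) = base(x + d(x)), so the reference -> subject mapping
        # (resampling convention) is approximately -d for smooth small d
        disps.append(-d)
    mean_disp = np.mean(disps, axis=0)
    fields = [DeformationField(d - mean_disp, spec.spacing) for d in disps]
    # the frame contract: mean image / mask are the averages of the training
    # data warped back into the reference frame through the fields
    from stvquant import warp_mask, warp_volume
    warped_imgs = [warp_volume(im, f).data for im, f in zip(images, fields)]
    warped_masks = [warp_mask(mk, f, "to_reference").data
                    for mk, f in zip(masks, fields)]
    mean_image = Volume(np.mean(warped_imgs, axis=0), spec.spacing)
    mean_mask_data = np.clip(np.mean(warped_masks, axis=0), 0, 1)
    frame = MeanModelFrame(
        mean_image=mean_image,
        mean_mask=mask_like(base, mean_mask_data, kind="probabilistic"),
        fields=fields)
    model = train_aam(frame, images, var_frac=var_frac)
    return model, images, disps, masks


@pytest.fixture(scope="session")
def synthetic_model():
    return make_synthetic_model()
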