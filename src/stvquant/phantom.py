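"""Synthetic contrast-enhanced knee-stack generator with known synovium.

Real trial MRIs are not redistributable, so every stage of the pipeline is
exercised on phantoms that reproduce the features the method depends on:

* a bright, curved/L-shaped synovium "shell" of known voxel count, standing
  in for enhancing synovium around the joint;
* darker background tissue, giving the image the bimodal intensity
  histogram the targeted-thresholding step assumes;
* bright vessel-like tubes *outside* the synovium — the classic false
  positive of contrast-enhanced knee MRI;
* optionally an intermediate-intensity effusion blob;
* per-subject smooth random deformations emulating anatomical variability
  across a training cohort.

Default geometry is a desk-scale stand-in for a sagittal stack: 64x64x12
voxels at (0.5, 0.5, 3.3) mm, the 3.3 mm through-plane spacing being 3 mm
slice thickness plus 0.3 mm gap.  Intensities are drawn per voxel from the
low/high Gaussians; no further MR physics is simulated.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawning (one child per subject, one stream each for noise and warp), so a
spec + seed pair is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volio import Mask, Volume, mask_like

DEFAULT_CENTERLINE: tuple[tuple[float, float], ...] = ((16.0, 46.0), (16.0, 18.0), (44.0, 18.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic knee stack.

    ``centerline`` holds in-plane voxel coordinates of the synovium shell's
    polyline (an L by default); the shell is the set of voxels within
    ``shell_thickness_mm / 2`` of that polyline on ``slices``.
    """

    grid: tuple[int, int, int] = (64, 64, 12)
    spacing: tuple[float, float, float] = (0.5, 0.5, 3.3)
    centerline: tuple[tuple[float, float], ...] = DEFAULT_CENTERLINE
    shell_thickness_mm: float = 2.0
    slices: tuple[int, int] = (2, 9)  # inclusive through-plane extent
    mu_low: float = 100.0
    sigma_low: float = 20.0
    mu_high: float = 800.0
    sigma_high: float = 40.0
    n_vessels: int = 2
    vessel_radius_mm: float = 0.7
    vessel_margin_mm: float = 5.0
    effusion: tuple[float, float, float] | None = None  # (cx, cy, radius_mm)
    effusion_mu: float | None = None
    warp_sigma: float = 1.0  # RMS displacement magnitude, mm
    warp_smooth_vox: tuple[float, float, float] = (6.0, 6.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_high <= self.mu_low:
            raise ValueError("mu_high must exceed mu_low")
        if self.sigma_low <= 0 or self.sigma_high <= 0:
            raise ValueError("sigmas must be positive")
        if self.shell_thickness_mm < min(self.spacing[:2]):
            raise ValueError("shell thickness must be at least one in-plane voxel")
        if self.warp_sigma < 0:
            raise ValueError("warp_sigma must be non-negative")


def _polyline_distance_mm(spec: PhantomSpec) -> np.ndarray:
    """In-plane distance (mm) from every (x, y) voxel centre to the centerline."""
    nx, ny, _ = spec.grid
    dx, dy = spec.spacing[0], spec.spacing[1]
    xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy, indexing="ij")
    pts = np.stack([xs, ys], axis=-1)  # (nx, ny, 2)
    best = np.full((nx, ny), np.inf)
    cl = np.asarray(spec.centerline, dtype=float)
    cl_mm = cl * np.array([dx, dy])
    for a, b in zip(cl_mm[:-1], cl_mm[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + t[..., None] * ab
        d = np.linalg.norm(pts - proj, axis=-1)
        best = np.minimum(best, d)
    return best


def _synovium_mask(spec: PhantomSpec) -> np.ndarray:
    dist = _polyline_distance_mm(spec)
    z0, z1 = spec.slices
    nz = spec.grid[2]
    if z0 < 0 or z1 >= nz or z0 > z1:
        raise ValueError(f"synovium slices {spec.slices} exceed grid of {nz} slices")
    radius = spec.shell_thickness_mm / 2.0
    mask = np.zeros(spec.grid, dtype=bool)
    for z in range(z0, z1 + 1):
        # taper the shell at the through-plane ends for a genuinely 3-D shape
        r = radius * (0.6 if z in (z0, z1) else 1.0)
        mask[:, :, z] = dist <= r
    if not mask.any():
        raise ValueError("synovium shell is empty on the requested grid")
    return mask


def _place_vessels(spec: PhantomSpec, synovium: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Bright through-plane tubes kept ``vessel_margin_mm`` clear of the shell."""
    if spec.n_vessels == 0:
        return np.zeros(spec.grid, dtype=bool)
    dist = _polyline_distance_mm(spec)
    nx, ny, nz = spec.grid
    dx, dy = spec.spacing[0], spec.spacing[1]
    shell_r = spec.shell_thickness_mm / 2.0
    vessels = np.zeros(spec.grid, dtype=bool)
    placed = 0
    for _ in range(1000):
        if placed == spec.n_vessels:
            break
        cx = rng.uniform(4, nx - 5)
        cy = rng.uniform(4, ny - 5)
        if dist[int(round(cx)), int(round(cy))] < shell_r + spec.vessel_margin_mm:
            continue
        xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy, indexing="ij")
        tube = (xs - cx * dx) ** 2 + (ys - cy * dy) ** 2 <= spec.vessel_radius_mm ** 2
        vessels |= tube[:, :, None] & np.ones(nz, dtype=bool)[None, None, :]
        placed += 1
    if placed < spec.n_vessels:
        raise ValueError("could not place vessels clear of the synovium shell")
    vessels &= ~synovium  # strict disjointness contract
    return vessels


def _mu_sigma_maps(spec: PhantomSpec, synovium: np.ndarray,
                   vessels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = np.full(spec.grid, spec.mu_low, dtype=np.float64)
    sig = np.full(spec.grid, spec.sigma_low, dtype=np.float64)
    enhancing = synovium | vessels
    mu[enhancing] = spec.mu_high
    sig[enhancing] = spec.sigma_high
    if spec.effusion is not None:
        cx, cy, r_mm = spec.effusion
        nx, ny, nz = spec.grid
        dx, dy = spec.spacing[0], spec.spacing[1]
        xs, ys = np.meshgrid(np.arange(nx) * dx, np.arange(ny) * dy, indexing="ij")
        blob = ((xs - cx * dx) ** 2 + (ys - cy * dy) ** 2 <= r_mm ** 2)
        blob3 = blob[:, :, None] & np.ones(nz, dtype=bool)[None, None, :] & ~enhancing
        mu_eff = spec.effusion_mu if spec.effusion_mu is not None else \
            0.5 * (spec.mu_low + spec.mu_high)
        mu[blob3] = mu_eff
    return mu, sig


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, Mask, float]:
    """Generate the base (unwarped) phantom.

    Returns the image, the ground-truth synovium mask, and the true volume
    in mm^3 (= ground-truth voxel count x voxel volume).
    """
    ss = np.random.SeedSequence(spec.seed)
    noise_rng, vessel_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    synovium = _synovium_mask(spec)
    vessels = _place_vessels(spec, synovium, vessel_rng)
    mu, sig = _mu_sigma_maps(spec, synovium, vessels)
    img = mu + noise_rng.standard_normal(spec.grid) * sig
    vol = Volume(img, spec.spacing)
    mask = mask_like(vol, synovium.astype(np.float64), kind="binary")
    true_volume = float(synovium.sum()) * vol.voxel_volume_mm3
    return vol, mask, true_volume


def _min_jacobian(disp_mm: np.ndarray, spacing: Sequence[float]) -> float:
    grads = np.empty(disp_mm.shape[:3] + (3, 3))
    for c in range(3):
        g = np.gradient(disp_mm[..., c], *spacing, edge_order=1)
        for k in range(3):
            grads[..., c, k] = g[k]
    return float(np.linalg.det(grads + np.eye(3)).min())


def random_displacement(shape: Sequence[int], spacing: Sequence[float],
                        rms_mm: float, smooth_vox: Sequence[float],
                        rng: np.random.Generator,
                        jac_floor: float = 0.2) -> np.ndarray:
    """Smooth random displacement field, (nx, ny, nz, 3), in mm.

    White noise smoothed per component with a Gaussian of ``smooth_vox``
    voxels, rescaled so the RMS displacement magnitude equals ``rms_mm``,
    then — the diffeomorphic contract — shrunk geometrically until the
    Jacobian determinant of x -> x + d(x) stays above ``jac_floor``
    everywhere, so the warp is guaranteed invertible.  ``rms_mm`` is
    therefore an upper bound on the realized RMS magnitude; unlucky draws
    are damped rather than allowed to fold.
    """
    if rms_mm == 0:
        return np.zeros(tuple(shape) + (3,))
    comps = []
    for _ in range(3):
        w = rng.standard_normal(tuple(shape))
        comps.append(ndimage.gaussian_filter(w, sigma=smooth_vox, mode="nearest"))
    d = np.stack(comps, axis=-1)
    rms = np.sqrt(np.mean(np.sum(d ** 2, axis=-1)))
    d = d * (rms_mm / rms)
    for _ in range(30):
        if _min_jacobian(d, spacing) > jac_floor:
            break
        d = d * 0.8
    return d


def warp_arrays(mu: np.ndarray, disp_mm: np.ndarray,
                spacing: Sequence[float], order: int) -> np.ndarray:
    """Pull back an array through a displacement field given in mm."""
    idx = np.indices(mu.shape).astype(np.float64)
    coords = [idx[k] + disp_mm[..., k] / spacing[k] for k in range(3)]
    return ndimage.map_coordinates(mu, np.stack(coords), order=order, mode="nearest")


def generate_cohort(spec: PhantomSpec, n: int,
                    seed: int | None = None) -> list[tuple[Volume, Mask, float]]:
    """Generate ``n`` subjects: the base phantom under independent smooth warps.

    The noiseless tissue maps and the ground-truth mask are warped with the
    same nearest-neighbour rule, so every warped voxel still belongs to
    exactly one tissue class and is drawn from that class's Gaussian — the
    phantom's defining invariant.  Per-voxel noise is then added fresh for
    each subject.  ``seed`` defaults to ``spec.seed``.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    base_seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)
    vessel_rng = np.random.default_rng(ss.spawn(1)[0])
    synovium = _synovium_mask(spec)
    vessels = _place_vessels(spec, synovium, vessel_rng)
    mu, sig = _mu_sigma_maps(spec, synovium, vessels)

    out: list[tuple[Volume, Mask, float]] = []
    for child in np.random.SeedSequence((base_seed, 1)).spawn(n):
        warp_rng, noise_rng = (np.random.default_rng(c) for c in child.spawn(2))
        disp = random_displacement(spec.grid, spec.spacing, spec.warp_sigma,
                                   spec.warp_smooth_vox, warp_rng)
        mu_w = warp_arrays(mu, disp, spec.spacing, order=0)
        sig_w = warp_arrays(sig, disp, spec.spacing, order=0)
        gt_w = warp_arrays(synovium.astype(np.float64), disp, spec.spacing, order=0)
        img = mu_w + noise_rng.standard_normal(spec.grid) * sig_w
        vol = Volume(img, spec.spacing)
        mask = mask_like(vol, gt_w, kind="binary")
        out.append((vol, mask, float(gt_w.sum()) * vol.voxel_volume_mm3))
    return out
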