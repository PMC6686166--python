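"""Targeted thresholding: two-Gaussian intensity model and voxel labels.

Contrast-enhanced knee stacks are strongly bimodal: enhancing tissue
(synovium, vessels) is bright, everything else dark.  The classifier
exploits this with two whole-image threshold sets: voxels below a low
threshold (default 25% of the image maximum) fit a "low" Gaussian, voxels
above a high threshold (default 75%) fit a "high" Gaussian.  A voxel inside
the region of interest is labelled synovitis iff its intensity is more
probable under the high PDF than under the low one; exact ties go to
not-synovitis, the conservative choice for volume estimates.

With unequal variances the two-PDF comparison is quadratic: when
sigma_high > sigma_low its decision set gains a second branch far below the
low mean, so extremely dark voxels could in principle be labelled
synovitis.  The rule is implemented exactly as stated (the artifact is
documented); ``monotone=True`` switches to the single crossing between the
means for users who want a monotone boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .volio import Mask, Volume

SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class IntensityModel:
    """Two fitted Gaussians and the threshold fractions that defined them."""

    t_low_frac: float
    t_high_frac: float
    max_intensity: float
    low: tuple[float, float]   # (mu, sigma)
    high: tuple[float, float]
    n_low: int
    n_high: int

    def __post_init__(self) -> None:
        if not 0 < self.t_low_frac < self.t_high_frac < 1:
            raise ValueError(
                f"need 0 < t_low_frac < t_high_frac < 1, got "
                f"({self.t_low_frac}, {self.t_high_frac})")
        if self.low[1] < SIGMA_FLOOR or self.high[1] < SIGMA_FLOOR:
            raise ValueError("sigmas must be at least the epsilon floor")
        if self.low[0] >= self.high[0]:
            raise ValueError("low-set mean must be below high-set mean")

    @property
    def t_low(self) -> float:
        return self.t_low_frac * self.max_intensity

    @property
    def t_high(self) -> float:
        return self.t_high_frac * self.max_intensity

    def equal_variance_boundary(self) -> float:
        """Decision boundary when sigmas are equal: midpoint of the means."""
        return 0.5 * (self.low[0] + self.high[0])

    def to_dict(self) -> dict:
        return {
            "t_low_frac": self.t_low_frac, "t_high_frac": self.t_high_frac,
            "max_intensity": self.max_intensity,
            "low": {"mu": self.low[0], "sigma": self.low[1], "n": self.n_low},
            "high": {"mu": self.high[0], "sigma": self.high[1], "n": self.n_high},
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def fit_intensity_model(vol: Volume, t_low_frac: float = 0.25,
                        t_high_frac: float = 0.75,
                        robust_max: bool = False) -> IntensityModel:
    """Fit the low/high Gaussians from whole-image threshold sets.

    The thresholds are fractions of the image maximum — the literal maximum
    by default, or the 99.9th percentile with ``robust_max=True`` (a single
    hot voxel otherwise drags both thresholds up).  The two sets are taken
    across the *entire* image, not restricted to any mask.
    """
    if not 0 < t_low_frac < t_high_frac < 1:
        raise ValueError(
            f"need 0 < t_low_frac < t_high_frac < 1, got "
            f"({t_low_frac}, {t_high_frac})")
    data = vol.data.ravel()
    mx = float(np.percentile(data, 99.9)) if robust_max else float(data.max())
    t_low, t_high = t_low_frac * mx, t_high_frac * mx
    low_set = data[data < t_low]
    high_set = data[data > t_high]
    if low_set.size == 0:
        raise ValueError(
            f"no voxels below the low threshold {t_low:.6g} "
            f"(t_low_frac={t_low_frac})")
    if high_set.size == 0:
        raise ValueError(
            f"no voxels above the high threshold {t_high:.6g} "
            f"(t_high_frac={t_high_frac})")

    def _moments(x: np.ndarray, name: str) -> tuple[float, float]:
        mu = float(x.mean())
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        if sd < SIGMA_FLOOR:
            warnings.warn(f"{name}-intensity set has (near-)zero variance; "
                          f"sigma clamped to {SIGMA_FLOOR}")
            sd = SIGMA_FLOOR
        return mu, sd

    low = _moments(low_set, "low")
    high = _moments(high_set, "high")
    return IntensityModel(t_low_frac=t_low_frac, t_high_frac=t_high_frac,
                          max_intensity=mx, low=low, high=high,
                          n_low=int(low_set.size), n_high=int(high_set.size))


def _log_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return -np.log(sigma) - 0.5 * ((x - mu) / sigma) ** 2


def classify_voxels(vol: Volume, roi: Mask, model: IntensityModel,
                    monotone: bool = False) -> Mask:
    """Label roi voxels synovitis where the high PDF beats the low PDF.

    The output is always a subset of ``roi``; exact PDF ties are labelled
    not-synovitis.  ``monotone=True`` replaces the two-PDF comparison with a
    simple cut at the crossing between the two means.
    """
    if roi.kind != "binary":
        raise ValueError("roi must be a binary mask")
    if not roi.same_grid(vol):
        raise ValueError(
            f"roi grid {roi.shape}/{roi.spacing} does not match volume grid "
            f"{vol.shape}/{vol.spacing}")
    x = vol.data
    if monotone:
        keep = x > _crossing_between_means(model)
    else:
        keep = _log_pdf(x, *model.high) > _log_pdf(x, *model.low)
    out = np.where(roi.data > 0, keep.astype(np.float64), 0.0)
    return roi.with_data(out, kind="binary")


def _crossing_between_means(model: IntensityModel) -> float:
    """The PDF crossing located between the two means.

    Solves the quadratic log-PDF equality; with equal sigmas this is the
    midpoint of the means."""
    (m1, s1), (m2, s2) = model.low, model.high
    if abs(s1 - s2) < 1e-12 * max(s1, s2):
        return 0.5 * (m1 + m2)
    a = 1.0 / (2 * s1 ** 2) - 1.0 / (2 * s2 ** 2)
    b = m2 / s2 ** 2 - m1 / s1 ** 2
    c = m1 ** 2 / (2 * s1 ** 2) - m2 ** 2 / (2 * s2 ** 2) + np.log(s2 / s1)
    roots = np.roots([a, b, c])
    roots = roots[np.isreal(roots)].real
    inside = roots[(roots > m1) & (roots < m2)]
    if inside.size:
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def rethreshold(vol: Volume, roi: Mask, t_low_frac: float,
                t_high_frac: float, robust_max: bool = False,
                monotone: bool = False) -> Mask:
    """Refit the intensity model with new fractions and reclassify the roi."""
    model = fit_intensity_model(vol, t_low_frac, t_high_frac,
                                robust_max=robust_max)
    return classify_voxels(vol, roi, model, monotone=monotone)
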