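"""Domain types and NIfTI I/O for volumetric images and masks.

A :class:`Volume` is a 3-D scalar image with voxel spacing in millimetres;
a :class:`Mask` is a label field (binary or probabilistic) living on the grid
of a paired Volume.  The through-plane axis is stored explicitly because the
sagittal knee stacks this package targets are strongly anisotropic: 3 mm
slices with a 0.3 mm gap, i.e. a centre-to-centre slice spacing of 3.3 mm.

Voxel volume uses the centre-to-centre slice spacing (thickness + gap) so
that summation over contiguous slices covers the joint without double
counting or holes; a thickness-only convention is available via
``slice_thickness_only`` where volumes are computed (see ``workflow``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage


class FormatError(ValueError):
    """Raised for unreadable, non-3D or otherwise malformed image files."""


class GridMismatchError(ValueError):
    """Raised when a mask and a volume do not share a voxel grid."""


@dataclass(frozen=True)
class Volume:
    """A 3-D scalar image with grid metadata.

    Parameters
    ----------
    data:
        3-D array of intensities (arbitrary units), axis order (x, y, z).
    spacing:
        Voxel spacing ``(dx, dy, dz)`` in mm.  ``dz`` is the centre-to-centre
        slice spacing (slice thickness + slice gap).
    origin:
        World coordinates of voxel (0, 0, 0) in mm.
    slice_axis:
        Index of the through-plane axis (2 for sagittal stacks stored x, y, z).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 2

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D image, got {data.ndim}-D")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be three positive values, got {self.spacing}")
        if not np.all(np.isfinite(data)):
            raise FormatError("image contains non-finite intensities")
        if self.slice_axis not in (0, 1, 2):
            raise FormatError(f"slice_axis must be 0, 1 or 2, got {self.slice_axis}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of a single voxel, dx*dy*dz in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | Mask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data, dtype=np.float64))


@dataclass(frozen=True)
class Mask:
    """A binary or probabilistic label field on a Volume's grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    slice_axis: int = 2
    kind: Literal["binary", "probabilistic"] = "binary"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if data.ndim != 3:
            raise FormatError(f"expected a 3-D mask, got {data.ndim}-D")
        if any(s <= 0 for s in self.spacing):
            raise FormatError(f"spacing must be positive, got {self.spacing}")
        if self.kind == "binary":
            if not np.isin(data, (0.0, 1.0)).all():
                raise ValueError("binary mask must contain only {0, 1}")
        else:
            if data.min() < 0 or data.max() > 1 + 1e-9:
                raise ValueError("probabilistic mask values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_count(self) -> int:
        if self.kind != "binary":
            raise ValueError("voxel_count is defined for binary masks only")
        return int(self.data.sum())

    def same_grid(self, other: "Volume | Mask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def with_data(self, data: np.ndarray, kind: str | None = None) -> "Mask":
        return replace(self, data=np.asarray(data, dtype=np.float64),
                       kind=kind or self.kind)


def mask_like(vol: Volume, data: np.ndarray, kind: str = "binary") -> Mask:
    """Build a Mask on ``vol``'s grid from an array."""
    return Mask(data=np.asarray(data, dtype=np.float64), spacing=vol.spacing,
                origin=vol.origin, slice_axis=vol.slice_axis, kind=kind)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine_from_grid(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file as a :class:`Volume`.

    The image is reoriented to canonical (RAS) axis order so that the
    anatomy-to-axis mapping is consistent across acquisitions; spacing and
    origin are taken from the header affine, with ``dz`` the through-plane
    centre-to-centre spacing.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FormatError(f"cannot read NIfTI file {path}: {exc}") from exc
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data=np.asarray(data, dtype=np.float64),
                  spacing=tuple(float(z) for z in zooms), origin=origin)


def read_mask(path: str | Path, kind: str = "binary") -> Mask:
    """Read a NIfTI-1 label field as a :class:`Mask`."""
    vol = read_volume(path)
    return mask_like(vol, vol.data, kind=kind)


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 with the grid encoded in the affine."""
    img = nib.Nifti1Image(vol.data.astype(np.float32),
                          _affine_from_grid(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def write_mask(mask: Mask, path: str | Path, paired: Volume | None = None) -> None:
    """Write a Mask as NIfTI-1; binary masks are written as integer labels.

    If ``paired`` is given, the mask grid is validated against it first.
    """
    if paired is not None and not mask.same_grid(paired):
        raise GridMismatchError(
            f"mask grid {mask.shape}/{mask.spacing} does not match "
            f"volume grid {paired.shape}/{paired.spacing}")
    if mask.kind == "binary":
        arr = mask.data.astype(np.uint8)
    else:
        arr = mask.data.astype(np.float32)
    img = nib.Nifti1Image(arr, _affine_from_grid(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Target grid for resampling: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid grid spacing {self.spacing}")


def resample_to_grid(vol: Volume, target: GridSpec,
                     interpolation: Literal["nearest", "linear"] = "linear") -> Volume:
    """Resample a volume onto ``target``.

    Linear interpolation for images, nearest for label maps.  World
    coordinates of target voxels are mapped into source voxel coordinates via
    both affines; samples falling outside the source grid take the edge value.
    Raises if the two grids do not overlap at all.
    """
    if interpolation not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    same = (tuple(target.shape) == vol.shape
            and np.allclose(target.spacing, vol.spacing)
            and np.allclose(target.origin, vol.origin))
    if same:
        return Volume(vol.data.copy(), vol.spacing, vol.origin, vol.slice_axis)

    # world coords of target voxel centres -> source voxel coords
    axes = [target.origin[k] + target.spacing[k] * np.arange(target.shape[k])
            for k in range(3)]
    world = np.meshgrid(*axes, indexing="ij")
    coords = [(world[k] - vol.origin[k]) / vol.spacing[k] for k in range(3)]

    lo = [c.min() for c in coords]
    hi = [c.max() for c in coords]
    if any(h < -0.5 or l > vol.shape[k] - 0.5 for k, (l, h) in enumerate(zip(lo, hi))):
        raise ValueError("target grid has no overlap with the source volume")

    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(vol.data, np.stack(coords), order=order,
                                  mode="nearest")
    return Volume(out, target.spacing, target.origin, vol.slice_axis)


def resample_mask_to_grid(mask: Mask, target: GridSpec) -> Mask:
    """Resample a mask (nearest neighbour for binary, linear for probabilistic)."""
    as_vol = Volume(mask.data, mask.spacing, mask.origin, mask.slice_axis)
    interp = "nearest" if mask.kind == "binary" else "linear"
    out = resample_to_grid(as_vol, target, interpolation=interp)
    data = np.clip(out.data, 0.0, 1.0)
    return Mask(data, out.spacing, out.origin, mask.slice_axis, mask.kind)
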