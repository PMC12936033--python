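"""Image grids, isotropic resampling, and peritumoral expansion.

The volume of interest used throughout the pipeline is the gross tumor
volume (GTV) plus a peritumoral ring obtained by expanding the GTV by a
physical margin (default 3 mm) and clipping the expansion to the lung mask,
so that the ring never includes chest wall or mediastinum.  GTV plus ring
together form the whole volume of interest (WVOI).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class ImageVolume:
    """A 3-D scalar image on a regular grid with physical spacing in mm."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be positive, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class RegionMask:
    """A binary voxel set sharing grid geometry with a companion volume."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {values.shape}")
        uniq = np.unique(values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        object.__setattr__(self, "values", values.astype(bool))
        object.__setattr__(
            self, "spacing_mm", tuple(float(s) for s in self.spacing_mm)
        )
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    def same_grid(self, other: "ImageVolume | RegionMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin, other.origin)
        )


@dataclass(frozen=True)
class WVOIRegions:
    """GTV, peritumoral ring, and their union (the WVOI)."""

    gtv: RegionMask
    ring: RegionMask
    wvoi: RegionMask

    def __post_init__(self) -> None:
        if np.any(self.gtv.values & self.ring.values):
            raise ValueError("gtv and ring overlap")
        if not np.array_equal(self.wvoi.values, self.gtv.values | self.ring.values):
            raise ValueError("wvoi must equal gtv | ring")


def resample_isotropic(
    volume: ImageVolume,
    masks: list[RegionMask],
    target_mm: float = 1.0,
    image_order: int = 0,
    subject_id: str | None = None,
) -> tuple[ImageVolume, list[RegionMask]]:
    """Resample an image and its masks to an isotropic grid.

    Masks always use nearest-neighbor interpolation so they stay binary.
    ``image_order`` selects the image interpolation (0 = nearest-neighbor,
    the default, 1 = trilinear).

    Raises ``ValueError`` if a nonempty mask becomes empty after resampling.
    """
    if target_mm <= 0:
        raise ValueError(f"target_mm must be positive, got {target_mm}")
    if image_order not in (0, 1):
        raise ValueError("image_order must be 0 (nearest) or 1 (linear)")
    zoom = np.asarray(volume.spacing_mm, dtype=float) / target_mm
    if np.allclose(zoom, 1.0):
        out_masks = [
            RegionMask(m.values, (target_mm,) * 3, m.origin) for m in masks
        ]
        return ImageVolume(volume.values, (target_mm,) * 3, volume.origin), out_masks

    new_values = ndimage.zoom(
        volume.values, zoom, order=image_order, mode="nearest", grid_mode=True
    )
    out_volume = ImageVolume(new_values, (target_mm,) * 3, volume.origin)
    out_masks = []
    for i, mask in enumerate(masks):
        if not mask.same_grid(volume):
            raise ValueError(f"mask {i} is not on the volume grid")
        resampled = ndimage.zoom(
            mask.values.astype(np.uint8), zoom, order=0, mode="nearest", grid_mode=True
        )
        was_nonempty = mask.n_voxels > 0
        out = RegionMask(resampled, (target_mm,) * 3, mask.origin)
        if was_nonempty and out.n_voxels == 0:
            who = f" (subject {subject_id})" if subject_id else ""
            raise ValueError(f"mask {i} became empty after resampling{who}")
        out_masks.append(out)
    return out_volume, out_masks


def expand_gtv(
    gtv: RegionMask, lung: RegionMask, margin_mm: float = 3.0
) -> WVOIRegions:
    """Expand the GTV by ``margin_mm`` and clip the ring to the lung mask.

    The ring is every non-GTV voxel whose Euclidean distance (in physical
    mm) to the nearest GTV voxel is <= ``margin_mm``, intersected with the
    lung mask.  The inclusive threshold is deliberate: a 1-voxel GTV at
    1 mm spacing and a 3 mm margin yields exactly the 123 lattice points
    with x^2+y^2+z^2 <= 9.
    """
    if gtv.n_voxels == 0:
        raise ValueError("gtv mask is empty")
    if not gtv.same_grid(lung):
        raise ValueError("gtv and lung masks are on different grids")
    if np.any(gtv.values & ~lung.values):
        warnings.warn(
            "GTV extends outside the lung mask; GTV kept verbatim, "
            "only the ring is clipped",
            stacklevel=2,
        )
    if margin_mm < 0:
        raise ValueError("margin_mm must be >= 0")

    if margin_mm == 0:
        ring_values = np.zeros(gtv.shape, dtype=bool)
    else:
        # EDT from the complement: distance of each voxel to nearest GTV voxel.
        dist = ndimage.distance_transform_edt(
            ~gtv.values, sampling=gtv.spacing_mm
        )
        ring_values = (dist <= margin_mm) & ~gtv.values & lung.values
    ring = RegionMask(ring_values, gtv.spacing_mm, gtv.origin)
    wvoi = RegionMask(gtv.values | ring_values, gtv.spacing_mm, gtv.origin)
    return WVOIRegions(gtv=gtv, ring=ring, wvoi=wvoi)


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(spacing: tuple[float, ...], origin: tuple[float, ...]) -> np.ndarray:
    affine = np.diag(list(spacing) + [1.0])
    affine[:3, 3] = origin
    return affine


def save_volume(volume: ImageVolume, path) -> None:
    img = nib.Nifti1Image(
        volume.values.astype(np.float32), _affine(volume.spacing_mm, volume.origin)
    )
    nib.save(img, str(path))


def save_mask(mask: RegionMask, path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing_mm, mask.origin)
    )
    nib.save(img, str(path))


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return ImageVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path) -> RegionMask:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return RegionMask(np.asarray(img.dataobj) > 0.5, spacing, origin)
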