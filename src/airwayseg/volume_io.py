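"""Reading, writing and cropping of CT volumes and binary masks.

Conventions used throughout the package:

* voxel indices are 0-based with a fixed ``(x, y, z)`` axis order;
* a :class:`CropBox` is half-open, ``[lo, hi)`` componentwise;
* Hounsfield values below ``HU_FLOOR`` (-2048, the CT minimum) are clamped
  on load with a warning, since scanner exports occasionally contain
  padding values below the CT range;
* binary masks are persisted as 0/1 integer volumes in the same container
  formats (NIfTI, MetaImage) as the CT data.

All geometric arithmetic is in voxel units; spacing and origin are carried
along for metric reporting only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

logger = logging.getLogger(__name__)

#: Minimum representable CT value; also the fill value outside constraint
#: regions (Eq. of the restricted image).
HU_FLOOR = -2048


@dataclass
class CTVolume:
    """A 3D integer Hounsfield-unit grid with voxel spacing and origin.

    ``data`` is indexed ``data[x, y, z]``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"CTVolume requires a 3D array, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("CTVolume shape components must all be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")
        if self.data.size and int(self.data.min()) < HU_FLOOR:
            raise ValueError(
                f"CTVolume contains values below the CT floor {HU_FLOOR}; "
                "clamp before constructing (load_volume does this automatically)"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)


@dataclass(frozen=True)
class CropBox:
    """Half-open axis-aligned index box ``[lo, hi)`` inside ``parent_shape``."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    parent_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        for a, (l, h, n) in enumerate(zip(self.lo, self.hi, self.parent_shape)):
            if not (0 <= l < h <= n):
                raise ValueError(
                    f"invalid CropBox on axis {a}: lo={l}, hi={h}, parent={n}"
                )

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(h - l for l, h in zip(self.lo, self.hi))

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, h) for l, h in zip(self.lo, self.hi))


def load_volume(path: str | Path) -> CTVolume:
    """Read a NIfTI or MetaImage volume into a :class:`CTVolume`.

    Values below -2048 HU are clamped to -2048 and a warning is logged.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"volume file not found: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - SimpleITK error text varies
        raise IOError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3D image, got {img.GetDimension()}D")
    # SimpleITK arrays come back (z, y, x); transpose to our (x, y, z).
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if data.size and data.min() < HU_FLOOR:
        n = int((data < HU_FLOOR).sum())
        logger.warning(
            "%s: clamped %d voxel(s) below %d HU to the CT floor", path, n, HU_FLOOR
        )
        data = np.maximum(data, HU_FLOOR)
    return CTVolume(
        data=np.ascontiguousarray(data),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )


def save_volume(vol: CTVolume, path: str | Path) -> None:
    """Write a volume (or 0/1 mask stored as integers) to NIfTI/MetaImage."""
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"parent directory does not exist: {path.parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    sitk.WriteImage(img, str(path))


def save_mask(mask: np.ndarray, path: str | Path,
              spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
              origin: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> None:
    """Persist a boolean mask as a 0/1 uint8 volume."""
    save_volume(CTVolume(np.asarray(mask).astype(np.uint8), spacing, origin), path)


def load_mask(path: str | Path) -> np.ndarray:
    """Load a 0/1 integer volume back as a boolean array."""
    vol = load_volume(path)
    vals = np.unique(vol.data)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"{path}: not a binary mask (values {vals[:10]})")
    return vol.data.astype(bool)


def crop(vol: CTVolume, box: CropBox) -> CTVolume:
    """Extract the subvolume ``vol[lo:hi]``; output voxel (i,j,k) equals
    input voxel lo+(i,j,k)."""
    if tuple(box.parent_shape) != vol.shape:
        raise ValueError(
            f"CropBox parent shape {box.parent_shape} does not match volume {vol.shape}"
        )
    return CTVolume(vol.data[box.slices].copy(), vol.spacing, vol.origin)


def paste(target: np.ndarray, patch: np.ndarray, box: CropBox,
          combine: str = "replace") -> None:
    """Write ``patch`` back into ``target`` at ``box`` (in place).

    ``combine='or'`` is used for accumulating binary masks.
    """
    if tuple(box.parent_shape) != target.shape:
        raise ValueError("CropBox parent shape does not match target")
    if tuple(patch.shape) != box.shape:
        raise ValueError("patch shape does not match CropBox")
    if combine == "replace":
        target[box.slices] = patch
    elif combine == "or":
        target[box.slices] |= patch
    else:
        raise ValueError(f"unknown combine mode {combine!r}")


def expand_box(surface_bbox: CropBox, R: int,
               parent_shape: tuple[int, int, int] | None = None) -> CropBox:
    """Expand a bounding box by ``R`` voxels per side, clamped to the parent."""
    if R < 0:
        raise ValueError("R must be >= 0")
    shape = tuple(parent_shape) if parent_shape is not None else surface_bbox.parent_shape
    lo = tuple(max(0, l - R) for l in surface_bbox.lo)
    hi = tuple(min(n, h + R) for h, n in zip(surface_bbox.hi, shape))
    return CropBox(lo=lo, hi=hi, parent_shape=shape)


def bbox_of_mask(mask: np.ndarray) -> CropBox:
    """Tight bounding box of the nonzero voxels of ``mask``."""
    if not mask.any():
        raise ValueError("cannot take bounding box of an empty mask")
    idx = np.nonzero(mask)
    lo = tuple(int(i.min()) for i in idx)
    hi = tuple(int(i.max()) + 1 for i in idx)
    return CropBox(lo=lo, hi=hi, parent_shape=tuple(mask.shape))
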