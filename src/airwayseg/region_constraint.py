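"""Quasi-spherical constraint-region initialization.

Each segmentation stage starts from a *seed surface*: a 26-connected patch
of voxels where the previous stage's result crossed its region boundary
(the very first stage uses a single user-supplied voxel).  From that
surface this module derives

* the region radius ``R = 3 * ceil(area / 100) + 5`` (floored at 8), using
  the surface voxel count as a stand-in for the airway cross-sectional
  area;
* the threshold window: ``Seed = min`` and ``Threshold = max - min + 1``
  of the HU values on the surface, optionally floored by
  ``initial_threshold_override``;
* a cropped working block (surface bounding box expanded by R);
* optional tracheal-wall enhancement of the block;
* the quasi-sphere itself: the dilation of the surface by a Euclidean ball
  of radius R, its one-layer boundary shell, and the restricted image that
  equals the block inside the region and the CT floor (-2048) outside.

Dilation by ``Sphere(R)`` is evaluated through the exact Euclidean
distance transform (``distance <= R``), which is identical to binary
dilation with the ball structuring element but does not scale with R.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Config, RADIUS_FLOOR
from .volume_io import HU_FLOOR, CTVolume, CropBox, bbox_of_mask, crop, expand_box

#: 26-connectivity structuring element (components of thin diagonal sheets
#: must not fragment).
STRUCT26 = np.ones((3, 3, 3), dtype=bool)
#: 6-connectivity element = Sphere(1), the propagation step of Eq. 7.
STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class SeedSurface:
    """One 26-connected seed point set, in parent-volume coordinates."""

    K: int
    voxels: np.ndarray  # (n, 3) int array of (x, y, z)
    surface_hu: np.ndarray  # (n,) HU values at those voxels
    bbox: CropBox

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.int64).reshape(-1, 3)
        self.surface_hu = np.asarray(self.surface_hu).reshape(-1)
        if len(self.voxels) == 0:
            raise ValueError("SeedSurface must contain at least one voxel")
        if len(self.surface_hu) != len(self.voxels):
            raise ValueError("surface_hu must have exactly one entry per voxel")

    @property
    def area(self) -> int:
        return len(self.voxels)


@dataclass
class RegionContext:
    """Per-region state after initialization."""

    K: int
    R: int
    Seed: int
    Threshold: int
    Threshold0: int
    box: CropBox
    T: CTVolume  # cropped (and possibly enhanced) image block
    P_area0: np.ndarray  # bool mask of the seed surface, crop coordinates
    is_bootstrap: bool = False

    def __post_init__(self) -> None:
        if self.R < RADIUS_FLOOR:
            raise ValueError(f"region radius {self.R} below the floor {RADIUS_FLOOR}")
        if self.Threshold < 1:
            raise ValueError("Threshold must be >= 1")
        if self.Seed < HU_FLOOR:
            raise ValueError(f"Seed below the CT floor {HU_FLOOR}")
        if not self.P_area0.any():
            raise ValueError("P_area0 must be nonzero")


@dataclass
class QuasiSphere:
    """Constraint region, its boundary shell, and the restricted image."""

    region: np.ndarray  # bool, crop coordinates
    shell: np.ndarray  # bool; region minus dilation by Sphere(R-1)
    restricted: np.ndarray  # int; block inside region, -2048 outside


def sphere_element(R: int) -> np.ndarray:
    """Euclidean-ball structuring element of radius ``R`` (side ``2R+1``)."""
    if R < 1:
        raise ValueError("sphere_element requires R >= 1")
    ax = np.arange(-R, R + 1)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return (x * x + y * y + z * z) <= R * R


def dilate_ball(mask: np.ndarray, R: int) -> np.ndarray:
    """Binary dilation of ``mask`` by ``sphere_element(R)``.

    Computed as Euclidean distance-to-mask <= R, which is exact on the
    integer grid and independent of R in cost.
    """
    if R == 0:
        return mask.copy()
    dist = ndimage.distance_transform_edt(~mask)
    return dist <= R


def extract_seed_surfaces(candidate: np.ndarray, volume: CTVolume,
                          first_label: int = 1) -> list[SeedSurface]:
    """Split a mask into 26-connected components, each a :class:`SeedSurface`.

    Components are numbered from ``first_label`` in lexicographic order of
    each component's minimum voxel, for deterministic stack ordering.
    """
    candidate = np.asarray(candidate, dtype=bool)
    if candidate.shape != volume.shape:
        raise ValueError(
            f"candidate shape {candidate.shape} does not match volume {volume.shape}"
        )
    if not candidate.any():
        return []
    labels, n = ndimage.label(candidate, structure=STRUCT26)
    comps = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        comps.append(vox)
    # deterministic ordering by each component's lexicographic minimum voxel
    comps.sort(key=lambda v: tuple(v[np.lexsort(v.T[::-1])][0]))
    surfaces = []
    for i, vox in enumerate(comps):
        hu = volume.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        mask = np.zeros(volume.shape, dtype=bool)
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        surfaces.append(
            SeedSurface(K=first_label + i, voxels=vox, surface_hu=hu,
                        bbox=bbox_of_mask(mask))
        )
    return surfaces


def compute_region_radius(area: int) -> int:
    """Initial region radius from the seed-surface voxel count.

    ``R = 3 * ceil(area / 100) + 5``, floored at 8 (the floor is only
    reachable through later radius adaptation; the formula itself gives
    >= 8 for any area >= 1).
    """
    if area < 1:
        raise ValueError("surface area must be >= 1")
    R = 3 * int(np.ceil(area / 100)) + 5
    return max(R, RADIUS_FLOOR)


def compute_threshold_params(surface_hu: np.ndarray) -> tuple[int, int]:
    """``Seed = min``, ``Threshold = max - min + 1`` over the surface HU."""
    hu = np.asarray(surface_hu)
    if hu.size == 0:
        raise ValueError("surface_hu must be nonempty")
    seed = int(hu.min())
    threshold = int(hu.max()) - seed + 1
    return seed, threshold


def _axis_wall_response(T: np.ndarray, axis: int, min_gradient: int) -> np.ndarray:
    """Wall response along one axis: local maxima of |forward difference|
    at or above ``min_gradient``, marking the brighter voxel of the pair,
    with runs along the axis collapsed to their brightest voxel."""
    d = np.diff(T, axis=axis)  # d[i] = T[i+1] - T[i]
    g = np.abs(d).astype(np.int64)
    # local maximum along the axis among the difference samples
    pad = [(0, 0)] * 3
    pad[axis] = (1, 1)
    gp = np.pad(g, pad, constant_values=-1)
    sl_lo = [slice(None)] * 3
    sl_hi = [slice(None)] * 3
    sl_lo[axis] = slice(0, g.shape[axis])
    sl_hi[axis] = slice(2, g.shape[axis] + 2)
    is_max = (g >= gp[tuple(sl_lo)]) & (g >= gp[tuple(sl_hi)]) & (g >= min_gradient)
    # mark the brighter voxel of each maximal difference pair
    lo = [slice(None)] * 3
    hi = [slice(None)] * 3
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    T_lo, T_hi = T[tuple(lo)], T[tuple(hi)]
    marked = np.zeros(T.shape, dtype=bool)
    take_hi = is_max & (d > 0)
    take_lo = is_max & (d <= 0)
    marked[tuple(hi)] |= take_hi
    marked[tuple(lo)] |= take_lo
    # collapse runs of marked voxels along this axis to the brightest voxel
    runs, n = ndimage.label(marked, structure=_axis_structure(axis))
    if n:
        keep = np.zeros_like(marked)
        bright = np.where(marked, T, np.iinfo(np.int64).min)
        for sl in ndimage.find_objects(runs):
            sub = bright[sl]
            flat = int(np.argmax(sub))
            idx = np.unravel_index(flat, sub.shape)
            keep[tuple(s.start + i for s, i in zip(sl, idx))] = True
        marked = keep
    return marked


def _axis_structure(axis: int) -> np.ndarray:
    s = np.zeros((3, 3, 3), dtype=bool)
    s[1, 1, 1] = True
    idx = [1, 1, 1]
    for off in (0, 2):
        idx[axis] = off
        s[tuple(idx)] = True
        idx[axis] = 1
    return s


def enhance_walls(T: CTVolume, strength: int, min_gradient: int = 100) -> CTVolume:
    """Raise the HU of a thinned tracheal-wall sheet by ``strength``.

    Forward differences along each axis locate local maxima of the CT
    gradient; the brighter voxel of each difference pair is marked, the
    per-axis maps are thinned along their own axis, and the superposition
    of the three maps is added to the block at ``strength`` HU.
    """
    if min(T.shape) < 3:
        raise ValueError("enhance_walls requires at least 3 voxels per axis")
    if strength == 0:
        return CTVolume(T.data.copy(), T.spacing, T.origin)
    data = T.data.astype(np.int64)
    marked = np.zeros(T.shape, dtype=bool)
    for axis in range(3):
        marked |= _axis_wall_response(data, axis, min_gradient)
    out = data.copy()
    out[marked] += int(strength)
    return CTVolume(out, T.spacing, T.origin)


def build_quasi_sphere(ctx: RegionContext) -> QuasiSphere:
    """Region = P_area0 dilated by Sphere(R); shell = region minus the
    Sphere(R-1) dilation; restricted image = block inside region, -2048
    outside."""
    dist = ndimage.distance_transform_edt(~ctx.P_area0)
    region = dist <= ctx.R
    inner = dist <= (ctx.R - 1)
    shell = region & ~inner
    restricted = np.where(region, ctx.T.data, HU_FLOOR).astype(np.int64)
    return QuasiSphere(region=region, shell=shell, restricted=restricted)


def init_region(surface: SeedSurface, volume: CTVolume, config: Config,
                is_bootstrap: bool = False) -> RegionContext:
    """Initialize a constraint region from a seed surface.

    Seed/Threshold are computed from the unenhanced volume (seed surfaces
    lie in the lumen, where enhancement never fires); the crop is the
    surface bounding box expanded by R; enhancement is applied to the
    cropped block when enabled.
    """
    R = compute_region_radius(surface.area)
    seed, threshold = compute_threshold_params(surface.surface_hu)
    threshold = max(threshold, config.region.initial_threshold_override)
    box = expand_box(surface.bbox, R, volume.shape)
    T = crop(volume, box)
    if config.region.enhancement:
        T = enhance_walls(T, config.region.enhancement_strength,
                          config.region.enhancement_min_gradient)
    P = np.zeros(box.shape, dtype=bool)
    off = np.asarray(box.lo)
    local = surface.voxels - off
    P[local[:, 0], local[:, 1], local[:, 2]] = True
    return RegionContext(
        K=surface.K, R=R, Seed=seed, Threshold=threshold, Threshold0=threshold,
        box=box, T=T, P_area0=P, is_bootstrap=is_bootstrap,
    )


def bootstrap_surface(volume: CTVolume, seed_voxel: tuple[int, int, int]) -> SeedSurface:
    """Wrap the user-supplied trachea voxel as an area-1 seed surface."""
    x, y, z = (int(c) for c in seed_voxel)
    for c, n in zip((x, y, z), volume.shape):
        if not (0 <= c < n):
            raise ValueError(f"seed voxel {seed_voxel} outside volume {volume.shape}")
    mask = np.zeros(volume.shape, dtype=bool)
    mask[x, y, z] = True
    return SeedSurface(
        K=1,
        voxels=np.array([[x, y, z]]),
        surface_hu=np.array([volume.data[x, y, z]]),
        bbox=bbox_of_mask(mask),
    )
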