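"""Synthetic branching-tube CT phantoms with voxel-exact ground truth.

The phantom emulates the three tissue plateaus a chest CT presents to an
airway segmenter: a dark lumen (about -1000 HU, inside the "definitely
airway" band below -950), a bright thin wall, and surrounding parenchyma
inside the uncertain band (-950, -775) where leakage originates.  Optional
Gaussian noise and deliberately inserted low-brightness wall gaps (1-3
voxels along the branch axis, the range the sealing algorithm is designed
for) complete the picture.

Geometry is a binary tree of straight cylindrical segments: the root
enters through the z=0 face (an open trachea, as in a real scan), each
child's radius is the parent's times ``radius_decay``, and bifurcation
planes alternate between xz and yz so the tree spreads in 3D.  Segments
are rasterized by exact distance-to-segment, which guarantees a continuous
wall shell of the requested thickness: a 6-connected path from lumen to
parenchyma must cross it.

Default palette: lumen -1000, parenchyma -940, wall -400, gap -935 HU.
The parenchyma sits at the dark end of the uncertain band, close enough to
the lumen that realistic segmentation windows (on the order of 100 HU)
reach it — the regime in which airway leakage actually happens and the
constraint region and gap sealing have something to do.  A brighter
parenchyma would make every threshold trivially safe and the leak
machinery untestable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .volume_io import HU_FLOOR, CTVolume


@dataclass(frozen=True)
class GapSpec:
    """A deliberate low-brightness wall gap on one branch.

    ``extent`` is the axial thickness of the gap ring in voxels; 1-3 is
    the sealable range (the closing-based sealing cannot bridge wider
    gaps), ``allow_oversize`` admits wider rings for negative tests.
    """

    branch_id: int
    axial_position: float
    extent: int
    gap_hu: int
    allow_oversize: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.axial_position <= 1.0:
            raise ValueError("axial_position must lie in [0, 1]")
        if self.extent < 1:
            raise ValueError("gap extent must be >= 1")
        if self.extent > 3 and not self.allow_oversize:
            raise ValueError(
                "gap extent > 3 voxels is outside the sealable range; "
                "set allow_oversize=True for negative tests"
            )


@dataclass(frozen=True)
class Branch:
    """One straight segment of the airway tree (voxel coordinates)."""

    branch_id: int
    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    generation: int
    parent_id: int | None


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (96, 96, 96)
    generations: int = 3
    root_radius: float = 4.0
    radius_decay: float = 0.8
    branch_angle: float = 35.0
    wall_thickness: int = 2
    root_length: float = 30.0
    length_decay: float = 0.8
    lumen_hu: int = -1000
    wall_hu: int = -400
    parenchyma_hu: int = -940
    noise_sd: float = 10.0
    gaps: tuple[GapSpec, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lumen_hu < self.parenchyma_hu < self.wall_hu):
            raise ValueError("need lumen_hu < parenchyma_hu < wall_hu")
        if self.lumen_hu > -950:
            raise ValueError("lumen_hu must be <= -950 (definitely-airway band)")
        if not (-950 < self.parenchyma_hu < -775):
            raise ValueError("parenchyma_hu must lie in (-950, -775)")
        if self.root_radius < 2:
            raise ValueError("root_radius must be >= 2")
        if self.wall_thickness < 1:
            raise ValueError("wall_thickness must be >= 1")
        if not (0 < self.radius_decay <= 1):
            raise ValueError("radius_decay must lie in (0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        for g in self.gaps:
            if not (self.lumen_hu < g.gap_hu < self.wall_hu):
                raise ValueError("gap_hu must lie strictly between lumen and wall HU")
        self.gaps = tuple(self.gaps)


@dataclass
class PhantomBundle:
    """A generated phantom with its voxel-exact ground truth."""

    volume: CTVolume
    lumen: np.ndarray
    wall: np.ndarray
    centerline: np.ndarray
    branch_count: int
    tree_length_voxels: int
    branches: list[Branch] = field(default_factory=list)
    branch_centerlines: list[np.ndarray] = field(default_factory=list)
    gap_voxels: list[np.ndarray] = field(default_factory=list)
    spec: PhantomSpec | None = None


def _rotation(axis: int, theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    if axis == 0:  # about x: mixes y, z
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])  # about y: mixes x, z


def build_tree(spec: PhantomSpec) -> list[Branch]:
    """Lay out the binary tree of straight segments, breadth-first ids."""
    nx, ny, nz = spec.shape
    root_start = np.array([nx / 2.0, ny / 2.0, 0.0])
    direction = np.array([0.0, 0.0, 1.0])
    theta = np.deg2rad(spec.branch_angle)
    branches: list[Branch] = []
    frontier = [(root_start, direction, None)]
    bid = 0
    for gen in range(spec.generations):
        length = spec.root_length * spec.length_decay ** gen
        radius = spec.root_radius * spec.radius_decay ** gen
        nxt = []
        for start, u, parent in frontier:
            end = start + u * length
            branches.append(
                Branch(branch_id=bid, p0=tuple(start), p1=tuple(end),
                       radius=radius, generation=gen, parent_id=parent)
            )
            axis = 1 if gen % 2 == 0 else 0  # alternate bifurcation planes
            for sign in (+1, -1):
                nxt.append((end, _rotation(axis, sign * theta) @ u, bid))
            bid += 1
        frontier = nxt
    return branches


def _segment_distance_block(branch: Branch, shape, margin: float):
    """Distance to the segment on a bounding sub-block; returns
    (slices, distance array, axial parameter t in [0,1])."""
    p0, p1 = np.asarray(branch.p0), np.asarray(branch.p1)
    lo = np.maximum(np.floor(np.minimum(p0, p1) - margin).astype(int), 0)
    hi = np.minimum(np.ceil(np.maximum(p0, p1) + margin).astype(int) + 1, shape)
    if (hi <= lo).any():
        raise ValueError(
            f"branch {branch.branch_id} lies entirely outside the volume"
        )
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    grid = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    pts = np.stack(grid, axis=-1).astype(float)
    v = p1 - p0
    vv = float(v @ v)
    t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
    proj = p0 + t[..., None] * v
    dist = np.linalg.norm(pts - proj, axis=-1)
    return sl, dist, t


def _check_fit(branch: Branch, shape, pad: float) -> None:
    p0, p1 = np.asarray(branch.p0), np.asarray(branch.p1)
    lo = np.minimum(p0, p1) - pad
    hi = np.maximum(p0, p1) + pad
    # the root is allowed to open through the z=0 entry face
    lo_ok = (lo >= 0) | (np.arange(3) == 2) & (branch.generation == 0)
    if not (lo_ok.all() and (hi <= np.asarray(shape)).all()):
        raise ValueError(
            f"branch {branch.branch_id} (generation {branch.generation}) does "
            f"not fit inside the volume {tuple(shape)} with clearance {pad}"
        )


def apply_gap(volume: CTVolume, wall: np.ndarray, gap: GapSpec,
              branches: list[Branch]) -> tuple[CTVolume, np.ndarray]:
    """Write ``gap_hu`` onto the wall ring of one branch.

    The gap is the set of wall voxels of the named branch whose axial
    projection lies within ``extent/2`` of the axial position; exactly
    those voxels change.  Returns the new volume and the (n, 3) gap voxel
    index array.
    """
    byid = {b.branch_id: b for b in branches}
    if gap.branch_id not in byid:
        raise ValueError(f"branch_id {gap.branch_id} does not exist")
    branch = byid[gap.branch_id]
    # generous margin: the wall-mask intersection bounds the ring exactly
    sl, dist, t = _segment_distance_block(branch, volume.shape, branch.radius + 8)
    p0, p1 = np.asarray(branch.p0), np.asarray(branch.p1)
    seg_len = float(np.linalg.norm(p1 - p0))
    axial = (t - gap.axial_position) * seg_len
    in_slab = np.abs(axial) <= gap.extent / 2.0
    ring = in_slab & (dist > branch.radius) & wall[sl]
    if not ring.any():
        raise ValueError(
            f"gap on branch {gap.branch_id} at position {gap.axial_position} "
            "covers no wall voxels"
        )
    out = volume.data.copy()
    block = out[sl]
    block[ring] = gap.gap_hu
    out[sl] = block
    idx_local = np.argwhere(ring)
    offset = np.array([s.start for s in sl])
    return CTVolume(out, volume.spacing, volume.origin), idx_local + offset


def _rasterize_centerline(branch: Branch, shape) -> np.ndarray:
    p0, p1 = np.asarray(branch.p0), np.asarray(branch.p1)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0) * 4)))
    pts = np.round(p0 + np.linspace(0, 1, n)[:, None] * (p1 - p0)).astype(int)
    pts = pts[((pts >= 0) & (pts < np.asarray(shape))).all(axis=1)]
    if len(pts) == 0:
        return pts.reshape(0, 3)
    _, keep = np.unique(pts, axis=0, return_index=True)
    return pts[np.sort(keep)]


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Rasterize the phantom described by ``spec``.

    Deterministic given ``rng_seed``.  The volume is parenchyma everywhere,
    overwritten by the wall shell then the lumen, gaps applied, Gaussian
    noise added, values rounded and clamped to the CT floor.
    """
    shape = np.asarray(spec.shape)
    branches = build_tree(spec)
    pad = spec.root_radius + spec.wall_thickness + 1
    for b in branches:
        _check_fit(b, shape, pad=b.radius + spec.wall_thickness + 1)
    lumen = np.zeros(spec.shape, dtype=bool)
    outer = np.zeros(spec.shape, dtype=bool)
    for b in branches:
        sl, dist, _ = _segment_distance_block(
            b, shape, b.radius + spec.wall_thickness + 1)
        lumen[sl] |= dist <= b.radius
        outer[sl] |= dist <= b.radius + spec.wall_thickness
    wall = outer & ~lumen

    volume = np.full(spec.shape, spec.parenchyma_hu, dtype=np.int64)
    volume[wall] = spec.wall_hu
    volume[lumen] = spec.lumen_hu
    vol = CTVolume(volume, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    gap_sets: list[np.ndarray] = []
    for gap in spec.gaps:
        vol, gvox = apply_gap(vol, wall, gap, branches)
        gap_sets.append(gvox)

    data = vol.data.astype(np.float64)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)
    data = np.maximum(np.rint(data), HU_FLOOR).astype(np.int64)
    vol = CTVolume(data, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))

    centerline = np.zeros(spec.shape, dtype=bool)
    per_branch = []
    for b in branches:
        pts = _rasterize_centerline(b, shape)
        per_branch.append(pts)
        centerline[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    centerline &= lumen

    return PhantomBundle(
        volume=vol,
        lumen=lumen,
        wall=wall,
        centerline=centerline,
        branch_count=len(branches),
        tree_length_voxels=int(centerline.sum()),
        branches=branches,
        branch_centerlines=per_branch,
        gap_voxels=gap_sets,
        spec=spec,
    )
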