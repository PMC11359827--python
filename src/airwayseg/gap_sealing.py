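"""Detection and sealing of low-brightness tracheal-wall gaps.

A wall gap is a stretch of airway wall whose HU has been dragged down by
noise and partial-volume averaging until it falls inside the segmentation
window; threshold growing then escapes through it into the parenchyma.
The sealing algorithm locates such gaps with morphological analysis of
the (deliberately bloomed) leaky segmentation, raises the CT value at the
gap voxels so the wall again blocks the front, and re-segments with a
threshold ratchet (+1 per round) that stops once the threshold has risen
200 HU above its pre-sealing value — roughly the lumen/wall contrast at
small airways, beyond which a gap is either sealed or unsealable.

Gap location combines two views of the combined segmentation mask
``X`` (current leaky result ∪ previous-round segmentation ∪ seed set):

* *crossed breaches*: a gap voxel is wall material, so it lies inside the
  wall slab — dark, but with certain-wall tissue on two opposing sides
  within the wall's span (``close_radius + 2`` voxels).  Removing those
  wall-interior voxels from the hole-filled ``X`` must split it into a
  seed (true airway) side and a leak side; components of the removed set
  that bridge the two sides are the through-paths.  A gap wider than
  ``close_radius + 1`` voxels has interior voxels with no opposing wall
  within the span, is not recognized as wall interior, and therefore
  cannot be sealed — the method's stated 3-voxel limit.
* *uncrossed slits*: when the two sides are not (yet) connected, the
  closing residue ``close(X) - X`` bridges them exactly where the slit
  is (:func:`locate_gaps`, which is purely geometric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import Config
from .region_constraint import (
    STRUCT6,
    STRUCT26,
    QuasiSphere,
    RegionContext,
    sphere_element,
)
from .volume_io import HU_FLOOR, CTVolume
from .wavefront_core import RegionResult, propagate_step, segment_region

logger = logging.getLogger(__name__)

#: HU bound of the "definitely non-airway" band; voxels at or above it are
#: treated as certain wall/tissue when classifying wall-interior material.
WALL_CERTAIN_HU = -775

#: the 13 positive grid directions (axis, face-diagonal, body-diagonal)
_DIRECTIONS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
]


@dataclass
class GapReport:
    """Bookkeeping of one seal/re-segment loop."""

    gap_voxels: np.ndarray  # (n, 3) crop coordinates of sealed voxels
    fill_hu: int
    rounds: int
    threshold_final: int
    capped: bool


def _closed(mask: np.ndarray, radius: int) -> np.ndarray:
    """Binary closing with a Euclidean ball, padded so the image border
    does not truncate the dilation."""
    ball = sphere_element(radius)
    padded = np.pad(mask, radius + 1)
    closed = ndimage.binary_closing(padded, structure=ball)
    sl = tuple(slice(radius + 1, -(radius + 1)) for _ in range(3))
    return closed[sl]


def _shift(mask: np.ndarray, d: tuple[int, int, int], k: int) -> np.ndarray:
    """Mask shifted so that out[v] = mask[v + k*d] (False past the edge)."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for delta, n in zip(d, mask.shape):
        off = delta * k
        if off >= 0:
            src.append(slice(off, n))
            dst.append(slice(0, n - off))
        else:
            src.append(slice(0, n + off))
            dst.append(slice(-off, n))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def _wall_interior(T: np.ndarray, close_radius: int) -> np.ndarray:
    """Voxels lying inside the wall slab.

    A wall-slab voxel has certain-wall tissue on two opposing sides along
    one of the 13 grid directions, with a combined span of at most
    ``close_radius + 2`` voxels, and the wall on each side must be at
    least two voxels deep along that direction (a glancing single-voxel
    contact — e.g. the digital staircase of a curved lumen surface — does
    not count as a wall face)."""
    bright = T >= WALL_CERTAIN_HU
    span = close_radius + 2
    out = np.zeros_like(bright)
    for d in _DIRECTIONS:
        neg = tuple(-c for c in d)
        fw = [_shift(bright, d, k) for k in range(1, span + 1)]
        bw = [_shift(bright, neg, k) for k in range(1, span + 1)]
        deep_fw = [fw[a - 1] & fw[a] for a in range(1, span)]
        deep_bw_cum = []
        acc = np.zeros_like(bright)
        for b in range(1, span):
            acc = acc | (bw[b - 1] & bw[b])
            deep_bw_cum.append(acc.copy())
        for a in range(1, span):
            b_max = span - a
            if b_max >= 1:
                out |= deep_fw[a - 1] & deep_bw_cum[b_max - 1]
    return out & ~bright


def _bridge_components(cand: np.ndarray, side_labels: np.ndarray,
                       require_labels: frozenset[int] | None = None,
                       reach: int = 1) -> np.ndarray:
    """Keep 26-components of ``cand`` whose ``reach``-neighborhood carries
    at least two distinct side labels; when ``require_labels`` is given,
    one of them must be among the touched labels."""
    out = np.zeros_like(cand)
    if not cand.any():
        return out
    labels, n = ndimage.label(cand, structure=STRUCT26)
    for sl, lab in zip(ndimage.find_objects(labels), range(1, n + 1)):
        grow = tuple(slice(max(0, s.start - reach), min(d, s.stop + reach))
                     for s, d in zip(sl, cand.shape))
        comp = labels[grow] == lab
        near = ndimage.binary_dilation(comp, structure=STRUCT26, iterations=reach)
        touched = np.unique(side_labels[grow][near])
        touched = set(int(t) for t in touched if t > 0)
        if len(touched) >= 2 and (require_labels is None or touched & require_labels):
            out[grow] |= comp
    return out


def locate_gaps(X_combined: np.ndarray, close_radius: int) -> np.ndarray:
    """Locate uncrossed wall slits between disconnected parts of a
    segmentation, by pure geometry.

    The closing residue ``close(X) - X`` responds exactly in narrow slits
    between two masses; a residue component is reported when it bridges
    two distinct 26-components of the hole-filled input.  A slit wider
    than the closing can span (about ``2 * close_radius``) produces no
    residue and is not found.  Breaches that the front has already
    crossed leave a single connected component and are handled by the
    HU-aware detection inside :func:`sealing_loop`.  May return an empty
    mask.
    """
    X = ndimage.binary_fill_holes(np.asarray(X_combined, dtype=bool))
    if not X.any():
        return np.zeros_like(X)
    sides, n = ndimage.label(X, structure=STRUCT26)
    if n < 2:
        return np.zeros_like(X)
    D1 = _closed(X, close_radius) & ~X
    # width limit: a slit voxel must see the two masses on opposing sides
    # within a span of close_radius + 2 (slit width <= close_radius + 1);
    # the closing itself can bridge slightly wider slits than the method
    # is meant to seal
    span = close_radius + 2
    ok = np.zeros_like(X)
    for d in _DIRECTIONS:
        neg = tuple(-c for c in d)
        fw = []
        acc = np.zeros_like(X)
        for k in range(1, span):
            acc = acc | _shift(X, d, k)
            fw.append(acc.copy())
        acc = np.zeros_like(X)
        bw = []
        for k in range(1, span):
            acc = acc | _shift(X, neg, k)
            bw.append(acc.copy())
        for a in range(1, span):
            b_max = span - a
            if b_max >= 1:
                ok |= fw[a - 1] & bw[b_max - 1]
    out = _bridge_components(D1 & ok, sides, reach=close_radius + 1)
    if not out.any():
        return out
    # complete the slit out to its mouth: the closing misses the slit's
    # perimeter ring, where the ball no longer fits
    big = np.iinfo(np.int64).max
    for _ in range(close_radius):
        hi = ndimage.grey_dilation(sides, footprint=STRUCT26)
        lo = ndimage.grey_erosion(np.where(sides > 0, sides, big),
                                  footprint=STRUCT26)
        two_sided = (hi > 0) & (lo < big) & (lo < hi)
        add = ndimage.binary_dilation(out, structure=STRUCT26) & ~X & ~out \
            & two_sided & ok
        if not add.any():
            break
        out |= add
    return out


#: leak masses smaller than this (a 3x3x3 blob) are treated as noise
#: debris rather than a leak worth sealing
_MIN_LEAK_SIZE = 27


def seal(T: CTVolume, gap_voxels: np.ndarray, fill_hu: int) -> CTVolume:
    """Raise the CT value at ``gap_voxels`` (an (n,3) index array or boolean
    mask) to ``fill_hu``; every other voxel is untouched."""
    if isinstance(gap_voxels, np.ndarray) and gap_voxels.dtype == bool:
        idx = np.argwhere(gap_voxels)
    else:
        idx = np.asarray(gap_voxels, dtype=np.int64).reshape(-1, 3)
    out = T.data.copy()
    if len(idx) == 0:
        return CTVolume(out, T.spacing, T.origin)
    cur = out[idx[:, 0], idx[:, 1], idx[:, 2]]
    bad = cur >= fill_hu
    if bad.any():
        offenders = idx[bad][:5].tolist()
        raise ValueError(
            f"seal: fill value {fill_hu} HU not greater than existing value at "
            f"{int(bad.sum())} voxel(s), e.g. {offenders}"
        )
    out[idx[:, 0], idx[:, 1], idx[:, 2]] = fill_hu
    return CTVolume(out, T.spacing, T.origin)


#: HU bound of the "definitely airway" band.
AIRWAY_CERTAIN_HU = -950


def _airway_like(mask: np.ndarray, T: np.ndarray) -> bool:
    """Whether a component sits in definitely-airway surroundings.

    Judged on the non-wall neighborhood rather than the member voxels:
    a mass grown by thresholding contains only in-window (dark) voxels by
    construction, so its own HU histogram is biased; its surroundings are
    not.  Airway lumen is embedded in sub-(-950) tissue, leaked parenchyma
    in uncertain-band tissue."""
    nb = ndimage.binary_dilation(mask, structure=STRUCT26)
    nb &= T < WALL_CERTAIN_HU
    vals = T[nb]
    if vals.size == 0:
        return False
    return float((vals < AIRWAY_CERTAIN_HU).mean()) >= 0.5


def _airway_lumen_side(clean: np.ndarray, P_area0: np.ndarray,
                       T: np.ndarray, wall_int: np.ndarray,
                       reach: int = 3) -> np.ndarray:
    """The true-airway side of a (possibly contaminated) clean mask.

    Wall-slab-interior voxels are removed from the clean mask and the
    component(s) holding the seed surface form the initial lumen side.
    A removed component adjacent to the lumen is then either *reattached*
    — when every farther component it bridges to is definitely-airway
    material (below -950 HU): narrow or tilted digital lumen pinched
    between wall responses — or declared a breach bridge, when it leads to
    uncertain-band material (leaked parenchyma).  Repeats until stable so
    a branch with several pinch points is reattached end to end.
    """
    core = clean & ~wall_int
    labels, n = ndimage.label(core, structure=STRUCT26)
    seed_labels = np.unique(labels[P_area0 & core])
    seed_labels = set(int(t) for t in seed_labels if t > 0)
    if not seed_labels:
        return clean.copy()
    lumen = np.isin(labels, list(seed_labels))
    removed, n_rem = ndimage.label(clean & wall_int, structure=STRUCT26)
    undecided = set(range(1, n_rem + 1))
    slices = ndimage.find_objects(removed)
    while True:
        changed = False
        for lab in sorted(undecided):
            sl = slices[lab - 1]
            grow = tuple(slice(max(0, s.start - 1), min(d, s.stop + 1))
                         for s, d in zip(sl, clean.shape))
            comp = removed[grow] == lab
            near = ndimage.binary_dilation(comp, structure=STRUCT26)
            if not (near & lumen[grow]).any():
                continue  # not reachable from the lumen side (yet)
            far = set(int(t) for t in np.unique(labels[grow][near])
                      if t > 0 and t not in seed_labels)
            far_air = [f for f in far if _airway_like(labels == f, T)]
            undecided.discard(lab)
            if len(far_air) == len(far):
                # everything beyond is airway: a pinched stretch of lumen
                lumen[grow] |= comp
                for f in far:
                    lumen |= labels == f
                    seed_labels.add(f)
                changed = len(far) > 0 or True
            else:
                # mixed bridge: reattach each airway-like far component
                # through its connecting corridor, and reattach the bridge
                # voxels far away from all uncertain-band far components
                # (pinched lumen running alongside the breach); what stays
                # out is the breach itself
                comp_global = np.zeros_like(clean)
                comp_global[grow] = comp
                for f in far_air:
                    fmask = labels == f
                    near_f = ndimage.binary_dilation(fmask, structure=STRUCT26,
                                                     iterations=2)
                    lumen |= (comp_global & near_f) | fmask
                    seed_labels.add(f)
                bad = np.zeros_like(clean)
                for f in far:
                    if f not in far_air:
                        bad |= labels == f
                bad_near = ndimage.binary_dilation(bad, structure=STRUCT26,
                                                   iterations=reach)
                lumen |= comp_global & ~bad_near
                changed = True
        if not changed:
            break
    return lumen


def _detect_breaches(ctx: RegionContext, qs: QuasiSphere, config: Config,
                     forbidden: np.ndarray | None,
                     clean: np.ndarray) -> np.ndarray:
    """Locate the sealable mouth of every wall breach in one region.

    The true-airway (lumen) side is derived from the settled clean
    segmentation via :func:`_airway_lumen_side`; the leak is everything a
    free bloom at the pre-sealing threshold reaches beyond it.  The mouth
    of a breach is the leak voxels face-adjacent to the lumen side that
    lie inside the wall slab (:func:`_wall_interior`); a mouth component
    is sealable only if it opens onto a substantial leak mass beyond the
    wall.  A breach wider than ``close_radius + 1`` voxels is not
    classified as wall interior, leaves no sealable mouth, and ends in
    the threshold cap — the method's 3-voxel sealing limit.  Finally,
    causal pruning keeps only mouth components whose sealing is necessary
    to stop the bloom from leaking.
    """
    T = ctx.T.data
    r = config.sealing.close_radius
    wall_int = _wall_interior(T, r)
    lumen = _airway_lumen_side(clean, ctx.P_area0, T, wall_int)
    bloom = _bloom(ctx, qs, ctx.Threshold, forbidden)
    leak = bloom & ~lumen
    out = np.zeros_like(leak)
    if int(leak.sum()) < _MIN_LEAK_SIZE:
        return out
    mouth = leak & ndimage.binary_dilation(lumen, structure=STRUCT6) & wall_int
    if not mouth.any():
        return out
    # the substantial leak mass beyond the wall slab (parenchyma-side
    # spill); scattered single out-of-window voxels are noise, not spill
    spill_labels, n_spill = ndimage.label(leak & ~wall_int, structure=STRUCT26)
    if n_spill == 0:
        return out
    sizes = np.bincount(spill_labels.ravel())
    big = sizes >= _MIN_LEAK_SIZE
    big[0] = False
    spill = big[spill_labels]
    if not spill.any():
        return out
    # crossing test: a gap voxel sits on a short straight all-dark line
    # from the lumen side to the spill (it crosses the wall); a pinched
    # lumen thread running parallel to the wall does not
    span = r + 2
    dark = T < WALL_CERTAIN_HU
    cross = np.zeros_like(mouth)
    for d in _DIRECTIONS:
        for sd in (d, tuple(-c for c in d)):
            nsd = tuple(-c for c in sd)
            # darkrun_f[j]: voxels v with v+1·sd .. v+j·sd all dark
            run_f = [np.ones_like(mouth)]
            run_b = [np.ones_like(mouth)]
            for k in range(1, span):
                run_f.append(run_f[-1] & _shift(dark, sd, k))
                run_b.append(run_b[-1] & _shift(dark, nsd, k))
            for a in range(1, span):
                for b_ in range(1, span + 1 - a):
                    cross |= (_shift(lumen, nsd, a) & _shift(spill, sd, b_)
                              & run_f[b_ - 1] & run_b[a - 1])
    mouth &= cross
    if not mouth.any():
        return out
    labels, n = ndimage.label(mouth, structure=STRUCT26)
    comps = []
    for lab in range(1, n + 1):
        comp = labels == lab
        mass = ndimage.binary_propagation(comp, structure=STRUCT6, mask=leak)
        if int((mass & spill).sum()) >= _MIN_LEAK_SIZE:
            comps.append(comp)
    if not comps:
        return out
    # a breach mouth hugs the spill; trim away the parts of a mouth
    # component that run off along the airway (pinched digital lumen rows
    # merge into the component on tilted branches)
    near_spill = spill.copy()
    for _ in range(r + 1):
        near_spill = ndimage.binary_dilation(near_spill, structure=STRUCT26)
    trimmed = [c & near_spill for c in comps]
    trimmed = [c for c in trimmed if c.any()]

    def leak_size(sealed_comps: list[np.ndarray]) -> int:
        forb = np.zeros_like(leak) if forbidden is None else forbidden.copy()
        for c in sealed_comps:
            forb |= c
        test = _bloom(ctx, qs, ctx.Threshold, forb)
        return int((test & ~lumen & spill).sum())

    if trimmed and leak_size(trimmed) < _MIN_LEAK_SIZE:
        active = trimmed
    elif leak_size(comps) < _MIN_LEAK_SIZE:
        active = comps
    else:
        active = trimmed or comps
    # causal pruning: drop components not needed to contain the spill
    # (greedy, smallest first, so redundant layers of one breach survive)
    if leak_size(active) < _MIN_LEAK_SIZE and len(active) > 1:
        active = sorted(active, key=lambda c: int(c.sum()))
        for comp in list(active):
            trial = [c for c in active if c is not comp]
            if trial and leak_size(trial) < _MIN_LEAK_SIZE:
                active = trial
    for c in active:
        out |= c
    return out


def _bloom(ctx: RegionContext, qs: QuasiSphere, threshold: int,
           forbidden: np.ndarray | None) -> np.ndarray:
    """Let the front (and with it any leak) expand to convergence inside
    the region at the given threshold, with the leak rules off.

    Allowing the error to spread within the constrained region is what
    makes a wall gap visible: the leak mass on the far side of the wall
    turns the breach into a narrow bridge between two bulky sides.
    """
    X = ctx.P_area0.copy()
    while True:
        acc = propagate_step(X, qs, ctx.Seed, threshold, forbidden)
        if not acc.any():
            return X
        X |= acc


def sealing_loop(ctx: RegionContext, qs: QuasiSphere, config: Config,
                 result: RegionResult,
                 forbidden: np.ndarray | None = None
                 ) -> tuple[RegionResult, GapReport]:
    """Iterate gap sealing and re-segmentation for one leak-flagged region.

    Round structure: reproduce the leak by blooming the front at the
    pre-sealing threshold, detect gap voxels on the combined mask (bloom,
    current result, surrounding segmented voxels, seed surface), seal the
    ones darker than the fill value, bump the working threshold by one,
    re-segment.  The loop exits when a round both finds no new gap voxels
    and re-runs without any leak event, or when the working threshold has
    climbed more than 200 HU above the pre-sealing threshold (``capped``).
    """
    seal_cfg = config.sealing
    Threshold0 = ctx.Threshold0
    fill_hu = ctx.Seed + Threshold0 + seal_cfg.cap + seal_cfg.fill_margin
    sealed = np.zeros(ctx.P_area0.shape, dtype=bool)
    working = Threshold0
    rounds = 0
    capped = False
    best_clean = None if result.leak_detected else result
    current = result

    stale = True  # detection inputs (T or current) changed since last round
    cand = np.zeros_like(sealed)
    while True:
        rounds += 1
        if stale:
            # keep the restricted image in sync with the sealed block
            qs.restricted = np.where(qs.region, ctx.T.data,
                                     HU_FLOOR).astype(np.int64)
            clean = current.X | ctx.P_area0
            if forbidden is not None:
                clean = clean | (forbidden & qs.region)
            cand = _detect_breaches(ctx, qs, config, forbidden, clean)
            stale = False
        new = cand & ~sealed & (ctx.T.data < fill_hu)
        had_leak = current.leak_events > 0 or current.leak_detected
        if not had_leak or not new.any():
            # either the last (re-)segmentation ran clean — the gap, if
            # any, is sealed — or the leak persists with nothing sealable
            if not had_leak:
                break
            if not new.any():
                # unsealable: ratchet the threshold toward the cap
                working += 1
                if working - Threshold0 > seal_cfg.cap:
                    capped = True
                    break
                continue
        if new.any():
            ctx.T = seal(ctx.T, new, fill_hu)
            sealed |= new
            stale = True
            logger.info("region %d: sealed %d gap voxel(s) in round %d",
                        ctx.K, int(new.sum()), rounds)
        working += 1
        if working - Threshold0 > seal_cfg.cap:
            capped = True
            break
        ctx.Threshold = working
        if stale:
            # re-segment only when something was sealed: with the block
            # unchanged, the attempt would settle identically
            qs.restricted = np.where(qs.region, ctx.T.data,
                                     HU_FLOOR).astype(np.int64)
            current = segment_region(ctx, qs, config, forbidden)
            if not current.leak_detected:
                best_clean = current

    final = best_clean if best_clean is not None else current
    report = GapReport(
        gap_voxels=np.argwhere(sealed),
        fill_hu=fill_hu,
        rounds=rounds,
        threshold_final=working,
        capped=capped,
    )
    return final, report
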