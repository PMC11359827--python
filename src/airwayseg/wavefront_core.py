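"""Region-constrained wavefront propagation.

One stage grows a segmentation ``X`` from the seed surface ``P_area0``
inside the quasi-spherical region: each iteration dilates ``X`` by
``Sphere(1)`` (the 6-neighborhood), keeps the new candidates whose
restricted-image value lies in the window ``[Seed, Seed + Threshold)``,
and superposes them onto ``X``.  The stage ends when nothing new is
accepted.

Two leak rules watch every attempt:

* the iteration count is capped at ``2R + slack`` (a front advancing one
  face-step per iteration crosses the region in at most 2R steps);
* the number of voxels accepted in a single iteration may not exceed
  ``growth_factor`` times the seed-surface area (airway width decreases
  gradually; an explosive front means the window has escaped the lumen).

On a leak the attempt rewinds to ``P_area0`` and the threshold decays by
1; if it reaches 0 the region is abandoned (and handed to gap sealing by
the pipeline).  A successful stage is hole-filled, its boundary crossing
components are counted (the bifurcation count), and those components
become the seed surfaces of the next stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Config, RADIUS_FLOOR
from .region_constraint import (
    STRUCT6,
    STRUCT26,
    QuasiSphere,
    RegionContext,
    SeedSurface,
    build_quasi_sphere,
    extract_seed_surfaces,
)
from .volume_io import CropBox, CTVolume, bbox_of_mask

logger = logging.getLogger(__name__)


@dataclass
class RegionResult:
    """Outcome of one constraint-region stage (crop coordinates)."""

    X: np.ndarray
    iterations: int
    leak_detected: bool
    threshold_used: int
    bifurcation_count: int
    next_surfaces: list[SeedSurface]
    radius_used: int
    #: number of rewind events (leak rule firings) across all attempts
    leak_events: int = 0
    #: X of the first attempt that tripped a leak rule (for gap location)
    first_leaky_X: np.ndarray | None = None


def propagate_step(X: np.ndarray, qs: QuasiSphere, Seed: int, Threshold: int,
                   forbidden: np.ndarray | None = None) -> np.ndarray:
    """One wavefront iteration: return the accepted new voxels only.

    Candidates are the face neighbors of ``X`` not already in ``X``;
    a candidate is accepted iff it lies in the region, is not globally
    forbidden, and its restricted value v passes the rejection criterion
    ``v - Seed >= Threshold`` — i.e. ``v < Seed + Threshold``.  The
    criterion is one-sided: anything darker than the window top is airway-
    like, and out-of-region voxels (restricted value -2048) are excluded
    by region membership, not by the window.
    """
    cand = ndimage.binary_dilation(X, structure=STRUCT6) & ~X
    if forbidden is not None:
        cand &= ~forbidden
    return cand & qs.region & (qs.restricted < Seed + Threshold)


def fill_holes(X: np.ndarray) -> np.ndarray:
    """Fill 6-connected background components that do not reach the crop
    border; border-connected background (e.g. the open lumen beyond the
    region) is left untouched."""
    return ndimage.binary_fill_holes(X, structure=STRUCT6)


def count_bifurcations(X: np.ndarray, shell: np.ndarray) -> int:
    """Number of 26-connected components of ``X`` ∩ shell."""
    if X.shape != shell.shape:
        raise ValueError("X and shell shapes differ")
    inter = X & shell
    if not inter.any():
        return 0
    _, n = ndimage.label(inter, structure=STRUCT26)
    return n


def segment_region(ctx: RegionContext, qs: QuasiSphere, config: Config,
                   forbidden: np.ndarray | None = None) -> RegionResult:
    """Run the propagation loop with threshold decay until clean or exhausted.

    Returns a clean result (possibly at a decayed threshold) or, when decay
    reaches 0, the seed surface itself with ``leak_detected`` set.  Leaks
    are results, not errors.
    """
    wf = config.wavefront
    area0 = int(ctx.P_area0.sum())
    cap = 2 * ctx.R + wf.iteration_slack
    growth_limit = wf.growth_factor * area0
    use_rules = wf.leak_rules and not (ctx.is_bootstrap and wf.bootstrap_exempt)

    threshold = ctx.Threshold
    leak_events = 0
    first_leaky: np.ndarray | None = None
    while threshold >= 1:
        X = ctx.P_area0.copy()
        it = 0
        leaked = False
        while True:
            acc = propagate_step(X, qs, ctx.Seed, threshold, forbidden)
            n_new = int(acc.sum())
            if n_new == 0:
                break
            it += 1
            if use_rules and n_new > growth_limit:
                leaked = True
            X |= acc
            if use_rules and it >= cap and not leaked:
                # still growing at the cap: the front should have crossed
                # the region by now
                more = propagate_step(X, qs, ctx.Seed, threshold, forbidden)
                if more.any():
                    leaked = True
            if leaked or (use_rules and it >= cap):
                break
        if leaked:
            leak_events += 1
            if first_leaky is None:
                first_leaky = X
            threshold -= 1
            continue
        X = fill_holes(X)
        count = count_bifurcations(X, qs.shell)
        return RegionResult(
            X=X, iterations=it, leak_detected=False, threshold_used=threshold,
            bifurcation_count=count, next_surfaces=[], radius_used=ctx.R,
            leak_events=leak_events, first_leaky_X=first_leaky,
        )
    return RegionResult(
        X=ctx.P_area0.copy(), iterations=0, leak_detected=True, threshold_used=0,
        bifurcation_count=0, next_surfaces=[], radius_used=ctx.R,
        leak_events=leak_events, first_leaky_X=first_leaky,
    )


def extract_next_surfaces(result: RegionResult, qs: QuasiSphere, box: CropBox,
                          parent: CTVolume, config: Config,
                          seed_area: int, exempt_area_rule: bool = False,
                          first_label: int = 1) -> list[SeedSurface]:
    """Components of X ∩ shell, mapped to parent coordinates.

    Surfaces whose area exceeds ``area_factor`` times the seed-surface area
    fail the boundary leak rule (airway width decreases gradually) and are
    dropped with a log message.
    """
    inter = result.X & qs.shell
    if not inter.any():
        return []
    # label in crop, then lift voxels to parent coordinates
    labels, n = ndimage.label(inter, structure=STRUCT26)
    off = np.asarray(box.lo)
    comps = []
    for lab in range(1, n + 1):
        vox = np.argwhere(labels == lab)
        comps.append(vox)
    comps.sort(key=lambda v: tuple((v + off)[np.lexsort(v.T[::-1])][0]))
    limit = config.wavefront.area_factor * seed_area
    hu_ceiling = config.region.next_surface_max_hu
    surfaces: list[SeedSurface] = []
    k = first_label
    for vox in comps:
        if not exempt_area_rule and config.wavefront.leak_rules and len(vox) > limit:
            logger.info(
                "dropping boundary surface of area %d (> %.1f x seed area %d): "
                "boundary leak rule", len(vox), config.wavefront.area_factor, seed_area,
            )
            continue
        pvox = vox + off
        hu = parent.data[pvox[:, 0], pvox[:, 1], pvox[:, 2]]
        if hu_ceiling is not None and np.median(hu) > hu_ceiling:
            logger.info(
                "dropping boundary surface of area %d with median HU %.0f "
                "(above the definitely-airway band)", len(vox), np.median(hu))
            continue
        mask = np.zeros(parent.shape, dtype=bool)
        mask[pvox[:, 0], pvox[:, 1], pvox[:, 2]] = True
        surfaces.append(SeedSurface(K=k, voxels=pvox, surface_hu=hu,
                                    bbox=bbox_of_mask(mask)))
        k += 1
    return surfaces


def adapt_radius(ctx: RegionContext, qs: QuasiSphere, config: Config,
                 forbidden: np.ndarray | None = None
                 ) -> tuple[RegionContext, QuasiSphere, RegionResult]:
    """Shrink the region until its boundary shows at most one bifurcation.

    A bifurcation count of 0 (front never reached the boundary) or > 2
    (multiple bifurcations inside one region) triggers a radius reduction
    by ``radius_step`` and a re-run; adaptation stops at count 1 or 2, or
    at the radius floor of 8.
    """
    result = segment_region(ctx, qs, config, forbidden)
    while (result.bifurcation_count == 0 or result.bifurcation_count > 2) \
            and ctx.R > RADIUS_FLOOR and not result.leak_detected:
        new_R = max(ctx.R - config.wavefront.radius_step, RADIUS_FLOOR)
        logger.info("region %d: bifurcation count %d at R=%d; reducing to R=%d",
                    ctx.K, result.bifurcation_count, ctx.R, new_R)
        ctx.R = new_R
        qs = build_quasi_sphere(ctx)
        result = segment_region(ctx, qs, config, forbidden)
    result.radius_used = ctx.R
    return ctx, qs, result
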