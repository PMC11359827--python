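"""Whole-tree segmentation from a single trachea seed, plus evaluation.

The pipeline keeps a LIFO stack of seed surfaces.  The bootstrap surface
is the user-supplied trachea voxel; each popped surface is initialized
into a quasi-spherical constraint region, segmented with radius
adaptation, handed to the gap-sealing loop when any leak rule fired, and
merged into the global mask; the boundary crossing surfaces it produced
are pushed for the next stages.  Segmentation ends when no surfaces
remain (or at the ``max_regions`` safety valve).

Evaluation against phantom ground truth follows the standard airway
challenge parameter set: branch count / branch detected %, tree length /
tree length detected %, leakage count, leakage volume and false positive
rate, with "correct" meaning inside the ground-truth lumen dilated by one
voxel and branch detection requiring more than 1 mm of centerline overlap
(one voxel at unit spacing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import Config
from .gap_sealing import GapReport, sealing_loop
from .phantom_gen import PhantomBundle
from .region_constraint import (
    STRUCT26,
    SeedSurface,
    bootstrap_surface,
    build_quasi_sphere,
    dilate_ball,
    init_region,
)
from .volume_io import CTVolume, paste
from .wavefront_core import adapt_radius, extract_next_surfaces

logger = logging.getLogger(__name__)


@dataclass
class RegionTrace:
    """Log record of one processed region (for diagnostics and tests)."""

    K: int
    R: int
    Seed: int
    Threshold0: int
    threshold_used: int
    iterations: int
    leak_events: int
    leak_detected: bool
    bifurcations: int
    sealed_voxels: int
    sealing_rounds: int
    capped: bool
    region_mask_parent: np.ndarray | None = None
    gap_voxels_parent: np.ndarray | None = None


@dataclass
class SegmentationRun:
    """Full output of :func:`segment_airway_tree`."""

    mask: np.ndarray
    traces: list[RegionTrace] = field(default_factory=list)

    @property
    def regions_processed(self) -> int:
        return len(self.traces)


@dataclass
class EvalMetrics:
    branch_count: int
    branch_total: int
    branch_detected_pct: float
    tree_length: float
    tree_length_total: float
    tree_length_detected_pct: float
    leakage_count: int
    leakage_volume: float
    false_positive_rate_pct: float

    def to_dict(self) -> dict:
        return {
            "branch_count": self.branch_count,
            "branch_total": self.branch_total,
            "branch_detected_pct": self.branch_detected_pct,
            "tree_length": self.tree_length,
            "tree_length_total": self.tree_length_total,
            "tree_length_detected_pct": self.tree_length_detected_pct,
            "leakage_count": self.leakage_count,
            "leakage_volume": self.leakage_volume,
            "false_positive_rate_pct": self.false_positive_rate_pct,
        }


def segment_airway_tree(volume: CTVolume, seed: tuple[int, int, int],
                        config: Config | None = None,
                        return_run: bool = False):
    """Segment the airway tree reachable from ``seed``.

    Returns the global boolean mask (and the full :class:`SegmentationRun`
    when ``return_run`` is set).  The mask always contains the seed voxel
    and is 26-connected by construction (every region grows from a surface
    of the previous one).
    """
    config = config or Config()
    seed = tuple(int(c) for c in seed)
    boot = bootstrap_surface(volume, seed)
    seed_hu = int(volume.data[seed])
    if seed_hu >= -775:
        logger.warning(
            "seed voxel HU %d is in the definitely-non-airway band (>= -775); "
            "is the seed inside the trachea?", seed_hu,
        )
    global_mask = np.zeros(volume.shape, dtype=bool)
    global_mask[seed] = True
    # working copy: gap seals persist here so downstream regions inherit
    # an already-sealed wall
    work = CTVolume(volume.data.copy(), volume.spacing, volume.origin)
    stack: list[tuple[SeedSurface, bool]] = [(boot, True)]
    traces: list[RegionTrace] = []
    k_counter = 1

    while stack:
        if len(traces) >= config.run.max_regions:
            logger.error("max_regions safeguard (%d) reached; stopping",
                         config.run.max_regions)
            break
        surface, is_boot = stack.pop()
        ctx = init_region(surface, work, config, is_bootstrap=is_boot)
        ctx.K = k_counter
        qs = build_quasi_sphere(ctx)
        forbidden = global_mask[ctx.box.slices] & ~ctx.P_area0
        ctx, qs, result = adapt_radius(ctx, qs, config, forbidden)
        report: GapReport | None = None
        if config.sealing.enabled and (result.leak_events > 0 or result.leak_detected):
            result, report = sealing_loop(ctx, qs, config, result, forbidden)
        if report is not None and len(report.gap_voxels):
            g = report.gap_voxels + np.asarray(ctx.box.lo)
            work.data[g[:, 0], g[:, 1], g[:, 2]] = report.fill_hu
        exempt = is_boot and config.wavefront.bootstrap_exempt
        nxt = extract_next_surfaces(
            result, qs, ctx.box, work, config,
            seed_area=surface.area, exempt_area_rule=exempt,
            first_label=k_counter + 1,
        )
        paste(global_mask, result.X, ctx.box, combine="or")
        for s in nxt:
            stack.append((s, False))
        region_parent = np.zeros(volume.shape, dtype=bool)
        paste(region_parent, qs.region, ctx.box, combine="or")
        gaps_parent = None
        if report is not None and len(report.gap_voxels):
            gaps_parent = report.gap_voxels + np.asarray(ctx.box.lo)
        traces.append(RegionTrace(
            K=ctx.K, R=ctx.R, Seed=ctx.Seed, Threshold0=ctx.Threshold0,
            threshold_used=result.threshold_used, iterations=result.iterations,
            leak_events=result.leak_events, leak_detected=result.leak_detected,
            bifurcations=result.bifurcation_count,
            sealed_voxels=0 if report is None else len(report.gap_voxels),
            sealing_rounds=0 if report is None else report.rounds,
            capped=False if report is None else report.capped,
            region_mask_parent=region_parent,
            gap_voxels_parent=gaps_parent,
        ))
        logger.info(
            "region %d: R=%d Seed=%d Thr0=%d used=%d iters=%d leaks=%d "
            "bif=%d sealed=%d%s",
            ctx.K, ctx.R, ctx.Seed, ctx.Threshold0, result.threshold_used,
            result.iterations, result.leak_events, result.bifurcation_count,
            0 if report is None else len(report.gap_voxels),
            " CAPPED" if (report is not None and report.capped) else "",
        )
        k_counter += 1 + len(nxt)

    run = SegmentationRun(mask=global_mask, traces=traces)
    return run if return_run else global_mask


def evaluate(pred: np.ndarray, truth: PhantomBundle,
             spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> EvalMetrics:
    """Score a predicted mask against phantom ground truth."""
    pred = np.asarray(pred, dtype=bool)
    if pred.shape != truth.lumen.shape:
        raise ValueError(
            f"prediction shape {pred.shape} does not match truth {truth.lumen.shape}"
        )
    s = float(np.mean(spacing))
    correct_zone = dilate_ball(truth.lumen, 1)

    detected = 0
    overlap_len = 0.0
    total_len = 0.0
    for pts in truth.branch_centerlines:
        if len(pts) == 0:
            continue
        inside = pred[pts[:, 0], pts[:, 1], pts[:, 2]]
        total_len += len(pts) * s
        if inside.sum() * s > 1.0:  # > 1 mm of centerline covered
            detected += 1
            overlap_len += float(inside.sum()) * s

    leakage = pred & ~correct_zone
    leakage_volume = float(leakage.sum()) * s ** 3
    correct = pred & correct_zone
    leakage_count = 0
    if leakage.any():
        labels, n = ndimage.label(leakage, structure=STRUCT26)
        grown = ndimage.binary_dilation(correct, structure=STRUCT26)
        adjacent = np.unique(labels[grown & leakage])
        leakage_count = int((adjacent > 0).sum())
    correct_volume = float(correct.sum()) * s ** 3
    fpr = 100.0 * leakage_volume / correct_volume if correct_volume else 0.0

    n_branches = truth.branch_count
    return EvalMetrics(
        branch_count=detected,
        branch_total=n_branches,
        branch_detected_pct=100.0 * detected / n_branches if n_branches else 0.0,
        tree_length=overlap_len,
        tree_length_total=total_len,
        tree_length_detected_pct=100.0 * overlap_len / total_len if total_len else 0.0,
        leakage_count=leakage_count,
        leakage_volume=leakage_volume,
        false_positive_rate_pct=fpr,
    )


def lumen_recall(pred: np.ndarray, truth: PhantomBundle) -> float:
    """Fraction of ground-truth lumen voxels recovered."""
    lum = truth.lumen
    return float((pred & lum).sum()) / float(lum.sum())
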