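"""Run configuration for the segmentation pipeline.

Grouped the way the algorithm is structured: ``region`` (initialization of
each quasi-spherical constraint region), ``wavefront`` (propagation and leak
rules), ``sealing`` (gap detection and sealing loop), ``run`` (orchestration
safeguards).

Two constants are fixed by the method and surfaced read-only:
``SEALING_CAP = 200`` HU (the lumen/wall contrast at small airways that
bounds the sealing loop's threshold ratchet) and ``RADIUS_FLOOR = 8``
voxels (the minimum constraint-region radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Threshold ratchet bound of the sealing loop, in HU (method constant).
SEALING_CAP = 200
#: Minimum quasi-sphere radius, in voxels (method constant).
RADIUS_FLOOR = 8


@dataclass
class RegionConfig:
    #: apply tracheal-wall enhancement preprocessing to each cropped block
    enhancement: bool = True
    #: HU added to the thinned wall sheet by the enhancement step
    enhancement_strength: int = 300
    #: gradient-magnitude floor (HU) below which no wall response is marked;
    #: keeps enhancement from firing on plain image noise
    enhancement_min_gradient: int = 100
    #: median-HU ceiling for next-stage seed surfaces: a surface whose
    #: median lies above the definitely-airway band was grown on leaked
    #: tissue and is discarded (None disables the check)
    next_surface_max_hu: int | None = -950
    #: floor on the initial in-region threshold (HU width).  Surface-derived
    #: thresholds (max-min+1 over the seed surface) reflect only local noise
    #: on piecewise-constant images; real partial-volume surfaces span on the
    #: order of 100-200 HU, and the floor restores that operating regime.
    initial_threshold_override: int = 100


@dataclass
class WavefrontConfig:
    #: per-iteration growth limit, as a multiple of the seed-surface area
    growth_factor: float = 2.5
    #: next-surface area limit, as a multiple of the seed-surface area
    area_factor: float = 1.5
    #: radius decrement per adaptation step (floor fixed at 8)
    radius_step: int = 2
    #: slack added to the 2R iteration cap
    iteration_slack: int = 4
    #: disable growth/area leak rules for the single-voxel bootstrap region,
    #: whose seed area of 1 makes those rules degenerate
    bootstrap_exempt: bool = True
    #: master switch for the leak rules (disabled only for oracle testing)
    leak_rules: bool = True


@dataclass
class SealingConfig:
    enabled: bool = True
    #: closing structuring-element radius; seals wall gaps up to ~3 voxels
    close_radius: int = 2
    #: threshold ratchet bound (read-only method constant)
    cap: int = SEALING_CAP
    #: margin added to Seed + Threshold0 + cap so sealed voxels fall outside
    #: every window the loop can reach
    fill_margin: int = 1


@dataclass
class RunConfig:
    #: hard bound on the number of regions processed (safety valve)
    max_regions: int = 10000
    log_level: str = "INFO"


@dataclass
class Config:
    region: RegionConfig = field(default_factory=RegionConfig)
    wavefront: WavefrontConfig = field(default_factory=WavefrontConfig)
    sealing: SealingConfig = field(default_factory=SealingConfig)
    run: RunConfig = field(default_factory=RunConfig)

    def __post_init__(self) -> None:
        if self.sealing.cap != SEALING_CAP:
            raise ValueError("sealing.cap is a method constant and must stay 200")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        return cls(
            region=RegionConfig(**d.get("region", {})),
            wavefront=WavefrontConfig(**d.get("wavefront", {})),
            sealing=SealingConfig(**d.get("sealing", {})),
            run=RunConfig(**d.get("run", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
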