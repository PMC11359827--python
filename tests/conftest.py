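"""Shared fixtures: phantoms and end-to-end runs reused across test modules.

Heavy end-to-end segmentations are session-scoped so each study condition
is computed once per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from airwayseg import (
    Config,
    GapSpec,
    PhantomSpec,
    dilate_ball,
    generate_phantom,
    segment_airway_tree,
)

#: trachea seed voxel for the default 96^3 phantom (inside the root lumen)
SEED = (48, 48, 2)


def default_spec(**overrides) -> PhantomSpec:
    kwargs = dict(rng_seed=7)
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


#: the two sealable wall gaps of the gap-sealing study condition: a severe
#: (1-voxel, so dark it reads as airway) and a moderate (2-voxel,
#: uncertain-band HU) low-brightness wall stretch on the main bronchus
SEALABLE_GAPS = (
    GapSpec(branch_id=0, axial_position=0.4, extent=1, gap_hu=-970),
    GapSpec(branch_id=0, axial_position=0.7, extent=2, gap_hu=-935),
)

#: a 4-voxel gap, beyond the closing-based sealing range
OVERSIZE_GAP = (
    GapSpec(branch_id=0, axial_position=0.5, extent=4, gap_hu=-935,
            allow_oversize=True),
)


@pytest.fixture(scope="session")
def clean_phantom():
    return generate_phantom(default_spec())


@pytest.fixture(scope="session")
def gapped_phantom():
    return generate_phantom(default_spec(gaps=SEALABLE_GAPS))


@pytest.fixture(scope="session")
def oversize_phantom():
    return generate_phantom(default_spec(gaps=OVERSIZE_GAP))


@pytest.fixture(scope="session")
def clean_run(clean_phantom):
    cfg = Config()
    return segment_airway_tree(clean_phantom.volume, SEED, cfg, return_run=True)


@pytest.fixture(scope="session")
def gapped_run_unsealed(gapped_phantom):
    cfg = Config()
    cfg.sealing.enabled = False
    return segment_airway_tree(gapped_phantom.volume, SEED, cfg, return_run=True)


@pytest.fixture(scope="session")
def gapped_run_sealed(gapped_phantom):
    cfg = Config()
    return segment_airway_tree(gapped_phantom.volume, SEED, cfg, return_run=True)


@pytest.fixture(scope="session")
def oversize_run(oversize_phantom):
    cfg = Config()
    return segment_airway_tree(oversize_phantom.volume, SEED, cfg, return_run=True)


def true_gap_mask(bundle) -> np.ndarray:
    mask = np.zeros(bundle.lumen.shape, dtype=bool)
    for g in bundle.gap_voxels:
        mask[g[:, 0], g[:, 1], g[:, 2]] = True
    return mask


def detected_gap_mask(run, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for t in run.traces:
        if t.gap_voxels_parent is not None:
            g = t.gap_voxels_parent
            mask[g[:, 0], g[:, 1], g[:, 2]] = True
    return mask


def union_of_regions(run, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for t in run.traces:
        if t.region_mask_parent is not None:
            mask |= t.region_mask_parent
    return mask
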