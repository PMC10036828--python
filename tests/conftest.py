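import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from klsnet import LabelAtlas, SimulationConfig, VolumeImage, simulate_connectivity_direct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_atlas():
    """Two-region atlas on a 4x3x2 grid: region 1 = 3 voxels, region 2 = 4."""
    labels = np.zeros((4, 3, 2), dtype=int)
    labels[0, 0, 0] = labels[0, 1, 0] = labels[0, 2, 0] = 1
    labels[1, 0, 0] = labels[1, 1, 0] = labels[1, 2, 0] = labels[2, 0, 0] = 2
    return LabelAtlas(
        labels=labels,
        region_ids=[1, 2],
        region_names=["left", "right"],
        lobe_map={1: "frontal", 2: "temporal"},
    )


@pytest.fixture
def toy_volume(toy_atlas, rng):
    data = rng.uniform(0.5, 1.5, size=toy_atlas.labels.shape)
    return VolumeImage(data=data, voxel_size=(2.0, 2.0, 2.0))


@pytest.fixture
def direct_cohort_factory():
    """Small direct-mode synthetic cohorts with sensible test defaults."""

    def make(seed=0, n_patients=20, n_controls=15, n_regions=10, planted=(), betas=None, **kw):
        cfg = SimulationConfig(
            n_patients=n_patients,
            n_controls=n_controls,
            n_regions=n_regions,
            planted_edges=[tuple(e) for e in planted],
            outcome_betas=dict(betas or {}),
            seed=seed,
            **kw,
        )
        return simulate_connectivity_direct(cfg)

    return make
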