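"""Shared fixtures: small deterministic clouds and one full synthetic scene.

The heavier scene fixtures are session-scoped so the end-to-end tests share
a single generation + feature computation pass.
"""

from __future__ import annotations

import numpy as np
import pytest

import shrubscan as ss
from shrubscan.synthetic import (SceneSpec, default_archetypes,
                                 generate_scene, make_reference_table,
                                 scatter_placements)


def make_cloud(n: int, seed: int, extent: float = 10.0,
               zlo: float = 0.0, zhi: float = 3.0) -> ss.PointCloud:
    """Uniform random test cloud with a mix of single and dual returns."""
    rng = np.random.default_rng(seed)
    dual = rng.uniform(0, 1, n) < 0.4
    return ss.PointCloud(
        x=rng.uniform(0, extent, n),
        y=rng.uniform(0, extent, n),
        z=rng.uniform(zlo, zhi, n),
        echo_index=np.where(dual & (rng.uniform(0, 1, n) < 0.5), 2, 1),
        num_echoes=np.where(dual, 2, 1),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scene3():
    """20 x 20 m scene with 8 shrubs of each of the 3 default archetypes."""
    arch = list(default_archetypes().values())
    placements = scatter_placements(arch, 8, (20.0, 20.0), seed=3)
    return generate_scene(SceneSpec(placements=placements, seed=3))


@pytest.fixture(scope="session")
def scene3_layered(scene3):
    dtm = ss.build_dtm(scene3.cloud)
    cloud = ss.assign_layers(ss.normalize_heights(scene3.cloud, dtm))
    return cloud


@pytest.fixture(scope="session")
def scene3_features(scene3_layered):
    return ss.compute_features(scene3_layered)


@pytest.fixture(scope="session")
def scene3_labeled(scene3, scene3_layered, scene3_features):
    refs, schema = make_reference_table(scene3)
    return ss.assemble_reference(scene3_layered, scene3_features, refs, schema)
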