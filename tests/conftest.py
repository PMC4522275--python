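"""Shared fixtures: one default scene generated once per session."""

import numpy as np
import pytest

import spectracell as sc


@pytest.fixture(scope="session")
def endmembers():
    return sc.default_endmembers()


@pytest.fixture(scope="session")
def default_scene(endmembers):
    """A default-config scene (~1600 nuclei) with ground truth."""
    config = sc.SceneConfig(seed=33)
    truth, cube = sc.generate_scene(config, endmembers)
    return truth, cube


@pytest.fixture(scope="session")
def unmixed_default(default_scene, endmembers):
    """OD-converted and unmixed default scene plus segmented cells."""
    truth, cube = default_scene
    od = sc.to_optical_density(cube)
    amap = sc.unmix_cube(od, endmembers)
    cells = sc.segment_nuclei(amap.channel("nuclear_red"))
    return truth, amap, cells


@pytest.fixture(scope="session")
def scored_default(unmixed_default):
    """Quantified and scored records of the default scene (truth regions)."""
    truth, amap, cells = unmixed_default
    records = sc.quantify_cells(cells, amap, truth.region_mask, image_id="img0")
    scorer = sc.PhenotypeScorer().fit(records)
    return scorer.transform(records), scorer.thresholds_, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
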