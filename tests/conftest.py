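"""Shared fixtures: one small simulated experiment reused across test modules.

Everything is generated programmatically with fixed seeds; no data files.
"""

import pytest

from tilemeth import linear_model
from tilemeth import synthetic_data as sd

SEED = 11


@pytest.fixture(scope="session")
def small_reference_config():
    return sd.ReferenceConfig(
        chromosomes=(("chr1", 200_000), ("chr2", 150_000), ("chr9", 40_000)))


@pytest.fixture(scope="session")
def reference(small_reference_config):
    return sd.generate_reference(small_reference_config, seed=SEED)


@pytest.fixture(scope="session")
def truth(reference):
    genome, probe_map, _ = reference
    cfg = sd.TruthConfig(dmr_count=8, cnv_count=4, ibd_count=1,
                         ibd_min_length=40_000)
    return sd.simulate_truth((genome, probe_map), cfg, seed=SEED)


@pytest.fixture(scope="session")
def intensity_table(reference, truth):
    genome, probe_map, _ = reference
    return sd.simulate_arrays(truth, (genome, probe_map),
                              sd.ArrayConfig(), seed=SEED)


@pytest.fixture(scope="session")
def estimates(intensity_table):
    return linear_model.fit_and_moderate(
        linear_model.normalize(intensity_table))
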