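import numpy as np
import pytest

from mionpipe import cluster, synth


@pytest.fixture(scope="session")
def kernel():
    return synth.mion_irf()


@pytest.fixture(scope="session")
def small_truth():
    """Desk-scale ground truth: 64 voxels, 2 networks x 2 regions,
    GB effect planted in network 1 only."""
    return synth.make_ground_truth(
        shape=(8, 4, 2), n_networks=2, regions_per_network=2,
        gb_effect=0.1, nf_effect=0.1, visual_effect=0.2,
        acf=cluster.AcfParams(0.9, 1.0, 3.0),
    )


@pytest.fixture(scope="session")
def gb_design():
    return synth.make_design("GB", seed=42)


@pytest.fixture(scope="session")
def quiet_run(small_truth, gb_design, kernel):
    """One noise-free GB run with planted effects."""
    return synth.simulate_task_run(
        gb_design, small_truth, seed=7, kernel=kernel, noise=False
    )
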