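import numpy as np
import pytest

from oscibrain import (
    HopfParams,
    SyntheticSpec,
    make_connectome,
    make_ground_truth_bold,
    make_heterogeneity_map,
)


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(n_regions=12, seed=101, duration=432, tr=0.72, subjects=4)


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return make_connectome(small_spec)


@pytest.fixture(scope="session")
def small_map(small_bundle):
    return make_heterogeneity_map(small_bundle.coords, 30.0, seed=102)


@pytest.fixture(scope="session")
def small_bold(small_spec, small_bundle):
    """Band-limited ground-truth BOLD from a homogeneous Hopf network."""
    p = HopfParams(a=-0.2, omega=2 * np.pi * 0.045, G=1.0, nu=0.06,
                   duration=small_spec.duration, tr=small_spec.tr)
    return make_ground_truth_bold(p, small_bundle, small_spec)
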