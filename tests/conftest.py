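import pytest

from rrgenesis.rr_filtering import FunnelConfig, run_funnel
from rrgenesis.synthetic_data import (
    DECOY_CLASSES,
    ScenarioConfig,
    generate_scenario,
)

#: desk-scale coordinate compression used throughout the tests: all of the
#: funnel's kb/Mb thresholds are divided by this factor, consistently on both
#: the generator and the filter side
SCALE = 100


@pytest.fixture(scope="session")
def full_config():
    return ScenarioConfig(
        seed=11,
        n_reference_genes=3,
        decoy_classes=frozenset(DECOY_CLASSES),
        genome_scale_divisor=SCALE,
    )


@pytest.fixture(scope="session")
def bundle(full_config):
    return generate_scenario(full_config)


@pytest.fixture(scope="session")
def bundle_dir(bundle, tmp_path_factory):
    return bundle.write(tmp_path_factory.mktemp("bundle") / "b")


@pytest.fixture(scope="session")
def funnel_config():
    return FunnelConfig(scale_divisor=SCALE)


@pytest.fixture(scope="session")
def funnel_result(bundle_dir, funnel_config):
    """One full funnel run over the decoy-complete session bundle."""
    return run_funnel(bundle_dir, funnel_config)


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))
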