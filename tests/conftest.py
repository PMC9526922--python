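import pytest

from dxnet import SyntheticSpec, build_plan, generate_synthetic, ghana_fixture


@pytest.fixture(scope="session")
def ghana():
    return ghana_fixture()


@pytest.fixture(scope="session")
def ghana_plan(ghana):
    return build_plan(ghana)


def small_instance(seed: int, **overrides):
    """A compact random instance (fast to plan) for property checks."""
    kwargs = dict(
        n_tiers=3,
        n_conditions=10,
        n_diagnostics=40,
        n_medicines=12,
        seed=seed,
    )
    kwargs.update(overrides)
    return generate_synthetic(SyntheticSpec(**kwargs))


@pytest.fixture
def synthetic_small():
    return small_instance(seed=11)
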