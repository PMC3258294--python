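import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture()
def truth30():
    """Small reference set; function-scoped because downstream generators
    record provenance into the manifest in place."""
    from estdex import synthetic

    return synthetic.simulate_reference(30, seed=11, n_de=4)


@pytest.fixture(scope="session")
def tiny_fixture(tmp_path_factory):
    """One tiny end-to-end fixture directory, generated once per session."""
    from estdex import pipeline

    out = tmp_path_factory.mktemp("fixture")
    pipeline.make_fixture("tiny", seed=7, out_dir=out)
    return out
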