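import pytest

from spliceatlas import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def config():
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def bundle(config, tmp_path_factory):
    """One full synthetic dataset, written to disk once per session."""
    out = tmp_path_factory.mktemp("synthetic")
    b = simulate_all(config, str(out))
    b["out_dir"] = str(out)
    return b


@pytest.fixture(scope="session")
def truth(bundle):
    return bundle["truth"]
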