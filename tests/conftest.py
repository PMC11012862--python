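import pytest

from gslsrm import transitions as tr


@pytest.fixture(scope="session")
def default_cfg() -> tr.TransitionConfig:
    return tr.default_config()


@pytest.fixture(scope="session")
def default_transitions(default_cfg):
    return tr.build_transitions(default_cfg)


@pytest.fixture(scope="session")
def transitions_by_id(default_transitions):
    return {t.analyte_id: t for t in default_transitions}
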