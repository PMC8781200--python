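import pytest

from renoimp import paper_default_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """(torso, kidney, tissue table, perfusion cases) of the default subject."""
    return paper_default_fixture()
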