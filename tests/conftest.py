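import pytest

from lncexon.core import Parameters
from lncexon.simulate import make_workspace


@pytest.fixture(scope="session")
def params() -> Parameters:
    return Parameters()


@pytest.fixture(scope="session")
def workspace(tmp_path_factory):
    """Default synthetic workspace (seed 7), built once per session."""
    outdir = tmp_path_factory.mktemp("ws")
    truth = make_workspace(7, outdir)
    return truth, outdir
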