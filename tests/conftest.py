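import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dviprior import build_cell_table, nine_cell_roster, nine_cell_spec


@pytest.fixture(scope="session")
def nine_roster():
    return nine_cell_roster()


@pytest.fixture(scope="session")
def nine_spec():
    return nine_cell_spec()


@pytest.fixture(scope="session")
def nine_table(nine_roster, nine_spec):
    return build_cell_table(nine_roster, nine_spec)
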