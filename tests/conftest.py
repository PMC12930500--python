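import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from basalcog import engine, workbench


@pytest.fixture(scope="session")
def fixture_runs():
    """Simulated trajectories of every canonical fixture (computed once)."""
    runs = {}
    for name in workbench.FIXTURE_NAMES:
        cfg = workbench.make_fixture(name)
        runs[name] = (cfg, engine.simulate_protocol(cfg.circuit, cfg.params, cfg.protocol))
    return runs
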