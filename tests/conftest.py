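"""Shared fixtures.

The scaled-down factorial study is expensive (several minutes), so it is run
once per session and shared by all aggregate-level tests.
"""

import importlib.util
from pathlib import Path

import numpy as np
import pytest

ROOT = Path(__file__).resolve().parent.parent

# Master seed for every stochastic fixture in the suite.
SUITE_SEED = 1


@pytest.fixture(scope="session")
def acceptance_mod():
    """The acceptance script, loaded as a module (it is the single place the
    desk-scale replication policy lives)."""
    spec = importlib.util.spec_from_file_location(
        "acceptance_script", ROOT / "scripts" / "acceptance.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    return mod


@pytest.fixture(scope="session")
def study_df(acceptance_mod):
    """Tidy per-scenario results of the full 72-cell study at desk scale."""
    return acceptance_mod.run_study(master_seed=SUITE_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SUITE_SEED)
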