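import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

from oxkinetics import presets as pr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def builtin():
    return pr.builtin_presets()


@pytest.fixture(scope="session")
def noiseless_bundles(builtin):
    """One noiseless bundle per wild-type dose preset (shared: generation is
    deterministic and read-only)."""
    return {
        name: pr.generate_bundle(builtin[name], seed=11, noise=pr.NoiseLevels.zero())
        for name in pr.WILDTYPE_DOSE_PRESETS
    }
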