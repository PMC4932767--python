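import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make helpers importable

from hydrosep.scales import builtin_scales


@pytest.fixture(scope="session")
def scales_by_id():
    return {s.id: s for s in builtin_scales()}


@pytest.fixture(scope="session")
def kd(scales_by_id):
    return scales_by_id["KD"]


@pytest.fixture(scope="session")
def eval_pools():
    """Five small synthetic evaluation pools (fully separated profiles)."""
    from hydrosep.synthetic import generate_eval_pools

    return generate_eval_pools(n_per_pool=20, separation_strength=1.0, seed=11)
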