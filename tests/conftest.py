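import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from mhcforge.simulate import FixtureSpec, simulate_haplotype


@pytest.fixture(scope="session")
def bundle():
    """Full-scale fixture (200 kb, 9 genes, 2 C4 cassettes) shared read-only."""
    return simulate_haplotype(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def small_bundle():
    """Reduced fixture for tests that re-run whole-pipeline steps."""
    return simulate_haplotype(FixtureSpec.small(seed=11))
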