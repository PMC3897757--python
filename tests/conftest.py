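import numpy as np
import pytest

from ldblocks import BlockSpec, simulate_panel


@pytest.fixture
def two_block_panel():
    """Two planted 3-SNP blocks, independent, complete data."""
    spec = BlockSpec(
        block_sizes=(3, 3), block_mafs=(0.3, 0.4), n_samples=60, seed=11
    )
    return simulate_panel(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return str(path)
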