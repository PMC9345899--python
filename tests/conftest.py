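import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tsrdiv.synthetic import SimConfig


@pytest.fixture
def small_config() -> SimConfig:
    """A fast configuration exercising every generator."""
    return SimConfig(
        seed=11,
        genome=[("chr1", 800_000), ("chr2", 600_000)],
        n_promoters=40,
        total_tags_per_sample=20_000,
        n_genes=40,
        n_tra=12,
        n_housekeeping=12,
        n_tissues=16,
        noise_tags_per_kb=0.02,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
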