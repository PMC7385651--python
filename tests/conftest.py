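import numpy as np
import pytest

from pipolin_scout.synthetic import PipolinTemplate, generate_pipolin_genome


@pytest.fixture(scope="session")
def template():
    return PipolinTemplate.from_seed(7)


@pytest.fixture(scope="session")
def planted_genome(template):
    """Single-contig genome with one pipolin planted at a tRNA locus."""
    return generate_pipolin_genome(template, genome_length=12_000, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
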