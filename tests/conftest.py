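import numpy as np
import pytest

from cnidopep import simdata as sd


@pytest.fixture(scope="session")
def small_transcriptome():
    """60 decoys + the six default precursor archetypes, fixed seed."""
    rng = np.random.default_rng(42)
    copy_numbers = [int(c) for c in rng.integers(3, 33, size=6)]
    specs = sd.default_precursor_specs(copy_numbers=copy_numbers)
    records, truths = sd.generate_transcriptome(60, specs, seed=42)
    return records, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
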