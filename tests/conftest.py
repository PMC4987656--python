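import pytest

from kranzless import synthetic_data as sd
from kranzless.residue_classifier import WindowLibrary


@pytest.fixture(scope="session")
def small_sim():
    """Small hexaploid-like reference with 5 split pairs and truth."""
    cfg = sd.SimConfig(n_genes=6, n_genotypes=4,
                       transcript_length_range=(300, 600), seed=1)
    records, truth = sd.simulate_reference(cfg)
    split, truth = sd.split_transcripts(records, 10, 30, seed=2, truth=truth)
    return cfg, records, split, truth


@pytest.fixture(scope="session")
def library():
    return WindowLibrary.packaged()
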