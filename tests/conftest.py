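import pytest

from ohnoscope import SeqEvolParams, run_event_script
from ohnoscope.presets import preset


def species_of(gene_id: str) -> str:
    return gene_id.split("_")[0]


@pytest.fixture(scope="session")
def fig2_result():
    """fig2_chordate history, structure only (no sequences)."""
    return run_event_script(preset("fig2_chordate"), seed=1,
                            with_sequences=False)


@pytest.fixture(scope="session")
def ghost_result():
    """ghost_2R history with sequences, seed 1."""
    return run_event_script(preset("ghost_2R"), SeqEvolParams(), seed=1)


@pytest.fixture(scope="session")
def conversion_result():
    """gene_conversion_MRF2 history with sequences, seed 1."""
    return run_event_script(preset("gene_conversion_MRF2"),
                            SeqEvolParams(rate=0.3), seed=1)
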