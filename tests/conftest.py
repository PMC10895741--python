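"""Shared fixtures: editor profiles and small deterministic simulations."""

import pytest

from bedit import synthetic_data as sd
from bedit.editor_model import get_profile


@pytest.fixture(scope="session")
def abe8e():
    return get_profile("GhABE8e")


@pytest.fixture(scope="session")
def genome_sim():
    """Default 100-kb genome with 5 genes and planted guide/off-target sites."""
    return sd.simulate_genome(sd.SimSpec(seed=1))


@pytest.fixture(scope="session")
def small_genome_sim():
    """Compact genome for fast per-test pipelines."""
    spec = sd.SimSpec(
        seed=7,
        genome=sd.GenomeSpec(
            length=40_000,
            genes=(
                sd.GeneSpec(codons=175, n_exons=1, strand="+"),
                sd.GeneSpec(codons=40, n_exons=2, strand="-"),
            ),
            offtarget_mismatches=(2,),
        ),
    )
    return sd.simulate_genome(spec)
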