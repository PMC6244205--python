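"""Shared fixtures: one default synthetic genome, identified once per session."""

import pytest

from nsltp.pipeline import identify_records
from nsltp.synthetic import GeneratorConfig, generate_genome


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=1)


@pytest.fixture(scope="session")
def genome(default_config):
    """The default synthetic genome: 50 genes, 3 tandem arrays."""
    return generate_genome(default_config)


@pytest.fixture(scope="session")
def identified(genome):
    """(records, cds_map) from running identification on the default genome."""
    return identify_records(genome.chromosomes, genome.models, genome.annotations)


def make_peptide(gaps, filler="A", nterm="M" * 10, cterm=""):
    """Peptide with a single 8CM at the requested gap vector."""
    g1, g2, g3, g4, g5 = gaps
    f = filler
    return (
        nterm + "C" + f * g1 + "C" + f * g2 + "CC" + f * g3
        + "C" + f + "C" + f * g4 + "C" + f * g5 + "C" + cterm
    )
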