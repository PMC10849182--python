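import pytest

from codonsel.genetic_code import all_directed_pairs
from codonsel.synthetic import SyntheticConfig, generate_dataset, selection_map

PAIRS = {p.label: p for p in all_directed_pairs()}


def pair(label: str):
    return PAIRS[label]


@pytest.fixture(scope="session")
def small_world():
    """A small selected world exercised by several modules: 30 genes,
    20 strains, planted selection S=1 on preferred codons."""
    cfg = SyntheticConfig(
        seed=11,
        genes=80,
        strains=20,
        codons_per_gene=200,
        S_by_codon=selection_map(1.0),
        theta=0.10,
        missing_rate=0.02,
    )
    alns, truth, expr = generate_dataset(cfg)
    return cfg, alns, truth, expr


@pytest.fixture(scope="session")
def clean_world():
    """Missing-data-free world for exact bookkeeping reconciliation."""
    cfg = SyntheticConfig(
        seed=3,
        genes=25,
        strains=20,
        codons_per_gene=150,
        S_by_codon=selection_map(0.8),
        theta=0.10,
        missing_rate=0.0,
    )
    alns, truth, expr = generate_dataset(cfg)
    return cfg, alns, truth, expr
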