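import pytest

from hgtclust import GenomeGeneOrder, ParsimonyConfig, Phylogeny


@pytest.fixture
def quartet_tree() -> Phylogeny:
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def equal_penalties() -> ParsimonyConfig:
    return ParsimonyConfig(gain_penalty=1.0, loss_penalty=1.0)


@pytest.fixture
def strict_penalties() -> ParsimonyConfig:
    return ParsimonyConfig(gain_penalty=2.0, loss_penalty=1.0)


@pytest.fixture
def simple_order() -> GenomeGeneOrder:
    return GenomeGeneOrder(
        genome_id="G1", replicon_id="chr",
        genes=("g1", "g2", "g3", "g4", "g5"),
    )
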