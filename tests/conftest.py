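import pytest

from segf.simulate import make_genome

# Desk-scale world: 14 panel genes of 300 bp separated by 200 bp of
# intergenic sequence (wider than one read, so no single wild-type read can
# touch two genes), spread over three chromosomes.
TEST_GENE_LEN = 300
TEST_GAP = 200


@pytest.fixture(scope="session")
def small_world():
    genome, panel = make_genome(11, gene_len=TEST_GENE_LEN, gap=TEST_GAP)
    return genome, panel


@pytest.fixture(scope="session")
def small_genome(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def small_panel(small_world):
    return small_world[1]
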