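import pytest

from prophagekit.genome_io import gene_sequence
from prophagekit.synthetic import SynthConfig, build_host_with_prophage


@pytest.fixture(scope="session")
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=1)


@pytest.fixture(scope="session")
def planted_locus(default_cfg):
    """(lysogen, excised, truth) for the default 50 kb / 5 kb / 26 nt locus."""
    return build_host_with_prophage(default_cfg)


@pytest.fixture(scope="session")
def anchor_gene_pair(planted_locus):
    """(reference gene seq, post-excision gene seq, stem spec)."""
    lysogen, excised, truth = planted_locus
    ref = gene_sequence(lysogen, lysogen.feature("anchor_tmRNA"))
    var = gene_sequence(excised, excised.feature("anchor_tmRNA"))
    return ref, var, truth.stem_spec
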