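import pytest

from thermosig.io_formats import Feature, GenomeRecord
from thermosig.synthetic_data import GenomeSpec, generate_genome


@pytest.fixture
def toy_genome():
    """Hand-built 60-base genome: one + CDS, one - CDS, one 16S feature."""
    #            0         1         2         3         4         5
    #            0123456789012345678901234567890123456789012345678901234567890
    seq = "TTTTATGAAATAACCCCTTATTTCATGGGGACGTACGTACGTACGTGGGGAAAATTTTCC"
    # + strand CDS at [4, 13): ATGAAATAA -> MK
    # - strand CDS at [17, 26): genome has TTATTTCAT; revcomp = ATGAAATAA -> MK
    features = [
        Feature("CDS", ((4, 13),), "+", {"locus_tag": "fwd"}),
        Feature("CDS", ((17, 26),), "-", {"locus_tag": "rev"}),
        Feature("rRNA_16S", ((30, 46),), "+", {"product": "16S ribosomal RNA"}),
    ]
    return GenomeRecord("toy", seq, "linear", features)


@pytest.fixture(scope="session")
def synthetic_genome():
    """Mid-sized deterministic genome shared across tests."""
    return generate_genome(GenomeSpec(length=100_000, n_cds=40, seed=11))
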