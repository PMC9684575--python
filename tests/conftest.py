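import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from reversionscan.genome import CodingTranscript, translate
from reversionscan.simulate import make_reference


@pytest.fixture(scope="session")
def toy_plus():
    """Plus-strand 2-exon transcript: 30-nt CDS split 12+18, with introns."""
    #                 exon1 (12 nt)    intron      exon2 (18 nt)
    cds = "ATGAAACCCGGGTTTACAGATTCAGCATAA"
    assert len(cds) == 30 and translate(cds, to_stop=False)[-1] == "*"
    contig = "NNNNN" + cds[:12] + "GTAAGTTTTCAG" + cds[12:] + "NNNNN"
    return (
        CodingTranscript(
            transcript_id="TOYP_tx", gene="TOYP", contig="toy_plus",
            strand="+", exons=((6, 17), (30, 47)), cds_sequence=cds,
        ),
        {"toy_plus": contig},
    )


@pytest.fixture(scope="session")
def toy_minus():
    """Minus-strand 2-exon transcript with the same 30-nt CDS."""
    from reversionscan.genome import revcomp

    cds = "ATGAAACCCGGGTTTACAGATTCAGCATAA"
    # genome carries the reverse complement; exon2 of the transcript comes
    # first on the genome
    contig = "NNNNN" + revcomp(cds[12:]) + "GTAAGTTTTCAG" + revcomp(cds[:12]) + "NNNNN"
    return (
        CodingTranscript(
            transcript_id="TOYM_tx", gene="TOYM", contig="toy_minus",
            strand="-", exons=((36, 47), (6, 23)),
            cds_sequence=cds,
        ),
        {"toy_minus": contig},
    )


@pytest.fixture(scope="session")
def brca2_like():
    """A long plus-strand transcript whose CDS reaches past c.5946, so that
    printed-style coding coordinates (codon 1982 etc.) are exercisable."""
    ref = make_reference(seed=42, genes={"BRCA2": (2100, "+")})
    return ref.transcripts["BRCA2"], ref.contigs


@pytest.fixture(scope="session")
def small_reference():
    return make_reference(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
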