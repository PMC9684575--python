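"""Coding-model tests: projection, mutation application, consequence calls."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from reversionscan.genome import (
    CdsChange,
    Variant,
    apply_changes,
    classify_consequence,
    project_to_cds,
    revcomp,
    translate,
    trim_alleles,
)

# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

_CODONS = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def oracle_translate(seq: str) -> str:
    """Codon-by-codon translation, independent of the package's table."""
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa = _CODONS[seq[i : i + 3]]
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


def splice(cds: str, start: int, ref_len: int, alt: str) -> str:
    """Character-level splicing oracle (1-based start)."""
    return cds[: start - 1] + alt + cds[start - 1 + ref_len :]


# --------------------------------------------------------------------------
# projection
# --------------------------------------------------------------------------

class TestProjection:
    def test_intronic_variant_is_noncoding(self, toy_plus):
        tx, _ = toy_plus
        v = Variant("v1", "toy_plus", 20, "T", "C")  # inside the intron
        assert project_to_cds(v, tx) is None

    def test_plus_strand_substitution(self, toy_plus):
        tx, _ = toy_plus
        # genomic 6 is CDS position 1 (the A of ATG)
        v = Variant("v2", "toy_plus", 7, "T", "C")
        ch = project_to_cds(v, tx)
        assert (ch.cds_start, ch.ref, ch.alt) == (2, "T", "C")

    def test_minus_strand_last_base_substitution(self, toy_minus):
        """Genomic C>T at the minus-strand transcript's last CDS base projects
        to cds position 1 with reverse-complemented alleles G>A... checked at
        the first CDS base: genomic position 47 carries the complement of A(TG).
        """
        tx, contigs = toy_minus
        # CDS position 1 sits at genomic 47 on the minus strand; genome base
        # there is complement of 'A' = 'T'. A genomic T>C is a cds A>G.
        assert contigs["toy_minus"][46] == "T"
        ch = project_to_cds(Variant("v3", "toy_minus", 47, "T", "C"), tx)
        assert (ch.cds_start, ch.ref, ch.alt) == (1, "A", "G")
        # and the last CDS base (position 30) sits at genomic 6
        base = contigs["toy_minus"][5]
        assert base == revcomp(tx.cds_sequence[-1])
        ch = project_to_cds(Variant("v4", "toy_minus", 6, base, "G"), tx)
        assert ch.cds_start == 30
        assert ch.ref == tx.cds_sequence[-1]
        assert ch.alt == "C"

    def test_anchored_deletion_like_printed_coordinates(self, brca2_like):
        """A 1-nt deletion at coding position 5946 lands on codon
        ceil(5946/3) = 1982, matching printed S1982Rfs-style annotations."""
        tx, contigs = brca2_like
        gpos = tx.cds_to_genomic(5946)
        seq = contigs[tx.contig]
        v = Variant("v5", tx.contig, gpos - 1, seq[gpos - 2 : gpos], seq[gpos - 2], origin="germline")
        ch = project_to_cds(v, tx)
        assert (ch.ref_len, ch.alt_len, ch.net_shift) == (1, 0, -1)
        cons = classify_consequence(tx, ch)
        assert cons.consequence == "frameshift"
        assert cons.codon == 1982
        # the deletion may left-align inside a repeat run but never past it
        assert ch.cds_start <= 5946
        assert math.ceil(5946 / 3) == 1982

    def test_ref_mismatch_raises(self, toy_plus):
        tx, _ = toy_plus
        with pytest.raises(ValueError, match="does not match"):
            project_to_cds(Variant("bad", "toy_plus", 7, "G", "C"), tx)

    def test_deletion_clipped_to_exon(self, toy_plus):
        tx, _ = toy_plus
        # deletion spanning the exon1/intron boundary: genomic 16-19 (2 coding)
        v = Variant("v6", "toy_plus", 15, "GGGTA", "G")
        ch = project_to_cds(v, tx)
        assert ch.alt == ""
        assert ch.ref_len == 2  # clipped to the coding bases at cds 11-12
        assert ch.cds_start == 11

    def test_other_contig_returns_none(self, toy_plus):
        tx, _ = toy_plus
        assert project_to_cds(Variant("v7", "elsewhere", 7, "T", "C"), tx) is None


def test_trim_alleles_anchored_indel():
    assert trim_alleles(100, "AT", "A") == (101, "T", "")
    assert trim_alleles(100, "A", "AGG") == (101, "", "GG")
    assert trim_alleles(100, "ACGT", "ACAT") == (102, "G", "A")


# --------------------------------------------------------------------------
# apply_changes
# --------------------------------------------------------------------------

class TestApplyChanges:
    def test_identity(self):
        assert apply_changes("ATGAAATAG", []) == "ATGAAATAG"

    def test_inverse_pair(self):
        cds = "ATGAAATAG"
        deleted = apply_changes(cds, [CdsChange(4, "A", "")])
        restored = apply_changes(deleted, [CdsChange(4, "", "A")])
        assert restored == cds

    def test_double_deletion_matches_splice_oracle(self, small_reference):
        cds = small_reference.transcripts["BRCA2"].cds_sequence[:60]
        got = apply_changes(cds, [CdsChange(10, cds[9], ""), CdsChange(25, cds[24:26], "")])
        expect = splice(splice(cds, 25, 2, ""), 10, 1, "")
        assert got == expect and len(got) == 57

    def test_partial_overlap_raises(self):
        cds = "ATGAAACCCGGGTAA"
        with pytest.raises(ValueError, match="overlap"):
            apply_changes(cds, [CdsChange(4, "AAA", ""), CdsChange(5, "AAC", "")])

    def test_encompassing_deletion_absorbs_inner_change(self):
        cds = "ATGAAACCCGGGTTTACATAA"
        # deleting cds 4..12 absorbs the inner 1-nt deletion at 7
        got = apply_changes(cds, [CdsChange(4, cds[3:12], ""), CdsChange(7, cds[6], "")])
        assert got == splice(cds, 4, 9, "")

    def test_wrong_ref_raises(self):
        with pytest.raises(ValueError, match="does not match"):
            apply_changes("ATGAAATAG", [CdsChange(4, "G", "")])


# --------------------------------------------------------------------------
# consequence classification
# --------------------------------------------------------------------------

class TestConsequence:
    def test_frameshift_notation_matches_translation_oracle(self, toy_plus):
        tx, _ = toy_plus
        cds = tx.cds_sequence
        ch = CdsChange(5, cds[4], "")  # 1-nt deletion in codon 2
        cons = classify_consequence(tx, ch)
        assert cons.consequence == "frameshift"
        mutated = splice(cds, 5, 1, "")
        prot = oracle_translate(mutated)
        # notation X{codon}Yfs*N with codon 2 and N = stop offset from codon 2
        ref_aa = oracle_translate(cds)[1]
        new_aa = prot[1]
        if "*" in prot[1:]:
            expected = f"{ref_aa}2{new_aa}fs*{prot[1:].index('*') + 1}"
        else:  # frame runs off the CDS end without a novel stop
            expected = f"{ref_aa}2{new_aa}fs"
        assert cons.protein_notation == expected

    def test_inframe_deletion(self, toy_plus):
        tx, _ = toy_plus
        cds = tx.cds_sequence
        cons = classify_consequence(tx, CdsChange(4, cds[3:6], ""))
        assert cons.consequence == "inframe_indel"

    def test_nonsense_substitution(self, toy_plus):
        tx, _ = toy_plus
        # codon 6 is ACA; A->T at its first base gives the TCA? no: position 16
        cds = tx.cds_sequence
        # make codon 2 AAA -> TAA
        cons = classify_consequence(tx, CdsChange(4, "A", "T"))
        assert cons.consequence == "nonsense"
        assert cons.protein_notation == "K2*"

    def test_silent_substitution(self, toy_plus):
        tx, _ = toy_plus
        # codon 3 CCC -> CCA is still proline
        cons = classify_consequence(tx, CdsChange(9, "C", "A"))
        assert cons.consequence == "silent"


# --------------------------------------------------------------------------
# properties
# --------------------------------------------------------------------------

_sense = [c for c, aa in _CODONS.items() if aa != "*"]


@st.composite
def random_cds(draw, max_codons=99):
    n = draw(st.integers(min_value=5, max_value=max_codons))
    body = draw(st.lists(st.sampled_from(_sense), min_size=n, max_size=n))
    stop = draw(st.sampled_from(["TAA", "TAG", "TGA"]))
    return "ATG" + "".join(body) + stop


@st.composite
def cds_and_change(draw):
    cds = draw(random_cds())
    kind = draw(st.sampled_from(["del", "ins", "sub"]))
    if kind == "del":
        start = draw(st.integers(1, len(cds) - 4))
        length = draw(st.integers(1, min(6, len(cds) - start)))
        return cds, CdsChange(start, cds[start - 1 : start - 1 + length], "")
    if kind == "ins":
        start = draw(st.integers(2, len(cds)))
        alt = draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
        return cds, CdsChange(start, "", alt)
    start = draw(st.integers(1, len(cds)))
    ref = cds[start - 1]
    alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
    return cds, CdsChange(start, ref, alt)


@settings(max_examples=200, deadline=None)
@given(cds_and_change())
def test_apply_matches_splice_oracle_and_frameshift_rule(case):
    cds, ch = case
    mutated = apply_changes(cds, [ch])
    assert mutated == splice(cds, ch.cds_start, ch.ref_len, ch.alt)
    assert translate(mutated) == oracle_translate(mutated).rstrip("*")
    assert (ch.net_shift % 3 != 0) == (len(mutated) % 3 != len(cds) % 3)


@settings(max_examples=100, deadline=None)
@given(random_cds(max_codons=60), st.integers(0, 1_000_000))
def test_disjoint_changes_associative(cds, seed):
    """Applying two disjoint deletions together equals applying them
    successively in coordinate order (with the second's coordinates adjusted)."""
    import numpy as np

    rng = np.random.default_rng(seed)
    if len(cds) < 20:
        return
    a = int(rng.integers(2, len(cds) // 2 - 2))
    b = int(rng.integers(len(cds) // 2 + 2, len(cds) - 2))
    ch_a, ch_b = CdsChange(a, cds[a - 1], ""), CdsChange(b, cds[b - 1], "")
    joint = apply_changes(cds, [ch_a, ch_b])
    seq = apply_changes(cds, [ch_b])
    seq = apply_changes(seq, [CdsChange(a, cds[a - 1], "")])
    assert joint == seq
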