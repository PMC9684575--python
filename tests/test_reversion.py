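"""Reversion-detection tests: window, ORF restoration, end-to-end calls."""

import numpy as np
import pytest

from reversionscan.copynumber import Segment, SegmentProfile, expected_vaf
from reversionscan.genome import CdsChange, CodingTranscript, apply_changes
from reversionscan.phasing import ReadPairObservation
from reversionscan.reversion import (
    PatientBundle,
    call_reversions,
    check_orf_restoration,
    codon_distance,
    find_candidates,
    is_truncating,
)
from reversionscan.simulate import SimulationConfig, cds_change_to_variant, simulate_cohort

from test_genome import oracle_translate, splice


def oracle_restored(cds: str, changes) -> bool:
    """Brute-force oracle: splice the mutated sequence directly and demand a
    full-length ORF (ATG .. natural stop, no internal stop)."""
    changes = sorted(changes, key=lambda c: (c.cds_start, -c.ref_len))
    # absorb changes inside deletions
    survivors = []
    for ch in changes:
        inside = any(
            d.alt == "" and d.cds_start <= ch.cds_start
            and ch.cds_start + max(ch.ref_len, 1) - 1 <= d.cds_start + d.ref_len - 1
            for d in survivors
        )
        if not inside:
            survivors.append(ch)
    seq = cds
    for ch in reversed(survivors):
        seq = splice(seq, ch.cds_start, ch.ref_len, ch.alt)
    if len(seq) % 3 != 0 or not seq.startswith("ATG"):
        return False
    prot = oracle_translate(seq)
    return prot.endswith("*") and len(prot) * 3 == len(seq)


class TestTruncating:
    def test_one_nt_deletion(self, toy_plus):
        tx, _ = toy_plus
        assert is_truncating(CdsChange(5, tx.cds_sequence[4], ""), tx)

    def test_inframe_deletion_not_truncating(self, toy_plus):
        tx, _ = toy_plus
        assert not is_truncating(CdsChange(4, tx.cds_sequence[3:6], ""), tx)

    def test_nonsense_substitution_verified_by_translation(self, toy_plus):
        tx, _ = toy_plus
        ch = CdsChange(4, "A", "T")  # AAA -> TAA at codon 2
        assert is_truncating(ch, tx)
        assert oracle_translate(splice(tx.cds_sequence, 4, 1, "T")) == "M*"


class TestWindow:
    def test_documented_distances(self):
        # germline codon 1716 / somatic 1723 and 1982 / 1998 pairs
        g1 = CdsChange(1716 * 3 - 2, "A", "")
        s1 = CdsChange(1723 * 3 - 2, "A", "")
        assert codon_distance(g1, s1) == 7
        g2 = CdsChange(5946, "T", "")
        s2 = CdsChange(1998 * 3 - 2, "A", "")
        assert codon_distance(g2, s2) == 16
        assert find_candidates(g1, [s1]) == [s1]

    def test_window_boundary(self):
        germ = CdsChange(300 * 3 - 2, "A", "")
        at_200 = CdsChange(500 * 3 - 2, "A", "")
        at_201 = CdsChange(501 * 3 - 2, "A", "")
        got = find_candidates(germ, [at_200, at_201])
        assert got == [at_200]

    def test_window_is_symmetric(self):
        germ = CdsChange(300 * 3 - 2, "A", "")
        upstream = CdsChange(150 * 3 - 2, "A", "")
        assert find_candidates(germ, [upstream]) == [upstream]

    def test_substitutions_only_for_nonsense_germline(self, toy_plus):
        tx, _ = toy_plus
        nonsense = CdsChange(4, "A", "T")
        frameshift = CdsChange(5, "A", "")
        sub = CdsChange(8, "C", "G")
        assert find_candidates(frameshift, [sub], tx) == []
        assert find_candidates(nonsense, [sub], tx) == [sub]


class TestOrfRestoration:
    def _toy90(self):
        """Deterministic 90-nt CDS for the compensating-indel example."""
        ref = __import__("reversionscan").make_reference(11, genes={"T": (30, "+")})
        return ref.transcripts["T"]

    def test_compensating_indel_pair(self):
        tx = self._toy90()
        cds = tx.cds_sequence
        rng = np.random.default_rng(5)
        # search a (germline -1 nt at codon 10, somatic -2 nt at codon 14)
        # pair whose bridged frame is stop-free; assert agreement with oracle
        found = 0
        for off_g in range(3):
            for off_s in range(3):
                germ = CdsChange(28 + off_g, cds[27 + off_g], "")
                som_start = 40 + off_s
                som = CdsChange(som_start, cds[som_start - 1 : som_start + 1], "")
                restored, mech, prot = check_orf_restoration(tx, germ, [som])
                assert restored == oracle_restored(cds, [germ, som])
                if restored:
                    found += 1
                    assert mech == "compensating_indel"
        assert found >= 1  # at least one bridged frame is clean here

    def test_single_frameshift_not_restored(self):
        tx = self._toy90()
        germ = CdsChange(28, tx.cds_sequence[27], "")
        restored, _, _ = check_orf_restoration(tx, germ, [])
        assert not restored

    def test_encompassing_deletion(self):
        tx = self._toy90()
        cds = tx.cds_sequence
        germ = CdsChange(30, cds[29], "")
        som = CdsChange(25, cds[24 : 24 + 27], "")  # 27-nt in-frame deletion over it
        restored, mech, _ = check_orf_restoration(tx, germ, [som])
        assert restored == oracle_restored(cds, [germ, som])
        assert restored
        assert mech == "encompassing_deletion"

    def test_nonsense_removed_by_inframe_deletion(self):
        tx = self._toy90()
        cds = tx.cds_sequence
        # plant a nonsense somewhere in codons 8..20 (single-base stop gain)
        germ = codon_idx = None
        for ci in range(8, 21):
            codon = cds[(ci - 1) * 3 : ci * 3]
            for off, b in [(i, bb) for i in range(3) for bb in "ACGT"]:
                new = codon[:off] + b + codon[off + 1 :]
                if b != codon[off] and oracle_translate(new) == "*":
                    germ, codon_idx = CdsChange((ci - 1) * 3 + off + 1, codon[off], b), ci
                    break
            if germ:
                break
        assert germ is not None
        start = (codon_idx - 1) * 3 + 1
        som = CdsChange(start, cds[start - 1 : start + 2], "")  # delete the codon
        restored, mech, _ = check_orf_restoration(tx, germ, [som])
        assert restored == oracle_restored(cds, [germ, som])
        assert restored
        assert mech == "encompassing_deletion"

    def test_restored_implies_net_shift_zero_mod3(self, rng):
        """Random germline/somatic pairs: restoration never co-occurs with a
        combined net shift that is not 0 mod 3."""
        from reversionscan.genome import surviving_changes

        tx = self._toy90()
        cds = tx.cds_sequence
        for _ in range(300):
            gpos = int(rng.integers(10, 40))
            glen = int(rng.integers(1, 3))
            germ = CdsChange(gpos, cds[gpos - 1 : gpos - 1 + glen], "")
            spos = int(rng.integers(45, 80))
            slen = int(rng.integers(1, 5))
            som = CdsChange(spos, cds[spos - 1 : spos - 1 + slen], "")
            restored, _, _ = check_orf_restoration(tx, germ, [som])
            shift = sum(c.net_shift for c in surviving_changes([germ, som]))
            if restored:
                assert shift % 3 == 0
            assert restored == oracle_restored(cds, [germ, som])


class TestBruteForceAgreement:
    def test_exhaustive_small_deletions_agree_with_translate_everything(self):
        """For random toy CDSs and germline frameshifts, the restoration
        verdict matches brute force over every somatic deletion of <= 6 nt in
        the window (a reduced-size version of the full sweep the acceptance
        checks run)."""
        from reversionscan.simulate import make_reference

        rng = np.random.default_rng(99)
        disagreements = 0
        for rep in range(25):
            ref = make_reference(1000 + rep, genes={"T": (int(rng.integers(20, 90)), "+")})
            tx = ref.transcripts["T"]
            cds = tx.cds_sequence
            gpos = int(rng.integers(4, len(cds) - 9))
            glen = int(rng.integers(1, 3))
            germ = CdsChange(gpos, cds[gpos - 1 : gpos - 1 + glen], "")
            for start in range(1, len(cds) - 3):
                for length in range(1, 7):
                    if start + length - 1 > len(cds):
                        continue
                    som = CdsChange(start, cds[start - 1 : start - 1 + length], "")
                    try:
                        got, _, _ = check_orf_restoration(tx, germ, [som])
                    except ValueError:
                        continue  # partial overlap: no joint haplotype
                    if got != oracle_restored(cds, [germ, som]):
                        disagreements += 1
        assert disagreements == 0


class TestCallReversions:
    def _bundle_from_sim(self, seed=1, n=400):
        cfg = SimulationConfig(
            seed=seed, n_patients=n, reversion_rate_post_platinum=0.5,
            carrier_rate_by_group={"brca_associated": 0.3, "other": 0.1},
            polyclonal_fraction=0.3,
            mechanism_mix={"compensating_indel": 0.5, "encompassing_deletion": 0.3,
                           "delins": 0.2},
        )
        return simulate_cohort(cfg)

    def test_planted_reversions_recovered_exactly(self):
        sim = self._bundle_from_sim()
        tp = fp = fn = 0
        polyclonal_seen = False
        for p in sim.patients:
            calls = call_reversions(p.bundle(sim.reference.transcripts))
            want = {r["variant_id"] for r in p.truth["reversions"]}
            got = set()
            for c in calls:
                from reversionscan.genome import project_to_cds

                got.add(next(
                    v.variant_id for v in p.somatic_variants
                    if project_to_cds(v, sim.reference.transcripts[c.gene]) == c.somatic[0]
                ))
            if len(want) == 2 and want == got:
                polyclonal_seen = True
            tp += len(want & got)
            fn += len(want - got)
            fp += len(got - want)
        assert fn == 0 and fp == 0 and tp > 0
        assert polyclonal_seen  # double-reversion patients are called twice

    def test_two_cis_pairs_blocks_call(self, toy_plus, small_reference):
        """A frame-restoring candidate with only two cis pairs and no
        encompassing deletion must not be called."""
        tx = small_reference.transcripts["BRCA2"]
        cds = tx.cds_sequence
        contigs = small_reference.contigs
        germ = CdsChange(700, cds[699], "")
        # find a compensating 2-nt deletion that restores the frame
        som = None
        for start in range(720, 800):
            cand = CdsChange(start, cds[start - 1 : start + 1], "")
            if oracle_restored(cds, [germ, cand]):
                som = cand
                break
        assert som is not None
        gv = cds_change_to_variant(tx, contigs, germ, "g0", "germline", vaf=0.5)
        sv = cds_change_to_variant(tx, contigs, som, "s0", "somatic", vaf=0.3)
        pairs = {("g0", "s0"): [ReadPairObservation(f"f{i}", "alt", "alt") for i in range(2)]}
        bundle = PatientBundle("PT", small_reference.transcripts, [gv], [sv], pairs)
        assert call_reversions(bundle) == []
        # with three pairs the same candidate is called
        pairs[("g0", "s0")].append(ReadPairObservation("f2", "alt", "alt"))
        calls = call_reversions(bundle)
        assert len(calls) == 1 and calls[0].restored

    def test_patient_without_germline_truncating_yields_nothing(self, small_reference):
        tx = small_reference.transcripts["BRCA2"]
        sv = cds_change_to_variant(
            tx, small_reference.contigs, CdsChange(700, tx.cds_sequence[699], ""),
            "s0", "somatic", vaf=0.3,
        )
        bundle = PatientBundle("PT", small_reference.transcripts, [], [sv], {})
        assert call_reversions(bundle) == []

    def test_loh_phasing_gates_encompassing_deletion(self, small_reference):
        tx = small_reference.transcripts["BRCA2"]
        cds = tx.cds_sequence
        contigs = small_reference.contigs
        germ = CdsChange(700, cds[699], "")
        som = None
        for lead in range(3, 30):
            start = 700 - lead
            cand = CdsChange(start, cds[start - 1 : start - 1 + 27], "")
            if cand.end >= 700 and oracle_restored(cds, [germ, cand]):
                som = cand
                break
        assert som is not None
        purity = 0.6
        vaf = expected_vaf(purity, 2, 2)
        gv = cds_change_to_variant(tx, contigs, germ, "g0", "germline", vaf=round(vaf, 4))
        sv = cds_change_to_variant(tx, contigs, som, "s0", "somatic", vaf=0.3)
        contig_len = len(contigs[tx.contig])
        loh = SegmentProfile([Segment(tx.contig, 1, contig_len, 2, 0)], purity=purity)
        het = SegmentProfile([Segment(tx.contig, 1, contig_len, 2, 1)], purity=purity)
        called = call_reversions(PatientBundle("PT", small_reference.transcripts,
                                               [gv], [sv], {}, profile=loh))
        assert len(called) == 1
        assert called[0].phasing.method == "loh_inference"
        assert called[0].mechanism == "encompassing_deletion"
        blocked = call_reversions(PatientBundle("PT", small_reference.transcripts,
                                                [gv], [sv], {}, profile=het))
        assert blocked == []
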