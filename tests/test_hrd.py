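"""HRD scar scores: smoothing, LST / HRD-LOH / NtAI rules, decile summary."""

import numpy as np
import pytest

from reversionscan.copynumber import Segment, SegmentProfile
from reversionscan.hrd import (
    MB,
    GenomeBuildInfo,
    ContigInfo,
    HrdScores,
    hrd_loh_score,
    hrd_sum,
    lst_score,
    ntai_score,
    purity_decile_summary,
    smooth_profile,
)
from reversionscan.simulate import make_build, simulate_segment_profile


@pytest.fixture(scope="module")
def build():
    return make_build(n_contigs=4, contig_length=200 * MB, cen=(95 * MB, 105 * MB))


def seg(contig, start_mb, end_mb, tcn, lcn):
    return Segment(contig, int(start_mb * MB), int(end_mb * MB), tcn, lcn)


class TestSmoothing:
    def test_spike_removed_and_neighbours_merged(self):
        profile = SegmentProfile(
            [seg("chr1", 1 / MB, 20, 2, 1), seg("chr1", 20.0001, 21, 5, 2),
             seg("chr1", 21.001, 41, 2, 1)],
            purity=0.5,
        )
        out = smooth_profile(profile)
        assert len(out.segments) == 1
        got = out.segments[0]
        assert (got.start, got.end, got.state) == (1, 41 * MB, (2, 1))
        assert got.length == pytest.approx(41 * MB, rel=1e-6)

    def test_already_smooth_unchanged(self):
        profile = SegmentProfile(
            [seg("chr1", 1 / MB, 20, 2, 1), seg("chr1", 20.1, 45, 3, 1)], purity=0.5
        )
        assert smooth_profile(profile).segments == profile.segments

    def test_empty_profile(self):
        assert smooth_profile(SegmentProfile([], purity=0.5)).segments == []

    def test_distant_same_state_segments_not_fused(self):
        profile = SegmentProfile(
            [seg("chr1", 1 / MB, 30, 3, 1), seg("chr1", 170, 200, 3, 1)], purity=0.5
        )
        assert len(smooth_profile(profile).segments) == 2

    def test_idempotent(self):
        profile = SegmentProfile(
            [seg("chr1", 1 / MB, 20, 2, 1), seg("chr1", 20.0001, 21, 5, 2),
             seg("chr1", 21.001, 41, 2, 1), seg("chr1", 50, 52, 2, 1)],
            purity=0.5,
        )
        once = smooth_profile(profile)
        assert smooth_profile(once).segments == once.segments


class TestLst:
    def test_balanced_diploid_genome_zero(self, build):
        profile = SegmentProfile(
            [seg(c, 1 / MB, 94, 2, 1) for c in build.contigs], purity=0.8
        )
        assert lst_score(profile, build) == 0

    def test_hand_enumerated_transitions(self, build):
        """Three qualifying >=10 Mb transitions plus two sub-10 Mb ones."""
        profile = SegmentProfile(
            [
                seg("chr1", 1 / MB, 15, 2, 1),     # |t1| 15 Mb vs 15 Mb
                seg("chr1", 15.0001, 30, 3, 1),    # |t2|
                seg("chr1", 30.0001, 45, 2, 0),    # |t3|
                seg("chr1", 45.0001, 60, 2, 1),
                seg("chr1", 60.0001, 65, 4, 1),    # 5 Mb: no transition either side
                seg("chr1", 65.0001, 94, 2, 1),
            ],
            purity=0.8,
        )
        assert lst_score(profile, build) == 3

    def test_centromere_straddling_transition_not_counted(self, build):
        profile = SegmentProfile(
            [seg("chr1", 80, 100, 2, 1), seg("chr1", 100.0001, 130, 3, 1)],
            purity=0.8,
        )
        assert lst_score(profile, build) == 0


class TestHrdLoh:
    def test_whole_contig_loh_excluded(self, build):
        profile = SegmentProfile([seg("chr1", 1 / MB, 200, 2, 0)], purity=0.8)
        assert hrd_loh_score(profile, build) == 0

    def test_length_threshold(self, build):
        profile = SegmentProfile(
            [seg("chr1", 20, 40.1, 2, 0), seg("chr2", 20, 40.1, 1, 0),
             seg("chr3", 20, 30, 2, 0)],  # 10 Mb: below threshold
            purity=0.8,
        )
        assert hrd_loh_score(profile, build) == 2

    def test_homozygous_deletion_not_loh(self, build):
        profile = SegmentProfile([seg("chr1", 20, 40.1, 0, 0)], purity=0.8)
        assert hrd_loh_score(profile, build) == 0


class TestNtai:
    def test_balanced_genome_zero(self, build):
        profile = SegmentProfile([seg(c, 1 / MB, 94, 2, 1) for c in build.contigs],
                                 purity=0.8)
        assert ntai_score(profile, build) == 0

    def test_p_terminal_imbalance_counts(self, build):
        profile = SegmentProfile([seg("chr1", 1 / MB, 30, 3, 1)], purity=0.8)
        assert ntai_score(profile, build) == 1

    def test_interior_imbalance_does_not_count(self, build):
        profile = SegmentProfile([seg("chr1", 20, 50, 3, 1)], purity=0.8)
        assert ntai_score(profile, build) == 0

    def test_centromere_crossing_telomeric_segment_excluded(self, build):
        profile = SegmentProfile([seg("chr1", 1 / MB, 130, 3, 1)], purity=0.8)
        assert ntai_score(profile, build) == 0


class TestHrdSum:
    def test_sum_identity_and_planted_recovery(self, build):
        rng = np.random.default_rng(0)
        for _ in range(30):
            targets = tuple(int(x) for x in rng.integers(0, 3, size=3))
            profile, planted, kept = simulate_segment_profile(
                targets, purity=0.9, build=build, rng=rng, sensitivity=None
            )
            scores = hrd_sum(profile, build)
            assert (scores.lst, scores.hrd_loh, scores.ntai) == targets
            assert scores.hrd_sum == sum(targets)
            assert kept == planted

    def test_invariant_under_segment_splitting(self, build):
        """Splitting any segment into contiguous equal-state pieces does not
        change the scores (smoothing re-merges them)."""
        profile, _, _ = simulate_segment_profile((2, 2, 2), 0.9, build,
                                                 np.random.default_rng(3))
        split = []
        for s in profile.segments:
            mid = (s.start + s.end) // 2
            split += [Segment(s.contig, s.start, mid, s.total_cn, s.minor_cn),
                      Segment(s.contig, mid + 1, s.end, s.total_cn, s.minor_cn)]
        shuffled = SegmentProfile(split, purity=profile.purity)
        assert hrd_sum(shuffled, build) == hrd_sum(profile, build)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            HrdScores(-1, 0, 0)


class TestPurityDeciles:
    def test_constant_scores_give_equal_medians(self):
        records = [(p, 7.0) for p in np.linspace(0.05, 1.0, 40)]
        out = purity_decile_summary(records)
        assert (out["median"] == 7.0).all()
        assert len(out) == 10

    def test_ten_records_one_per_decile(self):
        records = [(p, i) for i, p in enumerate(np.linspace(0.1, 1.0, 10))]
        out = purity_decile_summary(records)
        assert (out["n"] == 1).all()

    def test_fewer_than_ten_rejected(self):
        with pytest.raises(ValueError):
            purity_decile_summary([(0.5, 1.0)] * 9)

    def test_attenuated_cohort_median_nondecreasing(self):
        """With logistic detection sensitivity, the median scored HRD-sum per
        purity decile is non-decreasing (the purity-attenuation phenomenon)."""
        build = make_build()
        rng = np.random.default_rng(42)
        records = []
        for _ in range(200):
            purity = float(rng.uniform(0.05, 1.0))
            profile, _, _ = simulate_segment_profile(
                (5, 3, 4), purity, build, rng, sensitivity=(0.5, 10.0)
            )
            records.append((purity, hrd_sum(profile, build).hrd_sum))
        medians = purity_decile_summary(records)["median"].to_numpy()
        assert (np.diff(medians) >= 0).all()
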