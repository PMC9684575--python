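"""Genomic-scar measures of homologous-recombination deficiency.

Three scar counts are computed from an allele-specific copy-number profile:

* LST  — large-scale state transitions: within-arm breakpoints between two
  adjacent segments each >= 10 Mb whose allele-specific state differs,
  counted after smoothing away segments shorter than 3 Mb;
* HRD-LOH — LOH segments (minor copy 0, total copy >= 1) longer than 15 Mb
  that do not span a whole chromosome;
* NtAI — allelically imbalanced segments (2 * minor != total) extending to a
  telomere without crossing the centromere.

HRD-sum is their unweighted sum. Thresholds follow the canonical published
definitions of each score and are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .copynumber import Segment, SegmentProfile

MB = 1_000_000
SMOOTH_MIN_LEN = 3 * MB
LST_MIN_SEG = 10 * MB
HRD_LOH_MIN_LEN = 15 * MB


@dataclass(frozen=True)
class ContigInfo:
    length: int
    cen_start: int
    cen_end: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("contig length must be positive")
        if not 1 <= self.cen_start <= self.cen_end <= self.length:
            raise ValueError("centromere interval must lie within the contig")


@dataclass
class GenomeBuildInfo:
    """Per-contig lengths and centromere intervals."""

    contigs: dict[str, ContigInfo]

    def arm_of(self, seg: Segment) -> Optional[str]:
        """'p' if the segment lies entirely before the centromere, 'q' if
        entirely after, None if it overlaps the centromere or the contig is
        unknown."""
        info = self.contigs.get(seg.contig)
        if info is None:
            return None
        if seg.end < info.cen_start:
            return "p"
        if seg.start > info.cen_end:
            return "q"
        return None

    def touches_telomere(self, seg: Segment) -> bool:
        info = self.contigs.get(seg.contig)
        if info is None:
            return False
        return seg.start <= 1 or seg.end >= info.length

    def crosses_centromere(self, seg: Segment) -> bool:
        info = self.contigs.get(seg.contig)
        if info is None:
            return False
        return seg.start <= info.cen_end and seg.end >= info.cen_start

    def spans_contig(self, seg: Segment) -> bool:
        info = self.contigs.get(seg.contig)
        if info is None:
            return False
        return seg.start <= 1 and seg.end >= info.length


@dataclass(frozen=True)
class HrdScores:
    lst: int
    hrd_loh: int
    ntai: int

    def __post_init__(self):
        if min(self.lst, self.hrd_loh, self.ntai) < 0:
            raise ValueError("scar counts must be non-negative")

    @property
    def hrd_sum(self) -> int:
        return self.lst + self.hrd_loh + self.ntai


def smooth_profile(profile: SegmentProfile, min_len: int = SMOOTH_MIN_LEN) -> SegmentProfile:
    """Remove sub-threshold segments and re-merge equal-state neighbours.

    Adjacent same-contig segments with identical (total, minor) state are
    merged when the gap between them does not exceed ``min_len`` (gaps that
    large cannot come from a removed segment and are treated as real
    discontinuities). Deterministic and idempotent.
    """
    kept = [s for s in profile.segments if s.length >= min_len]
    merged: list[Segment] = []
    for seg in kept:
        if (
            merged
            and merged[-1].contig == seg.contig
            and merged[-1].state == seg.state
            and seg.start - merged[-1].end - 1 <= min_len
        ):
            prev = merged.pop()
            seg = Segment(prev.contig, prev.start, seg.end, seg.total_cn, seg.minor_cn)
        merged.append(seg)
    return SegmentProfile(merged, purity=profile.purity, ploidy=profile.ploidy)


def lst_score(profile: SegmentProfile, build: GenomeBuildInfo, min_seg: int = LST_MIN_SEG) -> int:
    """Count large-scale transitions on a smoothed profile."""
    n = 0
    segs = profile.segments
    for a, b in zip(segs, segs[1:]):
        if a.contig != b.contig:
            continue
        arm_a, arm_b = build.arm_of(a), build.arm_of(b)
        if arm_a is None or arm_a != arm_b:
            continue
        if a.length < min_seg or b.length < min_seg:
            continue
        if a.state != b.state:
            n += 1
    return n


def hrd_loh_score(
    profile: SegmentProfile, build: GenomeBuildInfo, min_len: int = HRD_LOH_MIN_LEN
) -> int:
    """Count LOH segments longer than ``min_len`` not spanning a whole
    chromosome. Homozygous deletions (total copy 0) do not count as LOH;
    segments with unknown minor copy number are skipped."""
    return sum(
        1
        for s in profile.segments
        if s.minor_cn == 0
        and s.total_cn >= 1
        and s.length > min_len
        and not build.spans_contig(s)
    )


def ntai_score(profile: SegmentProfile, build: GenomeBuildInfo, min_len: int = 0) -> int:
    """Count telomeric allelic-imbalance segments (no minimum length by
    default): imbalanced state reaching a contig end without crossing the
    centromere."""
    return sum(
        1
        for s in profile.segments
        if s.minor_cn is not None
        and 2 * s.minor_cn != s.total_cn
        and s.length >= min_len
        and build.touches_telomere(s)
        and not build.crosses_centromere(s)
    )


def hrd_sum(
    profile: SegmentProfile,
    build: GenomeBuildInfo,
    smooth_min_len: int = SMOOTH_MIN_LEN,
    lst_min_seg: int = LST_MIN_SEG,
    loh_min_len: int = HRD_LOH_MIN_LEN,
    ntai_min_len: int = 0,
) -> HrdScores:
    """All three scar scores on the smoothed profile, plus their sum."""
    smoothed = smooth_profile(profile, smooth_min_len)
    return HrdScores(
        lst=lst_score(smoothed, build, lst_min_seg),
        hrd_loh=hrd_loh_score(smoothed, build, loh_min_len),
        ntai=ntai_score(smoothed, build, ntai_min_len),
    )


def purity_decile_summary(records: Sequence[tuple[float, float]]) -> pd.DataFrame:
    """Median and quartiles of HRD-sum within purity deciles.

    ``records`` are (purity, hrd_sum) pairs; at least 10 are required.
    Deciles are purity quantile bins, so each holds ~n/10 tumors.
    """
    if len(records) < 10:
        raise ValueError("need at least 10 records to form purity deciles")
    df = pd.DataFrame(records, columns=["purity", "hrd_sum"])
    df["decile"] = pd.qcut(df["purity"].rank(method="first"), 10, labels=range(1, 11))
    out = (
        df.groupby("decile", observed=True)["hrd_sum"]
        .agg(
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
            n="size",
        )
        .reset_index()
    )
    out["decile"] = out["decile"].astype(int)
    return out
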