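"""Allele-specific copy-number model, expected VAF and zygosity inference.

The tumor specimen is modelled as a mixture of tumor cells (fraction
``purity``) carrying the segment's integer copy state and normal cells
contributing two copies at every autosomal locus. For a variant present on
``m`` of ``total_cn`` tumor copies, the expected variant allele fraction is

    E[VAF] = m * p / (total_cn * p + 2 * (1 - p))

Zygosity is inferred by maximising a binomial read-count likelihood over m;
loss of the wild-type allele requires the overlapping segment to have minor
copy number zero and the most likely m to equal the total copy number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .genome import Variant


@dataclass(frozen=True)
class Segment:
    """One allele-specific copy-number segment (1-based inclusive interval)."""

    contig: str
    start: int
    end: int
    total_cn: int
    minor_cn: Optional[int]

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"segment {self.contig}:{self.start}-{self.end}: end must exceed start")
        if self.total_cn < 0:
            raise ValueError("total_cn must be >= 0")
        if self.minor_cn is not None:
            if self.minor_cn < 0:
                raise ValueError("minor_cn must be >= 0")
            if self.minor_cn > self.total_cn - self.minor_cn:
                raise ValueError(
                    f"minor_cn {self.minor_cn} exceeds major allele count "
                    f"(total_cn {self.total_cn})"
                )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def state(self) -> tuple[int, Optional[int]]:
        return (self.total_cn, self.minor_cn)

    def contains(self, contig: str, pos: int) -> bool:
        return contig == self.contig and self.start <= pos <= self.end


@dataclass
class SegmentProfile:
    """Ordered, per-contig non-overlapping segments plus sample purity/ploidy."""

    segments: list[Segment]
    purity: float
    ploidy: float = 2.0

    def __post_init__(self):
        if not 0.0 < self.purity <= 1.0:
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        self.segments = sorted(self.segments, key=lambda s: (s.contig, s.start))
        by_contig: dict[str, int] = {}
        for seg in self.segments:
            prev_end = by_contig.get(seg.contig)
            if prev_end is not None and seg.start <= prev_end:
                raise ValueError(f"overlapping segments on {seg.contig} at {seg.start}")
            by_contig[seg.contig] = seg.end

    def overlapping(self, contig: str, pos: int) -> Optional[Segment]:
        hits = [s for s in self.segments if s.contains(contig, pos)]
        return hits[0] if len(hits) == 1 else None


@dataclass(frozen=True)
class ZygosityCall:
    variant_id: str
    zygosity: str  # biallelic_loss_of_wt | biallelic_second_hit | heterozygous | indeterminate
    best_m: Optional[int]
    segment: Optional[Segment]


def expected_vaf(purity: float, total_cn: int, m: int) -> float:
    """Expected variant allele fraction under the purity/copy-number mixture."""
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity {purity} outside (0, 1]")
    if m < 0 or m > total_cn:
        raise ValueError(f"mutated copies m={m} outside [0, total_cn={total_cn}]")
    if m == 0:
        return 0.0
    denom = total_cn * purity + 2.0 * (1.0 - purity)
    if denom == 0.0:
        return 0.0
    return m * purity / denom


def classify_zygosity(variant: Variant, profile: SegmentProfile) -> ZygosityCall:
    """Most-likely mutated copy number at a variant locus.

    best_m maximises Binomial(alt_reads | depth, E[VAF](purity, total_cn, m))
    over m in 1..total_cn. The call is biallelic_loss_of_wt when the segment
    has minor_cn == 0 and best_m equals total_cn; it is indeterminate when no
    unique overlapping segment exists, annotations are missing, or the
    segment carries no tumor copies.
    """
    seg = profile.overlapping(variant.contig, variant.pos)
    if seg is None or seg.minor_cn is None:
        return ZygosityCall(variant.variant_id, "indeterminate", None, seg)
    if variant.alt_reads is None or variant.depth is None or variant.depth == 0:
        return ZygosityCall(variant.variant_id, "indeterminate", None, seg)
    if seg.total_cn == 0:
        return ZygosityCall(variant.variant_id, "indeterminate", None, seg)
    ms = np.arange(1, seg.total_cn + 1)
    ps = np.clip(
        [expected_vaf(profile.purity, seg.total_cn, int(m)) for m in ms], 1e-9, 1 - 1e-9
    )
    loglik = stats.binom.logpmf(variant.alt_reads, variant.depth, ps)
    best_m = int(ms[int(np.argmax(loglik))])
    if seg.minor_cn == 0 and best_m == seg.total_cn:
        zygosity = "biallelic_loss_of_wt"
    else:
        zygosity = "heterozygous"
    return ZygosityCall(variant.variant_id, zygosity, best_m, seg)


@dataclass(frozen=True)
class GeneEvent:
    """A gene-level alteration used for biallelic-status logic."""

    kind: str  # mutation | homozygous_deletion | fusion
    origin: str = "somatic"  # germline | somatic
    is_lof: bool = True
    zygosity: Optional[str] = None

    def __post_init__(self):
        if self.kind not in {"mutation", "homozygous_deletion", "fusion"}:
            raise ValueError(f"unknown event kind {self.kind!r}")


def classify_biallelic_gene(events: Sequence[GeneEvent]) -> bool:
    """Gene-level biallelic inactivation.

    Biallelic when any LoF mutation shows loss of the wild-type allele, or a
    LoF mutation co-occurs with a homozygous deletion, a fusion, or a second
    somatic LoF mutation.
    """
    lof_muts = [e for e in events if e.kind == "mutation" and e.is_lof]
    if any(e.zygosity == "biallelic_loss_of_wt" for e in lof_muts):
        return True
    if not lof_muts:
        return False
    if any(e.kind in {"homozygous_deletion", "fusion"} for e in events):
        return True
    somatic_lof = [e for e in lof_muts if e.origin == "somatic"]
    return len(lof_muts) >= 2 and len(somatic_lof) >= 1
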