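"""Cis/trans phasing of a somatic candidate against a germline variant.

Two routes certify that a somatic lesion lies on the germline-mutant allele:

* read-pair counting — fragments whose two reads (or one read) span both
  sites; at least three fragments carrying both alternate alleles are
  required for a cis call;
* loss-of-heterozygosity inference — for somatic deletions that fully
  encompass the germline site no single fragment can report both alleles, so
  cis is inferred when the wild-type allele has been clonally lost (segment
  minor copy number zero with a germline VAF consistent with complete loss).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .copynumber import Segment, expected_vaf
from .genome import CdsChange

CIS_MIN_PAIRS = 3
LOH_VAF_TOLERANCE = 0.10

_GERM_ALLELES = {"ref", "alt", "deleted", "uncovered"}
_SOM_ALLELES = {"ref", "alt", "uncovered"}


@dataclass(frozen=True)
class ReadPairObservation:
    """Per-fragment allele calls at the germline and somatic sites.

    A germline site removed by the somatic deletion on the fragment is coded
    ``deleted``; such fragments support the somatic allele but are
    uninformative for read-based phasing.
    """

    fragment_id: str
    germline_site_allele: str
    somatic_site_allele: str

    def __post_init__(self):
        if self.germline_site_allele not in _GERM_ALLELES:
            raise ValueError(f"bad germline allele code {self.germline_site_allele!r}")
        if self.somatic_site_allele not in _SOM_ALLELES:
            raise ValueError(f"bad somatic allele code {self.somatic_site_allele!r}")
        if self.germline_site_allele == "uncovered" and self.somatic_site_allele == "uncovered":
            raise ValueError(f"fragment {self.fragment_id}: neither site covered")


@dataclass(frozen=True)
class PhasingResult:
    status: str  # cis | trans | ambiguous
    method: str  # read_pair | loh_inference
    n_cis_pairs: int = 0
    n_trans_pairs: int = 0

    def __post_init__(self):
        if self.status == "cis" and self.method == "read_pair" and self.n_cis_pairs < CIS_MIN_PAIRS:
            raise ValueError("cis by read pairs requires >= 3 supporting pairs")


def count_informative_pairs(pairs: Sequence[ReadPairObservation]) -> tuple[int, int]:
    """Count fragments supporting cis (alt/alt) and trans (alt at exactly one
    site, ref at the other). Uncovered or deleted sites make a fragment
    uninformative for this purpose."""
    n_cis = n_trans = 0
    for p in pairs:
        g, s = p.germline_site_allele, p.somatic_site_allele
        if g == "alt" and s == "alt":
            n_cis += 1
        elif (g == "alt" and s == "ref") or (g == "ref" and s == "alt"):
            n_trans += 1
    return n_cis, n_trans


def phase_by_reads(pairs: Sequence[ReadPairObservation]) -> PhasingResult:
    """Phase by spanning read pairs.

    cis requires at least three alt/alt fragments and a cis majority over
    conflicting trans fragments; trans (an extension beyond the cis
    certification the method was designed for) requires three trans fragments
    with zero cis support. Everything else is ambiguous.
    """
    n_cis, n_trans = count_informative_pairs(pairs)
    if n_cis >= CIS_MIN_PAIRS and n_trans < n_cis:
        status = "cis"
    elif n_trans >= CIS_MIN_PAIRS and n_cis == 0:
        status = "trans"
    else:
        status = "ambiguous"
    return PhasingResult(status, "read_pair", n_cis, n_trans)


def phase_by_loh(
    somatic: CdsChange,
    germline: CdsChange,
    segment: Segment,
    purity: float,
    germline_vaf: float,
    tolerance: float = LOH_VAF_TOLERANCE,
) -> PhasingResult:
    """Phase an encompassing somatic deletion by loss-of-wild-type logic.

    With the wild-type allele clonally lost, every retained copy carries the
    germline variant, so any somatic mutation of the locus must be in cis.
    Requires segment minor_cn == 0 and an observed germline VAF within
    ``tolerance`` of the value expected when all tumor copies are mutant.
    """
    if somatic.kind != "deletion":
        raise ValueError("LOH phasing applies to encompassing somatic deletions only")
    germ_end = max(germline.end, germline.cds_start)
    if not (somatic.cds_start <= germline.cds_start and germ_end <= somatic.end):
        raise ValueError(
            "somatic deletion does not encompass the germline site; use read-pair phasing"
        )
    if segment.minor_cn is None or segment.minor_cn != 0 or segment.total_cn == 0:
        return PhasingResult("ambiguous", "loh_inference")
    exp = expected_vaf(purity, segment.total_cn, segment.total_cn)
    if abs(germline_vaf - exp) <= tolerance:
        return PhasingResult("cis", "loh_inference")
    return PhasingResult("ambiguous", "loh_inference")
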