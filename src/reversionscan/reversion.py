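"""Reversion-mutation detection.

A reversion is a somatic change on the same allele as a pathogenic germline
truncating variant that restores the gene's open reading frame and hence
protein function. The search proceeds in three gates:

1. window — somatic indels whose first affected codon lies within 200 amino
   acids of the germline lesion (nonsense-reverting substitutions are also
   admitted when the germline variant is a nonsense codon);
2. phase — cis confirmation by spanning read pairs (>= 3 alt/alt fragments),
   or, for somatic deletions that fully encompass the germline site, by
   clonal loss-of-wild-type inference;
3. frame — the doubly mutated CDS must carry a combined net shift of 0 mod 3
   and translate through to the natural stop with no premature stop, i.e.
   yield a full-length open reading frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .copynumber import SegmentProfile
from .genome import (
    CdsChange,
    CodingTranscript,
    Variant,
    apply_changes,
    classify_consequence,
    project_to_cds,
    surviving_changes,
    translate,
)
from .phasing import PhasingResult, ReadPairObservation, phase_by_loh, phase_by_reads

WINDOW_AA = 200

MECH_COMPENSATING = "compensating_indel"
MECH_ENCOMPASSING = "encompassing_deletion"
MECH_DELINS = "delins"


@dataclass(frozen=True)
class ReversionCall:
    """A confirmed cis, ORF-restoring somatic event next to a germline lesion."""

    patient_id: str
    gene: str
    germline: CdsChange
    germline_notation: str
    somatic: tuple[CdsChange, ...]
    somatic_notation: str
    phasing: PhasingResult
    restored: bool
    mechanism: str
    distance_aa: int

    def __post_init__(self):
        if self.restored and self.phasing.status != "cis":
            raise ValueError("a restored call requires cis phasing")
        if self.distance_aa > WINDOW_AA:
            raise ValueError("somatic lesion outside the search window")
        if not self.somatic:
            raise ValueError("somatic change list must be non-empty")


def is_truncating(change: CdsChange, tx: CodingTranscript) -> bool:
    """True for frameshift or nonsense consequences."""
    return classify_consequence(tx, change).consequence in {"frameshift", "nonsense"}


def codon_distance(a: CdsChange, b: CdsChange) -> int:
    """Amino-acid distance between the first affected codons of two lesions."""
    return abs(a.first_codon - b.first_codon)


def find_candidates(
    germline: CdsChange,
    somatic_variants: Sequence[CdsChange],
    tx: Optional[CodingTranscript] = None,
    window_aa: int = WINDOW_AA,
) -> list[CdsChange]:
    """Somatic lesions within the +/- window around the germline lesion.

    Indels always qualify; substitutions qualify only when the germline
    variant is a nonsense codon (a reversion point mutation restoring a sense
    codon). The window is symmetric because documented reversions occur both
    up- and downstream of the germline lesion.
    """
    germline_is_nonsense = (
        tx is not None
        and classify_consequence(tx, germline).consequence == "nonsense"
    )
    out = []
    for som in somatic_variants:
        if codon_distance(germline, som) > window_aa:
            continue
        if som.kind == "substitution" and not germline_is_nonsense:
            continue
        out.append(som)
    return out


def check_orf_restoration(
    tx: CodingTranscript,
    germline: CdsChange,
    somatic: Sequence[CdsChange],
) -> tuple[bool, str, str]:
    """Does the germline + somatic combination restore a full-length ORF?

    Applies all lesions jointly (a somatic deletion fully encompassing the
    germline change annihilates it) and requires the mutated CDS to (i) keep
    a combined net shift of 0 mod 3, and (ii) translate from ATG to a stop at
    its natural end with no premature stop anywhere. Returns
    (restored, mechanism, restored protein summary).
    """
    all_changes = [germline, *somatic]
    mutated = apply_changes(tx.cds_sequence, all_changes)  # raises on partial overlap
    survivors = surviving_changes(all_changes)
    germline_absorbed = germline not in survivors

    if germline_absorbed:
        mechanism = MECH_ENCOMPASSING
    elif any(s.kind == "delins" for s in somatic) or (
        len(somatic) > 1
        and any(s.kind == "deletion" for s in somatic)
        and any(s.kind == "insertion" for s in somatic)
    ):
        mechanism = MECH_DELINS
    else:
        mechanism = MECH_COMPENSATING

    if len(mutated) % 3 != 0:
        return False, mechanism, ""
    if not mutated.startswith("ATG"):
        return False, mechanism, ""
    protein = translate(mutated, to_stop=False)
    if not protein or protein[-1] != "*" or "*" in protein[:-1]:
        return False, mechanism, ""
    return True, mechanism, protein[:-1]


@dataclass
class PatientBundle:
    """Everything the detector needs for one patient."""

    patient_id: str
    transcripts: Mapping[str, CodingTranscript]  # gene -> transcript
    germline_variants: Sequence[Variant]
    somatic_variants: Sequence[Variant]
    # (germline variant_id, somatic variant_id) -> spanning-fragment observations
    read_pairs: Mapping[tuple[str, str], Sequence[ReadPairObservation]] = field(
        default_factory=dict
    )
    profile: Optional[SegmentProfile] = None


def _encompasses_germline(som: CdsChange, germ: CdsChange) -> bool:
    germ_end = max(germ.end, germ.cds_start)
    return (
        som.kind == "deletion"
        and som.cds_start <= germ.cds_start
        and germ_end <= som.end
    )


def call_reversions(bundle: PatientBundle, window_aa: int = WINDOW_AA) -> list[ReversionCall]:
    """Scan one patient for reversion mutations.

    One call is emitted per somatic candidate that passes the window, a cis
    phasing gate (read pairs, or LOH inference for encompassing deletions)
    and the ORF-restoration test. Multiple independent calls per patient are
    allowed (polyclonal reversion).
    """
    calls: list[ReversionCall] = []
    for gv in bundle.germline_variants:
        tx = bundle.transcripts.get(_gene_of(gv, bundle.transcripts))
        if tx is None:
            continue
        germ = project_to_cds(gv, tx)
        if germ is None or not is_truncating(germ, tx):
            continue
        germ_notation = classify_consequence(tx, germ).protein_notation
        somatic_on_tx = [
            (sv, ch)
            for sv in bundle.somatic_variants
            if (ch := project_to_cds(sv, tx)) is not None
        ]
        candidates = find_candidates(germ, [ch for _, ch in somatic_on_tx], tx, window_aa)
        for sv, ch in somatic_on_tx:
            if ch not in candidates:
                continue
            phasing = _phase_candidate(bundle, gv, sv, germ, ch, tx)
            if phasing.status != "cis":
                continue
            try:
                restored, mechanism, _ = check_orf_restoration(tx, germ, [ch])
            except ValueError:  # incompatible (partially overlapping) haplotype
                continue
            if not restored:
                continue
            calls.append(
                ReversionCall(
                    patient_id=bundle.patient_id,
                    gene=tx.gene,
                    germline=germ,
                    germline_notation=germ_notation,
                    somatic=(ch,),
                    somatic_notation=classify_consequence(tx, ch).protein_notation
                    if not _encompasses_germline(ch, germ)
                    else f"del{ch.ref_len}nt",
                    phasing=phasing,
                    restored=True,
                    mechanism=mechanism,
                    distance_aa=codon_distance(germ, ch),
                )
            )
    return calls


def _gene_of(variant: Variant, transcripts: Mapping[str, CodingTranscript]) -> Optional[str]:
    for gene, tx in transcripts.items():
        if tx.contig == variant.contig:
            return gene
    return None


def _phase_candidate(
    bundle: PatientBundle,
    gv: Variant,
    sv: Variant,
    germ: CdsChange,
    som: CdsChange,
    tx: CodingTranscript,
) -> PhasingResult:
    pairs = bundle.read_pairs.get((gv.variant_id, sv.variant_id), ())
    if _encompasses_germline(som, germ):
        if bundle.profile is None or gv.vaf is None:
            return PhasingResult("ambiguous", "loh_inference")
        seg = bundle.profile.overlapping(gv.contig, gv.pos)
        if seg is None:
            return PhasingResult("ambiguous", "loh_inference")
        return phase_by_loh(som, germ, seg, bundle.profile.purity, gv.vaf)
    return phase_by_reads(pairs)
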