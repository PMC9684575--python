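"""Reference coding model and frame arithmetic.

A :class:`CodingTranscript` carries one canonical coding sequence per gene
together with its genomic exon layout, so that genomic variants can be
projected into CDS coordinates, applied to the sequence, and classified by
protein consequence (frameshift, nonsense, missense, in-frame indel, silent).
All coordinates are 1-based inclusive, matching HGVS ``c.`` usage; conversion
from VCF's anchored-base indel convention happens at the I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

START_CODON = "ATG"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate(cds: str, to_stop: bool = True) -> str:
    """Translate a DNA string codon by codon (standard nuclear code).

    With ``to_stop`` the protein ends before the first stop codon; otherwise
    stops are emitted as ``*``. A trailing partial codon is ignored.
    """
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = CODON_TO_AA[cds[i : i + 3].upper()]
        if aa == "*" and to_stop:
            return "".join(aas)
        aas.append(aa)
    return "".join(aas)


@dataclass(frozen=True)
class CodingTranscript:
    """One canonical coding transcript of a gene.

    ``exons`` are genomic 1-based inclusive intervals covering exactly the
    CDS, ordered 5'→3' in transcript orientation (descending genomic
    coordinates on the minus strand). ``cds_sequence`` is the coding-strand
    sequence, starting with ATG and ending with a stop codon.
    """

    transcript_id: str
    gene: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        cds = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", cds)
        object.__setattr__(self, "exons", tuple((int(a), int(b)) for a, b in self.exons))
        if len(cds) % 3 != 0:
            raise ValueError(f"{self.transcript_id}: CDS length {len(cds)} not a multiple of 3")
        if not cds.startswith(START_CODON):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")
        if CODON_TO_AA[cds[-3:]] != "*":
            raise ValueError(f"{self.transcript_id}: CDS does not end with a stop codon")
        if "*" in translate(cds[:-3], to_stop=False):
            raise ValueError(f"{self.transcript_id}: internal stop codon in CDS")
        for start, end in self.exons:
            if end < start:
                raise ValueError(f"{self.transcript_id}: malformed exon ({start},{end})")
        genomic_sorted = sorted(self.exons)
        for (a0, a1), (b0, b1) in zip(genomic_sorted, genomic_sorted[1:]):
            if b0 <= a1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")
        expected = self.exons if self.strand == "+" else tuple(sorted(self.exons, reverse=True))
        if self.exons != expected:
            raise ValueError(f"{self.transcript_id}: exons not ordered 5'→3' in transcript orientation")
        if sum(e - s + 1 for s, e in self.exons) != len(cds):
            raise ValueError(f"{self.transcript_id}: exon span does not match CDS length")

    @property
    def protein_sequence(self) -> str:
        return translate(self.cds_sequence)

    @property
    def n_codons(self) -> int:
        return len(self.cds_sequence) // 3

    def genomic_to_cds(self, gpos: int) -> Optional[int]:
        """Map a genomic position to a 1-based CDS coordinate, or None if non-coding."""
        offset = 0
        for start, end in self.exons:
            if start <= gpos <= end:
                if self.strand == "+":
                    return offset + (gpos - start) + 1
                return offset + (end - gpos) + 1
            offset += end - start + 1
        return None

    def cds_to_genomic(self, cpos: int) -> int:
        """Map a 1-based CDS coordinate to its genomic position."""
        if not 1 <= cpos <= len(self.cds_sequence):
            raise ValueError(f"CDS position {cpos} outside [1, {len(self.cds_sequence)}]")
        offset = 0
        for start, end in self.exons:
            length = end - start + 1
            if cpos <= offset + length:
                within = cpos - offset - 1
                return start + within if self.strand == "+" else end - within
            offset += length
        raise AssertionError("unreachable")

    def last_exon_cds_interval(self) -> tuple[int, int]:
        """CDS coordinate interval covered by the transcript's last exon."""
        s, e = self.exons[-1]
        length = e - s + 1
        return len(self.cds_sequence) - length + 1, len(self.cds_sequence)


@dataclass(frozen=True)
class Variant:
    """A genomic lesion in VCF-style representation (ref/alt non-empty,
    indels carry a shared anchor base)."""

    variant_id: str
    contig: str
    pos: int
    ref: str
    alt: str
    origin: str = "somatic"
    vaf: Optional[float] = None
    alt_reads: Optional[int] = None
    depth: Optional[int] = None

    def __post_init__(self):
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.ref == self.alt:
            raise ValueError(f"{self.variant_id}: ref equals alt")
        if self.origin not in {"germline", "somatic"}:
            raise ValueError(f"{self.variant_id}: origin must be germline or somatic")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"{self.variant_id}: VAF {self.vaf} outside [0,1]")
        if (
            self.alt_reads is not None
            and self.depth is not None
            and self.alt_reads > self.depth
        ):
            raise ValueError(f"{self.variant_id}: alt_reads > depth")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


@dataclass(frozen=True)
class CdsChange:
    """A lesion projected onto coding coordinates.

    Replaces ``ref`` (which occupies CDS positions ``cds_start ..
    cds_start+ref_len-1``) with ``alt``. A pure insertion (``ref == ""``)
    inserts ``alt`` immediately before ``cds_start``.
    """

    cds_start: int
    ref: str
    alt: str

    def __post_init__(self):
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if self.cds_start < 1:
            raise ValueError("cds_start must be >= 1")
        if self.ref == self.alt:
            raise ValueError("CdsChange ref equals alt")

    @property
    def ref_len(self) -> int:
        return len(self.ref)

    @property
    def alt_len(self) -> int:
        return len(self.alt)

    @property
    def net_shift(self) -> int:
        return self.alt_len - self.ref_len

    @property
    def end(self) -> int:
        """Last CDS position occupied by ref (cds_start - 1 for insertions)."""
        return self.cds_start + self.ref_len - 1

    @property
    def kind(self) -> str:
        if self.ref_len == 0:
            return "insertion"
        if self.alt_len == 0:
            return "deletion"
        if self.ref_len == self.alt_len == 1:
            return "substitution"
        if self.ref_len == self.alt_len:
            return "substitution" if self.ref_len == 1 else "delins"
        return "delins"

    @property
    def first_codon(self) -> int:
        """1-based index of the first codon touched by the change."""
        return math.ceil(self.cds_start / 3)


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Strip shared suffix then prefix from a ref/alt pair.

    Returns the 1-based position of the first remaining ref base (for pure
    insertions, the position before which the insertion goes).
    """
    ref, alt = ref.upper(), alt.upper()
    while ref and alt and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while ref and alt and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def project_to_cds(variant: Variant, tx: CodingTranscript) -> Optional[CdsChange]:
    """Project a genomic variant into CDS coordinates.

    Returns None for variants that do not touch the coding sequence.
    Deletions partially overlapping an exon are clipped to the coding
    interval. Alleles are reverse-complemented for minus-strand transcripts.
    Raises ValueError when the variant's ref disagrees with the transcript
    sequence (corrupt input).
    """
    if variant.contig != tx.contig:
        return None
    pos, ref, alt = trim_alleles(variant.pos, variant.ref, variant.alt)

    if not ref and alt:  # pure insertion between pos-1 and pos
        left = tx.genomic_to_cds(pos - 1)
        right = tx.genomic_to_cds(pos)
        if left is None or right is None:
            return None
        if tx.strand == "+":
            if right != left + 1:
                return None
            return CdsChange(cds_start=right, ref="", alt=alt)
        if left != right + 1:
            return None
        return CdsChange(cds_start=left, ref="", alt=revcomp(alt))

    coding = [
        (g, c)
        for g in range(pos, pos + len(ref))
        if (c := tx.genomic_to_cds(g)) is not None
    ]
    if not coding:
        return None
    cds_positions = sorted(c for _, c in coding)
    if cds_positions != list(range(cds_positions[0], cds_positions[0] + len(cds_positions))):
        raise ValueError(f"{variant.variant_id}: ref span maps to non-contiguous CDS positions")

    if alt and len(coding) != len(ref):
        # substitutions/delins must lie fully in the CDS; only deletions clip
        if len(alt) != len(ref):
            return None
        coding_sub = coding

    cds_start = cds_positions[0]
    expected_ref = tx.cds_sequence[cds_start - 1 : cds_start - 1 + len(cds_positions)]
    # ref bases on the coding strand
    genomic_ref = {g: b for g, b in zip(range(pos, pos + len(ref)), ref)}
    if tx.strand == "+":
        observed = "".join(genomic_ref[g] for g, _ in sorted(coding))
    else:
        observed = revcomp("".join(genomic_ref[g] for g, _ in sorted(coding)))
    if observed != expected_ref:
        raise ValueError(
            f"{variant.variant_id}: ref allele {observed!r} does not match "
            f"transcript sequence {expected_ref!r} at c.{cds_start}"
        )

    if not alt:  # deletion, clipped to coding part
        return CdsChange(cds_start=cds_start, ref=expected_ref, alt="")
    coding_alt = alt if tx.strand == "+" else revcomp(alt)
    return CdsChange(cds_start=cds_start, ref=expected_ref, alt=coding_alt)


def _encompasses(outer: CdsChange, inner: CdsChange) -> bool:
    """True when ``outer`` is a deletion whose ref span fully contains ``inner``."""
    if outer.kind != "deletion":
        return False
    if inner.ref_len == 0:  # insertion point strictly inside the deleted run
        return outer.cds_start + 1 <= inner.cds_start <= outer.end
    return outer.cds_start <= inner.cds_start and inner.end <= outer.end


def _overlaps(a: CdsChange, b: CdsChange) -> bool:
    if a.ref_len == 0 or b.ref_len == 0:
        return False
    return a.cds_start <= b.end and b.cds_start <= a.end


def apply_changes(cds: str, changes: Sequence[CdsChange]) -> str:
    """Apply a set of CDS changes, returning the mutated sequence.

    Changes may overlap only when a deletion fully encompasses another change,
    in which case the inner change is annihilated (models a large somatic
    deletion removing the germline lesion). Any partial overlap raises, since
    the joint haplotype would be ambiguous.
    """
    ordered = sorted(changes, key=lambda c: (c.cds_start, -c.ref_len))
    survivors: list[CdsChange] = []
    for ch in ordered:
        if ch.end > len(cds):
            raise ValueError(f"change at c.{ch.cds_start} extends past CDS end")
        if ch.ref and cds[ch.cds_start - 1 : ch.end] != ch.ref:
            raise ValueError(
                f"change ref {ch.ref!r} does not match CDS at c.{ch.cds_start}"
            )
        absorbed = False
        for prev in survivors:
            if _encompasses(prev, ch):
                absorbed = True
                break
            if _encompasses(ch, prev):
                raise ValueError(
                    "encompassing deletion must be applied in coordinate order"
                )
            if _overlaps(prev, ch):
                raise ValueError(
                    f"partially overlapping changes at c.{prev.cds_start} and c.{ch.cds_start}"
                )
        if not absorbed:
            survivors.append(ch)
    out = cds
    for ch in sorted(survivors, key=lambda c: c.cds_start, reverse=True):
        out = out[: ch.cds_start - 1] + ch.alt + out[ch.cds_start - 1 + ch.ref_len :]
    return out


def surviving_changes(changes: Sequence[CdsChange]) -> list[CdsChange]:
    """The subset of changes left after encompassing-deletion absorption."""
    ordered = sorted(changes, key=lambda c: (c.cds_start, -c.ref_len))
    survivors: list[CdsChange] = []
    for ch in ordered:
        if any(_encompasses(prev, ch) for prev in survivors):
            continue
        survivors.append(ch)
    return survivors


@dataclass(frozen=True)
class Consequence:
    consequence: str  # frameshift | nonsense | inframe_indel | missense | silent
    protein_notation: str
    codon: int


def classify_consequence(tx: CodingTranscript, change: CdsChange) -> Consequence:
    """Protein-level consequence of a single CDS change.

    Frameshift iff the net length shift is not a multiple of 3; frameshift
    notation follows the X{codon}Yfs*N pattern where codon is the first
    altered codon (ceil(cds_start/3)), Y the first novel residue and N the
    1-based offset of the new stop in the shifted frame.
    """
    codon = change.first_codon
    protein = tx.protein_sequence
    ref_aa = protein[codon - 1] if codon <= len(protein) else "*"
    mutated = apply_changes(tx.cds_sequence, [change])
    mutated_tail = translate(mutated[(codon - 1) * 3 :], to_stop=False)
    new_aa = mutated_tail[0] if mutated_tail else "*"

    if change.net_shift % 3 != 0:
        stop_offset = mutated_tail.find("*") + 1  # 0 -> not found
        if stop_offset > 0:
            notation = f"{ref_aa}{codon}{new_aa}fs*{stop_offset}"
        else:
            notation = f"{ref_aa}{codon}{new_aa}fs"
        return Consequence("frameshift", notation, codon)

    full = translate(mutated, to_stop=False)
    premature_stop = "*" in full[:-1]

    if change.ref_len == change.alt_len:  # substitution (SNV or MNV)
        if premature_stop:
            return Consequence("nonsense", f"{ref_aa}{codon}*", codon)
        if full == translate(tx.cds_sequence, to_stop=False):
            return Consequence("silent", f"{ref_aa}{codon}=", codon)
        return Consequence("missense", f"{ref_aa}{codon}{new_aa}", codon)

    # in-frame indel; a junction codon can still create a premature stop
    label = {"deletion": "del", "insertion": "ins", "delins": "delins"}.get(change.kind, "delins")
    if premature_stop:
        return Consequence("nonsense", f"{ref_aa}{codon}{label}*", codon)
    return Consequence("inframe_indel", f"{ref_aa}{codon}{label}", codon)
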