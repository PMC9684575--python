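"""Synthetic cohorts with planted ground truth.

The generator emulates the study conditions end to end: a lineage-stratified
cohort with canonical BRCA-associated tumors carrying germline BRCA1/2
truncating variants at elevated rates, tumors with clonal loss of the
wild-type allele, planted frame-restoring somatic lesions with configurable
spanning-read-pair support, allele-specific copy-number profiles with known
scar counts whose detectability attenuates with tumor purity, and 96-channel
mutation catalogs drawn from known signature mixtures. Every emitted record
is reproducible from a single seed, and the ground truth is rich enough that
noise-free simulations must be recovered exactly by the analysis stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort import BRCA_ASSOCIATED_LINEAGES, CohortRecord
from .copynumber import Segment, SegmentProfile, expected_vaf
from .genome import CODON_TO_AA, CdsChange, CodingTranscript, Variant, revcomp, translate
from .hrd import ContigInfo, GenomeBuildInfo, HrdScores
from .phasing import ReadPairObservation
from .reversion import PatientBundle
from .signatures import CHANNELS, MutationCatalog96, SignatureMatrix

_SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_STOP_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa == "*")
MB = 1_000_000


# ---------------------------------------------------------------------------
# reference model
# ---------------------------------------------------------------------------

@dataclass
class ReferenceBundle:
    contigs: dict[str, str]
    transcripts: dict[str, CodingTranscript]  # keyed by gene


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(_STOP_CODONS)
    return "ATG" + "".join(body) + str(stop)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_reference(
    seed: int,
    genes: Mapping[str, tuple[int, str]] | None = None,
    n_exons: int = 3,
    intron_len: int = 80,
    flank: int = 50,
) -> ReferenceBundle:
    """Random coding transcripts, one contig per gene.

    ``genes`` maps gene name to (codon count, strand). Defaults model BRCA1
    (minus strand) and BRCA2 (plus strand) at reduced lengths that keep the
    200-codon reversion window meaningful. Deterministic per seed.
    """
    genes = genes or {"BRCA1": (600, "-"), "BRCA2": (800, "+")}
    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    transcripts: dict[str, CodingTranscript] = {}
    for gene, (n_codons, strand) in genes.items():
        if n_codons < 20:
            raise ValueError("transcripts need at least 20 codons")
        cds = _random_cds(rng, n_codons)
        cut_space = np.arange(9, len(cds) - 9)
        k_cuts = min(n_exons - 1, max(len(cut_space) // 10, 0))
        cuts = sorted(rng.choice(cut_space, size=k_cuts, replace=False)) if k_cuts else []
        chunks = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
        introns = [_random_seq(rng, intron_len) for _ in range(n_exons - 1)]
        contig_name = f"chr_{gene}"

        if strand == "+":
            genomic_chunks = chunks
        else:
            genomic_chunks = [revcomp(c) for c in reversed(chunks)]
        seq_parts = [_random_seq(rng, flank)]
        exon_genomic: list[tuple[int, int]] = []
        pos = flank
        for i, chunk in enumerate(genomic_chunks):
            exon_genomic.append((pos + 1, pos + len(chunk)))
            seq_parts.append(chunk)
            pos += len(chunk)
            if i < len(genomic_chunks) - 1:
                seq_parts.append(introns[i])
                pos += intron_len
        seq_parts.append(_random_seq(rng, flank))
        contig_seq = "".join(seq_parts)

        if strand == "+":
            exons = tuple(exon_genomic)
        else:
            exons = tuple(reversed(exon_genomic))
        contigs[contig_name] = contig_seq
        transcripts[gene] = CodingTranscript(
            transcript_id=f"{gene}_tx1",
            gene=gene,
            contig=contig_name,
            strand=strand,
            exons=exons,
            cds_sequence=cds,
        )
    return ReferenceBundle(contigs=contigs, transcripts=transcripts)


def extract_cds(contig_seq: str, exons: Sequence[tuple[int, int]], strand: str) -> str:
    """Independent CDS extraction from a contig (used in round-trip checks)."""
    if strand == "+":
        return "".join(contig_seq[s - 1 : e] for s, e in exons)
    return "".join(revcomp(contig_seq[s - 1 : e]) for s, e in exons)


# ---------------------------------------------------------------------------
# variant construction helpers
# ---------------------------------------------------------------------------

def _cds_span_single_exon(tx: CodingTranscript, cds_start: int, length: int) -> bool:
    """True when CDS positions [cds_start, cds_start+length-1] map to a
    contiguous genomic run (i.e. lie within one exon)."""
    g = [tx.cds_to_genomic(c) for c in range(cds_start, cds_start + length)]
    return all(abs(b - a) == 1 for a, b in zip(g, g[1:])) if len(g) > 1 else True


def cds_change_to_variant(
    tx: CodingTranscript,
    contigs: Mapping[str, str],
    change: CdsChange,
    variant_id: str,
    origin: str,
    vaf: Optional[float] = None,
    alt_reads: Optional[int] = None,
    depth: Optional[int] = None,
) -> Variant:
    """Render a CDS change as a VCF-style genomic variant (anchored indels)."""
    seq = contigs[tx.contig]
    if change.ref_len and not _cds_span_single_exon(tx, change.cds_start, change.ref_len):
        raise ValueError("change spans an exon boundary; not representable as one record")

    if change.kind == "substitution" or (change.ref_len == change.alt_len and change.ref_len > 0):
        gpos = [tx.cds_to_genomic(c) for c in range(change.cds_start, change.end + 1)]
        start = min(gpos)
        ref = seq[start - 1 : start - 1 + change.ref_len]
        alt = change.alt if tx.strand == "+" else revcomp(change.alt)
        return Variant(variant_id, tx.contig, start, ref, alt, origin, vaf, alt_reads, depth)

    if change.kind == "deletion":
        gpos = [tx.cds_to_genomic(c) for c in range(change.cds_start, change.end + 1)]
        start, end = min(gpos), max(gpos)
        anchor = seq[start - 2]
        return Variant(
            variant_id, tx.contig, start - 1,
            anchor + seq[start - 1 : end], anchor, origin, vaf, alt_reads, depth,
        )

    if change.kind == "insertion":
        ins = change.alt if tx.strand == "+" else revcomp(change.alt)
        if tx.strand == "+":
            gpos = tx.cds_to_genomic(change.cds_start - 1)
        else:
            gpos = tx.cds_to_genomic(change.cds_start)
        anchor = seq[gpos - 1]
        return Variant(variant_id, tx.contig, gpos, anchor, anchor + ins, origin,
                       vaf, alt_reads, depth)

    # delins: anchored like a deletion with inserted sequence appended
    gpos = [tx.cds_to_genomic(c) for c in range(change.cds_start, change.end + 1)]
    start, end = min(gpos), max(gpos)
    anchor = seq[start - 2]
    ins = change.alt if tx.strand == "+" else revcomp(change.alt)
    return Variant(
        variant_id, tx.contig, start - 1,
        anchor + seq[start - 1 : end], anchor + ins, origin, vaf, alt_reads, depth,
    )


def _restores_orf(cds: str, germ: CdsChange, som: CdsChange) -> bool:
    """Generator-local restoration check by direct string splicing (kept
    independent of the detector's apply/translate pathway)."""
    changes = sorted([germ, som], key=lambda c: c.cds_start)
    a, b = changes
    a_end = a.cds_start + a.ref_len - 1
    b_end = b.cds_start + b.ref_len - 1
    if a.kind == "deletion" and b.cds_start >= a.cds_start and b_end <= a_end:
        mutated = cds[: a.cds_start - 1] + cds[a_end:]
    else:
        if b.cds_start <= a_end:  # overlap: not constructible
            return False
        mutated = (
            cds[: a.cds_start - 1] + a.alt + cds[a_end : b.cds_start - 1]
            + b.alt + cds[b_end:]
        )
    if len(mutated) % 3 != 0 or not mutated.startswith("ATG"):
        return False
    prot = translate(mutated, to_stop=False)
    return bool(prot) and prot[-1] == "*" and "*" not in prot[:-1]


# ---------------------------------------------------------------------------
# simulation configuration
# ---------------------------------------------------------------------------

def logistic_sensitivity(purity: float, midpoint: float, slope: float) -> float:
    """Probability that a planted copy-number event is detected at a given
    tumor purity (logistic in purity)."""
    return 1.0 / (1.0 + math.exp(-slope * (purity - midpoint)))


@dataclass
class SimulationConfig:
    """Study conditions for the cohort simulator.

    Defaults mirror the modelled study: ~30% canonical BRCA-associated
    lineages, germline carrier rates of 5.5% (BRCA-associated) and 1.4%
    (other), a BRCA1:BRCA2 carrier split of 0.4:0.6, and a reversion rate
    among platinum-exposed carriers on the order of 11/846. Signature
    mixtures default to the reported scale of the HRD signature fraction
    (0.44).
    """

    seed: int = 0
    n_patients: int = 2000
    lineage_mix: Mapping[str, float] = field(default_factory=lambda: {
        "breast": 0.12, "ovarian": 0.05, "prostate": 0.07, "pancreas": 0.06,
        "lung": 0.14, "colorectal": 0.09, "other": 0.47,
    })
    carrier_rate_by_group: Mapping[str, float] = field(default_factory=lambda: {
        "brca_associated": 0.055, "other": 0.014,
    })
    gene_mix: Mapping[str, float] = field(default_factory=lambda: {
        "BRCA1": 0.4, "BRCA2": 0.6,
    })
    platinum_rate: float = 0.5
    reversion_rate_post_platinum: float = 0.013
    polyclonal_fraction: float = 0.18
    mechanism_mix: Mapping[str, float] = field(default_factory=lambda: {
        "compensating_indel": 0.77, "encompassing_deletion": 0.15, "delins": 0.08,
    })
    biallelic_rate: float = 0.6
    read_pairs_cis: tuple[int, int] = (4, 12)
    pair_miscall_rate: float = 0.0
    background_somatic_mean: float = 3.0
    purity_range: tuple[float, float] = (0.2, 0.9)
    scar_targets: tuple[int, int, int] = (5, 3, 4)
    sensitivity_midpoint: Optional[float] = None  # None -> full sensitivity
    sensitivity_slope: float = 10.0
    signature_mixture: Mapping[str, float] = field(default_factory=lambda: {
        "SigHRD": 0.44, "SigFlat": 0.56,
    })
    n_snvs: int = 10_000

    def __post_init__(self):
        for name, mix in (("lineage_mix", self.lineage_mix),
                          ("gene_mix", self.gene_mix),
                          ("mechanism_mix", self.mechanism_mix),
                          ("signature_mixture", self.signature_mixture)):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for name in ("platinum_rate", "reversion_rate_post_platinum",
                     "polyclonal_fraction", "biallelic_rate", "pair_miscall_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for rate in self.carrier_rate_by_group.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("carrier rates must be in [0, 1]")


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedPatient:
    patient_id: str
    record: CohortRecord
    germline_variants: list[Variant]
    somatic_variants: list[Variant]
    read_pairs: dict[tuple[str, str], list[ReadPairObservation]]
    profile: Optional[SegmentProfile]
    truth: dict

    def bundle(self, transcripts: Mapping[str, CodingTranscript]) -> PatientBundle:
        return PatientBundle(
            patient_id=self.patient_id,
            transcripts=transcripts,
            germline_variants=self.germline_variants,
            somatic_variants=self.somatic_variants,
            read_pairs=self.read_pairs,
            profile=self.profile,
        )


@dataclass
class CohortSimulation:
    cfg: SimulationConfig
    reference: ReferenceBundle
    patients: list[SimulatedPatient]

    @property
    def ground_truth(self) -> dict[str, dict]:
        return {p.patient_id: p.truth for p in self.patients}

    @property
    def records(self) -> list[CohortRecord]:
        return [p.record for p in self.patients]


def _choice(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix)
    return keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]


def _plant_germline(rng: np.random.Generator, tx: CodingTranscript) -> CdsChange:
    """A truncating germline lesion at a codon with >=210 codons of CDS on
    both sides (keeps the full ±200-codon search window on the transcript)."""
    n = tx.n_codons
    cds = tx.cds_sequence
    for _ in range(500):
        codon = int(rng.integers(211, n - 211))
        kind = _choice(rng, {"del1": 0.45, "del2": 0.20, "ins1": 0.15, "nonsense": 0.20})
        start = (codon - 1) * 3 + 1 + int(rng.integers(0, 3))
        if kind == "del1":
            if not _cds_span_single_exon(tx, start, 1):
                continue
            return CdsChange(start, cds[start - 1], "")
        if kind == "del2":
            if start + 1 > len(cds) - 3 or not _cds_span_single_exon(tx, start, 2):
                continue
            return CdsChange(start, cds[start - 1 : start + 1], "")
        if kind == "ins1":
            base = str(rng.choice(list("ACGT")))
            if base == cds[start - 2]:  # anchored VCF form would re-align
                continue
            return CdsChange(start, "", base)
        # nonsense: single-base substitution creating a stop codon
        c0 = (codon - 1) * 3
        ref_codon = cds[c0 : c0 + 3]
        options = []
        for off in range(3):
            for b in "ACGT":
                if b == ref_codon[off]:
                    continue
                new = ref_codon[:off] + b + ref_codon[off + 1 :]
                if CODON_TO_AA[new] == "*":
                    options.append((off, b))
        if options:
            off, b = options[int(rng.integers(0, len(options)))]
            pos = c0 + off + 1
            if _cds_span_single_exon(tx, pos, 1):
                return CdsChange(pos, cds[pos - 1], b)
    raise RuntimeError("could not plant a germline truncating lesion")


def _plant_reversion(
    rng: np.random.Generator,
    tx: CodingTranscript,
    germ: CdsChange,
    mechanism: str,
    taken: list[tuple[int, int]],
) -> Optional[CdsChange]:
    """A somatic lesion restoring the frame under the given mechanism, placed
    in the ±200-codon window, within one exon, and disjoint from intervals in
    ``taken``. Returns None if no placement is found."""
    cds = tx.cds_sequence
    germ_is_sub = germ.kind == "substitution"

    def free(start: int, length: int, margin: int = 6) -> bool:
        # margin absorbs indel re-alignment in repeats so that planted
        # lesions can never drift into partial overlap
        end = start + max(length, 1) - 1
        for s, e in taken:
            if start - margin <= e and s <= end + margin:
                return False
        return True

    for _ in range(400):
        if mechanism == "encompassing_deletion":
            lead = int(rng.integers(2, 40))
            start = germ.cds_start - lead
            length = 3 * int(rng.integers(4, 24))
            end = start + length - 1
            if start < 4 or end > len(cds) - 3:
                continue
            if end < max(germ.end, germ.cds_start):
                continue
            if not _cds_span_single_exon(tx, start, length):
                continue
            som = CdsChange(start, cds[start - 1 : end], "")
            if _restores_orf(cds, germ, som):
                return som
            continue

        if germ_is_sub:  # nonsense germline: reverting substitution
            codon0 = (germ.first_codon - 1) * 3
            germ_off = germ.cds_start - codon0 - 1
            ref_codon = cds[codon0 : codon0 + 3]
            mut_codon = list(ref_codon)
            mut_codon[germ_off] = germ.alt
            options = []
            for off in range(3):
                if off == germ_off:
                    continue
                for b in "ACGT":
                    if b == ref_codon[off]:
                        continue
                    trial = list(mut_codon)
                    trial[off] = b
                    if CODON_TO_AA["".join(trial)] != "*":
                        options.append((off, b))
            if not options:
                return None
            off, b = options[int(rng.integers(0, len(options)))]
            pos = codon0 + off + 1
            if not free(pos, 1) or not _cds_span_single_exon(tx, pos, 1):
                continue
            som = CdsChange(pos, cds[pos - 1], b)
            if _restores_orf(cds, germ, som):
                return som
            continue

        # compensating indel or delins near a frameshift germline lesion
        offset = int(rng.integers(2, 150)) * (1 if rng.random() < 0.5 else -1)
        codon = germ.first_codon + offset
        if not 3 <= codon <= tx.n_codons - 3:
            continue
        start = (codon - 1) * 3 + 1 + int(rng.integers(0, 3))
        if mechanism == "delins":
            ref_len = int(rng.integers(1, 7))
            alt_len_choices = [
                l for l in range(1, 7)
                if (germ.net_shift + l - ref_len) % 3 == 0 and l != ref_len
            ]
            if not alt_len_choices:
                continue
            alt_len = alt_len_choices[int(rng.integers(0, len(alt_len_choices)))]
            end = start + ref_len - 1
            if end > len(cds) - 3 or not free(start, ref_len):
                continue
            if not _cds_span_single_exon(tx, start, ref_len):
                continue
            alt = "".join(rng.choice(list("ACGT"), size=alt_len))
            ref = cds[start - 1 : end]
            if alt == ref or alt[0] == ref[0] or alt[-1] == ref[-1]:
                continue  # avoid alleles that trim down to a different event
            som = CdsChange(start, ref, alt)
        else:  # compensating_indel
            shifts = [s for s in (-4, -2, -1, 1, 2, 4) if (germ.net_shift + s) % 3 == 0]
            shift = shifts[int(rng.integers(0, len(shifts)))]
            if shift < 0:
                length = -shift
                end = start + length - 1
                if end > len(cds) - 3 or not free(start, length):
                    continue
                if not _cds_span_single_exon(tx, start, length):
                    continue
                som = CdsChange(start, cds[start - 1 : end], "")
            else:
                if not free(start, 1):
                    continue
                alt = "".join(rng.choice(list("ACGT"), size=shift))
                if alt[-1] == cds[start - 2]:
                    continue  # avoid ambiguity with left-aligned duplication
                som = CdsChange(start, "", alt)
        if _restores_orf(cds, germ, som):
            return som
    return None


def _miscall(rng: np.random.Generator, allele: str, rate: float) -> str:
    if rate > 0 and allele in {"ref", "alt"} and rng.random() < rate:
        return "alt" if allele == "ref" else "ref"
    return allele


def simulate_cohort(cfg: SimulationConfig, reference: Optional[ReferenceBundle] = None) -> CohortSimulation:
    """Simulate a full cohort with planted reversions and ground truth."""
    rng = np.random.default_rng(cfg.seed)
    reference = reference or make_reference(cfg.seed)
    patients: list[SimulatedPatient] = []

    for i in range(cfg.n_patients):
        pid = f"P{i:05d}"
        lineage = _choice(rng, cfg.lineage_mix)
        brca_assoc = lineage in BRCA_ASSOCIATED_LINEAGES
        group = "brca_associated" if brca_assoc else "other"
        purity = float(rng.uniform(*cfg.purity_range))
        platinum = rng.random() < cfg.platinum_rate
        platinum_months = float(np.round(rng.lognormal(math.log(4.8), 0.45), 1)) if platinum else None
        carrier = rng.random() < cfg.carrier_rate_by_group[group]

        germline_variants: list[Variant] = []
        somatic_variants: list[Variant] = []
        read_pairs: dict[tuple[str, str], list[ReadPairObservation]] = {}
        profile: Optional[SegmentProfile] = None
        truth: dict = {
            "lineage": lineage, "carrier_gene": None, "germline": None,
            "reversions": [], "biallelic": False, "purity": purity,
            "platinum_months": platinum_months,
        }
        gene = "none"

        if carrier:
            gene = _choice(rng, cfg.gene_mix)
            tx = reference.transcripts[gene]
            germ = _plant_germline(rng, tx)
            has_reversion = (
                platinum and rng.random() < cfg.reversion_rate_post_platinum
            )
            biallelic = has_reversion or rng.random() < cfg.biallelic_rate
            m = 2 if biallelic else 1
            germ_vaf = round(expected_vaf(purity, 2, m), 6)
            depth = int(rng.integers(120, 260))
            gv = cds_change_to_variant(
                tx, reference.contigs, germ, f"{pid}_g0", "germline",
                vaf=germ_vaf, alt_reads=int(round(germ_vaf * depth)), depth=depth,
            )
            germline_variants.append(gv)
            contig_len = len(reference.contigs[tx.contig])
            profile = SegmentProfile(
                [Segment(tx.contig, 1, contig_len, 2, 0 if biallelic else 1)],
                purity=purity,
            )
            truth.update(
                carrier_gene=gene, biallelic=biallelic,
                germline={"cds_start": germ.cds_start, "ref": germ.ref, "alt": germ.alt},
            )

            taken = [(germ.cds_start, max(germ.end, germ.cds_start))]
            if has_reversion:
                n_events = 2 if rng.random() < cfg.polyclonal_fraction else 1
                for j in range(n_events):
                    mechanism = _choice(rng, cfg.mechanism_mix)
                    if germ.kind == "substitution" and mechanism == "delins":
                        mechanism = "compensating_indel"
                    som = _plant_reversion(rng, tx, germ, mechanism, taken)
                    if som is None:
                        som = _plant_reversion(rng, tx, germ, "encompassing_deletion", taken)
                        mechanism = "encompassing_deletion"
                    if som is None:
                        continue
                    encompassing = (
                        som.kind == "deletion"
                        and som.cds_start <= germ.cds_start
                        and max(germ.end, germ.cds_start) <= som.end
                    )
                    if not encompassing:
                        taken.append((som.cds_start, max(som.end, som.cds_start)))
                    som_vaf = round(expected_vaf(purity, 2, 1), 6)
                    sdepth = int(rng.integers(120, 260))
                    sv = cds_change_to_variant(
                        tx, reference.contigs, som, f"{pid}_s{len(somatic_variants)}",
                        "somatic", vaf=som_vaf,
                        alt_reads=int(round(som_vaf * sdepth)), depth=sdepth,
                    )
                    somatic_variants.append(sv)
                    pairs: list[ReadPairObservation] = []
                    if encompassing:
                        for f in range(int(rng.integers(2, 6))):
                            pairs.append(ReadPairObservation(f"{sv.variant_id}_f{f}", "deleted", "alt"))
                    else:
                        n_cis = int(rng.integers(cfg.read_pairs_cis[0], cfg.read_pairs_cis[1] + 1))
                        for f in range(n_cis):
                            pairs.append(ReadPairObservation(
                                f"{sv.variant_id}_f{f}",
                                _miscall(rng, "alt", cfg.pair_miscall_rate),
                                _miscall(rng, "alt", cfg.pair_miscall_rate),
                            ))
                        for f in range(int(rng.integers(0, 4))):
                            pairs.append(ReadPairObservation(
                                f"{sv.variant_id}_r{f}",
                                _miscall(rng, "ref", cfg.pair_miscall_rate),
                                _miscall(rng, "ref", cfg.pair_miscall_rate),
                            ))
                    read_pairs[(gv.variant_id, sv.variant_id)] = pairs
                    truth["reversions"].append({
                        "variant_id": sv.variant_id,
                        "cds_start": som.cds_start, "ref": som.ref, "alt": som.alt,
                        "mechanism": mechanism,
                        "phasing_method": "loh_inference" if encompassing else "read_pair",
                    })

            # background somatic noise on the carrier gene
            n_bg = int(rng.poisson(cfg.background_somatic_mean))
            for _ in range(n_bg):
                bg = _plant_background(rng, tx, taken)
                if bg is None:
                    continue
                bg_vaf = float(np.round(rng.uniform(0.1, 0.6), 4))
                bdepth = int(rng.integers(60, 200))
                bv = cds_change_to_variant(
                    tx, reference.contigs, bg, f"{pid}_s{len(somatic_variants)}",
                    "somatic", vaf=bg_vaf,
                    alt_reads=int(round(bg_vaf * bdepth)), depth=bdepth,
                )
                somatic_variants.append(bv)
                if bg.kind != "substitution":
                    taken.append((bg.cds_start, max(bg.end, bg.cds_start)))
                    # frameshift noise: give trans or no pair support so the
                    # phasing gate must reject it
                    if rng.random() < 0.5:
                        read_pairs[(gv.variant_id, bv.variant_id)] = [
                            ReadPairObservation(f"{bv.variant_id}_t{f}", "alt", "ref")
                            for f in range(2)
                        ] + [
                            ReadPairObservation(f"{bv.variant_id}_u{f}", "ref", "alt")
                            for f in range(2)
                        ]

        record = CohortRecord(
            patient_id=pid, lineage=lineage, brca_associated=brca_assoc,
            germline_status=gene if carrier else "none",
            somatic_lof="none", purity=purity, platinum_months=platinum_months,
        )
        patients.append(SimulatedPatient(
            patient_id=pid, record=record,
            germline_variants=germline_variants, somatic_variants=somatic_variants,
            read_pairs=read_pairs, profile=profile, truth=truth,
        ))
    return CohortSimulation(cfg=cfg, reference=reference, patients=patients)


def _plant_background(
    rng: np.random.Generator, tx: CodingTranscript, taken: list[tuple[int, int]]
) -> Optional[CdsChange]:
    """A non-reversion somatic lesion: mostly missense substitutions, with
    occasional frameshift indels that must be rejected by the phasing gate."""
    cds = tx.cds_sequence
    for _ in range(50):
        pos = int(rng.integers(4, len(cds) - 3))
        if any(s <= pos <= e for s, e in taken):
            continue
        if rng.random() < 0.7:
            ref = cds[pos - 1]
            codon0 = (pos - 1) // 3 * 3
            off = pos - codon0 - 1
            ref_codon = cds[codon0 : codon0 + 3]
            alts = [
                b for b in "ACGT"
                if b != ref
                and CODON_TO_AA[ref_codon[:off] + b + ref_codon[off + 1 :]] != "*"
            ]
            if not alts:
                continue
            return CdsChange(pos, ref, str(rng.choice(alts)))
        length = int(rng.integers(1, 3))
        if pos + length - 1 > len(cds) - 3 or not _cds_span_single_exon(tx, pos, length):
            continue
        if any(s - 6 <= pos + length - 1 and pos <= e + 6 for s, e in taken):
            continue
        return CdsChange(pos, cds[pos - 1 : pos - 1 + length], "")
    return None


# ---------------------------------------------------------------------------
# segment-profile simulation with planted scars
# ---------------------------------------------------------------------------

def make_build(n_contigs: int = 12, contig_length: int = 200 * MB,
               cen: tuple[int, int] = (95 * MB, 105 * MB)) -> GenomeBuildInfo:
    """A uniform synthetic genome build for scar-score simulations."""
    return GenomeBuildInfo({
        f"chr{i + 1}": ContigInfo(contig_length, cen[0], cen[1])
        for i in range(n_contigs)
    })


def simulate_segment_profile(
    scar_targets: tuple[int, int, int],
    purity: float,
    build: GenomeBuildInfo,
    rng: Optional[np.random.Generator] = None,
    sensitivity: Optional[tuple[float, float]] = None,
) -> tuple[SegmentProfile, HrdScores, HrdScores]:
    """Plant exactly (LST, HRD-LOH, NtAI) scar events, one per chromosome arm.

    Each event is then dropped independently with probability 1 - s(purity),
    where s is the logistic detection sensitivity (``sensitivity`` is a
    (midpoint, slope) pair; None means s = 1, i.e. every planted event is
    scored). Returns (profile, planted counts, retained counts).
    """
    lst_n, loh_n, ntai_n = scar_targets
    if min(scar_targets) < 0:
        raise ValueError("scar targets must be non-negative")
    rng = rng or np.random.default_rng(0)
    arms = [(c, a) for c in build.contigs for a in ("p", "q")]
    if lst_n + loh_n + ntai_n > len(arms):
        raise ValueError(
            f"cannot plant {lst_n + loh_n + ntai_n} events on {len(arms)} arms"
        )
    s = 1.0 if sensitivity is None else logistic_sensitivity(purity, *sensitivity)

    segments: list[Segment] = []
    kept = [0, 0, 0]
    arm_iter = iter(arms)

    def arm_bounds(contig: str, arm: str) -> tuple[int, int]:
        info = build.contigs[contig]
        return (1, info.cen_start - 1) if arm == "p" else (info.cen_end + 1, info.length)

    for _ in range(lst_n):
        contig, arm = next(arm_iter)
        lo, hi = arm_bounds(contig, arm)
        if rng.random() < s:
            mid = lo + 30 * MB
            segments += [
                Segment(contig, lo, mid - 1, 2, 1),
                Segment(contig, mid, min(mid + 30 * MB, hi), 3, 1),
            ]
            kept[0] += 1
    for _ in range(loh_n):
        contig, arm = next(arm_iter)
        lo, hi = arm_bounds(contig, arm)
        if rng.random() < s:
            start = lo + 19 * MB
            segments.append(Segment(contig, start, start + 20 * MB, 2, 0))
            kept[1] += 1
    for _ in range(ntai_n):
        contig, arm = next(arm_iter)
        lo, hi = arm_bounds(contig, arm)
        if rng.random() < s:
            if arm == "p":
                segments.append(Segment(contig, 1, lo + 30 * MB, 3, 1))
            else:
                segments.append(Segment(contig, hi - 30 * MB, hi, 3, 1))
            kept[2] += 1

    profile = SegmentProfile(segments, purity=purity)
    return profile, HrdScores(lst_n, loh_n, ntai_n), HrdScores(*kept)


# ---------------------------------------------------------------------------
# signature catalogs
# ---------------------------------------------------------------------------

def synthetic_signature_matrix(
    k: int = 2, names: Optional[Sequence[str]] = None, overlap: float = 0.0
) -> SignatureMatrix:
    """Well-separated synthetic signatures: signature j is uniform over its
    own block of 96/k channels, optionally blended with a flat component
    (``overlap`` in [0, 1)) to make the problem less than trivially
    orthogonal."""
    if not 1 <= k <= 96:
        raise ValueError("k must be in [1, 96]")
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    names = list(names) if names is not None else [f"Sig{j + 1}" for j in range(k)]
    if len(names) != k:
        raise ValueError("need one name per signature")
    block = 96 // k
    mat = np.full((k, 96), overlap / 96.0)
    for j in range(k):
        lo = j * block
        hi = 96 if j == k - 1 else lo + block
        mat[j, lo:hi] += (1.0 - overlap) / (hi - lo)
    return SignatureMatrix(names=names, matrix=mat)


def simulate_catalog(
    signature_mixture: Mapping[str, float],
    n_snvs: int,
    sigs: SignatureMatrix,
    rng: Optional[np.random.Generator] = None,
) -> tuple[MutationCatalog96, np.ndarray]:
    """Multinomial draw of ``n_snvs`` mutations from a signature mixture.

    Returns the catalog and the true weight vector aligned to ``sigs.names``.
    """
    if n_snvs <= 0:
        raise ValueError("n_snvs must be positive")
    if abs(sum(signature_mixture.values()) - 1.0) > 1e-9:
        raise ValueError("signature mixture must sum to 1")
    unknown = set(signature_mixture) - set(sigs.names)
    if unknown:
        raise ValueError(f"mixture names not in signature matrix: {sorted(unknown)}")
    rng = rng or np.random.default_rng(0)
    w = np.array([signature_mixture.get(name, 0.0) for name in sigs.names])
    p = w @ sigs.matrix
    counts = rng.multinomial(n_snvs, p / p.sum())
    return MutationCatalog96(counts.astype(float)), w
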