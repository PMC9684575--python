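"""Readers and writers for the pipeline's file dialects.

All derived outputs are TSV (diff-able, test-friendly). Standard formats go
through standard libraries: FASTA via Biopython, VCF reading via cyvcf2,
tables via pandas. Indels are anchored-base in VCF and converted to the
internal trimmed representation at projection time.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .cohort import CohortRecord
from .copynumber import Segment, SegmentProfile
from .genome import CodingTranscript, Variant
from .hrd import ContigInfo, GenomeBuildInfo
from .phasing import ReadPairObservation

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(contigs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in contigs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# transcript table (one row per exon)
# ---------------------------------------------------------------------------

def write_transcripts(transcripts: Mapping[str, CodingTranscript], path: str | Path) -> None:
    rows = []
    for tx in transcripts.values():
        for start, end in tx.exons:
            rows.append({
                "transcript_id": tx.transcript_id, "gene": tx.gene,
                "contig": tx.contig, "strand": tx.strand,
                "exon_start": start, "exon_end": end,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_transcripts(path: str | Path, contigs: Mapping[str, str]) -> dict[str, CodingTranscript]:
    """Rebuild transcripts from the exon table; the CDS is extracted from the
    reference contigs (the table is authoritative for structure)."""
    from .simulate import extract_cds

    df = pd.read_csv(path, sep="\t")
    out: dict[str, CodingTranscript] = {}
    for (tid, gene, contig, strand), sub in df.groupby(
        ["transcript_id", "gene", "contig", "strand"], sort=False
    ):
        exons = list(zip(sub["exon_start"].astype(int), sub["exon_end"].astype(int)))
        cds = extract_cds(contigs[contig], exons, strand)
        out[gene] = CodingTranscript(
            transcript_id=tid, gene=gene, contig=contig, strand=strand,
            exons=tuple(exons), cds_sequence=cds,
        )
    return out


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=ORIGIN,Number=1,Type=String,Description="germline or somatic">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Variant allele fraction">
##INFO=<ID=AR,Number=1,Type=Integer,Description="Alt-supporting reads">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">
##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(
    variants: Sequence[tuple[str, Variant]],
    path: str | Path,
    contig_lengths: Optional[Mapping[str, int]] = None,
) -> None:
    """Write (patient_id, variant) records as a plain-text VCF v4.2."""
    contig_lines = "".join(
        f"##contig=<ID={name},length={length}>\n"
        for name, length in (contig_lengths or {}).items()
    )
    lines = [_VCF_HEADER.format(contigs=contig_lines)]
    ordered = sorted(variants, key=lambda pv: (pv[1].contig, pv[1].pos, pv[0]))
    for patient_id, v in ordered:
        info = [f"ORIGIN={v.origin}", f"PATIENT={patient_id}"]
        if v.vaf is not None:
            info.append(f"VAF={v.vaf:.6g}")
        if v.alt_reads is not None:
            info.append(f"AR={v.alt_reads}")
        if v.depth is not None:
            info.append(f"DP={v.depth}")
        lines.append(
            f"{v.contig}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t"
            + ";".join(info) + "\n"
        )
    Path(path).write_text("".join(lines))


def read_vcf(path: str | Path) -> list[tuple[str, Variant]]:
    """Read a VCF into (patient_id, Variant) pairs."""
    out: list[tuple[str, Variant]] = []
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            if len(rec.ALT) != 1:
                raise ValueError(f"{path}:{rec.CHROM}:{rec.POS}: multi-allelic records unsupported")
            vaf = rec.INFO.get("VAF")
            ar = rec.INFO.get("AR")
            dp = rec.INFO.get("DP")
            out.append((
                str(rec.INFO.get("PATIENT", "")),
                Variant(
                    variant_id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    contig=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=rec.ALT[0],
                    origin=str(rec.INFO.get("ORIGIN", "somatic")),
                    vaf=float(vaf) if vaf is not None else None,
                    alt_reads=int(ar) if ar is not None else None,
                    depth=int(dp) if dp is not None else None,
                ),
            ))
    finally:
        vcf.close()
    return out


# ---------------------------------------------------------------------------
# read-pair observations
# ---------------------------------------------------------------------------

def write_pairs(
    pairs: Mapping[tuple[str, str], Sequence[ReadPairObservation]],
    path: str | Path,
    patient_of: Optional[Mapping[tuple[str, str], str]] = None,
) -> None:
    rows = []
    for (germ_id, som_id), obs in sorted(pairs.items()):
        for o in obs:
            rows.append({
                "patient_id": (patient_of or {}).get((germ_id, som_id), ""),
                "germline_variant_id": germ_id, "somatic_variant_id": som_id,
                "fragment_id": o.fragment_id,
                "germ_allele": o.germline_site_allele,
                "som_allele": o.somatic_site_allele,
            })
    pd.DataFrame(rows, columns=[
        "patient_id", "germline_variant_id", "somatic_variant_id",
        "fragment_id", "germ_allele", "som_allele",
    ]).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> dict[tuple[str, str], list[ReadPairObservation]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[tuple[str, str], list[ReadPairObservation]] = {}
    for row in df.itertuples(index=False):
        key = (row.germline_variant_id, row.somatic_variant_id)
        out.setdefault(key, []).append(
            ReadPairObservation(row.fragment_id, row.germ_allele, row.som_allele)
        )
    return out


# ---------------------------------------------------------------------------
# segments
# ---------------------------------------------------------------------------

def write_segments(profiles: Mapping[str, SegmentProfile], path: str | Path) -> None:
    """Per-patient segment tables in one TSV with sample purity/ploidy columns."""
    rows = []
    for patient_id, profile in sorted(profiles.items()):
        for s in profile.segments:
            rows.append({
                "patient_id": patient_id, "contig": s.contig,
                "start": s.start, "end": s.end,
                "tcn": s.total_cn, "lcn": "" if s.minor_cn is None else s.minor_cn,
                "purity": profile.purity, "ploidy": profile.ploidy,
            })
    pd.DataFrame(rows, columns=[
        "patient_id", "contig", "start", "end", "tcn", "lcn", "purity", "ploidy",
    ]).to_csv(path, sep="\t", index=False)


def read_segments(path: str | Path) -> dict[str, SegmentProfile]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, SegmentProfile] = {}
    for patient_id, sub in df.groupby("patient_id", sort=False):
        segments = [
            Segment(
                str(r.contig), int(r.start), int(r.end), int(r.tcn),
                None if pd.isna(r.lcn) else int(r.lcn),
            )
            for r in sub.itertuples(index=False)
        ]
        out[str(patient_id)] = SegmentProfile(
            segments, purity=float(sub["purity"].iloc[0]),
            ploidy=float(sub["ploidy"].iloc[0]),
        )
    return out


# ---------------------------------------------------------------------------
# genome build
# ---------------------------------------------------------------------------

def write_build(build: GenomeBuildInfo, path: str | Path) -> None:
    rows = [
        {"contig": name, "length": info.length,
         "cen_start": info.cen_start, "cen_end": info.cen_end}
        for name, info in build.contigs.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_build(path: str | Path) -> GenomeBuildInfo:
    df = pd.read_csv(path, sep="\t")
    return GenomeBuildInfo({
        str(r.contig): ContigInfo(int(r.length), int(r.cen_start), int(r.cen_end))
        for r in df.itertuples(index=False)
    })


# ---------------------------------------------------------------------------
# cohort table
# ---------------------------------------------------------------------------

def write_cohort(records: Sequence[CohortRecord], path: str | Path) -> None:
    rows = [{
        "patient_id": r.patient_id, "lineage": r.lineage,
        "brca_associated": r.brca_associated,
        "germline_status": r.germline_status, "somatic_lof": r.somatic_lof,
        "purity": "" if r.purity is None else r.purity,
        "platinum_months": "" if r.platinum_months is None else r.platinum_months,
    } for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> list[CohortRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        CohortRecord(
            patient_id=str(r.patient_id), lineage=str(r.lineage),
            brca_associated=bool(r.brca_associated),
            germline_status=str(r.germline_status), somatic_lof=str(r.somatic_lof),
            purity=None if pd.isna(r.purity) else float(r.purity),
            platinum_months=None if pd.isna(r.platinum_months) else float(r.platinum_months),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# config / json
# ---------------------------------------------------------------------------

def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# simulation bundle
# ---------------------------------------------------------------------------

def write_simulation(sim, outdir: str | Path) -> dict[str, Path]:
    """Emit every input the pipeline consumes, plus the ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "transcripts": outdir / "transcripts.tsv",
        "germline": outdir / "germline.vcf",
        "somatic": outdir / "somatic.vcf",
        "pairs": outdir / "pairs.tsv",
        "segments": outdir / "segments.tsv",
        "cohort": outdir / "cohort.tsv",
        "truth": outdir / "ground_truth.json",
    }
    contig_lengths = {name: len(seq) for name, seq in sim.reference.contigs.items()}
    write_fasta(sim.reference.contigs, paths["reference"])
    write_transcripts(sim.reference.transcripts, paths["transcripts"])
    germ, som, pair_map, pair_patients, profiles = [], [], {}, {}, {}
    for p in sim.patients:
        germ += [(p.patient_id, v) for v in p.germline_variants]
        som += [(p.patient_id, v) for v in p.somatic_variants]
        for key, obs in p.read_pairs.items():
            pair_map[key] = obs
            pair_patients[key] = p.patient_id
        if p.profile is not None:
            profiles[p.patient_id] = p.profile
    write_vcf(germ, paths["germline"], contig_lengths)
    write_vcf(som, paths["somatic"], contig_lengths)
    write_pairs(pair_map, paths["pairs"], pair_patients)
    write_segments(profiles, paths["segments"])
    write_cohort(sim.records, paths["cohort"])
    write_json(sim.ground_truth, paths["truth"])
    return paths


def load_patient_bundles(
    reference_path: str | Path,
    transcripts_path: str | Path,
    germline_path: str | Path,
    somatic_path: str | Path,
    pairs_path: str | Path,
    segments_path: str | Path,
):
    """Reassemble per-patient bundles from the on-disk dialects."""
    from .reversion import PatientBundle

    contigs = read_fasta(reference_path)
    transcripts = read_transcripts(transcripts_path, contigs)
    germ = read_vcf(germline_path)
    som = read_vcf(somatic_path)
    pairs = read_pairs(pairs_path)
    profiles = read_segments(segments_path)

    patients: dict[str, dict] = {}
    for pid, v in germ:
        patients.setdefault(pid, {"g": [], "s": []})["g"].append(v)
    for pid, v in som:
        patients.setdefault(pid, {"g": [], "s": []})["s"].append(v)
    variant_patient = {v.variant_id: pid for pid, v in germ + som}

    bundles = []
    for pid in sorted(patients):
        ppairs = {
            key: obs for key, obs in pairs.items()
            if variant_patient.get(key[0]) == pid
        }
        bundles.append(PatientBundle(
            patient_id=pid,
            transcripts=transcripts,
            germline_variants=patients[pid]["g"],
            somatic_variants=patients[pid]["s"],
            read_pairs=ppairs,
            profile=profiles.get(pid),
        ))
    return bundles, contigs, transcripts
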