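"""Cohort- and variant-level filters applied before reversion analysis.

Three families of filters:

* tumor-mutational-burden (TMB) exclusion of hypermutated tumors (>20
  nonsynonymous mutations per callable megabase), which would otherwise
  contribute coincidental BRCA1/2 indels;
* somatic-call filtering for exome data (interval blacklist, population
  recurrence, and a low-VAF/low-support/low-coverage rule), with a whitelist
  of known-oncogenic variants that bypasses everything;
* an optional per-gene C-terminal rule dropping truncating germline variants
  in the last exon beyond the functional domains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .genome import CodingTranscript, Variant, classify_consequence, project_to_cds

logger = logging.getLogger(__name__)

REASON_WHITELISTED = "whitelisted"
REASON_BLACKLIST = "blacklist_region"
REASON_POPULATION = "population_recurrent"
REASON_LOW_SUPPORT = "low_support"
REASON_INDETERMINATE = "indeterminate_annotations"
REASON_PASS = "pass"


@dataclass
class FilterConfig:
    """Thresholds and resources for all pre-analysis filters.

    ``read_support_min`` is the smallest passing alt-read count: the default 4
    encodes "three or fewer reads" failing. ``rule3_conjunctive`` keeps the
    low-support rule a conjunction of its three clauses (VAF < vaf_min AND
    alt_reads < read_support_min AND depth < coverage_min); the disjunctive
    alternative removes a variant when any clause holds.
    """

    tmb_threshold: float = 20.0
    callable_mb: float = 1.14
    population_occurrence_max: int = 10
    vaf_min: float = 0.05
    read_support_min: int = 4
    coverage_min: int = 20
    blacklist: Sequence[tuple[str, int, int]] = field(default_factory=tuple)
    whitelist: frozenset[str] = field(default_factory=frozenset)
    cterminal_bounds: Mapping[str, int] = field(default_factory=dict)
    rule3_conjunctive: bool = True

    def __post_init__(self):
        for name in ("tmb_threshold", "callable_mb", "population_occurrence_max",
                     "vaf_min", "read_support_min", "coverage_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for contig, start, end in self.blacklist:
            if end < start:
                raise ValueError(f"malformed blacklist interval {contig}:{start}-{end}")
        self.whitelist = frozenset(self.whitelist)


def compute_tmb(nonsynonymous_count: int, callable_mb: float) -> float:
    """Nonsynonymous mutations per callable megabase."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    return nonsynonymous_count / callable_mb


def exclude_high_tmb(cohort: Sequence[Mapping], cfg: FilterConfig) -> list:
    """Retain patients whose TMB is at or below the threshold (strictly
    greater is excluded)."""
    retained = []
    for patient in cohort:
        tmb = compute_tmb(patient["nonsynonymous_count"],
                          patient.get("callable_mb", cfg.callable_mb))
        if tmb <= cfg.tmb_threshold:
            retained.append(patient)
    return retained


def _in_blacklist(v: Variant, cfg: FilterConfig) -> bool:
    end = v.pos + len(v.ref) - 1
    return any(c == v.contig and v.pos <= e and end >= s for c, s, e in cfg.blacklist)


def filter_somatic_calls(
    variants: Sequence[Variant],
    cfg: FilterConfig,
    occurrence: Optional[Mapping[str, int]] = None,
) -> tuple[list[Variant], list[tuple[str, str, str]]]:
    """Apply the somatic-call filter chain.

    ``occurrence`` maps variant keys (contig:pos:ref:alt) to the number of
    non-cancer individuals carrying the variant. Returns the retained
    variants and an audit list of (variant_id, status, reason) covering every
    input. Whitelisted variants are always retained; variants with missing
    annotations are retained but flagged indeterminate and logged.
    """
    occurrence = occurrence or {}
    retained: list[Variant] = []
    audit: list[tuple[str, str, str]] = []
    for v in variants:
        if v.key in cfg.whitelist:
            retained.append(v)
            audit.append((v.variant_id, "retained", REASON_WHITELISTED))
            continue
        if _in_blacklist(v, cfg):
            audit.append((v.variant_id, "removed", REASON_BLACKLIST))
            continue
        occ = occurrence.get(v.key, 0)
        if occ >= cfg.population_occurrence_max:
            audit.append((v.variant_id, "removed", REASON_POPULATION))
            continue
        if v.vaf is None or v.alt_reads is None or v.depth is None:
            logger.warning("variant %s missing VAF/read annotations; retained as indeterminate",
                           v.variant_id)
            retained.append(v)
            audit.append((v.variant_id, "retained", REASON_INDETERMINATE))
            continue
        clauses = (
            v.vaf < cfg.vaf_min,
            v.alt_reads < cfg.read_support_min,
            v.depth < cfg.coverage_min,
        )
        low_support = all(clauses) if cfg.rule3_conjunctive else any(clauses)
        if low_support:
            audit.append((v.variant_id, "removed", REASON_LOW_SUPPORT))
            continue
        retained.append(v)
        audit.append((v.variant_id, "retained", REASON_PASS))
    return retained, audit


def filter_cterminal(
    germline_variants: Sequence[Variant],
    tx: CodingTranscript,
    cfg: FilterConfig,
) -> list[Variant]:
    """Drop truncating germline variants in the transcript's last exon beyond
    the gene's configured C-terminal bound.

    Only truncating consequences (frameshift, nonsense) are subject to the
    rule; missense and in-frame events at the same positions are retained.
    Genes without a configured bound are untouched.
    """
    bound = cfg.cterminal_bounds.get(tx.gene)
    if bound is None:
        return list(germline_variants)
    last_lo, last_hi = tx.last_exon_cds_interval()
    retained = []
    for v in germline_variants:
        change = project_to_cds(v, tx)
        if change is None:
            retained.append(v)
            continue
        cons = classify_consequence(tx, change)
        truncating = cons.consequence in {"frameshift", "nonsense"}
        in_last_exon = last_lo <= change.cds_start <= last_hi
        if truncating and in_last_exon and change.cds_start > bound:
            continue
        retained.append(v)
    return retained
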