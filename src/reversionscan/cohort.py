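"""Cohort-level prevalence tables, Fisher comparisons and summaries."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

# Canonical BRCA-associated lineages
BRCA_ASSOCIATED_LINEAGES = frozenset({"breast", "ovarian", "prostate", "pancreas"})


@dataclass(frozen=True)
class CohortRecord:
    patient_id: str
    lineage: str
    brca_associated: bool
    germline_status: str = "none"  # BRCA1 | BRCA2 | none
    somatic_lof: str = "none"  # BRCA1 | BRCA2 | none
    purity: Optional[float] = None
    platinum_months: Optional[float] = None

    def __post_init__(self):
        if not self.lineage:
            raise ValueError("lineage must be non-empty")
        for fieldname in ("germline_status", "somatic_lof"):
            if getattr(self, fieldname) not in {"BRCA1", "BRCA2", "none"}:
                raise ValueError(f"bad {fieldname} {getattr(self, fieldname)!r}")


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """100*count/denominator, rounded half-up to ``decimals`` places (the
    rounding convention used for printed prevalence figures)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-decimals)
    return float(
        (Decimal(100) * Decimal(count) / Decimal(denominator)).quantize(q, ROUND_HALF_UP)
    )


def prevalence_table(
    cohort: Sequence[CohortRecord],
    group_of: Callable[[CohortRecord], str],
    is_case: Callable[[CohortRecord], bool],
) -> pd.DataFrame:
    """Per-group case counts, denominators and rounded percentages.

    ``group_of`` assigns each patient to a group; ``is_case`` marks the
    numerator. Groups with a zero denominator are omitted with a warning.
    """
    if not cohort:
        raise ValueError("cohort must be non-empty")
    rows = []
    groups: dict[str, list[CohortRecord]] = {}
    for rec in cohort:
        groups.setdefault(group_of(rec), []).append(rec)
    for group, members in sorted(groups.items()):
        denom = len(members)
        if denom == 0:  # pragma: no cover - cannot happen via setdefault
            logger.warning("group %s has zero denominator; omitted", group)
            continue
        count = sum(1 for m in members if is_case(m))
        rows.append(
            {"group": group, "count": count, "denominator": denom,
             "percent": percent(count, denom)}
        )
    return pd.DataFrame(rows, columns=["group", "count", "denominator", "percent"])


def compare_rates_fisher(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    Returns (odds ratio, p). The two-sided p sums hypergeometric
    probabilities of all tables (with the observed margins) at most as
    probable as the observed one.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margin in contingency table")
    odds_ratio, p = stats.fisher_exact(table, alternative="two-sided")
    return float(odds_ratio), float(p)


def summarize_durations(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, min, max) of a set of durations; median of an even-sized set
    is the mean of the middle two order statistics."""
    if len(values) == 0:
        raise ValueError("no durations to summarize")
    return float(np.median(values)), float(min(values)), float(max(values))


def oncoprint_table(
    cohort: Sequence[CohortRecord],
    reversion_calls: Sequence,
    co_mutations: Optional[Mapping[str, Sequence[str]]] = None,
    loss_of_wt: Optional[Mapping[str, bool]] = None,
) -> pd.DataFrame:
    """Wide patient-by-feature table for reversion-positive patients.

    One row per patient with at least one reversion call; columns carry the
    lineage, germline gene, reversion mechanism(s), loss-of-wild-type flag
    and comma-joined co-mutated genes.
    """
    co_mutations = co_mutations or {}
    loss_of_wt = loss_of_wt or {}
    by_patient: dict[str, list] = {}
    for call in reversion_calls:
        by_patient.setdefault(call.patient_id, []).append(call)
    records = {rec.patient_id: rec for rec in cohort}
    rows = []
    for pid in sorted(by_patient):
        calls = by_patient[pid]
        rec = records.get(pid)
        rows.append(
            {
                "patient_id": pid,
                "lineage": rec.lineage if rec else "",
                "germline_gene": calls[0].gene,
                "n_reversions": len(calls),
                "mechanisms": ",".join(sorted({c.mechanism for c in calls})),
                "loss_of_wt": bool(loss_of_wt.get(pid, False)),
                "co_mutated_genes": ",".join(sorted(co_mutations.get(pid, ()))),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "lineage", "germline_gene", "n_reversions",
            "mechanisms", "loss_of_wt", "co_mutated_genes",
        ],
    )
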