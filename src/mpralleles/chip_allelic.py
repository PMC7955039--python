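"""Allele-specific ChIP-seq read imbalance at heterozygous variants.

A variant is examined in a ChIP-seq dataset only when it is heterozygous in
the assayed cell line and lies inside a peak.  Imbalance strength is

    strength(a, b) = 1 - min(a, b) / max(a, b)

so 0 means balanced reads and 0.5 means the strong allele has twice the reads
of the weak allele.  Per (variant, dataset), replicate results are combined
into a reproducibility score: the minimum replicate strength when all
replicates prefer the same allele, 0 otherwise.  A dataset call is allelic
when the score exceeds 0.4, the summed reads depart from 50:50 by a two-sided
binomial test (p < 0.05), and at least 6 reads are available.  Three
consistency filters then retain a (variant, protein) event only when the
variant is allelic in at least half of the heterozygous-in-peak datasets for
that protein, at least 75% of the allelic datasets prefer the same allele,
and replicates agree on the preferred allele.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ARS_THRESHOLD = 0.4
MIN_TOTAL_READS = 6
BINOMIAL_ALPHA = 0.05
MIN_ALLELIC_FRACTION = 0.50
MIN_CONSENSUS_FRACTION = 0.75


def strength(reads_a: int, reads_b: int) -> float:
    """Allelic imbalance strength: one minus weak/strong reads.

    0 means balanced reads; 0.5 means the strong allele has twice the reads
    of the weak allele; 1 means all reads carry one allele."""
    if reads_a < 0 or reads_b < 0:
        raise ValueError("read counts must be non-negative")
    if reads_a + reads_b == 0:
        raise ValueError("strength undefined for zero total reads")
    lo, hi = min(reads_a, reads_b), max(reads_a, reads_b)
    return 1.0 - lo / hi


def preferred(reads_a: int, reads_b: int) -> str | None:
    """'allele1' / 'allele2' for the stronger allele, None on a tie."""
    if reads_a == reads_b:
        return None
    return "allele1" if reads_a > reads_b else "allele2"


@dataclass(frozen=True)
class AllelicReadRecord:
    """Replicated allele-specific read counts at one heterozygous site."""

    variant_id: str
    cell_line: str
    dataset_id: str
    protein: str
    replicate: int
    reads_allele1: int
    reads_allele2: int
    het: bool = True
    in_peak: bool = True


@dataclass
class AllelicCall:
    """Combined per-(variant, dataset) allelic imbalance call."""

    variant_id: str
    dataset_id: str
    protein: str
    cell_line: str
    is_allelic: bool
    preferred_allele: str | None
    strength: float
    score: float
    p_binomial: float
    total_reads: int
    n_replicates: int
    dropped_replicates: int = 0


def replicate_consistent_score(records: Sequence[AllelicReadRecord]) -> float:
    """Minimum replicate strength when all replicates prefer the same allele,
    else 0.  This is the default reproducibility score; a different score
    function with the same signature can be plugged into
    :func:`call_allelic_dataset`."""
    prefs = [preferred(r.reads_allele1, r.reads_allele2) for r in records]
    if None in prefs or len(set(prefs)) != 1:
        return 0.0
    return min(strength(r.reads_allele1, r.reads_allele2) for r in records)


def call_allelic_dataset(
    records: Sequence[AllelicReadRecord],
    ars_threshold: float = ARS_THRESHOLD,
    alpha: float = BINOMIAL_ALPHA,
    min_total: int = MIN_TOTAL_READS,
    score_fn: Callable[[Sequence[AllelicReadRecord]], float] | None = None,
) -> AllelicCall:
    """Combine the replicates of one (variant, dataset) into an allelic call."""
    if not records:
        raise ValueError("no records")
    first = records[0]
    if not all(r.het and r.in_peak for r in records):
        raise ValueError("records must be heterozygous and inside a peak")
    usable = [r for r in records if r.reads_allele1 + r.reads_allele2 > 0]
    dropped = len(records) - len(usable)
    if not usable:
        return AllelicCall(
            first.variant_id, first.dataset_id, first.protein, first.cell_line,
            False, None, 0.0, 0.0, 1.0, 0, 0, dropped,
        )
    score = (score_fn or replicate_consistent_score)(usable)
    sum_a = sum(r.reads_allele1 for r in usable)
    sum_b = sum(r.reads_allele2 for r in usable)
    total = sum_a + sum_b
    p_binom = stats.binomtest(sum_a, total, 0.5).pvalue
    is_allelic = score > ars_threshold and p_binom < alpha and total >= min_total
    return AllelicCall(
        variant_id=first.variant_id,
        dataset_id=first.dataset_id,
        protein=first.protein,
        cell_line=first.cell_line,
        is_allelic=bool(is_allelic),
        preferred_allele=preferred(sum_a, sum_b),
        strength=strength(sum_a, sum_b),
        score=float(score),
        p_binomial=float(p_binom),
        total_reads=total,
        n_replicates=len(usable),
        dropped_replicates=dropped,
    )


def call_allelic_table(
    reads: pd.DataFrame,
    **kwargs,
) -> list[AllelicCall]:
    """Per-dataset calls from a long read table.

    Columns: variant_id, cell_line, dataset_id, protein, replicate,
    reads_allele1, reads_allele2, het, in_peak.  Non-heterozygous or
    out-of-peak rows are ignored.
    """
    usable = reads.loc[reads["het"].astype(bool) & reads["in_peak"].astype(bool)]
    calls = []
    for (_, _), sub in usable.groupby(["variant_id", "dataset_id"], sort=True):
        records = [
            AllelicReadRecord(
                variant_id=r.variant_id,
                cell_line=r.cell_line,
                dataset_id=r.dataset_id,
                protein=r.protein,
                replicate=int(r.replicate),
                reads_allele1=int(r.reads_allele1),
                reads_allele2=int(r.reads_allele2),
            )
            for r in sub.itertuples(index=False)
        ]
        calls.append(call_allelic_dataset(records, **kwargs))
    return calls


@dataclass
class AllelicEvent:
    """A (variant, protein) pair surviving the consistency filters."""

    variant_id: str
    protein: str
    consensus_allele: str
    k_allelic: int
    n_het: int
    strengths_by_cell_line: dict[str, list[float]] = field(default_factory=dict)


def apply_consistency_filters(
    calls: Iterable[AllelicCall],
    min_allelic_fraction: float = MIN_ALLELIC_FRACTION,
    min_consensus_fraction: float = MIN_CONSENSUS_FRACTION,
) -> list[AllelicEvent]:
    """Retain (variant, protein) events with reproducible, same-direction
    imbalance.  Filters only remove events, never create them."""
    grouped: dict[tuple[str, str], list[AllelicCall]] = {}
    for c in calls:
        grouped.setdefault((c.variant_id, c.protein), []).append(c)
    events = []
    for (variant, protein), group in sorted(grouped.items()):
        n_het = len(group)
        if n_het == 0:
            continue
        allelic = [c for c in group if c.is_allelic]
        k = len(allelic)
        if k == 0 or k / n_het < min_allelic_fraction:
            continue
        prefs = Counter(c.preferred_allele for c in allelic)
        consensus, n_consensus = prefs.most_common(1)[0]
        if consensus is None or n_consensus / k < min_consensus_fraction:
            continue
        strengths: dict[str, list[float]] = {}
        for c in allelic:
            if c.preferred_allele == consensus:
                strengths.setdefault(c.cell_line, []).append(c.strength)
        events.append(
            AllelicEvent(
                variant_id=variant,
                protein=protein,
                consensus_allele=consensus,
                k_allelic=k,
                n_het=n_het,
                strengths_by_cell_line=strengths,
            )
        )
    return events


def summarize_allelic_profile(events: Sequence[AllelicEvent]) -> pd.DataFrame:
    """One row per (variant, protein): consensus allele, median strength
    across cell lines (each cell line contributing its median), and the
    "(k of n)" dataset counts."""
    rows = []
    for e in events:
        per_cell = [float(np.median(v)) for v in e.strengths_by_cell_line.values()]
        rows.append(
            {
                "variant_id": e.variant_id,
                "protein": e.protein,
                "consensus_allele": e.consensus_allele,
                "median_strength": float(np.median(per_cell)) if per_cell else np.nan,
                "k_allelic": e.k_allelic,
                "n_het": e.n_het,
                "n_cell_lines": len(e.strengths_by_cell_line),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "protein", "consensus_allele", "median_strength",
                 "k_allelic", "n_het", "n_cell_lines"],
    )


def calls_to_frame(calls: Sequence[AllelicCall]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in calls])
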