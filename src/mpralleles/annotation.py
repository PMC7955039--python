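"""Target-gene assignment and evidence tiers for variants.

Target genes are the union of chromatin-looping (promoter-interacting) genes
and eQTL genes; when neither source nominates a gene, the nearest gene by
genomic distance to the transcript span is used.  Evidence tiers: (1) some
gene has both an eQTL and a looping interaction; (2) an eQTL for at least one
gene; (3) looping only; (4) neither.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .oligo import VariantRecord


@dataclass(frozen=True)
class GeneAnnotation:
    variant_id: str
    target_genes: frozenset[str]
    evidence: dict
    tier: int
    nearest_gene: str
    nearest_distance: int


def _nearest_gene(variant: VariantRecord, gene_table: pd.DataFrame) -> tuple[str, int]:
    sub = gene_table.loc[gene_table["chrom"] == variant.chrom]
    if sub.empty:
        raise ValueError(f"chromosome {variant.chrom} absent from gene table")
    vs, ve = variant.start, variant.end
    best_gene, best_dist = None, None
    # ties broken lexicographically by gene symbol
    for row in sub.sort_values("gene").itertuples(index=False):
        if row.start < ve and vs < row.end:
            dist = 0
        elif row.start >= ve:
            dist = row.start - ve
        else:
            dist = vs - row.end
        if best_dist is None or dist < best_dist:
            best_gene, best_dist = row.gene, dist
    return best_gene, int(best_dist)


def assign_targets(
    variant: VariantRecord,
    loop_genes: Mapping[str, Iterable[str]],
    eqtl_genes: Mapping[str, Iterable[str]],
    gene_table: pd.DataFrame,
) -> GeneAnnotation:
    """Annotate one variant with target genes and an evidence tier.

    ``loop_genes`` / ``eqtl_genes`` map variant id -> gene iterables;
    ``gene_table`` has columns chrom, start, end, gene (0-based half-open
    transcript spans)."""
    loops = set(loop_genes.get(variant.id, ()))
    eqtls = set(eqtl_genes.get(variant.id, ()))
    nearest, dist = _nearest_gene(variant, gene_table)
    union = loops | eqtls
    targets = union if union else {nearest}
    if loops & eqtls:
        tier = 1
    elif eqtls:
        tier = 2
    elif loops:
        tier = 3
    else:
        tier = 4
    evidence = {
        g: {
            "eqtl": g in eqtls,
            "looping": g in loops,
            "nearest": g == nearest,
        }
        for g in targets | {nearest}
    }
    return GeneAnnotation(
        variant_id=variant.id,
        target_genes=frozenset(targets),
        evidence=evidence,
        tier=tier,
        nearest_gene=nearest,
        nearest_distance=dist,
    )


def _pairs_to_mapping(table: pd.DataFrame) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for row in table.itertuples(index=False):
        out.setdefault(row.variant_id, set()).add(row.gene)
    return out


def annotate_variants(
    variants: Iterable[VariantRecord],
    loop_table: pd.DataFrame,
    eqtl_table: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> pd.DataFrame:
    """Annotation table for a variant set.

    ``loop_table`` and ``eqtl_table`` are (variant_id, gene) pair tables; an
    empty DataFrame means no evidence of that kind."""
    loops = _pairs_to_mapping(loop_table) if len(loop_table) else {}
    eqtls = _pairs_to_mapping(eqtl_table) if len(eqtl_table) else {}
    rows = []
    for v in variants:
        ann = assign_targets(v, loops, eqtls, gene_table)
        rows.append(
            {
                "variant_id": ann.variant_id,
                "target_genes": ",".join(sorted(ann.target_genes)),
                "tier": ann.tier,
                "nearest_gene": ann.nearest_gene,
                "nearest_distance": ann.nearest_distance,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "target_genes", "tier", "nearest_gene",
                 "nearest_distance"],
    )
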