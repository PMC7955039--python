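"""Seeded synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study conditions of a barcoded reporter screen of
disease-associated variants: ~170-base allele-specific oligos tagged by
random barcodes (median 729 barcodes per oligo, lognormal), three plasmid and
three mRNA replicates with negative-binomial count noise, planted enhancer
effects (fold >= 1.5) and allelic effects (>= 25% between alleles), ChIP-seq
peak sets with planted enrichment at chosen variants, and replicated binomial
allele-specific reads at heterozygous sites.  Every generator is a pure
function of (parameters, seed) and ships a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .barcodes import ROLE_MRNA, ROLE_PLASMID
from .enrichment import PeakSet
from .motifs import PWM
from .oligo import VariantRecord

BARCODE_MEDIAN = 729.0
BARCODE_SIGMA = 0.4  # lognormal sigma approximating the observed histogram
N_REPLICATES = 3
DISPERSION = 0.05  # typical plasmid-library NB dispersion
READS_PER_BARCODE = 20.0

_BASES = np.array(list("ACGT"))


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None):
    mean = np.asarray(mean, dtype=float)
    if size is None and mean.shape:
        size = mean.shape
    if dispersion <= 0:
        return rng.poisson(mean, size)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Reference genome + variants


@dataclass
class SimulatedVariants:
    genome: dict[str, str]
    variants: list[VariantRecord]
    truth: pd.DataFrame


def gen_reference_and_variants(
    n_variants: int,
    seed: int | None = None,
    n_loci: int | None = None,
    locus_length: int = 3000,
    multiallelic_frac: float = 0.01,
    planted_overlapping: Mapping[int, PWM] | None = None,
    planted_adjacent: Mapping[int, PWM] | None = None,
    adjacent_offset: int = 30,
) -> SimulatedVariants:
    """Random reference loci (one chromosome each) with variants placed at
    least 200 bases from the edges; ~1% of variants get a second alternative
    allele.

    ``planted_overlapping`` maps variant index -> motif whose consensus is
    written around the variant so that the alternative allele completes the
    site and the reference allele breaks it; ``planted_adjacent`` writes the
    consensus ``adjacent_offset`` bases downstream of the variant in both
    alleles' shared flank.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    if n_loci is None:
        n_loci = max(1, n_variants // 10)
    chroms = [f"locus_{i + 1}" for i in range(n_loci)]
    # variants sit on a grid of slots spaced widely enough that planted
    # motifs never collide; the locus grows to fit its variant load
    spacing = 80
    max_per_locus = -(-n_variants // n_loci)
    locus_length = max(locus_length, 400 + spacing * (max_per_locus + 1))
    genome = {c: list(_random_seq(rng, locus_length)) for c in chroms}

    planted_overlapping = dict(planted_overlapping or {})
    planted_adjacent = dict(planted_adjacent or {})

    slots = {
        c: list(range(200, locus_length - 200, spacing)) for c in chroms
    }
    rows = []
    records = []
    for i in range(n_variants):
        chrom = chroms[i % n_loci]
        avail = slots[chrom]
        pos0 = avail.pop(int(rng.integers(len(avail))))
        seq = genome[chrom]

        planted_tf = None
        adjacent_tf = None
        if i in planted_overlapping:
            pwm = planted_overlapping[i]
            start = pos0 - pwm.width // 2
            cons = pwm.consensus
            seq[start : start + pwm.width] = list(cons)
            col = pwm.width // 2
            weak = "ACGT"[int(pwm.matrix[col].argmin())]
            if weak == cons[col]:  # degenerate column; pick any other base
                weak = next(b for b in "ACGT" if b != cons[col])
            seq[pos0] = weak
            ref, alts = weak, (cons[col],)
            planted_tf = pwm.tf_name
        else:
            ref = seq[pos0]
            others = [b for b in "ACGT" if b != ref]
            n_alts = 2 if rng.random() < multiallelic_frac else 1
            alts = tuple(
                str(a) for a in rng.choice(others, size=n_alts, replace=False)
            )
        if i in planted_adjacent:
            pwm = planted_adjacent[i]
            start = pos0 + adjacent_offset
            seq[start : start + pwm.width] = list(pwm.consensus)
            adjacent_tf = pwm.tf_name

        risk = alts[0] if rng.random() < 0.5 else ref
        vid = f"rs{100000 + i}"
        records.append(
            VariantRecord(
                id=vid, chrom=chrom, pos=pos0 + 1, ref=ref, alts=alts,
                risk_allele=risk, locus_id=chrom,
            )
        )
        rows.append(
            {
                "variant_id": vid,
                "chrom": chrom,
                "pos": pos0 + 1,
                "ref": ref,
                "alts": ",".join(alts),
                "locus_id": chrom,
                "planted_overlapping_tf": planted_tf,
                "planted_adjacent_tf": adjacent_tf,
            }
        )
    genome_str = {c: "".join(s) for c, s in genome.items()}
    return SimulatedVariants(genome_str, records, pd.DataFrame(rows))


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n{seq}\n")


# ---------------------------------------------------------------------------
# MPRA counts


@dataclass
class SimulatedMPRA:
    barcode_counts: pd.DataFrame  # barcode, oligo_id, sample, count
    samples: pd.DataFrame
    truth: pd.DataFrame  # per variant: planted effects
    barcode_map: dict[str, str] = field(default_factory=dict)

    def oligo_counts(self) -> pd.DataFrame:
        out = self.barcode_counts.pivot_table(
            index="oligo_id", columns="sample", values="count",
            aggfunc="sum", fill_value=0, observed=True,
        ).reindex(columns=self.samples.index, fill_value=0)
        out.columns.name = None
        return out


def gen_mpra_counts(
    variants: Sequence[VariantRecord],
    seed: int | None = None,
    n_replicates: int = N_REPLICATES,
    barcode_median: float = BARCODE_MEDIAN,
    barcode_sigma: float = BARCODE_SIGMA,
    reads_per_barcode: float = READS_PER_BARCODE,
    dispersion: float = DISPERSION,
    enhancer_folds: Mapping[str, float] | None = None,
    allelic_log2: Mapping[str, float] | None = None,
) -> SimulatedMPRA:
    """Barcode-level counts for plasmid and mRNA replicates.

    Barcode multiplicity per oligo is rounded lognormal with the target
    median; per (barcode, sample) counts are independent NB draws.  mRNA
    means are scaled by the variant's planted enhancer fold (all alleles) and
    by 2**allelic_log2 for non-reference alleles of planted allelic variants.
    """
    enhancer_folds = dict(enhancer_folds or {})
    allelic_log2 = dict(allelic_log2 or {})
    for fold in enhancer_folds.values():
        if fold < 0:
            raise ValueError("enhancer fold must be non-negative")
    rng = np.random.default_rng(seed)

    oligo_ids: list[str] = []
    rna_scale: list[float] = []
    truth_rows = []
    for v in variants:
        fold = float(enhancer_folds.get(v.id, 1.0))
        dlog2 = float(allelic_log2.get(v.id, 0.0))
        for allele in v.alleles:
            mult = 2.0**dlog2 if allele != v.ref else 1.0
            oligo_ids.append(f"{v.id}|{allele}")
            rna_scale.append(fold * mult)
        truth_rows.append(
            {
                "variant_id": v.id,
                "ref": v.ref,
                "is_enhancer": fold >= 1.5,
                "enhancer_fold": fold,
                "is_allelic": abs(dlog2) > 0,
                "allelic_log2": dlog2,
            }
        )
    n_oligos = len(oligo_ids)
    rna_scale_arr = np.asarray(rna_scale)

    n_bc = np.maximum(
        1,
        np.round(
            rng.lognormal(np.log(barcode_median), barcode_sigma, size=n_oligos)
        ),
    ).astype(int)
    total = int(n_bc.sum())
    oligo_idx = np.repeat(np.arange(n_oligos), n_bc)
    barcodes = np.array([f"bc{i:08d}" for i in range(total)])

    samples = pd.DataFrame(
        {
            "role": [ROLE_PLASMID] * n_replicates + [ROLE_MRNA] * n_replicates,
            "replicate": list(range(1, n_replicates + 1)) * 2,
        },
        index=[f"plasmid_{r}" for r in range(1, n_replicates + 1)]
        + [f"mRNA_{r}" for r in range(1, n_replicates + 1)],
    )
    samples.index.name = "sample"

    frames = []
    rna_mean = reads_per_barcode * rna_scale_arr[oligo_idx]
    for s, row in samples.iterrows():
        mean = rna_mean if row["role"] == ROLE_MRNA else reads_per_barcode
        counts = _nb(rng, np.broadcast_to(mean, (total,)), dispersion)
        frames.append(
            pd.DataFrame(
                {
                    "barcode": barcodes,
                    "oligo_id": pd.Categorical.from_codes(
                        oligo_idx, categories=oligo_ids
                    ),
                    "sample": s,
                    "count": counts,
                }
            )
        )
    barcode_counts = pd.concat(frames, ignore_index=True)
    barcode_map = {
        b: f"{oligo_ids[i]}|forward" for b, i in zip(barcodes, oligo_idx)
    }
    truth = pd.DataFrame(truth_rows)
    return SimulatedMPRA(barcode_counts, samples, truth, barcode_map)


def gen_oligo_counts(
    n_oligos: int,
    seed: int | None = None,
    n_replicates: int = N_REPLICATES,
    mean_total: float = BARCODE_MEDIAN * READS_PER_BARCODE,
    sigma: float = BARCODE_SIGMA,
    dispersion: float = DISPERSION,
    folds: float | np.ndarray = 1.0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Oligo-level count matrix with NB noise of the given dispersion.

    Oligos are named ``v<i>|A`` (one allele per synthetic variant).  Returns
    (counts, roles, truth); ``folds`` may be a scalar or per-oligo array of
    planted mRNA/plasmid fold changes.
    """
    rng = np.random.default_rng(seed)
    folds = np.broadcast_to(np.asarray(folds, dtype=float), (n_oligos,))
    base = rng.lognormal(np.log(mean_total), sigma, size=n_oligos)
    sample_names = [f"plasmid_{r}" for r in range(1, n_replicates + 1)] + [
        f"mRNA_{r}" for r in range(1, n_replicates + 1)
    ]
    roles = pd.Series(
        [ROLE_PLASMID] * n_replicates + [ROLE_MRNA] * n_replicates,
        index=sample_names,
    )
    cols = {}
    for s in sample_names:
        mean = base * folds if roles[s] == ROLE_MRNA else base
        cols[s] = _nb(rng, mean, dispersion)
    index = [f"v{i:05d}|A" for i in range(n_oligos)]
    counts = pd.DataFrame(cols, index=pd.Index(index, name="oligo_id"))
    truth = pd.DataFrame(
        {"oligo_id": index, "fold": folds, "is_enhancer": folds >= 1.5}
    )
    return counts, roles, truth


# ---------------------------------------------------------------------------
# ChIP-seq peaks and allele-specific reads


@dataclass
class SimulatedChip:
    peak_sets: list[PeakSet]
    reads: pd.DataFrame
    truth: pd.DataFrame


def gen_peaksets(
    variants: Sequence[VariantRecord],
    seed: int | None = None,
    n_datasets: int = 10,
    p_target: float = 0.5,
    p_background: float = 0.1,
    target_ids: frozenset | set = frozenset(),
    width_range: tuple[int, int] = (200, 1000),
    names: Sequence[str] | None = None,
) -> tuple[list[PeakSet], pd.DataFrame]:
    """Peak sets with planted in-peak enrichment at ``target_ids``.

    Each variant is covered by a peak of width 200-1000 with probability
    ``p_target`` (targets) or ``p_background`` (all others), independently per
    dataset.
    """
    rng = np.random.default_rng(seed)
    peak_sets = []
    rows = []
    for d in range(n_datasets):
        name = names[d] if names else f"dataset_{d + 1}"
        intervals = []
        for v in variants:
            p = p_target if v.id in target_ids else p_background
            covered = rng.random() < p
            if covered:
                width = int(rng.integers(width_range[0], width_range[1] + 1))
                offset = int(rng.integers(0, width))
                start = max(0, v.start - offset)
                intervals.append((v.chrom, start, start + width))
            rows.append(
                {"dataset": name, "variant_id": v.id, "in_peak": covered}
            )
        peak_sets.append(PeakSet(name, intervals))
    return peak_sets, pd.DataFrame(rows)


def gen_allelic_reads(
    variants: Sequence[VariantRecord],
    seed: int | None = None,
    proteins: Sequence[str] = ("TF_A", "TF_B"),
    cell_lines: Sequence[str] = ("LCL_1", "LCL_2"),
    datasets_per_protein: int = 2,
    n_replicates: int = 2,
    n_reads: int = 40,
    ratios: Mapping[str, float] | None = None,
    default_ratio: float = 0.5,
    het_prob: float = 0.7,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicated binomial allele-specific read counts at heterozygous sites.

    ``ratios`` maps variant id -> probability that a read carries allele 1;
    heterozygosity is drawn per (variant, cell line).  Only heterozygous,
    in-peak rows are emitted.
    """
    rng = np.random.default_rng(seed)
    ratios = dict(ratios or {})
    rows = []
    truth_rows = []
    for v in variants:
        ratio = float(ratios.get(v.id, default_ratio))
        truth_rows.append(
            {
                "variant_id": v.id,
                "allelic_binding_ratio": ratio,
                "is_allelic_binding": abs(ratio - 0.5) > 1e-12,
            }
        )
        for cell in cell_lines:
            if rng.random() >= het_prob:
                continue
            for protein in proteins:
                for d in range(datasets_per_protein):
                    dataset = f"{protein}_{cell}_ds{d + 1}"
                    for rep in range(1, n_replicates + 1):
                        a = int(rng.binomial(n_reads, ratio))
                        rows.append(
                            {
                                "variant_id": v.id,
                                "cell_line": cell,
                                "dataset_id": dataset,
                                "protein": protein,
                                "replicate": rep,
                                "reads_allele1": a,
                                "reads_allele2": n_reads - a,
                                "het": True,
                                "in_peak": True,
                            }
                        )
    cols = ["variant_id", "cell_line", "dataset_id", "protein", "replicate",
            "reads_allele1", "reads_allele2", "het", "in_peak"]
    return pd.DataFrame(rows, columns=cols), pd.DataFrame(truth_rows)


def gen_chipseq_data(
    variants: Sequence[VariantRecord],
    seed: int | None = None,
    n_datasets: int = 10,
    p_target: float = 0.5,
    p_background: float = 0.1,
    target_ids: frozenset | set = frozenset(),
    allelic_ratios: Mapping[str, float] | None = None,
    **allelic_kwargs,
) -> SimulatedChip:
    """Peak sets plus allele-specific read counts (two seeded sub-streams)."""
    ss = np.random.SeedSequence(seed)
    peak_seed, read_seed = ss.spawn(2)
    peak_sets, peak_truth = gen_peaksets(
        variants, np.random.default_rng(peak_seed), n_datasets=n_datasets,
        p_target=p_target, p_background=p_background, target_ids=target_ids,
    )
    reads, read_truth = gen_allelic_reads(
        variants, np.random.default_rng(read_seed), ratios=allelic_ratios,
        **allelic_kwargs,
    )
    truth = peak_truth.merge(read_truth, on="variant_id", how="outer")
    return SimulatedChip(peak_sets, reads, truth)


# ---------------------------------------------------------------------------
# Annotation tables


def gen_annotation_tables(
    variants: Sequence[VariantRecord],
    tier_spec: Mapping[str, int],
    locus_length: int = 3000,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Loop and eQTL pair tables plus a gene table reproducing ``tier_spec``.

    Every chromosome gets two genes; tier 1 variants loop to and are eQTLs
    for the same gene, tier 2 only eQTL, tier 3 only loop, tier 4 neither.
    """
    chroms = sorted({v.chrom for v in variants})
    gene_rows = []
    gene_of: dict[str, str] = {}
    for chrom in chroms:
        g1, g2 = f"GENE_{chrom}_1", f"GENE_{chrom}_2"
        gene_rows.append({"chrom": chrom, "start": 100, "end": 600, "gene": g1})
        gene_rows.append(
            {"chrom": chrom, "start": locus_length - 600,
             "end": locus_length - 100, "gene": g2}
        )
        gene_of[chrom] = g1
    loop_rows, eqtl_rows = [], []
    for v in variants:
        tier = int(tier_spec.get(v.id, 4))
        gene = gene_of[v.chrom]
        if tier == 1:
            loop_rows.append({"variant_id": v.id, "gene": gene})
            eqtl_rows.append({"variant_id": v.id, "gene": gene})
        elif tier == 2:
            eqtl_rows.append({"variant_id": v.id, "gene": gene})
        elif tier == 3:
            loop_rows.append({"variant_id": v.id, "gene": gene})
        elif tier != 4:
            raise ValueError(f"invalid tier {tier} for {v.id}")
    cols = ["variant_id", "gene"]
    return (
        pd.DataFrame(loop_rows, columns=cols),
        pd.DataFrame(eqtl_rows, columns=cols),
        pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "gene"]),
    )


# ---------------------------------------------------------------------------
# Motifs


def gen_pwms(
    n: int,
    seed: int | None = None,
    width: int = 8,
    concentration: float = 0.85,
    sharp_center: float = 0.997,
    family_size: int = 2,
) -> list[PWM]:
    """Random informative motifs with a highly informative central column.

    With the default concentrations, a sequence carrying the full consensus
    scores 100% relative while a single mismatch at the central column drops
    below the 40% weak-site cutoff, so planted variants create clean
    binding-site altering events.
    """
    rng = np.random.default_rng(seed)
    pwms = []
    for i in range(n):
        cons = rng.integers(0, 4, size=width)
        mat = np.full((width, 4), (1.0 - concentration) / 3.0)
        mat[np.arange(width), cons] = concentration
        center = width // 2
        mat[center] = (1.0 - sharp_center) / 3.0
        mat[center, cons[center]] = sharp_center
        pwms.append(
            PWM(f"TF{i + 1:02d}", mat, family=f"FAM{i // family_size + 1}")
        )
    return pwms
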