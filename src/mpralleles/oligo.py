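"""Design of allele-specific reporter-assay oligos.

Each candidate variant is turned into one test sequence per allele: a fixed
amount of genomic flank on either side with the allele substituted in the
middle, plus two fixed 15-base synthesis adapters.  For a SNP the genomic core
is exactly 170 bases (84 upstream of the variant base, 85 downstream) so the
adapter-flanked oligo is 200 bases.  For indels the flanks are chosen so that
the *longest* allele reaches 170 bases and every allele of the variant shares
byte-identical flanks.

Coordinates follow the VCF convention on input (1-based, ``pos`` is the first
reference base of the variant) and are converted to 0-based half-open
internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ADAPTER_5 = "ACTGGCCGCTTGACG"
ADAPTER_3 = "CACTGCGGCTCCTGC"
CORE_LENGTH = 170
UPSTREAM_FLANK = 84

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_SEQ = re.compile(r"^[ACGT]+$")


class ValidationError(ValueError):
    """Malformed variant, allele, or sequence input."""


class BoundaryError(ValueError):
    """Variant lies too close to a chromosome end for full flanks."""


def _check_seq(seq: str, what: str = "sequence") -> str:
    if not isinstance(seq, str) or not seq:
        raise ValidationError(f"{what} must be a non-empty string")
    if not _VALID_SEQ.match(seq):
        raise ValidationError(f"{what} contains non-ACGT characters: {seq!r}")
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGT string (an involution)."""
    _check_seq(seq)
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class VariantRecord:
    """One candidate risk variant with its alleles and genomic context."""

    id: str
    chrom: str
    pos: int  # 1-based position of the first reference base
    ref: str
    alts: tuple[str, ...]
    risk_allele: str | None = None
    locus_id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValidationError(f"{self.id}: pos must be >= 1, got {self.pos}")
        object.__setattr__(self, "alts", tuple(self.alts))
        if not self.alts:
            raise ValidationError(f"{self.id}: at least one alternative allele required")
        _check_seq(self.ref, f"{self.id} ref allele")
        for a in self.alts:
            _check_seq(a, f"{self.id} alt allele")
        alleles = (self.ref, *self.alts)
        if len(set(alleles)) != len(alleles):
            raise ValidationError(f"{self.id}: alleles must be pairwise distinct: {alleles}")

    @property
    def alleles(self) -> tuple[str, ...]:
        """Reference allele first, then alternatives in input order."""
        return (self.ref, *self.alts)

    @property
    def start(self) -> int:
        """0-based start of the reference span."""
        return self.pos - 1

    @property
    def end(self) -> int:
        """0-based half-open end of the reference span."""
        return self.pos - 1 + len(self.ref)


@dataclass(frozen=True)
class OligoRecord:
    """A designed allele-specific test sequence."""

    variant_id: str
    allele: str
    core_seq: str
    full_seq: str
    orientation: str  # "forward" | "reverse_complement"

    @property
    def oligo_id(self) -> str:
        """Orientation-free identifier (forward/revcomp pairs share it)."""
        return f"{self.variant_id}|{self.allele}"

    @property
    def record_id(self) -> str:
        return f"{self.variant_id}|{self.allele}|{self.orientation}"


def _fetch(genome: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """Uppercased slice of a chromosome from a dict of strings or a pyfaidx Fasta."""
    try:
        seq = genome[chrom]
    except KeyError as exc:
        raise ValidationError(f"chromosome {chrom!r} absent from genome") from exc
    return str(seq[start:end]).upper()


def _chrom_length(genome: Mapping[str, object], chrom: str) -> int:
    return len(genome[chrom])


def add_adapters(core_seq: str) -> str:
    """Flank a genomic core with the two fixed 15-base synthesis adapters."""
    _check_seq(core_seq, "core sequence")
    return ADAPTER_5 + core_seq + ADAPTER_3


def extract_context(
    variant: VariantRecord,
    genome: Mapping[str, object],
    core_length: int = CORE_LENGTH,
    upstream: int = UPSTREAM_FLANK,
) -> list[OligoRecord]:
    """Forward-orientation oligos for every allele of one variant.

    The first base of the longest allele sits at core position ``upstream``
    (0-based); the downstream flank is truncated so the longest allele's core
    is exactly ``core_length``.  All alleles share identical flanks.
    """
    max_len = max(len(a) for a in variant.alleles)
    right_len = core_length - upstream - max_len
    if right_len < 0:
        raise ValidationError(
            f"{variant.id}: allele length {max_len} exceeds available core space"
        )
    v0 = variant.start
    if v0 - upstream < 0:
        raise BoundaryError(f"{variant.id}: fewer than {upstream} bases upstream")
    if variant.end + right_len > _chrom_length(genome, variant.chrom):
        raise BoundaryError(f"{variant.id}: fewer than {right_len} bases downstream")
    left = _fetch(genome, variant.chrom, v0 - upstream, v0)
    right = _fetch(genome, variant.chrom, variant.end, variant.end + right_len)
    _check_seq(left, f"{variant.id} upstream flank")
    if right_len:
        _check_seq(right, f"{variant.id} downstream flank")
    genome_ref = _fetch(genome, variant.chrom, v0, variant.end)
    if genome_ref != variant.ref:
        raise ValidationError(
            f"{variant.id}: ref allele {variant.ref!r} does not match genome {genome_ref!r}"
        )
    records = []
    for allele in variant.alleles:
        core = left + allele + right
        records.append(
            OligoRecord(variant.id, allele, core, add_adapters(core), "forward")
        )
    return records


def design_library(
    variants: Iterable[VariantRecord],
    genome: Mapping[str, object],
    both_orientations: bool = True,
) -> list[OligoRecord]:
    """Forward (and optionally reverse-complement) oligos for a variant set."""
    oligos: list[OligoRecord] = []
    for variant in variants:
        fwd = extract_context(variant, genome)
        oligos.extend(fwd)
        if both_orientations:
            for rec in fwd:
                rc = reverse_complement(rec.core_seq)
                oligos.append(
                    OligoRecord(
                        rec.variant_id, rec.allele, rc, add_adapters(rc),
                        "reverse_complement",
                    )
                )
    return oligos


# ---------------------------------------------------------------------------
# I/O


def read_variants_tsv(path: str | Path) -> list[VariantRecord]:
    """Variant table: columns id, chrom, pos, ref, alts (comma-separated),
    optional risk_allele and locus_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "chrom", "pos", "ref", "alts"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"variant table missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        risk = getattr(row, "risk_allele", None)
        locus = getattr(row, "locus_id", None)
        out.append(
            VariantRecord(
                id=row.id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alts=tuple(str(row.alts).split(",")),
                risk_allele=None if pd.isna(risk) else risk,
                locus_id=None if pd.isna(locus) else str(locus),
            )
        )
    return out


def read_variants_vcf(path: str | Path) -> list[VariantRecord]:
    """Convert a VCF into variant records (ID field used as identifier)."""
    from cyvcf2 import VCF

    out = []
    for v in VCF(str(path)):
        out.append(
            VariantRecord(
                id=v.ID or f"{v.CHROM}:{v.POS}",
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
            )
        )
    return out


def write_design_fasta(oligos: Sequence[OligoRecord], path: str | Path) -> None:
    """Adapter-flanked sequences, record id ``variant|allele|orientation``."""
    with open(path, "w") as fh:
        for rec in oligos:
            fh.write(f">{rec.record_id}\n{rec.full_seq}\n")


def design_manifest(oligos: Sequence[OligoRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo_id": [o.oligo_id for o in oligos],
            "variant_id": [o.variant_id for o in oligos],
            "allele": [o.allele for o in oligos],
            "orientation": [o.orientation for o in oligos],
            "core_seq": [o.core_seq for o in oligos],
            "full_seq": [o.full_seq for o in oligos],
        }
    )


def write_design_manifest(oligos: Sequence[OligoRecord], path: str | Path) -> None:
    design_manifest(oligos).to_csv(path, sep="\t", index=False)
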