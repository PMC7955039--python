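"""Barcode-to-oligo association and oligo-level count matrices.

Reporter mRNA and plasmid libraries are read out by sequencing a random
20-base barcode placed in the reporter 3' UTR.  A read is accepted when the
constant region 3' of the barcode matches the reference constant region with
Levenshtein distance <= 4 and the two bases immediately adjacent to the
barcode match exactly.  Barcodes mapping to more than one oligo are dropped;
accepted barcodes are summed to the oligo level, and oligos with fewer than 30
distinct barcodes in the plasmid control are excluded.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import edlib
import pandas as pd

BARCODE_LENGTH = 20
MIN_BARCODES = 30
MAX_CONSTANT_DISTANCE = 4

ROLE_PLASMID = "plasmid_DNA"
ROLE_MRNA = "mRNA"


@dataclass(frozen=True)
class MatchResult:
    """Outcome of screening one read for a usable barcode."""

    barcode: str | None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.barcode is not None


def match_constant_region(
    read: str,
    constant_ref: str,
    barcode_length: int = BARCODE_LENGTH,
    max_distance: int = MAX_CONSTANT_DISTANCE,
) -> MatchResult:
    """Extract the barcode from a read, or reject it.

    The read layout is ``[barcode][constant region...]``; the first two bases
    of ``constant_ref`` are the bases directly adjacent to the barcode and
    must match exactly, and the whole constant segment must be within
    ``max_distance`` Levenshtein edits of the reference.
    """
    if len(constant_ref) < 2:
        raise ValueError("constant reference must include the two adjacent bases")
    if len(read) < barcode_length + 2:
        return MatchResult(None, "too_short")
    barcode = read[:barcode_length]
    segment = read[barcode_length : barcode_length + len(constant_ref)]
    if segment[:2] != constant_ref[:2]:
        return MatchResult(None, "adjacent_mismatch")
    dist = edlib.align(segment, constant_ref, mode="NW", task="distance")["editDistance"]
    if dist > max_distance:
        return MatchResult(None, "constant_mismatch")
    return MatchResult(barcode)


def build_barcode_map(observations: Iterable[tuple[str, str]]) -> dict[str, str]:
    """Barcode -> oligo map keeping only uniquely mapped barcodes.

    ``observations`` are (barcode, oligo record id) pairs, typically
    ``variant|allele|orientation``.  A barcode seen with two or more distinct
    oligos is discarded entirely.
    """
    seen: dict[str, str] = {}
    ambiguous: set[str] = set()
    for barcode, oligo in observations:
        if barcode in ambiguous:
            continue
        prev = seen.get(barcode)
        if prev is None:
            seen[barcode] = oligo
        elif prev != oligo:
            del seen[barcode]
            ambiguous.add(barcode)
    return seen


def _strip_orientation(oligo_record_id: str) -> str:
    """Merge forward/reverse-complement records of one allele into one row."""
    parts = oligo_record_id.split("|")
    if len(parts) >= 3 and parts[-1] in ("forward", "reverse_complement"):
        return "|".join(parts[:-1])
    return oligo_record_id


@dataclass
class CountMatrix:
    """Oligo x sample barcode-summed counts with sample metadata.

    ``counts``: DataFrame indexed by oligo id (``variant|allele``), one column
    per sample.  ``samples``: DataFrame indexed by sample name with columns
    ``role`` (plasmid_DNA / mRNA) and ``replicate``.  ``barcode_multiplicity``:
    distinct barcodes per oligo observed in the plasmid control.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    barcode_multiplicity: pd.Series | None = None
    unmapped: dict[str, int] = field(default_factory=dict)
    filters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)}")

    @property
    def roles(self) -> pd.Series:
        return self.samples.loc[self.counts.columns, "role"]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        out = self.counts.copy()
        out.index.name = "oligo_id"
        if self.barcode_multiplicity is not None:
            out = out.join(self.barcode_multiplicity.rename("n_barcodes"))
        out.to_csv(path, sep="\t")
        sidecar = {
            "samples": {
                s: {"role": r.role, "replicate": int(r.replicate)}
                for s, r in self.samples.iterrows()
            },
            "unmapped": self.unmapped,
            "filters": self.filters,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1, sort_keys=True)
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", index_col="oligo_id")
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        mult = None
        if "n_barcodes" in df.columns:
            mult = df.pop("n_barcodes")
        samples = pd.DataFrame.from_dict(meta["samples"], orient="index")
        return cls(df, samples, mult, meta.get("unmapped", {}), meta.get("filters", {}))


def count_barcodes(
    barcode_counts: pd.DataFrame,
    barcode_map: Mapping[str, str],
    samples: pd.DataFrame,
    min_barcodes: int = MIN_BARCODES,
) -> CountMatrix:
    """Sum mapped barcodes to oligo level and apply the plasmid barcode filter.

    ``barcode_counts`` is a long table with columns barcode, sample, count.
    Forward and reverse-complement oligos of one allele are summed into a
    single row.  Oligos whose number of distinct barcodes in the plasmid
    control falls below ``min_barcodes`` are excluded.
    """
    if not barcode_map:
        raise ValueError("barcode map is empty")
    required = {"barcode", "sample", "count"}
    if not required <= set(barcode_counts.columns):
        raise ValueError(f"barcode table needs columns {sorted(required)}")
    df = barcode_counts.copy()
    mapped_oligo = df["barcode"].map(
        {b: _strip_orientation(o) for b, o in barcode_map.items()}
    )
    unmapped_mask = mapped_oligo.isna()
    unmapped = (
        df.loc[unmapped_mask].groupby("sample", observed=True)["count"].sum().astype(int).to_dict()
    )
    df = df.loc[~unmapped_mask].assign(oligo_id=mapped_oligo[~unmapped_mask])

    counts = (
        df.pivot_table(
            index="oligo_id", columns="sample", values="count", aggfunc="sum", fill_value=0, observed=True
        )
        .reindex(columns=samples.index, fill_value=0)
        .astype(int)
    )
    counts.columns.name = None

    plasmid_samples = samples.index[samples["role"] == ROLE_PLASMID]
    in_plasmid = df["sample"].isin(plasmid_samples) & (df["count"] > 0)
    multiplicity = (
        df.loc[in_plasmid].groupby("oligo_id", observed=True)["barcode"].nunique()
        .reindex(counts.index, fill_value=0)
        .rename("n_barcodes")
    )
    keep = multiplicity >= min_barcodes
    counts = counts.loc[keep].sort_index()
    multiplicity = multiplicity.loc[keep].sort_index()

    zero_cols = [c for c in counts.columns if counts[c].sum() == 0]
    if zero_cols:
        import warnings

        warnings.warn(f"samples with zero mapped barcodes: {zero_cols}", stacklevel=2)

    return CountMatrix(
        counts=counts,
        samples=samples,
        barcode_multiplicity=multiplicity,
        unmapped={str(k): int(v) for k, v in unmapped.items()},
        filters={"min_barcodes": int(min_barcodes)},
    )


def barcodes_from_reads(
    reads: Iterable[str], constant_ref: str, **kwargs
) -> tuple[Counter, Counter]:
    """Screen raw reads; returns (accepted barcode counts, rejection reasons)."""
    accepted: Counter = Counter()
    rejected: Counter = Counter()
    for read in reads:
        res = match_constant_region(read, constant_ref, **kwargs)
        if res.accepted:
            accepted[res.barcode] += 1
        else:
            rejected[res.reason] += 1
    return accepted, rejected
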