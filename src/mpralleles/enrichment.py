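"""Resampling-based enrichment of a variant set within genomic peak sets.

For each peak dataset, the observed number of input loci overlapping a peak
(by at least one base) is compared with a null distribution obtained by
repeatedly sampling the same number of loci, without replacement, from a
matched negative set (2000 iterations by default).  The resulting z-score
yields a one-sided upper-tail p-value; across a batch of datasets a
Bonferroni correction is applied.

All intervals are 0-based half-open; variants are treated as 1-base loci
(indels as their reference span).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

N_ITERATIONS = 2000

Region = tuple[str, int, int]


class PeakSet:
    """A named set of genomic intervals with fast point/interval overlap."""

    def __init__(self, name: str, intervals: Iterable[Region]):
        self.name = name
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        n = 0
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"{name}: empty interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
            n += 1
        self.n_intervals = n
        # merge per chromosome so overlap queries are a single bisect
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            starts, ends = [], []
            for s, e in ivs:
                if ends and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged[chrom] = (np.asarray(starts), np.asarray(ends))

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "PeakSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
                         names=["chrom", "start", "end"], dtype={0: str})
        return cls(name or path.stem, df.itertuples(index=False, name=None))

    def overlaps(self, regions: Sequence[Region]) -> np.ndarray:
        """Boolean array: does each region intersect >= 1 peak by >= 1 base."""
        out = np.zeros(len(regions), dtype=bool)
        for i, (chrom, start, end) in enumerate(regions):
            merged = self._merged.get(chrom)
            if merged is None:
                continue
            starts, ends = merged
            idx = np.searchsorted(starts, end, side="left")
            out[i] = idx > 0 and ends[idx - 1] > start
        return out


def as_regions(variants) -> list[Region]:
    """Normalize inputs to 0-based half-open regions.

    Accepts (chrom, start, end) triples, VariantRecord-like objects (with
    chrom/start/end), or a DataFrame with chrom/start/end columns.
    """
    if isinstance(variants, pd.DataFrame):
        return list(
            variants[["chrom", "start", "end"]].itertuples(index=False, name=None)
        )
    out = []
    for v in variants:
        if isinstance(v, tuple):
            out.append((v[0], int(v[1]), int(v[2])))
        else:
            out.append((v.chrom, v.start, v.end))
    return out


def count_overlap(variants, peaks: PeakSet) -> int:
    """Number of input regions intersecting at least one peak (each counted once)."""
    return int(peaks.overlaps(as_regions(variants)).sum())


@dataclass
class EnrichmentResult:
    dataset: str
    n_input: int
    observed: int
    expected_mean: float
    expected_sd: float
    z_score: float
    p_value: float
    fold: float
    degenerate: bool = False
    p_corrected: float | None = None


def reli_enrichment(
    input_set,
    negative_set,
    peaks: PeakSet,
    n_iter: int = N_ITERATIONS,
    seed: int | np.random.Generator | None = None,
) -> EnrichmentResult:
    """Resampling enrichment of ``input_set`` in ``peaks`` against a negative set.

    Each iteration draws ``len(input_set)`` loci without replacement from the
    negative set; the distribution of their overlap counts provides the null
    mean and sd for a one-sided z-test.
    """
    input_regions = as_regions(input_set)
    neg_regions = as_regions(negative_set)
    n_input = len(input_regions)
    if len(neg_regions) < n_input:
        raise ValueError("negative set smaller than the input set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = int(peaks.overlaps(input_regions).sum())
    neg_in_peak = peaks.overlaps(neg_regions)
    n_neg = len(neg_regions)
    counts = np.empty(n_iter, dtype=np.int64)
    for i in range(n_iter):
        idx = rng.choice(n_neg, size=n_input, replace=False)
        counts[i] = neg_in_peak[idx].sum()
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))

    degenerate = sd == 0.0
    if degenerate:
        z = 0.0 if observed == mean else np.inf * np.sign(observed - mean)
        p = 1.0 if observed <= mean else 1.0 / n_iter
    else:
        z = (observed - mean) / sd
        p = float(stats.norm.sf(z))
    fold = observed / mean if mean > 0 else (np.inf if observed > 0 else 0.0)
    if observed == 0:
        fold = 0.0
    return EnrichmentResult(
        dataset=peaks.name,
        n_input=n_input,
        observed=observed,
        expected_mean=mean,
        expected_sd=sd,
        z_score=float(z),
        p_value=float(p),
        fold=float(fold),
        degenerate=degenerate,
    )


def reli_batch(
    input_set,
    negative_set,
    peak_sets: Sequence[PeakSet],
    n_iter: int = N_ITERATIONS,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the enrichment test over many datasets with Bonferroni correction.

    The correction count is the number of datasets actually tested.  Each
    dataset gets its own child RNG stream derived from ``seed`` so results do
    not depend on dataset order.
    """
    import zlib

    results = []
    for peaks in peak_sets:
        child = np.random.SeedSequence(
            [0 if seed is None else int(seed), zlib.crc32(peaks.name.encode())]
        )
        results.append(
            reli_enrichment(
                input_set, negative_set, peaks, n_iter,
                np.random.default_rng(child),
            )
        )
    n_datasets = len(results)
    rows = []
    for r in results:
        r.p_corrected = min(1.0, r.p_value * n_datasets)
        rows.append(vars(r).copy())
    df = pd.DataFrame(rows).sort_values(
        ["p_corrected", "p_value", "dataset"], ignore_index=True
    )
    return df


def read_regions(path: str | Path) -> list[Region]:
    """Variant loci from a BED3 file or a TSV with chrom/start/end columns."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = [c.lower() for c in df.columns]
    if {"chrom", "start", "end"} <= set(cols):
        df.columns = cols
    else:  # headerless BED
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        df = df.iloc[:, :3]
        df.columns = ["chrom", "start", "end"]
    return as_regions(df[["chrom", "start", "end"]])
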