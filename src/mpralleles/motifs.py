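"""PWM scanning, binding-site altering events, and TF classification.

Windows are scored with the log2-likelihood system, sum over positions of
log2(p_base / background_base).  Because raw score ranges depend on a motif's
information content, scores are expressed as a *relative score*: the
percentage of the motif's maximum achievable log-likelihood score (negative
scores are kept negative rather than clamped).  A binding-site altering event
for a motif at a variant is one allele scoring >= 70% relative while the
other scores < 40%, with the scored windows restricted to those overlapping
the variant base(s).

An allelically bound TF whose motif has an altering event at the variant is a
*variant overlapping* TF; an allelically bound TF without one is a *variant
adjacent* TF.  Family-level enrichments compare event fractions between
variant sets with a two-sided two-proportion z-test; the variant-adjacent
analysis uses dinucleotide-shuffled input sequences as background.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .oligo import reverse_complement

STRONG_SCORE = 70.0
WEAK_SCORE = 40.0
PAD = 25
MIN_EVENTS = 3
MIN_SITES = 5
FAMILY_PADJ = 1e-4
PSEUDOCOUNT = 1e-3

_ALPHABET = "ACGT"
_IDX = {c: i for i, c in enumerate(_ALPHABET)}


def encode(seq: str) -> np.ndarray:
    try:
        return np.array([_IDX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT character in sequence: {exc}") from exc


class PWM:
    """A position weight matrix with log2-likelihood scoring.

    ``matrix`` is (width, 4) base probabilities over ACGT per position;
    a pseudocount is added and rows renormalized so all probabilities are
    positive.  ``background`` defaults to uniform 0.25.
    """

    def __init__(
        self,
        tf_name: str,
        matrix,
        family: str | None = None,
        background=None,
        pseudocount: float = PSEUDOCOUNT,
    ):
        mat = np.asarray(matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[1] != 4:
            raise ValueError("matrix must be (width, 4) over ACGT")
        if mat.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if (mat < 0).any():
            raise ValueError("probabilities must be non-negative")
        mat = mat + pseudocount
        mat = mat / mat.sum(axis=1, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
        bg = bg / bg.sum()
        if (bg <= 0).any():
            raise ValueError("background frequencies must be positive")
        self.tf_name = tf_name
        self.family = family if family is not None else tf_name
        self.matrix = mat
        self.background = bg
        self.log_odds = np.log2(mat / bg)
        self.max_score = float(self.log_odds.max(axis=1).sum())

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.log_odds.argmax(axis=1))

    def __repr__(self) -> str:  # pragma: no cover
        return f"PWM({self.tf_name}, width={self.width}, family={self.family})"


@dataclass(frozen=True)
class MotifHit:
    """Best-scoring window of one motif in one sequence."""

    tf_name: str
    sequence_id: str | None
    offset: int  # 0-based window start on the forward sequence
    strand: str  # "+" | "-"
    width: int
    score_bits: float
    relative_score: float

    @property
    def center(self) -> float:
        return self.offset + self.width / 2.0


def loglik_score(pwm: PWM, window: str, strand: str = "+") -> float:
    """Log2-likelihood score of one window (reverse strand scores the
    reverse complement)."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != motif width {pwm.width}")
    if strand == "-":
        window = reverse_complement(window)
    idx = encode(window)
    return float(pwm.log_odds[np.arange(pwm.width), idx].sum())


def scan_scores(pwm: PWM, seq: str) -> tuple[np.ndarray, np.ndarray]:
    """Scores of every window on both strands.

    Returns (forward, reverse) arrays indexed by window start on the forward
    sequence; reverse-strand scores are of the window's reverse complement.
    """
    enc = encode(seq)
    w = pwm.width
    if len(enc) < w:
        raise ValueError("sequence shorter than motif width")
    windows = np.lib.stride_tricks.sliding_window_view(enc, w)
    pos = np.arange(w)
    fwd = pwm.log_odds[pos[None, :], windows].sum(axis=1)
    rc_windows = 3 - windows[:, ::-1]
    rev = pwm.log_odds[pos[None, :], rc_windows].sum(axis=1)
    return fwd, rev


def best_hit(
    pwm: PWM,
    seq: str,
    sequence_id: str | None = None,
    variant_span: tuple[int, int] | None = None,
    restrict_to_variant: bool = False,
) -> MotifHit | None:
    """Best window over both strands, optionally restricted to windows that
    overlap the variant span (0-based half-open in sequence coordinates).
    Ties prefer the forward strand, then the leftmost offset."""
    if pwm.max_score <= 0:
        raise ValueError(f"uninformative PWM {pwm.tf_name}: max score <= 0")
    fwd, rev = scan_scores(pwm, seq)
    n = len(fwd)
    if restrict_to_variant:
        if variant_span is None:
            raise ValueError("variant_span required when restricting windows")
        vs, ve = variant_span
        starts = np.arange(n)
        mask = (starts < ve) & (starts + pwm.width > vs)
        if not mask.any():
            return None
        fwd = np.where(mask, fwd, -np.inf)
        rev = np.where(mask, rev, -np.inf)
    if fwd.max() >= rev.max():
        strand, offset, score = "+", int(fwd.argmax()), float(fwd.max())
    else:
        strand, offset, score = "-", int(rev.argmax()), float(rev.max())
    return MotifHit(
        tf_name=pwm.tf_name,
        sequence_id=sequence_id,
        offset=offset,
        strand=strand,
        width=pwm.width,
        score_bits=score,
        relative_score=100.0 * score / pwm.max_score,
    )


def relative_best_score(
    pwm: PWM,
    seq: str,
    variant_span: tuple[int, int] | None = None,
    restrict_to_variant: bool = False,
) -> float:
    """Best relative score (percent of the motif's maximum achievable score).

    May be negative for poor matches; only the >=70 / <40 comparisons matter
    downstream."""
    hit = best_hit(pwm, seq, None, variant_span, restrict_to_variant)
    if hit is None:
        raise ValueError("no window overlaps the variant span")
    return hit.relative_score


@dataclass(frozen=True)
class AlteringEvent:
    """A motif created or broken by a variant: one allele scores >= 70%
    relative, the other < 40%, in windows overlapping the variant."""

    variant_id: str
    tf_name: str
    family: str
    strong_allele: str
    weak_allele: str
    strong_score: float
    weak_score: float


def detect_altering_events(
    variant_id: str,
    allele_seqs: Mapping[str, tuple[str, tuple[int, int]]],
    pwms: Sequence[PWM],
    strong: float = STRONG_SCORE,
    weak: float = WEAK_SCORE,
) -> list[AlteringEvent]:
    """Binding-site altering events over all motifs and allele pairs.

    ``allele_seqs`` maps allele -> (padded sequence, variant span within it).
    Events are symmetric in allele ordering: each unordered pair yields at
    most one event per motif.
    """
    if len(allele_seqs) < 2:
        raise ValueError("need at least two alleles")
    events = []
    for pwm in pwms:
        scores = {}
        for allele, (seq, span) in allele_seqs.items():
            hit = best_hit(pwm, seq, None, span, restrict_to_variant=True)
            scores[allele] = hit.relative_score if hit is not None else -np.inf
        alleles = sorted(scores)
        for i in range(len(alleles)):
            for j in range(i + 1, len(alleles)):
                a, b = alleles[i], alleles[j]
                hi_allele, lo_allele = (a, b) if scores[a] >= scores[b] else (b, a)
                hi, lo = scores[hi_allele], scores[lo_allele]
                if hi >= strong and lo < weak:
                    events.append(
                        AlteringEvent(
                            variant_id=variant_id,
                            tf_name=pwm.tf_name,
                            family=pwm.family,
                            strong_allele=hi_allele,
                            weak_allele=lo_allele,
                            strong_score=float(hi),
                            weak_score=float(lo),
                        )
                    )
    return events


def classify_tfs(
    variant_id: str,
    allelic_proteins: Iterable[str],
    events: Sequence[AlteringEvent],
    pwms: Sequence[PWM],
) -> pd.DataFrame:
    """Classify allelically bound TFs as variant overlapping or adjacent.

    A TF with allelic ChIP-seq reads and an altering event for any of its
    motifs is variant overlapping; with allelic reads but no event it is
    variant adjacent (TFs lacking any motif in the collection are flagged).
    TFs without allelic reads are not classified.
    """
    event_tfs = {e.tf_name.upper() for e in events if e.variant_id == variant_id}
    motif_tfs = {p.tf_name.upper() for p in pwms}
    rows = []
    for protein in sorted(set(allelic_proteins)):
        key = protein.upper()
        rows.append(
            {
                "variant_id": variant_id,
                "tf": protein,
                "classification": (
                    "variant_overlapping" if key in event_tfs else "variant_adjacent"
                ),
                "has_motif": key in motif_tfs,
            }
        )
    return pd.DataFrame(
        rows, columns=["variant_id", "tf", "classification", "has_motif"]
    )


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Two-sided two-proportion z-test (pooled variance)."""
    if n1 == 0 or n2 == 0:
        raise ValueError("zero denominator")
    p1, p2 = k1 / n1, k2 / n2
    pool = (k1 + k2) / (n1 + n2)
    var = pool * (1 - pool) * (1 / n1 + 1 / n2)
    if var == 0:
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _family_fraction_table(
    fg: Mapping[str, int], n_fg: int, bg: Mapping[str, int], n_bg: int,
    min_count: int, padj_threshold: float, count_col: str,
) -> pd.DataFrame:
    families = sorted(set(fg) | set(bg))
    rows = []
    for fam in families:
        k1, k2 = fg.get(fam, 0), bg.get(fam, 0)
        if n_fg == 0 or n_bg == 0:
            continue
        z, p = two_proportion_ztest(k1, n_fg, k2, n_bg)
        rows.append(
            {
                "family": fam,
                count_col: k1,
                "fraction_fg": k1 / n_fg,
                "fraction_bg": k2 / n_bg,
                "z": z,
                "p_value": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["family", count_col, "fraction_fg", "fraction_bg", "z", "p_value"]
    )
    if len(table):
        table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["reported"] = (table[count_col] >= min_count) & (
            table["p_adj"] < padj_threshold
        )
        table = table.sort_values(["p_adj", "family"], ignore_index=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["reported"] = pd.Series(dtype=bool)
    return table


def overlapping_family_enrichment(
    events_fg: Sequence[AlteringEvent],
    n_fg: int,
    events_bg: Sequence[AlteringEvent],
    n_bg: int,
    min_events: int = MIN_EVENTS,
    padj_threshold: float = FAMILY_PADJ,
) -> pd.DataFrame:
    """Motif families enriched for altering events at allelic enhancer
    variants versus non-allelic enhancer variants.

    The per-family fraction is the share of variants in each set with at
    least one altering event for a motif of that family.  The full table is
    returned; rows passing the event-count and p_adj filters are flagged
    ``reported``.
    """

    def per_family(events):
        seen: dict[str, set] = {}
        for e in events:
            seen.setdefault(e.family, set()).add(e.variant_id)
        return {fam: len(v) for fam, v in seen.items()}

    return _family_fraction_table(
        per_family(events_fg), n_fg, per_family(events_bg), n_bg,
        min_events, padj_threshold, "n_events",
    )


def adjacent_motif_enrichment(
    sequences: Mapping[str, str],
    pwms: Sequence[PWM],
    seed: int | np.random.Generator | None = None,
    hit_threshold: float = STRONG_SCORE,
    min_sites: int = MIN_SITES,
    padj_threshold: float = FAMILY_PADJ,
) -> pd.DataFrame:
    """Motif families enriched in input sequences versus their dinucleotide
    shuffles.

    A "hit" is any window (either strand) with relative score at or above
    ``hit_threshold``; per family the fraction of sequences containing a hit
    is compared between foreground and the shuffled background.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fg = dict(sequences)
    bg = {sid: dinuc_shuffle(s, rng) for sid, s in fg.items()}

    def per_family(seqs: Mapping[str, str]) -> dict[str, int]:
        fam_hits: dict[str, set] = {}
        for pwm in pwms:
            for sid, s in seqs.items():
                if len(s) < pwm.width:
                    continue
                hit = best_hit(pwm, s, sid)
                if hit.relative_score >= hit_threshold:
                    fam_hits.setdefault(pwm.family, set()).add(sid)
        return {fam: len(v) for fam, v in fam_hits.items()}

    n = len(fg)
    return _family_fraction_table(
        per_family(fg), n, per_family(bg), n, min_sites, padj_threshold, "n_sites"
    )


def dinuc_shuffle(seq: str, seed: int | np.random.Generator | None = None) -> str:
    """Uniform random shuffle preserving exact dinucleotide counts
    (Altschul-Erickson Eulerian-walk shuffle)."""
    if len(seq) < 2:
        raise ValueError("sequence must have length >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(seq) == 2:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    def reaches_last(last_edge: dict[str, str]) -> bool:
        for v in last_edge:
            cur, steps = v, 0
            while cur != last and steps <= len(vertices):
                if cur not in last_edge:
                    return False
                cur = last_edge[cur]
                steps += 1
            if cur != last:
                return False
        return True

    while True:
        last_edge = {
            v: edges[v][rng.integers(len(edges[v]))] for v in vertices if v != last
        }
        if reaches_last(last_edge):
            break

    walk_lists: dict[str, list[str]] = {}
    for v in vertices:
        lst = list(edges[v])
        if v != last:
            lst.remove(last_edge[v])
        rng.shuffle(lst)
        if v != last:
            lst.append(last_edge[v])
        walk_lists[v] = lst

    out = [seq[0]]
    ptr = {v: 0 for v in vertices}
    for _ in range(len(seq) - 1):
        v = out[-1]
        out.append(walk_lists[v][ptr[v]])
        ptr[v] += 1
    return "".join(out)


def hit_position_distribution(
    classification: pd.DataFrame,
    best_hits: Mapping[str, MotifHit],
    variant_center: float,
) -> pd.DataFrame:
    """Offsets of best-hit window centers relative to the variant, per class.

    ``classification`` is the output of :func:`classify_tfs`;
    ``best_hits`` maps TF name -> its best hit in the scanned sequence.
    """
    rows = []
    for row in classification.itertuples(index=False):
        hit = best_hits.get(row.tf)
        if hit is None:
            continue
        rows.append(
            {
                "tf": row.tf,
                "classification": row.classification,
                "center_offset": hit.center - variant_center,
            }
        )
    return pd.DataFrame(rows, columns=["tf", "classification", "center_offset"])


# ---------------------------------------------------------------------------
# I/O


def read_meme(
    path: str | Path,
    families: Mapping[str, str] | None = None,
    pseudocount: float = PSEUDOCOUNT,
) -> list[PWM]:
    """Load a minimal-format MEME motif file (optionally with a TF -> family
    mapping for the metadata the format lacks)."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        name = m.name
        mat = np.column_stack([m.pwm[c] for c in _ALPHABET])
        fam = families.get(name) if families else None
        out.append(PWM(name, mat, family=fam, pseudocount=pseudocount))
    return out


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    lines = [
        "MEME version 4", "",
        "ALPHABET= ACGT", "",
        "strands: + -", "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25", "",
    ]
    for p in pwms:
        lines.append(f"MOTIF {p.tf_name}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {p.width} nsites= 20 E= 0"
        )
        for row in p.matrix:
            lines.append(" " + " ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_matrix_tsv(path: str | Path, **kwargs) -> PWM:
    """Single-motif loader: TSV with columns A, C, G, T, one row per position;
    the file stem is the TF name."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    mat = df[list(_ALPHABET)].to_numpy(dtype=float)
    return PWM(path.stem, mat, **kwargs)
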