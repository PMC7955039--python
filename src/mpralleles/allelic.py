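"""Allelic (genotype-dependent) enhancer activity testing.

Only enhancer variants are tested.  For each allele, every barcode yields a
plasmid-normalized activity ratio

    r_b = log2( (rna_b / sf_rna + pc) / (dna_b / sf_dna + pc) ),   pc = 1,

with mRNA and plasmid counts matched by barcode identity and ratios pooled
across transfection replicates.  Each unordered pair of alleles of an
enhancer variant is compared with a two-sample Student t-test (pooled
variance); p-values are Benjamini-Hochberg adjusted across all tested pairs.
A variant is an allelic enhancer variant when some pair is significant
(p_adj < 0.05) and the activity ratio between the alleles changes by at least
25% (linear fold >= 1.25 or <= 0.8).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import MPRAActivityResults, oligo_variant, size_factors
from .barcodes import ROLE_MRNA, ROLE_PLASMID

PSEUDOCOUNT = 1.0


def normalized_log_ratios(
    rna_counts: np.ndarray,
    dna_counts: np.ndarray,
    sf_rna: float,
    sf_dna: float,
    pseudocount: float = PSEUDOCOUNT,
) -> np.ndarray:
    """Per-barcode plasmid-normalized log2 activity ratios.

    The pseudocount is applied after size-factor scaling, so a barcode with
    rna = 0, dna = 3 and unit size factors gives log2(1/4) = -2.
    """
    rna = np.asarray(rna_counts, dtype=float)
    dna = np.asarray(dna_counts, dtype=float)
    if rna.shape != dna.shape:
        raise ValueError("rna and dna counts must be barcode-matched")
    if rna.size == 0:
        raise ValueError("allele has zero barcodes")
    return np.log2((rna / sf_rna + pseudocount) / (dna / sf_dna + pseudocount))


def _pair_samples(samples: pd.DataFrame) -> list[tuple[str, str]]:
    """Pair each mRNA replicate with the plasmid sample of the same replicate
    index (or the single plasmid control when only one exists)."""
    rna = samples.index[samples["role"] == ROLE_MRNA]
    dna = samples.index[samples["role"] == ROLE_PLASMID]
    if len(rna) == 0 or len(dna) == 0:
        raise ValueError("need both mRNA and plasmid samples")
    if len(dna) == 1:
        return [(r, dna[0]) for r in rna]
    dna_by_rep = {int(samples.loc[d, "replicate"]): d for d in dna}
    pairs = []
    for r in rna:
        rep = int(samples.loc[r, "replicate"])
        if rep not in dna_by_rep:
            raise ValueError(f"no plasmid sample for replicate {rep}")
        pairs.append((r, dna_by_rep[rep]))
    return pairs


class AllelicSkew:
    """Model of between-allele activity differences at enhancer variants.

    Parameters
    ----------
    barcode_counts : DataFrame
        Long table with columns barcode, oligo_id (``variant|allele``),
        sample, count.
    samples : DataFrame
        Indexed by sample name with columns role and replicate.
    en_vars : set
        Variants to test (the enhancer-variant call set).
    allele_order : mapping, optional
        variant id -> allele tuple, reference first; used to orient
        delta_log2 (second vs first allele).  Defaults to sorted order.
    """

    def __init__(
        self,
        barcode_counts: pd.DataFrame,
        samples: pd.DataFrame,
        en_vars: Sequence[str] | frozenset,
        allele_order: Mapping[str, tuple[str, ...]] | None = None,
        pseudocount: float = PSEUDOCOUNT,
    ):
        self.barcode_counts = barcode_counts
        self.samples = samples
        self.en_vars = frozenset(en_vars)
        self.allele_order = dict(allele_order) if allele_order else None
        self.pseudocount = pseudocount

    def _size_factors(self) -> pd.Series:
        oligo = self.barcode_counts.pivot_table(
            index="oligo_id", columns="sample", values="count",
            aggfunc="sum", fill_value=0, observed=True,
        ).reindex(columns=self.samples.index, fill_value=0)
        return size_factors(oligo)

    def ratios(self, size_factors_: pd.Series | None = None) -> pd.DataFrame:
        """Barcode-level log ratios for all enhancer-variant alleles (long)."""
        sf = self._size_factors() if size_factors_ is None else size_factors_
        df = self.barcode_counts
        variant = df["oligo_id"].map(oligo_variant)
        df = df.loc[variant.isin(self.en_vars)]
        out = []
        for rna_s, dna_s in _pair_samples(self.samples):
            rna = df.loc[df["sample"] == rna_s, ["oligo_id", "barcode", "count"]]
            dna = df.loc[df["sample"] == dna_s, ["oligo_id", "barcode", "count"]]
            merged = dna.merge(
                rna, on=["oligo_id", "barcode"], how="left", suffixes=("_dna", "_rna")
            )
            merged["count_rna"] = merged["count_rna"].fillna(0.0)
            merged["ratio"] = normalized_log_ratios(
                merged["count_rna"].to_numpy(),
                merged["count_dna"].to_numpy(),
                sf[rna_s],
                sf[dna_s],
                self.pseudocount,
            )
            merged["replicate"] = rna_s
            out.append(merged[["oligo_id", "barcode", "replicate", "ratio"]])
        return pd.concat(out, ignore_index=True)

    def fit(
        self,
        fc_threshold: float = 1.25,
        padj_threshold: float = 0.05,
        size_factors_: pd.Series | None = None,
    ) -> "AllelicSkewResults":
        ratios = self.ratios(size_factors_)
        grp = ratios.groupby("oligo_id", observed=True)["ratio"]
        summ = grp.agg(n="count", mean="mean", var="var")
        summ["variant_id"] = summ.index.map(oligo_variant)
        summ["allele"] = [o.rsplit("|", 1)[1] for o in summ.index]

        rows = []
        skipped = []
        for variant, sub in summ.groupby("variant_id"):
            alleles = list(sub["allele"])
            if self.allele_order and variant in self.allele_order:
                order = [a for a in self.allele_order[variant] if a in alleles]
                order += sorted(set(alleles) - set(order))
            else:
                order = sorted(alleles)
            sub = sub.set_index("allele").loc[order]
            for i in range(len(order)):
                for j in range(i + 1, len(order)):
                    a1, a2 = order[i], order[j]
                    n1, n2 = int(sub.loc[a1, "n"]), int(sub.loc[a2, "n"])
                    if n1 < 2 or n2 < 2:
                        skipped.append((variant, a1, a2, "too_few_barcodes"))
                        continue
                    m1, m2 = sub.loc[a1, "mean"], sub.loc[a2, "mean"]
                    v1, v2 = sub.loc[a1, "var"], sub.loc[a2, "var"]
                    df_t = n1 + n2 - 2
                    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_t
                    delta = m2 - m1
                    if sp2 == 0:
                        t_stat = 0.0 if delta == 0 else np.inf * np.sign(delta)
                        p = 1.0 if delta == 0 else 0.0
                    else:
                        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
                        t_stat = delta / se
                        p = 2.0 * stats.t.sf(abs(t_stat), df=df_t)
                    rows.append(
                        {
                            "variant_id": variant,
                            "allele_1": a1,
                            "allele_2": a2,
                            "n_1": n1,
                            "n_2": n2,
                            "delta_log2": delta,
                            "fold_between_alleles": 2.0**delta,
                            "t": t_stat,
                            "df": df_t,
                            "p_value": p,
                        }
                    )
        table = pd.DataFrame(
            rows,
            columns=[
                "variant_id", "allele_1", "allele_2", "n_1", "n_2",
                "delta_log2", "fold_between_alleles", "t", "df", "p_value",
            ],
        )
        if len(table):
            table["p_adj"] = multipletests(table["p_value"], method="fdr_bh")[1]
            fold = table["fold_between_alleles"]
            table["is_allelic"] = (table["p_adj"] < padj_threshold) & (
                (fold >= fc_threshold) | (fold <= 1.0 / fc_threshold)
            )
        else:
            table["p_adj"] = pd.Series(dtype=float)
            table["is_allelic"] = pd.Series(dtype=bool)
        return AllelicSkewResults(self, table, skipped,
                                  {"fc_threshold": fc_threshold,
                                   "padj_threshold": padj_threshold})


class AllelicSkewResults:
    """Per-allele-pair t-test results with allelic enVar calls."""

    def __init__(self, model, table: pd.DataFrame, skipped, thresholds):
        self.model = model
        self.table = table
        self.skipped = skipped
        self.thresholds = thresholds

    @property
    def allelic_en_vars(self) -> frozenset:
        if not len(self.table):
            return frozenset()
        return frozenset(self.table.loc[self.table["is_allelic"], "variant_id"])

    def variant_calls(self) -> pd.DataFrame:
        """One row per variant: the most significant pair and the allelic flag."""
        if not len(self.table):
            return pd.DataFrame(
                columns=["variant_id", "allele_1", "allele_2", "delta_log2",
                         "fold_between_alleles", "p_value", "p_adj", "is_allelic"]
            )
        best = (
            self.table.sort_values(["p_adj", "p_value"])
            .groupby("variant_id", as_index=False)
            .first()
        )
        any_allelic = self.table.groupby("variant_id")["is_allelic"].any()
        best["is_allelic"] = best["variant_id"].map(any_allelic)
        return best

    def genotype_dependence(
        self, activity: MPRAActivityResults
    ) -> pd.DataFrame:
        """Per-variant table of max activity vs genotype dependence.

        Genotype dependence is the normalized activity fold change between
        the second (non-reference-like) and first allele of the most
        significant pair; max activity is the largest activity fold change of
        any allele of the variant.
        """
        act = activity.table
        act_var = act.index.map(oligo_variant)
        max_fc = act.groupby(act_var)["fold_change"].max()
        best = self.variant_calls()
        best["max_activity_fold"] = best["variant_id"].map(max_fc)
        best = best.rename(columns={"fold_between_alleles": "genotype_dependence"})
        return best[
            ["variant_id", "allele_1", "allele_2", "max_activity_fold",
             "genotype_dependence", "p_value", "p_adj", "is_allelic"]
        ]

    def summary(self) -> str:
        n_var = self.table["variant_id"].nunique() if len(self.table) else 0
        lines = [
            "Allelic enhancer-activity results",
            "=================================",
            f"enhancer variants tested: {n_var}",
            f"allele pairs tested:      {len(self.table)}",
            f"pairs skipped:            {len(self.skipped)}",
            f"allelic enVars:           {len(self.allelic_en_vars)}",
            f"thresholds:               p_adj < {self.thresholds['padj_threshold']:g}, "
            f"fold >= {self.thresholds['fc_threshold']:g}",
        ]
        return "\n".join(lines)

    def plot(self, activity: MPRAActivityResults, ax=None):
        """Scatter of genotype dependence vs maximum activity per variant."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dep = self.genotype_dependence(activity)
        for flag, sub in dep.groupby("is_allelic"):
            ax.scatter(
                sub["max_activity_fold"], sub["genotype_dependence"],
                label="allelic enVar" if flag else "enVar", s=12,
            )
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("max activity fold change")
        ax.set_ylabel("genotype dependence (allele2 / allele1)")
        ax.legend()
        return ax

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)
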