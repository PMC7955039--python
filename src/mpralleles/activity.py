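"""Enhancer-activity testing: mRNA vs plasmid counts per oligo.

The model is a per-oligo negative-binomial comparison of reporter mRNA
barcode counts against plasmid-input counts across transfection replicates.
Counts are normalized by median-of-ratios size factors; each oligo gets a
log2 fold change (mRNA over plasmid on normalized counts), a Wald-type
statistic with a moment-estimated, floored NB dispersion, and a
Benjamini-Hochberg adjusted p-value.  An allele is an enhancer allele
(enAllele) when p_adj < 0.05 and its activity is at least 1.5-fold; a variant
is an enhancer variant (enVar) when any of its alleles is an enAllele.

Because the dispersion is estimated from a handful of replicates, the Wald
statistic is referred to a Student-t distribution with ``n_samples - 2``
degrees of freedom rather than a normal; with 3+3 replicates a normal
reference would roughly double the nominal type-I error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .barcodes import ROLE_MRNA, ROLE_PLASMID, CountMatrix

LFC_CAP = 10.0  # sentinel magnitude for oligos with zero counts in one group


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one positive scalar per sample).

    factor_j = median over zero-free rows i of count_ij / geomean_i(count).
    """
    mat = counts.to_numpy(dtype=float)
    zero_free = (mat > 0).all(axis=1)
    if not zero_free.any():
        raise ValueError(
            "no row is free of zeros; add a pseudocount or filter low-count oligos"
        )
    sub = mat[zero_free]
    log_geo_mean = np.log(sub).mean(axis=1, keepdims=True)
    factors = np.exp(np.median(np.log(sub) - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


@dataclass
class EnVarCallSet:
    """Enhancer calls at allele and variant level.

    ``non_en_vars`` is the resampling negative set: variants with no allele
    reaching p_adj < 0.05 together with more than a 10% fold change.
    """

    en_vars: frozenset
    en_alleles: frozenset
    non_en_vars: frozenset
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.en_vars & self.non_en_vars)


def oligo_variant(oligo_id: str) -> str:
    """Variant id from an ``variant|allele`` oligo id."""
    return oligo_id.rsplit("|", 1)[0]


class MPRAActivity:
    """Per-oligo enhancer-activity model.

    Parameters
    ----------
    counts : DataFrame
        Oligo x sample integer counts (index ``variant|allele``).
    roles : Mapping or Series
        Sample name -> role, role in {"plasmid_DNA", "mRNA"}.
    """

    def __init__(self, counts: pd.DataFrame, roles: Mapping[str, str] | pd.Series):
        roles = pd.Series(dict(roles) if not isinstance(roles, pd.Series) else roles)
        roles = roles.reindex(counts.columns)
        if roles.isna().any():
            raise ValueError("every sample column needs a role")
        bad = set(roles.unique()) - {ROLE_PLASMID, ROLE_MRNA}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if (roles == ROLE_PLASMID).sum() == 0 or (roles == ROLE_MRNA).sum() == 0:
            raise ValueError("need at least one plasmid and one mRNA sample")
        self.counts = counts
        self.roles = roles

    @classmethod
    def from_count_matrix(cls, cm: CountMatrix) -> "MPRAActivity":
        return cls(cm.counts, cm.roles)

    def fit(
        self,
        dispersion_floor: float = 0.01,
        lfc_cap: float = LFC_CAP,
        size_factors_: pd.Series | None = None,
    ) -> "MPRAActivityResults":
        """Estimate per-oligo fold changes and significance."""
        sf = size_factors(self.counts) if size_factors_ is None else size_factors_
        norm = self.counts.to_numpy(dtype=float) / sf.to_numpy()
        is_rna = (self.roles == ROLE_MRNA).to_numpy()
        rna, dna = norm[:, is_rna], norm[:, ~is_rna]
        n_r, n_d = rna.shape[1], dna.shape[1]

        mu_r, mu_d = rna.mean(axis=1), dna.mean(axis=1)
        base_mean = norm.mean(axis=1)

        # residual (within-group) variance pooled over both groups
        ss = ((rna - mu_r[:, None]) ** 2).sum(axis=1) + (
            (dna - mu_d[:, None]) ** 2
        ).sum(axis=1)
        df_resid = max(n_r + n_d - 2, 1)
        s2 = ss / df_resid

        with np.errstate(divide="ignore", invalid="ignore"):
            disp = (s2 - base_mean) / base_mean**2
        disp = np.where(np.isfinite(disp), disp, dispersion_floor)
        disp = np.maximum(disp, dispersion_floor)

        # delta-method SE of log2(mean ratio) under the NB variance model
        mu_r_safe = np.maximum(mu_r, 0.5)
        mu_d_safe = np.maximum(mu_d, 0.5)
        var_r = mu_r_safe + disp * mu_r_safe**2
        var_d = mu_d_safe + disp * mu_d_safe**2
        se = np.sqrt(
            var_r / (n_r * mu_r_safe**2) + var_d / (n_d * mu_d_safe**2)
        ) / np.log(2.0)

        with np.errstate(divide="ignore"):
            lfc = np.log2(mu_r / mu_d)
        zero_rna = mu_r == 0
        zero_dna = mu_d == 0
        lfc = np.where(zero_rna, -lfc_cap, lfc)
        lfc = np.where(zero_dna & ~zero_rna, lfc_cap, lfc)

        wald = lfc / se
        p = 2.0 * stats.t.sf(np.abs(wald), df=df_resid)
        identical = s2 == 0
        p = np.where(identical & (lfc == 0), 1.0, p)
        p_adj = multipletests(p, method="fdr_bh")[1]

        table = pd.DataFrame(
            {
                "base_mean": base_mean,
                "mean_plasmid": mu_d,
                "mean_mrna": mu_r,
                "log2_fold_change": lfc,
                "fold_change": np.power(2.0, lfc),
                "dispersion": disp,
                "se": se,
                "stat": wald,
                "p_value": p,
                "p_adj": p_adj,
            },
            index=self.counts.index,
        )
        table.index.name = "oligo_id"
        table.loc[zero_rna, "fold_change"] = 0.0
        return MPRAActivityResults(self, table, sf, df_resid)


class MPRAActivityResults:
    """Fitted per-oligo activity estimates with enhancer calling."""

    def __init__(
        self,
        model: MPRAActivity,
        table: pd.DataFrame,
        size_factors: pd.Series,
        df_resid: int,
    ):
        self.model = model
        self.table = table
        self.size_factors = size_factors
        self.df_resid = df_resid

    def call_enhancers(
        self,
        allele_map: Mapping[str, str] | None = None,
        fc_threshold: float = 1.5,
        padj_threshold: float = 0.05,
        negative_fc: float = 1.10,
    ) -> EnVarCallSet:
        """Apply the enAllele / enVar decision thresholds.

        ``allele_map`` maps oligo id -> variant id; by default the variant id
        is taken from the ``variant|allele`` oligo naming.
        """
        t = self.table
        if allele_map is None:
            variants = t.index.map(oligo_variant)
        else:
            variants = t.index.map(lambda o: allele_map[o])
        zero_rna = t["mean_mrna"] == 0
        is_en = (
            (t["p_adj"] < padj_threshold)
            & (t["fold_change"] >= fc_threshold)
            & ~zero_rna
        )
        self.table = t = t.assign(variant_id=variants, is_enAllele=is_en)
        en_alleles = frozenset(t.index[is_en])
        en_vars = frozenset(t.loc[is_en, "variant_id"])
        active = (t["p_adj"] < padj_threshold) & (t["fold_change"] > negative_fc)
        non_en = frozenset(set(t["variant_id"])) - frozenset(
            t.loc[active, "variant_id"]
        )
        return EnVarCallSet(
            en_vars=en_vars,
            en_alleles=en_alleles,
            non_en_vars=frozenset(non_en),
            thresholds={
                "fc_threshold": fc_threshold,
                "padj_threshold": padj_threshold,
                "negative_fc": negative_fc,
            },
        )

    def summary(self, padj_threshold: float = 0.05, fc_threshold: float = 1.5) -> str:
        t = self.table
        n_sig = int((t["p_adj"] < padj_threshold).sum())
        n_en = int(
            ((t["p_adj"] < padj_threshold) & (t["fold_change"] >= fc_threshold)).sum()
        )
        lines = [
            "MPRA enhancer-activity results",
            "==============================",
            f"oligos tested:        {len(t)}",
            f"samples:              {len(self.model.counts.columns)}"
            f" ({int((self.model.roles == ROLE_PLASMID).sum())} plasmid,"
            f" {int((self.model.roles == ROLE_MRNA).sum())} mRNA)",
            f"residual df:          {self.df_resid}",
            f"p_adj < {padj_threshold:g}:         {n_sig}",
            f"enAlleles (fold >= {fc_threshold:g}): {n_en}",
            f"median size factor:   {self.size_factors.median():.3f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None, fc_threshold: float = 1.5, padj_threshold: float = 0.05):
        """Histogram of activity fold changes, enhancer alleles highlighted."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.table
        en = (t["p_adj"] < padj_threshold) & (t["fold_change"] >= fc_threshold)
        bins = np.linspace(t["log2_fold_change"].min(), t["log2_fold_change"].max(), 50)
        ax.hist(t.loc[~en, "log2_fold_change"], bins=bins, label="other", alpha=0.7)
        ax.hist(t.loc[en, "log2_fold_change"], bins=bins, label="enAllele", alpha=0.7)
        ax.set_xlabel("log2 fold change (mRNA / plasmid)")
        ax.set_ylabel("oligos")
        ax.legend()
        return ax

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")
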