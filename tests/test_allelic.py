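"""Allelic-skew model: ratios, t-tests, and allelic enVar calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mpralleles.allelic import AllelicSkew, normalized_log_ratios
from mpralleles.simulate import gen_mpra_counts, gen_reference_and_variants


class TestNormalizedLogRatios:
    def test_equal_counts_give_zero(self):
        r = normalized_log_ratios([5, 9, 100], [5, 9, 100], 1.0, 1.0)
        assert np.allclose(r, 0.0)

    def test_pseudocount_closed_form(self):
        r = normalized_log_ratios([0], [3], 1.0, 1.0)
        assert r[0] == pytest.approx(np.log2(1 / 4))

    def test_twofold_limit_for_large_counts(self):
        r = normalized_log_ratios([2_000_000], [1_000_000], 1.0, 1.0)
        assert r[0] == pytest.approx(1.0, abs=1e-5)

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            normalized_log_ratios([], [], 1.0, 1.0)


def _barcode_frame(allele_counts: dict, n_rep=1, rna_scale=None):
    """allele_counts: oligo_id -> per-barcode plasmid count list."""
    rna_scale = rna_scale or {}
    rows = []
    i = 0
    for oligo, dna in allele_counts.items():
        scale = rna_scale.get(oligo, 1.0)
        for c in dna:
            bc = f"bc{i:05d}"
            for r in range(1, n_rep + 1):
                rows.append({"barcode": bc, "oligo_id": oligo,
                             "sample": f"plasmid_{r}", "count": c})
                rows.append({"barcode": bc, "oligo_id": oligo,
                             "sample": f"mRNA_{r}", "count": int(round(c * scale))})
            i += 1
    samples = pd.DataFrame(
        {
            "role": ["plasmid_DNA"] * n_rep + ["mRNA"] * n_rep,
            "replicate": list(range(1, n_rep + 1)) * 2,
        },
        index=pd.Index(
            [f"plasmid_{r}" for r in range(1, n_rep + 1)]
            + [f"mRNA_{r}" for r in range(1, n_rep + 1)],
            name="sample",
        ),
    )
    return pd.DataFrame(rows), samples


class TestFit:
    def test_identical_alleles_not_allelic(self):
        counts = list(range(50, 80))
        bc, samples = _barcode_frame({"v1|A": counts, "v1|G": counts})
        res = AllelicSkew(bc, samples, {"v1"}).fit(
            size_factors_=pd.Series(1.0, index=samples.index)
        )
        row = res.table.iloc[0]
        assert row["t"] == pytest.approx(0.0)
        assert row["p_value"] == pytest.approx(1.0)
        assert not row["is_allelic"]

    def test_twentypercent_fold_not_allelic_despite_significance(self):
        # deterministic 1.2-fold difference: p ~ 0 but below the 25% rule
        dna = [100_000] * 20
        bc, samples = _barcode_frame(
            {"v1|A": dna, "v1|G": dna}, rna_scale={"v1|G": 1.2}
        )
        res = AllelicSkew(bc, samples, {"v1"}).fit(
            size_factors_=pd.Series(1.0, index=samples.index)
        )
        row = res.table.iloc[0]
        assert row["p_adj"] < 0.05
        assert row["fold_between_alleles"] == pytest.approx(1.2, abs=1e-3)
        assert not row["is_allelic"]

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(4)
        a = rng.integers(50, 150, size=40).tolist()
        g = rng.integers(50, 150, size=40).tolist()
        bc, samples = _barcode_frame(
            {"v1|A": a, "v1|G": g}, rna_scale={"v1|G": 1.6}
        )
        sf = pd.Series(1.0, index=samples.index)
        fwd = AllelicSkew(bc, samples, {"v1"},
                          allele_order={"v1": ("A", "G")}).fit(size_factors_=sf)
        rev = AllelicSkew(bc, samples, {"v1"},
                          allele_order={"v1": ("G", "A")}).fit(size_factors_=sf)
        f, r = fwd.table.iloc[0], rev.table.iloc[0]
        assert f["delta_log2"] == pytest.approx(-r["delta_log2"])
        assert f["fold_between_alleles"] == pytest.approx(
            1.0 / r["fold_between_alleles"]
        )
        assert f["p_value"] == pytest.approx(r["p_value"])

    def test_single_barcode_allele_skipped(self):
        bc, samples = _barcode_frame({"v1|A": [100] * 10, "v1|G": [100]})
        res = AllelicSkew(bc, samples, {"v1"}).fit(
            size_factors_=pd.Series(1.0, index=samples.index)
        )
        assert len(res.table) == 0
        assert res.skipped == [("v1", "A", "G", "too_few_barcodes")]

    def test_t_matches_scipy_on_raw_ratios(self):
        rng = np.random.default_rng(8)
        a = rng.integers(20, 200, size=30).tolist()
        g = rng.integers(20, 200, size=30).tolist()
        bc, samples = _barcode_frame({"v1|A": a, "v1|G": g},
                                     rna_scale={"v1|G": 1.4})
        sf = pd.Series(1.0, index=samples.index)
        model = AllelicSkew(bc, samples, {"v1"}, allele_order={"v1": ("A", "G")})
        res = model.fit(size_factors_=sf)
        ratios = model.ratios(size_factors_=sf)
        ra = ratios.loc[ratios.oligo_id == "v1|A", "ratio"]
        rg = ratios.loc[ratios.oligo_id == "v1|G", "ratio"]
        t, p = stats.ttest_ind(rg, ra, equal_var=True)
        assert res.table.iloc[0]["t"] == pytest.approx(t, rel=1e-10)
        assert res.table.iloc[0]["p_value"] == pytest.approx(p, rel=1e-10)


class TestRecovery:
    def test_detection_monotone_in_effect_size(self):
        deltas = [0.0, 0.2, 0.5, 1.0]
        rates = []
        for k, delta in enumerate(deltas):
            sv = gen_reference_and_variants(30, seed=100 + k, n_loci=3)
            planted = {v.id: delta for v in sv.variants}
            mpra = gen_mpra_counts(
                sv.variants, seed=200 + k, barcode_median=300.0,
                allelic_log2=planted,
            )
            en_vars = {v.id for v in sv.variants}
            res = AllelicSkew(
                mpra.barcode_counts, mpra.samples, en_vars,
                allele_order={v.id: v.alleles for v in sv.variants},
            ).fit()
            rates.append(len(res.allelic_en_vars) / len(en_vars))
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.2
        assert rates[-1] >= 0.9

    def test_genotype_dependence_table(self):
        from mpralleles.activity import MPRAActivity

        sv = gen_reference_and_variants(12, seed=31, n_loci=2)
        planted = {v.id: 1.0 for v in sv.variants[:4]}
        folds = {v.id: 2.0 for v in sv.variants[:6]}
        mpra = gen_mpra_counts(sv.variants, seed=32, barcode_median=200.0,
                               enhancer_folds=folds, allelic_log2=planted)
        act = MPRAActivity(mpra.oligo_counts(), mpra.samples["role"]).fit()
        calls = act.call_enhancers()
        res = AllelicSkew(
            mpra.barcode_counts, mpra.samples, calls.en_vars,
            allele_order={v.id: v.alleles for v in sv.variants},
        ).fit()
        dep = res.genotype_dependence(act)
        assert set(dep.columns) >= {
            "variant_id", "max_activity_fold", "genotype_dependence", "is_allelic"
        }
        assert dep["variant_id"].is_unique
        # planted allelic variants that are enVars show dependence away from 1
        flagged = dep.loc[dep["variant_id"].isin(planted) & dep["is_allelic"]]
        assert (abs(np.log2(flagged["genotype_dependence"])) > 0.5).all()
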