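"""Allele-specific ChIP-seq imbalance: strength, calls, consistency filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpralleles.chip_allelic import (
    AllelicCall,
    AllelicReadRecord,
    apply_consistency_filters,
    call_allelic_dataset,
    call_allelic_table,
    strength,
    summarize_allelic_profile,
)


class TestStrength:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            (100, 50, 0.5),  # twice the reads -> 0.5
            (7, 7, 0.0),
            (77, 18, 1 - 18 / 77),
            (50, 100, 0.5),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert strength(a, b) == pytest.approx(expected)

    def test_zero_total_undefined(self):
        with pytest.raises(ValueError):
            strength(0, 0)

    def test_one_sided_zero_is_fully_imbalanced(self):
        assert strength(0, 5) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.integers(min_value=1, max_value=1000),
        st.integers(min_value=1, max_value=1000),
        st.integers(min_value=1, max_value=20),
    )
    def test_scale_invariance_and_symmetry(self, a, b, k):
        assert strength(a, b) == pytest.approx(strength(b, a))
        assert strength(k * a, k * b) == pytest.approx(strength(a, b))
        assert 0.0 <= strength(a, b) < 1.0


def _records(pairs, **kw):
    return [
        AllelicReadRecord(
            variant_id=kw.get("variant_id", "rs1"),
            cell_line=kw.get("cell_line", "LCL_1"),
            dataset_id=kw.get("dataset_id", "ds1"),
            protein=kw.get("protein", "TF_A"),
            replicate=i + 1,
            reads_allele1=a,
            reads_allele2=b,
        )
        for i, (a, b) in enumerate(pairs)
    ]


class TestCallAllelicDataset:
    def test_strong_replicated_imbalance_is_allelic(self):
        call = call_allelic_dataset(_records([(77, 18), (66, 23)]))
        assert call.is_allelic
        assert call.preferred_allele == "allele1"
        assert call.score == pytest.approx(min(1 - 18 / 77, 1 - 23 / 66))

    def test_weak_imbalance_not_allelic(self):
        call = call_allelic_dataset(_records([(9, 7)]))
        assert not call.is_allelic
        assert call.score == pytest.approx(1 - 7 / 9)

    def test_replicate_direction_conflict_scores_zero(self):
        call = call_allelic_dataset(_records([(30, 10), (12, 28)]))
        assert call.score == 0.0
        assert not call.is_allelic

    def test_zero_read_replicate_dropped(self):
        call = call_allelic_dataset(_records([(0, 0), (40, 8)]))
        assert call.dropped_replicates == 1
        assert call.n_replicates == 1
        assert call.is_allelic

    def test_min_total_reads_gate(self):
        call = call_allelic_dataset(_records([(5, 0)]))
        assert not call.is_allelic  # 5 reads < 6 even though fully imbalanced
        call = call_allelic_dataset(_records([(8, 0)]))
        assert call.is_allelic

    def test_tie_has_no_preference(self):
        call = call_allelic_dataset(_records([(20, 20)]))
        assert call.preferred_allele is None
        assert call.strength == 0.0
        assert not call.is_allelic


def _call(variant="rs1", protein="TF_A", dataset="ds1", cell="LCL_1",
          is_allelic=True, preferred="allele1", strength_=0.6):
    return AllelicCall(
        variant_id=variant, dataset_id=dataset, protein=protein, cell_line=cell,
        is_allelic=is_allelic, preferred_allele=preferred, strength=strength_,
        score=strength_, p_binomial=0.001 if is_allelic else 0.8,
        total_reads=40, n_replicates=2,
    )


class TestConsistencyFilters:
    def test_below_half_allelic_removed(self):
        calls = [_call(dataset=f"d{i}", is_allelic=(i == 0)) for i in range(4)]
        assert apply_consistency_filters(calls) == []

    def test_half_allelic_boundary_retained(self):
        calls = [_call(dataset=f"d{i}", is_allelic=(i < 2)) for i in range(4)]
        events = apply_consistency_filters(calls)
        assert len(events) == 1
        assert events[0].k_allelic == 2 and events[0].n_het == 4

    def test_consensus_boundary_three_of_four(self):
        calls = [
            _call(dataset=f"d{i}", preferred="allele1" if i < 3 else "allele2")
            for i in range(4)
        ]
        events = apply_consistency_filters(calls)
        assert len(events) == 1
        assert events[0].consensus_allele == "allele1"

    def test_even_split_preference_removed(self):
        calls = [
            _call(dataset="d0", preferred="allele1"),
            _call(dataset="d1", preferred="allele2"),
        ]
        assert apply_consistency_filters(calls) == []

    def test_filters_only_remove_events(self):
        rng = np.random.default_rng(5)
        calls = [
            _call(
                variant=f"rs{i % 3}", protein=f"TF_{i % 2}", dataset=f"d{i}",
                is_allelic=bool(rng.integers(2)),
                preferred=("allele1", "allele2")[rng.integers(2)],
            )
            for i in range(30)
        ]
        events = apply_consistency_filters(calls)
        observed_pairs = {(c.variant_id, c.protein) for c in calls if c.is_allelic}
        assert {(e.variant_id, e.protein) for e in events} <= observed_pairs


class TestSummaries:
    def test_median_across_cell_lines(self):
        calls = [
            _call(dataset=f"d{i}", cell=f"LCL_{i}", strength_=s)
            for i, s in enumerate([0.5, 0.7, 0.9])
        ]
        events = apply_consistency_filters(calls)
        table = summarize_allelic_profile(events)
        assert table.iloc[0]["median_strength"] == pytest.approx(0.7)
        assert table.iloc[0]["n_cell_lines"] == 3

    def test_dataset_counts_reported(self):
        calls = [_call(dataset=f"d{i}", is_allelic=(i < 2)) for i in range(5)]
        # 2 of 5 heterozygous datasets allelic -> below 50%: removed
        assert apply_consistency_filters(calls) == []
        calls = [_call(dataset=f"d{i}", is_allelic=(i < 3)) for i in range(5)]
        table = summarize_allelic_profile(apply_consistency_filters(calls))
        assert (table.iloc[0]["k_allelic"], table.iloc[0]["n_het"]) == (3, 5)


class TestCalibrationAndRecovery:
    def _simulate_calls(self, p, n_draws, seed):
        rng = np.random.default_rng(seed)
        calls = []
        for i in range(n_draws):
            pairs = [
                (a := int(rng.binomial(40, p)), 40 - a) for _ in range(2)
            ]
            calls.append(call_allelic_dataset(_records(pairs, dataset_id=f"d{i}")))
        return calls

    def test_null_false_positive_rate_low(self):
        calls = self._simulate_calls(0.5, 400, seed=13)
        fpr = np.mean([c.is_allelic for c in calls])
        assert fpr < 0.05

    def test_planted_imbalance_recovered(self):
        calls = self._simulate_calls(0.8, 500, seed=14)
        recovery = np.mean([c.is_allelic for c in calls])
        assert recovery >= 0.9
        assert all(
            c.preferred_allele == "allele1" for c in calls if c.is_allelic
        )


def test_call_allelic_table_filters_non_het(toy_genome):
    import pandas as pd

    reads = pd.DataFrame(
        [
            {"variant_id": "rs1", "cell_line": "LCL_1", "dataset_id": "d1",
             "protein": "TF_A", "replicate": 1, "reads_allele1": 30,
             "reads_allele2": 5, "het": True, "in_peak": True},
            {"variant_id": "rs2", "cell_line": "LCL_1", "dataset_id": "d1",
             "protein": "TF_A", "replicate": 1, "reads_allele1": 30,
             "reads_allele2": 5, "het": False, "in_peak": True},
        ]
    )
    calls = call_allelic_table(reads)
    assert [c.variant_id for c in calls] == ["rs1"]
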