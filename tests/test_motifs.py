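"""PWM scanning against brute-force oracles, altering events, enrichment."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from mpralleles.motifs import (
    PWM,
    adjacent_motif_enrichment,
    best_hit,
    classify_tfs,
    detect_altering_events,
    dinuc_shuffle,
    hit_position_distribution,
    loglik_score,
    overlapping_family_enrichment,
    relative_best_score,
    two_proportion_ztest,
)
from mpralleles.oligo import reverse_complement
from mpralleles.simulate import gen_pwms

BASES = "ACGT"


def random_pwm(rng, width):
    mat = rng.dirichlet(np.ones(4) * 0.7, size=width)
    return PWM(f"TF_w{width}", mat)


def random_seq(rng, n):
    return "".join(rng.choice(list(BASES), size=n))


def oracle_score(pwm, window):
    """Independent per-column log-likelihood sum."""
    total = 0.0
    for i, base in enumerate(window):
        total += np.log2(pwm.matrix[i, BASES.index(base)] / pwm.background[BASES.index(base)])
    return total


class TestScanner:
    def test_columnwise_oracle_equivalence(self):
        rng = np.random.default_rng(1)
        for width in (4, 5, 8, 11):
            pwm = random_pwm(rng, width)
            for _ in range(25):
                window = random_seq(rng, width)
                assert loglik_score(pwm, window) == pytest.approx(
                    oracle_score(pwm, window), abs=1e-9
                )
                assert loglik_score(pwm, window, strand="-") == pytest.approx(
                    oracle_score(pwm, reverse_complement(window)), abs=1e-9
                )

    def test_consensus_scores_maximum(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 6)
        assert loglik_score(pwm, pwm.consensus) == pytest.approx(
            pwm.max_score, abs=1e-12
        )

    def test_background_matching_columns_contribute_zero(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        assert loglik_score(pwm, "ACGT") == pytest.approx(0.0, abs=1e-9)

    def test_full_enumeration_oracle_width_five(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 5)
        best = max(
            oracle_score(pwm, "".join(w))
            for w in itertools.product(BASES, repeat=5)
        )
        assert best == pytest.approx(pwm.max_score, abs=1e-9)
        seq = random_seq(rng, 40) + pwm.consensus + random_seq(rng, 40)
        assert relative_best_score(pwm, seq) == pytest.approx(100.0, abs=1e-9)

    def test_best_hit_matches_windowwise_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            pwm = random_pwm(rng, int(rng.integers(4, 9)))
            seq = random_seq(rng, 60)
            hit = best_hit(pwm, seq)
            w = pwm.width
            oracle_best = max(
                max(oracle_score(pwm, seq[i : i + w]),
                    oracle_score(pwm, reverse_complement(seq[i : i + w])))
                for i in range(len(seq) - w + 1)
            )
            assert hit.score_bits == pytest.approx(oracle_best, abs=1e-9)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(5)
        pwm = random_pwm(rng, 7)
        seq = random_seq(rng, 50)
        h1 = best_hit(pwm, seq)
        h2 = best_hit(pwm, reverse_complement(seq))
        assert h1.score_bits == pytest.approx(h2.score_bits, abs=1e-9)

    def test_wrong_window_length_rejected(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        with pytest.raises(ValueError):
            loglik_score(pwm, "ACGTA")

    def test_uninformative_pwm_rejected(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        with pytest.raises(ValueError, match="uninformative"):
            relative_best_score(pwm, "ACGTACGT")

    def test_negative_relative_scores_preserved(self):
        # consensus AAAA: a T-rich sequence scores negative on both strands
        mat = np.tile([0.97, 0.01, 0.01, 0.01], (4, 1))
        pwm = PWM("polyA", mat)
        rel = relative_best_score(pwm, "TGTGTGTGTG")
        assert rel < 0


class TestAlteringEvents:
    @staticmethod
    def _planted_pair(pwm):
        """Padded allele sequences: alt carries the consensus, ref breaks its
        central column."""
        rng = np.random.default_rng(7)
        left = random_seq(rng, 25 - pwm.width // 2)
        right = random_seq(rng, 25 - (pwm.width - pwm.width // 2) + 1)
        col = pwm.width // 2
        cons = pwm.consensus
        weak = BASES[int(pwm.matrix[col].argmin())]
        alt_seq = left + cons + right
        ref_seq = left + cons[:col] + weak + cons[col + 1 :] + right
        span = (len(left) + col, len(left) + col + 1)
        return {weak: (ref_seq, span), cons[col]: (alt_seq, span)}, weak, cons[col]

    def test_planted_disruption_detected(self):
        pwm = gen_pwms(1, seed=8)[0]
        alleles, ref, alt = self._planted_pair(pwm)
        events = detect_altering_events("rs9", alleles, [pwm])
        assert len(events) == 1
        ev = events[0]
        assert (ev.strong_allele, ev.weak_allele) == (alt, ref)
        assert ev.strong_score >= 70 and ev.weak_score < 40

    def test_rule_matches_score_oracle(self):
        # event iff one allele >= 70% and the other < 40%, scores recomputed
        # independently through relative_best_score
        rng = np.random.default_rng(9)
        pwms = gen_pwms(4, seed=10) + [random_pwm(rng, 6) for _ in range(4)]
        for trial in range(20):
            pos = 25
            seq = random_seq(rng, 51)
            ref, alt = rng.choice(list(BASES), size=2, replace=False)
            alleles = {
                a: (seq[:pos] + a + seq[pos + 1 :], (pos, pos + 1))
                for a in (ref, alt)
            }
            events = detect_altering_events("v", alleles, pwms)
            got = {(e.tf_name, e.strong_allele, e.weak_allele) for e in events}
            expected = set()
            for pwm in pwms:
                scores = {
                    a: relative_best_score(pwm, s, span, True)
                    for a, (s, span) in alleles.items()
                }
                hi = max(scores, key=scores.get)
                lo = min(scores, key=scores.get)
                if hi != lo and scores[hi] >= 70 and scores[lo] < 40:
                    expected.add((pwm.tf_name, hi, lo))
            assert got == expected

    def test_symmetric_in_allele_order(self):
        pwm = gen_pwms(1, seed=12)[0]
        alleles, _, _ = self._planted_pair(pwm)
        flipped = dict(reversed(list(alleles.items())))
        e1 = detect_altering_events("v", alleles, [pwm])
        e2 = detect_altering_events("v", flipped, [pwm])
        assert e1 == e2

    def test_requires_two_alleles(self):
        pwm = gen_pwms(1, seed=13)[0]
        with pytest.raises(ValueError):
            detect_altering_events("v", {"A": ("ACGT" * 10, (5, 6))}, [pwm])


class TestClassification:
    def _event(self, tf, variant="rs1"):
        from mpralleles.motifs import AlteringEvent

        return AlteringEvent(variant, tf, tf, "A", "G", 90.0, 20.0)

    def test_rules(self):
        pwms = gen_pwms(2, seed=14)
        tf1, tf2 = (p.tf_name for p in pwms)
        events = [self._event(tf1)]
        # allelic reads + event -> overlapping; reads + no event -> adjacent
        table = classify_tfs("rs1", {tf1, tf2}, events, pwms)
        byclass = dict(zip(table["tf"], table["classification"]))
        assert byclass[tf1] == "variant_overlapping"
        assert byclass[tf2] == "variant_adjacent"

    def test_event_without_allelic_reads_unclassified(self):
        pwms = gen_pwms(1, seed=15)
        events = [self._event(pwms[0].tf_name)]
        table = classify_tfs("rs1", set(), events, pwms)
        assert len(table) == 0

    def test_no_motif_tf_flagged_adjacent(self):
        pwms = gen_pwms(1, seed=16)
        table = classify_tfs("rs1", {"NOMOTIF"}, [], pwms)
        assert table.iloc[0]["classification"] == "variant_adjacent"
        assert not table.iloc[0]["has_motif"]


class TestProportions:
    def test_matches_statsmodels(self):
        from statsmodels.stats.proportion import proportions_ztest

        for k1, n1, k2, n2 in [(10, 50, 10, 400), (3, 7, 5, 11), (0, 10, 4, 9)]:
            z, p = two_proportion_ztest(k1, n1, k2, n2)
            z_ref, p_ref = proportions_ztest([k1, k2], [n1, n2])
            assert z == pytest.approx(z_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_fractions_p_one(self):
        z, p = two_proportion_ztest(5, 50, 40, 400)
        assert z == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_family_report_filter_keeps_full_table(self):
        from mpralleles.motifs import AlteringEvent

        events_fg = [
            AlteringEvent(f"v{i}", "TF1", "FAM1", "A", "G", 90, 10)
            for i in range(2)  # only 2 events: below the reporting cutoff
        ]
        table = overlapping_family_enrichment(events_fg, 10, [], 100)
        assert len(table) == 1
        assert not table.iloc[0]["reported"]


class TestAdjacentEnrichment:
    def test_planted_motif_enriched(self):
        rng = np.random.default_rng(3)
        pwms = gen_pwms(2, seed=3)
        seqs = {}
        for i in range(40):
            s = random_seq(rng, 80)
            if i < 24:  # plant the first motif in 60% of the foreground
                s = s[:30] + pwms[0].consensus + s[30 + pwms[0].width :]
            seqs[f"s{i}"] = s
        table = adjacent_motif_enrichment(seqs, pwms, seed=3)
        row = table.set_index("family").loc[pwms[0].family]
        assert row["p_adj"] < 1e-4
        assert row["fraction_fg"] > row["fraction_bg"]

    def test_min_sites_filter(self):
        # sharp motif in short sequences: spurious hits are essentially
        # impossible, so exactly the four planted sites are found
        rng = np.random.default_rng(5)
        pwms = gen_pwms(1, seed=4, concentration=0.99)
        seqs = {}
        for i in range(30):
            s = random_seq(rng, 40)
            if i < 4:  # only four sequences carry a site
                s = s[:10] + pwms[0].consensus + s[10 + pwms[0].width :]
            seqs[f"s{i}"] = s
        table = adjacent_motif_enrichment(seqs, pwms, seed=4)
        row = table.set_index("family").iloc[0]
        assert row["n_sites"] == 4
        assert not row["reported"]


class TestDinucShuffle:
    def test_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            s = random_seq(rng, int(rng.integers(10, 200)))
            sh = dinuc_shuffle(s, rng)
            assert Counter(zip(sh, sh[1:])) == Counter(zip(s, s[1:]))
            assert len(sh) == len(s)
            assert Counter(sh) == Counter(s)

    def test_two_letter_sequence_fixed(self):
        assert dinuc_shuffle("AC", 1) == "AC"

    def test_seeded_determinism(self):
        s = random_seq(np.random.default_rng(7), 170)
        assert dinuc_shuffle(s, 42) == dinuc_shuffle(s, 42)
        assert dinuc_shuffle(s, 42) != dinuc_shuffle(s, 43)


class TestPositionDistribution:
    def test_adjacent_site_mode_near_plant(self):
        rng = np.random.default_rng(8)
        pwm = gen_pwms(1, seed=9)[0]
        core = random_seq(rng, 170)
        offset = 85 + 30  # plant 30 bases downstream of the center
        core = core[:offset] + pwm.consensus + core[offset + pwm.width :]
        hit = best_hit(pwm, core, "rs1")
        classification = pd.DataFrame(
            [{"variant_id": "rs1", "tf": pwm.tf_name,
              "classification": "variant_adjacent", "has_motif": True}]
        )
        table = hit_position_distribution(
            classification, {pwm.tf_name: hit}, 85.0
        )
        assert abs(table.iloc[0]["center_offset"] - 30) < pwm.width

    def test_empty_class_empty_histogram(self):
        table = hit_position_distribution(
            pd.DataFrame(columns=["variant_id", "tf", "classification", "has_motif"]),
            {},
            85.0,
        )
        assert len(table) == 0
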