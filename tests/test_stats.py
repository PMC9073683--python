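import math

import numpy as np
import pytest

from spacerscan.errors import DegenerateInputError
from spacerscan.scan import MotifPairQuery, SpacerFrequencyProfile, profile
from spacerscan.stats import (
    LEFT_CONTROLS,
    RIGHT_CONTROLS,
    compare_to_controls,
    enrichment,
    make_control_queries,
    normalize_profile,
    orientation_comparison,
    paired_t_test,
    pearson,
    t_critical,
)


def _prof(counts, total_bp, label="AAAG(N)ACGT"):
    return SpacerFrequencyProfile(
        query_label=label, counts=dict(counts), total_bp=total_bp, n_sequences=1
    )


def paired_t_oracle(x, y):
    """Direct-formula oracle: t = mean(d) / (sd(d)/sqrt(n)), sample sd."""
    d = np.asarray(x, float) - np.asarray(y, float)
    n = d.size
    return d.mean() / (d.std(ddof=1) / math.sqrt(n))


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx**2).sum() * (dy**2).sum()))


class TestNormalize:
    def test_per_bp_frequency(self):
        norm = normalize_profile(_prof({5: 100}, 1000))
        assert norm.normalized[5] == pytest.approx(0.1)

    def test_zero_counts_stay_zero(self):
        norm = normalize_profile(_prof({n: 0 for n in range(31)}, 500))
        assert all(v == 0 for v in norm.normalized.values())

    def test_algebraic_inverse(self, rng):
        counts = {n: int(rng.integers(0, 50)) for n in range(31)}
        norm = normalize_profile(_prof(counts, 12345))
        for n, c in counts.items():
            assert norm.normalized[n] * 12345 == pytest.approx(c)

    def test_zero_coverage_rejected(self):
        with pytest.raises(ValueError):
            normalize_profile(_prof({0: 1}, 0))


class TestEnrichment:
    def test_constant_twofold(self):
        prom = normalize_profile(_prof({n: 2 for n in range(5)}, 1000))
        gen = normalize_profile(_prof({n: 1 for n in range(5)}, 1000))
        res = enrichment(prom, gen)
        assert res.min_ratio == res.max_ratio == pytest.approx(2.0)

    def test_self_enrichment_is_one(self, rng):
        counts = {n: int(rng.integers(1, 50)) for n in range(31)}
        norm = normalize_profile(_prof(counts, 9999))
        res = enrichment(norm, norm)
        assert all(v == pytest.approx(1.0) for v in res.ratio.values())

    def test_zero_genome_count_flagged_not_zero(self):
        prom = normalize_profile(_prof({0: 1, 1: 1}, 100))
        gen = normalize_profile(_prof({0: 1, 1: 0}, 100))
        res = enrichment(prom, gen)
        assert res.undefined == {1}
        assert 1 not in res.ratio

    def test_mismatched_labels_rejected(self):
        a = normalize_profile(_prof({0: 1}, 10, label="A"))
        b = normalize_profile(_prof({0: 1}, 10, label="B"))
        with pytest.raises(ValueError):
            enrichment(a, b)


class TestControls:
    def test_twelve_left_first_combinations(self):
        ctrl = make_control_queries("left-first")
        assert len(ctrl.queries) == 12
        pairs = {(q.left_motif, q.right_motif) for q in ctrl.queries}
        assert ("AAGA", "CATG") in pairs
        assert ("GAAA", "TCAG") in pairs
        assert pairs == {(l, r) for l in LEFT_CONTROLS for r in RIGHT_CONTROLS}

    def test_right_first_mirrors(self):
        ctrl = make_control_queries("right-first")
        assert ("CATG", "AAGA") in {(q.left_motif, q.right_motif) for q in ctrl.queries}
        assert len(ctrl.queries) == 12

    def test_no_control_equals_true_motif(self):
        for ctrl in (make_control_queries("left-first"), make_control_queries("right-first")):
            for q in ctrl.queries:
                assert q.left_motif not in {"AAAG", "ACGT"}
                assert q.right_motif not in {"AAAG", "ACGT"}

    def test_spacer_range_propagates(self):
        ctrl = make_control_queries("left-first", 3, 17)
        assert all((q.min_spacer, q.max_spacer) == (3, 17) for q in ctrl.queries)

    def test_deterministic_order(self):
        a = [q.label for q in make_control_queries("left-first").queries]
        b = [q.label for q in make_control_queries("left-first").queries]
        assert a == b


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t_test([1, 2, 3, 4], [2, 2, 4, 3])
        assert res.statistic == pytest.approx(-0.5222, abs=5e-4)
        assert res.df == 3
        assert res.n == 4

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1, 2, 3], [1, 2, 3])

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_t_test([1, 2, 3], [2, 3, 4])

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        a, b = paired_t_test(x, y), paired_t_test(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert paired_t_test(x, y).statistic == pytest.approx(
                paired_t_oracle(x, y), abs=1e-9
            )


class TestTCritical:
    def test_thirty_df_five_percent(self):
        assert round(t_critical(30, 0.05), 2) == 2.04

    def test_normal_limit(self):
        assert t_critical(10**7, 0.05) == pytest.approx(1.959964, abs=1e-4)

    def test_monotone_decreasing_in_df(self):
        vals = [t_critical(df, 0.05) for df in (1, 2, 5, 10, 30, 100)]
        assert vals == sorted(vals, reverse=True)

    @pytest.mark.parametrize("df,alpha", [(0, 0.05), (5, 0.0), (5, 1.0)])
    def test_invalid_arguments(self, df, alpha):
        with pytest.raises(ValueError):
            t_critical(df, alpha)


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [3, 5, 7]).statistic == pytest.approx(1.0)
        assert pearson([1, 2, 3], [-1, -2, -3]).statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        res = pearson([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert round(res.statistic, 1) == 0.8

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_matches_formula_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert pearson(x, y).statistic == pytest.approx(
                pearson_oracle(x, y), abs=1e-9
            )


class TestOrientationComparison:
    def test_paired_t_over_full_range_and_pearson_subset(self, rng):
        counts_a = {n: int(rng.integers(10, 100)) for n in range(31)}
        counts_b = {n: counts_a[n] + int(rng.integers(-5, 15)) for n in range(31)}
        res = orientation_comparison(_prof(counts_a, 1000), _prof(counts_b, 1000))
        assert res["paired_t"].df == 30
        assert res["pearson"].n == 6
        assert abs(res["pearson"].statistic) <= 1

    def test_control_comparison_runs_per_control(self, rng):
        from conftest import random_dna

        seqs = [random_dna(rng, 2000) for _ in range(5)]
        true_prof = profile(seqs, MotifPairQuery("AAAG", "ACGT"))
        ctrl_profs = [
            profile(seqs, q) for q in make_control_queries("left-first").queries[:3]
        ]
        out = compare_to_controls(true_prof, ctrl_profs)
        assert len(out) == 3
        assert all(r.df == 30 for _, r in out)
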