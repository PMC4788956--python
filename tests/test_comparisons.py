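"""Mann-Whitney machinery, stratified tests, binned fractions, resampling."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from conftest import enum_mwu_p_greater, make_gene, make_pathway_summary
from genarch.comparisons import (
    SkippedComparison,
    StratumSpec,
    _exact_u_counts,
    binned_case_fraction,
    compare_gene_metric,
    compare_pathway_averages,
    exact_mwu_p_greater,
    mann_whitney_greater,
    resampled_pathway_comparison,
    stratified_comparison,
)


class TestMannWhitneyExact:
    def test_fully_separated_samples(self):
        r = mann_whitney_greater([4, 5, 6], [1, 2, 3])
        assert r.p_one_sided == pytest.approx(1 / 20)  # 1 of C(6,3)=20 labelings
        assert r.U == 9

    def test_reversed_separation_gives_p_one(self):
        r = mann_whitney_greater([1, 2, 3], [4, 5, 6])
        assert r.U == 0
        assert r.p_one_sided == 1.0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_greater([], [1.0])

    def test_matches_enumeration_on_random_tie_free_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(1, 6))
            m = int(rng.integers(1, 10 - n + 1))
            pooled = rng.permutation(np.arange(n + m, dtype=float))
            x, y = pooled[:n], pooled[n:]
            u, p = exact_mwu_p_greater(x, y)
            assert p == enum_mwu_p_greater(x, y)

    def test_swap_identity(self):
        # p>(x,y) + p>(y,x) = 1 + P(U = u_obs) under the exact null
        rng = np.random.default_rng(7)
        for _ in range(30):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.permutation(np.arange(n + m, dtype=float))
            x, y = pooled[:n], pooled[n:]
            u, p_xy = exact_mwu_p_greater(x, y)
            _, p_yx = exact_mwu_p_greater(y, x)
            counts = _exact_u_counts(n, m)
            p_eq = counts[int(u)] / sum(counts)
            assert p_xy + p_yx == pytest.approx(1 + p_eq, abs=1e-12)

    def test_u_count_distribution_sums_to_binomial(self):
        counts = _exact_u_counts(4, 5)
        from math import comb

        assert sum(counts) == comb(9, 4)
        assert counts == counts[::-1]  # U distribution is symmetric

    def test_asymptotic_close_to_exact_at_moderate_n(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pooled = rng.permutation(np.arange(12, dtype=float))
            x, y = pooled[:6], pooled[6:]
            _, p_exact = exact_mwu_p_greater(x, y)
            p_approx = mann_whitney_greater(x, y, exact_cutoff=0).p_one_sided
            assert p_approx == pytest.approx(p_exact, abs=0.02)

    def test_ties_fall_back_to_corrected_asymptotic(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [2.0, 2.0, 1.0, 0.5]
        r = mann_whitney_greater(x, y)
        expected = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert r.p_one_sided == pytest.approx(float(expected.pvalue))


class TestGeneAndPathwayComparisons:
    def test_identical_groups_not_significant(self):
        genes = [make_gene(f"G{i}", 1000 + i) for i in range(20)]
        r = compare_gene_metric(genes, genes, "l_tr")
        assert r.p_one_sided >= 0.4

    def test_missing_metric_values_dropped(self):
        case = [make_gene(f"C{i}", 5000, n_ex=3) for i in range(10)]
        other = [make_gene(f"O{i}", 4000, n_ex=1) for i in range(10)]  # no introns
        other += [make_gene(f"O{i+10}", 4000, n_ex=2) for i in range(5)]
        r = compare_gene_metric(case, other, "avg_int")
        assert r.n_other == 5  # single-exon genes contribute no avg_int

    def test_all_missing_in_group_errors(self):
        case = [make_gene("C", 5000, n_ex=1)]
        other = [make_gene("O", 4000, n_ex=2)]
        with pytest.raises(ValueError):
            compare_gene_metric(case, other, "avg_int")

    def test_pathway_average_comparison_detects_shift(self):
        case = [make_pathway_summary(f"C{i}", "case", 9000 + i) for i in range(8)]
        other = [make_pathway_summary(f"O{i}", "other", 1000 + i) for i in range(30)]
        r = compare_pathway_averages(case + other, "mean_L_tr")
        assert r.p_one_sided < 0.01
        assert r.n_case == 8 and r.n_other == 30


class TestStratified:
    def _genes(self):
        case = [make_gene(f"C{i}", 40_000 + 100 * i, ntr=1) for i in range(8)]
        case += [make_gene(f"C{8+i}", 30_000 + 100 * i, ntr=2) for i in range(2)]
        other = [make_gene(f"O{i}", 20_000 + 100 * i, ntr=1) for i in range(20)]
        other += [make_gene(f"O{20+i}", 25_000, ntr=2) for i in range(6)]
        return case, other

    def test_fixed_ntr_stratum_compares_length(self):
        case, other = self._genes()
        r = stratified_comparison(case, other, StratumSpec("fixed_Ntr", 1))
        assert r.n_case == 8 and r.n_other == 20
        assert r.p_one_sided < 0.01

    def test_small_stratum_skipped(self):
        case, other = self._genes()
        r = stratified_comparison(case, other, StratumSpec("fixed_Ntr", 2, min_group_size=5))
        assert isinstance(r, SkippedComparison)
        assert r.n_case == 2

    def test_interval_is_half_open(self):
        case = [make_gene("C", 50_000, ntr=3)] + [
            make_gene(f"C{i}", 30_000, ntr=2) for i in range(6)
        ]
        other = [make_gene(f"O{i}", 30_000 + i, ntr=1) for i in range(6)]
        r = stratified_comparison(
            case, other, StratumSpec("Ltr_interval", (25_000, 50_000), min_group_size=1)
        )
        # the L_tr = 50,000 gene is excluded from [25k, 50k)
        assert r.n_case == 6

    def test_bad_stratum_rejected(self):
        with pytest.raises(ValueError):
            StratumSpec("fixed_Ntr", 0)
        with pytest.raises(ValueError):
            StratumSpec("Ltr_interval", (10, 10))


class TestBinnedFractions:
    def test_example_bins(self):
        genes = [
            make_gene("A", 500),
            make_gene("B", 1500),
            make_gene("C", 3500),
            make_gene("D", 4000),
        ]
        bins = binned_case_fraction(genes, {"C"}, axis="L_tr", bin_width=3000)
        assert bins[0].bin_lo == 0 and bins[0].fraction == 0
        assert bins[1].bin_lo == 3000 and bins[1].fraction == 0.5

    def test_case_conservation(self):
        rng = np.random.default_rng(0)
        genes = [make_gene(f"G{i}", float(v)) for i, v in enumerate(rng.integers(1, 50_000, 200))]
        case = {g.gene_symbol for g in genes[:57]}
        bins = binned_case_fraction(genes, case, bin_width=3000)
        assert sum(b.n_case for b in bins) == 57
        assert sum(b.n_total for b in bins) == 200

    def test_ntr_axis_integer_bins(self):
        genes = [make_gene(f"G{i}", 1000, ntr=n) for i, n in enumerate([1, 1, 2, 5])]
        bins = binned_case_fraction(genes, {"G3"}, axis="N_tr")
        by_lo = {b.bin_lo: b for b in bins}
        assert by_lo[1].n_total == 2
        assert by_lo[5].fraction == 1.0
        assert by_lo[3].n_total == 0 and by_lo[3].fraction is None

    def test_min_bin_n_flags_not_drops(self):
        genes = [make_gene("A", 100), make_gene("B", 4000)]
        bins = binned_case_fraction(genes, set(), bin_width=3000, min_bin_n=2)
        assert all(b.below_min_n for b in bins if b.n_total > 0)
        assert len(bins) == 2

    def test_increasing_case_probability_gives_increasing_trend(self):
        rng = np.random.default_rng(11)
        lengths = rng.uniform(0, 60_000, 4000)
        prob = lengths / 60_000
        case = {f"G{i}" for i in range(4000) if rng.random() < prob[i]}
        genes = [make_gene(f"G{i}", float(v)) for i, v in enumerate(lengths)]
        bins = [
            b
            for b in binned_case_fraction(genes, case, bin_width=6000)
            if b.n_total >= 50
        ]
        fracs = [b.fraction for b in bins]
        rho = stats.spearmanr(range(len(fracs)), fracs).statistic
        assert rho > 0.8


class TestResampling:
    def _summaries(self, case_mean=1e9, n_other=30):
        case = [make_pathway_summary("C", "case", case_mean)]
        other = [make_pathway_summary(f"O{i}", "other", 1000.0 + i) for i in range(n_other)]
        return case + other

    def test_floor_when_case_mean_above_everything(self):
        p = resampled_pathway_comparison(self._summaries(), n_iter=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_seed_reproducibility(self):
        s = self._summaries(case_mean=1015.0)
        p1 = resampled_pathway_comparison(s, n_iter=500, seed=123)
        p2 = resampled_pathway_comparison(s, n_iter=500, seed=123)
        assert p1 == p2

    def test_null_calibration_mean_half(self):
        rng = np.random.default_rng(5)
        ps = []
        for rep in range(400):
            vals = rng.normal(size=24)
            summaries = [
                make_pathway_summary(f"P{i}", "case" if i < 3 else "other", float(v))
                for i, v in enumerate(vals)
            ]
            ps.append(resampled_pathway_comparison(summaries, n_iter=199, seed=rep))
        assert np.mean(ps) == pytest.approx(0.5, abs=0.05)

    def test_too_few_other_pathways_errors(self):
        case = [make_pathway_summary(f"C{i}", "case", 10.0) for i in range(5)]
        other = [make_pathway_summary("O", "other", 1.0)]
        with pytest.raises(ValueError):
            resampled_pathway_comparison(case + other, n_iter=100, seed=0)
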