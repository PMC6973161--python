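"""Crossover counting, Kosambi maps, Marey rates, distortion, histograms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from invcross.io import HET, MISSING, REC, GenotypeMatrix, MarkerMap
from invcross.landscape import (
    build_genetic_map,
    co_count_histogram,
    compare_co_distributions,
    count_crossovers,
    kosambi_cm,
    kosambi_r,
    marey_recombination_rates,
    per_cell_mean,
    segregation_distortion_scan,
)


def _single_chrom_matrix(rows, n_markers=6, chrom_map=None):
    mm = chrom_map or MarkerMap.from_records(
        [(f"m{k}", "1", 100_000 * (k + 1)) for k in range(n_markers)]
    )
    calls = np.array(rows, dtype=np.int8)
    return GenotypeMatrix([f"i{k}" for k in range(len(rows))], calls, mm)


class TestCountCrossovers:
    @pytest.mark.parametrize(
        "row, expected_count, expected_intervals",
        [
            ([HET, HET, HET, HET, HET, HET], 0, []),
            ([REC, REC, HET, HET, HET, HET], 1, [1]),
            ([REC, MISSING, HET, HET, HET, HET], 1, [0]),  # switch spans a gap -> leftmost interval
            ([REC, REC, HET, HET, REC, REC], 2, [1, 3]),
            ([REC, MISSING, MISSING, MISSING, MISSING, HET], 1, [0]),
        ],
    )
    def test_switch_scoring(self, row, expected_count, expected_intervals):
        g = _single_chrom_matrix([row])
        profile = count_crossovers(g)
        assert profile.counts.loc["i0", "1"] == expected_count
        assert profile.intervals.get(("i0", "1"), []) == expected_intervals

    def test_uninformative_chromosome_is_missing_not_zero(self):
        row = [REC, MISSING, MISSING, MISSING, MISSING, MISSING]
        g = _single_chrom_matrix([row])
        profile = count_crossovers(g)
        assert np.isnan(profile.counts.loc["i0", "1"])

    def test_total_matches_interval_recombinants_without_missing(self, control_population):
        """With complete data, summed CO counts equal summed interval recombinants."""
        genotypes, _ = control_population
        profile = count_crossovers(genotypes)
        gm = build_genetic_map(genotypes)
        assert profile.total() == gm.intervals["recombinant"].sum()


class TestPerCellMean:
    @pytest.mark.parametrize(
        "total, n, expected",
        [(1894, 418, 9.06), (1362, 416, 6.55), (0, 100, 0.0)],
    )
    def test_study_values(self, total, n, expected):
        assert round(per_cell_mean(total, n), 2) == expected

    def test_linearity(self):
        assert per_cell_mean(500, 200) == 2 * per_cell_mean(250, 200)

    def test_requires_individuals(self):
        with pytest.raises(ValueError):
            per_cell_mean(10, 0)


class TestKosambi:
    def test_closed_forms(self):
        assert kosambi_cm(0.0) == 0.0
        assert kosambi_cm(0.25) == pytest.approx(25 * np.log(3), abs=1e-12)

    @pytest.mark.parametrize("r", np.arange(0.01, 0.50, 0.02))
    def test_inverse_round_trip(self, r):
        assert kosambi_r(kosambi_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_strictly_increasing_and_convex(self):
        r = np.linspace(0.0, 0.49, 200)
        d = kosambi_cm(r)
        assert np.all(np.diff(d) > 0)
        assert np.all(np.diff(d, 2) > 0)

    @pytest.mark.parametrize("bad", [-0.01, 0.5, 0.7])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            kosambi_cm(bad)


class TestGeneticMap:
    def test_no_recombinants_means_zero_length(self):
        g = _single_chrom_matrix([[HET] * 6, [REC] * 6])
        gm = build_genetic_map(g)
        assert gm.total_cm() == 0.0

    def test_matches_brute_force_pair_counting(self):
        """r-hat per interval equals direct enumeration over individuals."""
        rng = np.random.default_rng(5)
        calls = rng.choice([REC, HET, MISSING], size=(20, 6), p=[0.4, 0.4, 0.2]).astype(np.int8)
        calls[:, 0] = rng.choice([REC, HET], size=20)  # keep rows informative
        g = _single_chrom_matrix(list(calls))
        gm = build_genetic_map(g)
        for k, row in gm.intervals.iterrows():
            rec = inf = 0
            for ind in range(20):
                a, b = calls[ind, k], calls[ind, k + 1]
                if a != MISSING and b != MISSING:
                    inf += 1
                    rec += int(a != b)
            assert row["informative"] == inf
            if inf:
                assert row["r"] == pytest.approx(rec / inf)
            assert row["d_cm"] == pytest.approx(0.0 if inf == 0 else kosambi_cm(min(rec / inf, 0.4999)))

    def test_interval_r_estimates_within_binomial_error(self):
        """On synthetic data with known interval r, estimates track truth."""
        rng = np.random.default_rng(21)
        n, m = 5000, 8
        r_true = np.array([0.02, 0.10, 0.25, 0.05, 0.15, 0.30, 0.08])
        start = rng.integers(2, size=n)
        switches = rng.random((n, m - 1)) < r_true
        cum = np.column_stack([np.zeros(n, int), np.cumsum(switches, axis=1)])
        calls = (start[:, None] + cum) % 2
        calls = np.where(calls == 1, HET, REC).astype(np.int8)
        mm = MarkerMap.from_records([(f"m{k}", "1", 10**5 * (k + 1)) for k in range(m)])
        g = GenotypeMatrix([f"i{k}" for k in range(n)], calls, mm)
        gm = build_genetic_map(g)
        se = np.sqrt(r_true * (1 - r_true) / n)
        assert np.all(np.abs(gm.intervals["r"].to_numpy() - r_true) < 3.5 * se)


class TestMarey:
    def test_uniform_map_has_constant_rate(self):
        rng = np.random.default_rng(2)
        n = 2000
        r = 0.1
        switches = rng.random((n, 5)) < r
        calls = np.column_stack([np.zeros(n, int), *np.cumsum(switches, axis=1).T]) % 2
        calls = np.where(calls == 1, HET, REC).astype(np.int8)
        g = _single_chrom_matrix(list(calls))  # equally spaced markers
        gm = build_genetic_map(g)
        track = marey_recombination_rates(gm, g.marker_map)
        rates = track.rates["rate_cm_per_mbp"].to_numpy()
        assert rates.std() / rates.mean() < 0.15

    def test_rate_integral_recovers_total_length(self, control_population):
        genotypes, _ = control_population
        gm = build_genetic_map(genotypes)
        track = marey_recombination_rates(gm, genotypes.marker_map)
        for chrom in genotypes.marker_map.chromosomes:
            rates = track.rates[track.rates["chromosome"] == chrom]
            integral = (rates["rate_cm_per_mbp"] * rates["mbp_span"]).sum()
            assert integral == pytest.approx(gm.total_cm(chrom), abs=1e-9)

    def test_zero_physical_span_rejected(self):
        mm = MarkerMap.from_records([("a", "1", 5), ("b", "1", 6)])
        g = GenotypeMatrix(["x"], np.array([[HET, HET]], dtype=np.int8), mm)
        gm = build_genetic_map(g)
        bad = MarkerMap.from_records([("a", "1", 5), ("b", "1", 6)])
        object.__setattr__(bad, "table", bad.table.assign(pos_bp=[5, 5]))
        with pytest.raises(ValueError, match="span"):
            marey_recombination_rates(gm, bad)


class TestDistortion:
    def test_balanced_marker_not_flagged(self):
        calls = np.array([[HET], [REC]] * 50, dtype=np.int8).reshape(100, 1)
        calls = np.repeat(calls, 2, axis=1)
        mm = MarkerMap.from_records([("a", "1", 1), ("b", "1", 2)])
        scan = segregation_distortion_scan(GenotypeMatrix([f"i{k}" for k in range(100)], calls, mm))
        assert scan.flagged == []

    def test_deviation_arithmetic(self):
        n = 414
        n_het = int(round(0.60 * n))
        calls = np.array([[HET, HET]] * n_het + [[REC, REC]] * (n - n_het), dtype=np.int8)
        mm = MarkerMap.from_records([("a", "1", 1), ("b", "1", 2)])
        scan = segregation_distortion_scan(GenotypeMatrix([f"i{k}" for k in range(n)], calls, mm), k_sd=2)
        row = scan.table.iloc[0]
        assert row["delta"] == pytest.approx(np.sqrt(0.25 / n))
        assert abs(row["freq_het"] - 0.5) > 2 * row["delta"]
        assert scan.flagged == ["a", "b"]

    def test_type_one_rate_near_nominal_on_null(self):
        """Balanced population: flag rate approximates the two-sided normal level."""
        rng = np.random.default_rng(8)
        n, m = 400, 1000
        calls = rng.choice([REC, HET], size=(n, m)).astype(np.int8)
        mm = MarkerMap.from_records([(f"m{k}", "1", k + 1) for k in range(m)])
        scan = segregation_distortion_scan(GenotypeMatrix([f"i{k}" for k in range(n)], calls, mm), k_sd=2)
        rate = len(scan.flagged) / m
        assert 0.01 < rate < 0.09  # nominal ~4.6% for k_sd = 2


class TestCompareDistributions:
    def test_identical_histograms(self):
        assert compare_co_distributions([5, 10, 3], [5, 10, 3]) == (0.0, 1.0)

    def test_study_inversion_row_is_overwhelming(self):
        """Control vs mutant CO classes inside the inversion differ beyond doubt."""
        chi2, p = compare_co_distributions([158, 222, 32], [400, 0, 18])
        assert p < 1e-60

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(3)
        a = np.array([12, 10, 8])
        b = np.array([20, 6, 4])
        chi2_obs, p_chi2 = compare_co_distributions(a, b)
        # permutation oracle: shuffle group labels of the 60 individuals
        values = np.concatenate([np.repeat(np.arange(3), a), np.repeat(np.arange(3), b)])
        labels = np.array([0] * a.sum() + [1] * b.sum())
        stat = []
        for _ in range(20_000):
            rng.shuffle(labels)
            ha = np.bincount(values[labels == 0], minlength=3)
            hb = np.bincount(values[labels == 1], minlength=3)
            stat.append(compare_co_distributions(ha, hb)[0])
        p_perm = np.mean(np.array(stat) >= chi2_obs - 1e-12)
        assert p_chi2 == pytest.approx(p_perm, abs=0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_co_distributions([0, 0, 5], [0, 0, 7])
        with pytest.raises(ValueError):
            compare_co_distributions([1, 2], [1, 2, 3])


def test_histogram_collects_counts(control_population):
    genotypes, _ = control_population
    profile = count_crossovers(genotypes)
    hist = co_count_histogram(profile, "1")
    assert hist.sum() == genotypes.n_individuals
    assert hist @ np.arange(hist.size) == profile.total("1")
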