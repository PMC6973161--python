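"""Pairing + post-meiotic-selection model: algebra, simulation, calibration."""

import math

import numpy as np
import pytest

from invcross.inversion import (
    PairingModel,
    RegionEventTable,
    RegionPartition,
    calibrate_pairing,
    classify_region_events,
    even_conditioned_moments,
    gamete_viable,
    predict_lod_heatmap,
    simulate_inversion_gametes,
)
from invcross.io import HET, REC, GenotypeMatrix
from invcross.landscape import count_crossovers


class TestSelectionAlgebra:
    @pytest.mark.parametrize("count, viable", [(0, True), (1, False), (2, True), (3, False), (4, True)])
    def test_even_rule(self, count, viable):
        assert gamete_viable(count) is viable

    def test_moment_limits(self):
        assert even_conditioned_moments(0.0) == (1.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            even_conditioned_moments(-0.1)

    @pytest.mark.parametrize("lam", np.linspace(0.0, 5.0, 26))
    def test_matches_truncated_poisson_sums(self, lam):
        """Closed forms agree with brute-force series over the Poisson pmf."""
        n = np.arange(0, 60)
        pmf = np.exp(-lam) * lam**n / np.array([math.factorial(int(k)) for k in n])
        even = n % 2 == 0
        expected = (pmf[even].sum(), pmf[even & (n >= 2)].sum(), (n * pmf)[even].sum())
        got = even_conditioned_moments(lam)
        for g, e in zip(got, expected):
            assert g == pytest.approx(e, abs=1e-12)

    @pytest.mark.parametrize("lam", [0.1, 0.5, 1.0, 2.5, 5.0])
    def test_parity_normalisation(self, lam):
        p_even, _, _ = even_conditioned_moments(lam)
        p_odd = (1 - math.exp(-2 * lam)) / 2
        assert p_even + p_odd == pytest.approx(1.0, abs=1e-14)


class TestPartition:
    def test_from_markers_layout(self, partition):
        assert partition.region1 == (0, 1)
        assert partition.inversion == (2, 22)
        assert partition.region3 == (23, 26)
        assert partition.spanning_intervals == (1, 22)
        assert len(partition.region_intervals("inversion")) == 20

    def test_interval_region_lookup(self, partition):
        assert partition.interval_region(0) == "region1"
        assert partition.interval_region(1) == "spanning"
        assert partition.interval_region(10) == "inversion"
        assert partition.interval_region(22) == "spanning"
        assert partition.interval_region(24) == "region3"

    def test_bad_layout_rejected(self, study_map):
        with pytest.raises(ValueError, match="ordered, disjoint"):
            RegionPartition.from_markers(
                study_map, "3", ("CH3-1", "CH3-2"), ("CH3-4", "CH3-23"), ("CH3-24", "CH3-27")
            )


class TestClassification:
    def test_all_het_individual_is_zero_class(self, study_map, partition):
        sl = study_map.chromosome_slice("3")
        sub = study_map.table.iloc[sl].reset_index(drop=True)
        from invcross.io import MarkerMap

        chrom_map = MarkerMap(sub)
        calls = np.full((1, 27), HET, dtype=np.int8)
        g = GenotypeMatrix(["quiet"], calls, chrom_map)
        events = classify_region_events(count_crossovers(g), partition)
        assert events.class_counts["zero"] == 1

    def test_generator_respects_exclusivity(self, partition, study_map):
        """Model gametes never mix regions (structural guarantee)."""
        model = PairingModel(0.2, 0.3, 0.5, 0.5, 1.0, 0.5)
        sim = simulate_inversion_gametes(model, 3000, partition, study_map, seed=2)
        events = classify_region_events(count_crossovers(sim), partition)
        assert events.class_counts["mixed"] == 0
        assert events.class_counts["spanning"] == 0
        assert sum(events.class_counts.values()) == 3000

    def test_table_style_construction(self):
        events = RegionEventTable.from_class_counts(418, region1=3, inversion={2: 18}, region3=48)
        assert events.class_vector.tolist() == [3, 18, 48, 349]
        assert events.mean_counts == pytest.approx((3 / 418, 36 / 418, 48 / 418))


class TestSimulation:
    def test_viable_gametes_never_carry_odd_inversion_counts(self, partition, study_map):
        model = PairingModel(0.1, 0.6, 0.3, 0.3, 1.2, 0.4)
        inv_ivs = set(partition.region_intervals("inversion"))
        for seed in range(5):
            sim = simulate_inversion_gametes(model, 500, partition, study_map, seed=seed)
            profile = count_crossovers(sim)
            for ind in sim.individuals:
                hits = [iv for iv in profile.intervals.get((ind, "3"), []) if iv in inv_ivs]
                assert len(hits) % 2 == 0

    def test_region3_only_model_confines_crossovers(self, partition, study_map):
        model = PairingModel(0.0, 0.0, 1.0, 0.0, 0.0, 0.8)
        sim = simulate_inversion_gametes(model, 1000, partition, study_map, seed=7)
        profile = count_crossovers(sim)
        for ind in sim.individuals:
            for iv in profile.intervals.get((ind, "3"), []):
                assert partition.interval_region(iv) == "region3"

    def test_viable_fraction_matches_closed_form(self, partition, study_map):
        """Rejection rate reproduces Z = (1 + exp(-2 lam)) / 2 when P2 = 1."""
        lam = 0.5
        model = PairingModel(0.0, 1.0, 0.0, 0.0, lam, 0.0)
        n = 100_000
        _, truth = simulate_inversion_gametes(model, n, partition, study_map, seed=3, return_truth=True)
        attempts = n + truth["n_rejected"]
        z_expected = (1 + math.exp(-2 * lam)) / 2
        se = math.sqrt(z_expected * (1 - z_expected) / attempts)
        assert n / attempts == pytest.approx(z_expected, abs=3.5 * se)

    def test_degenerate_survival_aborts(self, partition, study_map):
        model = PairingModel(0.0, 1.0, 0.0, 0.0, 30.0, 0.0)
        with pytest.raises(RuntimeError, match="survival"):
            simulate_inversion_gametes(model, 10, partition, study_map, seed=0, min_survival=0.6)

    def test_selection_inert_without_inversion_pairing(self, partition, study_map):
        """With P2 = 0 the class frequencies match plain multinomial-Poisson expectations."""
        model = PairingModel(0.3, 0.0, 0.7, 0.4, 0.0, 0.6)
        n = 20_000
        sim = simulate_inversion_gametes(model, n, partition, study_map, seed=5)
        events = classify_region_events(count_crossovers(sim), partition)
        expected = model.class_probabilities(events.interval_counts)
        for name in ("region1", "region3", "zero"):
            p = expected[name]
            se = math.sqrt(p * (1 - p) / n)
            assert events.class_counts[name] / n == pytest.approx(p, abs=3.5 * se)


class TestCalibration:
    def test_recovers_generating_simplex_on_average(self, partition, study_map):
        """Mean of 8 replicate fits at n = 10^4 lands within 0.02 of truth."""
        true = PairingModel(0.2, 0.3, 0.5, 0.4, 1.2, 0.6)
        estimates = []
        for seed in range(8):
            sim = simulate_inversion_gametes(true, 10_000, partition, study_map, seed=600 + seed)
            events = classify_region_events(count_crossovers(sim), partition)
            fit = calibrate_pairing(events, grid_step=0.02)
            estimates.append(fit.model.probabilities)
        mean = np.mean(estimates, axis=0)
        assert np.abs(mean - np.array([0.2, 0.3, 0.5])).max() < 0.02

    def test_exclusivity_violations_rejected(self):
        events = RegionEventTable(
            n=100,
            class_counts={"region1": 5, "inversion": 5, "region3": 5, "zero": 75, "spanning": 0, "mixed": 10},
            mean_counts=(0.05, 0.1, 0.05),
        )
        with pytest.raises(ValueError, match="exclusivity"):
            calibrate_pairing(events)

    def test_fit_report_exposes_surface(self):
        events = RegionEventTable.from_class_counts(418, region1=3, inversion={2: 18}, region3=48)
        fit = calibrate_pairing(events, grid_step=0.05)
        assert {"P1", "P2", "score"} <= set(fit.grid.columns)
        assert np.isfinite(fit.grid["score"]).sum() > 100
        assert fit.summary()["viable_fraction_Z"] < 1.0


class TestPredictedHeatmap:
    def test_no_recombination_means_uniform_maximal_lod(self, partition, study_map):
        model = PairingModel(1 / 3, 1 / 3, 1 / 3, 0.0, 0.0, 0.0)
        n = 50
        matrix = predict_lod_heatmap(model, partition, study_map, n, seed=1)
        off = matrix.lod[~np.eye(27, dtype=bool)]
        assert np.allclose(off, n * np.log10(2), atol=1e-9)

    def test_fitted_male_model_shows_inversion_block(self, partition, study_map):
        """Markers flanking the inverted segment stay tightly linked."""
        from invcross.simulate import pairing_model

        model = pairing_model("male")
        matrix = predict_lod_heatmap(model, partition, study_map, 418, seed=4)
        ids = matrix.marker_map.marker_ids
        i, j = ids.index("CH3-3"), ids.index("CH3-23")
        assert matrix.lod[i, j] > 50  # tight linkage across ~19 Mbp
        # outside-region pair on an ordinary chromosome arm decays far more
        assert matrix.r_hat[i, j] < 0.1
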