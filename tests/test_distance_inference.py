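"""Loop calibration, d = L0 - dL conversion, peak fitting, bootstrap."""
import numpy as np
import pytest

from dnacaliper.distance_inference import (
    bootstrap_peak_uncertainty,
    calibrate_loop_length,
    deltaL_to_distance,
    fit_molecule_peaks,
    per_molecule_average_distribution,
)
from dnacaliper.errors import ArgumentError, DomainError, FitError
from dnacaliper.simulator import simulate_deltaL_dataset


class TestCalibration:
    def test_exact_line_recovered(self):
        n = np.array([0, 10, 20, 30, 40], dtype=float)
        pts = np.column_stack([n, 28.0 - 0.5 * n])
        cal = calibrate_loop_length(pts)
        assert cal.L0 == pytest.approx(28.0)
        assert cal.slope == pytest.approx(0.5)
        assert cal.residual_rms == pytest.approx(0.0, abs=1e-12)

    def test_noisy_ladder_within_three_se(self, rng):
        lengths = np.repeat([10, 20, 30, 40, 50], 10).astype(float)
        dl = 28.0 - 0.4 * lengths + rng.normal(0, 0.3, len(lengths))
        cal = calibrate_loop_length(np.column_stack([lengths, dl]))
        assert abs(cal.L0 - 28.0) <= 3 * cal.se_L0
        assert abs(cal.slope - 0.4) <= 3 * cal.se_slope

    def test_single_length_rank_deficient(self):
        pts = np.column_stack([np.full(5, 20.0), np.linspace(19, 21, 5)])
        with pytest.raises(FitError):
            calibrate_loop_length(pts)


class TestDistanceConversion:
    def _cal(self):
        n = np.array([0, 10, 20, 30], dtype=float)
        return calibrate_loop_length(np.column_stack([n, 28.0 - 0.5 * n]))

    def test_deltaL_equal_L0_gives_zero(self):
        d, _ = deltaL_to_distance(28.0, self._cal())
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_folded_unloop_peak_converts_to_2nm(self):
        d, se = deltaL_to_distance(26.0, self._cal(), deltaL_se=0.1)
        assert d == pytest.approx(2.0, abs=1e-9)
        assert se >= 0.1  # quadrature includes the measurement error

    def test_far_exceeding_L0_flagged(self):
        with pytest.raises(DomainError):
            deltaL_to_distance(38.0, self._cal())

    def test_involution_with_generating_relation(self):
        cal = self._cal()
        for d_true in (0.5, 1.0, 2.0, 5.0):
            d, _ = deltaL_to_distance(cal.L0 - d_true, cal)
            assert d == pytest.approx(d_true, abs=1e-9)


class TestMoleculePeaks:
    def test_single_gaussian_recovered(self, rng):
        vals = rng.normal(26.0, 0.5, 50)
        fit = fit_molecule_peaks(vals, expected_k=1)
        assert len(fit.peaks) == 1
        assert abs(fit.peaks[0].mean - 26.0) <= 3 * 0.5 / np.sqrt(50)

    def test_four_well_separated_components(self):
        mols = simulate_deltaL_dataset(
            [(12.0, 0.5, 1), (17.0, 0.5, 1), (22.0, 0.5, 1), (27.0, 0.5, 1)],
            n_molecules=1, cycles_per_molecule=400, seed=8,
        )
        fit = fit_molecule_peaks(mols[0], expected_k=4)
        means = sorted(p.mean for p in fit.peaks)
        for m, truth in zip(means, [12.0, 17.0, 22.0, 27.0]):
            assert m == pytest.approx(truth, abs=0.3)

    def test_degenerate_identical_observations(self):
        fit = fit_molecule_peaks(np.full(20, 26.0), expected_k=2)
        assert len(fit.peaks) == 1
        assert fit.peaks[0].mean == 26.0
        assert fit.peaks[0].sigma == pytest.approx(0.05)

    def test_component_cap_by_sample_size(self, rng):
        vals = rng.normal(20.0, 0.5, 8)  # 8 obs cannot support 4 components
        fit = fit_molecule_peaks(vals, expected_k=4)
        assert len(fit.peaks) == 1


class TestPopulationAveraging:
    def _fits(self, means, seed=0):
        mols = [
            simulate_deltaL_dataset([(m, 0.5, 1.0)], 1, 30, seed=seed + i)[0]
            for i, m in enumerate(means)
        ]
        return [fit_molecule_peaks(m, expected_k=1) for m in mols]

    def test_sixteen_molecules_recover_population_mean(self, rng):
        true_means = 26.0 + rng.normal(0, 0.3, 16)
        pop = per_molecule_average_distribution(self._fits(true_means),
                                                expected_k=1)
        peak = pop.peaks[0]
        assert abs(peak.mean - 26.0) <= 3 * max(peak.stderr, 0.3 / 4)

    def test_identical_molecule_means_zero_sem(self):
        from dnacaliper.distance_inference import MoleculePeaks, PeakEstimate

        fits = [
            MoleculePeaks(f"m{i}", [PeakEstimate(26.0, 0.5, 1.0, 0.1, 30)],
                          True, 30)
            for i in range(8)
        ]
        pop = per_molecule_average_distribution(fits, expected_k=1)
        assert pop.peaks[0].stderr == 0.0

    def test_two_clusters_resolved(self, rng):
        means = np.concatenate([20 + rng.normal(0, 0.2, 8),
                                26 + rng.normal(0, 0.2, 8)])
        pop = per_molecule_average_distribution(self._fits(means),
                                                expected_k=2)
        got = sorted(p.mean for p in pop.peaks)
        assert got[0] == pytest.approx(20.0, abs=0.5)
        assert got[1] == pytest.approx(26.0, abs=0.5)

    def test_single_molecule_passthrough_warns(self):
        fits = self._fits([26.0])
        with pytest.warns(UserWarning):
            pop = per_molecule_average_distribution(fits, expected_k=1)
        assert len(pop.peaks) == 1

    def test_sem_decreases_with_molecule_count(self, rng):
        small = per_molecule_average_distribution(
            self._fits(26 + rng.normal(0, 0.3, 8)), expected_k=1
        )
        large = per_molecule_average_distribution(
            self._fits(26 + rng.normal(0, 0.3, 32)), expected_k=1
        )
        assert large.peaks[0].stderr < small.peaks[0].stderr


class TestBootstrap:
    def _population(self, n_mol=16, sigma_between=0.3, seed=1):
        rng = np.random.default_rng(seed)
        means = 26.0 + rng.normal(0, sigma_between, n_mol)
        from dnacaliper.distance_inference import MoleculePeaks, PeakEstimate

        fits = [
            MoleculePeaks(f"m{i}", [PeakEstimate(m, 0.5, 1.0, 0.1, 30)],
                          True, 30)
            for i, m in enumerate(means)
        ]
        return per_molecule_average_distribution(fits, expected_k=1)

    def test_bootstrap_se_matches_sem_oracle(self):
        pop = self._population()
        sigma_b = pop.peaks[0].sigma
        boot = bootstrap_peak_uncertainty(pop, n_iter=2000, seed=3)
        assert boot.peak_se[0] == pytest.approx(sigma_b / 4.0, rel=0.20)

    def test_iteration_count_convergence(self):
        pop = self._population()
        b1 = bootstrap_peak_uncertainty(pop, n_iter=300, seed=5)
        b2 = bootstrap_peak_uncertainty(pop, n_iter=3000, seed=6)
        w1 = b1.peak_ci[0, 1] - b1.peak_ci[0, 0]
        w2 = b2.peak_ci[0, 1] - b2.peak_ci[0, 0]
        assert w1 == pytest.approx(w2, rel=0.25)

    def test_zero_variance_gives_zero_width_ci(self):
        from dnacaliper.distance_inference import MoleculePeaks, PeakEstimate

        fits = [
            MoleculePeaks(f"m{i}", [PeakEstimate(26.0, 0.5, 1.0, 0.1, 30)],
                          True, 30)
            for i in range(8)
        ]
        pop = per_molecule_average_distribution(fits, expected_k=1)
        boot = bootstrap_peak_uncertainty(pop, n_iter=200, seed=1)
        assert boot.peak_ci[0, 0] == boot.peak_ci[0, 1] == 26.0

    def test_too_few_iterations_rejected(self):
        with pytest.raises(ArgumentError):
            bootstrap_peak_uncertainty(self._population(), n_iter=50)

    def test_seed_reproducibility(self):
        pop = self._population()
        a = bootstrap_peak_uncertainty(pop, n_iter=200, seed=9)
        b = bootstrap_peak_uncertainty(pop, n_iter=200, seed=9)
        assert np.array_equal(a.peak_ci, b.peak_ci)
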