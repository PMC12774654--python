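"""Generative model: traces, event logs, mixtures, Bell first passage."""
import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from dnacaliper.errors import ArgumentError, ConfigurationError, DomainError
from dnacaliper.presets import get_preset
from dnacaliper.rng import rng_stream
from dnacaliper.simulator import (
    BellTransition,
    ConformationGeometry,
    ForceProtocol,
    KineticModel,
    NoiseSpec,
    bell_mean_unfolding_force,
    bell_unfolding_cdf,
    calibrate_bell_k0,
    sample_sites,
    sample_unfolding_force,
    simulate_deltaL_dataset,
    simulate_force_jump_trace,
    simulate_ramp_trace,
)


def _noiseless(seed=0):
    return NoiseSpec(sigma_x=0.0, sigma_deltaL=0.0, seed=seed)


class TestForceJumpTrace:
    def test_noiseless_steps_equal_generating_deltaL_exactly(self):
        preset = get_preset("k_endtoend", n_molecules=1, cycles=6)
        trace, log = simulate_force_jump_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            _noiseless(3),
        )
        # every logged unloop step is exactly L0 - d = 27.0 before noise
        assert np.allclose(log["deltaL_true"], 27.0)
        # and the emitted extension steps match the log exactly
        for _, row in log.iterrows():
            k = int(round(row["time_s"] * trace.sampling_rate))
            step = trace.extension[k] - trace.extension[k - 1]
            assert step == pytest.approx(row["deltaL_true"], abs=1e-9)

    def test_na_geometry_logs_26nm_folded_unloops(self):
        preset = get_preset("na_endtoend", n_molecules=1, cycles=20)
        _, log = simulate_force_jump_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            _noiseless(11),
        )
        folded = log.loc[log["event_type"] == "unloop_folded", "deltaL_true"]
        assert len(folded) > 0
        assert np.allclose(folded, 26.0)
        # unfold-first cycles split 26 into 6 + 20
        unfold = log.loc[log["event_type"] == "unfold", "deltaL_true"]
        if len(unfold):
            assert np.allclose(unfold, 6.0)

    def test_site_sampling_uniform_within_binomial_99_bounds(self):
        sites = ["a", "b", "c", "d"]
        n = 10_000
        drawn = sample_sites(sites, n, rng_stream(1, "sites"))
        counts = pd.Series(drawn).value_counts()
        p = 0.25
        half = 2.576 * np.sqrt(n * p * (1 - p))
        for s in sites:
            assert abs(counts[s] - n * p) < half

    def test_unknown_geometry_site_rejected(self):
        preset = get_preset("k_endtoend")
        bad_geom = ConformationGeometry(
            "bad", {"nope": 1.0}, loop_extension_nm=28.0
        )
        with pytest.raises(ConfigurationError):
            simulate_force_jump_trace(
                preset.design, bad_geom, preset.protocol, preset.kinetics,
                _noiseless(),
            )

    def test_seed_determinism(self):
        preset = get_preset("k_endtoend", n_molecules=1, cycles=3)
        noise = NoiseSpec(seed=9)
        t1, l1 = simulate_force_jump_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            noise,
        )
        t2, l2 = simulate_force_jump_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            noise,
        )
        assert np.array_equal(t1.extension, t2.extension)
        pd.testing.assert_frame_equal(l1, l2)


class TestRampTrace:
    def test_seed_determinism(self):
        preset = get_preset("na_directional", n_molecules=1, cycles=3)
        noise = NoiseSpec(seed=4)
        t1, l1 = simulate_ramp_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            noise,
        )
        t2, l2 = simulate_ramp_trace(
            preset.design, preset.geometry, preset.protocol, preset.kinetics,
            noise,
        )
        assert np.array_equal(t1.extension, t2.extension)
        pd.testing.assert_frame_equal(l1, l2)

    def test_logged_unfolding_forces_follow_first_passage_law(self):
        # mean of sampled forces vs quadrature of the analytic density
        tr = BellTransition(1e-3, 1.5)
        forces = sample_unfolding_force(tr, 6.0, rng=rng_stream(2, "f"),
                                        size=1000)
        analytic = bell_mean_unfolding_force(tr, 6.0)
        se = np.std(forces, ddof=1) / np.sqrt(len(forces))
        assert abs(np.mean(forces) - analytic) < 3 * se

    def test_large_dx_concentrates_forces_at_zero(self):
        tr = BellTransition(1.0, 500.0)
        forces = sample_unfolding_force(tr, 6.0, rng=rng_stream(3, "f"),
                                        size=200)
        assert np.max(forces) < 0.5


class TestDeltaLDataset:
    def test_zero_sigma_single_component(self):
        mols = simulate_deltaL_dataset([(26.0, 0.0, 1.0)], 3, 10, seed=1)
        for m in mols:
            assert np.allclose(m.deltaL, 26.0)

    def test_mixture_means_within_three_se(self):
        comps = [(18.0, 0.5, 1.0), (21.0, 0.5, 1.0), (24.0, 0.5, 1.0)]
        mols = simulate_deltaL_dataset(comps, 10, 300, seed=2)
        values = np.concatenate([m.deltaL for m in mols])
        for mean, sigma, _ in comps:
            sel = values[np.abs(values - mean) < 1.5]
            se = sigma / np.sqrt(len(sel))
            assert abs(np.mean(sel) - mean) < 3 * se

    def test_zero_weight_component_never_sampled(self):
        comps = [(10.0, 0.1, 1.0), (50.0, 0.1, 0.0)]
        mols = simulate_deltaL_dataset(comps, 5, 100, seed=3)
        values = np.concatenate([m.deltaL for m in mols])
        assert np.all(values < 20)

    def test_empty_components_rejected(self):
        with pytest.raises(ArgumentError):
            simulate_deltaL_dataset([], 3, 10, seed=1)


class TestBellFirstPassage:
    def test_sampled_cdf_matches_analytic_ks(self):
        tr = BellTransition(5e-4, 1.5)
        draws = sample_unfolding_force(tr, 6.0, rng=rng_stream(5, "ks"),
                                       size=10_000)
        stat = kstest(draws, lambda F: bell_unfolding_cdf(F, tr, 6.0)).statistic
        assert stat < 0.02

    def test_huge_k0_means_instant_unfolding(self):
        tr = BellTransition(1e6, 1.5)
        assert bell_mean_unfolding_force(tr, 6.0) < 0.1

    def test_calibration_reaches_target_mean(self):
        tr = calibrate_bell_k0(21.0, dx=1.5, ramp_rate=6.0)
        assert bell_mean_unfolding_force(tr, 6.0) == pytest.approx(21.0, abs=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DomainError):
            BellTransition(-1.0, 1.0)
        with pytest.raises(DomainError):
            sample_unfolding_force(BellTransition(1.0, 1.0), ramp_rate=0.0)
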