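"""PFGSTE attenuation model, mono-exponential fitting and inversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffuspect import (DecayCurve, DiffusionSpectrum, GradientSchedule,
                        NoiseSpec, PFGSTEModel, b_factor,
                        build_reference_schedule, extract_peaks,
                        fit_monoexponential, invert_dosy,
                        simulate_pfgste_decay)

D_PEPTIDE = 3.40e-10
D_SEED = 1.56e-11  # slow species: fibril-seed regime


class TestSchedule:
    def test_reference_schedule_values(self, reference_schedule):
        assert len(reference_schedule) == 32
        assert reference_schedule.gradients[0] == pytest.approx(0.0177)
        assert reference_schedule.gradients[-1] == pytest.approx(2.5)
        assert reference_schedule.delta == 2e-3
        assert reference_schedule.big_delta == 50e-3

    def test_b_factor_zero_gradient(self):
        sched = GradientSchedule(gradients=np.array([0.0, 1.0]),
                                 delta=2e-3, big_delta=50e-3)
        assert b_factor(sched)[0] == 0.0

    def test_b_factor_at_max_gradient(self, reference_schedule):
        # gamma^2 g^2 delta^2 (Delta - delta/3) at g = 2.5 T/m
        assert b_factor(reference_schedule)[-1] == pytest.approx(8.83e10,
                                                             rel=1e-3)

    @settings(max_examples=20, derandomize=True)
    @given(g=st.floats(1e-3, 5.0))
    def test_b_quadratic_in_gradient(self, g):
        s1 = GradientSchedule(gradients=np.array([g]), delta=2e-3,
                              big_delta=50e-3)
        s2 = GradientSchedule(gradients=np.array([2 * g]), delta=2e-3,
                              big_delta=50e-3)
        assert b_factor(s2)[0] == pytest.approx(4 * b_factor(s1)[0],
                                                rel=1e-12)

    @pytest.mark.parametrize("kw", [
        dict(gradients=np.array([1.0, 0.5]), delta=2e-3, big_delta=50e-3),
        dict(gradients=np.array([-0.1, 0.5]), delta=2e-3, big_delta=50e-3),
        dict(gradients=np.array([0.1]), delta=0.0, big_delta=50e-3),
        dict(gradients=np.array([0.1]), delta=9e-3, big_delta=2e-3),
    ])
    def test_invalid_schedule_rejected(self, kw):
        with pytest.raises(ValueError):
            GradientSchedule(**kw)

    def test_decay_curve_length_mismatch(self, reference_schedule):
        with pytest.raises(ValueError):
            DecayCurve(gradients=reference_schedule.gradients,
                       intensities=np.zeros(5), schedule=reference_schedule)


class TestMonoexponential:
    def test_exact_model_recovered(self, reference_schedule):
        decay = simulate_pfgste_decay([(0.8, D_PEPTIDE)], reference_schedule)
        fit = fit_monoexponential(decay)
        assert fit.D == pytest.approx(D_PEPTIDE, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
        assert not fit.degenerate

    def test_constant_signal_flagged_degenerate(self, reference_schedule):
        decay = DecayCurve(gradients=reference_schedule.gradients,
                           intensities=np.full(32, 2.0),
                           schedule=reference_schedule)
        assert fit_monoexponential(decay).degenerate

    def test_two_component_decay_inflates_residual(self, reference_schedule):
        two = simulate_pfgste_decay([(0.5, D_PEPTIDE), (0.5, 1.7e-11)],
                                    reference_schedule)
        one = simulate_pfgste_decay([(1.0, D_PEPTIDE)], reference_schedule)
        r_two = fit_monoexponential(two).residual
        r_one = fit_monoexponential(one).residual
        assert r_one < 1e-9          # exact model class
        assert r_two > 1e-2          # model inadequacy is visible

    def test_monte_carlo_recovery_at_snr_100(self, reference_schedule):
        estimates = [
            fit_monoexponential(simulate_pfgste_decay(
                [(1.0, D_PEPTIDE)], reference_schedule,
                NoiseSpec(snr=100, seed=seed))).D
            for seed in range(20)]
        assert abs(np.median(estimates) - D_PEPTIDE) / D_PEPTIDE < 0.02


class TestInversion:
    def test_single_component_mode_on_grid(self, reference_schedule):
        decay = simulate_pfgste_decay([(1.0, D_PEPTIDE)], reference_schedule)
        spec = invert_dosy(decay)
        mode = spec.grid[np.argmax(spec.weights)]
        cell = np.log10(spec.grid[1] / spec.grid[0])
        assert abs(np.log10(mode / D_PEPTIDE)) <= cell
        sel = np.abs(np.log10(spec.grid / D_PEPTIDE)) <= 0.2
        assert spec.weights[sel].sum() / spec.total_weight >= 0.95

    def test_mass_conservation(self, reference_schedule):
        decay = simulate_pfgste_decay([(0.6, D_PEPTIDE), (0.4, D_SEED)],
                                      reference_schedule)
        spec = invert_dosy(decay)
        s0 = fit_monoexponential(
            simulate_pfgste_decay([(1.0, D_PEPTIDE)], reference_schedule)
        ).amplitude  # = 1 by construction; total injected weight here
        assert spec.total_weight == pytest.approx(1.0, rel=0.02)
        assert s0 == pytest.approx(1.0, rel=1e-6)

    def test_zero_signal_gives_empty_spectrum(self, reference_schedule):
        decay = DecayCurve(gradients=reference_schedule.gradients,
                           intensities=np.zeros(32),
                           schedule=reference_schedule)
        spec = invert_dosy(decay)
        assert np.all(spec.weights == 0.0)
        assert extract_peaks(spec) == []

    def test_reforward_residual_improves_as_lambda_shrinks(
            self, reference_schedule):
        decay = simulate_pfgste_decay([(0.5, D_PEPTIDE), (0.5, D_SEED)],
                                      reference_schedule)
        resid = [invert_dosy(decay, regularization=lam).residual_norm
                 for lam in (1e-1, 1e-2, 1e-3, 1e-4)]
        assert all(a >= b - 1e-12 for a, b in zip(resid, resid[1:]))

    def test_peak_count_monotone_in_lambda(self, reference_schedule):
        decay = simulate_pfgste_decay([(0.5, D_PEPTIDE), (0.5, D_SEED)],
                                      reference_schedule,
                                      NoiseSpec(snr=200, seed=4))
        counts = [len(extract_peaks(invert_dosy(decay, regularization=lam)))
                  for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_grid_coverage_warning(self, reference_schedule):
        decay = simulate_pfgste_decay([(1.0, 3.4e-10)], reference_schedule)
        with pytest.warns(UserWarning, match="outside the grid"):
            invert_dosy(decay, grid=np.logspace(-12, -11, 64))

    def test_model_interface_matches_functions(self, reference_schedule):
        decay = simulate_pfgste_decay([(1.0, D_PEPTIDE)], reference_schedule)
        model = PFGSTEModel(decay)
        assert model.fit().D == fit_monoexponential(decay).D
        np.testing.assert_array_equal(model.fit_spectrum().weights,
                                      invert_dosy(decay).weights)


class TestPeaks:
    def test_single_component_single_full_peak(self, reference_schedule):
        decay = simulate_pfgste_decay([(1.0, D_PEPTIDE)], reference_schedule)
        peaks = extract_peaks(invert_dosy(decay))
        assert len(peaks) == 1
        assert peaks[0].weight_fraction == pytest.approx(1.0)

    def test_two_component_fractions_conserved(self, reference_schedule):
        decay = simulate_pfgste_decay([(0.5, D_PEPTIDE), (0.5, D_SEED)],
                                      reference_schedule)
        peaks = extract_peaks(invert_dosy(decay))
        assert len(peaks) == 2
        assert sum(p.weight_fraction for p in peaks) == pytest.approx(
            1.0, abs=1e-6)

    def test_flat_spectrum_empty(self):
        spec = DiffusionSpectrum(grid=np.logspace(-12, -8, 16),
                                 weights=np.zeros(16), regularization=0.0,
                                 residual_norm=0.0)
        assert extract_peaks(spec) == []

    def test_resolution_limits(self, reference_schedule):
        # components at D ratio 5 resolve at SNR 200; ratio 1.5 merges
        for ratio, expected in ((5.0, 2), (1.5, 1)):
            decay = simulate_pfgste_decay(
                [(0.5, D_PEPTIDE), (0.5, D_PEPTIDE / ratio)],
                reference_schedule, NoiseSpec(snr=200, seed=0))
            n = len(extract_peaks(invert_dosy(decay)))
            assert n == expected, f"ratio {ratio}: {n} peaks"

    def test_min_fraction_filters_small_peaks(self, reference_schedule):
        decay = simulate_pfgste_decay([(0.97, D_PEPTIDE), (0.03, D_SEED)],
                                      reference_schedule)
        assert len(extract_peaks(invert_dosy(decay), min_fraction=0.1)) == 1
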