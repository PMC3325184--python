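import numpy as np
import pytest

from popcode.decoding import (
    DecoderSpec,
    DegenerateConditionError,
    DetectionCondition,
    DiscriminationCondition,
    detect_trial,
    discriminate_trial,
    llr_interval,
    log_tuning,
    predict_choice_probability,
    predicted_pse,
    predicted_psychometric,
    read_out,
    readout_weights,
    reduced_log_likelihood,
    weighting_profile,
)
from popcode.encoding import PopulationParams, population_response
from popcode.spectra import NoiseSpec, ParameterError, make_frequency_grid


def _dense_readout_oracle(L, center, width, n_fine=200_001):
    """Independent quadrature: dense trapezoid of the Gaussian-weighted
    piecewise-linear likelihood, normalized over the grid support."""
    from popcode.encoding import FWHH_TO_SIGMA

    x = L.grid.log2_frequencies
    xf = np.linspace(x[0], x[-1], n_fine)
    lf = np.interp(xf, x, L.value)
    sigma = width * FWHH_TO_SIGMA
    g = np.exp(-0.5 * ((xf - np.log2(center)) / sigma) ** 2)
    return np.trapezoid(g * lf, xf) / np.trapezoid(g, xf)


class TestReducedLogLikelihood:
    def test_single_spike_peaks_at_preferred_frequency(self, pop, grid):
        counts = np.zeros(pop.n_neurons)
        i = 42
        counts[i] = 1.0
        L = reduced_log_likelihood(counts, pop, grid)
        peak = grid.frequencies[np.argmax(L.value)]
        assert abs(np.log2(peak / pop.f_pref[i])) <= grid.log2_step

    def test_zero_counts_give_flat_zero(self, pop, grid):
        L = reduced_log_likelihood(np.zeros(pop.n_neurons), pop, grid)
        assert not L.value.any()

    def test_linearity_in_counts(self, pop, grid):
        rng = np.random.default_rng(0)
        r1 = rng.gamma(2.0, 1.0, pop.n_neurons)
        r2 = rng.gamma(2.0, 1.0, pop.n_neurons)
        a, b = 0.7, -1.3
        lhs = reduced_log_likelihood(a * r1 + b * r2, pop, grid).value
        rhs = (a * reduced_log_likelihood(r1, pop, grid).value
               + b * reduced_log_likelihood(r2, pop, grid).value)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_highpass_noise_elevates_high_frequency_likelihood(self, pop, grid, noise):
        m_hp = population_response(pop, 5.5, 0.15, noise["highpass"], grid).mean_count
        m_no = population_response(pop, 5.5, 0.15, noise["none"], grid).mean_count
        L_hp = reduced_log_likelihood(m_hp, pop, grid)
        L_no = reduced_log_likelihood(m_no, pop, grid)
        j = grid.nearest_index(16.0)
        assert L_hp.value[j] > L_no.value[j]

    def test_length_mismatch(self, pop, grid):
        with pytest.raises(ParameterError):
            reduced_log_likelihood(np.zeros(3), pop, grid)


class TestReadOut:
    def test_zero_width_is_point_evaluation(self, pop, grid):
        rng = np.random.default_rng(1)
        L = reduced_log_likelihood(rng.gamma(1.0, 1.0, pop.n_neurons), pop, grid)
        j = grid.nearest_index(5.5)
        center = grid.frequencies[j]
        assert read_out(L, center, 0.0) == pytest.approx(L.value[j], abs=1e-12)

    def test_unit_mass_on_constant(self, pop, grid):
        from popcode.decoding import ReducedLogLikelihood

        L = ReducedLogLikelihood(grid=grid, value=np.full(len(grid), 3.25))
        for width in (0.5, 2.0, 4.2):
            assert read_out(L, 5.5, width) == pytest.approx(3.25, abs=1e-10)

    @pytest.mark.parametrize("width", [0.5, 2.0, 4.2])
    def test_matches_refined_quadrature(self, pop, grid, noise, width):
        m = population_response(pop, 5.5, 0.15, noise["highpass"], grid).mean_count
        L = reduced_log_likelihood(m, pop, grid)
        got = read_out(L, 5.5, width)
        oracle = _dense_readout_oracle(L, 5.5, width)
        assert got == pytest.approx(oracle, rel=1e-6)

    def test_center_outside_grid(self, pop, grid):
        L = reduced_log_likelihood(np.ones(pop.n_neurons), pop, grid)
        with pytest.raises(ParameterError):
            read_out(L, 500.0, 1.0)


class TestWeightingProfile:
    def test_zero_width_weights_are_log_tuning(self, pop, grid):
        j = grid.nearest_index(5.5)
        center = grid.frequencies[j]
        w = weighting_profile(center, 0.0, pop, grid)
        expected = log_tuning(pop, np.array([center]))[:, 0]
        assert np.allclose(w, expected, atol=1e-12)
        assert pop.f_pref[np.argmax(w)] == pytest.approx(center, rel=0.05)

    def test_weighted_sum_equals_readout_integral(self, pop, grid):
        rng = np.random.default_rng(2)
        w = weighting_profile(5.5, 2.0, pop, grid)
        for _ in range(100):
            counts = rng.gamma(1.5, 2.0, pop.n_neurons)
            L = reduced_log_likelihood(counts, pop, grid)
            direct = read_out(L, 5.5, 2.0)
            assert w @ counts == pytest.approx(direct, rel=1e-8)

    def test_broad_width_spreads_weight_to_insensitive_neurons(self, pop, grid):
        w0 = weighting_profile(5.5, 0.0, pop, grid)
        w4 = weighting_profile(5.5, 4.2, pop, grid)
        far = np.abs(np.log2(pop.f_pref / 5.5)) > 2.0
        assert w0[far].max() < 1e-4 * w0.max()
        assert w4[far].max() > 0.02 * w4.max()


class TestIntervalDecisions:
    def test_llr_requires_ordered_frequencies(self, pop, grid, decoder):
        with pytest.raises(ParameterError):
            llr_interval(np.ones(pop.n_neurons), 4.0, 5.5, decoder, pop, grid)

    def test_llr_offset_invariance(self, pop, grid, decoder):
        # the interval LLR is a difference of read-outs, so adding any
        # constant to the reduced log likelihood changes nothing
        from popcode.decoding import ReducedLogLikelihood

        rng = np.random.default_rng(3)
        counts = rng.gamma(1.0, 1.0, pop.n_neurons)
        L = reduced_log_likelihood(counts, pop, grid)
        base = read_out(L, 7.0, 2.0) - read_out(L, 4.0, 2.0)
        shifted = ReducedLogLikelihood(grid=grid, value=L.value + 123.4)
        assert (read_out(shifted, 7.0, 2.0) - read_out(shifted, 4.0, 2.0)
                == pytest.approx(base, abs=1e-8))

    def test_mean_response_to_high_grating_gives_positive_llr(self, pop, grid, noise):
        dec = DecoderSpec(width=1e-6, efficiency=1.0)
        m = population_response(pop, 7.0, 0.15, noise["none"], grid).mean_count
        assert llr_interval(m, 7.0, 4.3, dec, pop, grid) > 0

    def test_noiseless_discrimination_is_deterministic(self, pop, grid, noise, decoder):
        m_hi = population_response(pop, 7.0, 0.15, noise["none"], grid).mean_count
        m_lo = population_response(pop, 4.3, 0.15, noise["none"], grid).mean_count
        assert discriminate_trial(m_lo, m_hi, 7.0, 4.3, decoder, pop, grid) == 2
        assert discriminate_trial(m_hi, m_lo, 7.0, 4.3, decoder, pop, grid) == 1

    def test_tie_broken_by_fair_coin(self, pop, grid, decoder):
        counts = np.ones(pop.n_neurons)
        picks = [discriminate_trial(counts, counts, 7.0, 4.3, decoder, pop, grid,
                                    rng=s) for s in range(200)]
        frac = np.mean(np.array(picks) == 1)
        assert 0.35 < frac < 0.65

    def test_detection_picks_signal_interval_on_means(self, pop, grid, noise, decoder):
        sig = population_response(pop, 5.5, 0.3, noise["broadband"], grid).mean_count
        blank = population_response(pop, None, 0.0, noise["broadband"], grid).mean_count
        assert detect_trial(sig, blank, 5.5, decoder, pop, grid) == 1
        assert detect_trial(blank, sig, 5.5, decoder, pop, grid) == 2

    def test_notched_noise_detection_nearly_unimpaired_at_zero_width(
            self, pop, grid, noise):
        dec = DecoderSpec(width=0.0, efficiency=1.0)
        p = {k: predict_choice_probability(
            pop, dec, DetectionCondition(5.5, 0.01, noise[k]), grid)
            for k in ("none", "notched", "broadband")}
        assert abs(p["notched"] - p["none"]) < 0.15
        assert p["broadband"] < p["none"] - 0.3


class TestChoiceProbability:
    def test_identical_stimuli_give_half(self, pop, grid, noise, decoder):
        cond = DiscriminationCondition(5.5, 5.5, noise["broadband"],
                                       noise["broadband"], 0.15)
        assert predict_choice_probability(pop, decoder, cond, grid) == 0.5

    def test_vanishing_efficiency_gives_half(self, pop, grid, noise):
        dec = DecoderSpec(width=4.2, efficiency=1e-9)
        cond = DiscriminationCondition(5.5, 9.0, noise["lowpass"],
                                       noise["broadband"], 0.15)
        assert predict_choice_probability(pop, dec, cond, grid) == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("cond_kind", ["disc", "det"])
    def test_analytic_agrees_with_monte_carlo(self, pop, grid, noise, cond_kind):
        if cond_kind == "disc":
            cond = DiscriminationCondition(5.5, 7.4, noise["lowpass"],
                                           noise["broadband"], 0.15)
        else:
            cond = DetectionCondition(5.5, 0.12, noise["broadband"])
        ana = predict_choice_probability(
            pop, DecoderSpec(width=4.2, efficiency=0.8, mode="analytic"), cond, grid)
        mc = predict_choice_probability(
            pop, DecoderSpec(width=4.2, efficiency=0.8, mode="monte_carlo",
                             n_sims=100_000), cond, grid, seed=11)
        assert abs(ana - mc) < 0.005


class TestPredictedPsychometric:
    def test_symmetric_pairing_is_unbiased(self, pop, grid, noise, decoder):
        pse = predicted_pse(pop, decoder, 5.5, noise["broadband"],
                            noise["broadband"], 0.15, grid)
        assert pse == pytest.approx(5.5, abs=1e-6)

    def test_lowpass_standard_shifts_pse_down(self, pop, grid, noise, decoder):
        pse = predicted_pse(pop, decoder, 5.5, noise["lowpass"],
                            noise["broadband"], 0.15, grid)
        assert pse < 5.5

    def test_curve_feeds_matching_frequency(self, pop, grid, noise, decoder):
        from popcode.psychometrics import fit_weibull, matching_frequency

        comps = np.geomspace(1.9, 15.6, 8)
        probs = predicted_psychometric(pop, decoder, 5.5, comps, noise["lowpass"],
                                       noise["broadband"], 0.15, grid)
        assert np.all(np.diff(probs) > 0)
        n = np.full(8, 100_000.0)
        fit = fit_weibull(np.log2(comps), n, n * probs, gamma=0.0, x_scale="log2")
        pse_fit = matching_frequency(fit)
        pse_direct = predicted_pse(pop, decoder, 5.5, noise["lowpass"],
                                   noise["broadband"], 0.15, grid)
        assert np.log2(pse_fit / pse_direct) == pytest.approx(0.0, abs=0.15)

    def test_bias_symmetry_with_symmetric_bands(self, decoder):
        # log-symmetric population and noise bands about the standard:
        # low-pass and high-pass PSE shifts are equal and opposite
        g = make_frequency_grid(5.5 * 2 ** -4, 5.5 * 2 ** 4, 64)
        p = PopulationParams(f_pref=5.5 * 2.0 ** np.linspace(-2, 2, 81))
        band = NoiseSpec("broadband", lower_bound=5.5 * 2 ** -2.0,
                         upper_bound=5.5 * 2 ** 2.0)
        lp = NoiseSpec("lowpass", cutoff=5.5, lower_bound=5.5 * 2 ** -2.0)
        hp = NoiseSpec("highpass", cutoff=5.5, upper_bound=5.5 * 2 ** 2.0)
        pse_lp = predicted_pse(p, decoder, 5.5, lp, band, 0.15, g,
                               bracket=(2.0, 15.0))
        pse_hp = predicted_pse(p, decoder, 5.5, hp, band, 0.15, g,
                               bracket=(2.0, 15.0))
        b_lp = np.log2(pse_lp / 5.5)
        b_hp = np.log2(pse_hp / 5.5)
        assert b_lp < -0.02 and b_hp > 0.02
        assert b_lp + b_hp == pytest.approx(0.0, abs=0.02)
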