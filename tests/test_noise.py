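"""Noise colours: spectral matrices, covariance factors, samplers, truncation."""

import numpy as np
import pytest

from crnoise.noise import (
    AuxiliarySpectrumParams,
    NoiseModel,
    apply_truncation,
    correlation_factor,
    factor_covariance,
    noise_spectrum_N,
    sample_auxiliary,
    sample_mixed,
    sample_ou,
    sample_power_law,
    sample_white,
)
from crnoise.presets import predator_prey_preset

try:
    from hypothesis import given, strategies as st

    HAVE_HYPOTHESIS = True
except ImportError:  # pragma: no cover
    HAVE_HYPOTHESIS = False

B_ONES = np.ones((2, 2))


def _periodogram(rec, dt):
    """One-sided power spectral density of a (n_steps,) record."""
    n = rec.shape[0]
    F = dt * np.fft.rfft(rec, axis=0)
    return np.abs(F) ** 2 / (n * dt)


class TestCorrelationFactor:
    def test_white_is_flat(self):
        m = NoiseModel(covariance=B_ONES, variant="white")
        assert np.all(correlation_factor(m, np.linspace(0, 9, 11)) == 1.0)

    def test_ou_lorentzian_values(self):
        m = NoiseModel(covariance=B_ONES, variant="ou", tau=100.0)
        assert correlation_factor(m, np.array([0.0]))[0] == 1.0
        assert correlation_factor(m, np.array([0.01]))[0] == pytest.approx(0.5)

    def test_power_law_pole_guard(self):
        m = NoiseModel(covariance=B_ONES, variant="power", alpha=2.0)
        with pytest.raises(ValueError, match="diverges"):
            correlation_factor(m, np.array([0.0, 1.0]))
        assert correlation_factor(m, np.array([2.0]))[0] == pytest.approx(0.25)

    def test_auxiliary_limits(self):
        aux = predator_prey_preset()
        # omega -> 0 limit is alpha / omega0^4; large omega decays to zero
        assert aux.spectrum(0.0) == pytest.approx(0.000384 / 0.016**2)
        assert aux.spectrum(100.0) < 1e-4 * aux.spectrum(0.0)
        # resonant (squared) form has a strict interior maximum
        om = np.linspace(0.0, 1.0, 2001)
        s = aux.spectrum(om)
        assert 0 < np.argmax(s) < len(om) - 1

    def test_printed_denominator_variant_is_monotone(self):
        aux = AuxiliarySpectrumParams(
            0.000384, 0.04, 0.04, 0.016, squared_denominator=False
        )
        om = np.linspace(0.0, 1.0, 2001)
        s = aux.spectrum(om)
        assert np.argmax(s) in (0, len(om) - 1)


class TestSpectralMatrix:
    def test_white_constant_in_omega(self):
        m = NoiseModel(covariance=B_ONES, variant="white")
        N = noise_spectrum_N(m, np.array([0.0, 0.5, 3.0]))
        assert np.allclose(N, B_ONES[None])

    def test_mixed_limit_values(self):
        B = np.array([[2.0, 1.0], [1.0, 3.0]])
        m = NoiseModel(covariance=B, variant="mixed", taus=(100.0, 0.0))
        assert np.allclose(noise_spectrum_N(m, 0.0), B)
        N = noise_spectrum_N(m, 0.01)  # omega tau = 1
        assert N[0, 0] == pytest.approx(B[0, 0] / 2)
        assert N[1, 1] == pytest.approx(B[1, 1])
        assert N[0, 1] == pytest.approx(B[0, 1] * (0.5 - 0.5j))
        assert np.allclose(N, N.conj().T)

    def test_mixed_with_equal_times_reduces_to_common_ou(self):
        B = np.array([[2.0, 0.5], [0.5, 1.0]])
        om = np.linspace(0.0, 2.0, 41)
        mixed = NoiseModel(covariance=B, variant="mixed", taus=(7.0, 7.0))
        common = NoiseModel(covariance=B, variant="ou", tau=7.0)
        assert np.allclose(
            noise_spectrum_N(mixed, om), noise_spectrum_N(common, om), atol=1e-12
        )

    def test_reduced_mask_zeroes_rows_and_columns(self):
        om = np.linspace(0.0, 1.0, 7)
        for variant, kw in [
            ("white", {}),
            ("ou", {"tau": 5.0}),
            ("mixed", {"taus": (5.0, 0.0)}),
        ]:
            m = NoiseModel(covariance=B_ONES, variant=variant, mask=(True, False), **kw)
            N = noise_spectrum_N(m, om)
            assert np.allclose(N[:, 1, :], 0.0) and np.allclose(N[:, :, 1], 0.0)
            assert not np.allclose(N[:, 0, 0], 0.0)

    if HAVE_HYPOTHESIS:

        @given(
            st.lists(st.floats(-5.0, 5.0), min_size=2, max_size=2),
            st.floats(0.0, 10.0),
            st.sampled_from(["white", "ou", "mixed", "aux"]),
        )
        def test_hermitian_for_random_covariances(self, offdiag_seed, omega, variant):
            a, c = abs(offdiag_seed[0]) + 1.0, abs(offdiag_seed[1]) + 1.0
            b = min(a, c) * 0.9  # keeps B positive definite
            B = np.array([[a, b], [b, c]])
            kw = {}
            if variant == "ou":
                kw["tau"] = 3.0
            if variant == "mixed":
                kw["taus"] = (2.0, 0.5)
            if variant == "aux":
                kw["aux"] = predator_prey_preset()
            m = NoiseModel(covariance=B, variant=variant, **kw)
            N = noise_spectrum_N(m, omega)
            assert np.allclose(N, N.conj().T, atol=1e-12)


class TestFactorCovariance:
    def test_rank_one_factor(self):
        b = factor_covariance(B_ONES)
        assert np.abs(b @ b.T - B_ONES).max() < 1e-12

    def test_identity_and_diagonal(self):
        assert np.allclose(factor_covariance(np.eye(2)), np.eye(2))
        assert np.allclose(
            factor_covariance(np.diag([4.0, 9.0])), np.diag([2.0, 3.0])
        )

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="negative eigenvalue"):
            factor_covariance(np.array([[1.0, 2.0], [2.0, 1.0]]))

    def test_tiny_negative_eigenvalue_clipped(self):
        v = np.array([1.0, 1.0]) / np.sqrt(2)
        B = np.outer(v, v) - 1e-13 * np.eye(2)
        b = factor_covariance(B)
        assert np.abs(b @ b.T - np.outer(v, v)).max() < 1e-10


class TestSamplers:
    def test_white_increment_covariance(self):
        rng = np.random.default_rng(0)
        B = np.array([[2.0, 1.0], [1.0, 2.0]])
        dt = 0.01
        rec = sample_white(100_000, dt, factor_covariance(B), rng)[:, :, 0]
        increments = rec * dt  # eta dt = b z sqrt(dt)
        est = np.cov((increments / np.sqrt(dt)).T)
        se = B.max() * 3 / np.sqrt(100_000)
        assert np.abs(est - B).max() < 3 * se + 0.05

    def test_comonotone_for_rank_one_covariance(self):
        rng = np.random.default_rng(1)
        rec = sample_white(20_000, 0.01, factor_covariance(B_ONES), rng)[:, :, 0]
        corr = np.corrcoef(rec.T)[0, 1]
        assert corr == pytest.approx(1.0, abs=1e-10)

    def test_zero_factor_gives_zero_record(self):
        rng = np.random.default_rng(2)
        assert np.all(sample_white(100, 0.01, np.zeros((2, 2)), rng) == 0.0)
        assert np.all(sample_ou(5.0, 100, 0.01, np.zeros((2, 2)), rng) == 0.0)

    def test_ou_stationary_moments_and_autocorrelation(self):
        rng = np.random.default_rng(3)
        tau, dt, lag = 100.0, 0.01, 10_000  # lag = tau
        rec = sample_ou(tau, 150_000, dt, np.eye(1), rng, n_sites=8)[:, 0, :]
        var = rec.var(axis=0)
        # stationary variance B/(2 tau) = 0.005 per site
        assert var.mean() == pytest.approx(0.005, rel=3 * 0.3 / np.sqrt(8))
        ac = np.array(
            [np.corrcoef(rec[:-lag, i], rec[lag:, i])[0, 1] for i in range(8)]
        )
        assert ac.mean() == pytest.approx(
            np.exp(-1), abs=3 * ac.std(ddof=1) / np.sqrt(8) + 0.02
        )

    def test_ou_requires_valid_tau(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_ou(-1.0, 10, 0.01, np.eye(1), rng)
        with pytest.raises(ValueError, match="exceed"):
            sample_ou(0.005, 10, 0.01, np.eye(1), rng)

    @pytest.mark.parametrize("alpha,tol", [(0.0, 0.05), (2.0, 0.1)])
    def test_power_law_periodogram_slope(self, alpha, tol):
        # frequency synthesis reproduces the requested spectral exponent
        rng = np.random.default_rng(4)
        n_steps, dt = 8192, 0.01
        acc = np.zeros(n_steps // 2 + 1)
        for _ in range(100):
            rec = sample_power_law(alpha, n_steps, dt, np.eye(1), rng)[:, 0, 0]
            acc += _periodogram(rec, dt)
        acc /= 100
        om = 2 * np.pi * np.fft.rfftfreq(n_steps, dt)
        sel = slice(5, n_steps // 8)
        slope = np.polyfit(np.log(om[sel]), np.log(acc[sel]), 1)[0]
        assert slope == pytest.approx(-alpha, abs=tol)

    def test_red_noise_is_low_frequency_dominated(self):
        rng = np.random.default_rng(5)
        rec = sample_power_law(2.0, 100_000, 0.01, np.eye(1), rng)[:, 0, 0]
        step_scale = np.abs(np.diff(rec)).mean()
        assert rec.std() > 20 * step_scale

    def test_auxiliary_matches_target_spectrum(self):
        rng = np.random.default_rng(6)
        params = predator_prey_preset()
        n_steps, dt = 20_000, 0.01
        acc = np.zeros(n_steps // 2 + 1)
        for _ in range(200):
            rec = sample_auxiliary(params, n_steps, dt, np.eye(1), rng)[:, 0, 0]
            acc += _periodogram(rec, dt)
        acc /= 200
        om = 2 * np.pi * np.fft.rfftfreq(n_steps, dt)
        band = (om > 0.02) & (om < 1.0)
        rel = np.abs(acc[band] - params.spectrum(om[band])) / params.spectrum(om[band])
        assert np.median(rel) < 0.10

    def test_auxiliary_zero_numerator_gives_zero(self):
        rng = np.random.default_rng(7)
        params = AuxiliarySpectrumParams(0.0, 0.0, 0.04, 0.016)
        rec = sample_auxiliary(params, 256, 0.01, np.eye(1), rng)
        assert np.abs(rec).max() == 0.0

    def test_mixed_sampler_matches_analytic_cross_spectrum(self):
        rng = np.random.default_rng(8)
        taus = np.array([20.0, 0.0])
        n_steps, dt = 20_000, 0.01
        b = factor_covariance(B_ONES)
        accP = np.zeros((2, n_steps // 2 + 1))
        accX = np.zeros(n_steps // 2 + 1, dtype=complex)
        reps = 80
        for _ in range(reps):
            rec = sample_mixed(taus, n_steps, dt, b, rng)[:, :, 0]
            F = dt * np.fft.rfft(rec, axis=0) / np.sqrt(n_steps * dt)
            accP += np.abs(F.T) ** 2
            accX += F[:, 0] * np.conj(F[:, 1])
        accP /= reps
        accX /= reps
        om = 2 * np.pi * np.fft.rfftfreq(n_steps, dt)
        m = NoiseModel(covariance=B_ONES, variant="mixed", taus=tuple(taus))
        N = noise_spectrum_N(m, om)
        band = (om > 0.05) & (om < 5.0)
        assert np.median(
            np.abs(accP[0, band] / N[band, 0, 0].real - 1.0)
        ) < 5 / np.sqrt(reps)
        assert np.median(
            np.abs(accP[1, band] / N[band, 1, 1].real - 1.0)
        ) < 5 / np.sqrt(reps)
        # cross spectrum keeps both magnitude and phase
        ratio = accX[band] / N[band, 0, 1]
        assert np.abs(np.median(ratio.real) - 1.0) < 0.2
        assert np.abs(np.median(ratio.imag)) < 0.2


class TestTruncation:
    def test_reference_white_noise_never_clamped(self):
        # threshold -k sqrt(Omega) = -100 vs sample scale 1/sqrt(dt) = 10
        rng = np.random.default_rng(9)
        rec = sample_white(100_000, 0.01, factor_covariance(B_ONES), rng)
        out, frac = apply_truncation(rec, np.array([10.0, 10.0]), 100.0)
        assert frac == 0.0
        assert np.array_equal(out, rec)

    def test_clamp_applied_at_threshold(self):
        k = np.array([2.0, 3.0])
        rec = np.full((5, 2, 1), -100.0)
        out, frac = apply_truncation(rec, k, 4.0)
        assert frac == 1.0
        assert np.allclose(out[:, 0, 0], -4.0)
        assert np.allclose(out[:, 1, 0], -6.0)

    def test_record_above_threshold_unchanged(self):
        rec = np.zeros((4, 2, 3)) + 1.0
        out, frac = apply_truncation(rec, np.array([1.0, 1.0]), 1.0)
        assert frac == 0.0 and np.array_equal(out, rec)


class TestModelValidation:
    def test_variant_aliases(self):
        assert NoiseModel(covariance=B_ONES, variant="ou", tau=1.0).variant == (
            "ornstein_uhlenbeck"
        )
        assert NoiseModel(covariance=B_ONES, variant="red", alpha=2.0).variant == (
            "power_law"
        )

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            ({"variant": "ou"}, "tau"),
            ({"variant": "power"}, "alpha"),
            ({"variant": "aux"}, "Auxiliary"),
            ({"variant": "mixed"}, "per species"),
            ({"variant": "white", "omega_strength": -1.0}, "Omega"),
        ],
    )
    def test_missing_parameters_rejected(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            NoiseModel(covariance=B_ONES, **kwargs)

    def test_non_psd_covariance_rejected(self):
        with pytest.raises(ValueError, match="semi-definite"):
            NoiseModel(covariance=np.array([[1.0, 3.0], [3.0, 1.0]]), variant="white")
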