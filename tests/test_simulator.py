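"""Forward-simulator tests: discretisation, conservation, limits."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from istlung import (
    BreathSeries,
    LognormalSpec,
    SinewaveForcing,
    ThetaParams,
    VentilatorSettings,
    build_lung,
    default_body,
    discretize_lognormal,
    simulate,
)
from istlung.exceptions import (
    ConfigurationError,
    UnphysicalDistributionError,
    UnphysicalForcingError,
)
from istlung.recovery import _sinusoid_fit


class TestDiscretizeLognormal:
    def test_degenerate_sigma_zero_is_uniform(self):
        w = discretize_lognormal(LognormalSpec(1.0, 0.0), 125)
        assert np.allclose(w, 1.0 / 125)

    def test_cv_matches_lognormal_moments(self):
        # oracle: Monte-Carlo moments of the continuous lognormal
        sigma = 0.3
        rng = np.random.default_rng(12345)
        draws = np.exp(sigma * rng.standard_normal(1_000_000))
        cv_mc = draws.std() / draws.mean()
        w = discretize_lognormal(LognormalSpec(1.0, sigma), 125)
        cv_disc = w.std() / w.mean()  # CV is scale-invariant
        assert abs(cv_disc - cv_mc) / cv_mc < 0.02
        # closed form as a cross-check on the oracle itself
        assert abs(cv_mc - np.sqrt(np.exp(sigma**2) - 1)) < 0.01

    @hyp_settings(max_examples=50, derandomize=True)
    @given(
        mu=st.floats(0.1, 5.0),
        sigma=st.floats(0.0, 1.8),
        n=st.integers(1, 200),
        total=st.floats(0.1, 10.0),
    )
    def test_weights_normalised_and_nonnegative(self, mu, sigma, n, total):
        w = discretize_lognormal(LognormalSpec(mu, sigma), n, total=total)
        assert len(w) == n
        assert np.all(w >= 0)
        assert abs(w.sum() - total) < 1e-12 * max(1.0, total)

    def test_absurd_sigma_raises(self):
        with pytest.raises(UnphysicalDistributionError):
            discretize_lognormal(LognormalSpec(1.0, 500.0), 125)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            LognormalSpec(mu=-1.0)
        with pytest.raises(ConfigurationError):
            LognormalSpec(sigma=-0.1)


class TestBuildLung:
    def test_homogeneous_structure(self, settings):
        theta = ThetaParams(2.0, 4.9)
        lung = build_lung(theta, settings, n_alv=125, n_ds=10)
        assert np.allclose(lung.alveolar_volumes, 2.0 / 125)
        assert np.allclose(lung.vent_fractions, 1 / 125)
        assert np.allclose(lung.perf_fractions, 1 / 125)
        assert abs(lung.deadspace_volumes.sum() - settings.dead_space) < 1e-12
        assert np.all(lung.alveolar_concentrations == 0)

    def test_fraction_sums_for_heterogeneous_lung(self, settings):
        theta = ThetaParams(
            2.3, 4.9, LognormalSpec(1.1, 0.9), LognormalSpec(0.9, 1.3)
        )
        lung = build_lung(theta, settings)
        assert abs(lung.vent_fractions.sum() - 1) < 1e-12
        assert abs(lung.perf_fractions.sum() - 1) < 1e-12

    def test_emphysema_preset_wider_than_healthy(self, settings):
        # oracle: quantile ratio exp(sigma*(z_max - z_min)) grows with sigma
        healthy = build_lung(
            ThetaParams(2.3, 4.9, LognormalSpec(1.0, 0.3)), settings
        )
        emphysema = build_lung(
            ThetaParams(2.3, 4.9, LognormalSpec(1.0, 1.2)), settings
        )
        ratio = lambda lung: lung.vent_fractions.max() / lung.vent_fractions.min()
        assert ratio(emphysema) > ratio(healthy)

    def test_invalid_counts_raise(self, settings):
        with pytest.raises(ConfigurationError):
            build_lung(ThetaParams(2.0, 4.9), settings, n_alv=0)
        with pytest.raises(ConfigurationError):
            build_lung(ThetaParams(2.0, 4.9), settings, n_ds=0)


class TestSimulate:
    def test_no_tracer_no_signal(self, settings):
        lung = build_lung(ThetaParams(2.0, 4.9), settings)
        forcing = SinewaveForcing(180.0, mean_fraction=0.0, amplitude_fraction=0.0)
        s = simulate(lung, default_body(), settings, forcing, 30, q_p=4.9)
        assert np.all(s.f_et == 0) and np.all(s.f_mixed_exp == 0)
        assert np.all(s.uptake == 0)

    def test_washin_without_uptake_converges_to_inspired(self, settings):
        lung = build_lung(ThetaParams(2.0, 0.0), settings)
        forcing = SinewaveForcing(180.0, mean_fraction=0.04, amplitude_fraction=0.0)
        s = simulate(lung, None, settings, forcing, 300, q_p=0.0)
        assert np.all(np.diff(s.f_et) > -1e-15)  # monotone washin
        assert abs(s.f_et[-1] - 0.04) < 1e-4

    def test_per_breath_mass_conservation(self, settings):
        theta = ThetaParams(
            2.3, 4.9, LognormalSpec(1.0, 0.9), LognormalSpec(1.0, 1.3)
        )
        lung = build_lung(theta, settings)
        s = simulate(lung, default_body(), settings, SinewaveForcing(60.0),
                     60, q_p=theta.q_p)
        inspired = settings.alveolar_tidal_volume * s.f_insp
        rel = np.abs(s.mass_residual) / np.maximum(inspired, 1e-12)
        assert np.max(rel) < 1e-10

    def test_homogeneous_limit_matches_single_compartment(self, settings):
        theta = ThetaParams(2.0, 4.9)
        f = SinewaveForcing(180.0)
        s125 = simulate(build_lung(theta, settings, 125), default_body(),
                        settings, f, 80, q_p=4.9)
        s1 = simulate(build_lung(theta, settings, 1), default_body(),
                      settings, f, 80, q_p=4.9)
        rel = np.abs(s125.f_et - s1.f_et) / np.maximum(s1.f_et, 1e-12)
        assert np.max(rel) < 1e-8

    def test_endtidal_amplitude_low_pass_behaviour(self, settings):
        # single-compartment low-pass: output amplitude below input, and
        # faster forcing (60 s) attenuated more than slower (180 s)
        theta = ThetaParams(2.3, 4.9, LognormalSpec(1.0, 0.3), LognormalSpec(1.0, 0.5))
        lung = build_lung(theta, settings)
        amps = {}
        for period in (180.0, 60.0):
            f = SinewaveForcing(period)
            n = int(4 * period / settings.breath_duration)
            s = simulate(lung, default_body(), settings, f, n, q_p=theta.q_p)
            bpp = int(period / settings.breath_duration)
            t = s.t_start[-2 * bpp:] + settings.breath_duration
            amps[period], _ = _sinusoid_fit(t, s.f_et[-2 * bpp:], 2 * np.pi / period)
        assert amps[180.0] < f.amplitude_fraction
        assert amps[60.0] < amps[180.0]

    def test_amplitude_monotone_in_sigma_v(self, settings):
        # heterogeneity shrinks the apparent (effective) volume seen by the
        # ventilation-weighted end-tidal signal, so the steady-state end-tidal
        # amplitude grows monotonically with sigma_V
        period = 60.0
        f = SinewaveForcing(period)
        bpp = int(period / settings.breath_duration)
        amps = []
        for sv in (0.0, 0.3, 0.6, 0.9, 1.2):
            theta = ThetaParams(2.3, 4.9, LognormalSpec(1.0, sv),
                                LognormalSpec(1.0, 0.5))
            lung = build_lung(theta, settings)
            s = simulate(lung, default_body(), settings, f, 6 * bpp, q_p=theta.q_p)
            t = s.t_start[-2 * bpp:] + settings.breath_duration
            amp, _ = _sinusoid_fit(t, s.f_et[-2 * bpp:], 2 * np.pi / period)
            amps.append(amp)
        assert np.all(np.diff(amps) >= -1e-12)

    def test_unphysical_forcing_rejected(self):
        with pytest.raises(UnphysicalForcingError):
            SinewaveForcing(180.0, mean_fraction=0.02, amplitude_fraction=0.05)
        with pytest.raises(UnphysicalForcingError):
            SinewaveForcing(180.0, mean_fraction=0.99, amplitude_fraction=0.02)

    def test_series_csv_round_trip(self, settings, tmp_path):
        lung = build_lung(ThetaParams(2.0, 4.9), settings)
        s = simulate(lung, default_body(), settings, SinewaveForcing(60.0),
                     24, q_p=4.9)
        path = tmp_path / "series.csv"
        s.to_csv(path)
        back = BreathSeries.from_csv(path)
        for fieldname in ("t_start", "f_insp", "f_et", "f_mixed_exp",
                          "uptake", "f_venous"):
            assert np.allclose(getattr(back, fieldname), getattr(s, fieldname))


class TestSettingsValidation:
    def test_tidal_volume_must_exceed_dead_space(self):
        with pytest.raises(ConfigurationError):
            VentilatorSettings(tidal_volume=0.1, dead_space=0.15)

    def test_body_flow_fractions_must_sum_to_one(self):
        from istlung import BodyCompartmentSet

        with pytest.raises(ConfigurationError):
            BodyCompartmentSet(flow_fractions=np.array([0.5, 0.2, 0.1, 0.1, 0.0]))
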