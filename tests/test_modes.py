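"""Dynamical-model fits, Arrhenius analysis, and cross-section bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lipidqens.constants import GAS_CONSTANT, HBAR_UEV_S
from lipidqens.modes import (
    HWHMProfile,
    arrhenius_fit,
    d54dmpe_composition,
    exclude_unreliable,
    fick_fit,
    incoherent_fraction,
    jump_diffusion_fit,
    localized_mode_summary,
    read_profile,
    relaxation_time,
    write_profile,
    IsotopicComposition,
)


def fick_profile(D, q2, sigma=None):
    gamma = HBAR_UEV_S * D * q2
    return HWHMProfile("slow", 358.0, q2, gamma, sigma)


def jump_profile(D, tau0, q2, sigma=None):
    rate = D * q2 / (1.0 + D * q2 * tau0)
    return HWHMProfile("slow_HW", 358.0, q2, HBAR_UEV_S * rate, sigma)


class TestFickFit:
    def test_hand_computed_slope_conversion(self):
        # slope 2 μeV·Å² converts through ħ to D ≈ 3.039e9 Å²/s
        prof = HWHMProfile("slow", 358.0, np.array([1.0, 2.0, 3.0]),
                           np.array([2.0, 4.0, 6.0]))
        fit = fick_fit(prof)
        assert fit.D == pytest.approx(2.0 / HBAR_UEV_S, rel=1e-12)
        assert fit.D == pytest.approx(3.039e9, rel=1e-3)

    def test_scaling_linearity(self):
        q2 = np.linspace(0.2, 3.0, 8)
        base = fick_fit(fick_profile(2.0e9, q2))
        doubled = fick_fit(HWHMProfile("slow", 358.0, q2,
                                       2 * HBAR_UEV_S * 2.0e9 * q2))
        assert doubled.D == pytest.approx(2 * base.D, rel=1e-12)

    def test_round_trip_recovery(self):
        q2 = np.linspace(0.1, 3.3, 17)
        fit = fick_fit(fick_profile(3.43e9, q2))
        assert fit.D == pytest.approx(3.43e9, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fick_fit(HWHMProfile("slow", 358.0, np.array([1.0, 2.0]),
                                 np.array([1.0, 2.0])))


class TestJumpDiffusion:
    def test_noise_free_recovery(self):
        q2 = np.linspace(0.1, 3.3, 12)
        fit = jump_diffusion_fit(jump_profile(3.0e9, 1.0e-11, q2), seed=0)
        assert fit.D == pytest.approx(3.0e9, rel=1e-6)
        assert fit.tau0 == pytest.approx(1.0e-11, rel=1e-6)

    def test_high_q_plateau_is_hbar_over_tau0(self):
        fit = jump_diffusion_fit(
            jump_profile(3.0e9, 1.0e-11, np.linspace(0.1, 3.3, 12)), seed=0
        )
        plateau = fit.gamma_curve(np.array([1e12]))[0]
        assert plateau == pytest.approx(HBAR_UEV_S / 1.0e-11, rel=1e-4)
        assert plateau == pytest.approx(65.8, rel=1e-2)

    def test_fickian_limit_matches_fick_fit(self):
        # DQ²τ₀ ≪ 1: jump model degenerates to Fick's law
        q2 = np.linspace(0.1, 3.3, 12)
        prof = fick_profile(2.0e9, q2, sigma=np.full(12, 1e-4))
        jd = jump_diffusion_fit(prof, seed=0)
        fk = fick_fit(prof)
        assert jd.D == pytest.approx(fk.D, rel=1e-3)
        curve_j = jd.gamma_curve(q2)
        curve_f = fk.gamma_curve(q2)
        assert np.allclose(curve_j, curve_f, rtol=1e-4)

    def test_insufficient_span_rejected(self):
        q2 = np.linspace(1.0, 2.0, 6)
        with pytest.raises(ValueError, match="factor 3"):
            jump_diffusion_fit(jump_profile(3e9, 1e-11, q2), seed=0)


class TestLocalizedMode:
    def test_constant_gamma_is_flat(self):
        q2 = np.linspace(0.3, 3.0, 10)
        prof = HWHMProfile("fast", 358.0, q2, np.full(10, 250.0))
        mean, std, flat = localized_mode_summary(prof, (0.39, 2.80))
        assert mean == pytest.approx(250.0)
        assert std == pytest.approx(0.0, abs=1e-12)
        assert flat

    def test_linear_trend_is_not_flat(self):
        q2 = np.linspace(0.3, 3.0, 10)
        prof = HWHMProfile("fast", 358.0, q2, 100.0 * q2,
                           gamma_sigma=np.full(10, 1.0))
        _, _, flat = localized_mode_summary(prof, (0.2, 3.1))
        assert not flat

    def test_noisy_constant_mean_within_sampling_error(self, rng):
        q2 = np.linspace(0.3, 3.0, 30)
        gamma = 250.0 * (1 + 0.1 * rng.standard_normal(30))
        prof = HWHMProfile("fast", 358.0, q2, gamma)
        mean, std, _ = localized_mode_summary(prof, (q2[0], q2[-1]))
        assert abs(mean - 250.0) < 3 * std / np.sqrt(len(q2))

    def test_empty_window_rejected(self):
        prof = HWHMProfile("fast", 358.0, np.array([1.0, 2.0, 3.0]),
                           np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError):
            localized_mode_summary(prof, (10.0, 20.0))


class TestArrhenius:
    def test_two_point_hand_value(self):
        # τ₀ halves from 300 to 330 K → Ea = R ln2 / (1/300 − 1/330)
        fit = arrhenius_fit(np.array([300.0, 330.0]), np.array([2e-12, 1e-12]),
                           fitted_on="tau0", allow_two_points=True)
        expected = GAS_CONSTANT * np.log(2) / (1 / 300 - 1 / 330)
        assert fit.activation_energy == pytest.approx(expected, rel=1e-12)
        assert fit.activation_energy == pytest.approx(1.90e4, rel=1e-2)

    def test_temperature_independent_values_give_zero(self):
        fit = arrhenius_fit(np.array([300.0, 330.0, 360.0]),
                           np.full(3, 5e-12), fitted_on="tau0")
        assert fit.activation_energy == pytest.approx(0.0, abs=1e-8)

    def test_sign_convention_for_diffusion(self):
        # D grows with T → positive activation energy under the D convention
        T = np.array([300.0, 330.0, 360.0])
        Ea = 2.0e4
        D = 1e9 * np.exp(-Ea / (GAS_CONSTANT * T))
        fit = arrhenius_fit(T, D, fitted_on="D")
        assert fit.activation_energy == pytest.approx(Ea, rel=1e-10)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_fit(np.array([300.0, 330.0, 360.0]),
                          np.array([1.0, -1.0, 1.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(ea=st.floats(1e3, 1e5), pref=st.floats(1e-13, 1e-10))
    def test_exact_recovery_property(self, ea, pref):
        """Noise-free Arrhenius data return Ea and prefactor exactly."""
        T = np.array([300.0, 313.0, 330.0, 343.0, 358.0, 368.0])
        tau = pref * np.exp(ea / (GAS_CONSTANT * T))
        fit = arrhenius_fit(T, tau, fitted_on="tau0")
        assert fit.activation_energy == pytest.approx(ea, rel=1e-9)
        assert fit.prefactor == pytest.approx(pref, rel=1e-6)


class TestRelaxationTime:
    def test_hbar_definition_gives_one_picosecond(self):
        assert relaxation_time(658.2119569) == pytest.approx(1.0e-12, rel=1e-9)

    def test_260_uev_value(self):
        assert relaxation_time(260.0) == pytest.approx(2.53e-12, rel=1e-2)

    def test_doubling_halves_tau(self):
        assert relaxation_time(100.0) == pytest.approx(2 * relaxation_time(200.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            relaxation_time(0.0)


class TestIncoherentFraction:
    def test_headgroup_share_with_heavy_water(self):
        comp = d54dmpe_composition("D2O", 10.0)
        frac = incoherent_fraction(comp, {"lipid": {"H": 12.0}})
        assert frac == pytest.approx(0.86, abs=0.01)

    def test_fully_protiated_species_is_unity(self):
        comp = IsotopicComposition({"mol": (1.0, {"H": 10.0})})
        assert incoherent_fraction(comp, {"mol": {"H": 10.0}}) == 1.0

    def test_comparable_shares_with_light_water(self):
        comp = d54dmpe_composition("H2O", 10.0)
        head = incoherent_fraction(comp, {"lipid": {"H": 12.0}})
        water = incoherent_fraction(comp, {"water": {"H": 2.0}})
        assert head == pytest.approx(0.36, abs=0.01)
        assert water == pytest.approx(0.60, abs=0.01)
        # same order of magnitude: the two populations are comparable
        assert 0.3 < water / head / (20 / 12) < 1.2

    def test_unknown_nuclide_lists_table(self):
        comp = IsotopicComposition({"mol": (1.0, {"X": 1.0})})
        with pytest.raises(KeyError, match="unknown nuclide"):
            comp.total_cross_section()

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(mult=st.floats(0.5, 20.0))
    def test_doubling_counts_leaves_fraction_unchanged(self, mult):
        base = d54dmpe_composition("D2O", 10.0)
        scaled = IsotopicComposition(
            species={
                name: (m, {n: c * mult for n, c in counts.items()})
                for name, (m, counts) in base.species.items()
            }
        )
        target = {"lipid": {"H": 12.0}}
        target_scaled = {"lipid": {"H": 12.0 * mult}}
        assert incoherent_fraction(scaled, target_scaled) == pytest.approx(
            incoherent_fraction(base, target), rel=1e-12
        )

    def test_species_order_permutation_invariance(self):
        a = d54dmpe_composition("D2O", 10.0)
        b = IsotopicComposition(species=dict(reversed(list(a.species.items()))))
        t = {"lipid": {"H": 12.0}}
        assert incoherent_fraction(a, t) == incoherent_fraction(b, t)


class TestExcludeUnreliable:
    def test_exactly_the_noisy_points_removed(self):
        q2 = np.linspace(0.2, 3.3, 10)
        gamma = np.full(10, 5.0)
        sigma = np.full(10, 0.25)
        sigma[0] = sigma[-1] = 3.0  # 60% relative error at the endpoints
        prof = HWHMProfile("fast", 358.0, q2, gamma, sigma)
        filt = exclude_unreliable(prof, 0.5)
        assert len(filt) == 8
        assert set(filt.excluded_q_squared) == {q2[0], q2[-1]}

    def test_infinite_threshold_is_identity(self):
        q2 = np.linspace(0.2, 3.3, 5)
        prof = HWHMProfile("fast", 358.0, q2, np.full(5, 5.0), np.full(5, 10.0))
        filt = exclude_unreliable(prof, np.inf)
        assert len(filt) == 5

    def test_everything_excluded_raises(self):
        q2 = np.linspace(0.2, 3.3, 5)
        prof = HWHMProfile("fast", 358.0, q2, np.full(5, 1.0), np.full(5, 10.0))
        with pytest.raises(ValueError, match="threshold"):
            exclude_unreliable(prof, 0.5)


def test_profile_text_round_trip(tmp_path):
    q2 = np.linspace(0.2, 3.3, 7)
    prof = HWHMProfile("slow", 330.0, q2, 2.0 * q2, 0.1 * q2,
                       excluded_q_squared=[0.1])
    path = tmp_path / "profile.txt"
    write_profile(prof, path)
    back = read_profile(path)
    assert back.mode == "slow"
    assert back.temperature == 330.0
    assert np.allclose(back.q_squared, prof.q_squared)
    assert np.allclose(back.gamma, prof.gamma)
    assert np.allclose(back.gamma_sigma, prof.gamma_sigma)
    assert back.excluded_q_squared == [0.1]
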