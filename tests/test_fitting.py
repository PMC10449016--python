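"""Per-Q fitting and the staged two-sample protocol."""

import copy

import numpy as np
import pytest

from lipidqens.fitting import (
    ComponentSpec,
    bootstrap_slow_profile,
    fit_single_spectrum,
    headgroup_protocol,
    water_protocol,
)
from lipidqens.forward import EnergyGrid
from lipidqens.synthetic import (
    GroundTruth,
    ModeTruth,
    default_energy_grid,
    default_ground_truth,
    default_q_grid,
    generate_qens_dataset,
    generate_resolution,
)


def one_q_dataset(modes, q=0.92, mode="high_intensity", noise=True, seed=0,
                  background=60.0, count_scale=7.0e3):
    """Single-Q spectrum generated from explicit constant-Γ mode truths."""
    truth = GroundTruth(
        headgroup={
            label: ModeTruth(kind="constant", amplitude=amp, gamma_ref=g)
            for label, (amp, g) in modes.items()
        },
        water={},
        background={"high_intensity": background, "high_resolution": background},
        count_scale=count_scale,
        seed=seed,
    )
    qv = np.array([q])
    res = generate_resolution(mode, qv)
    data = generate_qens_dataset(
        truth, design=[("headgroup_only", mode, 358.0)], q_values=qv,
        noise=noise, resolutions={mode: res},
    )
    sp = data[("headgroup_only", mode, 358.0)]
    return sp, res, truth


class TestFitSingleSpectrum:
    def test_noise_free_single_lorentzian_exact_recovery(self):
        sp, res, truth = one_q_dataset({"slow": (100.0 / 7e3, 15.0)},
                                       noise=False, background=2.0)
        fit = fit_single_spectrum(
            sp.energy, sp.intensities[0], sp.uncertainties[0], res, 0, 0.92,
            [ComponentSpec("slow")], seed=1, n_starts=4,
        )
        assert fit.hwhms["slow"] == pytest.approx(15.0, rel=1e-6)
        assert fit.amplitudes["slow"] == pytest.approx(100.0, rel=1e-6)
        assert fit.background == pytest.approx(2.0, rel=1e-6)
        assert fit.red_chi2 < 1e-6

    def test_too_few_data_points_rejected(self):
        sp, res, _ = one_q_dataset({"slow": (1.0, 15.0)})
        with pytest.raises(ValueError, match="at least 10"):
            fit_single_spectrum(
                EnergyGrid(sp.energy.values[:8]), sp.intensities[0, :8],
                sp.uncertainties[0, :8], res, 0, 0.92,
                [ComponentSpec("slow")], seed=1,
            )

    def test_more_parameters_than_points_rejected(self):
        sp, res, _ = one_q_dataset({"slow": (1.0, 15.0)})
        comps = [ComponentSpec(f"m{i}") for i in range(6)]
        with pytest.raises(ValueError, match="free parameters"):
            fit_single_spectrum(
                EnergyGrid(sp.energy.values[:12]), sp.intensities[0, :12],
                sp.uncertainties[0, :12], res, 0, 0.92, comps, seed=1,
            )

    def test_mode_ordering_enforced(self):
        sp, res, _ = one_q_dataset(
            {"slow": (2.0, 3.0), "medium": (2.4, 40.0), "fast": (1.5, 300.0)},
            seed=5,
        )
        fit = fit_single_spectrum(
            sp.energy, sp.intensities[0], sp.uncertainties[0], res, 0, 0.92,
            [ComponentSpec("slow"), ComponentSpec("medium"), ComponentSpec("fast")],
            seed=2, n_starts=8,
        )
        assert fit.converged
        assert fit.hwhms["slow"] < fit.hwhms["medium"] < fit.hwhms["fast"]

    def test_three_lorentzian_recovery_over_seeds(self):
        """Γ=(3, 40, 300) μeV at peak ≈ 1e4 counts: joint 3σ recovery rate."""
        n_seeds, hits = 60, 0
        truth_g = {"slow": 3.0, "medium": 40.0, "fast": 300.0}
        for seed in range(n_seeds):
            sp, res, _ = one_q_dataset(
                {"slow": (2.0, 3.0), "medium": (2.4, 40.0), "fast": (1.5, 300.0)},
                seed=seed,
            )
            fit = fit_single_spectrum(
                sp.energy, sp.intensities[0], sp.uncertainties[0], res, 0, 0.92,
                [ComponentSpec("slow"), ComponentSpec("medium"),
                 ComponentSpec("fast")],
                seed=seed, n_starts=8,
            )
            if not fit.converged:
                continue
            ok = all(
                abs(fit.hwhms[m] - g) < 3 * fit.sigmas[f"hwhm_{m}"]
                for m, g in truth_g.items()
            )
            hits += ok
        assert hits / n_seeds >= 0.90

    def test_one_sigma_coverage_calibration(self):
        """Nominal 1σ intervals of a well-conditioned fit cover the truth
        at roughly the normal-theory rate."""
        n_seeds, hits = 100, 0
        for seed in range(n_seeds):
            sp, res, _ = one_q_dataset({"medium": (3.0, 40.0)}, seed=seed)
            fit = fit_single_spectrum(
                sp.energy, sp.intensities[0], sp.uncertainties[0], res, 0, 0.92,
                [ComponentSpec("medium")], seed=seed, n_starts=2,
            )
            if fit.converged:
                hits += abs(fit.hwhms["medium"] - 40.0) < fit.sigmas["hwhm_medium"]
        assert 0.55 <= hits / n_seeds <= 0.80


class TestHeadgroupProtocol:
    def test_temperature_mismatch_rejected(self, truth, q_grid, resolutions):
        data = generate_qens_dataset(
            truth,
            design=[("headgroup_only", "high_intensity", 358.0),
                    ("headgroup_only", "high_resolution", 330.0)],
            q_values=q_grid, resolutions=resolutions,
        )
        with pytest.raises(ValueError, match="temperature"):
            headgroup_protocol(
                data[("headgroup_only", "high_intensity", 358.0)],
                data[("headgroup_only", "high_resolution", 330.0)],
                resolutions["high_intensity"], resolutions["high_resolution"],
            )

    def test_wrong_sample_rejected(self, truth, q_grid, resolutions,
                                   water_pair_358):
        hi_w, hr_w = water_pair_358
        with pytest.raises(ValueError, match="headgroup_only"):
            headgroup_protocol(hi_w, hr_w, resolutions["high_intensity"],
                               resolutions["high_resolution"])

    def test_q_grid_mismatch_rejected(self, truth, resolutions):
        a = generate_qens_dataset(
            truth, design=[("headgroup_only", "high_intensity", 358.0)],
            q_values=default_q_grid(17),
        )
        b = generate_qens_dataset(
            truth, design=[("headgroup_only", "high_resolution", 358.0)],
            q_values=default_q_grid(9),
        )
        with pytest.raises(ValueError, match="Q grids"):
            headgroup_protocol(
                a[("headgroup_only", "high_intensity", 358.0)],
                b[("headgroup_only", "high_resolution", 358.0)],
                generate_resolution("high_intensity", default_q_grid(17)),
                generate_resolution("high_resolution", default_q_grid(9)),
            )

    def test_fixing_contract_is_bit_exact(self, headgroup_result_358):
        """Stage-1 medium parameters reappear unchanged in stage 2."""
        s1 = headgroup_result_358.high_intensity
        s2 = headgroup_result_358.high_resolution
        for f1, f2 in zip(s1.fits, s2.fits):
            assert f2.amplitudes["medium"] == f1.amplitudes["medium"]
            assert f2.hwhms["medium"] == f1.hwhms["medium"]
            assert "amp_medium" in f2.fixed and "hwhm_medium" in f2.fixed

    def test_slow_width_recovered_at_interior_q(
        self, truth, headgroup_pair_358, headgroup_result_358, resolutions
    ):
        """Γ_slow from the narrow window tracks the generative Fickian law
        at interior Q once protocol-level uncertainties are attached."""
        hi, hr = headgroup_pair_358
        prof = bootstrap_slow_profile(
            hi, hr, resolutions["high_intensity"], resolutions["high_resolution"],
            headgroup_result_358, n_bootstrap=10, seed=3, n_starts=3,
        )
        interior = prof.q_squared > 0.6
        truth_gamma = np.array(
            [truth.headgroup["slow"].gamma(q2, 358.0) for q2 in prof.q_squared]
        )
        dev = np.abs(prof.gamma - truth_gamma)
        within = dev[interior] < np.maximum(
            3.5 * prof.gamma_sigma[interior], 0.10 * truth_gamma[interior]
        )
        assert np.all(within)

    def test_mode_ordering_holds_at_every_q(self, headgroup_result_358):
        for fit in headgroup_result_358.high_intensity.fits:
            if fit.converged:
                assert (fit.hwhms["slow"] < fit.hwhms["medium"]
                        < fit.hwhms["fast"])


class TestWaterProtocol:
    def test_missing_headgroup_temperature_rejected(
        self, truth, q_grid, resolutions, water_pair_358, headgroup_result_358
    ):
        hi_w, hr_w = water_pair_358
        other = copy.deepcopy(headgroup_result_358)
        other.high_intensity.temperature = 330.0
        with pytest.raises(ValueError, match="330"):
            water_protocol(hi_w, hr_w, other,
                           resolutions["high_intensity"],
                           resolutions["high_resolution"])

    def test_wrong_sample_rejected(self, headgroup_pair_358,
                                   headgroup_result_358, resolutions):
        hi, hr = headgroup_pair_358
        with pytest.raises(ValueError, match="headgroup_plus_water"):
            water_protocol(hi, hr, headgroup_result_358,
                           resolutions["high_intensity"],
                           resolutions["high_resolution"])

    def test_headgroup_parameters_fixed_bit_exact(
        self, water_pair_358, headgroup_result_358, resolutions
    ):
        hi_w, hr_w = water_pair_358
        wat = water_protocol(hi_w, hr_w, headgroup_result_358,
                             resolutions["high_intensity"],
                             resolutions["high_resolution"],
                             seed=3, n_starts=4)
        for iq, fit in enumerate(wat.high_intensity.fits):
            s1 = headgroup_result_358.high_intensity.fits[iq]
            s2 = headgroup_result_358.high_resolution.fits[iq]
            assert fit.hwhms["slow"] == s2.hwhms["slow"]
            assert fit.amplitudes["medium"] == s1.amplitudes["medium"]
            assert fit.hwhms["fast"] == s1.hwhms["fast"]

    def test_zero_water_amplitude_fits_are_consistent_with_zero(
        self, q_grid, resolutions
    ):
        """A water-labelled sample generated with no water signal yields
        water amplitudes consistent with zero."""
        truth = default_ground_truth(seed=17)
        for mt in truth.water.values():
            mt.amplitude = 0.0
        data = generate_qens_dataset(
            truth,
            design=[("headgroup_only", "high_intensity", 358.0),
                    ("headgroup_only", "high_resolution", 358.0),
                    ("headgroup_plus_water", "high_intensity", 358.0),
                    ("headgroup_plus_water", "high_resolution", 358.0)],
            q_values=q_grid, resolutions=resolutions,
        )
        head = headgroup_protocol(
            data[("headgroup_only", "high_intensity", 358.0)],
            data[("headgroup_only", "high_resolution", 358.0)],
            resolutions["high_intensity"], resolutions["high_resolution"],
            seed=5, n_starts=6,
        )
        wat = water_protocol(
            data[("headgroup_plus_water", "high_intensity", 358.0)],
            data[("headgroup_plus_water", "high_resolution", 358.0)],
            head, resolutions["high_intensity"], resolutions["high_resolution"],
            seed=6, n_starts=6,
        )
        head_scale = np.median(
            [f.amplitudes["medium"] for f in head.high_intensity.fits]
        )
        for fit in wat.high_intensity.fits:
            if not fit.converged:
                continue
            for mode in ("medium_speed_HW", "fast_water"):
                amp = fit.amplitudes[mode]
                sigma = fit.sigmas.get(f"amp_{mode}", np.nan)
                small = amp < 0.05 * head_scale
                assert small or (np.isfinite(sigma) and amp < 2 * sigma)
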