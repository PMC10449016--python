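"""End-to-end orchestration of the staged analysis.

Runs, in order: elastic-scan transition analysis, the two-stage
headgroup protocol per temperature, the water protocol per temperature,
Γ(Q²) dynamical-model fits per mode, Arrhenius fits across temperature,
relaxation-time conversion, and a comparison table against literature
DMPC reference constants.  A stage failure is logged and its dependent
stages are skipped; whatever completed is still written out.

Every output directory receives the effective configuration (including
all seeds), so a run can be reproduced exactly from its own artifacts.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import synthetic
from .elastic import detect_transitions, harmonic_baseline, write_trace
from .fitting import (
    HeadgroupFitResult,
    WaterFitResult,
    bootstrap_slow_profile,
    headgroup_protocol,
    water_protocol,
)
from .modes import (
    arrhenius_fit,
    exclude_unreliable,
    fick_fit,
    jump_diffusion_fit,
    localized_mode_summary,
    relaxation_time,
    write_profile,
)
from .spectra import QENSSpectrum, read_spectrum

__all__ = ["RunConfig", "run_full_analysis", "dmpc_reference"]

log = logging.getLogger("lipidqens")


def dmpc_reference() -> dict:
    """Literature DMPC comparison constants (never recomputed here)."""
    text = (
        importlib.resources.files("lipidqens")
        .joinpath("data/dmpc_reference.yaml")
        .read_text()
    )
    return yaml.safe_load(text)


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    outdir: str
    seed: int = 0
    # synthetic generation (used when no input paths are given)
    synthetic: bool = True
    temperatures: tuple[float, ...] = (300.0, 358.0)
    n_q: int = 17
    # input paths: {(sample, mode, T): path} — alternative to synthetic
    spectrum_paths: dict = field(default_factory=dict)
    # protocol options
    n_starts: int = 8
    n_bootstrap: int = 16
    relative_error_threshold: float = 0.5
    include_water: bool = True
    run_elastic: bool = True
    elastic_transition: tuple[float, float] = (325.0, 0.4)
    q_band: tuple[float, float] = (1.375, 1.725)
    fast_mode_window: tuple[float, float] = (0.39, 2.80)

    def validate(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be ≥ 1")
        if not self.synthetic and not self.spectrum_paths:
            raise ValueError("either synthetic mode or spectrum paths required")
        if self.include_water and not self.synthetic:
            needed = {
                (s, m, T)
                for s in ("headgroup_only", "headgroup_plus_water")
                for m in ("high_intensity", "high_resolution")
                for T in self.temperatures
            }
            missing = needed - set(self.spectrum_paths)
            if missing:
                raise ValueError(f"missing spectra for design cells: {sorted(missing)}")

    def save(self, path: Path) -> None:
        d = asdict(self)
        d["spectrum_paths"] = {
            "|".join(map(str, k)): str(v) for k, v in self.spectrum_paths.items()
        }
        path.write_text(yaml.safe_dump(d, sort_keys=False))


def _load_spectra(config: RunConfig) -> dict[tuple[str, str, float], QENSSpectrum]:
    if config.synthetic:
        truth = synthetic.default_ground_truth(seed=config.seed)
        truth.temperatures = tuple(config.temperatures)
        design = [
            (s, m, T)
            for s in (
                ("headgroup_only", "headgroup_plus_water")
                if config.include_water
                else ("headgroup_only",)
            )
            for m in ("high_intensity", "high_resolution")
            for T in config.temperatures
        ]
        data = synthetic.generate_qens_dataset(
            truth, design=design, q_values=synthetic.default_q_grid(config.n_q)
        )
        outdir = Path(config.outdir)
        truth.save(outdir / "ground_truth.yaml")
        return data
    return {k: read_spectrum(v) for k, v in config.spectrum_paths.items()}


def run_full_analysis(config: RunConfig) -> dict:
    """Execute all requested stages; return (and write) the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    log.addHandler(fh)
    config.save(outdir / "config.yaml")
    report: dict = {"stages": {}, "failures": {}}
    rng = np.random.SeedSequence(config.seed)
    seeds = iter(int(s >> 1) for s in rng.generate_state(64))

    # ---- elastic scan ------------------------------------------------
    if config.run_elastic:
        try:
            t_c, frac = config.elastic_transition
            trace = synthetic.generate_elastic_trace(
                [(t_c, frac)], seed=next(seeds)
            )
            write_trace(trace, outdir / "elastic_trace.txt")
            slope, intercept, _ = harmonic_baseline(
                trace, fit_window=(trace.temperatures[0], t_c - 10.0)
            )
            det = detect_transitions(trace, 1, seed=next(seeds))
            log.info(
                "elastic: harmonic slope %.4g /K, transition at %.1f K (±%.1f)",
                slope, det.temperatures[0], det.sigmas[0],
            )
            report["stages"]["elastic"] = {
                "harmonic_slope_per_K": slope,
                "transitions_K": det.temperatures,
                "transition_sigmas_K": det.sigmas,
                "significant": det.significant,
            }
        except Exception as exc:  # pragma: no cover - defensive
            log.exception("elastic stage failed")
            report["failures"]["elastic"] = str(exc)

    # ---- spectra -----------------------------------------------------
    try:
        spectra = _load_spectra(config)
    except Exception as exc:
        log.exception("could not load or generate spectra")
        report["failures"]["spectra"] = str(exc)
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        return report
    q_values = next(iter(spectra.values())).q_values
    res_hi = synthetic.generate_resolution("high_intensity", q_values)
    res_hr = synthetic.generate_resolution("high_resolution", q_values)

    head_results: dict[float, HeadgroupFitResult] = {}
    water_results: dict[float, WaterFitResult] = {}
    slow_D: dict[float, tuple[float, float]] = {}
    water_fits: dict[str, dict[float, object]] = {"slow_HW": {}, "medium_speed_HW": {}}
    fast_water_gamma: dict[float, float] = {}

    for T in config.temperatures:
        # -- headgroup protocol ---------------------------------------
        try:
            hi = spectra[("headgroup_only", "high_intensity", T)]
            hr = spectra[("headgroup_only", "high_resolution", T)]
            log.info("headgroup protocol at %s K: stage 1 (high-intensity, "
                     "3 free modes) then stage 2 (high-resolution, medium fixed)", T)
            head = headgroup_protocol(
                hi, hr, res_hi, res_hr, seed=next(seeds), n_starts=config.n_starts
            )
            head_results[T] = head
            head.high_intensity.write(outdir / f"headgroup_hi_{T:g}K.txt")
            head.high_resolution.write(outdir / f"headgroup_hr_{T:g}K.txt")
            prof = bootstrap_slow_profile(
                hi, hr, res_hi, res_hr, head,
                n_bootstrap=config.n_bootstrap, seed=next(seeds),
                n_starts=max(config.n_starts // 2, 2),
            )
            prof = exclude_unreliable(prof, config.relative_error_threshold)
            write_profile(prof, outdir / f"profile_slow_{T:g}K.txt")
            fick = fick_fit(prof)
            slow_D[T] = (fick.D, fick.D_sigma)
            log.info("slow-mode Fickian D(%s K) = %.3g ± %.2g Å²/s", T, fick.D, fick.D_sigma)
            # localized fast mode
            pfast = head.high_intensity.profile("fast")
            mean_g, std_g, flat = localized_mode_summary(pfast, config.fast_mode_window)
            report["stages"].setdefault("fast_mode", {})[T] = {
                "mean_gamma_ueV": mean_g, "std_gamma_ueV": std_g, "flat": flat,
            }
        except Exception as exc:
            log.exception("headgroup stage failed at %s K", T)
            report["failures"][f"headgroup_{T:g}K"] = str(exc)
            continue

        # -- water protocol -------------------------------------------
        if not config.include_water:
            continue
        try:
            hi_w = spectra[("headgroup_plus_water", "high_intensity", T)]
            hr_w = spectra[("headgroup_plus_water", "high_resolution", T)]
            log.info("water protocol at %s K: all headgroup parameters fixed "
                     "from the headgroup-sample fits", T)
            wat = water_protocol(
                hi_w, hr_w, head, res_hi, res_hr,
                seed=next(seeds), n_starts=config.n_starts,
            )
            water_results[T] = wat
            wat.high_resolution.write(outdir / f"water_hr_{T:g}K.txt")
            wat.high_intensity.write(outdir / f"water_hi_{T:g}K.txt")
            for mode, src in (
                ("slow_HW", wat.high_resolution),
                ("medium_speed_HW", wat.high_intensity),
            ):
                p = exclude_unreliable(
                    src.profile(mode), config.relative_error_threshold
                )
                jd = jump_diffusion_fit(p, seed=next(seeds))
                water_fits[mode][T] = jd
                log.info("%s jump-diffusion at %s K: D=%.3g Å²/s, tau0=%.3g s",
                         mode, T, jd.D, jd.tau0)
            pfw = exclude_unreliable(
                wat.high_intensity.profile("fast_water"),
                config.relative_error_threshold,
            )
            mean_g, _, _ = localized_mode_summary(
                pfw, (pfw.q_squared[0], pfw.q_squared[-1])
            )
            fast_water_gamma[T] = mean_g
        except Exception as exc:
            log.exception("water stage failed at %s K", T)
            report["failures"][f"water_{T:g}K"] = str(exc)

    report["stages"]["slow_mode_D"] = {
        f"{T:g}": {"D": d, "sigma": s} for T, (d, s) in slow_D.items()
    }

    # ---- Arrhenius fits ---------------------------------------------
    try:
        if len(slow_D) >= 3:
            Ts = sorted(slow_D)
            af = arrhenius_fit(
                np.array(Ts), np.array([slow_D[T][0] for T in Ts]), fitted_on="D"
            )
            report["stages"]["arrhenius_headgroup_slow_D"] = {
                "Ea_kJ_mol": af.activation_energy / 1e3,
                "Ea_sigma_kJ_mol": af.activation_energy_sigma / 1e3,
            }
        for mode, fits in water_fits.items():
            if len(fits) >= 3:
                Ts = sorted(fits)
                af = arrhenius_fit(
                    np.array(Ts), np.array([fits[T].tau0 for T in Ts]),
                    fitted_on="tau0",
                )
                report["stages"][f"arrhenius_{mode}_tau0"] = {
                    "Ea_kJ_mol": af.activation_energy / 1e3,
                    "Ea_sigma_kJ_mol": af.activation_energy_sigma / 1e3,
                }
    except Exception as exc:
        log.exception("Arrhenius stage failed")
        report["failures"]["arrhenius"] = str(exc)

    # ---- relaxation times and literature comparison -----------------
    if fast_water_gamma:
        report["stages"]["fast_water_relaxation_ps"] = {
            f"{T:g}": relaxation_time(g) * 1e12 for T, g in fast_water_gamma.items()
        }
    ref = dmpc_reference()
    comparison = {"reference": ref}
    if 358.0 in slow_D:
        comparison["headgroup_slow_D_vs_DMPC"] = {
            "this_analysis_358K": slow_D[358.0][0],
            "DMPC_316K_literature": ref["headgroup_slow_mode"]["D"],
        }
    report["stages"]["literature_comparison"] = comparison

    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    log.removeHandler(fh)
    return report
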