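"""Per-Q spectral fitting and the staged two-sample analysis protocol.

The analysis contrast rests on selective deuteration: a tail-deuterated
lipid hydrated with D₂O shows essentially only the headgroup hydrogens,
while the same lipid with H₂O adds the water hydrogens.  The protocol is
therefore staged:

1. **Headgroup sample, high-intensity mode** — three free Lorentzians
   (slow / medium / fast) + flat background, fitted independently at
   each Q.
2. **Headgroup sample, high-resolution mode** — two Lorentzians, with
   the medium mode's amplitude and width *fixed per Q* from stage 1 and
   the slow mode free; the narrow window resolves the slow width.
3. **Water sample, high-resolution mode** — all headgroup parameters
   fixed from stages 1–2; only the slow hydration-water mode (plus
   background) is free, since the window is too narrow for the faster
   water modes.
4. **Water sample, high-intensity mode** — headgroup still fixed; three
   water Lorentzians fitted with Γ_slow HW pinned from stage 3, except
   at Q bins where stage 3 failed to converge (there it is freed).

Each per-Q fit is weighted least squares (weights 1/σ²) with seeded
multi-start initialization; mode ordering Γ_fast > Γ_medium > Γ_slow is
enforced through bounded width-ratio parameters.  Parameters marked
fixed are returned bit-identical to their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import lmfit

from .forward import (
    EnergyGrid,
    ResolutionFunction,
    convolve_resolution,
    lorentzian_binned,
)
from .modes import HWHMProfile, exclude_unreliable  # noqa: F401  (re-export)
from .spectra import QENSSpectrum

__all__ = [
    "ComponentSpec",
    "SingleQFit",
    "SpectralFitResult",
    "fit_single_spectrum",
    "headgroup_protocol",
    "water_protocol",
    "predict_spectrum",
    "bootstrap_slow_profile",
    "exclude_unreliable",
    "HeadgroupFitResult",
    "WaterFitResult",
]

HEADGROUP_MODES = ("slow", "medium", "fast")
WATER_MODES = ("slow_HW", "medium_speed_HW", "fast_water")

#: minimum multiplicative separation enforced between adjacent free widths
MIN_WIDTH_RATIO = 1.5
#: tolerance for matching Q grids between spectra / earlier fits, Å⁻¹
Q_MATCH_TOL = 0.02


@dataclass
class ComponentSpec:
    """One Lorentzian mode in a fit template.

    ``amplitude`` / ``hwhm`` values of ``None`` are free parameters;
    numbers are fixed (pinned from an earlier protocol stage) and are
    guaranteed to come back unchanged to the last bit.
    """

    label: str
    amplitude: float | None = None
    hwhm: float | None = None

    @property
    def hwhm_free(self) -> bool:
        return self.hwhm is None


@dataclass
class SingleQFit:
    """Best composite model at one Q with 1σ uncertainties."""

    q: float
    amplitudes: dict[str, float]
    hwhms: dict[str, float]
    background: float
    sigmas: dict[str, float]  # keyed amp_<label>, hwhm_<label>, background
    red_chi2: float
    converged: bool
    fixed: frozenset[str] = frozenset()

    def param(self, name: str) -> float:
        if name == "background":
            return self.background
        kind, _, label = name.partition("_")
        return self.amplitudes[label] if kind == "amp" else self.hwhms[label]


@dataclass
class SpectralFitResult:
    """Per-Q fits for one spectrum at one protocol stage."""

    stage: str
    sample: str
    resolution_mode: str
    temperature: float
    q_values: np.ndarray
    labels: tuple[str, ...]
    fits: list[SingleQFit] = field(default_factory=list)

    def fit_at(self, q_index: int) -> SingleQFit:
        return self.fits[q_index]

    def profile(
        self, label: str, converged_only: bool = True
    ) -> HWHMProfile:
        """Γ(Q²) profile for one mode, from converged fits with finite σ."""
        q2, g, s = [], [], []
        for q, fit in zip(self.q_values, self.fits):
            if converged_only and not fit.converged:
                continue
            gamma = fit.hwhms.get(label)
            sigma = fit.sigmas.get(f"hwhm_{label}")
            if gamma is None or gamma <= 0:
                continue
            if sigma is None or not np.isfinite(sigma) or sigma <= 0:
                continue
            q2.append(q * q)
            g.append(gamma)
            s.append(sigma)
        if not q2:
            raise ValueError(f"no usable fits for mode {label!r}")
        return HWHMProfile(
            mode=label,
            temperature=self.temperature,
            q_squared=np.array(q2),
            gamma=np.array(g),
            gamma_sigma=np.array(s),
        )

    def to_table(self) -> "np.ndarray":
        """Long-format rows (Q, name, value, sigma, fixed) as object array."""
        rows = []
        for q, fit in zip(self.q_values, self.fits):
            for label in self.labels:
                for kind, val in (
                    ("amp", fit.amplitudes[label]),
                    ("hwhm", fit.hwhms[label]),
                ):
                    name = f"{kind}_{label}"
                    rows.append(
                        (q, name, val, fit.sigmas.get(name, np.nan),
                         name in fit.fixed)
                    )
            rows.append(
                (q, "background", fit.background,
                 fit.sigmas.get("background", np.nan), "background" in fit.fixed)
            )
        return np.array(rows, dtype=object)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# stage: {self.stage}\n# sample: {self.sample}\n")
            fh.write(f"# resolution_mode: {self.resolution_mode}\n")
            fh.write(f"# temperature: {self.temperature}\n")
            fh.write("# columns: Q parameter value sigma fixed\n")
            for q, name, val, sig, fx in self.to_table():
                fh.write(f"{q:.6g} {name} {val:.10g} {sig:.6g} {int(fx)}\n")


class _CompositeEvaluator:
    """Fast composite-model evaluation with fixed-width shapes precomputed."""

    def __init__(
        self,
        energy: EnergyGrid,
        resolution: ResolutionFunction,
        q_index: int,
        components: list[ComponentSpec],
        pad_factor: float = 5.0,
    ) -> None:
        self.energy = energy
        self.resolution = resolution
        self.q_index = q_index
        self.components = components
        pad = pad_factor * resolution.support_width
        self.ext = energy.extended(pad)
        # unit-amplitude convolved shape for every fixed-width component
        self.fixed_shapes: dict[str, np.ndarray] = {}
        for comp in components:
            if comp.hwhm is not None:
                self.fixed_shapes[comp.label] = self._unit_shape(comp.hwhm)

    def _unit_shape(self, hwhm: float) -> np.ndarray:
        # counts per channel = convolved density × channel width, so that
        # amplitudes are in count·μeV units and transfer between grids of
        # different binning (the staged protocol fixes them across modes)
        dens = lorentzian_binned(hwhm, self.ext)
        conv = convolve_resolution(
            dens, self.ext, self.resolution, self.q_index, self.energy
        )
        return conv * self.energy.spacing

    def __call__(self, values: dict[str, float]) -> np.ndarray:
        total = np.full(len(self.energy), values["background"])
        for comp in self.components:
            amp = values[f"amp_{comp.label}"]
            if comp.label in self.fixed_shapes:
                total += amp * self.fixed_shapes[comp.label]
            else:
                total += amp * self._unit_shape(values[f"hwhm_{comp.label}"])
        return total


def _build_params(
    components: list[ComponentSpec],
    background: float | None,
    amp_starts: dict[str, float],
    width_starts: dict[str, float],
    bg_start: float,
    amp_max: float,
    gamma_lo: float,
    gamma_hi: float,
    ordered_labels: tuple[str, ...],
) -> lmfit.Parameters:
    """Parameter set with the width ordering of one mode family enforced.

    Free widths inside ``ordered_labels`` (listed slow → fast) are
    chained additively: Γ_k = Γ_{k-1} + δ_k with δ_k > 0 bounded, so the
    ordering holds by construction.  Widths of modes outside the family
    (e.g. fixed headgroup modes under a water fit) never constrain it.
    """
    params = lmfit.Parameters()
    prev_chain_width: str | None = None
    max_fixed_in_chain = 0.0
    for comp in components:
        aname = f"amp_{comp.label}"
        if comp.amplitude is not None:
            params.add(aname, value=comp.amplitude, vary=False)
        else:
            params.add(aname, value=amp_starts[comp.label], min=0.0, max=amp_max)
        gname = f"hwhm_{comp.label}"
        in_chain = comp.label in ordered_labels
        if comp.hwhm is not None:
            params.add(gname, value=comp.hwhm, vary=False)
            if in_chain:
                max_fixed_in_chain = max(max_fixed_in_chain, comp.hwhm)
        elif not in_chain or prev_chain_width is None:
            lo = gamma_lo
            if in_chain and max_fixed_in_chain > 0:
                lo = max(lo, MIN_WIDTH_RATIO * max_fixed_in_chain)
            start = float(np.clip(width_starts[comp.label], lo * 1.01, gamma_hi))
            params.add(gname, value=start, min=lo, max=gamma_hi)
            if in_chain:
                prev_chain_width = comp.label
        else:
            dname = f"dwidth_{comp.label}"
            d0 = max(
                width_starts[comp.label] - width_starts[prev_chain_width],
                gamma_lo,
            )
            params.add(dname, value=d0, min=gamma_lo, max=2.0 * gamma_hi)
            params.add(gname, expr=f"hwhm_{prev_chain_width} + {dname}")
            prev_chain_width = comp.label
    if background is not None:
        params.add("background", value=background, vary=False)
    else:
        params.add("background", value=max(bg_start, 0.0), min=0.0)
    return params


def fit_single_spectrum(
    energy: EnergyGrid,
    intensity: np.ndarray,
    sigma: np.ndarray,
    resolution: ResolutionFunction,
    q_index: int,
    q_value: float,
    components: list[ComponentSpec],
    background: float | None = None,
    seed: int | None = None,
    n_starts: int = 8,
    ordered_labels: tuple[str, ...] | None = None,
) -> SingleQFit:
    """Weighted multi-start least-squares fit of one Q slice.

    Components are listed slow → fast; free widths belonging to the
    ordered family (``ordered_labels``, defaulting to all components)
    are chained through bounded positive increments so the returned Γ
    always respect the ordering.  The best of ``n_starts`` seeded starts
    (by χ²; ties by smaller slowest width) is returned.  If no start
    converges the result is flagged and parameter uncertainties are
    NaN — no exception is raised for non-convergence.
    """
    if ordered_labels is None:
        ordered_labels = tuple(c.label for c in components)
    intensity = np.asarray(intensity, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    good = sigma > 0
    if int(np.sum(good)) < 10:
        raise ValueError("need at least 10 energy points with positive uncertainty")
    n_free = sum(c.amplitude is None for c in components)
    n_free += sum(c.hwhm is None for c in components)
    n_free += int(background is None)
    if n_free >= int(np.sum(good)):
        raise ValueError(
            f"{n_free} free parameters but only {int(np.sum(good))} data points"
        )
    evaluator = _CompositeEvaluator(energy, resolution, q_index, components)

    def residual(params: lmfit.Parameters) -> np.ndarray:
        vals = {name: params[name].value for name in params}
        model = evaluator(vals)
        return ((model - intensity) / sigma)[good]

    dE = energy.spacing
    half_window = 0.5 * (energy.window[1] - energy.window[0])
    gamma_lo = max(1e-3 * dE, 1e-4 * half_window)
    gamma_hi = 2.0 * half_window
    # background start: outer 10% of the window
    n_edge = max(int(0.05 * len(energy)), 2)
    bg_start = float(np.mean(np.r_[intensity[:n_edge], intensity[-n_edge:]]))
    area = max(float(np.sum(intensity - bg_start) * dE), 10.0 * dE)
    free_amp_labels = [c.label for c in components if c.amplitude is None]
    free_width_labels = [c.label for c in components if c.hwhm is None]

    rng = np.random.default_rng(seed)
    best: tuple[float, float, lmfit.minimizer.MinimizerResult] | None = None
    for _ in range(max(n_starts, 1)):
        amp_starts = {
            lab: area / max(len(free_amp_labels), 1) * rng.lognormal(0.0, 0.3)
            for lab in free_amp_labels
        }
        # log-spaced width ladder spanning the window, jittered per start
        if free_width_labels:
            ladder = np.geomspace(
                max(gamma_lo * 3.0, dE), half_window, len(free_width_labels) + 2
            )[1:-1]
            ladder = ladder * rng.lognormal(0.0, 0.5, size=ladder.size)
            ladder = np.sort(ladder)
        width_starts = {
            lab: float(ladder[i]) for i, lab in enumerate(free_width_labels)
        }
        params = _build_params(
            components, background, amp_starts, width_starts,
            bg_start, amp_max=1e3 * area, gamma_lo=gamma_lo, gamma_hi=gamma_hi,
            ordered_labels=ordered_labels,
        )
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        slow_g = (
            res.params[f"hwhm_{free_width_labels[0]}"].value
            if free_width_labels
            else 0.0
        )
        key = (res.redchi, slow_g)
        if best is None or key < (best[0], best[1]):
            best = (res.redchi, slow_g, res)

    fixed = frozenset(
        [f"amp_{c.label}" for c in components if c.amplitude is not None]
        + [f"hwhm_{c.label}" for c in components if c.hwhm is not None]
        + (["background"] if background is not None else [])
    )
    if best is None:
        nan = float("nan")
        return SingleQFit(
            q=q_value,
            amplitudes={c.label: (c.amplitude if c.amplitude is not None else nan)
                        for c in components},
            hwhms={c.label: (c.hwhm if c.hwhm is not None else nan)
                   for c in components},
            background=background if background is not None else nan,
            sigmas={},
            red_chi2=nan,
            converged=False,
            fixed=fixed,
        )
    res = best[2]
    amplitudes, hwhms, sigmas = {}, {}, {}
    for comp in components:
        if comp.amplitude is not None:
            amplitudes[comp.label] = comp.amplitude  # bit-exact fixing contract
            sigmas[f"amp_{comp.label}"] = 0.0
        else:
            p = res.params[f"amp_{comp.label}"]
            amplitudes[comp.label] = float(p.value)
            sigmas[f"amp_{comp.label}"] = (
                float(p.stderr) if p.stderr is not None else float("nan")
            )
        if comp.hwhm is not None:
            hwhms[comp.label] = comp.hwhm
            sigmas[f"hwhm_{comp.label}"] = 0.0
        else:
            p = res.params[f"hwhm_{comp.label}"]
            hwhms[comp.label] = float(p.value)
            sigmas[f"hwhm_{comp.label}"] = (
                float(p.stderr) if p.stderr is not None else float("nan")
            )
    if background is not None:
        bg = background
        sigmas["background"] = 0.0
    else:
        p = res.params["background"]
        bg = float(p.value)
        sigmas["background"] = (
            float(p.stderr) if p.stderr is not None else float("nan")
        )
    converged = bool(res.success) and bool(res.errorbars)
    return SingleQFit(
        q=q_value,
        amplitudes=amplitudes,
        hwhms=hwhms,
        background=bg,
        sigmas=sigmas,
        red_chi2=float(res.redchi),
        converged=converged,
        fixed=fixed,
    )


def _check_q_match(q_a: np.ndarray, q_b: np.ndarray) -> None:
    if q_a.size != q_b.size or np.any(np.abs(q_a - q_b) > Q_MATCH_TOL):
        raise ValueError(
            f"Q grids cannot be matched within {Q_MATCH_TOL} Å⁻¹"
        )


def _per_q_seeds(seed: int | None, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep below 2^31


@dataclass
class HeadgroupFitResult:
    """Both stages of the headgroup-sample protocol."""

    high_intensity: SpectralFitResult  # stage 1: 3 free modes
    high_resolution: SpectralFitResult  # stage 2: slow free, medium fixed


@dataclass
class WaterFitResult:
    """Both stages of the water-sample protocol."""

    high_resolution: SpectralFitResult  # stage 1: slow_HW only
    high_intensity: SpectralFitResult  # stage 2: 3 water modes


def _fit_spectrum_per_q(
    spectrum: QENSSpectrum,
    resolution: ResolutionFunction,
    component_builder,
    background: float | None,
    stage: str,
    labels: tuple[str, ...],
    seed: int | None,
    n_starts: int,
    ordered_labels: tuple[str, ...] | None = None,
) -> SpectralFitResult:
    seeds = _per_q_seeds(seed, spectrum.n_q)
    result = SpectralFitResult(
        stage=stage,
        sample=spectrum.sample,
        resolution_mode=spectrum.resolution_mode,
        temperature=spectrum.temperature,
        q_values=spectrum.q_values,
        labels=labels,
    )
    for iq in range(spectrum.n_q):
        q, intensity, sigma = spectrum.slice_q(iq)
        comps = component_builder(iq)
        fit = fit_single_spectrum(
            spectrum.energy, intensity, sigma, resolution, iq, q,
            comps, background=background, seed=seeds[iq], n_starts=n_starts,
            ordered_labels=ordered_labels,
        )
        result.fits.append(fit)
    return result


def headgroup_protocol(
    hi_spectrum: QENSSpectrum,
    hr_spectrum: QENSSpectrum,
    hi_resolution: ResolutionFunction,
    hr_resolution: ResolutionFunction,
    seed: int | None = None,
    n_starts: int = 8,
) -> HeadgroupFitResult:
    """Two-stage headgroup fit: high-intensity first, then high-resolution.

    Stage 1 fits slow+medium+fast (all free) per Q on the wide-window
    spectrum; stage 2 fits the narrow-window spectrum with the medium
    mode fixed per Q from stage 1 and only the slow mode (and
    background) free — the configuration that actually resolves Γ_slow.
    """
    for sp in (hi_spectrum, hr_spectrum):
        if sp.sample != "headgroup_only":
            raise ValueError("headgroup protocol needs headgroup_only spectra")
    if hi_spectrum.temperature != hr_spectrum.temperature:
        raise ValueError(
            "high-intensity and high-resolution spectra are at different "
            f"temperatures ({hi_spectrum.temperature} vs {hr_spectrum.temperature} K)"
        )
    _check_q_match(hi_spectrum.q_values, hr_spectrum.q_values)
    ss = np.random.SeedSequence(seed).spawn(2)

    hi_result = _fit_spectrum_per_q(
        hi_spectrum,
        hi_resolution,
        lambda iq: [ComponentSpec("slow"), ComponentSpec("medium"),
                    ComponentSpec("fast")],
        background=None,
        stage="headgroup_stage1",
        labels=HEADGROUP_MODES,
        seed=int(ss[0].generate_state(1)[0] >> 1),
        n_starts=n_starts,
    )

    def stage2_components(iq: int) -> list[ComponentSpec]:
        s1 = hi_result.fits[iq]
        return [
            ComponentSpec("slow"),
            ComponentSpec(
                "medium",
                amplitude=s1.amplitudes["medium"],
                hwhm=s1.hwhms["medium"],
            ),
        ]

    hr_result = _fit_spectrum_per_q(
        hr_spectrum,
        hr_resolution,
        stage2_components,
        background=None,
        stage="headgroup_stage2",
        labels=("slow", "medium"),
        seed=int(ss[1].generate_state(1)[0] >> 1),
        n_starts=n_starts,
    )
    return HeadgroupFitResult(high_intensity=hi_result, high_resolution=hr_result)


def predict_spectrum(
    spectrum: QENSSpectrum,
    resolution: ResolutionFunction,
    result: SpectralFitResult,
) -> np.ndarray:
    """Fitted model counts on the spectrum's (Q, E) grid."""
    out = np.empty_like(spectrum.intensities)
    for iq in range(spectrum.n_q):
        fit = result.fits[iq]
        comps = [
            ComponentSpec(lab, amplitude=fit.amplitudes[lab], hwhm=fit.hwhms[lab])
            for lab in result.labels
            if np.isfinite(fit.hwhms[lab]) and np.isfinite(fit.amplitudes[lab])
        ]
        ev = _CompositeEvaluator(spectrum.energy, resolution, iq, comps)
        vals = {f"amp_{c.label}": c.amplitude for c in comps}
        vals.update({f"hwhm_{c.label}": c.hwhm for c in comps})
        vals["background"] = fit.background
        out[iq] = ev(vals)
    return out


def bootstrap_slow_profile(
    hi_spectrum: QENSSpectrum,
    hr_spectrum: QENSSpectrum,
    hi_resolution: ResolutionFunction,
    hr_resolution: ResolutionFunction,
    base: HeadgroupFitResult,
    n_bootstrap: int = 24,
    seed: int | None = None,
    n_starts: int = 4,
) -> HWHMProfile:
    """Γ_slow(Q²) with uncertainties from a seeded full-protocol bootstrap.

    Covariance-derived σ on Γ_slow understate the true uncertainty where
    slow and medium widths both fall below the resolution (low Q): the
    error made when the medium mode is fixed from stage 1 propagates
    into stage 2 but is invisible to the stage-2 covariance.  The
    parametric bootstrap replays the *whole* two-stage protocol on
    replicate spectra drawn around the fitted models (Gaussian with the
    per-bin counting σ), so those degenerate bins show up with honestly
    large error bars and can be screened by the usual relative-error
    filter.
    """
    point = base.high_resolution.profile("slow", converged_only=False)
    hi_model = predict_spectrum(hi_spectrum, hi_resolution, base.high_intensity)
    hr_model = predict_spectrum(hr_spectrum, hr_resolution, base.high_resolution)
    rng = np.random.default_rng(seed)
    gammas = np.full((n_bootstrap, hi_spectrum.n_q), np.nan)
    for b in range(n_bootstrap):
        hi_rep = QENSSpectrum(
            q_values=hi_spectrum.q_values,
            energy=hi_spectrum.energy,
            intensities=np.clip(
                hi_model + hi_spectrum.uncertainties
                * rng.standard_normal(hi_model.shape), 0.0, None,
            ),
            uncertainties=hi_spectrum.uncertainties,
            temperature=hi_spectrum.temperature,
            resolution_mode=hi_spectrum.resolution_mode,
            sample=hi_spectrum.sample,
        )
        hr_rep = QENSSpectrum(
            q_values=hr_spectrum.q_values,
            energy=hr_spectrum.energy,
            intensities=np.clip(
                hr_model + hr_spectrum.uncertainties
                * rng.standard_normal(hr_model.shape), 0.0, None,
            ),
            uncertainties=hr_spectrum.uncertainties,
            temperature=hr_spectrum.temperature,
            resolution_mode=hr_spectrum.resolution_mode,
            sample=hr_spectrum.sample,
        )
        rep = headgroup_protocol(
            hi_rep, hr_rep, hi_resolution, hr_resolution,
            seed=int(rng.integers(0, 2**31 - 1)), n_starts=n_starts,
        )
        for iq, fit in enumerate(rep.high_resolution.fits):
            if fit.converged:
                gammas[b, iq] = fit.hwhms["slow"]
    n_ok = np.sum(np.isfinite(gammas), axis=0)
    boot_sigma = np.nanstd(gammas, axis=0, ddof=1)
    # fall back to the covariance σ where the bootstrap could not resolve one
    q2_all = hi_spectrum.q_values**2
    sig_map = dict(zip(point.q_squared, point.gamma_sigma))
    gam_map = dict(zip(point.q_squared, point.gamma))
    q2, g, s = [], [], []
    for iq, q2v in enumerate(q2_all):
        if q2v not in gam_map or not np.isfinite(gam_map[q2v]):
            continue
        sigma = boot_sigma[iq] if n_ok[iq] >= 3 else sig_map[q2v]
        if not np.isfinite(sigma) or sigma <= 0:
            continue
        q2.append(q2v)
        g.append(gam_map[q2v])
        s.append(float(sigma))
    return HWHMProfile(
        mode="slow",
        temperature=hi_spectrum.temperature,
        q_squared=np.array(q2),
        gamma=np.array(g),
        gamma_sigma=np.array(s),
    )


def water_protocol(
    hi_spectrum: QENSSpectrum,
    hr_spectrum: QENSSpectrum,
    headgroup: HeadgroupFitResult,
    hi_resolution: ResolutionFunction,
    hr_resolution: ResolutionFunction,
    seed: int | None = None,
    n_starts: int = 8,
) -> WaterFitResult:
    """Water-sample fits with every headgroup parameter pinned.

    The six per-Q headgroup parameters (slow from the high-resolution
    stage, medium and fast from the high-intensity stage) are fixed from
    the headgroup-sample results at the same temperature.  The narrow
    window is fitted first for Γ_slow HW alone; the wide window then
    fits the three water modes with Γ_slow HW fixed — freed only at Q
    bins where the narrow-window fit did not converge.
    """
    for sp in (hi_spectrum, hr_spectrum):
        if sp.sample != "headgroup_plus_water":
            raise ValueError("water protocol needs headgroup_plus_water spectra")
    if hi_spectrum.temperature != hr_spectrum.temperature:
        raise ValueError("water spectra pair temperatures differ")
    head_T = headgroup.high_intensity.temperature
    if head_T != hi_spectrum.temperature:
        raise ValueError(
            f"headgroup fits are at {head_T} K but water spectra are at "
            f"{hi_spectrum.temperature} K"
        )
    _check_q_match(hi_spectrum.q_values, hr_spectrum.q_values)
    _check_q_match(hi_spectrum.q_values, headgroup.high_intensity.q_values)
    ss = np.random.SeedSequence(seed).spawn(2)

    def fixed_head(iq: int) -> list[ComponentSpec]:
        s1 = headgroup.high_intensity.fits[iq]
        s2 = headgroup.high_resolution.fits[iq]
        return [
            ComponentSpec("slow", amplitude=s2.amplitudes["slow"],
                          hwhm=s2.hwhms["slow"]),
            ComponentSpec("medium", amplitude=s1.amplitudes["medium"],
                          hwhm=s1.hwhms["medium"]),
            ComponentSpec("fast", amplitude=s1.amplitudes["fast"],
                          hwhm=s1.hwhms["fast"]),
        ]

    hr_result = _fit_spectrum_per_q(
        hr_spectrum,
        hr_resolution,
        lambda iq: fixed_head(iq) + [ComponentSpec("slow_HW")],
        background=None,
        stage="water_stage1",
        labels=("slow", "medium", "fast", "slow_HW"),
        seed=int(ss[0].generate_state(1)[0] >> 1),
        n_starts=n_starts,
        ordered_labels=("slow_HW",),
    )

    def stage2_components(iq: int) -> list[ComponentSpec]:
        w1 = hr_result.fits[iq]
        if w1.converged:
            slow_hw = ComponentSpec("slow_HW", hwhm=w1.hwhms["slow_HW"])
        else:  # narrow-window fit failed here: free the width
            slow_hw = ComponentSpec("slow_HW")
        return fixed_head(iq) + [
            slow_hw,
            ComponentSpec("medium_speed_HW"),
            ComponentSpec("fast_water"),
        ]

    hi_result = _fit_spectrum_per_q(
        hi_spectrum,
        hi_resolution,
        stage2_components,
        background=None,
        stage="water_stage2",
        labels=("slow", "medium", "fast") + WATER_MODES,
        seed=int(ss[1].generate_state(1)[0] >> 1),
        n_starts=n_starts,
        ordered_labels=WATER_MODES,
    )
    return WaterFitResult(high_resolution=hr_result, high_intensity=hi_result)
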