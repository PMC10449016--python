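"""Synthetic study generator with serialized ground truth.

Everything the analysis pipeline consumes can be generated here with a
known ground truth: QENS spectrum pairs (two samples × two resolution
modes × six temperatures), Gaussian resolution kernels, elastic-scan
traces with phase-transition drops, and Brownian + rotational-diffusion
trajectories.

The default ground truth mirrors the experimental design it emulates: a
tail-deuterated PE lipid hydrated at 10 waters per lipid, measured at
300–368 K on a near-backscattering spectrometer with 3.6 and 13 μeV
resolution modes over Q = 0.17–1.82 Å⁻¹.  Mode widths are generated
from physical laws — the headgroup slow mode from a Fickian D, the
translational water modes from jump-diffusion (D, τ₀) pairs, the fast
modes Q-independent — with Arrhenius temperature dependence tying the
six temperatures together.  Counting statistics are Poisson.

Every generator is a pure function of (parameters, seed); ground truth
is serialized next to the data so downstream checks read it from the
file rather than hard-coding numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .constants import GAS_CONSTANT, HBAR_UEV_S
from .forward import (
    CompositeSpectralModel,
    EnergyGrid,
    LorentzComponent,
    ResolutionFunction,
    evaluate_composite,
)
from .md import Trajectory
from .elastic import ElasticTrace
from .spectra import (
    ENERGY_WINDOWS,
    QENSSpectrum,
    RESOLUTION_FWHM,
)

__all__ = [
    "ModeTruth",
    "GroundTruth",
    "default_ground_truth",
    "default_q_grid",
    "default_energy_grid",
    "generate_resolution",
    "generate_qens_dataset",
    "generate_elastic_trace",
    "generate_trajectory",
]

#: the six measurement temperatures, K
DEFAULT_TEMPERATURES = (300.0, 313.0, 330.0, 343.0, 358.0, 368.0)

#: default energy-grid spacings per resolution mode, μeV
DEFAULT_SPACING = {"high_resolution": 0.25, "high_intensity": 4.0}

#: reference temperature at which truth values are quoted, K
T_REF = 358.0


def default_q_grid(n_q: int = 17) -> np.ndarray:
    """Evenly spaced Q bins across the instrument's 0.17–1.82 Å⁻¹ range."""
    return np.linspace(0.17, 1.82, n_q)


def default_energy_grid(mode: str) -> EnergyGrid:
    lo, hi = ENERGY_WINDOWS[mode]
    dE = DEFAULT_SPACING[mode]
    return EnergyGrid(np.arange(lo, hi + dE / 2, dE))


@dataclass
class ModeTruth:
    """Ground truth for one Lorentzian mode.

    ``kind`` selects the Γ(Q²) law:

    * ``fick`` — Γ = ħ D Q², from ``D_ref`` (Å² s⁻¹);
    * ``jump`` — Γ = ħ D Q²/(1 + D Q² τ₀), from ``D_ref`` and
      ``tau0_ref`` (s);
    * ``constant`` — Q-independent Γ = ``gamma_ref`` (μeV).

    Temperature dependence is Arrhenius about the reference temperature:
    rates (D, Γ) carry exp(−Ea/R · (1/T − 1/T_ref)), residence times the
    opposite sign.  ``amplitude`` is the mode's weight in the composite.
    """

    kind: str  # "fick" | "jump" | "constant"
    amplitude: float
    D_ref: float | None = None
    tau0_ref: float | None = None
    gamma_ref: float | None = None
    Ea_rate: float = 0.0  # J/mol, applies to D or Γ
    Ea_tau0: float = 0.0  # J/mol, applies to τ₀ (jump only)

    def __post_init__(self) -> None:
        if self.kind not in ("fick", "jump", "constant"):
            raise ValueError(f"unknown mode kind {self.kind!r}")
        if self.kind == "fick" and not (self.D_ref and self.D_ref > 0):
            raise ValueError("fick mode needs positive D_ref")
        if self.kind == "jump" and not (
            self.D_ref and self.D_ref > 0 and self.tau0_ref and self.tau0_ref > 0
        ):
            raise ValueError("jump mode needs positive D_ref and tau0_ref")
        if self.kind == "constant" and not (self.gamma_ref and self.gamma_ref > 0):
            raise ValueError("constant mode needs positive gamma_ref")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def _arrhenius(self, ref: float, ea: float, temperature: float, sign: float) -> float:
        return ref * np.exp(
            sign * ea / GAS_CONSTANT * (1.0 / temperature - 1.0 / T_REF)
        )

    def D(self, temperature: float) -> float:
        assert self.D_ref is not None
        return self._arrhenius(self.D_ref, self.Ea_rate, temperature, -1.0)

    def tau0(self, temperature: float) -> float:
        assert self.tau0_ref is not None
        return self._arrhenius(self.tau0_ref, self.Ea_tau0, temperature, +1.0)

    def gamma(self, q_squared: float, temperature: float) -> float:
        """True HWHM (μeV) at one Q² and temperature."""
        if self.kind == "fick":
            return HBAR_UEV_S * self.D(temperature) * q_squared
        if self.kind == "jump":
            d, t0 = self.D(temperature), self.tau0(temperature)
            return HBAR_UEV_S * d * q_squared / (1.0 + d * q_squared * t0)
        assert self.gamma_ref is not None
        return self._arrhenius(self.gamma_ref, self.Ea_rate, temperature, -1.0)


@dataclass
class GroundTruth:
    """Complete generative truth for a two-sample QENS study."""

    headgroup: dict[str, ModeTruth]
    water: dict[str, ModeTruth]
    background: dict[str, float]  # counts per resolution mode
    count_scale: float  # converts model density to counts
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "headgroup": {k: asdict(v) for k, v in self.headgroup.items()},
            "water": {k: asdict(v) for k, v in self.water.items()},
            "background": dict(self.background),
            "count_scale": self.count_scale,
            "temperatures": list(self.temperatures),
            "seed": self.seed,
            "reference_temperature": T_REF,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            headgroup={k: ModeTruth(**v) for k, v in d["headgroup"].items()},
            water={k: ModeTruth(**v) for k, v in d["water"].items()},
            background=dict(d["background"]),
            count_scale=float(d["count_scale"]),
            temperatures=tuple(d["temperatures"]),
            seed=int(d["seed"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_ground_truth(seed: int = 0) -> GroundTruth:
    """Truth values inside the ranges the emulated experiment reports.

    The headgroup slow mode uses the liquid-crystalline-phase D of
    3.43 × 10⁹ Å² s⁻¹ at 358 K; the fast modes sit inside the observed
    0.1–0.4 meV band; the hydration-water residence times carry the
    reported activation energies of 4 (medium-speed) and 23 (slow)
    kJ mol⁻¹.  Amplitudes split 12 : 20 between headgroup and water
    hydrogens, matching the per-lipid hydrogen inventory.
    """
    head_shares = {"slow": 0.35, "medium": 0.40, "fast": 0.25}
    water_shares = {"slow_HW": 0.35, "medium_speed_HW": 0.40, "fast_water": 0.25}
    headgroup = {
        "slow": ModeTruth(
            kind="fick", amplitude=12.0 * head_shares["slow"],
            D_ref=3.43e9, Ea_rate=30e3,
        ),
        "medium": ModeTruth(
            kind="jump", amplitude=12.0 * head_shares["medium"],
            D_ref=5.0e10, tau0_ref=5.0e-12, Ea_rate=20e3, Ea_tau0=10e3,
        ),
        "fast": ModeTruth(
            kind="constant", amplitude=12.0 * head_shares["fast"],
            gamma_ref=260.0, Ea_rate=5e3,
        ),
    }
    water = {
        "slow_HW": ModeTruth(
            kind="jump", amplitude=20.0 * water_shares["slow_HW"],
            D_ref=2.5e9, tau0_ref=6.0e-11, Ea_rate=25e3, Ea_tau0=23e3,
        ),
        "medium_speed_HW": ModeTruth(
            kind="jump", amplitude=20.0 * water_shares["medium_speed_HW"],
            D_ref=8.0e10, tau0_ref=2.0e-12, Ea_rate=15e3, Ea_tau0=4e3,
        ),
        "fast_water": ModeTruth(
            kind="constant", amplitude=20.0 * water_shares["fast_water"],
            gamma_ref=300.0, Ea_rate=3e3,
        ),
    }
    return GroundTruth(
        headgroup=headgroup,
        water=water,
        background={"high_resolution": 60.0, "high_intensity": 60.0},
        count_scale=7.0e3,
        seed=seed,
    )


def generate_resolution(
    mode: str,
    q_values: np.ndarray,
    spacing_uev: float | None = None,
    seed: int | None = None,
    width_jitter: float = 0.0,
) -> ResolutionFunction:
    """Gaussian resolution kernels of the mode's nominal FWHM per Q.

    ``width_jitter`` (e.g. 0.05) applies a seeded uniform ±jitter to the
    per-Q FWHM, emulating the Q-dependence of measured kernels; zero
    gives identical kernels across Q.
    """
    if mode not in RESOLUTION_FWHM:
        raise ValueError(f"unknown resolution mode {mode!r}")
    fwhm = RESOLUTION_FWHM[mode]
    dE = spacing_uev if spacing_uev is not None else DEFAULT_SPACING[mode]
    lo, hi = ENERGY_WINDOWS[mode]
    if (hi - lo) < 4.0 * fwhm:
        raise ValueError("energy window too narrow for the kernel support")
    n_q = np.asarray(q_values).size
    if width_jitter > 0:
        rng = np.random.default_rng(seed)
        widths = fwhm * (1.0 + width_jitter * rng.uniform(-1.0, 1.0, size=n_q))
    else:
        widths = np.full(n_q, fwhm)
    return ResolutionFunction.gaussian(widths, dE, n_q=n_q)


def _composite_for(
    truth: GroundTruth,
    sample: str,
    mode: str,
    temperature: float,
    q: float,
    resolution: ResolutionFunction,
) -> CompositeSpectralModel:
    comps = []
    mode_sets = [truth.headgroup]
    if sample == "headgroup_plus_water":
        mode_sets.append(truth.water)
    for modes in mode_sets:
        for label, mt in modes.items():
            comps.append(
                LorentzComponent(
                    label=label,
                    amplitude=mt.amplitude * truth.count_scale,
                    hwhm=mt.gamma(q * q, temperature),
                )
            )
    return CompositeSpectralModel(
        components=comps,
        background=0.0,
        resolution=resolution,
    )


def generate_qens_dataset(
    truth: GroundTruth,
    design: list[tuple[str, str, float]] | None = None,
    q_values: np.ndarray | None = None,
    noise: bool = True,
    resolutions: dict[str, ResolutionFunction] | None = None,
) -> dict[tuple[str, str, float], QENSSpectrum]:
    """Spectra for every (sample, resolution mode, temperature) design cell.

    Each spectrum is the resolution-convolved composite model for its
    sample scaled to counts, plus flat background, with seeded Poisson
    counting noise; σ = √counts with a floor of 1.  The design defaults
    to the full two-sample × two-mode grid at every truth temperature.
    """
    if q_values is None:
        q_values = default_q_grid()
    if design is None:
        design = [
            (s, m, T)
            for s in ("headgroup_only", "headgroup_plus_water")
            for m in ("high_intensity", "high_resolution")
            for T in truth.temperatures
        ]
    for sample, _, _ in design:
        if sample == "headgroup_plus_water" and not truth.water:
            raise ValueError("design requests the water sample but truth has no water modes")
    if resolutions is None:
        resolutions = {
            m: generate_resolution(m, q_values, seed=truth.seed)
            for m in ("high_resolution", "high_intensity")
        }
    rng = np.random.default_rng(truth.seed)
    out: dict[tuple[str, str, float], QENSSpectrum] = {}
    for sample, mode, T in design:
        energy = default_energy_grid(mode)
        res = resolutions[mode]
        n_q = np.asarray(q_values).size
        intensities = np.empty((n_q, len(energy)))
        for iq, q in enumerate(np.asarray(q_values)):
            model = _composite_for(truth, sample, mode, T, q, res)
            # counts per channel = density × ΔE; flat background is in counts
            intensities[iq] = (
                evaluate_composite(model, iq, energy) * energy.spacing
                + truth.background[mode]
            )
        if noise:
            intensities = rng.poisson(np.clip(intensities, 0.0, None)).astype(float)
        uncertainties = np.sqrt(np.clip(intensities, 1.0, None))
        out[(sample, mode, T)] = QENSSpectrum(
            q_values=np.asarray(q_values, float),
            energy=energy,
            intensities=intensities,
            uncertainties=uncertainties,
            temperature=T,
            resolution_mode=mode,
            sample=sample,
        )
    return out


def generate_elastic_trace(
    transitions: list[tuple[float, float]],
    baseline_slope: float = -4.0e-3,
    t_grid: np.ndarray | None = None,
    noise_level: float = 0.02,
    seed: int | None = None,
    drop_width: float = 2.0,
    intensity_scale: float = 1.0e4,
    ramp: str = "heating",
) -> ElasticTrace:
    """Log-linear elastic trace with sigmoidal drops at given transitions.

    ``transitions`` lists (temperature K, drop fraction in (0,1)) pairs;
    each multiplies the harmonic baseline exp(a + slope·T) by
    1 − f·σ((T−T_c)/width).  Noise is multiplicative Gaussian of the
    given fractional level, seeded.
    """
    if t_grid is None:
        t_grid = np.arange(240.0, 371.0, 1.0)
    t_grid = np.asarray(t_grid, dtype=float)
    for tc, frac in transitions:
        if not (t_grid[0] < tc < t_grid[-1]):
            raise ValueError(f"transition at {tc} K lies outside the T grid")
        if not (0.0 < frac < 1.0):
            raise ValueError(f"drop fraction must be in (0, 1), got {frac}")
    lnI = np.log(intensity_scale) + baseline_slope * (t_grid - t_grid[0])
    intensity = np.exp(lnI)
    for tc, frac in transitions:
        sigmoid = 1.0 / (1.0 + np.exp(-(t_grid - tc) / drop_width))
        intensity = intensity * (1.0 - frac * sigmoid)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity * (1.0 + noise_level * rng.standard_normal(t_grid.size))
        intensity = np.clip(intensity, 1e-12, None)
    return ElasticTrace(t_grid, intensity, ramp=ramp)


def generate_trajectory(
    n_molecules: int,
    D_t: float,
    D_r: float,
    n_frames: int,
    dt: float,
    seed: int | None = None,
    bond_length: float = 3.0,
) -> Trajectory:
    """Brownian anchors with rigid rotating two-atom vectors.

    Each molecule has a P-like anchor undergoing 3-D Gaussian-increment
    Brownian motion (per-axis step variance 2·D_t·dt, with D_t in
    Å² ns⁻¹ and dt in ps) and an N-like partner at fixed ``bond_length``
    along a unit vector undergoing isotropic rotational diffusion:
    per-step transverse Gaussian kicks of variance 2·D_r·dt (D_r in
    ps⁻¹) followed by renormalization, which gives
    ⟨cos θ(t)⟩ = exp(−2 D_r t) in the small-step limit.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_molecules <= 0 or n_frames < 1:
        raise ValueError("need at least one molecule and one frame")
    if D_t < 0 or D_r < 0:
        raise ValueError("diffusion coefficients must be non-negative")
    rng = np.random.default_rng(seed)
    d_t_ps = D_t * 1e-3  # Å²/ns → Å²/ps
    step_sigma = np.sqrt(2.0 * d_t_ps * dt)
    # subdivide rotational steps so the small-angle approximation holds;
    # a single kick of variance 2·D_r·dt would under-rotate by O((D_r dt)²)
    n_sub = max(int(np.ceil(2.0 * D_r * dt / 0.005)), 1)
    rot_sigma = np.sqrt(2.0 * D_r * dt / n_sub)

    anchors = np.zeros((n_frames, n_molecules, 3))
    anchors[0] = rng.uniform(0.0, 50.0, size=(n_molecules, 3))
    if step_sigma > 0:
        steps = rng.normal(0.0, step_sigma, size=(n_frames - 1, n_molecules, 3))
        anchors[1:] = anchors[0] + np.cumsum(steps, axis=0)
    else:
        anchors[1:] = anchors[0]

    # isotropic random initial orientations
    u = rng.standard_normal((n_molecules, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    orientations = np.empty((n_frames, n_molecules, 3))
    orientations[0] = u
    for f in range(1, n_frames):
        if rot_sigma > 0:
            for _ in range(n_sub):
                # orthonormal transverse basis per molecule
                ref = np.where(
                    np.abs(u[:, :1]) < 0.9,
                    np.tile([1.0, 0.0, 0.0], (n_molecules, 1)),
                    np.tile([0.0, 1.0, 0.0], (n_molecules, 1)),
                )
                e1 = np.cross(u, ref)
                e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
                e2 = np.cross(u, e1)
                kicks = rng.normal(0.0, rot_sigma, size=(n_molecules, 2))
                u = u + kicks[:, :1] * e1 + kicks[:, 1:] * e2
                u /= np.linalg.norm(u, axis=1, keepdims=True)
        orientations[f] = u

    coords = np.empty((n_frames, 2 * n_molecules, 3))
    coords[:, 0::2, :] = anchors
    coords[:, 1::2, :] = anchors + bond_length * orientations
    labels = []
    mol_index = []
    for m in range(n_molecules):
        labels.extend(["P", "N"])
        mol_index.extend([m, m])
    groups = {
        "P": np.arange(0, 2 * n_molecules, 2),
        "N": np.arange(1, 2 * n_molecules, 2),
    }
    return Trajectory(
        coords=coords,
        dt=dt,
        labels=labels,
        groups=groups,
        mol_index=np.array(mol_index),
    )
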