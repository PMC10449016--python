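"""From per-Q quasi-elastic linewidths to physical dynamics parameters.

A Lorentzian HWHM profile Γ(Q²) for one mode at one temperature is the
raw observable; this module turns it into

* a Fickian translational diffusion coefficient, Γ = ħ D Q² (origin-
  constrained linear fit);
* a jump-diffusion pair (D, τ₀), Γ = ħ D Q² / (1 + D Q² τ₀), which is
  Fickian at low Q and plateaus at ħ/τ₀ at high Q;
* a localized-mode summary (mean/std of a Q-independent Γ with a
  flatness check) for rotational motions;
* Arrhenius activation energies from D(T) or τ₀(T) series;
* relaxation times τ = ħ/Γ;
* and the bound-incoherent-cross-section bookkeeping that justifies
  assigning a sample's QENS signal to a particular hydrogen population.

Unit conventions: Γ and its σ in μeV, Q² in Å⁻², D in Å² s⁻¹, τ₀ in s,
activation energies in J mol⁻¹.  ħ in μeV·s is the single conversion
constant — there is deliberately no h-vs-ħ or factor-of-2 variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import (
    CROSS_SECTION_TABLE_VERSION,
    GAS_CONSTANT,
    HBAR_UEV_S,
    INCOHERENT_CROSS_SECTIONS,
    gamma_to_tau,
)

__all__ = [
    "HWHMProfile",
    "DiffusionFit",
    "ArrheniusFit",
    "IsotopicComposition",
    "fick_fit",
    "jump_diffusion_fit",
    "localized_mode_summary",
    "arrhenius_fit",
    "relaxation_time",
    "incoherent_fraction",
    "exclude_unreliable",
    "write_profile",
    "read_profile",
    "d54dmpe_composition",
]


@dataclass
class HWHMProfile:
    """Γ vs Q² series for one mode at one temperature, with 1σ errors."""

    mode: str
    temperature: float
    q_squared: np.ndarray
    gamma: np.ndarray
    gamma_sigma: np.ndarray | None = None
    excluded_q_squared: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.q_squared = np.asarray(self.q_squared, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.gamma_sigma is not None:
            self.gamma_sigma = np.asarray(self.gamma_sigma, dtype=float)
            if self.gamma_sigma.shape != self.gamma.shape:
                raise ValueError("gamma_sigma shape mismatch")
            if np.any(self.gamma_sigma <= 0):
                raise ValueError("gamma_sigma must be strictly positive")
        if self.q_squared.shape != self.gamma.shape:
            raise ValueError("q_squared and gamma must have the same shape")
        if np.any(np.diff(self.q_squared) <= 0):
            raise ValueError("q_squared must be strictly increasing")
        if np.any(self.gamma <= 0):
            raise ValueError("all HWHM values must be positive")

    def __len__(self) -> int:
        return self.q_squared.size

    @property
    def weights(self) -> np.ndarray:
        """1/σ² weights, or unit weights when uncertainties are absent."""
        if self.gamma_sigma is None:
            return np.ones_like(self.gamma)
        return 1.0 / self.gamma_sigma**2


@dataclass
class DiffusionFit:
    """Result of a translational-diffusion model fit to Γ(Q²)."""

    model: str  # "fick" | "jump_diffusion"
    D: float  # Å² s⁻¹
    D_sigma: float
    tau0: float | None = None  # s, jump model only
    tau0_sigma: float | None = None
    red_chi2: float = float("nan")
    converged: bool = True
    n_points: int = 0

    def gamma_curve(self, q_squared: np.ndarray) -> np.ndarray:
        """Model Γ (μeV) on an arbitrary Q² grid."""
        q2 = np.asarray(q_squared, dtype=float)
        if self.model == "fick":
            return HBAR_UEV_S * self.D * q2
        rate = self.D * q2 / (1.0 + self.D * q2 * (self.tau0 or 0.0))
        return HBAR_UEV_S * rate


@dataclass
class ArrheniusFit:
    """ln(value) vs 1/T regression summarized as an activation energy."""

    activation_energy: float  # J mol⁻¹
    activation_energy_sigma: float
    prefactor: float
    fitted_on: str  # "D" | "tau0"
    slope: float
    intercept: float
    n_points: int


def exclude_unreliable(
    profile: HWHMProfile, relative_error_threshold: float = 0.5
) -> HWHMProfile:
    """Drop points whose relative HWHM uncertainty exceeds the threshold.

    Mirrors the practice of setting aside individual Q bins whose fitted
    widths carry disproportionate error bars before interpreting Γ(Q²).
    Excluded Q² values are recorded on the returned profile.
    """
    if len(profile) == 0:
        raise ValueError("profile is empty")
    if profile.gamma_sigma is None:
        return profile
    rel = profile.gamma_sigma / profile.gamma
    keep = rel <= relative_error_threshold
    if not np.any(keep):
        raise ValueError(
            "all points exceed the relative-error threshold "
            f"{relative_error_threshold}; review the threshold"
        )
    return HWHMProfile(
        mode=profile.mode,
        temperature=profile.temperature,
        q_squared=profile.q_squared[keep],
        gamma=profile.gamma[keep],
        gamma_sigma=profile.gamma_sigma[keep],
        excluded_q_squared=list(profile.excluded_q_squared)
        + [float(q) for q in profile.q_squared[~keep]],
    )


def write_profile(profile: HWHMProfile, path) -> None:
    """Write a Γ(Q²) profile as metadata-headed ``Q2 gamma sigma`` text."""
    from pathlib import Path

    with Path(path).open("w") as fh:
        fh.write(f"# mode: {profile.mode}\n")
        fh.write(f"# temperature: {profile.temperature}\n")
        if profile.excluded_q_squared:
            fh.write(
                "# excluded_q_squared: "
                + " ".join(f"{q:.6g}" for q in profile.excluded_q_squared)
                + "\n"
            )
        fh.write("# columns: q_squared gamma gamma_sigma\n")
        sig = (
            profile.gamma_sigma
            if profile.gamma_sigma is not None
            else np.full_like(profile.gamma, np.nan)
        )
        for q2, g, s in zip(profile.q_squared, profile.gamma, sig):
            fh.write(f"{q2:.8g} {g:.8g} {s:.8g}\n")


def read_profile(path) -> HWHMProfile:
    """Read a profile written by :func:`write_profile`."""
    from pathlib import Path

    meta: dict[str, str] = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                k, _, v = body.partition(":")
                meta[k.strip()] = v.strip()
        elif line.strip():
            rows.append([float(v) for v in line.split()])
    arr = np.array(rows)
    sig = arr[:, 2]
    excluded = [
        float(v) for v in meta.get("excluded_q_squared", "").split() if v
    ]
    return HWHMProfile(
        mode=meta.get("mode", "unknown"),
        temperature=float(meta.get("temperature", "nan")),
        q_squared=arr[:, 0],
        gamma=arr[:, 1],
        gamma_sigma=None if np.all(np.isnan(sig)) else sig,
        excluded_q_squared=excluded,
    )


def fick_fit(profile: HWHMProfile) -> DiffusionFit:
    """Origin-constrained weighted linear fit Γ = ħ D Q².

    The Fickian law has no intercept; the slope (μeV Å²) divided by ħ
    gives D in Å² s⁻¹.  Weights are 1/σ(Γ)².
    """
    if len(profile) < 3:
        raise ValueError("Fickian fit needs at least 3 points")
    x = profile.q_squared
    y = profile.gamma
    w = profile.weights
    sxx = np.sum(w * x * x)
    slope = np.sum(w * x * y) / sxx
    # variance of the weighted through-origin slope
    if profile.gamma_sigma is not None:
        slope_var = 1.0 / sxx
    else:
        resid = y - slope * x
        slope_var = np.sum(resid**2) / max(len(profile) - 1, 1) / sxx
    resid = (y - slope * x) * np.sqrt(w)
    dof = max(len(profile) - 1, 1)
    return DiffusionFit(
        model="fick",
        D=slope / HBAR_UEV_S,
        D_sigma=float(np.sqrt(slope_var)) / HBAR_UEV_S,
        red_chi2=float(np.sum(resid**2) / dof),
        n_points=len(profile),
    )


def jump_diffusion_fit(profile: HWHMProfile, seed: int | None = None) -> DiffusionFit:
    """Weighted nonlinear fit of the jump-diffusion law.

    Γ(Q²) = ħ D Q² / (1 + D Q² τ₀): a random walk of residence time τ₀
    between jumps.  Multi-start over τ₀ decades guards against the
    Fickian ridge at τ₀ → 0.
    """
    if len(profile) < 4:
        raise ValueError("jump-diffusion fit needs at least 4 points")
    q2 = profile.q_squared
    if q2[-1] / q2[0] < 3.0:
        raise ValueError("profile must span at least a factor 3 in Q²")
    y = profile.gamma
    sig = (
        profile.gamma_sigma
        if profile.gamma_sigma is not None
        else np.ones_like(y)
    )

    # work in log-parameters to keep D, τ₀ positive
    def resid(p: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            D, tau0 = np.exp(np.clip(p, -200.0, 200.0))
            model = HBAR_UEV_S * D * q2 / (1.0 + D * q2 * tau0)
        return (model - y) / sig

    slope0 = np.sum(y * q2) / np.sum(q2 * q2)
    d0 = max(slope0 / HBAR_UEV_S, 1e3)
    best = None
    # τ₀ starts spanning sub-ps to ns
    for tau_start in 10.0 ** np.arange(-14.0, -8.0):
        sol = least_squares(resid, x0=[np.log(d0), np.log(tau_start)], method="lm")
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    D, tau0 = np.exp(best.x)
    dof = max(len(profile) - 2, 1)
    chi2 = 2.0 * best.cost
    # covariance from J^T J, scaled if no real uncertainties were given
    JTJ = best.jac.T @ best.jac
    try:
        cov_log = np.linalg.inv(JTJ)
        if profile.gamma_sigma is None:
            cov_log *= chi2 / dof
        d_sig = float(np.sqrt(cov_log[0, 0])) * D
        t_sig = float(np.sqrt(cov_log[1, 1])) * tau0
        converged = bool(best.success)
    except np.linalg.LinAlgError:
        d_sig = t_sig = float("nan")
        converged = False
    return DiffusionFit(
        model="jump_diffusion",
        D=float(D),
        D_sigma=d_sig,
        tau0=float(tau0),
        tau0_sigma=t_sig,
        red_chi2=chi2 / dof,
        converged=converged,
        n_points=len(profile),
    )


def localized_mode_summary(
    profile: HWHMProfile, q_squared_window: tuple[float, float]
) -> tuple[float, float, bool]:
    """Mean and standard deviation of Γ inside a Q² window, plus flatness.

    A Q-independent Γ signals localized (rotational) motion.  The
    flatness flag is True when a weighted linear fit of Γ vs Q² inside
    the window has a slope consistent with zero at 2σ.
    """
    lo, hi = q_squared_window
    mask = (profile.q_squared >= lo) & (profile.q_squared <= hi)
    if not np.any(mask):
        raise ValueError("Q² window contains no profile points")
    if int(np.sum(mask)) < 3:
        raise ValueError("need at least 3 points inside the Q² window")
    x = profile.q_squared[mask]
    y = profile.gamma[mask]
    mean = float(np.mean(y))
    std = float(np.std(y, ddof=0))
    w = profile.weights[mask]
    # weighted straight-line fit; slope σ from the weighted normal equations
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (y - yb)) / sxx
    if profile.gamma_sigma is not None:
        slope_sigma = np.sqrt(1.0 / sxx)
    else:
        resid = y - yb - slope * (x - xb)
        s2 = np.sum(resid**2) / max(x.size - 2, 1)
        slope_sigma = np.sqrt(s2 / sxx)
    flat = bool(abs(slope) <= 2.0 * slope_sigma)
    return mean, std, flat


def arrhenius_fit(
    temperatures: np.ndarray,
    values: np.ndarray,
    fitted_on: str = "tau0",
    sigma: np.ndarray | None = None,
    allow_two_points: bool = False,
) -> ArrheniusFit:
    """Activation energy from a linear fit of ln(value) against 1/T.

    For residence times the slope is +Ea/R (τ₀ grows on cooling); for
    diffusion coefficients it is −Ea/R.  Regression is unweighted by
    default; pass ``sigma`` (1σ on the values) for 1/σ² weighting of the
    log-values via error propagation.
    """
    T = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0) or np.any(T <= 0):
        raise ValueError("temperatures and values must be positive")
    min_pts = 2 if allow_two_points else 3
    if T.size < min_pts:
        raise ValueError(f"need at least {min_pts} (T, value) pairs")
    if fitted_on not in ("D", "tau0"):
        raise ValueError("fitted_on must be 'D' or 'tau0'")
    x = 1.0 / T
    y = np.log(v)
    if sigma is not None:
        w = (v / np.asarray(sigma, dtype=float)) ** 2  # var(ln v) = (σ/v)²
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xb = np.sum(w * x) / W
    yb = np.sum(w * y) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = float(np.sum(w * (x - xb) * (y - yb)) / sxx)
    intercept = float(yb - slope * xb)
    if sigma is not None:
        slope_sigma = float(np.sqrt(1.0 / sxx))
    else:
        resid = y - intercept - slope * x
        s2 = np.sum(resid**2) / max(x.size - 2, 1)
        slope_sigma = float(np.sqrt(s2 / sxx))
    sign = 1.0 if fitted_on == "tau0" else -1.0
    return ArrheniusFit(
        activation_energy=sign * slope * GAS_CONSTANT,
        activation_energy_sigma=slope_sigma * GAS_CONSTANT,
        prefactor=float(np.exp(intercept)),
        fitted_on=fitted_on,
        slope=slope,
        intercept=intercept,
        n_points=int(T.size),
    )


def relaxation_time(gamma_uev: float) -> float:
    """Relaxation time τ = ħ/Γ in seconds, from a HWHM in μeV."""
    return gamma_to_tau(gamma_uev)


@dataclass
class IsotopicComposition:
    """Nuclide inventory of a sample for incoherent cross-section sums.

    ``species`` maps a species name to (multiplicity, {nuclide: count}).
    The bound incoherent cross-section table is versioned because the
    derived percentages depend on it.
    """

    species: dict[str, tuple[float, dict[str, float]]]
    cross_sections: dict[str, float] = field(
        default_factory=lambda: dict(INCOHERENT_CROSS_SECTIONS)
    )
    table_version: str = CROSS_SECTION_TABLE_VERSION

    def total_cross_section(self, only: dict[str, dict[str, float]] | None = None) -> float:
        """Σ multiplicity × count × σ_inc, in barn.

        ``only`` optionally restricts the sum to given per-species
        nuclide counts (a sub-inventory, e.g. just headgroup hydrogens).
        """
        total = 0.0
        source = (
            {name: (self.species[name][0], counts) for name, counts in only.items()}
            if only is not None
            else self.species
        )
        for name, (mult, counts) in source.items():
            for nuclide, count in counts.items():
                if count < 0:
                    raise ValueError(f"negative count for {nuclide} in {name}")
                if nuclide not in self.cross_sections:
                    raise KeyError(
                        f"unknown nuclide {nuclide!r}; table "
                        f"{self.table_version} contains "
                        f"{sorted(self.cross_sections)}"
                    )
                total += mult * count * self.cross_sections[nuclide]
        return total


def incoherent_fraction(
    composition: IsotopicComposition, target: dict[str, dict[str, float]]
) -> float:
    """Share of total bound incoherent scattering carried by a sub-inventory.

    ``target`` maps species names to the nuclide counts to attribute to
    the group of interest (e.g. the 12 headgroup hydrogens of a
    tail-deuterated lipid).  Returns a number in [0, 1].
    """
    total = composition.total_cross_section()
    if total <= 0:
        raise ValueError("total incoherent cross section must be positive")
    part = composition.total_cross_section(only=target)
    return part / total


def d54dmpe_composition(water: str = "D2O", n_water: float = 10.0) -> IsotopicComposition:
    """Tail-deuterated DMPE with ``n_water`` waters per lipid.

    DMPE is C33H66NO8P; tail deuteration replaces the 54 acyl-chain
    hydrogens with deuterium, leaving 12 headgroup/glycerol hydrogens.
    """
    if water not in ("D2O", "H2O"):
        raise ValueError("water must be 'D2O' or 'H2O'")
    lipid = {"H": 12.0, "D": 54.0, "C": 33.0, "N": 1.0, "O": 8.0, "P": 1.0}
    w_nuc = "D" if water == "D2O" else "H"
    water_counts = {w_nuc: 2.0, "O": 1.0}
    return IsotopicComposition(
        species={"lipid": (1.0, lipid), "water": (n_water, water_counts)}
    )
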