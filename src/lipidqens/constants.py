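"""Physical constants and nuclear cross-section data.

Single source of truth for every unit conversion in the package.  The
internal energy unit is μeV throughout; meV appears only at I/O
boundaries.
"""

from __future__ import annotations

from types import MappingProxyType

#: Reduced Planck constant in μeV·s (= 0.6582119569 meV·ps).
HBAR_UEV_S: float = 6.582119569e-10

#: Universal gas constant, J mol⁻¹ K⁻¹.
GAS_CONSTANT: float = 8.314462618

#: Bound incoherent neutron scattering cross sections, barn.
#: Values follow the standard tabulation of bound cross sections
#: (Sears 1992); version tag below identifies the table revision.
INCOHERENT_CROSS_SECTIONS = MappingProxyType(
    {
        "H": 80.27,
        "D": 2.05,
        "C": 0.001,
        "N": 0.50,
        "O": 0.0008,
        "P": 0.005,
    }
)

CROSS_SECTION_TABLE_VERSION = "sears-1992"


def gamma_to_tau(gamma_uev: float) -> float:
    """Convert a Lorentzian HWHM Γ (μeV) to a relaxation time τ = ħ/Γ (s).

    Parameters
    ----------
    gamma_uev : float
        Half-width at half-maximum in μeV; must be positive.

    Returns
    -------
    float
        Relaxation time in seconds.
    """
    if gamma_uev <= 0:
        raise ValueError(f"HWHM must be positive, got {gamma_uev}")
    return HBAR_UEV_S / gamma_uev


def rate_to_gamma(rate_per_s: float) -> float:
    """Convert a relaxation rate (s⁻¹) to a Lorentzian HWHM in μeV."""
    return HBAR_UEV_S * rate_per_s
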