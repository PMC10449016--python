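"""QENS spectrum container and columnar text I/O.

A spectrum is intensity on a (Q, E) grid with per-bin counting
uncertainties plus the metadata that drives the analysis protocol:
temperature, resolution mode and sample label.  On disk it is a plain
text table — comment-header ``# key: value`` lines followed by
``Q  E  I  sigma`` rows — so that instrument-reduced data can be dropped
in with any text tooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import EnergyGrid

__all__ = ["QENSSpectrum", "read_spectrum", "write_spectrum"]

RESOLUTION_MODES = ("high_resolution", "high_intensity")
SAMPLES = ("headgroup_only", "headgroup_plus_water")

#: instrument energy windows per resolution mode, μeV
ENERGY_WINDOWS = {
    "high_resolution": (-30.0, 60.0),
    "high_intensity": (-500.0, 1500.0),
}

#: nominal Gaussian FWHM energy resolution per mode, μeV
RESOLUTION_FWHM = {
    "high_resolution": 3.6,
    "high_intensity": 13.0,
}


@dataclass
class QENSSpectrum:
    """Measured or synthetic intensities on a (Q, E) grid with uncertainties."""

    q_values: np.ndarray  # Å⁻¹, strictly increasing
    energy: EnergyGrid  # μeV
    intensities: np.ndarray  # counts, shape (nQ, nE)
    uncertainties: np.ndarray  # counts, > 0, shape (nQ, nE)
    temperature: float  # K
    resolution_mode: str
    sample: str

    def __post_init__(self) -> None:
        self.q_values = np.asarray(self.q_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.uncertainties = np.asarray(self.uncertainties, dtype=float)
        nq, ne = self.q_values.size, len(self.energy)
        if self.intensities.shape != (nq, ne):
            raise ValueError(
                f"intensity shape {self.intensities.shape} != ({nq}, {ne})"
            )
        if self.uncertainties.shape != (nq, ne):
            raise ValueError("uncertainty array shape mismatch")
        if np.any(np.diff(self.q_values) <= 0):
            raise ValueError("Q values must be strictly increasing")
        if np.any(self.uncertainties <= 0):
            raise ValueError("uncertainties must be strictly positive")
        if self.resolution_mode not in RESOLUTION_MODES:
            raise ValueError(f"unknown resolution mode {self.resolution_mode!r}")
        if self.sample not in SAMPLES:
            raise ValueError(f"unknown sample label {self.sample!r}")

    @property
    def n_q(self) -> int:
        return self.q_values.size

    def slice_q(self, q_index: int) -> tuple[float, np.ndarray, np.ndarray]:
        """(Q, I(E), σ(E)) at one Q bin."""
        return (
            float(self.q_values[q_index]),
            self.intensities[q_index],
            self.uncertainties[q_index],
        )


def write_spectrum(spectrum: QENSSpectrum, path: str | Path) -> None:
    """Write a spectrum as header-commented ``Q E I sigma`` text."""
    path = Path(path)
    nq, ne = spectrum.intensities.shape
    q_col = np.repeat(spectrum.q_values, ne)
    e_col = np.tile(spectrum.energy.values, nq)
    table = np.column_stack(
        [q_col, e_col, spectrum.intensities.ravel(), spectrum.uncertainties.ravel()]
    )
    header = (
        f"# sample: {spectrum.sample}\n"
        f"# temperature: {spectrum.temperature}\n"
        f"# resolution_mode: {spectrum.resolution_mode}\n"
        "# columns: Q E I sigma\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, table, fmt="%.10g")


def read_spectrum(path: str | Path) -> QENSSpectrum:
    """Read a spectrum written by :func:`write_spectrum`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(
        path, sep=r"\s+", comment="#", names=["Q", "E", "I", "sigma"], header=None
    )
    q_values = np.array(sorted(df["Q"].unique()))
    ne = df[df["Q"] == q_values[0]].shape[0]
    df = df.sort_values(["Q", "E"], kind="stable")
    energies = df["E"].to_numpy()[:ne]
    return QENSSpectrum(
        q_values=q_values,
        energy=EnergyGrid(energies),
        intensities=df["I"].to_numpy().reshape(q_values.size, ne),
        uncertainties=df["sigma"].to_numpy().reshape(q_values.size, ne),
        temperature=float(meta["temperature"]),
        resolution_mode=meta["resolution_mode"],
        sample=meta["sample"],
    )
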