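"""Circular dichroism ellipticity conversion.

Converts measured ellipticity θ (millidegrees) to mean residue ellipticity

    [θ] = θ / (10 · [P] · l · n)      (deg·cm²·dmol⁻¹)

with [P] the molar protein concentration, l the path length in cm and n the
number of residues. Buffer-blank subtraction is assumed done upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EllipticityReading", "mean_residue_ellipticity", "mean_residue_ellipticity_spectrum"]


@dataclass(frozen=True)
class EllipticityReading:
    theta: float  # mdeg
    protein_conc: float  # mol/L
    path_length: float  # cm
    n_residues: int

    def __post_init__(self) -> None:
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive")
        if not self.path_length > 0:
            raise ValueError("path_length must be positive")
        if self.n_residues < 1:
            raise ValueError("n_residues must be at least 1")


def mean_residue_ellipticity(reading: EllipticityReading) -> float:
    """Mean residue ellipticity [θ] in deg·cm²·dmol⁻¹."""
    return reading.theta / (10.0 * reading.protein_conc * reading.path_length * reading.n_residues)


def mean_residue_ellipticity_spectrum(
    theta_mdeg, protein_conc: float, path_length: float, n_residues: int
) -> np.ndarray:
    """Vectorized [θ] over a wavelength series of θ values (mdeg)."""
    if not protein_conc > 0 or not path_length > 0 or n_residues < 1:
        raise ValueError("protein_conc, path_length must be positive; n_residues >= 1")
    theta = np.asarray(theta_mdeg, dtype=float)
    return theta / (10.0 * protein_conc * path_length * n_residues)
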