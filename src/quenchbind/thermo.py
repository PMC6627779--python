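"""Van't Hoff thermodynamics of binding and docking-score conversion.

A linear Van't Hoff analysis, ln Ka = −ΔH/(R·T) + ΔS/R, assumes a
temperature-independent enthalpy (ΔCp = 0) over the narrow experimental
range; ΔG then follows from ΔG = ΔH − T·ΔS. Docking energy scores in
kcal/mol convert to association constants via Kb = exp(−ΔG/(R·T)) with R in
kcal/(mol·K) for unit coherence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "R_GAS",
    "R_KCAL",
    "VantHoffFit",
    "ThermoRecord",
    "ThermoReport",
    "vant_hoff_fit",
    "gibbs_free_energy",
    "thermo_report",
    "kb_from_score",
    "score_from_kb",
    "ka_at_temperature",
    "dominant_forces",
]

R_GAS = 8.314  # J/(mol K)
R_KCAL = 1.987e-3  # kcal/(mol K), for docking scores quoted in kcal/mol


@dataclass(frozen=True)
class VantHoffFit:
    delta_h: float  # J/mol
    delta_s: float  # J/(mol K)
    delta_h_stderr: float
    delta_s_stderr: float
    r_squared: float
    gas_constant: float = R_GAS

    def ln_ka(self, temperature: float) -> float:
        """Predicted ln Ka at ``temperature`` on the fitted line."""
        return -self.delta_h / (self.gas_constant * temperature) + self.delta_s / self.gas_constant


@dataclass(frozen=True)
class ThermoRecord:
    temperature: float  # K
    delta_g: float  # J/mol
    t_delta_s: float  # J/mol
    delta_g_stderr: float


@dataclass(frozen=True)
class ThermoReport:
    fit: VantHoffFit
    records: tuple[ThermoRecord, ...]
    force_label: str


def vant_hoff_fit(temperatures: Sequence[float], ka_values: Sequence[float]) -> VantHoffFit:
    """OLS of ln Ka against 1/T; ΔH = −R·slope, ΔS = R·intercept."""
    t = np.asarray(temperatures, dtype=float)
    ka = np.asarray(ka_values, dtype=float)
    if t.size != ka.size:
        raise ValueError("temperatures and ka_values must have equal length")
    if np.unique(t).size < 2:
        raise ValueError("Van't Hoff regression needs at least 2 distinct temperatures")
    if np.any(ka <= 0):
        raise ValueError("all Ka must be positive")
    if np.any(t <= 0):
        raise ValueError("temperatures must be positive (kelvin)")
    res = stats.linregress(1.0 / t, np.log(ka))
    return VantHoffFit(
        delta_h=-R_GAS * float(res.slope),
        delta_s=R_GAS * float(res.intercept),
        delta_h_stderr=R_GAS * float(res.stderr) if np.isfinite(res.stderr) else 0.0,
        delta_s_stderr=R_GAS * float(res.intercept_stderr)
        if np.isfinite(res.intercept_stderr)
        else 0.0,
        r_squared=float(res.rvalue**2),
    )


def gibbs_free_energy(fit: VantHoffFit, temperature: float) -> ThermoRecord:
    """ΔG = ΔH − T·ΔS at ``temperature``, with T·ΔS alongside.

    The ΔG standard error propagates the ΔH and ΔS errors as independent.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    t_ds = temperature * fit.delta_s
    stderr = float(np.hypot(fit.delta_h_stderr, temperature * fit.delta_s_stderr))
    return ThermoRecord(
        temperature=temperature,
        delta_g=fit.delta_h - t_ds,
        t_delta_s=t_ds,
        delta_g_stderr=stderr,
    )


def thermo_report(fit: VantHoffFit, temperatures: Sequence[float]) -> ThermoReport:
    """Per-temperature ΔG/TΔS records plus the dominant-force label."""
    records = tuple(gibbs_free_energy(fit, t) for t in temperatures)
    mid = float(np.median(np.asarray(temperatures, dtype=float)))
    return ThermoReport(fit=fit, records=records, force_label=dominant_forces(fit.delta_h, fit.delta_s, mid))


def kb_from_score(delta_g_kcal: float, temperature: float = 300.0) -> float:
    """Association constant Kb = exp(−ΔG/(R·T)) from a kcal/mol energy score.

    Default temperature 300 K matches the thermostat temperature convention of
    the docking/MD workflows these scores come from.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return float(np.exp(-delta_g_kcal / (R_KCAL * temperature)))


def score_from_kb(k_b: float, temperature: float = 300.0) -> float:
    """Inverse of :func:`kb_from_score`: ΔG = −R·T·ln(Kb) in kcal/mol."""
    if not k_b > 0:
        raise ValueError("k_b must be positive")
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return float(-R_KCAL * temperature * np.log(k_b))


def ka_at_temperature(delta_h: float, delta_s: float, temperature: float) -> float:
    """Ka = exp(−ΔH/(R·T) + ΔS/R) — the Van't Hoff line evaluated forward.

    ΔH in J/mol, ΔS in J/(mol·K). Exact inverse of :func:`vant_hoff_fit` for
    data lying on the line.
    """
    if not temperature > 0:
        raise ValueError("temperature must be positive (kelvin)")
    return float(np.exp(-delta_h / (R_GAS * temperature) + delta_s / R_GAS))


#: canonical force labels, following the standard enthalpy/entropy sign rules
#: for protein-ligand association
LABEL_H_BOND_VDW = "enthalpy-driven: hydrogen bond / van der Waals"
LABEL_HYDROPHOBIC = "entropy-driven: hydrophobic"
LABEL_ELECTROSTATIC = "electrostatic"
LABEL_UNFAVORABLE = "indeterminate (both terms unfavorable)"


def dominant_forces(delta_h: float, delta_s: float, temperature: float = 298.0) -> str:
    """Classify the dominant intermolecular force from the signs and the
    enthalpy/entropy balance at ``temperature``.

    ΔH < 0 with ΔS < 0, or ΔH < 0 dominating T·ΔS, points to hydrogen bonding
    and van der Waals contacts; ΔH > 0 with ΔS > 0 to hydrophobic burial;
    ΔH < 0 with a dominant positive T·ΔS to electrostatics.
    """
    if not np.isfinite(delta_h) or not np.isfinite(delta_s):
        raise ValueError("delta_h and delta_s must be finite")
    t_ds = temperature * delta_s
    if delta_h > 0 and delta_s > 0:
        return LABEL_HYDROPHOBIC
    if delta_h < 0 and delta_s < 0:
        return LABEL_H_BOND_VDW
    if delta_h < 0 and delta_s >= 0:
        return LABEL_H_BOND_VDW if abs(delta_h) > abs(t_ds) else LABEL_ELECTROSTATIC
    return LABEL_UNFAVORABLE
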