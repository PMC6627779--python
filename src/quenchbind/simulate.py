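"""Forward models with ground truth for every analysis stage.

The titration simulator emulates static-quenching binding experiments on an
n-site identical-independent-site isotherm with exact mass conservation:

    Σν = n·Kb·[L]free / (1 + Kb·[L]free)
    [L]tot = [L]free + Σν·[P]tot

Signal transduction is linear in fractional occupancy,
F = F0·(1 − q_max·Σν/n): the minimal monotone, protein-concentration-
independent choice, under which the single-site q_max = 1 case reduces
exactly to the Stern-Volmer form F0/F = 1 + Kb·[L]free. Defaults mirror the
study design the package targets: serum-albumin solutions at 2, 4 and 8 µM
titrated with 1 µM ligand aliquots at 288 K.

TCSPC decays are generated from the multiexponential model with Poisson
counting noise. All randomness is seeded; one independent stream is derived
per protein concentration so adding a series never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lifetime import DecayTrace
from .thermo import ka_at_temperature  # noqa: F401  (re-export: Van't Hoff forward model)
from .titration import TitrationSeries

__all__ = [
    "SimConfig",
    "GroundTruthRecord",
    "GroundTruth",
    "solve_free_ligand",
    "binding_density",
    "simulate_titration",
    "simulate_decay",
    "ka_at_temperature",
]


def _default_protein_concs() -> tuple[float, ...]:
    return (2e-6, 4e-6, 8e-6)


def _default_ligand_grid() -> np.ndarray:
    return np.arange(0, 31, dtype=float) * 1e-6  # 0-30 µM in 1 µM steps


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of a simulated static-quenching titration.

    ``q_max`` is the maximal fractional quenching at saturation, in [0, 1]
    (0 disables signal transduction entirely);
    ``noise_rel`` the relative standard deviation of multiplicative Gaussian
    intensity noise.
    """

    k_b_true: float = 7e4  # M^-1
    n_sites_true: float = 3.0
    q_max: float = 0.8
    f0: float = 100.0
    protein_concs: tuple[float, ...] = field(default_factory=_default_protein_concs)
    ligand_grid: np.ndarray = field(default_factory=_default_ligand_grid)
    noise_rel: float = 0.0
    seed: int = 0
    temperature: float = 288.0

    def __post_init__(self) -> None:
        if not self.k_b_true > 0:
            raise ValueError("k_b_true must be positive")
        if self.n_sites_true < 1:
            raise ValueError("n_sites_true must be >= 1")
        if not 0 <= self.q_max <= 1:
            raise ValueError("q_max must lie in [0, 1]")
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be non-negative")
        object.__setattr__(self, "ligand_grid", np.asarray(self.ligand_grid, dtype=float))


@dataclass(frozen=True)
class GroundTruthRecord:
    protein_conc: float
    ligand_total: np.ndarray
    ligand_free: np.ndarray
    sigma_nu: np.ndarray
    f_noiseless: np.ndarray


@dataclass(frozen=True)
class GroundTruth:
    """Simulator manifest: per-point truth enabling parameter-recovery tests."""

    config: SimConfig
    records: tuple[GroundTruthRecord, ...]

    def record_for(self, protein_conc: float) -> GroundTruthRecord:
        for rec in self.records:
            if rec.protein_conc == protein_conc:
                return rec
        raise KeyError(f"no ground-truth record at protein_conc={protein_conc}")


def solve_free_ligand(ligand_total, protein_total, k_b, n_sites):
    """Free ligand concentration from total concentrations by mass balance.

    Substituting the isotherm into mass conservation gives the quadratic

        Kb·Lf² + (1 + Kb·(n·Ptot − Ltot))·Lf − Ltot = 0,

    whose unique root in [0, Ltot] is returned via the numerically stable
    quadratic formula (no cancellation for either sign of the linear
    coefficient). Accepts scalars or arrays.
    """
    l_tot = np.asarray(ligand_total, dtype=float)
    p_tot = np.asarray(protein_total, dtype=float)
    kb = np.asarray(k_b, dtype=float)
    if np.any(l_tot < 0) or np.any(p_tot < 0) or np.any(kb < 0) or np.any(np.asarray(n_sites) < 0):
        raise ValueError("all inputs must be non-negative")
    b = 1.0 + kb * (n_sites * p_tot - l_tot)
    disc = np.sqrt(b * b + 4.0 * kb * l_tot)
    with np.errstate(divide="ignore", invalid="ignore"):
        # stable root: 2c'/(b+sqrt) when b>=0, (-b+sqrt)/(2a) otherwise
        root_pos_b = np.where(b + disc > 0, 2.0 * l_tot / (b + disc), 0.0)
        root_neg_b = np.where(kb > 0, (-b + disc) / (2.0 * kb), l_tot)
    lf = np.where(kb == 0, l_tot, np.where(b >= 0, root_pos_b, root_neg_b))
    lf = np.clip(lf, 0.0, l_tot)
    return float(lf) if lf.ndim == 0 else lf


def binding_density(k_b, n_sites, ligand_free):
    """Binding density Σν = n·Kb·Lf / (1 + Kb·Lf) of n identical independent
    sites; lies in [0, n)."""
    kb = np.asarray(k_b, dtype=float)
    lf = np.asarray(ligand_free, dtype=float)
    if np.any(kb < 0) or np.any(lf < 0) or np.any(np.asarray(n_sites) < 0):
        raise ValueError("all inputs must be non-negative")
    x = kb * lf
    out = n_sites * x / (1.0 + x)
    return float(out) if out.ndim == 0 else out


def simulate_titration(config: SimConfig) -> tuple[list[TitrationSeries], GroundTruth]:
    """Simulate one static-quenching titration per protein concentration.

    For each (Ptot, Ltot) pair the free ligand is solved exactly, the binding
    density and the noiseless intensity F = F0·(1 − q_max·Σν/n) computed, and
    multiplicative Gaussian noise applied from a per-series stream derived
    deterministically from ``(seed, series index)``. Intensities are floored
    at a small positive value to respect the positivity invariant.
    """
    series_list: list[TitrationSeries] = []
    records: list[GroundTruthRecord] = []
    for idx, p_tot in enumerate(config.protein_concs):
        l_tot = config.ligand_grid
        l_free = solve_free_ligand(l_tot, p_tot, config.k_b_true, config.n_sites_true)
        sigma_nu = binding_density(config.k_b_true, config.n_sites_true, l_free)
        f_clean = config.f0 * (1.0 - config.q_max * sigma_nu / config.n_sites_true)
        if config.noise_rel > 0:
            rng = np.random.default_rng([config.seed, idx])
            f_obs = f_clean * (1.0 + config.noise_rel * rng.standard_normal(f_clean.size))
            f_obs = np.maximum(f_obs, 1e-9 * config.f0)
        else:
            f_obs = f_clean.copy()
        series_list.append(
            TitrationSeries(
                protein_conc=p_tot,
                temperature=config.temperature,
                ligand_total=l_tot.copy(),
                intensity=f_obs,
                label=f"sim_P{p_tot:.3g}",
            )
        )
        records.append(
            GroundTruthRecord(
                protein_conc=p_tot,
                ligand_total=l_tot.copy(),
                ligand_free=l_free,
                sigma_nu=sigma_nu,
                f_noiseless=f_clean,
            )
        )
    return series_list, GroundTruth(config=config, records=tuple(records))


def simulate_decay(
    amplitudes,
    lifetimes,
    time_range: float = 25.0,
    n_bins: int = 256,
    peak_counts: int = 10_000,
    seed: int = 0,
    noise: bool = True,
) -> DecayTrace:
    """Simulate a TCSPC histogram from a multiexponential decay.

    Expected counts follow Σ αi·exp(−t/τi) scaled so the peak bin expects
    ``peak_counts``; Poisson sampling is applied unless ``noise`` is False
    (the infinite-counts limit, returning the expected values exactly).
    """
    amps = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(lifetimes, dtype=float)
    if amps.size != taus.size:
        raise ValueError("amplitudes and lifetimes must have equal length")
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    t = np.linspace(0.0, time_range, n_bins)
    expected = np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)
    expected = expected / float(np.max(expected)) * peak_counts
    if noise:
        rng = np.random.default_rng(seed)
        counts = rng.poisson(expected).astype(float)
    else:
        counts = expected
    return DecayTrace(time=t, counts=counts)
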