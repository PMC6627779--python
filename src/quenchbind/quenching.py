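"""Stern-Volmer and double-logarithmic quenching fits, and the
static-vs-dynamic quenching classification.

The Stern-Volmer relation F0/F = 1 + K_SV·[Q] is fitted by ordinary least
squares with a free intercept; the double-log (binding equilibrium) relation

    log10((F0−F)/F) = n·log10(Ka) − n·log10([Q]_tot − ((F0−F)/F)·[P]_tot)

yields the association constant Ka and apparent site number n from slope and
intercept. Static quenching is diagnosed by K_SV falling with temperature
while excited-state lifetimes stay unchanged (τ0/τ ≈ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .titration import TitrationSeries

__all__ = [
    "SternVolmerFit",
    "DoubleLogFit",
    "QuenchingMechanism",
    "QuenchingVerdict",
    "stern_volmer_fit",
    "double_log_fit",
    "classify_quenching",
]


@dataclass(frozen=True)
class SternVolmerFit:
    k_sv: float  # Stern-Volmer constant, M^-1
    intercept: float  # dimensionless; 1 for ideal Stern-Volmer behaviour
    k_sv_stderr: float
    intercept_stderr: float
    r_squared: float
    temperature: float  # K
    n_points: int


@dataclass(frozen=True)
class DoubleLogFit:
    k_a: float  # association constant, M^-1
    n_sites: float  # apparent number of binding sites
    k_a_stderr: float
    n_sites_stderr: float
    r_squared: float
    n_points_used: int
    temperature: float  # K


class QuenchingMechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class QuenchingVerdict:
    mechanism: QuenchingMechanism
    ksv_trend: int  # sign of dK_SV/dT: -1 decreasing, +1 increasing, 0 mixed
    mean_lifetime_ratio_deviation: float  # mean |τ0/τ − 1|; NaN if no ratios


def stern_volmer_fit(series: TitrationSeries) -> SternVolmerFit:
    """OLS fit of F0/F against total quencher concentration.

    The intercept is fitted rather than pinned to 1; its deviation from unity
    is a linearity diagnostic. Requires at least three points including a
    ligand-free point that defines F0.
    """
    if len(series) < 3:
        raise ValueError("Stern-Volmer fit requires at least 3 titration points")
    f0 = series.f0  # raises if no zero-ligand point
    x = series.ligand_total
    y = f0 / series.intensity
    res = stats.linregress(x, y)
    return SternVolmerFit(
        k_sv=float(res.slope),
        intercept=float(res.intercept),
        k_sv_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
        temperature=series.temperature,
        n_points=len(series),
    )


def double_log_fit(
    series: TitrationSeries,
    bracket_denominator: str = "F",
) -> DoubleLogFit:
    """Double-logarithmic binding fit; slope = n, intercept = n·log10(Ka).

    The bound-ligand estimate inside the bracket multiplies the protein
    concentration by (F0−F)/F (``bracket_denominator="F"``, the printed form)
    or (F0−F)/F0 (``"F0"``, the common variant). Points with F ≥ F0 or with a
    non-positive bracket are dropped with a warning; at least three usable
    points must remain.
    """
    if bracket_denominator not in ("F", "F0"):
        raise ValueError("bracket_denominator must be 'F' or 'F0'")
    f0 = series.f0
    f = series.intensity
    lig = series.ligand_total
    usable = (lig > 0) & (f0 - f > 0)
    if np.any(~usable[lig > 0]):
        warnings.warn(
            f"dropping {int(np.sum(~usable) - np.sum(lig == 0))} point(s) with F >= F0",
            stacklevel=2,
        )
    denom = f if bracket_denominator == "F" else f0
    with np.errstate(divide="ignore", invalid="ignore"):
        bound_frac = (f0 - f) / denom
        bracket = lig - bound_frac * series.protein_conc
    ok = usable & (bracket > 0)
    if np.any(usable & ~ok):
        warnings.warn(
            f"dropping {int(np.sum(usable & ~ok))} point(s) with non-positive free-ligand bracket",
            stacklevel=2,
        )
    if int(np.sum(ok)) < 3:
        raise ValueError("fewer than 3 usable points for the double-log fit")
    x = np.log10(bracket[ok])
    y = np.log10((f0 - f[ok]) / f[ok])
    res = stats.linregress(x, y)
    n = float(res.slope)
    if n == 0:
        raise ValueError("zero slope: no concentration dependence of quenching")
    log_ka = float(res.intercept) / n
    k_a = 10.0**log_ka
    # var(log10 Ka) from independent slope/intercept errors of the line
    var_log_ka = (res.intercept_stderr / n) ** 2 + (res.intercept * res.stderr / n**2) ** 2
    k_a_stderr = k_a * np.log(10.0) * np.sqrt(var_log_ka)
    return DoubleLogFit(
        k_a=k_a,
        n_sites=n,
        k_a_stderr=float(k_a_stderr),
        n_sites_stderr=float(res.stderr),
        r_squared=float(res.rvalue**2),
        n_points_used=int(np.sum(ok)),
        temperature=series.temperature,
    )


def classify_quenching(
    fits: Sequence[SternVolmerFit],
    lifetime_ratios: Sequence[float] = (),
    ratio_threshold: float = 0.05,
) -> QuenchingVerdict:
    """Classify the quenching mechanism from K_SV(T) and τ0/τ ratios.

    Static quenching: K_SV strictly decreases with temperature and, when
    lifetime ratios are supplied, they stay within ``ratio_threshold`` of
    unity. Dynamic: K_SV increases with temperature (lifetime ratios, if
    given, deviate from unity). Anything else — conflicting evidence or a
    single temperature with no lifetime data — is indeterminate.
    """
    fits = sorted(fits, key=lambda f: f.temperature)
    ksv = np.array([f.k_sv for f in fits])
    if ksv.size >= 2:
        diffs = np.diff(ksv)
        if np.all(diffs < 0):
            trend = -1
        elif np.all(diffs > 0):
            trend = 1
        else:
            trend = 0
    else:
        trend = 0
    ratios = np.asarray(list(lifetime_ratios), dtype=float)
    deviation = float(np.mean(np.abs(ratios - 1.0))) if ratios.size else float("nan")
    has_ratios = ratios.size > 0
    ratios_near_unity = has_ratios and deviation < ratio_threshold

    if trend < 0 and (not has_ratios or ratios_near_unity):
        mechanism = QuenchingMechanism.STATIC
    elif trend > 0 and (not has_ratios or not ratios_near_unity):
        mechanism = QuenchingMechanism.DYNAMIC
    else:
        mechanism = QuenchingMechanism.INDETERMINATE
    return QuenchingVerdict(
        mechanism=mechanism,
        ksv_trend=trend,
        mean_lifetime_ratio_deviation=deviation,
    )
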