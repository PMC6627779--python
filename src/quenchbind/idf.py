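"""Interaction density function (IDF) analysis and the Scatchard fit.

The IDF method is model-independent: equal fractional quenching ΔF at
different total protein concentrations implies equal binding density Σν
(ligand bound per protein) and equal free ligand [L]free, because the signal
change reports only on the occupancy state. Mass conservation

    [L]tot = [L]free + Σν · [P]tot

then makes [L]tot linear in [P]tot at fixed ΔF: the slope is Σν and the
intercept is [L]free. Repeating at several ΔF levels traces the binding
isotherm without assuming its functional form; the Scatchard linearization

    Σν/[L]free = n·Kb − Kb·Σν

finally yields the site count n and binding constant Kb, with linearity
itself diagnosing non-cooperative, identical, independent sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .titration import TitrationSeries

__all__ = [
    "QuenchCurve",
    "IDFPoint",
    "CooperativityFlag",
    "ScatchardFit",
    "build_quench_curve",
    "idf_extract",
    "scatchard_fit",
    "idf_pipeline",
]


class CooperativityFlag(str, Enum):
    NON_COOPERATIVE_LINEAR = "non_cooperative_linear"
    NONLINEAR = "nonlinear"


@dataclass(frozen=True)
class QuenchCurve:
    """Monotone interpolant mapping ΔF (%) to total ligand (mol/L) for one
    titration at fixed protein concentration."""

    protein_conc: float
    delta_f_knots: np.ndarray  # percent, strictly increasing
    ligand_knots: np.ndarray  # mol/L

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_interp", PchipInterpolator(self.delta_f_knots, self.ligand_knots)
        )

    @property
    def delta_f_range(self) -> tuple[float, float]:
        return float(self.delta_f_knots[0]), float(self.delta_f_knots[-1])

    def ligand_total_at(self, delta_f) -> np.ndarray | float:
        """Total ligand concentration producing quenching level ``delta_f``."""
        lo, hi = self.delta_f_range
        df = np.asarray(delta_f, dtype=float)
        if np.any(df < lo) or np.any(df > hi):
            raise ValueError(f"ΔF level outside curve range [{lo:.3g}, {hi:.3g}] %")
        out = self._interp(df)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class IDFPoint:
    """One mass-conservation regression at a fixed ΔF level."""

    delta_f_level: float  # percent
    sigma_nu: float  # bound ligand per protein (slope)
    ligand_free: float  # mol/L (intercept)
    slope_stderr: float
    intercept_stderr: float
    n_curves_used: int


@dataclass(frozen=True)
class ScatchardFit:
    k_b: float  # M^-1
    n_sites: float
    k_b_stderr: float
    n_sites_stderr: float
    r_squared: float
    cooperativity_flag: CooperativityFlag


def build_quench_curve(series: TitrationSeries, noise_tolerance: float = 2.0) -> QuenchCurve:
    """Shape-preserving monotone interpolant of [L]tot as a function of ΔF.

    ΔF must be non-decreasing along the titration up to ``noise_tolerance``
    percentage points; small inversions and ties are merged by averaging the
    offending knots. A monotone piecewise cubic (PCHIP) is used so that the
    inverse map is single-valued — no parametric sigmoid is imposed.
    """
    if len(series) < 5:
        raise ValueError("quench curve needs at least 5 titration points")
    delta_f = series.quench_percents()
    drops = np.diff(delta_f)
    if np.any(drops < -noise_tolerance):
        worst = float(np.min(drops))
        raise ValueError(
            f"ΔF decreases by {-worst:.2f} points along the titration "
            f"(tolerance {noise_tolerance}); curve is not monotone"
        )
    # merge ties / small inversions by averaging neighbouring knots
    df_list = list(delta_f)
    lig_list = list(series.ligand_total)
    i = 1
    while i < len(df_list):
        if df_list[i] <= df_list[i - 1]:
            df_list[i - 1] = 0.5 * (df_list[i - 1] + df_list[i])
            lig_list[i - 1] = 0.5 * (lig_list[i - 1] + lig_list[i])
            del df_list[i], lig_list[i]
            i = max(i - 1, 1)
        else:
            i += 1
    if len(df_list) < 3:
        raise ValueError("fewer than 3 distinct ΔF knots after merging ties")
    return QuenchCurve(
        protein_conc=series.protein_conc,
        delta_f_knots=np.asarray(df_list, dtype=float),
        ligand_knots=np.asarray(lig_list, dtype=float),
    )


def auto_levels(curves: Sequence[QuenchCurve], n_levels: int = 10, trim: float = 0.05) -> np.ndarray:
    """Evenly spaced ΔF levels spanning the common range of all curves,
    trimmed by ``trim`` of the span at each end."""
    lo = max(c.delta_f_range[0] for c in curves)
    hi = min(c.delta_f_range[1] for c in curves)
    if hi <= lo:
        raise ValueError("curves share no common ΔF range")
    span = hi - lo
    return np.linspace(lo + trim * span, hi - trim * span, n_levels)


def idf_extract(
    curves: Sequence[QuenchCurve],
    levels: Sequence[float] | None = None,
    n_levels: int = 10,
    trim: float = 0.05,
    exclude_negative_intercept: bool = True,
) -> list[IDFPoint]:
    """Extract (Σν, [L]free) pairs by the equal-ΔF mass-conservation
    construction across ≥2 protein concentrations.

    At each ΔF level, [L]tot is read off every curve and regressed against
    [P]tot: slope = Σν, intercept = [L]free. Levels with a negative free
    ligand intercept are unphysical and excluded with a warning (they are
    still diagnostic of noise near the range ends).
    """
    if len(curves) < 2:
        raise ValueError("IDF extraction needs curves at >= 2 protein concentrations")
    p_tot = np.array([c.protein_conc for c in curves])
    if np.unique(p_tot).size < 2:
        raise ValueError("protein concentrations must be distinct")
    if levels is None:
        levels = auto_levels(curves, n_levels=n_levels, trim=trim)
    points: list[IDFPoint] = []
    dropped = 0
    for level in np.asarray(levels, dtype=float):
        l_tot = np.array([c.ligand_total_at(level) for c in curves])
        res = stats.linregress(p_tot, l_tot)
        if exclude_negative_intercept and res.intercept < 0:
            dropped += 1
            continue
        points.append(
            IDFPoint(
                delta_f_level=float(level),
                sigma_nu=float(res.slope),
                ligand_free=float(res.intercept),
                slope_stderr=float(res.stderr) if np.isfinite(res.stderr) else 0.0,
                intercept_stderr=float(res.intercept_stderr)
                if np.isfinite(res.intercept_stderr)
                else 0.0,
                n_curves_used=len(curves),
            )
        )
    if dropped:
        warnings.warn(f"excluded {dropped} ΔF level(s) with negative free-ligand intercept", stacklevel=2)
    return points


def scatchard_fit(
    points: Sequence[IDFPoint],
    r2_threshold: float = 0.95,
    significance: float = 2.0,
) -> ScatchardFit:
    """Scatchard regression of Σν/[L]free on Σν over the IDF points.

    Slope = −Kb, intercept = n·Kb. A non-negative slope means no saturable
    binding and is an error; r² below ``r2_threshold`` flags deviation from
    the single-class linear (non-cooperative) model.

    Points whose Σν or [L]free fall below ``significance`` times their own
    standard error from the mass-conservation regression are screened out:
    such levels (typically the low-ΔF end) carry enormous leverage on
    Σν/[L]free while being statistically indistinguishable from zero. If
    fewer than 3 points survive the screen, all positive-[L]free points are
    used instead. Set ``significance=0`` to disable.
    """
    usable = [p for p in points if p.ligand_free > 0]
    if significance > 0:
        screened = [
            p
            for p in usable
            if p.sigma_nu > significance * p.slope_stderr
            and p.ligand_free > significance * p.intercept_stderr
        ]
        if len(screened) >= 3:
            usable = screened
    if len(usable) < 3:
        raise ValueError("Scatchard fit needs at least 3 points with positive free ligand")
    nu = np.array([p.sigma_nu for p in usable])
    y = nu / np.array([p.ligand_free for p in usable])
    if np.ptp(nu) == 0:
        raise ValueError("degenerate Scatchard input: binding density is constant")
    res = stats.linregress(nu, y)
    if res.slope >= 0:
        raise ValueError("no saturable binding detected (non-negative Scatchard slope)")
    k_b = -float(res.slope)
    n_sites = float(res.intercept) / k_b
    # n = intercept / Kb with slope/intercept errors treated as independent
    n_stderr = abs(n_sites) * np.hypot(
        res.intercept_stderr / res.intercept if res.intercept else 0.0,
        res.stderr / res.slope,
    )
    r2 = float(res.rvalue**2)
    flag = (
        CooperativityFlag.NON_COOPERATIVE_LINEAR
        if r2 >= r2_threshold
        else CooperativityFlag.NONLINEAR
    )
    return ScatchardFit(
        k_b=k_b,
        n_sites=n_sites,
        k_b_stderr=float(res.stderr),
        n_sites_stderr=float(n_stderr),
        r_squared=r2,
        cooperativity_flag=flag,
    )


def idf_pipeline(
    series: Sequence[TitrationSeries],
    levels: Sequence[float] | None = None,
    n_levels: int = 10,
    trim: float = 0.05,
    r2_threshold: float = 0.95,
    significance: float = 2.0,
) -> tuple[list[IDFPoint], ScatchardFit]:
    """Convenience composition: titrations → quench curves → IDF points →
    Scatchard fit."""
    curves = [build_quench_curve(s) for s in series]
    points = idf_extract(curves, levels=levels, n_levels=n_levels, trim=trim)
    return points, scatchard_fit(points, r2_threshold=r2_threshold, significance=significance)
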