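"""TCSPC decay analysis: multiexponential tail fits and average lifetimes.

Decays are fitted from the peak channel onward (tail fit, no instrument
response deconvolution) as I(t) = b + Σ αi·exp(−t/τi) by weighted nonlinear
least squares with Poisson weights. The intensity-weighted average lifetime

    τ_avg = Σ αi·τi² / Σ αi·τi

feeds the τ0/τ quenching diagnostic: ratios near unity across a titration
indicate the quencher does not shorten the excited state, the signature of
static (ground-state complex) quenching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DecayTrace",
    "LifetimeFit",
    "read_decay_table",
    "fit_multiexponential",
    "average_lifetime",
    "lifetime_ratio_series",
]


@dataclass(frozen=True)
class DecayTrace:
    """A TCSPC histogram: photon counts on a uniform time grid (ns)."""

    time: np.ndarray  # ns, strictly increasing, uniform
    counts: np.ndarray  # photon counts, >= 0

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.ndim != 1 or c.ndim != 1 or t.size != c.size:
            raise ValueError("time and counts must be 1-D of equal length")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be uniform")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "counts", c)

    @property
    def total_counts(self) -> float:
        return float(np.sum(self.counts))

    @property
    def bin_width(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass(frozen=True)
class LifetimeFit:
    """Multiexponential decomposition of a decay trace.

    ``amplitudes`` are normalized to sum to 1 and sorted with ``lifetimes``
    ascending; ``tau_avg`` is the intensity-weighted average lifetime.
    """

    lifetimes: tuple[float, ...]  # ns, ascending
    amplitudes: tuple[float, ...]  # fractional, sum 1
    baseline: float  # counts
    chi_squared_reduced: float
    tau_avg: float  # ns

    @property
    def n_components(self) -> int:
        return len(self.lifetimes)


def read_decay_table(path) -> DecayTrace:
    """Read a decay CSV with columns ``time_ns,counts``."""
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    for col in ("time_ns", "counts"):
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path.name}")
    return DecayTrace(
        time=frame["time_ns"].to_numpy(dtype=float),
        counts=frame["counts"].to_numpy(dtype=float),
    )


def _model(params: np.ndarray, t: np.ndarray, n: int, fit_baseline: bool) -> np.ndarray:
    amps = params[:n]
    taus = params[n : 2 * n]
    base = params[-1] if fit_baseline else 0.0
    return base + np.sum(amps[:, None] * np.exp(-t[None, :] / taus[:, None]), axis=0)


def fit_multiexponential(
    trace: DecayTrace,
    n_components: int = 2,
    fit_baseline: bool = True,
    n_starts: int = 5,
) -> LifetimeFit:
    """Weighted least-squares tail fit of a sum of ``n_components`` exponentials.

    Fitting starts at the peak channel; weights are Poisson
    (1/sqrt(max(counts, 1))). Initialization is a deterministic multi-start
    grid of log-spaced lifetimes between the bin width and half the fitted
    time range; the start with the best reduced χ² wins. Components are
    returned sorted by lifetime with amplitudes normalized to sum 1.
    """
    if n_components not in (1, 2, 3):
        raise ValueError("n_components must be 1, 2 or 3")
    peak = int(np.argmax(trace.counts))
    t = trace.time[peak:] - trace.time[peak]
    y = trace.counts[peak:]
    if y.size < 10 * n_components:
        raise ValueError(
            f"trace has {y.size} bins past the peak; "
            f"need at least {10 * n_components} for {n_components} component(s)"
        )
    sigma = np.sqrt(np.maximum(y, 1.0))
    dt = trace.bin_width
    t_range = float(t[-1] - t[0])
    n_params = 2 * n_components + (1 if fit_baseline else 0)

    # deterministic multi-start: sliding windows over a log-spaced tau grid
    tau_grid = np.geomspace(dt, t_range / 2.0, n_starts + n_components - 1)
    amp0 = max(float(y[0]), 1.0) / n_components
    base0 = max(float(np.min(y)), 0.0) if fit_baseline else None

    lower = np.concatenate(
        [np.zeros(n_components), np.full(n_components, dt / 100.0), [0.0] if fit_baseline else []]
    )
    upper = np.concatenate(
        [
            np.full(n_components, 10.0 * float(np.max(y)) + 10.0),
            np.full(n_components, 100.0 * t_range),
            [float(np.max(y))] if fit_baseline else [],
        ]
    )

    def residuals(params: np.ndarray) -> np.ndarray:
        return (_model(params, t, n_components, fit_baseline) - y) / sigma

    best = None
    for s in range(n_starts):
        tau0 = tau_grid[s : s + n_components]
        x0 = np.concatenate(
            [np.full(n_components, amp0), tau0, [base0] if fit_baseline else []]
        )
        try:
            sol = least_squares(
                residuals, x0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
            )
        except Exception:  # a bad start may fail; others may still succeed
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success and best.cost > 1e10:
        raise RuntimeError(
            f"multiexponential fit failed to converge from {n_starts} starts "
            f"({n_components} components, {y.size} bins)"
        )

    redchi = float(2.0 * best.cost / max(y.size - n_params, 1))
    amps = np.asarray(best.x[:n_components])
    taus = np.asarray(best.x[n_components : 2 * n_components])
    base = float(best.x[-1]) if fit_baseline else 0.0
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    total = float(np.sum(amps))
    if total <= 0:
        raise RuntimeError("degenerate fit: all amplitudes zero")
    amps = amps / total
    return LifetimeFit(
        lifetimes=tuple(float(v) for v in taus),
        amplitudes=tuple(float(v) for v in amps),
        baseline=base,
        chi_squared_reduced=redchi,
        tau_avg=average_lifetime(amps, taus),
    )


def average_lifetime(amplitudes, lifetimes=None) -> float:
    """Intensity-weighted average lifetime τ_avg = Σ αi·τi² / Σ αi·τi.

    Accepts either a :class:`LifetimeFit` or separate amplitude and lifetime
    sequences. By Cauchy-Schwarz, τ_avg is never below the amplitude-weighted
    mean lifetime, with equality only when all lifetimes coincide.
    """
    if isinstance(amplitudes, LifetimeFit):
        fit = amplitudes
        amplitudes, lifetimes = fit.amplitudes, fit.lifetimes
    a = np.asarray(amplitudes, dtype=float)
    tau = np.asarray(lifetimes, dtype=float)
    if a.size != tau.size:
        raise ValueError("amplitudes and lifetimes must have equal length")
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    denom = float(np.sum(a * tau))
    if denom <= 0:
        raise ValueError("all amplitudes are zero; average lifetime undefined")
    return float(np.sum(a * tau**2) / denom)


def lifetime_ratio_series(tau0: float, fits: Sequence[LifetimeFit]) -> list[float]:
    """τ0/τ_avg for each fit, in titration order."""
    if not tau0 > 0:
        raise ValueError("tau0 must be positive")
    return [tau0 / fit.tau_avg for fit in fits]
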