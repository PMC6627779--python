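"""Titration data containers, file I/O and steady-state corrections.

Internal units are mol/L for concentrations, K for temperature and cm for
optical path lengths; file dialects convert at the boundary so that a single
unit system flows through every downstream fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EmissionSpectrum",
    "TitrationSeries",
    "AbsorbanceReading",
    "correct_inner_filter",
    "quench_percent",
    "concentration_from_absorbance",
    "read_titration_table",
    "write_titration_table",
]

#: multiplicative factors mapping a declared concentration unit to mol/L
_CONC_FACTORS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single fluorescence emission scan at fixed temperature.

    Parameters
    ----------
    wavelengths : array-like
        Emission wavelengths in nm, strictly increasing.
    intensities : array-like
        Fluorescence intensity in arbitrary units, finite and non-negative.
    temperature : float
        Sample temperature in K.
    excitation_wavelength : float
        Excitation wavelength in nm.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    temperature: float
    excitation_wavelength: float

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        it = np.asarray(self.intensities, dtype=float)
        if wl.ndim != 1 or it.ndim != 1 or wl.size != it.size:
            raise ValueError("wavelengths and intensities must be 1-D of equal length")
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(it)) or np.any(it < 0):
            raise ValueError("intensities must be finite and non-negative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", it)

    def intensity_at(self, wavelength: float, window: float = 0.0) -> float:
        """Intensity at ``wavelength`` nm, optionally averaged over ±``window`` nm.

        With ``window == 0`` the nearest sampled point is read; otherwise the
        mean over all samples within the window is returned.
        """
        if window > 0:
            mask = np.abs(self.wavelengths - wavelength) <= window
            if not np.any(mask):
                raise ValueError(f"no samples within {window} nm of {wavelength} nm")
            return float(np.mean(self.intensities[mask]))
        idx = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        return float(self.intensities[idx])


@dataclass(frozen=True)
class AbsorbanceReading:
    """An absorbance measurement with its Beer-Lambert calibration."""

    absorbance: float
    epsilon: float  # molar extinction coefficient, M^-1 cm^-1
    path_length: float = 1.0  # cm

    def __post_init__(self) -> None:
        if self.absorbance < 0 or self.epsilon < 0 or self.path_length < 0:
            raise ValueError("absorbance, epsilon and path_length must be non-negative")


@dataclass(frozen=True)
class TitrationSeries:
    """One fluorescence titration at fixed protein concentration and temperature.

    ``intensity`` holds the analysis-wavelength fluorescence F at each total
    ligand concentration; the entry at ``ligand_total == 0`` is F0.
    ``absorbance_ex``/``absorbance_em`` optionally hold the excitation/emission
    absorbances used for the inner-filter correction;
    ``inner_filter_applied`` records whether intensities were already corrected.
    """

    protein_conc: float  # mol/L
    temperature: float  # K
    ligand_total: np.ndarray  # mol/L, non-decreasing
    intensity: np.ndarray  # fluorescence units, > 0
    absorbance_ex: np.ndarray | None = None
    absorbance_em: np.ndarray | None = None
    inner_filter_applied: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        lt = np.asarray(self.ligand_total, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        if lt.ndim != 1 or it.ndim != 1 or lt.size != it.size:
            raise ValueError("ligand_total and intensity must be 1-D of equal length")
        if np.any(np.diff(lt) < 0):
            raise ValueError("ligand_total must be non-decreasing")
        if np.any(lt < 0):
            raise ValueError("ligand_total must be non-negative")
        if not np.all(it > 0):
            raise ValueError("intensity must be strictly positive")
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        object.__setattr__(self, "ligand_total", lt)
        object.__setattr__(self, "intensity", it)
        for name in ("absorbance_ex", "absorbance_em"):
            a = getattr(self, name)
            if a is not None:
                a = np.asarray(a, dtype=float)
                if a.size != lt.size:
                    raise ValueError(f"{name} must match the titration length")
                if np.any(a < 0):
                    raise ValueError(f"{name} must be non-negative")
                object.__setattr__(self, name, a)

    def __len__(self) -> int:
        return int(self.ligand_total.size)

    @property
    def f0(self) -> float:
        """Unquenched intensity F0, read from the ligand-free point."""
        zeros = np.flatnonzero(self.ligand_total == 0.0)
        if zeros.size == 0:
            raise ValueError("series has no ligand_total == 0 point; F0 is undefined")
        return float(self.intensity[zeros[0]])

    def quench_percents(self) -> np.ndarray:
        """ΔF (%) at every titration point relative to F0."""
        f0 = self.f0
        return np.array([quench_percent(f0, f) for f in self.intensity])

    def with_inner_filter_correction(self) -> "TitrationSeries":
        """Return a copy with intensities inner-filter corrected.

        Requires both absorbance columns; a no-op (same data, flag set) is not
        permitted silently — calling this twice raises.
        """
        if self.inner_filter_applied:
            raise ValueError("inner-filter correction already applied")
        if self.absorbance_ex is None or self.absorbance_em is None:
            raise ValueError("absorbance_ex and absorbance_em are required")
        corrected = correct_inner_filter(self.intensity, self.absorbance_ex, self.absorbance_em)
        return replace(self, intensity=corrected, inner_filter_applied=True)


def correct_inner_filter(f_obs, a_ex, a_em):
    """Inner-filter-effect correction F_corr = F_obs * 10**((A_ex + A_em)/2).

    Accepts scalars or arrays (broadcast). The correction is monotone
    increasing in each absorbance and is the identity iff A_ex + A_em == 0.
    """
    f_obs = np.asarray(f_obs, dtype=float)
    a_ex = np.asarray(a_ex, dtype=float)
    a_em = np.asarray(a_em, dtype=float)
    if np.any(a_ex < 0) or np.any(a_em < 0):
        raise ValueError("absorbances must be non-negative")
    if not np.all(np.isfinite(f_obs)):
        raise ValueError("f_obs must be finite")
    out = f_obs * 10.0 ** ((a_ex + a_em) / 2.0)
    return float(out) if out.ndim == 0 else out


def quench_percent(f0: float, f: float) -> float:
    """Fluorescence quenching percentage ΔF = |F − F0| / F0 · 100."""
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    return abs(f - f0) / f0 * 100.0


def concentration_from_absorbance(reading: AbsorbanceReading) -> float:
    """Beer-Lambert concentration c = A / (ε · l) in mol/L."""
    if reading.epsilon == 0 or reading.path_length == 0:
        raise ValueError("epsilon and path_length must be non-zero")
    return reading.absorbance / (reading.epsilon * reading.path_length)


_DEFAULT_COLUMNS = {
    "ligand_total": "ligand_total",
    "intensity": "intensity",
    "a_ex": "a_ex",
    "a_em": "a_em",
    "added_volume": "added_volume",
}


def _parse_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_titration_table(
    path,
    dialect: Mapping[str, str] | None = None,
    *,
    apply_inner_filter: bool = True,
    correct_dilution: bool = False,
    metadata: Mapping[str, float] | None = None,
) -> TitrationSeries:
    """Read a titration CSV into a validated :class:`TitrationSeries`.

    The file carries ``#``-prefixed header lines ``protein_conc=…``,
    ``temperature=…`` and optionally ``units=…`` (concentration unit of both
    the ligand column and ``protein_conc``; default M). ``dialect`` renames
    columns, e.g. ``{"ligand_total": "piperine_uM"}``, and may itself carry a
    ``"units"`` entry overriding the header. ``metadata`` supplies or overrides
    ``protein_conc``/``temperature`` when the file lacks them.

    When both absorbance columns are present and ``apply_inner_filter`` is
    true, the inner-filter correction is applied once here, before any fit.
    ``correct_dilution`` rescales intensities by ``(V0 + v_added)/V0`` using a
    cumulative ``added_volume`` column and an ``initial_volume`` header entry
    (default off: small-aliquot titrations are conventionally left
    uncorrected).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _parse_header(path)
    if metadata:
        meta.update({k: str(v) for k, v in metadata.items()})
    cols = dict(_DEFAULT_COLUMNS)
    units = meta.get("units", "M")
    if dialect:
        units = dialect.get("units", units)
        cols.update({k: v for k, v in dialect.items() if k in cols})
    if units not in _CONC_FACTORS:
        raise ValueError(f"unknown concentration unit {units!r}; use one of {sorted(_CONC_FACTORS)}")
    factor = _CONC_FACTORS[units]

    frame = pd.read_csv(path, comment="#")
    for required in ("ligand_total", "intensity"):
        if cols[required] not in frame.columns:
            raise ValueError(f"missing required column {cols[required]!r} in {path.name}")
    for required in ("protein_conc", "temperature"):
        if required not in meta:
            raise ValueError(f"missing metadata {required!r} (header comment or `metadata=`)")

    ligand = frame[cols["ligand_total"]].to_numpy(dtype=float) * factor
    intensity = frame[cols["intensity"]].to_numpy(dtype=float)
    a_ex = frame[cols["a_ex"]].to_numpy(dtype=float) if cols["a_ex"] in frame.columns else None
    a_em = frame[cols["a_em"]].to_numpy(dtype=float) if cols["a_em"] in frame.columns else None

    if correct_dilution:
        if cols["added_volume"] not in frame.columns:
            raise ValueError("dilution correction requested but no added_volume column")
        if "initial_volume" not in meta:
            raise ValueError("dilution correction requires an initial_volume header entry")
        v0 = float(meta["initial_volume"])
        v_add = frame[cols["added_volume"]].to_numpy(dtype=float)
        intensity = intensity * (v0 + v_add) / v0

    series = TitrationSeries(
        protein_conc=float(meta["protein_conc"]) * factor,
        temperature=float(meta["temperature"]),
        ligand_total=ligand,
        intensity=intensity,
        absorbance_ex=a_ex,
        absorbance_em=a_em,
        label=path.stem,
    )
    if apply_inner_filter and a_ex is not None and a_em is not None:
        series = series.with_inner_filter_correction()
    return series


def write_titration_table(series: TitrationSeries, path) -> Path:
    """Write a series back to the CSV dialect of :func:`read_titration_table`.

    Values are written with 17 significant digits so a read/write/read
    round-trip is bit-identical for float64 data. Concentrations are written
    in mol/L (``units=M``).
    """
    path = Path(path)
    lines = [
        f"# protein_conc={series.protein_conc:.17g}",
        f"# temperature={series.temperature:.17g}",
        "# units=M",
    ]
    header = ["ligand_total", "intensity"]
    columns = [series.ligand_total, series.intensity]
    if series.absorbance_ex is not None and series.absorbance_em is not None:
        header += ["a_ex", "a_em"]
        columns += [series.absorbance_ex, series.absorbance_em]
    lines.append(",".join(header))
    for row in zip(*columns):
        lines.append(",".join(f"{v:.17g}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path
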