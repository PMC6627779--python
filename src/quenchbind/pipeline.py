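"""Pipeline orchestration: load → correct → fit → report.

A single config drives the full analysis: Stern-Volmer and double-log fits
per temperature, Van't Hoff thermodynamics over the per-temperature Ka
values, the IDF/Scatchard analysis over titrations at several protein
concentrations, TCSPC lifetime fits with the τ0/τ diagnostic, the quenching
mechanism classification, and docking-score conversions. Stages run only
when their inputs are present; a stage error is recorded and halts only its
dependents. Identical config + inputs yield an identical report up to the
timestamp.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, field_validator

from . import __version__
from .idf import idf_pipeline
from .lifetime import average_lifetime, fit_multiexponential, lifetime_ratio_series, read_decay_table
from .quenching import classify_quenching, double_log_fit, stern_volmer_fit
from .thermo import kb_from_score, thermo_report, vant_hoff_fit
from .titration import read_titration_table

__all__ = ["PipelineOptions", "PipelineConfig", "AnalysisReport", "run_pipeline", "report_schema"]


class PipelineOptions(BaseModel):
    bracket_denominator: Literal["F", "F0"] = "F"
    n_levels: int = 10
    trim: float = 0.05
    ratio_threshold: float = 0.05
    components: int = 2
    kb_temperature: float = 300.0
    scatchard_r2_threshold: float = 0.95
    tau0: Optional[float] = None  # ns; defaults to the first trace's tau_avg


class PipelineConfig(BaseModel):
    """Inputs for :func:`run_pipeline`.

    ``binding_series``: titration CSVs at one protein concentration, one per
    temperature (drives SV, double-log, Van't Hoff). ``idf_series``:
    titration CSVs at distinct protein concentrations, same temperature
    (drives IDF/Scatchard). ``decay_traces``: TCSPC CSVs ordered by quencher
    concentration. ``docking_scores_kcal``: energy scores to convert to Kb.
    """

    binding_series: list[Path] = Field(default_factory=list)
    idf_series: list[Path] = Field(default_factory=list)
    decay_traces: list[Path] = Field(default_factory=list)
    docking_scores_kcal: list[float] = Field(default_factory=list)
    options: PipelineOptions = Field(default_factory=PipelineOptions)
    output_dir: Optional[Path] = None
    seed: int = 0

    @field_validator("binding_series", "idf_series", "decay_traces")
    @classmethod
    def _files_exist(cls, paths: list[Path]) -> list[Path]:
        for p in paths:
            if not Path(p).exists():
                raise ValueError(f"input file does not exist: {p}")
        return paths

    def model_post_init(self, __context) -> None:
        if not (self.binding_series or self.idf_series or self.decay_traces or self.docking_scores_kcal):
            raise ValueError("config contains no analysis block")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = Path(path).parent
        for key in ("binding_series", "idf_series", "decay_traces"):
            if key in raw:
                raw[key] = [str((base / p)) if not Path(p).is_absolute() else p for p in raw[key]]
        return cls.model_validate(raw)


_UNITS = {
    "k_sv": "M^-1",
    "k_a": "M^-1",
    "k_b": "M^-1",
    "n_sites": "dimensionless",
    "temperature": "K",
    "delta_h": "J/mol",
    "delta_s": "J/(mol K)",
    "delta_g": "J/mol",
    "t_delta_s": "J/mol",
    "lifetimes": "ns",
    "tau_avg": "ns",
    "tau0": "ns",
    "delta_f_level": "percent",
    "ligand_free": "mol/L",
    "sigma_nu": "dimensionless",
    "score": "kcal/mol",
}


class AnalysisReport(BaseModel):
    """Machine-readable result of one pipeline run.

    ``units`` maps every numeric field name appearing in the sections to its
    unit string; ``provenance`` carries the config hash, package version and
    timestamp (the single non-deterministic field).
    """

    stern_volmer: list[dict] = Field(default_factory=list)
    double_log: list[dict] = Field(default_factory=list)
    vant_hoff: Optional[dict] = None
    thermodynamics: Optional[dict] = None
    quenching_verdict: Optional[dict] = None
    idf: Optional[dict] = None
    lifetime: Optional[dict] = None
    docking: list[dict] = Field(default_factory=list)
    units: dict[str, str] = Field(default_factory=lambda: dict(_UNITS))
    warnings: list[str] = Field(default_factory=list)
    errors: dict[str, str] = Field(default_factory=dict)
    provenance: dict = Field(default_factory=dict)

    def to_json(self, strip_timestamp: bool = False) -> str:
        data = self.model_dump(mode="json")
        if strip_timestamp:
            data.get("provenance", {}).pop("timestamp", None)
        return json.dumps(data, indent=2, sort_keys=True)


def report_schema() -> dict:
    """The JSON schema the report validates against."""
    return AnalysisReport.model_json_schema()


def _config_hash(config: PipelineConfig) -> str:
    blob = config.model_dump_json(exclude={"output_dir"}).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute every stage whose inputs are present and assemble the report."""
    report = AnalysisReport()
    report.provenance = {
        "config_hash": _config_hash(config),
        "package_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    opts = config.options

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        sv_fits = []
        dl_fits = []
        if config.binding_series:
            try:
                series = [read_titration_table(p) for p in config.binding_series]
            except Exception as exc:
                report.errors["load_binding"] = str(exc)
                series = []
            for s in series:
                try:
                    sv_fits.append(stern_volmer_fit(s))
                except Exception as exc:
                    report.errors[f"stern_volmer[{s.label}]"] = str(exc)
                try:
                    dl_fits.append(double_log_fit(s, bracket_denominator=opts.bracket_denominator))
                except Exception as exc:
                    report.errors[f"double_log[{s.label}]"] = str(exc)
            sv_fits.sort(key=lambda f: f.temperature)
            dl_fits.sort(key=lambda f: f.temperature)
            report.stern_volmer = [vars(f) for f in sv_fits]
            report.double_log = [vars(f) for f in dl_fits]

            temps = [f.temperature for f in dl_fits]
            if len(set(temps)) >= 2:
                try:
                    vh = vant_hoff_fit(temps, [f.k_a for f in dl_fits])
                    report.vant_hoff = vars(vh)
                    tr = thermo_report(vh, temps)
                    report.thermodynamics = {
                        "records": [vars(r) for r in tr.records],
                        "force_label": tr.force_label,
                    }
                except Exception as exc:
                    report.errors["vant_hoff"] = str(exc)

        lifetime_fits = []
        ratios: list[float] = []
        if config.decay_traces:
            for p in config.decay_traces:
                try:
                    trace = read_decay_table(p)
                    lifetime_fits.append(fit_multiexponential(trace, n_components=opts.components))
                except Exception as exc:
                    report.errors[f"lifetime[{Path(p).name}]"] = str(exc)
            if lifetime_fits:
                tau0 = opts.tau0 if opts.tau0 is not None else lifetime_fits[0].tau_avg
                ratios = lifetime_ratio_series(tau0, lifetime_fits)
                report.lifetime = {
                    "tau0": tau0,
                    "fits": [
                        {
                            "lifetimes": list(f.lifetimes),
                            "amplitudes": list(f.amplitudes),
                            "baseline": f.baseline,
                            "chi_squared_reduced": f.chi_squared_reduced,
                            "tau_avg": f.tau_avg,
                        }
                        for f in lifetime_fits
                    ],
                    "tau0_over_tau": ratios,
                }

        if sv_fits:
            verdict = classify_quenching(sv_fits, ratios, ratio_threshold=opts.ratio_threshold)
            report.quenching_verdict = {
                "mechanism": verdict.mechanism.value,
                "ksv_trend": verdict.ksv_trend,
                "mean_lifetime_ratio_deviation": verdict.mean_lifetime_ratio_deviation,
            }

        if config.idf_series:
            try:
                idf_input = [read_titration_table(p) for p in config.idf_series]
                points, fit = idf_pipeline(
                    idf_input,
                    n_levels=opts.n_levels,
                    trim=opts.trim,
                    r2_threshold=opts.scatchard_r2_threshold,
                )
                report.idf = {
                    "points": [vars(p) for p in points],
                    "k_b": fit.k_b,
                    "n_sites": fit.n_sites,
                    "k_b_stderr": fit.k_b_stderr,
                    "n_sites_stderr": fit.n_sites_stderr,
                    "r_squared": fit.r_squared,
                    "cooperativity_flag": fit.cooperativity_flag.value,
                }
            except Exception as exc:
                report.errors["idf"] = str(exc)

        for score in config.docking_scores_kcal:
            report.docking.append(
                {
                    "score": score,
                    "temperature": opts.kb_temperature,
                    "k_b": kb_from_score(score, opts.kb_temperature),
                }
            )

        report.warnings = sorted({str(w.message) for w in caught})

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
    return report
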