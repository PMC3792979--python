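"""End-to-end orchestration: quench -> bind -> thermo -> fret -> conf -> displace.

A run is driven by a plain YAML config (see :data:`DEFAULT_CONSTANTS` for the
constants block defaults, which match the reference albumin system).  Each
stage reads the CSV schemas of :mod:`ligandbind.spectra`, writes a tidy
results CSV into the output directory, and contributes to a single summary
mapping that is also written as ``summary.csv`` and a human-readable
``report.txt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import binding, conformation, displacement, fret, quenching, spectra
from .spectra import to_kelvin

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline",
           "analyze_quench_series", "analyze_binding_series",
           "DEFAULT_CONSTANTS"]

log = logging.getLogger("ligandbind")

DEFAULT_CONSTANTS: dict[str, float] = {
    "tau0_s": quenching.TAU0_HSA,
    "kappa2": fret.KAPPA2_ISOTROPIC,
    "refractive_index": fret.REFRACTIVE_INDEX_WATER,
    "Q_D": fret.QD_HSA,
    "n_residues": conformation.HSA_N_RESIDUES,
    "gas_constant": spectra.GAS_CONSTANT,
}

DEFAULT_MODES: dict[str, Any] = {
    "paper_mode": False,       # kelvin offset +273 instead of +273.15
    "correction": "pair",      # inner-filter mode: "pair" or "none"
    "r2_min": 0.995,
    "displacement_threshold": 50.0,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    stages: dict[str, dict[str, Any]]
    constants: dict[str, float] = field(default_factory=dict)
    modes: dict[str, Any] = field(default_factory=dict)
    output_dir: Path = Path("ligandbind_out")
    seed: int = 0

    def __post_init__(self) -> None:
        self.constants = {**DEFAULT_CONSTANTS, **self.constants}
        self.modes = {**DEFAULT_MODES, **self.modes}
        self.output_dir = Path(self.output_dir)
        for name, val in self.constants.items():
            if not (isinstance(val, (int, float)) and val > 0):
                raise ValueError(f"constant {name!r} must be a positive number")
        for stage, params in self.stages.items():
            for key, value in (params or {}).items():
                if key.endswith("_csv") and not Path(value).exists():
                    raise FileNotFoundError(
                        f"stage {stage!r}: input file not found: {value}")
                if key.endswith("_csvs"):
                    for p in value:
                        if not Path(p).exists():
                            raise FileNotFoundError(
                                f"stage {stage!r}: input file not found: {p}")


def load_config(path) -> RunConfig:
    """Parse a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(
        stages=raw.get("stages", {}),
        constants=raw.get("constants", {}),
        modes=raw.get("modes", {}),
        output_dir=raw.get("output_dir", "ligandbind_out"),
        seed=int(raw.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# Stage helpers (library-level, also used by the CLI subcommands)
# ---------------------------------------------------------------------------

def analyze_quench_series(series: spectra.TitrationSeries,
                          tau0: float = quenching.TAU0_HSA,
                          r2_min: float = 0.995,
                          correction: str = "pair",
                          reference_wavelength: float | None = None
                          ) -> quenching.SternVolmerResult:
    """Stern-Volmer analysis of one titration series."""
    points = quenching.quench_points_from_series(
        series, reference_wavelength=reference_wavelength, correction=correction)
    return quenching.stern_volmer_fit(points, tau0=tau0, r2_min=r2_min)


def analyze_binding_series(series: spectra.TitrationSeries,
                           correction: str = "pair",
                           reference_wavelength: float | None = None
                           ) -> binding.BindingFit:
    """Double-log binding fit (K_a, n) of one titration series."""
    points = quenching.quench_points_from_series(
        series, reference_wavelength=reference_wavelength, correction=correction)
    return binding.fit_binding_isotherm(series, [p.F for p in points])


def _read_all_series(path) -> dict[str, spectra.TitrationSeries]:
    ids = pd.read_csv(path, usecols=["series_id"])["series_id"].unique()
    return {str(sid): spectra.read_series(path, series_id=sid) for sid in ids}


def _markers_from_csv(path) -> list[displacement.DisplacementSeries]:
    df = pd.read_csv(path)
    needed = {"marker", "site", "ratio", "signal"}
    if not needed <= set(df.columns):
        raise spectra.ParseError(
            f"{path}: marker CSV needs columns {sorted(needed)}")
    out = []
    for (marker, site), grp in df.groupby(["marker", "site"]):
        grp = grp.sort_values("ratio")
        out.append(displacement.DisplacementSeries(
            marker=str(marker), site=str(site),
            signal_wavelength=float(grp["wavelength_nm"].iloc[0])
            if "wavelength_nm" in grp.columns else float("nan"),
            molar_ratios=grp["ratio"].to_numpy(dtype=float),
            signals=grp["signal"].to_numpy(dtype=float),
        ))
    return out


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages in dependency order.

    Returns the summary mapping; writes per-stage CSVs, ``summary.csv`` and
    ``report.txt`` under ``config.output_dir``.  A stage failure raises
    :class:`PipelineError` naming the stage; outputs of completed stages are
    preserved.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    c, m = config.constants, config.modes
    summary: dict[str, Any] = {}
    order = ["quench", "bind", "fret", "sync", "conf3d", "melt", "displace"]
    series_cache: dict[str, spectra.TitrationSeries] | None = None

    for stage in order:
        if stage not in config.stages:
            continue
        params = config.stages[stage] or {}
        log.info("stage %s: starting", stage)
        try:
            if stage == "quench":
                series_cache = _read_all_series(params["series_csv"])
                rows = []
                by_temp = {}
                for sid, series in series_cache.items():
                    res = analyze_quench_series(
                        series, tau0=c["tau0_s"], r2_min=m["r2_min"],
                        correction=m["correction"])
                    by_temp[series.temperature] = res
                    rows.append({
                        "series_id": sid, "temperature_C": series.temperature,
                        "K_SV": res.K_SV, "intercept": res.intercept,
                        "r2": res.r_squared, "k_q": res.k_q,
                        "n_points_retained": res.n_points,
                    })
                pd.DataFrame(rows).sort_values("temperature_C").to_csv(
                    out / "quench_results.csv", index=False)
                summary["K_SV_by_T"] = {r["temperature_C"]: r["K_SV"] for r in rows}
                summary["k_q_by_T"] = {r["temperature_C"]: r["k_q"] for r in rows}
                if len(by_temp) >= 2:
                    cls = quenching.classify_quenching(by_temp)
                    summary["quenching_mechanism"] = cls.label
                    summary["kq_above_diffusion_limit"] = cls.above_diffusion_limit

            elif stage == "bind":
                if series_cache is None:
                    series_cache = _read_all_series(params["series_csv"])
                rows = []
                k_by_t = {}
                for sid, series in series_cache.items():
                    fit = analyze_binding_series(series, correction=m["correction"])
                    k_by_t[series.temperature] = fit.K_a
                    rows.append({
                        "series_id": sid, "temperature_C": series.temperature,
                        "K_a": fit.K_a, "n": fit.n, "r2": fit.r_squared,
                        "points_used": fit.points_used,
                    })
                pd.DataFrame(rows).sort_values("temperature_C").to_csv(
                    out / "binding_results.csv", index=False)
                summary["K_a_by_T"] = {r["temperature_C"]: r["K_a"] for r in rows}
                summary["n_by_T"] = {r["temperature_C"]: r["n"] for r in rows}
                if len(k_by_t) >= 2:
                    thermo = binding.vant_hoff_fit(
                        {to_kelvin(t, paper_mode=m["paper_mode"]): k
                         for t, k in k_by_t.items()},
                        gas_constant=c["gas_constant"])
                    summary["delta_H_kJ_mol"] = thermo.delta_H
                    summary["delta_S_J_mol_K"] = thermo.delta_S
                    summary["delta_G_kJ_mol_by_T_K"] = dict(thermo.delta_G_by_T)
                    pd.DataFrame({
                        "T_K": list(thermo.delta_G_by_T),
                        "delta_G_kJ": list(thermo.delta_G_by_T.values()),
                        "delta_H_kJ": thermo.delta_H,
                        "delta_S_J": thermo.delta_S,
                    }).to_csv(out / "thermodynamics.csv", index=False)

            elif stage == "fret":
                donor = _single_spectrum(params["donor_csv"])
                acceptor = _single_spectrum(params["acceptor_csv"])
                eps = fret.epsilon_from_absorbance(
                    acceptor, path_cm=params.get("path_cm"),
                    conc_M=params.get("conc_M"))
                res = fret.fret_analysis(
                    donor, eps, float(params["f_ratio"]),
                    kappa2=c["kappa2"], refractive_index=c["refractive_index"],
                    Q_D=c["Q_D"])
                pd.DataFrame([{
                    "J_M_cm_nm4": res.J_nm4, "J_M_cm3": res.J_cm3,
                    "E": res.E, "R0_nm": res.R0, "r_nm": res.r,
                    **validity_cols(res),
                }]).to_csv(out / "fret_results.csv", index=False)
                summary["fret"] = {
                    "J_M_cm3": res.J_cm3, "E": res.E,
                    "R0_nm": res.R0, "r_nm": res.r,
                    **validity_cols(res),
                }

            elif stage == "sync":
                series = spectra.read_series(params["series_csv"])
                peaks, shift = conformation.synchronous_shift(
                    list(series.spectra),
                    delta_lambda=params.get("delta_lambda"))
                pd.DataFrame({
                    "ligand_conc_M": series.ligand_concs,
                    "peak_nm": peaks,
                }).to_csv(out / "sync_results.csv", index=False)
                key = f"sync_shift_nm_dl{params.get('delta_lambda', '')}"
                summary[key] = shift

            elif stage == "conf3d":
                paths = params.get("eem_csvs", [params.get("eem_csv")])
                surfaces = [spectra.read_eem(p) for p in paths]
                rows = []
                for i, surf in enumerate(surfaces):
                    for rec in conformation.find_3d_peaks(surf):
                        rows.append({
                            "surface": i, "label": rec.label,
                            "excitation_nm": rec.excitation,
                            "emission_nm": rec.emission,
                            "intensity": rec.intensity,
                        })
                pd.DataFrame(rows).to_csv(out / "eem_peaks.csv", index=False)
                summary["eem_peaks"] = [
                    r for r in rows if r["label"] in ("peak1", "peak2")]

            elif stage == "melt":
                curves = spectra.read_melt(params["melt_csv"])
                if not {"forward", "reverse"} <= set(curves):
                    raise spectra.ParseError(
                        "melt CSV must contain forward and reverse scans")
                res = conformation.melt_analysis(
                    curves["forward"], curves["reverse"],
                    evaluation_T=params.get("evaluation_T"))
                pd.DataFrame([{
                    "onset_T_C": res.onset_T,
                    "recovery_percent": res.recovery_percent,
                    "signal_at_start": res.signal_at_start,
                    "signal_at_end": res.signal_at_end,
                }]).to_csv(out / "melt_results.csv", index=False)
                summary["melt_onset_T_C"] = res.onset_T
                summary["melt_recovery_percent"] = res.recovery_percent

            elif stage == "displace":
                markers = _markers_from_csv(params["markers_csv"])
                site1 = [s for s in markers if s.site == "I"]
                site2 = [s for s in markers if s.site == "II"]
                verdict = displacement.assign_site(
                    site1, site2,
                    displacement_threshold=float(
                        params.get("threshold", m["displacement_threshold"])))
                pd.DataFrame([
                    {"marker": mk, "site": site, "max_loss_percent": loss}
                    for mk, (site, loss) in verdict.losses.items()
                ]).to_csv(out / "displacement_results.csv", index=False)
                summary["site_verdict"] = verdict.verdict
                summary["displacement_losses"] = {
                    mk: loss for mk, (_, loss) in verdict.losses.items()}
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err
        log.info("stage %s: done", stage)

    _write_summary(summary, out)
    return summary


def _single_spectrum(path) -> spectra.Spectrum:
    """Read a one-spectrum CSV (long format, single titration point)."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns or "value" not in df.columns:
        raise spectra.ParseError(f"{path}: need wavelength_nm and value columns")
    kind = str(df["kind"].iloc[0]) if "kind" in df.columns else "emission"
    return spectra.Spectrum(
        df["wavelength_nm"].to_numpy(dtype=float),
        df["value"].to_numpy(dtype=float), kind=kind)


def validity_cols(res: fret.FretResult) -> dict[str, bool]:
    return {
        "valid_half_to_double": res.valid_half_to_double,
        "valid_2_to_8nm": res.valid_2_to_8nm,
    }


def _flatten(prefix: str, obj: Any, rows: list[tuple[str, Any]]) -> None:
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            _flatten(f"{prefix}.{k}" if prefix else str(k), v, rows)
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            _flatten(f"{prefix}[{i}]", v, rows)
    else:
        rows.append((prefix, obj))


def _write_summary(summary: Mapping[str, Any], out: Path) -> None:
    rows: list[tuple[str, Any]] = []
    _flatten("", summary, rows)
    pd.DataFrame(rows, columns=["key", "value"]).to_csv(
        out / "summary.csv", index=False)
    with open(out / "report.txt", "w") as fh:
        fh.write("ligandbind pipeline summary\n")
        fh.write("=" * 27 + "\n")
        for key, val in rows:
            if isinstance(val, float):
                fh.write(f"{key}: {val:.6g}\n")
            else:
                fh.write(f"{key}: {val}\n")
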