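"""Orchestration of the full analysis and recovery scoring.

Runs the dielectric, band-trend and kinetics stages on a data directory
tree, cross-checks that the three independent crossover estimates
(VFT/Arrhenius intersection, band-trend kink, kinetic-rate kink) agree
within a stated window, and scores recovery against a synthetic-truth
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as skio
from .bands import SegmentedFit, Spectrum, fwhm, fit_bands, segmented_linear_fit
from .dielectric import (LossSpectrum, crossover_temperature,
                         fit_loss_spectrum, fit_tau_arrhenius, fit_vft,
                         glass_transition_temperature, tau_max_from_hn)
from .kinetics import (KineticsTrace, fit_crossover, fit_first_order,
                       linearized_check, make_rate_table)


# ---------------------------------------------------------------------------
# dielectric stage
# ---------------------------------------------------------------------------

@dataclass
class DielectricStageResult:
    Tg: float
    Tc: float
    log10_tau_at_Tc: float
    ea_gamma_kj_mol: float
    relaxation_map: pd.DataFrame
    vft: object
    gamma_arrhenius: object
    warnings: list[str] = field(default_factory=list)


def dielectric_stage(spectra: list[LossSpectrum], *,
                     alpha_regime_min_T: float = 300.0,
                     gamma_max_T: float = 295.0,
                     tau_ref: float = 100.0,
                     max_restarts: int = 5,
                     log10_tau_stderr_max: float = 0.15,
                     rng: int | None = 0) -> DielectricStageResult:
    """HN fits -> relaxation map -> VFT/Arrhenius -> Tg and Tc.

    Standard broadband-dielectric protocol for a system whose secondary
    (gamma) peak leaves the measured window above the glass transition:

    1. Glassy spectra (T < ``alpha_regime_min_T``) are fitted with a
       single HN process, no dc term, and labelled gamma; the gamma
       Arrhenius law and average HN shape/strength come from these.
    2. Supercooled spectra get a free alpha HN process + dc term while
       the gamma contribution is pinned to its glassy-state Arrhenius
       extrapolation — the gamma flank is otherwise scale/time
       degenerate and corrupts the alpha parameters.
       Without glassy spectra the stage falls back to an unconstrained
       two-process fit.

    Map rows enter the temperature-law fits only when the fitted peak
    passed the two-decade window rule and its log10(tau) standard error
    is below ``log10_tau_stderr_max``.  Tc is the VFT/Arrhenius
    intersection bracketed in (Tg+10, Tg+150) K.
    """
    from .dielectric import HNParams

    rows = []
    notes: list[str] = []
    glassy_specs = [s for s in spectra if s.temperature < alpha_regime_min_T]
    melt_specs = [s for s in spectra if s.temperature >= alpha_regime_min_T]

    gamma_shapes, gamma_strengths = [], []
    for i, s in enumerate(glassy_specs):
        try:
            fit = fit_loss_spectrum(s, n_processes=1, with_dc=False,
                                    max_restarts=max_restarts,
                                    rng=None if rng is None else rng + i)
        except (ValueError, RuntimeError) as exc:
            notes.append(f"{s.temperature:.0f} K: fit failed ({exc})")
            continue
        if not fit.success:
            notes.append(f"{s.temperature:.0f} K: poor fit ({fit.message})")
        for p in fit.processes:
            se = fit.stderr.get("p0_log10_tau", np.inf)
            if se > log10_tau_stderr_max:
                notes.append(f"{s.temperature:.0f} K: gamma tau poorly "
                             f"determined (log10 stderr {se:.3g}); excluded")
                continue
            rows.append({"temperature_K": s.temperature, "process": "gamma",
                         "tau_s": tau_max_from_hn(p),
                         "log10_tau_stderr": se})
            gamma_shapes.append((p.shape_sym, p.shape_asym))
            gamma_strengths.append(p.delta_eps)

    gamma_pin = None
    arr_glass = None
    if len(rows) >= 3 and gamma_shapes:
        glass_map = pd.DataFrame(rows)
        arr_glass = fit_tau_arrhenius(glass_map, label="gamma")
        mean_shapes = tuple(np.mean(gamma_shapes, axis=0))
        mean_de = float(np.mean(gamma_strengths))
        conv = tau_max_from_hn(HNParams(1.0, 1.0, *mean_shapes))

        def gamma_pin(T):
            return HNParams(delta_eps=mean_de,
                            tau_hn=float(arr_glass.tau(T)) / conv,
                            shape_sym=mean_shapes[0],
                            shape_asym=mean_shapes[1])

    for i, s in enumerate(melt_specs):
        pinned = None if gamma_pin is None else [gamma_pin(s.temperature)]
        n_proc = 1 if pinned else 2
        try:
            fit = fit_loss_spectrum(s, n_processes=n_proc, with_dc=True,
                                    max_restarts=max_restarts,
                                    fixed_processes=pinned,
                                    rng=None if rng is None else rng + 100 + i)
        except (ValueError, RuntimeError) as exc:
            notes.append(f"{s.temperature:.0f} K: fit failed ({exc})")
            continue
        if not fit.success:
            notes.append(f"{s.temperature:.0f} K: poor fit ({fit.message})")
        for rank, p in enumerate(fit.processes):
            label = ("alpha", "gamma")[rank]
            se = fit.stderr.get(f"p{rank}_log10_tau", np.inf)
            if se > log10_tau_stderr_max:
                notes.append(f"{s.temperature:.0f} K: {label} tau poorly "
                             f"determined (log10 stderr {se:.3g}); excluded")
                continue
            rows.append({"temperature_K": s.temperature, "process": label,
                         "tau_s": tau_max_from_hn(p),
                         "log10_tau_stderr": se})
        for p in fit.refused:
            notes.append(f"{s.temperature:.0f} K: refused process with "
                         f"tau_HN = {p.tau_hn:.3g} s (peak > 2 decades "
                         "outside window)")

    relax_map = pd.DataFrame(rows).sort_values(
        ["process", "temperature_K"]).reset_index(drop=True)

    vft = fit_vft(relax_map, label="alpha")
    gamma_rows = relax_map[(relax_map["process"] == "gamma")
                           & (relax_map["temperature_K"] <= gamma_max_T)]
    arr = (arr_glass if arr_glass is not None else
           fit_tau_arrhenius(gamma_rows.assign(process="gamma"),
                             label="gamma"))
    Tg = glass_transition_temperature(vft, tau_ref=tau_ref)
    Tc, log_tau = crossover_temperature(vft, arr, (Tg + 10.0, Tg + 150.0))
    return DielectricStageResult(Tg=float(Tg), Tc=float(Tc),
                                 log10_tau_at_Tc=float(log_tau),
                                 ea_gamma_kj_mol=float(arr.ea_kj_mol),
                                 relaxation_map=relax_map, vft=vft,
                                 gamma_arrhenius=arr, warnings=notes)


# ---------------------------------------------------------------------------
# band-trend stage
# ---------------------------------------------------------------------------

@dataclass
class BandTrendResult:
    trend: pd.DataFrame                 # temperature_K, position, area, fwhm
    position_fit: SegmentedFit
    area_fit: SegmentedFit
    warnings: list[str] = field(default_factory=list)


def band_trend_stage(spectra: list[Spectrum],
                     window: tuple[float, float] = (785.0, 845.0),
                     n_bands: int = 1,
                     centers_init=None,
                     max_T: float = 410.0,
                     band_index: int = 0,
                     min_points_per_side: int = 3) -> BandTrendResult:
    """Per-temperature Voigt fits -> position/area trends -> kink detection.

    Trend fits are restricted to ``max_T`` (default 410 K) to stay below
    the caramelization regime; the kink is located by the continuous
    two-segment regression with an F-test significance flag.
    """
    rows = []
    notes: list[str] = []
    for s in spectra:
        T = float(s.metadata.get("temperature_K", np.nan))
        if not np.isfinite(T) or T > max_T:
            continue
        fit = fit_bands(s, window=window, n_bands=n_bands,
                        centers_init=centers_init)
        if fit.flags:
            notes.extend(f"{T:.0f} K: {m}" for m in fit.flags)
        b = fit.bands[band_index]
        rows.append({"temperature_K": T, "position_cm1": b.center,
                     "area": b.area, "fwhm_cm1": fwhm(b)})
    trend = pd.DataFrame(rows).sort_values("temperature_K").reset_index(drop=True)
    pos_fit = segmented_linear_fit(trend["temperature_K"],
                                   trend["position_cm1"],
                                   min_points_per_side=min_points_per_side)
    area_fit = segmented_linear_fit(trend["temperature_K"], trend["area"],
                                    min_points_per_side=min_points_per_side)
    return BandTrendResult(trend=trend, position_fit=pos_fit,
                           area_fit=area_fit, warnings=notes)


# ---------------------------------------------------------------------------
# kinetics stage
# ---------------------------------------------------------------------------

@dataclass
class KineticsStageResult:
    rate_table: pd.DataFrame
    crossover: object
    diagnostics: pd.DataFrame           # linearization slope/R2 per T
    warnings: list[str] = field(default_factory=list)


def kinetics_stage(traces: list[KineticsTrace],
                   min_points_per_side: int = 3) -> KineticsStageResult:
    """First-order fits per temperature -> rate table -> crossover fit."""
    fits = {}
    diag_rows = []
    notes: list[str] = []
    for tr in traces:
        fit = fit_first_order(tr)
        if fit.flags:
            notes.extend(f"{tr.temperature:.0f} K: {m}" for m in fit.flags)
        fits[tr.temperature] = fit
        slope, _, r2, n_excl = linearized_check(tr, fit)
        diag_rows.append({"temperature_K": tr.temperature,
                          "lin_slope_per_s": slope, "r_squared": r2,
                          "n_excluded": n_excl})
    rate_table = make_rate_table(fits)
    crossover = fit_crossover(rate_table,
                              min_points_per_side=min_points_per_side)
    if not crossover.success:
        notes.append(crossover.message)
    return KineticsStageResult(rate_table=rate_table, crossover=crossover,
                               diagnostics=pd.DataFrame(diag_rows),
                               warnings=notes)


# ---------------------------------------------------------------------------
# full run + report
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "data": {"dielectric": None, "bands": None, "kinetics": None},
    "dielectric": {"alpha_regime_min_T": 300.0, "gamma_max_T": 295.0,
                   "tau_ref_s": 100.0, "max_restarts": 5},
    "bands": {"window": [785.0, 845.0], "n_bands": 1, "max_T": 410.0},
    "kinetics": {"min_points_per_side": 3},
    "agreement_window_K": 5.0,
    "seed": 0,
}


def load_config(path_or_dict) -> dict:
    import yaml
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full(config) -> dict:
    """Run every available stage and aggregate the headline quantities.

    Returns the analysis report as a JSON-serializable dict.  Missing
    data directories lead to a "partial" status with the corresponding
    fields absent; a stage exception is recorded with the stage name and
    the partial report is retained.
    """
    cfg = load_config(config)
    report: dict = {
        "status": "ok",
        "stage_errors": {},
        "provenance": {"config_hash": _config_hash(cfg),
                       "seed": cfg.get("seed", 0),
                       "versions": _versions()},
    }
    data = cfg.get("data", {})

    ddir = data.get("dielectric")
    if ddir and Path(ddir).is_dir():
        try:
            spectra = skio.read_directory(ddir, skio.read_loss_spectrum)
            dcfg = cfg["dielectric"]
            res = dielectric_stage(
                spectra,
                alpha_regime_min_T=dcfg["alpha_regime_min_T"],
                gamma_max_T=dcfg["gamma_max_T"],
                tau_ref=dcfg["tau_ref_s"],
                max_restarts=dcfg["max_restarts"],
                rng=cfg.get("seed", 0))
            report.update({
                "Tg_K": res.Tg, "Tc_dielectric_K": res.Tc,
                "log10_tau_at_Tc": res.log10_tau_at_Tc,
                "Ea_gamma_kj_mol": res.ea_gamma_kj_mol,
            })
            report["dielectric_warnings"] = res.warnings
        except Exception as exc:
            report["status"] = "partial"
            report["stage_errors"]["dielectric"] = str(exc)
    else:
        report["status"] = "partial"

    bdir = data.get("bands")
    if bdir and Path(bdir).is_dir():
        try:
            spectra = skio.read_directory(bdir, skio.read_spectrum)
            bcfg = cfg["bands"]
            res = band_trend_stage(spectra, window=tuple(bcfg["window"]),
                                   n_bands=bcfg["n_bands"],
                                   max_T=bcfg["max_T"])
            report["band_kinks"] = [{
                "window_cm1": list(bcfg["window"]),
                "breakpoint_K": res.position_fit.breakpoint,
                "significant": res.position_fit.significant,
            }]
        except Exception as exc:
            report["status"] = "partial"
            report["stage_errors"]["bands"] = str(exc)
    else:
        report["status"] = "partial"

    kdir = data.get("kinetics")
    if kdir and Path(kdir).is_dir():
        try:
            traces = skio.read_directory(kdir, skio.read_trace)
            res = kinetics_stage(
                traces,
                min_points_per_side=cfg["kinetics"]["min_points_per_side"])
            report.update({
                "Tc_kinetics_K": res.crossover.Tc,
                "Ea_below_kj_mol": res.crossover.ea_below_kj_mol,
                "Ea_above_kj_mol": res.crossover.ea_above_kj_mol,
                "kinetics_significant": res.crossover.significant,
            })
            report["rate_table"] = res.rate_table.to_dict(orient="records")
        except Exception as exc:
            report["status"] = "partial"
            report["stage_errors"]["kinetics"] = str(exc)
    else:
        report["status"] = "partial"

    # cross-technique coincidence of the crossover estimates
    estimates = [report.get("Tc_dielectric_K")]
    estimates += [k["breakpoint_K"] for k in report.get("band_kinks", [])]
    estimates.append(report.get("Tc_kinetics_K"))
    estimates = [e for e in estimates if e is not None]
    if len(estimates) >= 2:
        spread = max(estimates) - min(estimates)
        report["crossover_estimates_K"] = estimates
        report["crossover_spread_K"] = spread
        report["crossover_coincide"] = bool(
            spread <= 2.0 * cfg["agreement_window_K"])
    if report["stage_errors"] and len(estimates) == 0:
        report["status"] = "failed"
    return report


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"spectrokin": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}


def write_report(report: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, default=float))


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

DEFAULT_TOLERANCES = {
    "Tg_K": {"abs": 2.0},
    "Tc_dielectric_K": {"abs": 3.0},
    "log10_tau_at_Tc": {"abs": 0.3},
    "Ea_gamma_kj_mol": {"rel": 0.05},
    "Tc_kinetics_K": {"abs": 5.0},
    "Ea_below_kj_mol": {"abs": 4.5},
    "Ea_above_kj_mol": {"abs": 7.5},
}


def _flatten_manifest(manifest: dict) -> dict:
    flat = {k: v for k, v in manifest.items() if np.isscalar(v)}
    kin = manifest.get("kinetics", {})
    flat.setdefault("Tc_kinetics_K", kin.get("Tc_K"))
    flat.setdefault("Ea_below_kj_mol", kin.get("Ea_below_kj_mol"))
    flat.setdefault("Ea_above_kj_mol", kin.get("Ea_above_kj_mol"))
    return flat


def score_recovery(report: dict, manifest: dict,
                   tolerances: dict | None = None) -> dict:
    """Element-wise comparison of a report against synthetic truth.

    Every quantity named in ``tolerances`` must exist in both the report
    and the manifest; the overall pass flag is the conjunction of the
    per-quantity flags.  Report quantities without a tolerance entry are
    ignored and listed.
    """
    tolerances = DEFAULT_TOLERANCES if tolerances is None else tolerances
    truth = _flatten_manifest(manifest)
    per_quantity = {}
    for name, tol in tolerances.items():
        if name not in report:
            raise KeyError(f"quantity '{name}' required by the tolerance "
                           "table is absent from the report")
        if name not in truth or truth[name] is None:
            raise KeyError(f"quantity '{name}' absent from the manifest")
        est, tru = float(report[name]), float(truth[name])
        abs_err = abs(est - tru)
        rel_err = abs_err / abs(tru) if tru != 0 else np.inf
        if "abs" in tol:
            ok = abs_err <= tol["abs"]
        else:
            ok = rel_err <= tol["rel"]
        per_quantity[name] = {"truth": tru, "estimate": est,
                              "abs_error": abs_err, "rel_error": rel_err,
                              "pass": bool(ok)}
    ignored = sorted(k for k in report
                     if k.endswith(("_K", "_kj_mol", "_at_Tc"))
                     and k not in tolerances)
    return {"per_quantity": per_quantity,
            "overall_pass": all(q["pass"] for q in per_quantity.values()),
            "ignored_report_quantities": ignored}
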