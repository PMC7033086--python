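"""End-to-end study orchestration: data -> input function -> fits -> boron.

``run_study`` reads one or more subjects' TAC and blood tables, builds the
metabolite-corrected input function, fits all requested graphical models per
VOI, ranks them by goodness of fit, and converts the selected model's Vt
into boron-10 ppm at the requested post-injection times.  Per-VOI fit
failures are recorded as flagged rows and do not abort the remaining VOIs.
``report_tables`` writes the resulting tables as CSV plus a run log and a
JSON manifest with a configuration hash, so a rerun with identical inputs
is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .boron import estimate_tissue_boron
from .graphical import MODELS, GraphicalFit, fit_model, find_t_star
from .input_function import PlasmaInput, build_plasma_input, fit_biexponential
from .model_selection import GofReport, compare_models, gof_report
from .tac_data import (
    BloodSampleSeries,
    StudyConfig,
    TissueTAC,
    ValidationError,
    read_blood_samples,
    read_tac_table,
)

__all__ = ["AnalysisOptions", "VoiResult", "SubjectResult", "StudyReport",
           "run_study", "report_tables"]

logger = logging.getLogger("fbpakin.study")


@dataclass(frozen=True)
class AnalysisOptions:
    """Which models to fit and how t* is chosen per model.

    ``t_star`` maps model -> either a time in minutes or ``"auto"`` (1%
    maximum-relative-error search over frame midpoints).  MA2 defaults to a
    fixed 20 min; the Logan plot and MA1 default to the automatic search.
    """

    models: tuple = MODELS
    t_star: dict = field(default_factory=lambda: {"logan": "auto", "ma1": "auto", "ma2": 20.0})
    max_rel_error: float = 0.01
    boron_times: tuple = (60.0, 120.0)  # min post-injection


@dataclass(frozen=True)
class VoiResult:
    voi_name: str
    fits: dict  # model -> GraphicalFit
    gofs: dict  # model -> GofReport
    best_model: str | None
    errors: dict  # model -> error message for failed fits


@dataclass(frozen=True)
class SubjectResult:
    subject_id: str
    plasma: PlasmaInput
    vois: list  # VoiResult
    whole_blood_input: PlasmaInput | None


@dataclass(frozen=True)
class StudyReport:
    subjects: list  # SubjectResult
    options: AnalysisOptions
    config: StudyConfig
    vt_table: pd.DataFrame
    gof_table: pd.DataFrame
    boron_table: pd.DataFrame
    log_lines: tuple


def _fit_voi(tac: TissueTAC, plasma: PlasmaInput, options: AnalysisOptions, log) -> VoiResult:
    fits, gofs, errors = {}, {}, {}
    for model in options.models:
        setting = options.t_star.get(model, "auto")
        try:
            if setting == "auto":
                if model == "ma2":
                    raise ValidationError("MA2 uses a fixed t*, not the auto search")
                res = find_t_star(tac, plasma, model, options.max_rel_error)
                fit = res.fit
                if not res.converged:
                    log(f"{tac.voi_name}/{model}: t* search did not converge; "
                        f"using latest feasible t*={res.t_star:.2f} min")
            else:
                fit = fit_model(model, tac, plasma, float(setting))
            for w in fit.warnings:
                log(f"{tac.voi_name}/{model}: warning {w}")
            if not fit.is_reliable:
                log(f"{tac.voi_name}/{model}: rejected by quality control "
                    f"(Vt={fit.vt:.3g}, SE={fit.vt_se:.3g})")
            fits[model] = fit
            gofs[model] = gof_report(fit)
            log(f"{tac.voi_name}/{model}: t*={fit.t_star:.2f} min, "
                f"n={fit.n_points_used}, Vt={fit.vt:.4f}")
        except (ValidationError, np.linalg.LinAlgError) as exc:
            errors[model] = str(exc)
            log(f"{tac.voi_name}/{model}: FAILED - {exc}")
    usable = [gofs[m] for m in gofs if fits[m].is_reliable]
    best = compare_models(usable).best_model if usable else None
    return VoiResult(tac.voi_name, fits, gofs, best, errors)


def _load_subject(subject, index: int):
    """Accept (tac_path, blood_path) pairs or in-memory (dict, BloodSampleSeries)."""
    tac_src, blood_src = subject
    sid = f"subject{index + 1}"
    if isinstance(tac_src, dict):
        tacs = tac_src
    else:
        sid = os.path.splitext(os.path.basename(str(tac_src)))[0]
        tacs = read_tac_table(tac_src)
    if isinstance(blood_src, BloodSampleSeries):
        blood = blood_src
    else:
        if not os.path.exists(blood_src):
            raise FileNotFoundError(f"blood sample file not found: {blood_src}")
        blood = read_blood_samples(blood_src)
    return sid, tacs, blood


def run_study(
    subjects,
    config: StudyConfig | None = None,
    options: AnalysisOptions | None = None,
) -> StudyReport:
    """Analyze one or more subjects and aggregate across them.

    ``subjects`` is a list of ``(tac_source, blood_source)`` pairs, each
    either file paths or in-memory objects (a VOI->TissueTAC dict and a
    BloodSampleSeries).  Aggregation across subjects is the unweighted mean
    with the sample (n-1) standard deviation.
    """
    config = config or StudyConfig()
    options = options or AnalysisOptions()
    if not subjects:
        raise ValidationError("run_study needs at least one subject")
    lines: list[str] = []

    def log(msg: str):
        lines.append(msg)
        logger.info(msg)

    results: list[SubjectResult] = []
    for i, subject in enumerate(subjects):
        sid, tacs, blood = _load_subject(subject, i)
        plasma = build_plasma_input(blood, config)
        log(f"{sid}: input function fit a1={plasma.biexp.a1:.3f} l1={plasma.biexp.lambda1:.4f} "
            f"a2={plasma.biexp.a2:.3f} l2={plasma.biexp.lambda2:.5f}")
        # whole-blood curve for the whole-blood boron row (V = 1, no
        # metabolite correction)
        try:
            wb_series = BloodSampleSeries(
                blood.sample_times, blood.whole_blood, blood.whole_blood)
            wb_input = PlasmaInput(
                wb_series,
                fit_biexponential(wb_series.sample_times, wb_series.plasma),
            )
        except (ValidationError, Exception) as exc:  # noqa: BLE001 - degrade gracefully
            wb_input = None
            log(f"{sid}: whole-blood extrapolation unavailable ({exc})")
        vois = [_fit_voi(tac, plasma, options, log) for tac in tacs.values()]
        results.append(SubjectResult(sid, plasma, vois, wb_input))

    vt_table = _aggregate_vt(results)
    gof_table = _aggregate_gof(results)
    boron_table = _boron_table(results, config, options, log)
    return StudyReport(results, options, config, vt_table, gof_table, boron_table,
                       tuple(lines))


def _aggregate_vt(results: list[SubjectResult]) -> pd.DataFrame:
    """Mean +- sample SD of Vt per (voi, model); QC-rejected fits are excluded."""
    rows = []
    for sub in results:
        for voi in sub.vois:
            for model, fit in voi.fits.items():
                vt = fit.vt if fit.is_reliable else np.nan
                rows.append((sub.subject_id, voi.voi_name, model, vt, fit.t_star,
                             voi.best_model == model))
            for model, msg in voi.errors.items():
                rows.append((sub.subject_id, voi.voi_name, model, np.nan, np.nan, False))
    per_fit = pd.DataFrame(
        rows, columns=["subject", "voi", "model", "Vt", "t_star", "selected"])
    agg = (
        per_fit.groupby(["voi", "model"], sort=False)
        .agg(Vt_mean=("Vt", "mean"), Vt_sd=("Vt", lambda s: s.std(ddof=1)),
             t_star_mean=("t_star", "mean"), n_subjects=("Vt", "count"),
             selected=("selected", "any"))
        .reset_index()
    )
    return agg


def _aggregate_gof(results: list[SubjectResult]) -> pd.DataFrame:
    rows = []
    for sub in results:
        for voi in sub.vois:
            for model, g in voi.gofs.items():
                rows.append((sub.subject_id, voi.voi_name, model, g.n, g.p, g.ssr,
                             g.aic, g.chi2_reduced, g.sy_x, g.r2))
    per_fit = pd.DataFrame(
        rows, columns=["subject", "voi", "model", "n", "p", "SSR", "AIC",
                       "chi2_reduced", "Sy.x", "R2"])
    agg = (
        per_fit.groupby(["voi", "model"], sort=False)
        .agg(AIC_mean=("AIC", "mean"), AIC_sd=("AIC", lambda s: s.std(ddof=1)),
             chi2_mean=("chi2_reduced", "mean"), Syx_mean=("Sy.x", "mean"),
             R2_mean=("R2", "mean"))
        .reset_index()
    )
    return agg


def _boron_table(results, config, options, log) -> pd.DataFrame:
    """Boron ppm per VOI (selected model's Vt) plus plasma and whole-blood rows."""
    rows: dict[str, dict] = {}
    counts: dict[str, int] = {}
    for sub in results:
        entries = []
        for voi in sub.vois:
            if voi.best_model is None:
                log(f"{sub.subject_id}/{voi.voi_name}: no successful fit; "
                    "excluded from boron table")
                continue
            entries.append((voi.voi_name, voi.fits[voi.best_model].vt, sub.plasma))
        entries.append(("plasma", 1.0, sub.plasma))
        if sub.whole_blood_input is not None:
            entries.append(("whole_blood", 1.0, sub.whole_blood_input))
        for name, vt, curve in entries:
            row = rows.setdefault(name, {f"H_{int(t)}min": 0.0 for t in options.boron_times})
            counts[name] = counts.get(name, 0) + 1
            for t in options.boron_times:
                est = estimate_tissue_boron(vt, curve, t, config, voi_name=name)
                row[f"H_{int(t)}min"] += est.therapeutic_ppm
    records = []
    for name, row in rows.items():
        rec = {"voi": name}
        for key, total in row.items():
            rec[key] = total / counts[name]
        records.append(rec)
    df = pd.DataFrame(records)
    if not df.empty:
        first = f"H_{int(options.boron_times[0])}min"
        df = df.sort_values(first, ascending=False, kind="mergesort").reset_index(drop=True)
    return df


def _config_hash(config: StudyConfig, options: AnalysisOptions) -> str:
    payload = {
        "config": {k: getattr(config, k) for k in (
            "injected_dose_g", "specific_activity_kBq_mol", "therapeutic_dose_g",
            "mw_boron", "mw_fbpa", "mw_bpa")},
        "metabolite_fractions": list(map(list, config.metabolite_fractions)),
        "models": list(options.models),
        "t_star": {k: str(v) for k, v in options.t_star.items()},
        "max_rel_error": options.max_rel_error,
        "boron_times": list(options.boron_times),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def report_tables(report: StudyReport, out_dir, seed: int | None = None) -> dict:
    """Write vt.csv, gof.csv, boron.csv, run.log and manifest.json; return paths."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "vt": os.path.join(out_dir, "vt.csv"),
        "gof": os.path.join(out_dir, "gof.csv"),
        "boron": os.path.join(out_dir, "boron.csv"),
        "log": os.path.join(out_dir, "run.log"),
        "manifest": os.path.join(out_dir, "manifest.json"),
    }
    report.vt_table.to_csv(paths["vt"], index=False)
    report.gof_table.to_csv(paths["gof"], index=False)
    report.boron_table.to_csv(paths["boron"], index=False)
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(report.log_lines) + "\n")
    manifest = {
        "package": "fbpakin",
        "version": __version__,
        "config_hash": _config_hash(report.config, report.options),
        "seed": seed,
        "n_subjects": len(report.subjects),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
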