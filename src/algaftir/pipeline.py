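"""End-to-end orchestration: preprocess -> features -> fit -> evaluate.

One configured run executes any subset of the three calibration
strategies on an identical preprocessed spectral matrix and emits a
combined comparison table (method x response rows with N, R2, RMSEC,
Q2, RMSECV, RPD, RMSEP) plus per-sample predicted-vs-determined CSVs.

Conventions mirrored from the reference workflow:

* the univariate models use band areas and LOO cross-validation;
* OPLS uses the full fingerprint region on a 2 cm^-1 grid, the union
  of the response-wise outlier lists, and 5-fold cross-validation;
* MCR-ALS decomposes the full calibration matrix (outliers included),
  then calibrates each resolved concentration profile response-wise;
  it gets no external validation by default.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from algaftir import bands as bands_mod
from algaftir import evaluation as ev
from algaftir import mcr_als as mcr_mod
from algaftir import opls as opls_mod
from algaftir import ulra as ulra_mod
from algaftir.preprocess import PreprocessConfig, preprocess_pipeline
from algaftir.spectra_io import (
    CompositionTable,
    SpectrumSet,
    join_xy,
    read_composition,
    read_spectrum_matrix,
    regrid,
)

logger = logging.getLogger("algaftir")

__all__ = ["RunConfig", "RunResult", "run"]

_RESPONSES = {"protein": "protein_pct", "lipid": "lipid_pct", "carbohydrate": "carb_pct"}
_BAND_FOR = {"protein": "protein_band", "lipid": "lipid_band", "carbohydrate": "carb_band"}


@dataclass
class RunConfig:
    """Configuration of a full comparison run.

    Inputs can be given as paths (CSV) or as in-memory objects.  The
    calibration/external split defaults to holding out the species
    named ``external_species`` (or the metadata role column when
    present).
    """

    spectra_path: str | None = None
    composition_path: str | None = None
    references_path: str | None = None
    spectra: SpectrumSet | None = None
    composition: CompositionTable | None = None
    references: SpectrumSet | None = None

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    regrid_spacing: float = 2.0
    methods: tuple = ("ulra", "opls", "mcr")
    external_species: str | None = None
    external_ids: list = field(default_factory=list)
    outliers: dict = field(default_factory=dict)  # response -> list of ids
    opls_components: tuple | str = (2, 2, 1)  # or "auto"
    opls_max_components: tuple = (4, 3, 2)
    mcr: mcr_mod.McrConfig = field(default_factory=mcr_mod.McrConfig)
    seed: int = 0
    out_dir: str | None = None


@dataclass
class RunResult:
    comparison: pd.DataFrame
    reports: list
    predictions: dict  # (method, response) -> DataFrame
    models: dict
    excluded: dict
    extras: dict = field(default_factory=dict)


def _load(cfg: RunConfig):
    spectra = cfg.spectra
    if spectra is None:
        if cfg.spectra_path is None:
            raise ValueError("no spectra given (spectra or spectra_path)")
        spectra = read_spectrum_matrix(cfg.spectra_path, orientation="wide")
    comp = cfg.composition
    if comp is None:
        if cfg.composition_path is None:
            raise ValueError("no composition given")
        comp = read_composition(cfg.composition_path)
    refs = cfg.references
    if refs is None and cfg.references_path is not None:
        refs = read_spectrum_matrix(cfg.references_path, orientation="wide")
    return spectra, comp, refs


def _split_ids(cfg: RunConfig, spectra: SpectrumSet):
    ids = spectra.sample_ids
    meta = spectra.metadata
    if cfg.external_ids:
        ext = [s for s in ids if s in set(cfg.external_ids)]
    elif cfg.external_species is not None and meta is not None and "species" in meta:
        ext = [s for s in ids if meta.loc[s, "species"] == cfg.external_species]
    elif meta is not None and "role" in meta:
        ext = [s for s in ids if meta.loc[s, "role"] == "external"]
    else:
        ext = []
    cal = [s for s in ids if s not in set(ext)]
    if set(cal) & set(ext):
        raise ValueError("calibration and external sets overlap")
    return cal, ext


def _subset(spectra: SpectrumSet, ids):
    idx = [spectra.sample_ids.index(s) for s in ids]
    meta = spectra.metadata.loc[ids] if spectra.metadata is not None else None
    return SpectrumSet(spectra.axis, spectra.intensities[idx], ids, meta)


def _pairs(ids, y, yhat, context):
    return ev.PredictionPairs(list(ids), np.asarray(y, float), np.asarray(yhat, float), context)


def _run_ulra(cfg, band_cal, band_ext, ycal, yext, excluded):
    reports, preds, models = [], {}, {}
    for resp, col in _RESPONSES.items():
        bname = _BAND_FOR[resp]
        x = band_cal[bname].to_numpy()
        y = ycal[col].to_numpy()
        ids = list(band_cal.index)
        policy = ev.OutlierPolicy("explicit_list", list(cfg.outliers.get(resp, [])))
        x2, y2, kept, excl = ev.apply_outlier_policy(x, y, policy, ids)
        excluded[("ulra", resp)] = excl
        model = ulra_mod.fit_ulra(x2, y2, response=resp, band=bname)
        cal = _pairs(kept, y2, ulra_mod.predict_ulra(model, x2), "calibration")
        fit = lambda xt, yt: (lambda xe: ulra_mod.predict_ulra(ulra_mod.fit_ulra(xt.ravel(), yt), np.asarray(xe).ravel()))
        cv = ev.loo_cv(fit, x2.reshape(-1, 1), y2, sample_ids=kept)
        ext = None
        if band_ext is not None and len(band_ext):
            ext = _pairs(
                band_ext.index,
                yext[col].to_numpy(),
                ulra_mod.predict_ulra(model, band_ext[bname].to_numpy()),
                "external",
            )
        rep = ev.evaluate_regression("ULRA", resp, cal, cv, ext)
        rep.extra.update(intercept=model.intercept, slope=model.slope)
        reports.append(rep)
        models[("ulra", resp)] = model
        preds[("ulra", resp)] = _pred_frame(cal, cv, ext)

    # carbohydrate/protein ratio model (chained estimator)
    ratio_excl = sorted(set(cfg.outliers.get("carbohydrate", [])) | set(cfg.outliers.get("protein", [])))
    keep = [s for s in band_cal.index if s not in set(ratio_excl)]
    excluded[("ulra", "carb_protein_ratio")] = [s for s in band_cal.index if s not in keep]
    bt = band_cal.loc[keep]
    yc = ycal.loc[keep]
    x_ratio, zero_den = bands_mod.ratio_feature(bt, "carb_band", "protein_band")
    keep = [s for s in keep if s not in set(zero_den)]
    y_ratio = yc.loc[keep, "carb_pct"] / yc.loc[keep, "protein_pct"]
    ratio_model = ulra_mod.fit_ratio_model(x_ratio.loc[keep], y_ratio)
    cal = _pairs(keep, y_ratio, ulra_mod.predict_ulra(ratio_model, x_ratio.loc[keep]), "calibration")
    fit = lambda xt, yt: (lambda xe: ulra_mod.predict_ulra(ulra_mod.fit_ulra(xt.ravel(), yt), np.asarray(xe).ravel()))
    cv = ev.loo_cv(fit, x_ratio.loc[keep].to_numpy().reshape(-1, 1), y_ratio.to_numpy(), sample_ids=keep)
    ext = None
    if band_ext is not None and len(band_ext):
        xr_ext, _ = bands_mod.ratio_feature(band_ext, "carb_band", "protein_band")
        yr_ext = yext["carb_pct"] / yext["protein_pct"]
        ext = _pairs(xr_ext.index, yr_ext, ulra_mod.predict_ulra(ratio_model, xr_ext), "external")
    rep = ev.evaluate_regression("ULRA", "carb_protein_ratio", cal, cv, ext)
    rep.extra.update(intercept=ratio_model.intercept, slope=ratio_model.slope)
    reports.append(rep)
    models[("ulra", "carb_protein_ratio")] = ratio_model
    preds[("ulra", "carb_protein_ratio")] = _pred_frame(cal, cv, ext)
    return reports, preds, models


def _pred_frame(cal, cv=None, ext=None):
    frames = []
    for pairs in (cal, cv, ext):
        if pairs is None:
            continue
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": pairs.sample_ids,
                    "determined": pairs.y_true,
                    "predicted": pairs.y_pred,
                    "context": pairs.context,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _run_opls(cfg, spec_cal, spec_ext, ycal, yext, excluded):
    union_out = sorted({s for ids in cfg.outliers.values() for s in ids})
    keep = [s for s in spec_cal.sample_ids if s not in set(union_out)]
    excluded[("opls", "all")] = [s for s in spec_cal.sample_ids if s not in keep]
    sub = _subset(spec_cal, keep)
    X = sub.intensities
    Y = ycal.loc[keep].to_numpy()
    resp_names = list(_RESPONSES)

    if cfg.opls_components == "auto":
        (n_pred, n_ox, n_oy), traj = opls_mod.select_components(
            X, Y, *cfg.opls_max_components, k=5, seed=cfg.seed
        )
    else:
        n_pred, n_ox, n_oy = cfg.opls_components
        traj = None
    model = opls_mod.fit_opls(X, Y, n_pred, n_ox, n_oy, response_names=resp_names)
    yhat_cal = opls_mod.predict_opls(model, X)
    cv_pred, q2_pooled = opls_mod.cross_validate_opls(
        X, Y, n_pred, n_ox, n_oy, k=5, seed=cfg.seed
    )
    reports, preds = [], {}
    model_row = ev.EvalReport("OPLS", "(model)", len(keep))
    model_row.extra.update(
        components=f"{n_pred}+{n_ox}+{n_oy}",
        r2x_cum=model.r2x_cum,
        r2y_cum=model.r2y_cum,
        q2_cum=q2_pooled,
    )
    reports.append(model_row)
    yhat_ext = None
    if spec_ext is not None and len(spec_ext):
        yhat_ext = opls_mod.predict_opls(model, spec_ext.intensities)
    for j, resp in enumerate(resp_names):
        col = _RESPONSES[resp]
        cal = _pairs(keep, Y[:, j], yhat_cal[:, j], "calibration")
        cv = _pairs(keep, Y[:, j], cv_pred[:, j], "cross_validation")
        ext = None
        if yhat_ext is not None:
            ext = _pairs(spec_ext.sample_ids, yext[col].to_numpy(), yhat_ext[:, j], "external")
        rep = ev.evaluate_regression("OPLS", resp, cal, cv, ext)
        rep.extra.update(r2y=float(model.r2y_per_response[j]))
        reports.append(rep)
        preds[("opls", resp)] = _pred_frame(cal, cv, ext)
    corr, _flags = opls_mod.loading_correlations(model, X)
    extras = {
        "loading_correlations": pd.DataFrame(
            corr.T, index=sub.axis, columns=[f"component_{a+1}" for a in range(n_pred)]
        ),
        "selection_trajectory": traj,
        "scores": pd.DataFrame(
            model.T, index=keep, columns=[f"t{a+1}" for a in range(n_pred)]
        ),
    }
    return reports, preds, {("opls", "joint"): model}, extras


def _run_mcr(cfg, spec_cal, refs_pp, ycal, excluded):
    if refs_pp is None:
        raise ValueError("MCR requires reference spectra")
    D = spec_cal.intensities
    init = np.clip(refs_pp.intensities, 0.0, None)
    result = mcr_mod.mcr_als_fit(
        D, init, cfg.mcr, axis=spec_cal.axis,
        component_names=refs_pp.sample_ids,
    )
    reports, preds = [], {}
    model_row = ev.EvalReport("MCR-ALS", "(model)", len(spec_cal))
    model_row.extra.update(
        lof_pca=result.lof_pca, lof_exp=result.lof_exp, r2_pct=result.r2,
        iterations=result.iterations_run, converged=result.converged,
    )
    reports.append(model_row)
    comp_of = {"protein": "protein", "lipid": "lipid", "carbohydrate": "carbohydrate"}
    for resp, comp_name in comp_of.items():
        col = _RESPONSES[resp]
        k = result.component_names.index(comp_name)
        c_all = result.C[:, k]
        ids = spec_cal.sample_ids
        policy = ev.OutlierPolicy("explicit_list", list(cfg.outliers.get(resp, [])))
        c2, y2, kept, excl = ev.apply_outlier_policy(
            c_all, ycal[col].to_numpy(), policy, ids
        )
        excluded[("mcr", resp)] = excl
        model, rep = mcr_mod.calibrate_mcr_concentrations(c2, y2, response=resp, sample_ids=kept)
        reports.append(rep)
        cal = _pairs(kept, y2, ulra_mod.predict_ulra(model, c2), "calibration")
        preds[("mcr", resp)] = _pred_frame(cal)
    return reports, preds, {("mcr", "decomposition"): result}


def run(cfg: RunConfig) -> RunResult:
    """Execute the configured comparison; see module docstring."""
    spectra, comp, refs = _load(cfg)
    logger.info("loaded %d spectra, %d composition rows", len(spectra), len(comp))

    if cfg.regrid_spacing:
        spectra = regrid(spectra, cfg.regrid_spacing)
        if refs is not None:
            refs = regrid(refs, cfg.regrid_spacing)
    spectra = preprocess_pipeline(spectra, cfg.preprocess)
    refs_pp = preprocess_pipeline(refs, cfg.preprocess) if refs is not None else None
    logger.info("preprocessed onto %d-point axis [%g, %g]",
                spectra.axis.size, spectra.axis[0], spectra.axis[-1])

    cal_ids, ext_ids = _split_ids(cfg, spectra)
    paired = join_xy(spectra, comp)
    cal_ids = [s for s in cal_ids if s in set(paired.sample_ids)]
    ext_ids = [s for s in ext_ids if s in set(paired.sample_ids)]
    spec_cal = _subset(paired.spectra, cal_ids)
    spec_ext = _subset(paired.spectra, ext_ids) if ext_ids else None
    ycal = paired.composition.values().loc[cal_ids]
    yext = paired.composition.values().loc[ext_ids] if ext_ids else None
    logger.info("calibration n=%d, external n=%d", len(cal_ids), len(ext_ids))

    reports, predictions, models, excluded, extras = [], {}, {}, {}, {}
    band_cal = band_ext = None
    if "ulra" in cfg.methods:
        band_cal = bands_mod.band_table(spec_cal)
        band_ext = bands_mod.band_table(spec_ext) if spec_ext is not None else None
        r, p, m = _run_ulra(cfg, band_cal, band_ext, ycal, yext, excluded)
        reports += r
        predictions.update(p)
        models.update(m)
        logger.info("ULRA done (%d reports)", len(r))
    if "opls" in cfg.methods:
        r, p, m, ex = _run_opls(cfg, spec_cal, spec_ext, ycal, yext, excluded)
        reports += r
        predictions.update(p)
        models.update(m)
        extras.update(ex)
        logger.info("OPLS done")
    if "mcr" in cfg.methods:
        r, p, m = _run_mcr(cfg, spec_cal, refs_pp, ycal, excluded)
        reports += r
        predictions.update(p)
        models.update(m)
        logger.info("MCR-ALS done")

    comparison = ev.reports_to_frame(reports)
    result = RunResult(comparison, reports, predictions, models, excluded, extras)
    if cfg.out_dir:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: RunConfig, result: RunResult):
    os.makedirs(cfg.out_dir, exist_ok=True)
    result.comparison.to_csv(os.path.join(cfg.out_dir, "comparison.csv"), index=False)
    for (method, resp), frame in result.predictions.items():
        frame.to_csv(
            os.path.join(cfg.out_dir, f"predictions_{method}_{resp}.csv"), index=False
        )
    if "loading_correlations" in result.extras:
        result.extras["loading_correlations"].to_csv(
            os.path.join(cfg.out_dir, "opls_loading_correlations.csv"),
            index_label="wavenumber",
        )
    if "scores" in result.extras:
        result.extras["scores"].to_csv(
            os.path.join(cfg.out_dir, "opls_scores.csv"), index_label="sample_id"
        )
    excl = {f"{m}:{r}": ids for (m, r), ids in result.excluded.items()}
    with open(os.path.join(cfg.out_dir, "exclusions.json"), "w") as fh:
        json.dump(excl, fh, indent=1)
    logger.info("wrote outputs to %s", cfg.out_dir)
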