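"""Stage-wise experiment orchestration with on-disk artifacts.

Stages chain the analysis: ``simulate`` writes the synthetic datasets,
``preprocess`` the corrected calibration set, ``calibrate`` the base model
bundles, ``evaluate`` the base-model metrics, ``supplement`` the full
base-vs-supplemented transfer report, ``all`` everything.  Outputs are
deterministic for a fixed config + seed, and every gap-filling default in
force (elbow threshold, quantile method, fold ordering) is echoed into the
run log for auditability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .dataset import ANALYTES, SpectralDataset
from .assessment import metrics_report, pearson_matrix, specificity_report
from .io import read_spectra_csv, save_model, sha256_of, write_spectra_csv
from .modeling import CalibrationSettings, calibrate, predict
from .preprocessing import EmscBasis, crop_fingerprint, emsc_correct
from .supplementation import transfer_experiment
from .synthetic import (KineticParams, NoiseModel, TITRATION_DESIGNS,
                        TransferScenario, build_pure_library,
                        generate_transfer_scenario, simulate_titration)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "calibrate", "evaluate", "supplement", "all")

_FILES = {
    "base": "base_calibration.csv",
    "validation": "validation_batch.csv",
    "fed": "fed_batch.csv",
}


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's artifact is missing; the message names the stage to run."""


def _settings(config: ExperimentConfig, target: str | None = None) -> CalibrationSettings:
    override = None
    if target is not None:
        override = config.modeling.lv_overrides.get(target)
    return CalibrationSettings(
        crop_low=config.preprocessing.crop_low,
        crop_high=config.preprocessing.crop_high,
        max_lv=config.modeling.max_lv,
        n_folds=config.modeling.n_folds,
        elbow_tau=config.modeling.elbow_tau,
        lv_override=override,
    )


def _scenario_from_config(config: ExperimentConfig, seed: int) -> TransferScenario:
    sim = config.simulation
    params = KineticParams(**sim.kinetics) if sim.kinetics else KineticParams()
    noise = NoiseModel(**sim.noise) if sim.noise else NoiseModel()
    scenario = generate_transfer_scenario(
        seed=seed, params=params, noise=noise, n_batches=sim.n_batches,
        n_feeds=sim.n_feeds, bolus=sim.bolus_mM,
    )
    if sim.titration:
        library = scenario.library
        rng = np.random.default_rng(seed + 101)
        for analyte, overrides in sim.titration.items():
            kwargs = dict(TITRATION_DESIGNS[analyte])
            kwargs.update(overrides)
            scenario.titrations[analyte] = simulate_titration(
                analyte, noise=noise, seed=int(rng.integers(0, 2**31 - 1)),
                library=library, **kwargs,
            )
    return scenario


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(f"{path.name} not found; run the '{stage}' stage first")
    return path


def run_pipeline(config: ExperimentConfig, stage: str, out_dir, seed: int | None = None) -> dict:
    """Run one pipeline stage (or ``all``); returns a dict of artifact paths."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    artifacts: dict = {}

    if stage in ("simulate", "all"):
        scenario = _scenario_from_config(config, seed)
        for key, ds in (("base", scenario.base_calibration),
                        ("validation", scenario.validation_batch),
                        ("fed", scenario.fed_batch)):
            path = out / _FILES[key]
            write_spectra_csv(ds, path)
            artifacts[key] = path
        for analyte, series in scenario.titrations.items():
            path = out / f"titration_{analyte}.csv"
            write_spectra_csv(series.dataset, path)
            artifacts[f"titration_{analyte}"] = path
        corr = pearson_matrix(scenario.base_calibration.reference_table())
        corr.values.to_csv(out / "calibration_pearson.csv", float_format="%.6f")
        artifacts["pearson"] = out / "calibration_pearson.csv"
        logger.info("simulate: wrote %d calibration spectra, min |r| = %.4f",
                    scenario.base_calibration.n_samples, corr.min_abs_offdiagonal())

    if stage in ("preprocess", "all"):
        base = read_spectra_csv(_need(out / _FILES["base"], "simulate"))
        cropped = crop_fingerprint(base, config.preprocessing.crop_low,
                                   config.preprocessing.crop_high)
        basis = EmscBasis.from_dataset(cropped)
        corrected, params = emsc_correct(cropped, basis)
        path = out / "base_calibration_emsc.csv"
        write_spectra_csv(corrected, path)
        state = {
            "crop_low": config.preprocessing.crop_low,
            "crop_high": config.preprocessing.crop_high,
            "emsc_reference": basis.reference.tolist(),
            "n_invalid": int((~params.valid).sum()),
        }
        (out / "preprocess_state.json").write_text(json.dumps(state, sort_keys=True))
        artifacts["preprocessed"] = path

    if stage in ("calibrate", "all"):
        base_path = _need(out / _FILES["base"], "simulate")
        base = read_spectra_csv(base_path)
        provenance = sha256_of(base_path)
        for target in ANALYTES:
            model = calibrate(base, target, _settings(config, target))
            path = out / f"model_{target}.json"
            save_model(model, path, provenance=provenance)
            artifacts[f"model_{target}"] = path
            logger.info("calibrate: %s model with %d latent variables (RMSEC %.4g)",
                        target, model.n_lv, model.rmsec)

    if stage in ("evaluate", "all"):
        from .io import load_model
        base = read_spectra_csv(_need(out / _FILES["base"], "simulate"))
        validation = read_spectra_csv(_need(out / _FILES["validation"], "simulate"))
        fed = read_spectra_csv(_need(out / _FILES["fed"], "simulate"))
        rows, pairs = [], []
        for target in ANALYTES:
            model_path = _need(out / f"model_{target}.json", "calibrate")
            model = load_model(model_path)
            for name, ds in (("validation_batch", validation), ("fed_batch", fed)):
                pred = predict(model, ds)
                rows.append(metrics_report(model, ds.reference(target), pred, name).to_dict())
                pairs.append(pd.DataFrame({
                    "analyte": target, "dataset": name,
                    "measured": ds.reference(target), "predicted": pred,
                }))
        pd.DataFrame(rows).to_csv(out / "base_metrics.csv", index=False, float_format="%.10g")
        pd.concat(pairs, ignore_index=True).to_csv(
            out / "measured_vs_predicted.csv", index=False, float_format="%.10g")
        artifacts["base_metrics"] = out / "base_metrics.csv"

    if stage in ("supplement", "all"):
        base = read_spectra_csv(_need(out / _FILES["base"], "simulate"))
        validation = read_spectra_csv(_need(out / _FILES["validation"], "simulate"))
        fed = read_spectra_csv(_need(out / _FILES["fed"], "simulate"))
        from .synthetic import TitrationSeries
        titrations = {}
        for analyte in config.supplementation.targets:
            path = _need(out / f"titration_{analyte}.csv", "simulate")
            ds = read_spectra_csv(path)
            levels = np.unique(ds.reference(analyte))
            titrations[analyte] = TitrationSeries(
                component=analyte, concentrations=levels[levels > 0],
                stock_concentration=float("nan"), addition_volume=float("nan"),
                vessel_volume=float("nan"),
                replicate_count=int(ds.n_samples // max(levels.size, 1)),
                dataset=ds,
            )
        result = transfer_experiment(base, validation, fed, titrations,
                                     settings=_settings(config),
                                     targets=tuple(config.supplementation.targets))
        report_path = out / "transfer_report.csv"
        result.to_frame().to_csv(report_path, index=False, float_format="%.10g")
        artifacts["transfer_report"] = report_path

        library = build_pure_library()
        spec_rows = []
        for target, r in result.analytes.items():
            for label, model in (("base", r.base_model), ("supplemented", r.supplemented_model)):
                rep = specificity_report(model, library)
                for analyte, value in rep.cosines.items():
                    spec_rows.append({"model_target": target, "model": label,
                                      "pure_component": analyte, "cosine": value})
        pd.DataFrame(spec_rows).to_csv(out / "specificity_report.csv",
                                       index=False, float_format="%.10g")
        artifacts["specificity_report"] = out / "specificity_report.csv"

        run_log = {
            "seed": seed,
            "elbow_tau": config.modeling.elbow_tau,
            "n_folds": config.modeling.n_folds,
            "fold_ordering": "acquisition order, sample i -> fold i mod n_folds; "
                             "supplemented sets: process samples then titration levels "
                             "in concentration order",
            "quantile_method": "linear interpolation between closest ranks",
            "emsc": "basic EMSC, quadratic term, fit-set mean reference, "
                    "refit per CV fold and per (supplemented) calibration",
            "rmsecv_pooling": "residuals pooled across folds",
            "n_lv": {t: {"base": r.base_model.n_lv, "supplemented": r.supplemented_model.n_lv}
                     for t, r in result.analytes.items()},
            "improvement_rrmsep_percent": {t: r.improvement_fed
                                           for t, r in result.analytes.items()},
        }
        (out / "run_log.json").write_text(json.dumps(run_log, sort_keys=True, indent=1))
        artifacts["run_log"] = out / "run_log.json"

    return artifacts
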