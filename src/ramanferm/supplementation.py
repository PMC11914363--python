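"""Single-compound data supplementation and the batch->fed-batch transfer study.

The procedure under test: average the replicate titration spectra per
concentration level, append the target analyte's single-compound spectra to
the batch calibration set, re-calibrate from scratch (EMSC reference and
centering recomputed on the combined set), and compare base vs supplemented
model performance on the fed-batch and on the unseen validation batch.
Supplementation is per-target: the glucose model gains only glucose titration
spectra, and so on.  Non-target reference values of titration rows are their
true values in the synthetic matrix (zero by construction) but are never used
by the PLS1 models.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ANALYTES, REFERENCE_COLUMNS, SpectralDataset
from .assessment import MetricsReport, improvement, metrics_report
from .modeling import CalibratedModel, CalibrationSettings, calibrate, predict
from .synthetic import TitrationSeries

logger = logging.getLogger(__name__)


@dataclass
class SupplementationPlan:
    """How one analyte's calibration set is supplemented."""

    target: str
    average_replicates: bool = True     # collapse the 10 replicate spectra per level
    recompute_reference: bool = True    # EMSC reference + centering refit on combined set


def average_replicates(titration_dataset: SpectralDataset, component: str) -> SpectralDataset:
    """Channel-wise mean of the replicate spectra at each titration level.

    Groups rows by the (exact) reference concentration of ``component``;
    each group must share one concentration.  The averaged spectra keep the
    level's reference values and the ``single_compound`` role.
    """
    col = REFERENCE_COLUMNS[component]
    levels = titration_dataset.meta[col].to_numpy(dtype=float)
    if np.isnan(levels).any():
        raise ValueError("titration rows lack reference concentrations for the target")
    unique_levels = np.unique(levels)
    rows, metas = [], []
    for level in unique_levels:
        members = np.flatnonzero(levels == level)
        group_meta = titration_dataset.meta.iloc[members]
        for a in ANALYTES:
            vals = group_meta[REFERENCE_COLUMNS[a]].to_numpy(dtype=float)
            if np.unique(vals[~np.isnan(vals)]).size > 1:
                raise ValueError(f"mixed {a} concentrations within one replicate group")
        rows.append(titration_dataset.intensities[members].mean(axis=0))
        m = group_meta.iloc[0].copy()
        m["sample_id"] = f"{component[:3]}_lvl_{level:.4f}"
        metas.append(m)
    return SpectralDataset(
        grid=titration_dataset.grid,
        intensities=np.vstack(rows),
        meta=pd.DataFrame(metas).reset_index(drop=True),
        stage=titration_dataset.stage,
    )


def supplement_dataset(base_calibration: SpectralDataset, titration: TitrationSeries | None,
                       plan: SupplementationPlan) -> SpectralDataset:
    """Append (averaged) single-compound spectra of the plan's target analyte.

    Row order: base process samples in acquisition order, then titration
    levels in concentration order — the venetian-blinds ordering of the
    supplemented set.  The target's calibration range becomes the union of
    the base and titration ranges.
    """
    if titration is None:
        return base_calibration.copy()
    if titration.component != plan.target:
        raise ValueError(
            f"titration is for {titration.component!r} but the plan targets {plan.target!r}"
        )
    extra = titration.dataset
    if extra.grid != base_calibration.grid:
        raise ValueError("titration and base calibration grids differ")
    if np.isnan(extra.meta[REFERENCE_COLUMNS[plan.target]].to_numpy(dtype=float)).any():
        raise ValueError("target analyte missing from titration references")
    if plan.average_replicates:
        extra = average_replicates(extra, plan.target)
    order = np.argsort(extra.meta[REFERENCE_COLUMNS[plan.target]].to_numpy(dtype=float),
                       kind="stable")
    extra = extra.subset(order)
    return SpectralDataset.concat([base_calibration, extra])


@dataclass
class AnalyteTransfer:
    """Base vs supplemented results for one analyte."""

    target: str
    base_model: CalibratedModel
    supplemented_model: CalibratedModel
    base_fed: MetricsReport
    base_validation: MetricsReport
    supplemented_fed: MetricsReport
    supplemented_validation: MetricsReport
    improvement_fed: float            # rRMSEP improvement on fed-batch, percent
    range_base: tuple
    range_supplemented: tuple


@dataclass
class TransferResult:
    """Per-analyte transfer study outcome (Table-shaped export via to_frame)."""

    analytes: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for target, r in self.analytes.items():
            rows.append({
                "analyte": target,
                "cal_range_low": r.range_supplemented[0],
                "cal_range_high": r.range_supplemented[1],
                "rmsec": r.supplemented_fed.rmsec,
                "rmsecv": r.supplemented_fed.rmsecv,
                "rmsep_fed": r.supplemented_fed.rmsep,
                "rrmsep_fed": r.supplemented_fed.rrmsep,
                "n_lv": r.supplemented_model.n_lv,
                "rrmsep_fed_base": r.base_fed.rrmsep,
                "rrmsep_improvement": r.improvement_fed,
                "rrmsep_validation_base": r.base_validation.rrmsep,
                "rrmsep_validation_supplemented": r.supplemented_validation.rrmsep,
                "n_lv_base": r.base_model.n_lv,
            })
        return pd.DataFrame(rows)


def _reference_range(dataset: SpectralDataset, target: str) -> tuple:
    y = dataset.reference(target)
    return (float(np.nanmin(y)), float(np.nanmax(y)))


def transfer_experiment(base_calibration: SpectralDataset,
                        validation_batch: SpectralDataset,
                        fed_batch: SpectralDataset,
                        titrations: dict,
                        settings: CalibrationSettings | None = None,
                        targets=ANALYTES) -> TransferResult:
    """Run the full base-vs-supplemented transfer comparison.

    For each analyte: calibrate the base model on batch data, evaluate on the
    unseen validation batch and on the fed-batch, supplement the calibration
    set with that analyte's averaged titration spectra, re-calibrate from
    scratch, and re-evaluate.  Analytes without fed-batch references are
    skipped with a warning.
    """
    settings = settings or CalibrationSettings()
    result = TransferResult()
    for target in targets:
        if np.isnan(fed_batch.reference(target)).any():
            warnings.warn(f"{target}: fed-batch reference values missing; analyte skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        base_model = calibrate(base_calibration, target, settings)
        base_fed = metrics_report(base_model, fed_batch.reference(target),
                                  predict(base_model, fed_batch), dataset_id="fed_batch")
        base_val = metrics_report(base_model, validation_batch.reference(target),
                                  predict(base_model, validation_batch),
                                  dataset_id="validation_batch")

        plan = SupplementationPlan(target=target)
        supplemented = supplement_dataset(base_calibration, titrations.get(target), plan)
        supp_model = calibrate(supplemented, target, settings)
        supp_fed = metrics_report(supp_model, fed_batch.reference(target),
                                  predict(supp_model, fed_batch), dataset_id="fed_batch")
        supp_val = metrics_report(supp_model, validation_batch.reference(target),
                                  predict(supp_model, validation_batch),
                                  dataset_id="validation_batch")

        result.analytes[target] = AnalyteTransfer(
            target=target, base_model=base_model, supplemented_model=supp_model,
            base_fed=base_fed, base_validation=base_val,
            supplemented_fed=supp_fed, supplemented_validation=supp_val,
            improvement_fed=improvement(base_fed.rrmsep, supp_fed.rrmsep),
            range_base=_reference_range(base_calibration, target),
            range_supplemented=_reference_range(supplemented, target),
        )
        logger.info("%s: fed-batch rRMSEP %.2f%% -> %.2f%% (improvement %.2f%%)",
                    target, base_fed.rrmsep, supp_fed.rrmsep,
                    result.analytes[target].improvement_fed)
    return result
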