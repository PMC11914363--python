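"""End-to-end calibration of one analyte model: crop -> EMSC -> center -> PLS.

A :class:`CalibratedModel` carries the whole pipeline state estimated on the
calibration set (crop bounds, EMSC reference, centering means, PLS weights),
so unseen spectra are preprocessed exactly like the training data — the
prerequisite for honest batch-to-fed-batch transfer evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpectralDataset, WavenumberGrid
from .preprocessing import (CenteringState, EmscBasis, apply_centering,
                            crop_fingerprint, emsc_correct, mean_center,
                            FINGERPRINT_LOW, FINGERPRINT_HIGH)
from .pls import CVResult, PLSModel, cross_validate, fit_pls1, select_latent_variables


@dataclass
class CalibrationSettings:
    """Tunable modeling choices (config-exposed)."""

    crop_low: float = FINGERPRINT_LOW
    crop_high: float = FINGERPRINT_HIGH
    max_lv: int = 10
    n_folds: int = 7
    elbow_tau: float = 0.05
    lv_override: int | None = None


@dataclass
class CalibratedModel:
    """Pipeline state + fitted PLS1 model for one analyte."""

    target: str
    grid: WavenumberGrid            # cropped grid the model lives on
    crop_low: float
    crop_high: float
    emsc_basis: EmscBasis
    centering: CenteringState       # x column means and y mean of the calibration set
    pls: PLSModel
    cv: CVResult
    n_lv: int
    y_train: np.ndarray             # calibration reference values (for IQR-based metrics)

    @property
    def rmsec(self) -> float:
        return self.pls.rmsec

    @property
    def rmsecv(self) -> float:
        return float(self.cv.rmsecv[self.n_lv - 1])

    def regression_vector(self) -> np.ndarray:
        return self.pls.regression_vector(self.n_lv)


def calibrate(dataset: SpectralDataset, target: str,
              settings: CalibrationSettings | None = None) -> CalibratedModel:
    """Calibrate a PLS1 model for one analyte on a raw spectral dataset.

    Runs the full chain: fingerprint crop, venetian-blinds cross-validation
    with per-fold EMSC/centering refit, elbow-based LV selection, then a
    final fit with EMSC reference and centering estimated on the whole
    calibration set.
    """
    settings = settings or CalibrationSettings()
    y = dataset.reference(target)
    if np.isnan(y).any():
        raise ValueError(f"calibration requires reference values for every sample ({target})")

    cropped = crop_fingerprint(dataset, settings.crop_low, settings.crop_high)
    cv = cross_validate(cropped.intensities, y, max_lv=settings.max_lv,
                        n_folds=settings.n_folds, grid=cropped.grid, emsc=True)
    n_lv = select_latent_variables(cv, tau=settings.elbow_tau, override=settings.lv_override)

    basis = EmscBasis.from_dataset(cropped)
    corrected, _ = emsc_correct(cropped, basis)
    centered, state = mean_center(corrected)
    state.y_mean = float(y.mean())
    pls = fit_pls1(centered.intensities, y - state.y_mean, n_lv, allow_early_stop=True)

    return CalibratedModel(
        target=target, grid=cropped.grid, crop_low=settings.crop_low,
        crop_high=settings.crop_high, emsc_basis=basis, centering=state,
        pls=pls, cv=cv, n_lv=n_lv, y_train=y.copy(),
    )


def preprocess_like(model: CalibratedModel, dataset: SpectralDataset) -> SpectralDataset:
    """Apply the model's stored pipeline state (crop, EMSC, centering) to new data."""
    if dataset.stage == "raw":
        dataset = crop_fingerprint(dataset, model.crop_low, model.crop_high)
    if dataset.stage != "cropped":
        raise ValueError("predict expects raw or cropped spectra")
    if dataset.grid != model.grid:
        raise ValueError("dataset grid does not match the model's training grid")
    corrected, _ = emsc_correct(dataset, model.emsc_basis)
    return apply_centering(corrected, model.centering)


def predict(model: CalibratedModel, dataset: SpectralDataset) -> np.ndarray:
    """Predict concentrations on new raw spectra, un-centered to original units.

    Negative predictions are returned as-is (no clipping).
    """
    centered = preprocess_like(model, dataset)
    return model.pls.predict_centered(centered.intensities, n_lv=model.n_lv) + model.centering.y_mean
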