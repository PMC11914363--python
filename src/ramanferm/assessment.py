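"""Quantitative and qualitative model assessment.

Quantitative: RMSE variants and their IQR-normalized relatives,

    rRMSE = 100 * RMSE / (Q3 - Q1),

with Q1/Q3 the 25th/75th percentiles (linear interpolation between closest
ranks) of the calibration set (rRMSEC, rRMSECV) or of the application set
(rRMSEP); plus the rRMSEP improvement of a supplemented over a base model.

Qualitative: the Pearson cross-correlation structure of the reference
trajectories, and a specificity diagnostic comparing a model's regression
coefficient vector against the (centered) pure-component spectra via cosine
similarity.  The cosine score quantifies what is usually judged visually; it
is a package-level diagnostic, not a literature-standard statistic.  Negative
regression coefficients are reported as-is — with overlapping bands they need
not indicate negative correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ANALYTES
from .modeling import CalibratedModel
from .synthetic import PureComponentLibrary

logger = logging.getLogger(__name__)

#: Diagnostic band centers (cm^-1) reported in the per-band attribution table.
DEFAULT_BANDS = (
    (517.0, "glucose", "C2-C1-O1 bending"),
    (879.0, "ethanol", "C-C stretching"),
    (1046.0, "ethanol", "C-O stretching"),
    (1084.0, "ethanol", "CH3 rocking"),
    (1125.0, "glucose", "C-O-H bending"),
    (1455.0, "ethanol", "CH3 asym. deformation"),
)


def rmse(measured, predicted) -> float:
    """Root mean squared error; zero iff the vectors are identical."""
    measured = np.asarray(measured, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if measured.size != predicted.size:
        raise ValueError("measured and predicted lengths differ")
    if measured.size == 0:
        raise ValueError("need at least one sample")
    return float(np.sqrt(np.mean((measured - predicted) ** 2)))


def iqr(reference_values) -> tuple[float, float]:
    """(Q1, Q3) by linear interpolation between closest ranks."""
    ref = np.asarray(reference_values, dtype=float).ravel()
    if np.isnan(ref).any():
        raise ValueError("reference values contain NaN; cannot compute quartiles")
    q1, q3 = np.percentile(ref, [25.0, 75.0], method="linear")
    return float(q1), float(q3)


def rrmse_iqr(rmse_value: float, reference_values) -> float:
    """IQR-normalized relative RMSE in percent: 100 * RMSE / (Q3 - Q1)."""
    if rmse_value < 0:
        raise ValueError("RMSE cannot be negative")
    q1, q3 = iqr(reference_values)
    if q3 <= q1:
        raise ValueError("degenerate reference spread (Q3 == Q1); relative scale undefined")
    return 100.0 * rmse_value / (q3 - q1)


def improvement(rrmsep_base: float, rrmsep_supplemented: float) -> float:
    """Percent rRMSEP improvement of the supplemented over the base model.

    100 * (base - supplemented) / base.  Negative values (worsening) are
    allowed and logged.
    """
    if rrmsep_base <= 0:
        raise ValueError("base rRMSEP must be positive")
    value = 100.0 * (rrmsep_base - rrmsep_supplemented) / rrmsep_base
    if value < 0:
        logger.warning("supplementation worsened rRMSEP: %.2f%% -> %.2f%%",
                       rrmsep_base, rrmsep_supplemented)
    return value


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations among the reference analyte series."""

    values: pd.DataFrame   # signed, symmetric, unit diagonal

    @property
    def absolute(self) -> pd.DataFrame:
        return self.values.abs()

    def min_abs_offdiagonal(self) -> float:
        m = self.values.to_numpy()
        off = np.abs(m[~np.eye(m.shape[0], dtype=bool)])
        return float(off.min())


def pearson_matrix(reference_table) -> CorrelationMatrix:
    """Product-moment correlation matrix of the analyte reference series."""
    table = pd.DataFrame(reference_table)
    if len(table) < 3:
        raise ValueError("need at least three samples for a correlation")
    arr = table.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValueError("reference table contains NaN")
    stds = arr.std(axis=0)
    constant = [c for c, s in zip(table.columns, stds) if s == 0]
    if constant:
        raise ValueError(f"constant reference series: {constant}; correlation undefined")
    corr = np.corrcoef(arr, rowvar=False)
    return CorrelationMatrix(values=pd.DataFrame(corr, index=table.columns, columns=table.columns))


@dataclass
class MetricsReport:
    """Model statistics on one application dataset (concentration units + percent)."""

    target: str
    dataset_id: str
    n_lv: int
    rmsec: float
    rmsecv: float
    rmsep: float
    rrmsec: float
    rrmsecv: float
    rrmsep: float
    q1: float               # quartiles of the application reference values
    q3: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def metrics_report(model: CalibratedModel, measured, predicted,
                   dataset_id: str = "") -> MetricsReport:
    """Assemble RMSEC/RMSECV/RMSEP and their IQR-normalized variants.

    rRMSEC and rRMSECV are normalized by the calibration set's IQR, rRMSEP by
    the application dataset's own IQR.
    """
    measured = np.asarray(measured, dtype=float).ravel()
    if np.isnan(measured).any():
        raise ValueError("application dataset lacks reference values; cannot assess")
    rmsep = rmse(measured, predicted)
    q1, q3 = iqr(measured)
    return MetricsReport(
        target=model.target, dataset_id=dataset_id, n_lv=model.n_lv,
        rmsec=model.rmsec, rmsecv=model.rmsecv, rmsep=rmsep,
        rrmsec=rrmse_iqr(model.rmsec, model.y_train),
        rrmsecv=rrmse_iqr(model.rmsecv, model.y_train),
        rrmsep=rrmse_iqr(rmsep, measured),
        q1=q1, q3=q3,
    )


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


@dataclass
class SpecificityReport:
    """Regression-vector specificity diagnostics for one model."""

    target: str
    cosines: pd.Series       # cosine(b, centered pure spectrum) per analyte
    bands: pd.DataFrame      # per-band coefficient sign and magnitude

    @property
    def target_cosine(self) -> float:
        return float(self.cosines[self.target])

    def off_target_cosine(self, analyte: str) -> float:
        if analyte == self.target:
            raise ValueError("requested the target analyte as off-target")
        return float(self.cosines[analyte])


def specificity_report(model: CalibratedModel, library: PureComponentLibrary,
                       bands=DEFAULT_BANDS) -> SpecificityReport:
    """Compare a model's regression vector with centered pure-component spectra.

    Pure spectra are cropped to the model grid and mean-centered channel-wise
    before the cosine, matching the centered scale the regression vector
    operates on.  The band table lists the coefficient sign and magnitude at
    the canonical glucose/ethanol marker bands.
    """
    if library.grid != model.grid:
        library = library.crop(model.grid.values[0], model.grid.values[-1])
        if library.grid != model.grid:
            raise ValueError("pure-component library grid does not match the model grid")
    b = model.regression_vector()
    cosines = {}
    for analyte in ANALYTES:
        s = library.spectrum(analyte).intensity
        cosines[analyte] = cosine(b, s - s.mean())
    rows = []
    for center, analyte, assignment in bands:
        idx = model.grid.index_of(center)
        rows.append({
            "band_cm1": center, "analyte": analyte, "assignment": assignment,
            "coefficient": float(b[idx]),
            "sign": "+" if b[idx] >= 0 else "-",
            "magnitude": float(abs(b[idx])),
        })
    return SpecificityReport(target=model.target, cosines=pd.Series(cosines),
                             bands=pd.DataFrame(rows))
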