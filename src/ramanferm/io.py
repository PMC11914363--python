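"""Wide-CSV spectral dataset serialization and JSON model bundles.

Schema: ``sample_id, role, time_h, glucose_mM, ethanol_mM, biomass_gL,
wn_<wavenumber>, ...`` — one column per grid channel, the wavenumber embedded
in the column name.  Intensities are written with 17 significant digits so
float64 values round-trip bit-exactly.  Missing references are empty cells.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import META_COLUMNS, SpectralDataset, WavenumberGrid
from .modeling import CalibratedModel
from .pls import CVResult, PLSModel
from .preprocessing import CenteringState, EmscBasis

_WN_PREFIX = "wn_"


def _wn_column(value: float) -> str:
    return f"{_WN_PREFIX}{value:09.3f}"


def write_spectra_csv(dataset: SpectralDataset, path) -> None:
    """Serialize a dataset to the documented wide-CSV schema."""
    path = Path(path)
    cols = [_wn_column(v) for v in dataset.grid.values]
    frame = pd.concat(
        [dataset.meta[list(META_COLUMNS)].reset_index(drop=True),
         pd.DataFrame(dataset.intensities, columns=cols)],
        axis=1,
    )
    frame.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path, stage: str = "raw") -> SpectralDataset:
    """Parse a wide-CSV dataset; wavenumber columns must be strictly increasing."""
    path = Path(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required metadata columns {missing}")
    wn_cols = [c for c in frame.columns if c.startswith(_WN_PREFIX)]
    if not wn_cols:
        raise ValueError(f"{path.name}: no wavenumber columns found")
    try:
        values = np.array([float(c[len(_WN_PREFIX):]) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"{path.name}: malformed wavenumber column name") from exc
    if not np.all(np.diff(values) > 0):
        raise ValueError(f"{path.name}: wavenumber columns are not strictly increasing")
    intensities = frame[wn_cols].to_numpy(dtype=float)
    if np.isnan(intensities).any():
        raise ValueError(f"{path.name}: intensity cells are missing (row-length mismatch?)")
    return SpectralDataset(
        grid=WavenumberGrid(values),
        intensities=intensities,
        meta=frame[list(META_COLUMNS)].copy(),
        stage=stage,
    )


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def save_model(model: CalibratedModel, path, provenance: str = "") -> None:
    """Serialize a calibrated model (pipeline state + PLS arrays) to JSON."""
    bundle = {
        "target": model.target,
        "crop_low": model.crop_low,
        "crop_high": model.crop_high,
        "grid": model.grid.values.tolist(),
        "emsc_reference": model.emsc_basis.reference.tolist(),
        "x_mean": model.centering.x_mean.tolist(),
        "y_mean": model.centering.y_mean,
        "weights": model.pls.weights.tolist(),
        "x_loadings": model.pls.x_loadings.tolist(),
        "y_loadings": model.pls.y_loadings.tolist(),
        "n_lv": model.n_lv,
        "k_effective": model.pls.k_effective,
        "rmsec": model.pls.rmsec,
        "rmsecv_curve": model.cv.rmsecv.tolist(),
        "rmsec_curve": model.cv.rmsec.tolist(),
        "folds": model.cv.folds.tolist(),
        "y_train": model.y_train.tolist(),
        "calibration_sha256": provenance,
    }
    Path(path).write_text(json.dumps(bundle, sort_keys=True))


def load_model(path) -> CalibratedModel:
    bundle = json.loads(Path(path).read_text())
    grid = WavenumberGrid(np.array(bundle["grid"]))
    basis = EmscBasis.from_reference(grid, np.array(bundle["emsc_reference"]))
    pls = PLSModel(
        weights=np.array(bundle["weights"]),
        x_loadings=np.array(bundle["x_loadings"]),
        y_loadings=np.array(bundle["y_loadings"]),
        scores=np.zeros((0, len(bundle["y_loadings"]))),
        n_lv=bundle["n_lv"],
        k_effective=bundle["k_effective"],
        rmsec=bundle["rmsec"],
    )
    cv = CVResult(rmsecv=np.array(bundle["rmsecv_curve"]),
                  rmsec=np.array(bundle["rmsec_curve"]),
                  folds=np.array(bundle["folds"]))
    return CalibratedModel(
        target=bundle["target"], grid=grid,
        crop_low=bundle["crop_low"], crop_high=bundle["crop_high"],
        emsc_basis=basis,
        centering=CenteringState(x_mean=np.array(bundle["x_mean"]), y_mean=bundle["y_mean"]),
        pls=pls, cv=cv, n_lv=bundle["n_lv"], y_train=np.array(bundle["y_train"]),
    )
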