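"""Shared in-memory containers for Raman spectral datasets.

A dataset is a wide table: one row per acquired spectrum, one column per
wavenumber channel, plus per-sample metadata (role, process time, reference
concentrations).  Row order is acquisition order; interleaved cross-validation
folds and the wide-CSV serialization both rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Analytes monitored during the fermentation, in canonical order.
ANALYTES = ("glucose", "ethanol", "biomass")

#: Metadata column holding the reference concentration of each analyte.
REFERENCE_COLUMNS = {
    "glucose": "glucose_mM",
    "ethanol": "ethanol_mM",
    "biomass": "biomass_gL",
}

#: Required metadata columns of the wide-CSV schema, in order.
META_COLUMNS = ("sample_id", "role", "time_h", "glucose_mM", "ethanol_mM", "biomass_gL")

#: Allowed per-spectrum role tags.
ROLES = ("calibration", "validation_batch", "fed_batch", "single_compound")

#: Preprocessing stages, in the one order the pipeline allows.
STAGES = ("raw", "cropped", "emsc", "centered")


class PipelineOrderError(RuntimeError):
    """A preprocessing stage was applied out of order (must be crop -> EMSC -> center)."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Ordered axis of Raman shifts (cm^-1) shared by all spectra in a dataset."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float).ravel()
        if values.size < 2:
            raise ValueError("a wavenumber grid needs at least two channels")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "values", values)

    @classmethod
    def default(cls, start: float = 100.0, stop: float = 3400.0, step: float = 1.0) -> "WavenumberGrid":
        """Full instrument span, 100-3400 cm^-1 at 1 cm^-1 per channel."""
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.values)))

    def mask(self, low: float, high: float) -> np.ndarray:
        """Boolean channel mask for the closed interval [low, high]."""
        return (self.values >= low) & (self.values <= high)

    def crop(self, low: float, high: float) -> "WavenumberGrid":
        m = self.mask(low, high)
        if not m.any():
            raise ValueError(f"crop window [{low}, {high}] does not intersect the grid")
        return WavenumberGrid(self.values[m])

    def index_of(self, wavenumber: float) -> int:
        """Index of the channel closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavenumberGrid):
            return NotImplemented
        return self.values.shape == other.values.shape and bool(np.array_equal(self.values, other.values))

    def __hash__(self):  # frozen dataclass with array payload: identity hash is fine
        return id(self)


def _empty_meta(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:04d}" for i in range(n)],
            "role": ["calibration"] * n,
            "time_h": np.full(n, np.nan),
            "glucose_mM": np.full(n, np.nan),
            "ethanol_mM": np.full(n, np.nan),
            "biomass_gL": np.full(n, np.nan),
        }
    )


@dataclass
class SpectralDataset:
    """Intensity matrix plus per-spectrum reference concentrations and labels.

    Parameters
    ----------
    grid
        Wavenumber axis; ``intensities`` columns align to it.
    intensities
        ``(n_spectra, n_channels)`` float matrix.
    meta
        One row per spectrum with the columns in :data:`META_COLUMNS`.
        Reference concentrations may be NaN (application-only data).
    stage
        Preprocessing provenance tag, one of :data:`STAGES`.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    meta: pd.DataFrame = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        self.intensities = np.atleast_2d(np.asarray(self.intensities, dtype=float))
        if self.meta is None:
            self.meta = _empty_meta(self.intensities.shape[0])
        if self.intensities.shape[1] != len(self.grid):
            raise ValueError(
                f"intensity matrix has {self.intensities.shape[1]} channels, grid has {len(self.grid)}"
            )
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("metadata row count does not match the intensity matrix")
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"metadata is missing required columns: {missing}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown preprocessing stage {self.stage!r}")
        self.meta = self.meta.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def acquisition_order(self) -> np.ndarray:
        """Acquisition order is row order by construction."""
        return np.arange(self.n_samples)

    @property
    def roles(self) -> np.ndarray:
        return self.meta["role"].to_numpy()

    def reference(self, analyte: str) -> np.ndarray:
        """Reference concentration series for one analyte (may contain NaN)."""
        try:
            col = REFERENCE_COLUMNS[analyte]
        except KeyError:
            raise KeyError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}") from None
        return self.meta[col].to_numpy(dtype=float)

    def reference_table(self) -> pd.DataFrame:
        """Reference concentrations for all analytes, one column per analyte."""
        return pd.DataFrame({a: self.reference(a) for a in ANALYTES})

    def subset(self, rows) -> "SpectralDataset":
        rows = np.asarray(rows)
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities[rows],
            meta=self.meta.iloc[rows].reset_index(drop=True),
            stage=self.stage,
        )

    def with_intensities(self, intensities: np.ndarray, stage: str | None = None) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid,
            intensities=intensities,
            meta=self.meta.copy(),
            stage=self.stage if stage is None else stage,
        )

    def copy(self) -> "SpectralDataset":
        return SpectralDataset(
            grid=self.grid,
            intensities=self.intensities.copy(),
            meta=self.meta.copy(),
            stage=self.stage,
        )

    @classmethod
    def concat(cls, datasets) -> "SpectralDataset":
        """Stack datasets sharing a grid and stage; row order is preserved."""
        datasets = list(datasets)
        if not datasets:
            raise ValueError("nothing to concatenate")
        first = datasets[0]
        for d in datasets[1:]:
            if d.grid != first.grid:
                raise ValueError("cannot concatenate datasets with different wavenumber grids")
            if d.stage != first.stage:
                raise ValueError("cannot concatenate datasets at different preprocessing stages")
        return cls(
            grid=first.grid,
            intensities=np.vstack([d.intensities for d in datasets]),
            meta=pd.concat([d.meta for d in datasets], ignore_index=True),
            stage=first.stage,
        )
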