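"""Spectral preprocessing: fingerprint crop, EMSC, mean-centering.

The pipeline order is fixed — crop -> EMSC -> mean-center — and enforced via
the dataset's ``stage`` tag; applying a stage out of order raises
:class:`~ramanferm.dataset.PipelineOrderError`.  EMSC and centering state are
always estimated on a stated fitting set (the calibration data) and then
*applied* to unseen spectra, which is what makes transfer evaluation honest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataset import PipelineOrderError, SpectralDataset, WavenumberGrid

FINGERPRINT_LOW = 450.0
FINGERPRINT_HIGH = 1800.0

#: |b| below this is treated as "no signal"; the correction x/b is undefined.
EMSC_B_TOLERANCE = 1e-8


def crop_fingerprint(dataset: SpectralDataset, low: float = FINGERPRINT_LOW,
                     high: float = FINGERPRINT_HIGH) -> SpectralDataset:
    """Keep exactly the channels with low <= nu <= high (both ends inclusive).

    References and labels are untouched.  Idempotent; allowed on raw or
    already-cropped data, but not after EMSC or centering.
    """
    if dataset.stage not in ("raw", "cropped"):
        raise PipelineOrderError("cropping must precede EMSC and centering")
    mask = dataset.grid.mask(low, high)
    if not mask.any():
        raise ValueError(f"crop window [{low}, {high}] does not intersect the dataset grid")
    return SpectralDataset(
        grid=WavenumberGrid(dataset.grid.values[mask]),
        intensities=dataset.intensities[:, mask],
        meta=dataset.meta.copy(),
        stage="cropped",
    )


def _normalized_axis(grid: WavenumberGrid) -> np.ndarray:
    """Wavenumber axis mapped to [-1, 1] (conditioning of the polynomial columns)."""
    nu = grid.values
    return 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0


@dataclass
class EmscBasis:
    """EMSC regression basis: polynomial design plus the fit-set mean spectrum."""

    grid: WavenumberGrid
    reference: np.ndarray          # mean spectrum m(nu) of the fitting set
    design: np.ndarray             # (p, 4) columns [1, nu~, nu~^2, m]

    @classmethod
    def from_dataset(cls, dataset: SpectralDataset) -> "EmscBasis":
        if dataset.stage != "cropped":
            raise PipelineOrderError("build the EMSC basis on cropped data (crop -> EMSC -> center)")
        return cls.from_reference(dataset.grid, dataset.intensities.mean(axis=0))

    @classmethod
    def from_reference(cls, grid: WavenumberGrid, reference: np.ndarray) -> "EmscBasis":
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (len(grid),):
            raise ValueError("reference spectrum length does not match the grid")
        nu_t = _normalized_axis(grid)
        design = np.column_stack([np.ones_like(nu_t), nu_t, nu_t**2, reference])
        return cls(grid=grid, reference=reference, design=design)


@dataclass
class EmscParameters:
    """Per-spectrum EMSC decomposition x ~ a + d1*nu~ + d2*nu~^2 + b*m."""

    a: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    b: np.ndarray
    valid: np.ndarray   # False where |b| is below tolerance (correction undefined)


def emsc_correct(dataset: SpectralDataset, basis: EmscBasis):
    """Basic EMSC with a quadratic term and the fit-set mean as reference.

    Each spectrum is fitted by ordinary least squares on [1, nu~, nu~^2, m];
    the corrected spectrum is ``(x - a - d1 nu~ - d2 nu~^2) / b``.  The
    fitting-set mean is corrected to itself.  Spectra whose multiplicative
    scale |b| falls below tolerance are flagged invalid and returned as NaN.

    Returns ``(corrected dataset, EmscParameters)``.
    """
    if dataset.stage != "cropped":
        raise PipelineOrderError("EMSC must run on cropped, un-centered spectra")
    if dataset.grid != basis.grid:
        raise ValueError("EMSC basis grid does not match the dataset grid")

    coef, *_ = np.linalg.lstsq(basis.design, dataset.intensities.T, rcond=None)
    a, d1, d2, b = coef
    scale = np.linalg.norm(basis.reference) / np.sqrt(len(basis.grid))
    valid = np.abs(b) > EMSC_B_TOLERANCE * max(scale, 1.0)

    background = basis.design[:, :3] @ coef[:3]                 # (p, n)
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = ((dataset.intensities.T - background) / b).T
    if not valid.all():
        warnings.warn(
            f"{int((~valid).sum())} spectra have near-zero EMSC scale b; flagged invalid (NaN)",
            RuntimeWarning, stacklevel=2,
        )
        corrected[~valid] = np.nan

    return (
        dataset.with_intensities(corrected, stage="emsc"),
        EmscParameters(a=a, d1=d1, d2=d2, b=b, valid=valid),
    )


@dataclass
class CenteringState:
    """Column means of the calibration spectra (and optionally of y)."""

    x_mean: np.ndarray
    y_mean: float | None = None


def mean_center(dataset: SpectralDataset):
    """Center a fitting set on its own column means; returns the stored state.

    Unseen data must be centered with :func:`apply_centering` using the state
    stored here, not with its own means.
    """
    if dataset.stage != "emsc":
        raise PipelineOrderError("mean-centering comes after EMSC (crop -> EMSC -> center)")
    if dataset.n_samples < 2:
        raise ValueError("need at least two spectra to estimate column means")
    x_mean = dataset.intensities.mean(axis=0)
    centered = dataset.with_intensities(dataset.intensities - x_mean, stage="centered")
    return centered, CenteringState(x_mean=x_mean)


def apply_centering(dataset: SpectralDataset, state: CenteringState) -> SpectralDataset:
    """Center unseen spectra with the stored calibration means."""
    if dataset.stage != "emsc":
        raise PipelineOrderError("centering applies to EMSC-corrected spectra")
    if state.x_mean.shape != (len(dataset.grid),):
        raise ValueError("centering state does not match the dataset grid")
    return dataset.with_intensities(dataset.intensities - state.x_mean, stage="centered")


def revert_centering(dataset: SpectralDataset, state: CenteringState) -> SpectralDataset:
    """Inverse of centering (round-trip identity)."""
    if dataset.stage != "centered":
        raise PipelineOrderError("only centered datasets can be un-centered")
    return dataset.with_intensities(dataset.intensities + state.x_mean, stage="emsc")
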