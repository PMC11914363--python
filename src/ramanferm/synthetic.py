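"""Synthetic fermentation Raman data with fully known ground truth.

The generator emulates the data situation of Raman-monitored *S. cerevisiae*
cultivations: batch and fed-batch process trajectories (Monod growth on
glucose with stoichiometric ethanol production), a linear Beer-Lambert-like
mixture forward model rendering trajectories into Raman-like spectra with
fluorescence baseline, scatter and noise, and single-compound titration
series in blank medium.  Because substrate consumption, product formation and
growth are tied by fixed yields, the rendered process datasets carry the
strong pairwise analyte cross-correlations (|Pearson r| > 0.98) that make
implicit calibration models non-specific — which is the phenomenon the rest
of the package measures and repairs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.special import expit

from .dataset import ANALYTES, REFERENCE_COLUMNS, SpectralDataset, WavenumberGrid

#: Molar mass of glucose in g per mmol (conversion between mM and g/L).
MW_GLUCOSE = 0.18016

_SEED_MAX = 2**31 - 1


# ---------------------------------------------------------------------------
# Process kinetics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticParams:
    """Monod kinetics with fixed yields.

    Growth is tied to glucose uptake: ``dS/dt = -q_s(S) X`` with
    ``q_s = qs_max S / (Ks + S)`` and ``dX/dt = Y_xs MW dS/dt`` (so biomass is
    affine in glucose within each feed phase), and ethanol is stoichiometric,
    ``E = Y_es * (glucose fed - glucose left)``.  Defaults put a 20 g/L
    (111 mM) batch endpoint inside the usual batch calibration ranges
    (~159 mM ethanol, ~3.3 g/L biomass, depletion near 12 h).

    ``yield_biomass_fed`` applies to growth after the first glucose bolus; by
    default it equals the batch yield, so product and biomass keep co-varying
    through the fed phases the way the batch stoichiometry dictates, while the
    glucose boluses alone redistribute the substrate-to-product ratios.
    """

    qs_max: float = 10.9          # mmol glucose / (g DW h)
    ks: float = 5.6               # mM (Monod affinity)
    yield_biomass: float = 0.16   # g DW / g glucose, batch phase
    yield_biomass_fed: float = 0.16  # g DW / g glucose, post-feed phases
    yield_ethanol: float = 1.43   # mol ethanol / mol glucose
    depletion_threshold: float = 0.5  # mM; "glucose depleted" detection level
    # Batch-to-batch variability (lognormal CVs applied when a seed is given).
    # Yield jitter shifts the substrate/product/biomass ratios slightly from
    # run to run, so implicit models calibrated on pooled batches face small
    # correlation shifts even on a nominally identical validation batch.
    inoculum_cv: float = 0.08
    qs_cv: float = 0.05
    glucose_cv: float = 0.03
    yield_ethanol_cv: float = 0.04
    yield_biomass_cv: float = 0.04

    def validate(self) -> None:
        for name in ("qs_max", "ks", "yield_biomass", "yield_biomass_fed",
                     "yield_ethanol", "depletion_threshold"):
            if getattr(self, name) < 0:
                raise ValueError(f"kinetic parameter {name} must be non-negative")


@dataclass
class ProcessTrajectory:
    """Hourly-sampled fermentation state with exact stoichiometric bookkeeping."""

    time: np.ndarray          # h
    glucose: np.ndarray       # mM
    ethanol: np.ndarray       # mM
    biomass: np.ndarray       # g/L
    feed_events: list         # [(time_h, bolus_mM), ...]
    mode: str                 # "batch" | "fed_batch"
    params: dict              # effective (post-jitter) simulation parameters
    depletion_time: float     # h, final glucose depletion

    @property
    def n_samples(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_h": self.time, "glucose_mM": self.glucose,
             "ethanol_mM": self.ethanol, "biomass_gL": self.biomass}
        )


def _integrate_phase(s0: float, x0: float, qs_max: float, ks: float,
                     yield_biomass: float, threshold: float):
    """Integrate one feed phase (glucose ODE only; X is affine in S).

    Returns the solve_ivp solution (dense) and the phase duration, i.e. the
    time at which glucose crosses the depletion threshold.
    """

    def rhs(_t, y):
        s = max(y[0], 0.0)
        x = x0 + yield_biomass * MW_GLUCOSE * (s0 - s)
        return [-qs_max * s / (ks + s) * x]

    def depleted(_t, y):
        return y[0] - threshold

    depleted.terminal = True
    depleted.direction = -1

    sol = solve_ivp(rhs, (0.0, 2000.0), [s0], events=depleted,
                    dense_output=True, rtol=1e-10, atol=1e-10)
    if sol.t_events[0].size == 0:
        raise RuntimeError("glucose never reached the depletion threshold")
    return sol, float(sol.t_events[0][0])


def _simulate(params: KineticParams, initial_glucose: float, inoculum: float,
              sampling_interval: float, seed, n_feeds: int, bolus: float) -> ProcessTrajectory:
    params = params or KineticParams()
    params.validate()
    if inoculum <= 0:
        raise ValueError("inoculum must be positive: no growth possible otherwise")
    if initial_glucose < 0:
        raise ValueError("initial glucose must be non-negative")
    if sampling_interval <= 0:
        raise ValueError("sampling interval must be positive")
    if bolus < 0:
        raise ValueError("feed bolus must be non-negative")

    # Batch-to-batch variability: each seed is one cultivation.
    qs, s0, x0 = params.qs_max, float(initial_glucose), float(inoculum)
    y_es, y_xs, y_xs_fed = params.yield_ethanol, params.yield_biomass, params.yield_biomass_fed
    if seed is not None:
        rng = np.random.default_rng(seed)
        x0 *= float(np.exp(rng.normal(0.0, params.inoculum_cv)))
        qs *= float(np.exp(rng.normal(0.0, params.qs_cv)))
        s0 *= float(np.exp(rng.normal(0.0, params.glucose_cv)))
        y_es *= float(np.exp(rng.normal(0.0, params.yield_ethanol_cv)))
        jb = float(np.exp(rng.normal(0.0, params.yield_biomass_cv)))
        y_xs, y_xs_fed = y_xs * jb, y_xs_fed * jb

    threshold = params.depletion_threshold
    if s0 <= threshold:
        raise ValueError("depletion threshold is at or above the initial glucose concentration")

    # Integrate phase by phase; a feed is an instantaneous concentration step
    # triggered when glucose hits the depletion threshold.
    phases = []  # (t_start, t_end, sol, S_phase0, X_phase0, fed_cum, yield_b)
    t_start, s_phase, x_phase = 0.0, s0, x0
    fed_cum = s0  # total glucose supplied so far (initial charge + boluses), mM
    feed_events: list = []
    feeds_left = n_feeds
    while True:
        yb = y_xs if not feed_events else y_xs_fed
        sol, duration = _integrate_phase(s_phase, x_phase, qs, params.ks, yb, threshold)
        t_end = t_start + duration
        phases.append((t_start, t_end, sol, s_phase, x_phase, fed_cum, yb))
        if feeds_left == 0:
            break
        s_end = threshold
        x_end = x_phase + yb * MW_GLUCOSE * (s_phase - s_end)
        feed_events.append((t_end, bolus))
        s_phase, x_phase, t_start = s_end + bolus, x_end, t_end
        fed_cum += bolus
        feeds_left -= 1

    t_final = phases[-1][1]
    dt = sampling_interval
    n_samples = int(np.ceil(t_final / dt - 1e-12)) + 1
    times = dt * np.arange(n_samples)

    glucose = np.empty(n_samples)
    biomass = np.empty(n_samples)
    fed_at_t = np.empty(n_samples)
    last = len(phases) - 1
    for i, t in enumerate(times):
        for j, (ts, te, sol, sp, xp, fc, yb) in enumerate(phases):
            if t <= te or j == last:
                t_local = np.clip(min(t, te) - ts, 0.0, None)
                s = max(float(sol.sol(t_local)[0]), 0.0)
                glucose[i] = s
                biomass[i] = xp + yb * MW_GLUCOSE * (sp - s)
                fed_at_t[i] = fc
                break
    ethanol = y_es * (fed_at_t - glucose)

    effective = {
        "qs_max": qs, "ks": params.ks, "yield_biomass": y_xs,
        "yield_biomass_fed": y_xs_fed,
        "yield_ethanol": y_es,
        "depletion_threshold": threshold,
        "initial_glucose": s0, "inoculum": x0,
        "sampling_interval": sampling_interval, "bolus": bolus, "n_feeds": n_feeds,
    }
    return ProcessTrajectory(
        time=times, glucose=glucose, ethanol=ethanol, biomass=biomass,
        feed_events=feed_events, mode="batch" if n_feeds == 0 else "fed_batch",
        params=effective, depletion_time=t_final,
    )


def simulate_batch(params: KineticParams | None = None, initial_glucose: float = 111.0,
                   inoculum: float = 0.10, sampling_interval: float = 1.0,
                   seed: int | None = None) -> ProcessTrajectory:
    """Simulate one batch cultivation sampled hourly until glucose depletion.

    A 20 g/L (111 mM) initial glucose charge is consumed by Monod growth; the
    trajectory terminates once glucose falls below the depletion threshold
    (the sample after depletion is retained, so glucose reaches ~0).  With a
    seed, inoculum density, uptake capacity and the initial charge are
    jittered to emulate run-to-run variability.
    """
    return _simulate(params or KineticParams(), initial_glucose, inoculum,
                     sampling_interval, seed, n_feeds=0, bolus=0.0)


def simulate_fedbatch(params: KineticParams | None = None, n_feeds: int = 3,
                      bolus: float = 40.0, initial_glucose: float = 111.0,
                      inoculum: float = 0.10, sampling_interval: float = 1.0,
                      seed: int | None = None) -> ProcessTrajectory:
    """Simulate a fed-batch cultivation: glucose boluses fired at depletion.

    Each of the ``n_feeds`` feeds is an instantaneous glucose concentration
    step (feed volume is ignored), triggered when the substrate hits the
    depletion threshold — the off-gas-triggered spiking regime.  Ethanol and
    biomass therefore extend beyond the batch endpoint, and the analyte
    ratios after each bolus break the batch-phase cross-correlations.
    """
    if n_feeds < 0:
        raise ValueError("number of feeds must be non-negative")
    return _simulate(params or KineticParams(), initial_glucose, inoculum,
                     sampling_interval, seed, n_feeds=n_feeds, bolus=bolus)


# ---------------------------------------------------------------------------
# Pure component spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PeakSpec:
    """A single Raman band: center (cm^-1), FWHM (cm^-1), height per unit concentration."""

    center: float
    fwhm: float
    height: float
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("peak width (FWHM) must be positive")
        if self.height < 0:
            raise ValueError("peak height must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")

    def render(self, grid: WavenumberGrid) -> np.ndarray:
        nu = grid.values
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * np.log(2.0) * (nu - self.center) ** 2 / self.fwhm**2)
        half = self.fwhm / 2.0
        return self.height * half**2 / ((nu - self.center) ** 2 + half**2)


@dataclass
class PureComponentSpectrum:
    """Unit-concentration spectrum of one analyte.

    ``narrow`` holds the rendered sharp bands; ``broad`` an optional slowly
    varying additive profile (the ascending cell-suspension baseline for
    biomass).  ``intensity`` is their sum.
    """

    component: str
    grid: WavenumberGrid
    peaks: tuple
    narrow: np.ndarray = None
    broad: np.ndarray = None

    def __post_init__(self) -> None:
        lo, hi = self.grid.values[0], self.grid.values[-1]
        for p in self.peaks:
            if not (lo <= p.center <= hi):
                raise ValueError(
                    f"{self.component} peak at {p.center} cm^-1 lies outside the grid [{lo}, {hi}]"
                )
        if self.narrow is None:
            self.narrow = sum((p.render(self.grid) for p in self.peaks),
                              np.zeros(len(self.grid)))
        if self.broad is None:
            self.broad = np.zeros(len(self.grid))

    @property
    def intensity(self) -> np.ndarray:
        return self.narrow + self.broad


@dataclass
class PureComponentLibrary:
    """Unit-concentration spectra for glucose (per mM), ethanol (per mM), biomass (per g/L)."""

    grid: WavenumberGrid
    components: dict

    def spectrum(self, component: str) -> PureComponentSpectrum:
        return self.components[component]

    def matrix(self, suspension: bool = True) -> np.ndarray:
        """(3, n_channels) stack in canonical analyte order.

        ``suspension=True`` includes broad terms (single-compound acquisition
        mode); ``False`` keeps only the narrow bands (process mode).
        """
        rows = []
        for a in ANALYTES:
            s = self.components[a]
            rows.append(s.intensity if suspension else s.narrow)
        return np.vstack(rows)

    def crop(self, low: float, high: float) -> "PureComponentLibrary":
        m = self.grid.mask(low, high)
        new_grid = WavenumberGrid(self.grid.values[m])
        comps = {}
        for name, s in self.components.items():
            kept = tuple(p for p in s.peaks if low <= p.center <= high)
            comps[name] = PureComponentSpectrum(
                component=name, grid=new_grid, peaks=kept,
                narrow=s.narrow[m].copy(), broad=s.broad[m].copy(),
            )
        return PureComponentLibrary(grid=new_grid, components=comps)


def default_peak_tables() -> dict:
    """Band tables for the three analytes (centers from standard assignments).

    Glucose: C2-C1-O1 bending at 517 and C-O-H bending at 1125 cm^-1, plus
    ring/CH bands at 1060, 1365 and 1460 cm^-1 that overlap ethanol in the
    1000-1150 and 1400-1500 cm^-1 windows.  Ethanol: C-C stretch at 879, C-O
    stretch at 1046, CH3 rock at 1084 and the strong asymmetric CH3
    deformation at 1455 cm^-1.  Biomass: weak cell markers (phenylalanine
    1003, CH deformation 1450, amide I 1660 cm^-1).  The 879 cm^-1 ethanol
    band is free of glucose and biomass bands.
    """
    return {
        "glucose": (
            PeakSpec(517.0, 18.0, 0.65),
            PeakSpec(1060.0, 16.0, 0.39),
            PeakSpec(1125.0, 16.0, 0.78),
            PeakSpec(1365.0, 18.0, 0.26),
            PeakSpec(1460.0, 18.0, 0.33),
        ),
        "ethanol": (
            PeakSpec(879.0, 16.0, 0.70),
            PeakSpec(1046.0, 14.0, 0.45),
            PeakSpec(1084.0, 14.0, 0.40),
            PeakSpec(1276.0, 16.0, 0.15),
            PeakSpec(1455.0, 16.0, 0.55),
        ),
        "biomass": (
            PeakSpec(1003.0, 12.0, 6.0),
            PeakSpec(1450.0, 20.0, 4.0),
            PeakSpec(1660.0, 24.0, 5.0),
        ),
    }


def _biomass_broad_term(grid: WavenumberGrid, amplitude: float = 3.0) -> np.ndarray:
    """Ascending suspension baseline rising over 1200-1600 cm^-1, per g/L."""
    return amplitude * expit((grid.values - 1400.0) / 90.0)


def build_pure_library(peak_tables: dict | None = None,
                       grid: WavenumberGrid | None = None,
                       broad_terms: dict | None = None) -> PureComponentLibrary:
    """Build unit-concentration pure-component spectra from band tables."""
    grid = grid or WavenumberGrid.default()
    peak_tables = peak_tables if peak_tables is not None else default_peak_tables()
    if broad_terms is None:
        broad_terms = {"biomass": _biomass_broad_term(grid)}
    components = {}
    for name, peaks in peak_tables.items():
        broad = broad_terms.get(name)
        components[name] = PureComponentSpectrum(
            component=name, grid=grid, peaks=tuple(peaks),
            broad=None if broad is None else np.asarray(broad, dtype=float),
        )
    return PureComponentLibrary(grid=grid, components=components)


# ---------------------------------------------------------------------------
# Spectral forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseModel:
    """Instrumental nuisance model added on top of the noiseless mixture.

    ``baseline_amplitude * exp(-(nu - nu_min)/baseline_decay_constant)`` is a
    deterministic fluorescence/scatter background rising exponentially toward
    low wavenumbers.  Per spectrum: a random polynomial drift (coefficients
    drawn with the ``drift_coefficients`` standard deviations on a normalized
    axis), a multiplicative gain ``1 + N(0, multiplicative_gain_sd)``, and
    i.i.d. additive channel noise.  All parameters zero => rendering equals
    the exact noiseless mixture.
    """

    baseline_amplitude: float = 3000.0
    baseline_decay_constant: float = 350.0          # cm^-1
    drift_coefficients: tuple = (2.0, 1.0, 0.5)     # sd of offset/linear/quadratic
    multiplicative_gain_sd: float = 0.05
    additive_noise_sd: float = 4.0
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.baseline_amplitude < 0 or self.multiplicative_gain_sd < 0 or self.additive_noise_sd < 0:
            raise ValueError("noise standard deviations and amplitudes must be non-negative")
        if any(s < 0 for s in self.drift_coefficients):
            raise ValueError("drift coefficient standard deviations must be non-negative")

    @classmethod
    def none(cls) -> "NoiseModel":
        """Exact noiseless rendering."""
        return cls(0.0, 1.0, (0.0, 0.0, 0.0), 0.0, 0.0, seed=0)

    def with_seed(self, seed: int | None) -> "NoiseModel":
        return dataclasses.replace(self, seed=seed)

    def baseline(self, grid: WavenumberGrid) -> np.ndarray:
        if self.baseline_amplitude == 0.0:
            return np.zeros(len(grid))
        nu0 = grid.values[0]
        return self.baseline_amplitude * np.exp(-(grid.values - nu0) / self.baseline_decay_constant)


def extinction_profile(grid: WavenumberGrid) -> np.ndarray:
    """Slowly varying channel weight w(nu) in [0.5, 1] for particle extinction."""
    nu = grid.values
    return 0.5 + 0.5 * (nu - nu[0]) / (nu[-1] - nu[0])


def render_spectra(samples, library: PureComponentLibrary,
                   noise: NoiseModel | None = None,
                   biomass_mode: str = "fermentation_extinction",
                   role: str = "calibration",
                   k_ext: float = 0.005,
                   grid: WavenumberGrid | None = None,
                   sample_prefix: str = "s") -> SpectralDataset:
    """Render concentration samples into Raman-like spectra.

    The noiseless signal is ``[sum_a c_a s_a(nu)] * ext(nu, X) + baseline(nu)``.
    ``biomass_mode`` encodes the observed dichotomy between cell suspensions
    and running fermentations:

    - ``"suspension_baseline"``: ext = 1 and the biomass pure spectrum keeps
      its broad ascending baseline (single-compound acquisition).
    - ``"fermentation_extinction"``: broad biomass term off, and the whole
      mixture is attenuated by ``exp(-k_ext * X * w(nu))`` with a slowly
      varying w — non-linear Lorenz-Mie-like signal extinction by cells.

    ``samples`` is a :class:`ProcessTrajectory` or a DataFrame with columns
    ``glucose_mM, ethanol_mM, biomass_gL`` (and optionally ``time_h``).
    """
    if biomass_mode not in ("suspension_baseline", "fermentation_extinction"):
        raise ValueError(f"unknown biomass_mode {biomass_mode!r}")
    if grid is not None and grid != library.grid:
        raise ValueError("requested grid does not match the pure-component library grid")
    grid = library.grid
    noise = NoiseModel() if noise is None else noise

    if isinstance(samples, ProcessTrajectory):
        table = samples.to_frame()
    else:
        table = pd.DataFrame(samples)
    conc = table[["glucose_mM", "ethanol_mM", "biomass_gL"]].to_numpy(dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    n = conc.shape[0]

    suspension = biomass_mode == "suspension_baseline"
    pure = library.matrix(suspension=suspension)      # (3, p)
    mixture = conc @ pure                              # (n, p)
    if not suspension:
        w = extinction_profile(grid)
        mixture = mixture * np.exp(-k_ext * np.outer(conc[:, 2], w))

    rng = np.random.default_rng(noise.seed)
    nu = grid.values
    nu_t = 2.0 * (nu - nu[0]) / (nu[-1] - nu[0]) - 1.0
    design = np.vstack([np.ones_like(nu_t), nu_t, nu_t**2])  # (3, p)
    drift_sd = np.asarray(noise.drift_coefficients, dtype=float)
    drift_coef = rng.normal(0.0, 1.0, size=(n, 3)) * drift_sd
    gains = 1.0 + rng.normal(0.0, noise.multiplicative_gain_sd, size=n) \
        if noise.multiplicative_gain_sd > 0 else np.ones(n)
    gains = np.clip(gains, 0.1, None)
    eps = rng.normal(0.0, noise.additive_noise_sd, size=(n, len(grid))) \
        if noise.additive_noise_sd > 0 else 0.0

    # Gain (laser power / collection efficiency) scales all collected light —
    # analyte signal and fluorescence background alike — which is exactly the
    # multiplicative term EMSC is meant to absorb.
    intensities = gains[:, None] * (mixture + noise.baseline(grid)) + drift_coef @ design + eps

    meta = pd.DataFrame(
        {
            "sample_id": [f"{sample_prefix}{i:03d}" for i in range(n)],
            "role": [role] * n,
            "time_h": table["time_h"].to_numpy(dtype=float) if "time_h" in table else np.full(n, np.nan),
            "glucose_mM": conc[:, 0],
            "ethanol_mM": conc[:, 1],
            "biomass_gL": conc[:, 2],
        }
    )
    return SpectralDataset(grid=grid, intensities=intensities, meta=meta, stage="raw")


# ---------------------------------------------------------------------------
# Single-compound titration series
# ---------------------------------------------------------------------------

def add_stock(concentration: float, vessel_volume: float,
              stock_concentration: float, addition_volume: float) -> float:
    """Concentration after mixing one stock addition into the vessel.

    ``c <- (c V + c_stock V_add) / (V + V_add)``; the sample subsequently
    withdrawn for the reference assay restores the volume without changing
    the concentration.  The stock must not be below the current concentration
    (otherwise the level cannot step up).
    """
    if vessel_volume <= 0 or addition_volume <= 0:
        raise ValueError("volumes must be positive")
    if stock_concentration < concentration:
        raise ValueError("stock concentration is below the current vessel concentration; cannot step up")
    return (concentration * vessel_volume + stock_concentration * addition_volume) / (
        vessel_volume + addition_volume
    )


#: Per-analyte titration designs reproducing the measured single-compound ranges
#: (0-247 mM glucose with densified low end, 0-500 mM ethanol in 20 mM steps,
#: 0-~5 g/L biomass from a 14.3 g/L washed-cell stock).
TITRATION_DESIGNS = {
    "glucose": dict(stock_concentration=2776.0, n_additions=20, addition_volume=0.010,
                    spacing="exponential", target_max=247.08, growth=1.08, step_size=None),
    "ethanol": dict(stock_concentration=17100.0, n_additions=25, addition_volume=0.010,
                    spacing="linear_step", target_max=None, growth=None, step_size=20.0),
    "biomass": dict(stock_concentration=14.3, n_additions=11, addition_volume=0.050,
                    spacing="linear_step", target_max=None, growth=None, step_size=0.45),
}


@dataclass
class TitrationSeries:
    """Stepwise single-compound concentration series with replicate spectra."""

    component: str
    concentrations: np.ndarray   # achieved values after each addition (strictly increasing)
    stock_concentration: float
    addition_volume: float
    vessel_volume: float
    replicate_count: int
    dataset: SpectralDataset     # includes the blank (zero) level

    @property
    def levels(self) -> np.ndarray:
        """All measured levels, blank included."""
        return np.concatenate([[0.0], self.concentrations])


def titration_targets(spacing: str, n_additions: int, target_max: float | None,
                      growth: float | None, step_size: float | None) -> np.ndarray:
    """Target concentration schedule for one titration.

    ``linear_step``: constant increments of ``step_size``.  ``exponential``:
    geometrically growing increments (ratio ``growth``) normalized to end at
    ``target_max`` — more levels at low concentration, as in the measured
    glucose series.
    """
    if n_additions < 1:
        raise ValueError("need at least one addition")
    if spacing == "linear_step":
        if step_size is None or step_size <= 0:
            raise ValueError("linear_step spacing needs a positive step_size")
        return step_size * np.arange(1, n_additions + 1)
    if spacing == "exponential":
        if target_max is None or target_max <= 0:
            raise ValueError("exponential spacing needs a positive target_max")
        g = 1.08 if growth is None else growth
        if g <= 1.0:
            raise ValueError("exponential spacing needs growth > 1")
        increments = g ** np.arange(n_additions)
        increments *= target_max / increments.sum()
        return np.cumsum(increments)
    raise ValueError(f"unknown spacing {spacing!r}")


def simulate_titration(component: str, stock_concentration: float | None = None,
                       n_additions: int | None = None, addition_volume: float | None = None,
                       vessel_volume: float = 1.000, spacing: str | None = None,
                       step_size: float | None = None, target_max: float | None = None,
                       growth: float | None = None, replicate_count: int = 10,
                       noise: NoiseModel | None = None, seed: int | None = None,
                       library: PureComponentLibrary | None = None) -> TitrationSeries:
    """Simulate a stepwise single-compound titration in blank medium.

    Bookkeeping is add-then-sample: each prepared addition (volume
    ``addition_volume``, per-step stock computed from the target schedule and
    capped by ``stock_concentration``) is mixed into the vessel, then an
    equal sample volume is withdrawn, restoring the working volume without
    changing the concentration.  ``replicate_count`` spectra are acquired per
    level (blank included) in suspension mode (no cell-particle extinction,
    biomass keeps its ascending baseline).
    """
    if component not in ANALYTES:
        raise ValueError(f"unknown component {component!r}")
    design = TITRATION_DESIGNS[component]
    stock_concentration = design["stock_concentration"] if stock_concentration is None else stock_concentration
    n_additions = design["n_additions"] if n_additions is None else n_additions
    addition_volume = design["addition_volume"] if addition_volume is None else addition_volume
    spacing = design["spacing"] if spacing is None else spacing
    step_size = design["step_size"] if step_size is None else step_size
    target_max = design["target_max"] if target_max is None else target_max
    growth = design["growth"] if growth is None else growth
    if vessel_volume <= 0 or addition_volume <= 0:
        raise ValueError("volumes must be positive")

    targets = titration_targets(spacing, n_additions, target_max, growth, step_size)
    achieved = []
    c = 0.0
    for target in targets:
        needed_stock = (target * (vessel_volume + addition_volume) - c * vessel_volume) / addition_volume
        if needed_stock > stock_concentration + 1e-9:
            raise ValueError(
                f"step to {target:.2f} needs a {needed_stock:.1f} stock, above the "
                f"available {stock_concentration:.1f}"
            )
        c = add_stock(c, vessel_volume, needed_stock, addition_volume)
        achieved.append(c)
    achieved = np.asarray(achieved)
    if not np.all(np.diff(np.concatenate([[0.0], achieved])) > 0):
        raise ValueError("titration levels must be strictly increasing")

    levels = np.concatenate([[0.0], achieved])
    conc = pd.DataFrame(
        {"glucose_mM": 0.0, "ethanol_mM": 0.0, "biomass_gL": 0.0,
         "time_h": np.nan},
        index=range(levels.size * replicate_count),
    )
    conc[REFERENCE_COLUMNS[component]] = np.repeat(levels, replicate_count)

    library = library or build_pure_library()
    noise = NoiseModel() if noise is None else noise
    if seed is not None:
        noise = noise.with_seed(seed)
    dataset = render_spectra(conc, library, noise=noise, biomass_mode="suspension_baseline",
                             role="single_compound", sample_prefix=f"{component[:3]}_tit")
    return TitrationSeries(
        component=component, concentrations=achieved,
        stock_concentration=stock_concentration, addition_volume=addition_volume,
        vessel_volume=vessel_volume, replicate_count=replicate_count, dataset=dataset,
    )


# ---------------------------------------------------------------------------
# Reference assay error
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceAssay:
    """Measurement error of the off-line reference assays.

    The reference concentrations attached to rendered datasets are what an
    HPLC (glucose, ethanol) or dry-weight determination (biomass) would
    report: the true value plus independent noise with a relative component
    and an absolute floor (readings near the detection limit may come out
    slightly negative, as chromatogram integration does).  Titration levels are assayed once per level (one
    sample per concentration), so replicates share the level's measured
    value.  All zero => references are the exact simulation truth.
    """

    relative_sd: float = 0.025
    floor_glucose: float = 4.0    # mM
    floor_ethanol: float = 4.0    # mM
    floor_biomass: float = 0.06   # g/L

    @classmethod
    def none(cls) -> "ReferenceAssay":
        return cls(0.0, 0.0, 0.0, 0.0)

    def _sd(self, analyte: str, truth: np.ndarray) -> np.ndarray:
        floor = {"glucose": self.floor_glucose, "ethanol": self.floor_ethanol,
                 "biomass": self.floor_biomass}[analyte]
        return np.maximum(self.relative_sd * np.abs(truth), floor)

    def measure(self, dataset: SpectralDataset, rng: np.random.Generator,
                per_level: str | None = None) -> SpectralDataset:
        """Replace the dataset's true references by noisy assay readings.

        ``per_level``: analyte name whose unique concentration levels share
        one assay reading (titration series); otherwise every row is assayed
        independently.
        """
        out = dataset.copy()
        if per_level is not None:
            key = out.meta[REFERENCE_COLUMNS[per_level]].to_numpy(dtype=float)
            levels, level_idx = np.unique(key, return_inverse=True)
        for analyte, col in REFERENCE_COLUMNS.items():
            truth = out.meta[col].to_numpy(dtype=float)
            if np.isnan(truth).all():
                continue
            if per_level is not None:
                # one assay sample per titration level covers all analytes
                level_truth = np.array([truth[level_idx == i][0] for i in range(levels.size)])
                noisy = level_truth + rng.normal(0.0, self._sd(analyte, level_truth))
                measured = noisy[level_idx]
            else:
                measured = truth + rng.normal(0.0, self._sd(analyte, truth))
            out.meta[col] = measured
        return out


# ---------------------------------------------------------------------------
# Transfer scenario factory
# ---------------------------------------------------------------------------

@dataclass
class TransferScenario:
    """All datasets of one calibration-transfer study, with known ground truth."""

    base_calibration: SpectralDataset   # three batch cultivations, pooled
    validation_batch: SpectralDataset   # one unseen batch
    fed_batch: SpectralDataset          # three-bolus fed-batch
    titrations: dict                    # analyte -> TitrationSeries
    library: PureComponentLibrary
    trajectories: dict


def generate_transfer_scenario(seed: int, params: KineticParams | None = None,
                               noise: NoiseModel | None = None, n_batches: int = 3,
                               n_feeds: int = 3, bolus: float = 40.0,
                               assay: ReferenceAssay | None = None,
                               library: PureComponentLibrary | None = None) -> TransferScenario:
    """Generate the full study layout: 3 calibration batches (~38 hourly
    samples), one unseen validation batch (~13 samples), one fed-batch with
    three glucose boluses, and one titration series per analyte.  Dataset
    reference values are assay readings (see :class:`ReferenceAssay`); the
    underlying trajectories in ``trajectories`` keep the exact truth."""
    params = params or KineticParams()
    noise = NoiseModel() if noise is None else noise
    assay = ReferenceAssay() if assay is None else assay
    library = library or build_pure_library()
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, _SEED_MAX, size=2 * n_batches + 8)
    assay_rng = np.random.default_rng(seeds[-1])

    batches, trajectories = [], {}
    for b in range(n_batches):
        traj = simulate_batch(params, seed=int(seeds[b]))
        trajectories[f"batch{b + 1}"] = traj
        batches.append(render_spectra(traj, library, noise=noise.with_seed(int(seeds[n_batches + b])),
                                      biomass_mode="fermentation_extinction", role="calibration",
                                      sample_prefix=f"batch{b + 1}_"))
    base_calibration = assay.measure(SpectralDataset.concat(batches), assay_rng)

    k = 2 * n_batches
    traj_val = simulate_batch(params, seed=int(seeds[k]))
    trajectories["validation"] = traj_val
    validation = assay.measure(
        render_spectra(traj_val, library, noise=noise.with_seed(int(seeds[k + 1])),
                       biomass_mode="fermentation_extinction", role="validation_batch",
                       sample_prefix="val_"), assay_rng)

    traj_fed = simulate_fedbatch(params, n_feeds=n_feeds, bolus=bolus, seed=int(seeds[k + 2]))
    trajectories["fed_batch"] = traj_fed
    fed = assay.measure(
        render_spectra(traj_fed, library, noise=noise.with_seed(int(seeds[k + 3])),
                       biomass_mode="fermentation_extinction", role="fed_batch",
                       sample_prefix="fed_"), assay_rng)

    titrations = {}
    for i, a in enumerate(ANALYTES):
        series = simulate_titration(a, noise=noise, seed=int(seeds[k + 4 + i]), library=library)
        series.dataset = assay.measure(series.dataset, assay_rng, per_level=a)
        titrations[a] = series
    return TransferScenario(base_calibration=base_calibration, validation_batch=validation,
                            fed_batch=fed, titrations=titrations, library=library,
                            trajectories=trajectories)
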