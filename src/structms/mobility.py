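"""Drift-tube ion mobility: dead-time calibration, reduced mobility and
collision cross sections (CCS).

An ion of charge z drifting a length L under voltage V in helium at
pressure P and temperature T arrives after

    t_a = t0 + t_d,        t_d = L^2 / (K V),

where t0 is the time spent outside the drift region (the dead time) and K
the mobility.  Standardising K to 273.15 K and 760 torr gives the reduced
mobility K0, and the Mason-Schamp relation converts K0 to the rotationally
averaged momentum-transfer collision cross section

    Omega = (3 z e) / (16 N) * sqrt(2 pi / (mu k_B T)) * 1 / K0,

with mu the ion-neutral reduced mass and N the gas number density at the
standard state.  Because t_d = c * P/(T V) with c = L^2 * 273.15/(760 K0),
the intensity-weighted mean arrival time is linear in x = P/(T V) across a
multi-voltage series, and t0 is the intercept of that regression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import constants as c

logger = logging.getLogger(__name__)

__all__ = [
    "DriftRun",
    "ATDSet",
    "DeadTimeFit",
    "CCSD",
    "fit_dead_time",
    "reduced_mobility",
    "mason_schamp_ccs",
    "ccsd_from_run",
    "regrid_ccsd",
]


@dataclass
class DriftRun:
    """Arrival-time histogram at one drift voltage, with gas conditions."""

    t: np.ndarray  # arrival time, ms, strictly increasing
    intensity: np.ndarray
    voltage: float  # V across the drift region
    pressure: float  # torr
    temperature: float  # K

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.t.shape != self.intensity.shape or self.t.ndim != 1:
            raise ValueError("t and intensity must be 1-D arrays of equal length")
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("arrival times must be >= 0 and strictly increasing")
        if min(self.voltage, self.pressure, self.temperature) <= 0:
            raise ValueError("V, P, T must be positive")


@dataclass
class ATDSet:
    """Multi-voltage arrival-time series for one ion species."""

    runs: list[DriftRun]
    drift_length: float = 5.1  # cm
    ion_mass: float = 0.0  # Da
    buffer_gas_mass: float = c.HELIUM_MASS_DA  # Da
    charge: int = 1

    def __post_init__(self) -> None:
        if len(self.runs) < 2:
            raise ValueError("need >= 2 runs for dead-time fitting")
        if self.drift_length <= 0:
            raise ValueError("drift length must be positive")
        if self.charge < 1:
            raise ValueError("charge must be a positive integer")


@dataclass
class DeadTimeFit:
    t0: float  # ms
    slope: float  # ms per (torr K^-1 V^-1)
    r_squared: float

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError("t0 must be non-negative")
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class CCSD:
    """Collision cross section distribution on an ascending Angstrom^2 grid."""

    grid: np.ndarray  # A^2
    intensity: np.ndarray
    charge: int
    label: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.grid.shape != self.intensity.shape or self.grid.ndim != 1:
            raise ValueError("grid and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.intensity.sum() <= 0:
            raise ValueError("CCSD has no intensity")

    @property
    def apex(self) -> float:
        return float(self.grid[int(np.argmax(self.intensity))])

    @property
    def centroid(self) -> float:
        return float(np.average(self.grid, weights=self.intensity))


def _dominant_peak_mean(run: DriftRun) -> float:
    """Intensity-weighted mean arrival time of the dominant ATD peak.

    Restricted to apex +/- 2*FWHM so that minor conformers do not bias the
    dead-time regression.
    """
    y = run.intensity
    t = run.t
    apex = int(np.argmax(y))
    half = y[apex] / 2.0
    lo = apex
    while lo > 0 and y[lo] > half:
        lo -= 1
    hi = apex
    while hi < y.size - 1 and y[hi] > half:
        hi += 1
    fwhm = max(t[hi] - t[lo], t[1] - t[0])
    sel = (t >= t[apex] - 2 * fwhm) & (t <= t[apex] + 2 * fwhm)
    return float(np.average(t[sel], weights=y[sel]))


def fit_dead_time(atdset: ATDSet) -> DeadTimeFit:
    """Regress mean arrival time on x = P/(T V) over the voltage series.

    The intercept is the dead time t0 (ms); a negative fitted intercept is
    clipped to zero with a warning.
    """
    x = np.array([r.pressure / (r.temperature * r.voltage) for r in atdset.runs])
    y = np.array([_dominant_peak_mean(r) for r in atdset.runs])
    if np.ptp(x) == 0:
        raise ValueError("all runs share P/(T*V); dead-time regression degenerate")
    res = stats.linregress(x, y)
    t0 = float(res.intercept)
    if t0 < 0:
        logger.warning("fitted dead time %.4f ms is negative; clipping to 0", t0)
        t0 = 0.0
    return DeadTimeFit(t0=t0, slope=float(res.slope), r_squared=float(res.rvalue**2))


def reduced_mobility(
    t_d: float, voltage: float, drift_length: float, pressure: float, temperature: float
) -> float:
    """Reduced mobility K0 (cm^2 V^-1 s^-1) from a drift time (ms).

    K = L^2/(t_d V); K0 = K * (P/760) * (273.15/T).
    """
    if t_d <= 0:
        raise ValueError("non-positive drift time (dead time over-subtracted?)")
    k = drift_length**2 / ((t_d * c.MS_TO_S) * voltage)
    return k * (pressure / c.STANDARD_PRESSURE_TORR) * (
        c.STANDARD_TEMPERATURE_K / temperature
    )


def mason_schamp_ccs(
    k0: float, charge: int, temperature: float, ion_mass: float, buffer_gas_mass: float
) -> float:
    """Mason-Schamp CCS (A^2) from reduced mobility (cm^2 V^-1 s^-1)."""
    if min(k0, charge, temperature, ion_mass) <= 0 or buffer_gas_mass <= 0:
        raise ValueError("all arguments must be positive")
    mu = ion_mass * buffer_gas_mass / (ion_mass + buffer_gas_mass) * c.DA_TO_KG
    k0_si = k0 * c.CM2_TO_M2
    omega_m2 = (
        3.0
        * charge
        * c.ELEMENTARY_CHARGE_C
        / (16.0 * c.GAS_NUMBER_DENSITY_STP)
        * math.sqrt(2.0 * math.pi / (mu * c.BOLTZMANN_J_PER_K * temperature))
        / k0_si
    )
    return omega_m2 * c.M2_TO_A2


def ccsd_from_run(run: DriftRun, t0: float, set_meta: ATDSet) -> CCSD:
    """Map an arrival-time histogram to a CCS distribution.

    Each bin's arrival time is converted to drift time t_d = t_a - t0 and
    then, in one closed-form step (the drift-time form of the Mason-Schamp
    relation), to a cross section

        Omega = (3 z e)/(16 N) sqrt(2 pi/(mu k_B T)) * (760/P)(T/273.15)
                * t_d V / L^2.

    Intensities are carried over bin-for-bin; bins with t_d <= 0 are dropped
    with a warning.
    """
    t_d = run.t - t0
    keep = t_d > 0
    if not np.any(keep):
        raise ValueError("all bins have non-physical drift time after t0 subtraction")
    if not np.all(keep):
        logger.warning("dropping %d bins with t_d <= 0", int((~keep).sum()))
    t_d = t_d[keep]
    mu = (
        set_meta.ion_mass
        * set_meta.buffer_gas_mass
        / (set_meta.ion_mass + set_meta.buffer_gas_mass)
        * c.DA_TO_KG
    )
    prefac = (
        3.0
        * set_meta.charge
        * c.ELEMENTARY_CHARGE_C
        / (16.0 * c.GAS_NUMBER_DENSITY_STP)
        * np.sqrt(2.0 * np.pi / (mu * c.BOLTZMANN_J_PER_K * run.temperature))
    )
    # K0 expressed through t_d: K0 = (L^2/(t_d V)) (P/760)(273.15/T), SI units.
    k0_si = (
        (set_meta.drift_length * 0.01) ** 2
        / ((t_d * c.MS_TO_S) * run.voltage)
        * (run.pressure / c.STANDARD_PRESSURE_TORR)
        * (c.STANDARD_TEMPERATURE_K / run.temperature)
    )
    omega = prefac / k0_si * c.M2_TO_A2
    return CCSD(
        grid=omega,
        intensity=run.intensity[keep],
        charge=set_meta.charge,
        label=f"{set_meta.charge}+ @ {run.voltage:g} V",
    )


def regrid_ccsd(ccsd: CCSD, step: float = 5.0) -> CCSD:
    """Resample a CCSD onto a uniform grid (A^2) by linear interpolation.

    The nonlinear t -> Omega mapping makes native bins unevenly spaced; a
    density-correct comparison across charge states first rescales the
    intensity by the local bin width (the |dt/dOmega| Jacobian is constant in
    t, so the per-bin width in Omega carries it) and then interpolates.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    widths = np.gradient(ccsd.grid)
    density = ccsd.intensity / widths
    grid = np.arange(ccsd.grid[0], ccsd.grid[-1] + step, step)
    if grid.size < 2:
        raise ValueError("grid too narrow for requested step")
    intensity = np.interp(grid, ccsd.grid, density) * step
    return CCSD(grid=grid, intensity=intensity, charge=ccsd.charge, label=ccsd.label)
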