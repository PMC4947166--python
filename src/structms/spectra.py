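"""Native-MS interpretation: charge-series assignment, neutral mass,
cofactor stoichiometry, adduct accounting and species intensity ratios.

A native mass spectrum of an intact protein complex shows an envelope of
peaks [M + nH]^n+ over a narrow range of charge states n.  Given centroided
peak positions, the neutral mass follows from each peak as
``M = z * (m/z - m_proton)``; consistency of that mass across several charge
states identifies the envelope.  Cofactor stoichiometry is read off as the
nearest integer number of ligand masses separating two envelopes, and metal
or buffer adducts are accounted as ``count * (neutral mass - displaced
protons * m_proton)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .constants import ADDUCT_SPECIES, PROTON_MASS_DA

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "ChargeSeries",
    "MassEstimate",
    "AdductComposition",
    "assign_charge_series",
    "determine_mass",
    "stoichiometry",
    "adduct_mass",
    "intensity_ratio",
]


@dataclass
class Spectrum:
    """Centroided peak list: m/z (Th, ascending) and intensities (counts)."""

    mz: np.ndarray
    intensity: np.ndarray
    cone_voltage: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(self.mz <= 0):
            raise ValueError("m/z values must be strictly positive")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z values must be sorted strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    def __len__(self) -> int:
        return self.mz.size


@dataclass
class ChargeSeries:
    """A set of peaks assigned to consecutive charge states of one species."""

    charges: list[int]
    peak_indices: list[int]
    assumed_adduct_mass: float = PROTON_MASS_DA

    def __post_init__(self) -> None:
        if len(self.charges) != len(self.peak_indices):
            raise ValueError("charges and peak_indices must align")
        if len(self.charges) == 0:
            raise ValueError("empty charge series")
        if any(z <= 0 for z in self.charges):
            raise ValueError("charges must be positive")
        diffs = np.diff(self.charges)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("charges must be strictly monotone")
        if len(set(self.peak_indices)) != len(self.peak_indices):
            raise ValueError("one peak per charge state")


@dataclass
class MassEstimate:
    mass: float  # Da, intensity-weighted mean over charge states
    sd: float  # Da, intensity-weighted standard deviation
    per_charge_masses: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class AdductComposition:
    """Adduct inventory: (species name, count, neutral mass Da, displaced H+ per unit).

    ``neutral_mass``/``displaced_protons`` may be None for species listed in
    the built-in table (Na, K, Mg, Ca, Mn, Fe, Zn, H2O, NH4).
    """

    components: list[tuple[str, int, float | None, int | None]]

    def resolved(self) -> list[tuple[str, int, float, int]]:
        out = []
        for name, count, mass, displ in self.components:
            if count < 0:
                raise ValueError(f"negative count for {name}")
            if mass is None or displ is None:
                if name not in ADDUCT_SPECIES:
                    raise ValueError(
                        f"unknown adduct species {name!r} with no mass provided"
                    )
                tmass, tdispl = ADDUCT_SPECIES[name]
                mass = tmass if mass is None else mass
                displ = tdispl if displ is None else displ
            if mass <= 0:
                raise ValueError(f"non-positive mass for {name}")
            out.append((name, count, mass, displ))
        return out


def _neutral_mass(mz: float, z: int, carrier: float = PROTON_MASS_DA) -> float:
    return z * mz - z * carrier


def assign_charge_series(
    spectrum: Spectrum,
    z_min: int,
    z_max: int,
    tol_ppm: float = 100.0,
) -> list[ChargeSeries]:
    """Partition peaks into consistent charge-state series.

    Every (peak, charge) pair is taken as an anchor hypothesis for a neutral
    mass; the hypothesis is extended by looking for peaks at the predicted
    m/z of every other charge in ``[z_min, z_max]`` within ``tol_ppm``.
    Candidate series (>= 2 peaks, per-charge mass spread <= tol_ppm) are then
    selected greedily by summed intensity (longest series breaks ties), each
    peak used at most once.  Returns an empty list when nothing consistent is
    found.
    """
    if len(spectrum) < 2:
        raise ValueError("need at least 2 peaks")
    if not (1 <= z_min < z_max):
        raise ValueError("require 1 <= z_min < z_max")

    mz = spectrum.mz
    candidates: dict[frozenset, tuple[float, int, list[int], list[int]]] = {}
    for i in range(len(spectrum)):
        for z_anchor in range(z_min, z_max + 1):
            mass = _neutral_mass(mz[i], z_anchor)
            if mass <= 0:
                continue
            charges: list[int] = []
            idx: list[int] = []
            masses: list[float] = []
            for z in range(z_min, z_max + 1):
                pred = (mass + z * PROTON_MASS_DA) / z
                j = int(np.argmin(np.abs(mz - pred)))
                if abs(mz[j] - pred) / pred * 1e6 <= tol_ppm:
                    charges.append(z)
                    idx.append(j)
                    masses.append(_neutral_mass(mz[j], z))
            if len(idx) < 2 or len(set(idx)) != len(idx):
                continue
            # consecutive-charge requirement
            if any(b - a != 1 for a, b in zip(charges, charges[1:])):
                continue
            m_arr = np.array(masses)
            spread = (m_arr.max() - m_arr.min()) / m_arr.mean() * 1e6
            if spread > tol_ppm:
                continue
            key = frozenset(zip(charges, idx))
            if key not in candidates:
                total = float(spectrum.intensity[idx].sum())
                candidates[key] = (total, len(idx), charges, idx)

    # Greedy: summed intensity desc, longer series first on ties.
    order = sorted(candidates.values(), key=lambda c: (-c[0], -c[1]))
    used: set[int] = set()
    out: list[ChargeSeries] = []
    for total, _n, charges, idx in order:
        if used.intersection(idx):
            continue
        used.update(idx)
        out.append(ChargeSeries(charges=charges, peak_indices=idx))
    return out


def determine_mass(spectrum: Spectrum, series: ChargeSeries) -> MassEstimate:
    """Intensity-weighted neutral mass from an assigned charge series."""
    if len(series.charges) == 0:
        raise ValueError("empty charge series")
    masses = []
    weights = []
    for z, i in zip(series.charges, series.peak_indices):
        masses.append(z * spectrum.mz[i] - z * series.assumed_adduct_mass)
        weights.append(spectrum.intensity[i])
    m = np.asarray(masses)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        w = np.ones_like(w)
    mean = float(np.average(m, weights=w))
    var = float(np.average((m - mean) ** 2, weights=w))
    return MassEstimate(mass=mean, sd=math.sqrt(max(var, 0.0)), per_charge_masses=masses)


def stoichiometry(
    mass_bound: float,
    mass_apo: float,
    ligand_mass: float,
    mode: str = "adduct_aware",
    negative_slack: float = 0.1,
) -> tuple[int, float]:
    """Ligand count and residual mass separating bound and apo species.

    ``mode="adduct_aware"`` (default) assumes unresolved salt adducts can
    only add mass, so the count is the largest non-negative integer leaving
    a residual above -``negative_slack``*ligand (the slack absorbs centroid
    noise): a 113,609 vs 112,266.4 Da pair with a 525 Da ligand gives
    count 2 with +292.6 Da of adducts, not count 3 with an unphysical
    -232 Da.  ``mode="nearest"`` rounds (mass_bound - mass_apo)/ligand to
    the nearest non-negative integer instead.
    """
    if ligand_mass <= 0:
        raise ValueError("ligand_mass must be positive")
    delta = mass_bound - mass_apo
    if mode == "nearest":
        count = int(round(delta / ligand_mass))
    elif mode == "adduct_aware":
        count = int(math.floor(delta / ligand_mass + negative_slack))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if count < 0:
        if delta < -0.5 * ligand_mass:
            logger.warning(
                "mass_bound below mass_apo by more than half a ligand (%.1f Da); "
                "count clamped to 0",
                delta,
            )
        count = 0
    residual = delta - count * ligand_mass
    return count, residual


def adduct_mass(composition: AdductComposition) -> float:
    """Net mass shift of a salt-adduct composition.

    Each unit contributes its neutral mass minus the mass of the protons it
    displaces (a K+ adduct on a protonated ion replaces one H+, adding
    38.9637 - 1.00728 = 37.956 Da).
    """
    total = 0.0
    for _name, count, mass, displ in composition.resolved():
        total += count * (mass - displ * PROTON_MASS_DA)
    return total


def intensity_ratio(
    spectrum: Spectrum, series_a: ChargeSeries, series_b: ChargeSeries
) -> float:
    """Ratio of summed peak intensities of two charge series (a / b)."""
    ia = float(spectrum.intensity[list(series_a.peak_indices)].sum())
    ib = float(spectrum.intensity[list(series_b.peak_indices)].sum())
    if ib == 0:
        raise ZeroDivisionError("series_b has zero summed intensity")
    return ia / ib
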