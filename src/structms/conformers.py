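"""Conformer-family deconvolution of CCS distributions.

A protein complex's CCSD is modelled as a sum of Gaussian conformational
families.  Families are fitted once on a reference distribution (centres,
widths and amplitudes all free), then retained — centres and widths frozen —
across other charge states and cofactor stoichiometries, where only the
non-negative amplitudes are refitted.  Fractional populations are reported
as per-family Gaussian areas, and collision-induced unfolding series are
summarised by the intensity-weighted centroid per activation voltage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize
from scipy.optimize import nnls

from .mobility import CCSD, DriftRun

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianFamily",
    "FamilyFit",
    "UnfoldingProfile",
    "fit_families",
    "refit_amplitudes",
    "population_table",
    "unfolding_profile",
    "select_k_bic",
]

SQRT2PI = math.sqrt(2.0 * math.pi)


@dataclass
class GaussianFamily:
    centre: float  # A^2
    sigma: float  # A^2
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-height Gaussian evaluated on ``grid``."""
        return np.exp(-0.5 * ((grid - self.centre) / self.sigma) ** 2)


@dataclass
class FamilyFit:
    families: list[GaussianFamily]
    amplitudes: np.ndarray  # peak heights, one per family, >= 0
    key: str = ""  # e.g. "apo 21+"
    residual_rms: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.size != len(self.families):
            raise ValueError("one amplitude per family")
        if np.any(self.amplitudes < -1e-12):
            raise ValueError("amplitudes must be non-negative")
        centres = [f.centre for f in self.families]
        if any(b <= a for a, b in zip(centres, centres[1:])):
            raise ValueError("family centres must be strictly increasing")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be non-negative")

    @property
    def areas(self) -> np.ndarray:
        """Per-family Gaussian areas (amplitude * sigma * sqrt(2 pi))."""
        sig = np.array([f.sigma for f in self.families])
        return self.amplitudes * sig * SQRT2PI

    def model(self, grid: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(grid, dtype=float))
        for amp, fam in zip(self.amplitudes, self.families):
            out += amp * fam.profile(grid)
        return out


@dataclass
class UnfoldingProfile:
    points: list[tuple[float, float]]  # (cone voltage V, centroid A^2 or ms)
    onset_voltage: float | None = None
    axis: str = "ccs"  # "ccs" or "drift_time"


def _mixture_residual(params: Parameters, grid: np.ndarray, y: np.ndarray, k: int):
    model = np.zeros_like(y)
    for i in range(k):
        a = params[f"a{i}"].value
        cn = params[f"c{i}"].value
        s = params[f"s{i}"].value
        model += a * np.exp(-0.5 * ((grid - cn) / s) ** 2)
    return model - y


def fit_families(
    ccsd: CCSD,
    k: int,
    init_centres: list[float] | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> FamilyFit:
    """Fit ``k`` Gaussian families to a reference CCSD.

    Nonlinear least squares over k (centre, sigma, amplitude) triples with
    amplitudes constrained non-negative.  Unless ``init_centres`` is given,
    centres start equally spaced across the CCSD support (where intensity
    exceeds 1% of the maximum) and ``n_restarts`` seeded multi-start jitters
    guard against local minima.  Families are returned sorted by centre.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = ccsd.grid
    y = ccsd.intensity
    if np.count_nonzero(y) < 3 * k:
        raise ValueError("CCSD too degenerate for requested k")

    support = grid[y > 0.01 * y.max()]
    lo, hi = float(support.min()), float(support.max())
    span = max(hi - lo, float(grid[1] - grid[0]))
    if init_centres is None:
        init_centres = list(np.linspace(lo + span / (2 * k), hi - span / (2 * k), k))
    if len(init_centres) != k:
        raise ValueError("init_centres length must equal k")
    sigma0 = span / (4.0 * k)
    rng = np.random.default_rng(seed)

    best = None
    last_exc: Exception | None = None
    for restart in range(max(1, n_restarts)):
        jitter = np.zeros(k) if restart == 0 else rng.normal(0.0, span / (6 * k), size=k)
        params = Parameters()
        for i in range(k):
            c0 = float(np.clip(init_centres[i] + jitter[i], lo, hi))
            params.add(f"a{i}", value=float(y.max()) / k, min=0.0)
            params.add(f"c{i}", value=c0, min=lo - span, max=hi + span)
            params.add(f"s{i}", value=sigma0, min=span * 1e-4, max=span)
        try:
            res = minimize(
                _mixture_residual, params, args=(grid, y, k), method="leastsq"
            )
        except Exception as exc:  # pragma: no cover - lmfit rarely raises here
            last_exc = exc
            continue
        cost = float(np.sum(res.residual**2))
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise RuntimeError(f"family fit failed to converge: {last_exc}")

    cost, res = best
    triples = sorted(
        (
            (res.params[f"c{i}"].value, res.params[f"s{i}"].value, res.params[f"a{i}"].value)
            for i in range(k)
        ),
        key=lambda t: t[0],
    )
    families = []
    amps = []
    for i, (cn, s, a) in enumerate(triples):
        families.append(GaussianFamily(centre=cn, sigma=s, label=f"family{i + 1}"))
        amps.append(max(a, 0.0))
    # merge-degenerate centres would violate the strictly-increasing invariant
    for a, b in zip(families, families[1:]):
        if b.centre <= a.centre:
            b.centre = a.centre + 1e-9
    rms = math.sqrt(cost / grid.size)
    return FamilyFit(families=families, amplitudes=np.array(amps), key=ccsd.label, residual_rms=rms)


def refit_amplitudes(ccsd: CCSD, families: list[GaussianFamily]) -> FamilyFit:
    """Refit only the amplitudes of frozen families to another CCSD.

    Non-negative linear least squares (deterministic).  Warns when the frozen
    families cannot explain the distribution at all (all-zero solution).
    """
    if not families:
        raise ValueError("no families given")
    design = np.column_stack([f.profile(ccsd.grid) for f in families])
    amps, _ = nnls(design, ccsd.intensity)
    if np.all(amps == 0):
        logger.warning("all amplitudes zero: families do not explain CCSD %r", ccsd.label)
    resid = ccsd.intensity - design @ amps
    rms = float(np.sqrt(np.mean(resid**2)))
    return FamilyFit(families=list(families), amplitudes=amps, key=ccsd.label, residual_rms=rms)


def population_table(fits: list[FamilyFit]) -> pd.DataFrame:
    """Fractional population of each family per fitted species/charge state.

    All fits must share one family set; rows are fits (indexed by key),
    columns are family centres, entries are Gaussian-area fractions summing
    to 1 per row.
    """
    if not fits:
        raise ValueError("no fits given")
    ref = [(f.centre, f.sigma) for f in fits[0].families]
    rows = {}
    for fit in fits:
        if [(f.centre, f.sigma) for f in fit.families] != ref:
            raise ValueError("all fits must share one family set")
        areas = fit.areas
        total = areas.sum()
        if total <= 0:
            raise ValueError(f"fit {fit.key!r} has zero total population")
        rows[fit.key] = areas / total
    cols = [f"{f.centre:.0f}" for f in fits[0].families]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def unfolding_profile(
    runs_by_voltage: list[tuple[float, DriftRun | CCSD]],
    onset_threshold: float = 0.10,
) -> UnfoldingProfile:
    """Collision-induced unfolding summary over an activation-voltage series.

    The intensity-weighted centroid (drift-time axis for raw runs, CCS axis
    for CCSDs) is computed per voltage; the onset is the first voltage at
    which the centroid exceeds the lowest-voltage baseline by
    ``onset_threshold`` (fractional), or None if it never does.
    """
    if len(runs_by_voltage) < 3:
        raise ValueError("need >= 3 voltages")
    voltages = [v for v, _ in runs_by_voltage]
    if any(b <= a for a, b in zip(voltages, voltages[1:])):
        raise ValueError("voltages must be strictly increasing")
    points = []
    axis = None
    for v, obj in runs_by_voltage:
        if isinstance(obj, CCSD):
            cen = obj.centroid
            this_axis = "ccs"
        elif isinstance(obj, DriftRun):
            cen = float(np.average(obj.t, weights=obj.intensity))
            this_axis = "drift_time"
        else:
            raise TypeError("entries must be DriftRun or CCSD")
        axis = axis or this_axis
        if this_axis != axis:
            raise ValueError("mixed DriftRun/CCSD series")
        points.append((float(v), cen))
    baseline = points[0][1]
    onset = None
    for v, cen in points[1:]:
        if cen > baseline * (1.0 + onset_threshold):
            onset = v
            break
    return UnfoldingProfile(points=points, onset_voltage=onset, axis=axis)


def select_k_bic(ccsd: CCSD, k_max: int = 6, seed: int = 0) -> tuple[int, list[float]]:
    """BIC helper for choosing the number of families.

    Treats the residual sum of squares as a Gaussian likelihood:
    BIC = n ln(RSS/n) + 3k ln(n).  Returns (best k, per-k BIC list).
    """
    n = ccsd.grid.size
    bics = []
    for k in range(1, k_max + 1):
        try:
            fit = fit_families(ccsd, k, seed=seed)
            rss = max(fit.residual_rms**2 * n, 1e-300)
        except (ValueError, RuntimeError):
            bics.append(np.inf)
            continue
        bics.append(n * math.log(rss / n) + 3 * k * math.log(n))
    return int(np.argmin(bics)) + 1, bics
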