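"""Seeded generators for every input the analysis chain consumes.

Each generator is a pure function of its arguments (including the seed) and
returns its artefact together with a :class:`GroundTruth` carrying the
generating parameters, so that every analysis stage can be exercised
against known truth with no external data.

Defaults emulate the study system: a ~112 kDa homodimer electrosprayed at
charge states 19-23+ with an optional 525 Da cofactor, a 5.1 cm helium
drift tube read out at six voltages between 20 and 50 V at ~4 torr / 303 K,
conformer families centred on 4,550 / 5,085 / 5,736 / 6,400 (and for the
apo 22+ ion 7,042) A^2, and apo/holo deuterium-uptake tables with exposure
times 0, 0.25, 5, 60 and 240 min in triplicate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as c
from .geometry import Structure
from .hdx import PeptideUptake, UptakeTable
from .mobility import ATDSet, CCSD, DriftRun, mason_schamp_ccs
from .spectra import Spectrum

__all__ = [
    "GroundTruth",
    "gen_native_spectrum",
    "gen_atdset",
    "gen_ccsd",
    "gen_hdx_pair",
    "gen_toy_structure",
    "gen_ciu_series",
    "DEFAULT_FAMILY_CENTRES",
    "DEFAULT_HDX_REGIONS",
]

# Conformer-family centres (A^2) of the dimer, smallest to largest; the
# fifth appears only in the apo 22+ ion.
DEFAULT_FAMILY_CENTRES = (4550.0, 5085.0, 5736.0, 6400.0, 7042.0)

# Residue ranges with programmed protection changes in the apo state:
# multiplier < 1 destabilises apo (more apo uptake, positive difference),
# > 1 protects apo (more holo uptake, negative difference).
DEFAULT_HDX_REGIONS = {
    (187, 197): 0.2,
    (223, 240): 0.2,
    (441, 450): 0.2,
    (108, 123): 5.0,
    (460, 465): 5.0,
}


@dataclass
class GroundTruth:
    """Generating parameters of a synthetic artefact."""

    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=1, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def gen_native_spectrum(
    mass: float,
    z_range: tuple[int, int] = (19, 23),
    envelope_shape: str = "gaussian",
    ligand_mass: float = 525.0,
    ligand_counts: dict[int, float] | None = None,
    adduct_tail: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[Spectrum, GroundTruth]:
    """Synthetic native-MS charge-state envelope of a (ligand-bound) complex.

    One peak per (ligand count, charge): m/z = (M + n_lig*L + z*mH)/z, with
    an intensity envelope over z, species weighted by ``ligand_counts``
    (default apo only).  ``adduct_tail`` shifts each apex by tail/z Th,
    emulating unresolved salt adducts; ``noise`` adds Gaussian m/z jitter.
    """
    rng = np.random.default_rng(seed)
    z_min, z_max = z_range
    if not (1 <= z_min <= z_max):
        raise ValueError("invalid charge range")
    counts = ligand_counts or {0: 1.0}
    zs = np.arange(z_min, z_max + 1)
    if envelope_shape == "gaussian":
        mid = (z_min + z_max) / 2.0
        env = np.exp(-0.5 * ((zs - mid) / (max(z_max - z_min, 1) / 4.0)) ** 2)
    elif envelope_shape == "flat":
        env = np.ones_like(zs, dtype=float)
    else:
        raise ValueError(f"unknown envelope shape {envelope_shape!r}")

    mzs, intens = [], []
    for n_lig, weight in sorted(counts.items()):
        if weight < 0:
            raise ValueError("ligand weights must be non-negative")
        m_species = mass + n_lig * ligand_mass
        for z, e in zip(zs, env):
            mz = (m_species + z * c.PROTON_MASS_DA) / z + adduct_tail / z
            if noise > 0:
                mz += rng.normal(0.0, noise)
            mzs.append(mz)
            intens.append(1000.0 * weight * e)
    order = np.argsort(mzs)
    spectrum = Spectrum(
        mz=np.asarray(mzs)[order], intensity=np.asarray(intens)[order],
        label=f"synthetic M={mass:g}",
    )
    truth = GroundTruth(
        params=dict(
            mass=mass, z_range=list(z_range), ligand_mass=ligand_mass,
            ligand_counts={str(k): v for k, v in counts.items()},
            adduct_tail=adduct_tail, noise=noise, seed=seed,
        )
    )
    return spectrum, truth


def _drift_time_ms(k0: float, voltage: float, length_cm: float, pressure: float, temperature: float) -> float:
    k = k0 * (c.STANDARD_PRESSURE_TORR / pressure) * (temperature / c.STANDARD_TEMPERATURE_K)
    return 1e3 * length_cm**2 / (k * voltage)


def gen_atdset(
    k0_components: list[tuple[float, float]],
    charge: int,
    ion_mass: float,
    buffer_gas_mass: float = c.HELIUM_MASS_DA,
    drift_length: float = 5.1,
    voltages: tuple[float, ...] | None = None,
    pressure: float = 4.0,
    temperature: float = 303.15,
    t0: float = 0.25,
    broadening: bool = True,
    p_jitter: float = 0.005,
    timing_noise: float = 0.0,
    dt: float = 0.002,
    seed: int = 0,
) -> tuple[ATDSet, GroundTruth]:
    """Multi-voltage arrival-time distributions from known reduced mobilities.

    Per voltage V, each (K0, weight) component contributes a Gaussian peak at
    t0 + t_d(K0, V, P, T).  With ``broadening`` the width is the
    diffusion-limited drift-tube expression
    sigma_t = t_d * sqrt(16 kB T ln2 / (z e V)) / (2 sqrt(2 ln2)); otherwise
    the component is a delta in the nearest bin.  The cell pressure is
    jittered per run by ``p_jitter`` (fractional) to exercise the dead-time
    regression (temperature is held at its stable set point, so the mean
    arrival time stays exactly linear in P/(T V)); ``timing_noise`` adds a
    per-run arrival-time offset drawn from N(0, timing_noise * t_d) of the
    dominant component.
    """
    if abs(sum(w for _, w in k0_components) - 1.0) > 1e-9:
        raise ValueError("component weights must sum to 1")
    rng = np.random.default_rng(seed)
    if voltages is None:
        voltages = tuple(np.linspace(20.0, 50.0, 6))
    k0_dom = max(k0_components, key=lambda kw: kw[1])[0]
    runs = []
    run_meta = []
    for v in voltages:
        p_r = pressure * (1.0 + rng.normal(0.0, p_jitter)) if p_jitter else pressure
        t_r = temperature
        centres = []
        sigmas = []
        for k0, w in k0_components:
            # the ion's CCS is fixed; Mason-Schamp then makes K0 scale as
            # 1/sqrt(T), so the nominal-temperature K0 is rescaled per run
            k0_run = k0 * math.sqrt(temperature / t_r)
            td = _drift_time_ms(k0_run, v, drift_length, p_r, t_r)
            if broadening:
                sig = (
                    td
                    * math.sqrt(16.0 * c.BOLTZMANN_J_PER_K * t_r * math.log(2) / (charge * c.ELEMENTARY_CHARGE_C * v))
                    / (2.0 * math.sqrt(2.0 * math.log(2)))
                )
            else:
                sig = 0.0
            centres.append(t0 + td)
            sigmas.append(sig)
        shift = rng.normal(0.0, timing_noise * _drift_time_ms(k0_dom, v, drift_length, p_r, t_r)) if timing_noise else 0.0
        smax = max(max(sigmas), 5 * dt)
        tmin = max(0.0, min(centres) - 8 * smax)
        tmax = max(centres) + 8 * smax
        t = np.arange(tmin, tmax, dt)
        y = np.zeros_like(t)
        for (k0, w), centre, sig in zip(k0_components, centres, sigmas):
            if sig > 0:
                y += 1000.0 * w * np.exp(-0.5 * ((t - centre - shift) / sig) ** 2)
            else:
                y[int(np.argmin(np.abs(t - centre - shift)))] += 1000.0 * w
        runs.append(DriftRun(t=t, intensity=y, voltage=float(v), pressure=p_r, temperature=t_r))
        run_meta.append(dict(voltage=float(v), pressure=p_r, temperature=t_r, shift=shift))
    atdset = ATDSet(runs=runs, drift_length=drift_length, ion_mass=ion_mass,
                    buffer_gas_mass=buffer_gas_mass, charge=charge)
    true_ccs = [
        mason_schamp_ccs(k0, charge, temperature, ion_mass, buffer_gas_mass)
        for k0, _ in k0_components
    ]
    truth = GroundTruth(
        params=dict(
            k0_components=[list(kw) for kw in k0_components], true_ccs=true_ccs,
            charge=charge, ion_mass=ion_mass, buffer_gas_mass=buffer_gas_mass,
            drift_length=drift_length, t0=t0, pressure=pressure,
            temperature=temperature, runs=run_meta, seed=seed,
        )
    )
    return atdset, truth


def gen_ccsd(
    families: list[tuple[float, float, float]],
    n_samples: int = 20000,
    grid: np.ndarray | None = None,
    charge: int = 21,
    label: str = "",
    seed: int = 0,
) -> tuple[CCSD, GroundTruth]:
    """CCSD sampled from a Gaussian mixture of (centre, sigma, weight) families."""
    w = np.array([f[2] for f in families])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("family weights must sum to 1")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(families), size=n_samples, p=w)
    centres = np.array([f[0] for f in families])
    sigmas = np.array([f[1] for f in families])
    draws = rng.normal(centres[comp], sigmas[comp])
    if grid is None:
        lo = centres.min() - 5 * sigmas.max()
        hi = centres.max() + 5 * sigmas.max()
        grid = np.arange(lo, hi, 25.0)
    edges = np.concatenate([grid - np.diff(grid, prepend=grid[0] - (grid[1] - grid[0])) / 2,
                            [grid[-1] + (grid[-1] - grid[-2]) / 2]])
    hist, _ = np.histogram(draws, bins=edges)
    ccsd = CCSD(grid=np.asarray(grid, dtype=float), intensity=hist.astype(float),
                charge=charge, label=label or f"synthetic {charge}+")
    truth = GroundTruth(
        params=dict(families=[list(f) for f in families], n_samples=n_samples, seed=seed, charge=charge)
    )
    return ccsd, truth


def _random_sequence(n: int, rng: np.random.Generator, proline_frac: float = 0.05) -> str:
    residues = list("ACDEFGHIKLMNQRSTVWY")
    seq = [residues[i] for i in rng.integers(0, len(residues), size=n)]
    n_pro = int(proline_frac * n)
    pos = rng.choice(np.arange(1, n), size=n_pro, replace=False)
    for p in pos:
        seq[p] = "P"
    return "".join(seq)


def _default_peptide_map(n_residues: int, length: int = 12, step: int = 6) -> list[tuple[int, int]]:
    out = []
    s = 1
    while s + length - 1 <= n_residues:
        out.append((s, s + length - 1))
        s += step
    if out and out[-1][1] < n_residues:
        out.append((n_residues - length + 1, n_residues))
    return out


def gen_hdx_pair(
    n_residues: int = 505,
    peptide_map: list[tuple[int, int]] | None = None,
    base_protection: float = 100.0,
    delta_regions: dict[tuple[int, int], float] | None = None,
    timepoints: tuple[float, ...] = (0.0, 0.25, 5.0, 60.0, 240.0),
    noise_sd: float = 0.05,
    replicates: int = 3,
    k_intrinsic: float = 1.0,
    seed: int = 0,
) -> tuple[UptakeTable, UptakeTable, GroundTruth]:
    """Apo/holo peptide uptake tables from a protection-factor model.

    Each residue exchanges at k = k_intrinsic / PF (min^-1); peptide uptake
    at exposure t is the sum of 1 - exp(-k t) over its exchangeable amides
    (all but the first residue and prolines).  ``delta_regions`` multiplies
    the APO protection factor over residue ranges: multipliers < 1 give the
    apo state more uptake there (positive apo-holo difference), > 1 the
    holo state.  Gaussian replicate noise is applied at t > 0 only.
    """
    if delta_regions is None:
        delta_regions = dict(DEFAULT_HDX_REGIONS)
    covered = np.zeros(n_residues, dtype=int)
    for (s, e), _f in delta_regions.items():
        if not (1 <= s <= e <= n_residues):
            raise ValueError(f"region {(s, e)} outside [1, {n_residues}]")
        covered[s - 1 : e] += 1
    if np.any(covered > 1):
        raise ValueError("overlapping delta regions are contradictory")

    rng = np.random.default_rng(seed)
    seq = _random_sequence(n_residues, rng)
    pf_holo = np.full(n_residues, base_protection)
    pf_apo = pf_holo.copy()
    for (s, e), f in delta_regions.items():
        pf_apo[s - 1 : e] *= f
    tps = np.asarray(timepoints, dtype=float)
    if peptide_map is None:
        peptide_map = _default_peptide_map(n_residues)

    def build(state: str, pf: np.ndarray) -> UptakeTable:
        peptides = []
        for s, e in peptide_map:
            pep_seq = seq[s - 1 : e]
            # exchangeable: residues s+1..e, excluding prolines
            res_idx = [
                i for i in range(s, e)  # 0-based indices s..e-1 are residues s+1..e
                if seq[i] != "P"
            ]
            k = k_intrinsic / pf[res_idx]
            clean = np.array([np.sum(1.0 - np.exp(-k * t)) for t in tps])
            uptake = np.tile(clean[:, None], (1, replicates))
            if noise_sd > 0:
                jitter = rng.normal(0.0, noise_sd, size=uptake.shape)
                jitter[tps == 0, :] = 0.0
                uptake = np.clip(uptake + jitter, 0.0, None)
            peptides.append(
                PeptideUptake(sequence=pep_seq, start=s, end=e, timepoints=tps, uptake=uptake)
            )
        return UptakeTable(state=state, peptides=peptides)

    apo = build("apo", pf_apo)
    holo = build("holo", pf_holo)
    truth = GroundTruth(
        params=dict(
            n_residues=n_residues, sequence=seq, base_protection=base_protection,
            delta_regions={f"{s}-{e}": f for (s, e), f in delta_regions.items()},
            positive_regions=[[s, e] for (s, e), f in delta_regions.items() if f < 1],
            negative_regions=[[s, e] for (s, e), f in delta_regions.items() if f > 1],
            timepoints=list(tps), noise_sd=noise_sd, replicates=replicates,
            k_intrinsic=k_intrinsic, seed=seed,
            peptide_map=[list(p) for p in peptide_map],
        )
    )
    return apo, holo, truth


def gen_toy_structure(kind: str, params: dict | None = None, seed: int = 0) -> tuple[Structure, GroundTruth]:
    """Idealised structures with closed-form reference quantities.

    kinds: ``sphere-cloud`` (n points uniform in a ball of radius R;
    Rg -> R sqrt(3/5) as n grows), ``dumbbell`` (two spheres; exact Rg and
    spherical-cap SASA), ``helix`` (CA-only alpha-helix trace).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "sphere-cloud":
        n = int(params.pop("n", 500))
        big_r = float(params.pop("R", 20.0))
        atom_r = float(params.pop("atom_radius", 2.7))
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        radii = big_r * rng.random(n) ** (1.0 / 3.0)
        coords = dirs * radii[:, None]
        struct = Structure(elements=["C"] * n, coords=coords, radii=np.full(n, atom_r), label="sphere-cloud")
        truth = GroundTruth(params=dict(kind=kind, n=n, R=big_r, atom_radius=atom_r,
                                        expected_rg_limit=big_r * math.sqrt(3.0 / 5.0), seed=seed))
    elif kind == "dumbbell":
        r = float(params.pop("r", 2.0))
        sep = float(params.pop("separation", 6.0))
        coords = np.array([[-sep / 2, 0.0, 0.0], [sep / 2, 0.0, 0.0]])
        struct = Structure(elements=["X", "X"], coords=coords, radii=np.array([r, r]), label="dumbbell")
        truth = GroundTruth(params=dict(kind=kind, r=r, separation=sep, exact_rg=sep / 2.0, seed=seed))
    elif kind == "helix":
        n = int(params.pop("n_residues", 20))
        rise, hel_r, turn = 1.5, 2.3, math.radians(100.0)
        i = np.arange(n)
        coords = np.column_stack([hel_r * np.cos(turn * i), hel_r * np.sin(turn * i), rise * i])
        struct = Structure(elements=["C"] * n, coords=coords, radii=np.full(n, 2.7),
                           label="helix", atom_names=["CA"] * n)
        truth = GroundTruth(params=dict(kind=kind, n_residues=n, rise=rise, radius=hel_r, seed=seed))
    else:
        raise ValueError(f"unknown toy structure kind {kind!r}")
    if params:
        raise ValueError(f"unused params: {sorted(params)}")
    return struct, truth


def gen_ciu_series(
    voltages: tuple[float, ...] = (60.0, 92.0, 124.0, 156.0, 188.0, 220.0),
    compact_centre: float = 5085.0,
    extended_centre: float = 6400.0,
    sigma: float = 150.0,
    transition_voltage: float | None = 180.0,
    n_samples: int = 5000,
    charge: int = 21,
    seed: int = 0,
) -> tuple[list[tuple[float, CCSD]], GroundTruth]:
    """Collision-induced unfolding series: CCSDs over activation voltages.

    Below ``transition_voltage`` the compact conformer dominates; at and
    above it the population switches to the extended conformer.  With
    ``transition_voltage=None`` the series stays compact throughout (the
    cofactor-stabilised phenotype).
    """
    series = []
    grid = np.arange(compact_centre - 5 * sigma, extended_centre + 5 * sigma, 25.0)
    for i, v in enumerate(voltages):
        unfolded = transition_voltage is not None and v >= transition_voltage
        fams = (
            [(compact_centre, sigma, 0.1), (extended_centre, sigma, 0.9)]
            if unfolded
            else [(compact_centre, sigma, 0.9), (extended_centre, sigma, 0.1)]
        )
        ccsd, _ = gen_ccsd(fams, n_samples=n_samples, grid=grid, charge=charge,
                           label=f"ciu {v:g} V", seed=seed * 1000 + i)
        series.append((float(v), ccsd))
    truth = GroundTruth(
        params=dict(voltages=list(voltages), compact_centre=compact_centre,
                    extended_centre=extended_centre, sigma=sigma,
                    transition_voltage=transition_voltage, n_samples=n_samples, seed=seed)
    )
    return series, truth
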