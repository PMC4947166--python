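"""Geometric collision-cross-section models and shape summaries.

Three CCS estimators on atomic (or idealised) hard-sphere models:

* ``sphere_limit_ccs`` — the smallest cross section a globular protein of
  mass Mw could present, from a uniform-density sphere (rho = 0.904 Da/A^3)
  scaled from geometric area to a helium CCS.
* ``projection_approx_ccs`` — orientation-averaged shadow area (PA), a
  lower bound to scattering models.
* ``ehss_ccs`` — exact hard-sphere scattering (EHSS): probe trajectories are
  reflected specularly off atomic hard spheres, and the momentum-transfer
  weight (1 - cos chi) of the deflection angle chi is averaged over impact
  points and orientations.

Plus radius of gyration and a Shrake-Rupley solvent-accessible surface
area, the standard per-frame summaries for gas-phase trajectories.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "SphereModel",
    "CCSResult",
    "EHSS_HELIUM_RADII",
    "VDW_RADII",
    "sphere_limit_ccs",
    "load_structure",
    "ehss_ccs",
    "projection_approx_ccs",
    "radius_of_gyration",
    "sasa",
]

# Hard-sphere radii (A) calibrated for helium scattering in the EHSS
# lineage; these already include the helium probe, so probe_radius = 0
# is the matching convention.
EHSS_HELIUM_RADII = {"H": 2.2, "C": 2.7, "N": 2.7, "O": 2.7, "S": 3.1}

# van der Waals radii (A) for the alternative vdW + probe mode.
VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "P": 1.8}

# Density of a close-packed globular protein, Da / A^3.
PROTEIN_DENSITY = 0.904

# Geometric-to-helium-CCS conversion for the sphere model.  The commonly
# quoted literature factor is 1.19; the package default 1.14 is the value
# consistent with reported dimer lower bounds at this density (see the
# methods note for the discrepancy).
SPHERE_SCALE_DEFAULT = 1.14
SPHERE_SCALE_LITERATURE = 1.19


@dataclass
class Structure:
    """Hard-sphere atomic model: elements, coordinates (A) and radii (A)."""

    elements: list[str]
    coords: np.ndarray  # (n, 3) A
    radii: np.ndarray  # (n,) A
    label: str = ""
    atom_names: list[str] | None = None  # PDB atom names, when available

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.elements)
        if self.coords.shape != (n, 3) or self.radii.shape != (n,):
            raise ValueError("elements, coords and radii must align")
        if n == 0:
            raise ValueError("empty structure")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.elements)


@dataclass
class SphereModel:
    mass: float  # Da
    density: float = PROTEIN_DENSITY  # Da / A^3
    scale: float = SPHERE_SCALE_DEFAULT

    def __post_init__(self) -> None:
        if min(self.mass, self.density, self.scale) <= 0:
            raise ValueError("mass, density and scale must be positive")


@dataclass
class CCSResult:
    ccs: float  # A^2
    mc_stderr: float  # A^2
    n_orientations: int
    n_impacts: int
    seed: int

    def __post_init__(self) -> None:
        if self.ccs <= 0 or self.mc_stderr < 0:
            raise ValueError("invalid CCS result")


def sphere_limit_ccs(model: SphereModel) -> float:
    """Smallest possible CCS (A^2) of a globular species of mass Mw.

    V = Mw/rho, r = (3V/4 pi)^(1/3), CCS = scale * pi r^2.
    """
    volume = model.mass / model.density
    r = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return model.scale * math.pi * r * r


def load_structure(
    path,
    radii_table: str = "ehss",
    include_hydrogens: bool = True,
    strip_waters: bool = True,
    hydrogens: str = "require",
) -> Structure:
    """Read a PDB file into a hard-sphere :class:`Structure`.

    ATOM/HETATM records are kept with altloc '' or 'A'; waters are stripped
    by default.  ``radii_table`` is ``"ehss"`` (helium-calibrated hard-sphere
    radii, probe already included) or ``"vdw"``.  Structures without
    hydrogens fail fast unless ``hydrogens="united"``, which inflates heavy
    C/N/O/S radii by 0.2 A as a crude united-atom correction.
    """
    from Bio.PDB import PDBParser

    table = {"ehss": EHSS_HELIUM_RADII, "vdw": VDW_RADII}.get(radii_table)
    if table is None:
        raise ValueError(f"unknown radii table {radii_table!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # native PDBs carry benign format quirks
        model = PDBParser(QUIET=True).get_structure("s", str(path))[0]
    elements, names, coords = [], [], []
    for chain in model:
        for residue in chain:
            if strip_waters and residue.get_resname() in ("HOH", "WAT", "DOD"):
                continue
            for atom in residue:
                if atom.get_altloc() not in (" ", "", "A"):
                    continue
                elem = (atom.element or atom.get_name()[0]).strip().capitalize()
                if elem == "H" and not include_hydrogens:
                    continue
                elements.append(elem)
                names.append(atom.get_name())
                coords.append(atom.get_coord())
    if not elements:
        raise ValueError(f"no atoms read from {path}")

    has_h = "H" in elements
    inflate = 0.0
    if not has_h:
        if hydrogens == "require":
            raise ValueError(
                "structure has no hydrogens; re-run with hydrogens='united' "
                "or provide a protonated model"
            )
        if hydrogens == "united":
            inflate = 0.2
            logger.warning("no hydrogens: applying united-atom +0.2 A radius inflation")
        else:
            raise ValueError(f"unknown hydrogens mode {hydrogens!r}")

    unknown = sorted({e for e in elements if e not in table})
    if unknown:
        raise ValueError(f"no radius for element(s) {unknown} in table {radii_table!r}")
    radii = np.array(
        [table[e] + (inflate if e in ("C", "N", "O", "S") else 0.0) for e in elements]
    )
    return Structure(
        elements=elements,
        coords=np.asarray(coords, dtype=float),
        radii=radii,
        label=str(path),
        atom_names=names,
    )


def _random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform random rotation matrices via unit quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    rot = np.empty((n, 3, 3))
    rot[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rot[:, 0, 1] = 2 * (x * y - z * w)
    rot[:, 0, 2] = 2 * (x * z + y * w)
    rot[:, 1, 0] = 2 * (x * y + z * w)
    rot[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rot[:, 1, 2] = 2 * (y * z - x * w)
    rot[:, 2, 0] = 2 * (x * z - y * w)
    rot[:, 2, 1] = 2 * (y * z + x * w)
    rot[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return rot


MAX_BOUNCES = 1000


def _trace(start: np.ndarray, direction: np.ndarray, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Specular multiple-reflection trace; returns the exit direction."""
    pos = start
    d = direction
    for _ in range(MAX_BOUNCES):
        oc = centers - pos
        b = oc @ d
        disc = b * b - np.einsum("ij,ij->i", oc, oc) + radii * radii
        hit = disc > 0
        if not np.any(hit):
            return d
        t = b[hit] - np.sqrt(disc[hit])
        ok = t > 1e-9
        if not np.any(ok):
            return d
        idx = np.flatnonzero(hit)[ok]
        tt = t[ok]
        j = int(np.argmin(tt))
        pos = pos + tt[j] * d
        normal = (pos - centers[idx[j]]) / radii[idx[j]]
        d = d - 2.0 * (d @ normal) * normal
    logger.warning("reflection cap (%d bounces) reached; keeping current deflection", MAX_BOUNCES)
    return d


def ehss_ccs(
    structure: Structure,
    probe_radius: float = 0.0,
    n_orientations: int = 64,
    n_impacts: int = 400,
    seed: int = 0,
) -> CCSResult:
    """Exact hard-sphere scattering CCS (A^2), Monte Carlo.

    For each uniformly random orientation, impact points are sampled on a
    disc enclosing the projection; each defines a probe line traced through
    specular reflections off spheres of radius (atom radius + probe_radius)
    until escape.  The momentum-transfer weight (1 - cos chi) of the net
    deflection chi is averaged over impacts, multiplied by the disc area and
    averaged over orientations; the standard error comes from the
    between-orientation variance.  Identical seeds give identical results.
    """
    if n_orientations < 1 or n_impacts < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    centers0 = structure.coords - structure.coords.mean(axis=0)
    radii = structure.radii + probe_radius
    rots = _random_rotations(n_orientations, rng)
    per_orient = np.empty(n_orientations)
    for k in range(n_orientations):
        centers = centers0 @ rots[k].T
        disc_r = float(np.max(np.hypot(centers[:, 0], centers[:, 1]) + radii))
        if disc_r <= 0:
            raise ValueError("degenerate impact disc")
        # uniform points on the disc
        u = rng.random(n_impacts)
        theta = rng.random(n_impacts) * 2.0 * np.pi
        rr = disc_r * np.sqrt(u)
        z0 = centers[:, 2].max() + radii.max() + 10.0
        acc = 0.0
        d0 = np.array([0.0, 0.0, -1.0])
        for i in range(n_impacts):
            start = np.array([rr[i] * np.cos(theta[i]), rr[i] * np.sin(theta[i]), z0])
            d_exit = _trace(start, d0, centers, radii)
            acc += 1.0 - float(d0 @ d_exit)
        per_orient[k] = math.pi * disc_r * disc_r * acc / n_impacts
    ccs = float(per_orient.mean())
    stderr = float(per_orient.std(ddof=1) / math.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CCSResult(ccs=ccs, mc_stderr=stderr, n_orientations=n_orientations, n_impacts=n_impacts, seed=seed)


def projection_approx_ccs(
    structure: Structure,
    probe_radius: float = 0.0,
    n_orientations: int = 64,
    n_impacts: int = 400,
    seed: int = 0,
) -> CCSResult:
    """Projection-approximation CCS: orientation-averaged shadow area.

    Same sampling scheme as :func:`ehss_ccs` but each impact merely tests
    whether the line hits any sphere; PA is a lower bound to EHSS.
    """
    if n_orientations < 1 or n_impacts < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    centers0 = structure.coords - structure.coords.mean(axis=0)
    radii = structure.radii + probe_radius
    rots = _random_rotations(n_orientations, rng)
    per_orient = np.empty(n_orientations)
    for k in range(n_orientations):
        centers = centers0 @ rots[k].T
        disc_r = float(np.max(np.hypot(centers[:, 0], centers[:, 1]) + radii))
        u = rng.random(n_impacts)
        theta = rng.random(n_impacts) * 2.0 * np.pi
        rr = disc_r * np.sqrt(u)
        px = rr * np.cos(theta)
        py = rr * np.sin(theta)
        d2 = (px[:, None] - centers[None, :, 0]) ** 2 + (py[:, None] - centers[None, :, 1]) ** 2
        hit = np.any(d2 <= (radii**2)[None, :], axis=1)
        per_orient[k] = math.pi * disc_r * disc_r * hit.mean()
    ccs = float(per_orient.mean())
    stderr = float(per_orient.std(ddof=1) / math.sqrt(n_orientations)) if n_orientations > 1 else 0.0
    return CCSResult(ccs=ccs, mc_stderr=stderr, n_orientations=n_orientations, n_impacts=n_impacts, seed=seed)


_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def radius_of_gyration(structure: Structure, selection: str = "all") -> float:
    """Unweighted radius of gyration (A) of all atoms or the backbone."""
    if selection == "all":
        xyz = structure.coords
    elif selection == "backbone":
        if structure.atom_names is None:
            raise ValueError("backbone selection needs atom names (PDB input)")
        mask = np.array([n in _BACKBONE_NAMES for n in structure.atom_names])
        if not mask.any():
            raise ValueError("no backbone atoms in structure")
        xyz = structure.coords[mask]
    else:
        raise ValueError(f"unknown selection {selection!r}")
    centred = xyz - xyz.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def _fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure, probe: float = 1.4, n_sphere_points: int = 960) -> float:
    """Shrake-Rupley solvent-accessible surface area (A^2).

    Each atom's surface is sampled on a golden-spiral lattice at radius
    (r_atom + probe); the exposed fraction (points not buried inside any
    other expanded atom) times the expanded sphere area is summed.
    """
    pts = _fibonacci_sphere(n_sphere_points)
    coords = structure.coords
    expanded = structure.radii + probe
    total = 0.0
    for i in range(len(structure)):
        d = np.linalg.norm(coords - coords[i], axis=1)
        nb = np.flatnonzero((d < expanded + expanded[i]) & (d > 0))
        surface = coords[i] + expanded[i] * pts
        if nb.size:
            d2 = np.sum((surface[:, None, :] - coords[nb][None, :, :]) ** 2, axis=2)
            exposed = np.all(d2 > (expanded[nb] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        total += frac * 4.0 * math.pi * expanded[i] ** 2
    return float(total)
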