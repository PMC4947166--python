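"""Geometric CCS models, radius of gyration and SASA."""

import math

import numpy as np
import pytest

from structms.geometry import (
    SPHERE_SCALE_LITERATURE,
    SphereModel,
    Structure,
    ehss_ccs,
    load_structure,
    projection_approx_ccs,
    radius_of_gyration,
    sasa,
    sphere_limit_ccs,
)
from structms.synthetic import gen_toy_structure


class TestSphereLimit:
    def test_unit_radius_sphere(self):
        # Mw chosen so V = 4 pi/3, i.e. r = 1 A
        model = SphereModel(mass=(4 * math.pi / 3) * 0.904, scale=1.0)
        assert sphere_limit_ccs(model) == pytest.approx(math.pi, rel=1e-12)

    def test_matches_one_line_oracle_for_monomer(self):
        mw = 56135.0
        got = sphere_limit_ccs(SphereModel(mass=mw))
        oracle = 1.14 * math.pi * (3 * (mw / 0.904) / (4 * math.pi)) ** (2 / 3)
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_dimer_lower_bound(self):
        assert sphere_limit_ccs(SphereModel(mass=112270.0)) == pytest.approx(3430.0, rel=0.01)

    def test_literature_scale_option(self):
        got = sphere_limit_ccs(SphereModel(mass=112270.0, scale=SPHERE_SCALE_LITERATURE))
        assert got == pytest.approx(3581.0, rel=0.01)

    def test_mass_two_thirds_scaling(self):
        a = sphere_limit_ccs(SphereModel(mass=50000.0))
        b = sphere_limit_ccs(SphereModel(mass=100000.0))
        assert b == pytest.approx(a * 2 ** (2 / 3), rel=1e-12)


PDB_ONE_ATOM = (
    "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
    "ATOM      2  HA  ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
    "END\n"
)

PDB_ALTLOC = (
    "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C\n"
    "ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.50  0.00           C\n"
    "ATOM      3  HA  ALA A   1       1.000   0.000   0.000  1.00  0.00           H\n"
    "END\n"
)


class TestLoadStructure:
    def test_minimal_pdb(self, tmp_path):
        p = tmp_path / "one.pdb"
        p.write_text(PDB_ONE_ATOM)
        s = load_structure(p)
        assert len(s) == 2
        assert s.elements == ["C", "H"]
        assert s.radii == pytest.approx([2.7, 2.2])

    def test_coordinate_round_trip(self, tmp_path):
        """Writing a small helix as PDB text and re-reading preserves
        coordinates to the PDB format's 3-decimal precision."""
        helix, _ = gen_toy_structure("helix", {"n_residues": 5})
        lines = []
        for i, (x, y, z) in enumerate(helix.coords):
            lines.append(
                f"ATOM  {i + 1:5d}  CA  ALA A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
            )
        # hydrogen so the default radii mode accepts the file
        lines.append(
            "ATOM     99  HA  ALA A   9       0.000   0.000   9.000  1.00  0.00           H"
        )
        p = tmp_path / "helix.pdb"
        p.write_text("\n".join(lines) + "\nEND\n")
        s = load_structure(p)
        assert s.coords[: len(helix)] == pytest.approx(helix.coords, abs=1e-3)

    def test_altloc_a_only(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text(PDB_ALTLOC)
        s = load_structure(p)
        # independent text scan: count records that are not altloc B
        expected = sum(
            1 for ln in PDB_ALTLOC.splitlines() if ln.startswith("ATOM") and ln[16] != "B"
        )
        assert len(s) == expected

    def test_missing_hydrogens_fail_fast(self, tmp_path):
        p = tmp_path / "noh.pdb"
        p.write_text(PDB_ONE_ATOM.splitlines()[0] + "\nEND\n")
        with pytest.raises(ValueError, match="no hydrogens"):
            load_structure(p)
        s = load_structure(p, hydrogens="united")
        assert s.radii[0] == pytest.approx(2.9)


def oracle_dumbbell_ehss(r: float, sep: float, n_theta: int = 12, n_cells: int = 220, seed: int = 123) -> float:
    """Independent stratified-quadrature EHSS for a two-sphere dumbbell.

    Axial symmetry reduces the orientation average to the polar angle
    (Gauss-Legendre in cos theta over [0, 1]); the impact plane is covered
    by a jittered Cartesian grid (stratified quadrature, fixed seed).
    Scalar ray tracing is written independently of the package tracer.
    """
    rng = np.random.default_rng(seed)
    nodes, weights = np.polynomial.legendre.leggauss(n_theta)
    u = 0.5 * (nodes + 1.0)  # cos(theta) in (0, 1); mirror symmetry
    w = 0.5 * weights

    def trace(px, py, centers):
        # beam along -z from z = +inf; returns 1 - cos(chi)
        pos = np.array([px, py, 50.0])
        d = np.array([0.0, 0.0, -1.0])
        for _ in range(100):
            best_t, best_c = None, None
            for cx, cy, cz in centers:
                oc = np.array([cx, cy, cz]) - pos
                b = oc @ d
                disc = b * b - oc @ oc + r * r
                if disc <= 0:
                    continue
                t = b - math.sqrt(disc)
                if t > 1e-9 and (best_t is None or t < best_t):
                    best_t, best_c = t, np.array([cx, cy, cz])
            if best_t is None:
                return 1.0 - (-d[2])
            pos = pos + best_t * d
            n = (pos - best_c) / r
            d = d - 2.0 * (d @ n) * n
        return 1.0 - (-d[2])

    total = 0.0
    half = sep / 2.0
    for cu, cw in zip(u, w):
        st = math.sqrt(1.0 - cu * cu)
        centers = [(half * st, 0.0, half * cu), (-half * st, 0.0, -half * cu)]
        extent = half * st + r + 1e-9
        # bounding box of the projection; jittered-grid quadrature
        nx = n_cells
        ny = max(int(n_cells * (r / extent)), 40)
        hx, hy = 2 * extent / nx, 2 * r / ny
        acc = 0.0
        jit = rng.random((nx, ny, 2))
        for i in range(nx):
            for j in range(ny):
                px = -extent + (i + jit[i, j, 0]) * hx
                py = -r + (j + jit[i, j, 1]) * hy
                acc += trace(px, py, centers)
        total += cw * acc * hx * hy * 2  # mirror symmetry in y
    return total / 2.0  # py covered only [-r, r]; factor bookkeeping below


def test_oracle_sanity_single_sphere():
    """The oracle machinery reduces to pi R^2 for a single sphere."""
    # degenerate dumbbell: separation 0 superimposes the spheres
    val = oracle_dumbbell_ehss(2.0, 0.0, n_theta=4, n_cells=150)
    assert val == pytest.approx(math.pi * 4.0, rel=0.02)


class TestEHSS:
    def test_single_sphere_equals_geometric_cross_section(self):
        s = Structure(elements=["X"], coords=[[0.0, 0.0, 0.0]], radii=[2.7])
        res = ehss_ccs(s, probe_radius=1.0, n_orientations=32, n_impacts=500, seed=1)
        exact = math.pi * 3.7**2
        assert abs(res.ccs - exact) < 3 * max(res.mc_stderr, 1e-6) + 0.01 * exact

    def test_dumbbell_matches_quadrature_oracle(self):
        d, _ = gen_toy_structure("dumbbell", {"r": 2.0, "separation": 6.0})
        res = ehss_ccs(d, n_orientations=256, n_impacts=1500, seed=2)
        oracle = oracle_dumbbell_ehss(2.0, 6.0)
        assert res.ccs == pytest.approx(oracle, rel=0.01)

    def test_rotation_invariance(self):
        d, _ = gen_toy_structure("dumbbell", {"r": 2.0, "separation": 6.0})
        theta = 0.7
        rot = np.array(
            [
                [math.cos(theta), -math.sin(theta), 0.0],
                [math.sin(theta), math.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = Structure(elements=d.elements, coords=d.coords @ rot.T, radii=d.radii)
        a = ehss_ccs(d, n_orientations=128, n_impacts=500, seed=5)
        b = ehss_ccs(rotated, n_orientations=128, n_impacts=500, seed=9)
        assert abs(a.ccs - b.ccs) < 3 * (a.mc_stderr + b.mc_stderr)

    def test_seed_determinism(self):
        d, _ = gen_toy_structure("dumbbell", {})
        r1 = ehss_ccs(d, n_orientations=16, n_impacts=100, seed=7)
        r2 = ehss_ccs(d, n_orientations=16, n_impacts=100, seed=7)
        assert r1.ccs == r2.ccs
        assert r1.mc_stderr == r2.mc_stderr

    def test_ehss_at_least_projection_approximation(self):
        for seed in range(5):
            s, _ = gen_toy_structure("sphere-cloud", {"n": 25, "R": 8.0, "atom_radius": 2.2}, seed=seed)
            e = ehss_ccs(s, n_orientations=48, n_impacts=300, seed=seed)
            p = projection_approx_ccs(s, n_orientations=48, n_impacts=300, seed=seed)
            assert e.ccs >= p.ccs - 3 * (e.mc_stderr + p.mc_stderr)

    def test_stderr_scales_inverse_sqrt_orientations(self):
        s, _ = gen_toy_structure("sphere-cloud", {"n": 20, "R": 8.0}, seed=3)
        lo = ehss_ccs(s, n_orientations=24, n_impacts=200, seed=11)
        hi = ehss_ccs(s, n_orientations=96, n_impacts=200, seed=11)
        ratio = hi.mc_stderr / lo.mc_stderr
        assert 0.2 < ratio < 0.9  # expect ~0.5 with sampling scatter


class TestRadiusOfGyration:
    def test_two_point_case(self):
        s = Structure(elements=["X", "X"], coords=[[1, 0, 0], [-1, 0, 0]], radii=[1.0, 1.0])
        assert radius_of_gyration(s) == pytest.approx(1.0, rel=1e-12)

    def test_uniform_ball_limit(self):
        s, truth = gen_toy_structure("sphere-cloud", {"n": 60000, "R": 20.0}, seed=1)
        assert radius_of_gyration(s) == pytest.approx(truth.params["expected_rg_limit"], rel=0.01)

    def test_rigid_motion_invariance(self):
        s, _ = gen_toy_structure("sphere-cloud", {"n": 50}, seed=2)
        rg = radius_of_gyration(s)
        theta = 1.1
        rot = np.array(
            [
                [1, 0, 0],
                [0, math.cos(theta), -math.sin(theta)],
                [0, math.sin(theta), math.cos(theta)],
            ]
        )
        moved = Structure(
            elements=s.elements, coords=s.coords @ rot.T + np.array([5.0, -3.0, 2.0]), radii=s.radii
        )
        assert radius_of_gyration(moved) == pytest.approx(rg, abs=1e-9)

    def test_backbone_selection_requires_names(self):
        s, _ = gen_toy_structure("sphere-cloud", {"n": 10}, seed=0)
        with pytest.raises(ValueError):
            radius_of_gyration(s, selection="backbone")


class TestSASA:
    def test_single_atom_analytic(self):
        s = Structure(elements=["X"], coords=[[0.0, 0.0, 0.0]], radii=[1.7])
        assert sasa(s, probe=1.4) == pytest.approx(4 * math.pi * 3.1**2, rel=1e-12)

    def test_far_separated_additivity(self):
        s = Structure(
            elements=["X", "X"], coords=[[0, 0, 0], [100.0, 0, 0]], radii=[1.7, 2.0]
        )
        expected = 4 * math.pi * (1.7 + 1.4) ** 2 + 4 * math.pi * (2.0 + 1.4) ** 2
        assert sasa(s, probe=1.4) == pytest.approx(expected, rel=1e-12)

    def test_overlapping_spheres_match_cap_formula(self):
        """Two equal expanded spheres of radius R at distance d < 2R: each
        loses a cap of height h = R - d/2, area 2 pi R h."""
        r_atom, probe, d = 1.7, 1.4, 3.0
        big_r = r_atom + probe
        s = Structure(elements=["X", "X"], coords=[[0, 0, 0], [d, 0, 0]], radii=[r_atom, r_atom])
        h = big_r - d / 2
        expected = 2 * (4 * math.pi * big_r**2 - 2 * math.pi * big_r * h)
        assert sasa(s, probe=probe, n_sphere_points=5000) == pytest.approx(expected, rel=0.01)
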