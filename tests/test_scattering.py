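"""Structure factors, bulk solvent and scaling."""

import numpy as np
import pytest

from xtalrefine import (
    FormFactorTable,
    ScaleModel,
    SimulationSpec,
    UnitCell,
    babinet_factor,
    build_solvent_mask,
    direct_structure_factors,
    estimate_scales,
    estimate_scales_twin,
    generate_hkl,
    make_toy_structure,
    mask_structure_factors,
    simulate_observations,
    structure_factor_derivs,
    total_structure_factors,
)
from xtalrefine.cell import UnitCell
from xtalrefine.model import Atom, Structure
from xtalrefine.scattering import SolventMask, _ftotal_and_jac, symmetry_invariant_basis
from xtalrefine.symmetry import SpaceGroupInfo


def test_form_factors_match_electron_counts():
    tab = FormFactorTable()
    import gemmi

    for el in ("C", "N", "O", "S", "SE", "FE", "HG"):
        z = gemmi.Element(el.capitalize()).atomic_number
        assert tab.evaluate(el, np.array([0.0]))[0] == pytest.approx(z, rel=0.02)


class TestDirectSummation:
    def test_origin_atom_gives_form_factor_with_zero_phase(self):
        cell = UnitCell(10, 10, 10)
        st = Structure(cell, SpaceGroupInfo("P 1"),
                       [Atom("C", "A", 1, "LIG", "C1", np.zeros(3), occ=0.7, b_iso=1e-9)])
        hkl = np.array([[1, 0, 0], [2, 3, 1], [0, 0, 5]])
        f = direct_structure_factors(st, hkl)
        expected = 0.7 * FormFactorTable().evaluate("C", cell.s_squared(hkl))
        assert np.abs(np.abs(f) - expected).max() < 1e-9
        assert np.abs(np.angle(f)).max() < 1e-12

    def test_shift_theorem(self):
        cell = UnitCell(10, 10, 10)
        t = np.array([0.1, 0.2, 0.3])
        hkl = np.array([[1, 0, 0], [2, 3, 1], [-1, 4, 2]])
        sts = [
            Structure(cell, SpaceGroupInfo("P 1"),
                      [Atom("C", "A", 1, "LIG", "C1", cell.orthogonalize(fr), b_iso=5.0)])
            for fr in (np.zeros(3), t)
        ]
        f0, f1 = (direct_structure_factors(s, hkl) for s in sts)
        assert np.abs(np.abs(f1) - np.abs(f0)).max() < 1e-10
        dphase = np.angle(f1 * np.conj(f0))
        expected = (2 * np.pi * hkl @ t + np.pi) % (2 * np.pi) - np.pi
        assert np.abs(dphase - expected).max() < 1e-10

    def test_symmetry_equals_p1_expansion(self, p21_fixture):
        st, rset = p21_fixture
        hkl = rset.hkl[:80]
        f_sym = direct_structure_factors(st, hkl)
        cell, sg = st.cell, st.spacegroup
        expanded = []
        k = 0
        for op in sg.operators:
            for a in st.atoms:
                k += 1
                fr = cell.fractionalize(a.pos) @ op.rot.T + op.tran
                expanded.append(
                    Atom(a.element, "A", k, "LIG", "C1", cell.orthogonalize(fr),
                         occ=a.occ, b_iso=a.b_iso)
                )
        st_p1 = Structure(cell, SpaceGroupInfo("P 1"), expanded)
        f_p1 = direct_structure_factors(st_p1, hkl)
        assert (np.abs(f_sym - f_p1) / np.abs(f_sym)).max() < 1e-8

    def test_friedel_symmetry_without_anomalous(self, p21_fixture):
        st, rset = p21_fixture
        hkl = rset.hkl[:50]
        f = direct_structure_factors(st, hkl)
        fm = direct_structure_factors(st, -hkl)
        assert np.abs(fm - np.conj(f)).max() < 1e-12 * np.abs(f).max()

    def test_anomalous_breaks_friedel(self, p21_fixture):
        st, _ = p21_fixture
        st = st.copy()
        st.atoms.append(Atom("SE", "Z", 1, "LIG", "C1", st.positions().mean(axis=0),
                             b_iso=15.0))
        hkl = np.array([[1, 2, 3], [2, 1, 1], [3, 1, 2]])
        anom = {"SE": (-2.0, 4.0)}
        f = direct_structure_factors(st, hkl, anomalous=anom)
        fm = direct_structure_factors(st, -hkl, anomalous=anom)
        assert np.abs(np.abs(fm) - np.abs(f)).max() > 1e-3

    def test_missing_form_factor_names_element(self):
        cell = UnitCell(10, 10, 10)
        st = Structure(cell, SpaceGroupInfo("P 1"),
                       [Atom("C", "A", 1, "LIG", "C1", np.zeros(3), b_iso=5.0)])
        tab = FormFactorTable(coefficients={"O": FormFactorTable().coefficients["O"]})
        with pytest.raises(KeyError, match="C"):
            direct_structure_factors(st, np.array([[1, 0, 0]]), table=tab)


class TestDerivatives:
    def test_all_atomic_derivatives_match_finite_differences(self, p21_fixture):
        """d|F_total|/d{x, B, occ} and dF/dU vs central differences (1e-5)."""
        st, rset = p21_fixture
        st = st.copy()
        st.atoms[2].u_aniso = np.array(
            [[0.3, 0.02, 0.01], [0.02, 0.25, 0.03], [0.01, 0.03, 0.4]]
        )
        hkl = rset.hkl[:40]
        sfd = structure_factor_derivs(st, hkl)
        eps = 1e-5
        scale_f = np.abs(sfd.f).max()

        def fd(build_plus, build_minus):
            return (direct_structure_factors(build_plus, hkl)
                    - direct_structure_factors(build_minus, hkl)) / (2 * eps)

        for ai in (0, 2, 7):
            for j in range(3):
                sp, sm = st.copy(), st.copy()
                sp.atoms[ai].pos[j] += eps
                sm.atoms[ai].pos[j] -= eps
                d = fd(sp, sm)
                assert np.abs(d - sfd.d_xyz[:, ai, j]).max() < 1e-5 * np.abs(d).max()
            sp, sm = st.copy(), st.copy()
            sp.atoms[ai].occ = min(st.atoms[ai].occ + eps, 1.0)
            sm.atoms[ai].occ = st.atoms[ai].occ - eps
            ee = (sp.atoms[ai].occ - sm.atoms[ai].occ) / 2
            d = (direct_structure_factors(sp, hkl) - direct_structure_factors(sm, hkl)) / (2 * ee)
            assert np.abs(d - sfd.d_occ[:, ai]).max() < 1e-5 * scale_f
        # isotropic B
        sp, sm = st.copy(), st.copy()
        sp.atoms[0].b_iso += eps
        sm.atoms[0].b_iso -= eps
        d = fd(sp, sm)
        assert np.abs(d - sfd.d_b[:, 0]).max() < 1e-5 * np.abs(d).max()
        # anisotropic U components
        for c, (i, j) in enumerate([(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]):
            sp, sm = st.copy(), st.copy()
            for s_, sgn in ((sp, 1), (sm, -1)):
                s_.atoms[2].u_aniso[i, j] += sgn * eps
                s_.atoms[2].u_aniso[j, i] = s_.atoms[2].u_aniso[i, j]
            d = fd(sp, sm)
            assert np.abs(d - sfd.d_u[:, 2, c]).max() < 1e-5 * np.abs(d).max()

    def test_scale_parameter_derivatives_match_finite_differences(self, p21_fixture):
        st, rset = p21_fixture
        fp = direct_structure_factors(st, rset.hkl)
        cell = rset.cell
        s_cart = cell.recip_vectors(rset.hkl)
        s2 = np.einsum("ni,ni->n", s_cart, s_cart)
        basis = symmetry_invariant_basis(rset.spacegroup, cell)
        fm = np.exp(1j * s2)  # stand-in solvent transform, synthetic values
        layout = {"k": 0, "u": list(range(1, 1 + len(basis))),
                  "mask": [1 + len(basis), 2 + len(basis)],
                  "bab": [3 + len(basis), 4 + len(basis)]}
        p = np.concatenate([[1.3], 0.01 * np.ones(len(basis)), [0.4, 40.0], [0.2, 150.0]])
        ftot, jac, _ = _ftotal_and_jac(p, layout, rset, fp, fm, basis, cell,
                                       rset.hkl, s_cart, s2)
        for k in range(len(p)):
            e = 1e-6
            pp, pm = p.copy(), p.copy()
            pp[k] += e
            pm[k] -= e
            fp_, _, _ = _ftotal_and_jac(pp, layout, rset, fp, fm, basis, cell,
                                        rset.hkl, s_cart, s2)
            fm_, _, _ = _ftotal_and_jac(pm, layout, rset, fp, fm, basis, cell,
                                        rset.hkl, s_cart, s2)
            d = (fp_ - fm_) / (2 * e)
            assert np.abs(d - jac[:, k]).max() < 1e-5 * max(np.abs(d).max(), 1e-9)


class TestBabinet:
    def test_neutral_and_limits(self):
        s = np.array([0.0, 0.1, 0.5, 5.0])
        assert np.all(babinet_factor(s, 0.0, 100.0) == 1.0)
        assert babinet_factor(np.array([100.0]), 0.35, 200.0)[0] == pytest.approx(1.0)
        assert babinet_factor(np.array([0.0]), 0.35, 200.0)[0] == pytest.approx(0.65)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            babinet_factor(np.array([0.1]), -0.1, 100.0)


class TestSolventMask:
    def test_empty_cell_is_all_solvent(self):
        cell = UnitCell(20, 20, 20)
        st = Structure(cell, SpaceGroupInfo("P 1"), [])
        # Structure requires >= 0 atoms; build directly with no atoms
        mask = build_solvent_mask(st, 0.5)
        assert mask.solvent_fraction == 1.0
        f = mask_structure_factors(mask, np.array([[0, 0, 0], [1, 2, 0]]))
        assert f[0].real == pytest.approx(cell.volume)
        assert abs(f[1]) < 1e-9

    def test_f000_equals_solvent_fraction_times_volume(self):
        cell = UnitCell(20, 20, 20)
        st = Structure(cell, SpaceGroupInfo("P 1"),
                       [Atom("C", "A", 1, "LIG", "C1", [10, 10, 10], b_iso=20)])
        mask = build_solvent_mask(st, 0.5)
        assert 0 < mask.solvent_fraction < 1
        f000 = mask_structure_factors(mask, np.array([[0, 0, 0]]))[0].real
        assert f000 == pytest.approx(mask.solvent_fraction * cell.volume, abs=0.5**3)

    def test_half_cell_slab_matches_analytic_transform(self):
        cell = UnitCell(20, 20, 20)
        grid = np.zeros((64, 64, 64), dtype=bool)
        grid[:32] = True
        mask = SolventMask(grid=grid, cell=cell, probe_radius=1.0, shrink_radius=1.0)
        hs = np.array([[h, 0, 0] for h in [1, 3]])  # even h vanish exactly
        f = mask_structure_factors(mask, hs)
        for i, h in enumerate([1, 3]):
            analytic = cell.volume * (np.exp(1j * np.pi * h) - 1) / (2j * np.pi * h)
            # amplitude follows the sinc profile to 1% (the half-voxel edge
            # term is purely in quadrature with the main lobe)
            assert abs(abs(f[i]) - abs(analytic)) <= 0.01 * abs(analytic)
        f_even = mask_structure_factors(mask, np.array([[2, 0, 0], [4, 0, 0]]))
        assert np.abs(f_even).max() < 1e-9

    def test_complement_mask_negates_nonzero_coefficients(self):
        cell = UnitCell(20, 20, 20)
        rng = np.random.default_rng(0)
        grid = rng.random((16, 16, 16)) < 0.4
        hkl = np.array([[1, 0, 0], [2, 3, 1], [0, 1, 4]])
        f = mask_structure_factors(
            SolventMask(grid, cell, 1.0, 1.0), hkl
        )
        fc = mask_structure_factors(
            SolventMask(~grid, cell, 1.0, 1.0), hkl
        )
        assert np.abs(f + fc).max() < 1e-9

    def test_cavity_reassigned_to_protein(self):
        """A hollow shell's interior is not connected to bulk solvent."""
        cell = UnitCell(20, 20, 20)
        atoms = []
        k = 0
        for th in np.linspace(0, np.pi, 10)[1:-1]:
            for ph in np.linspace(0, 2 * np.pi, 14, endpoint=False):
                k += 1
                pos = np.array([10, 10, 10]) + 6.0 * np.array(
                    [np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)]
                )
                atoms.append(Atom("C", "A", k, "LIG", "C1", pos, b_iso=20))
        atoms.append(Atom("C", "A", k + 1, "LIG", "C1", [10, 10, 4.0], b_iso=20))
        atoms.append(Atom("C", "A", k + 2, "LIG", "C1", [10, 10, 16.0], b_iso=20))
        st = Structure(cell, SpaceGroupInfo("P 1"), atoms)
        mask = build_solvent_mask(st, 0.5, probe_radius=1.0, shrink_radius=0.0)
        centre = tuple((np.array([10, 10, 10]) / 20 * np.array(mask.grid.shape)).astype(int))
        assert not mask.grid[centre]
        # independent flood-fill oracle on the voxel graph
        from scipy import ndimage

        labels, n = ndimage.label(mask.grid)
        assert n == 1  # a single connected solvent component remains

    def test_too_coarse_grid_rejected(self, polyala5):
        with pytest.raises(ValueError, match="spacing"):
            build_solvent_mask(polyala5, 1.0, d_min=2.0)


class TestTotalStructureFactors:
    def test_neutral_scaling_is_identity(self, p21_fixture):
        st, rset = p21_fixture
        fp = direct_structure_factors(st, rset.hkl)
        f = total_structure_factors(fp, None, ScaleModel(), rset.cell, rset.hkl)
        assert np.array_equal(f, fp)

    def test_k_overall_doubles_amplitudes(self, p21_fixture):
        st, rset = p21_fixture
        fp = direct_structure_factors(st, rset.hkl)
        f = total_structure_factors(fp, None, ScaleModel(k_overall=2.0), rset.cell, rset.hkl)
        assert np.abs(f - 2.0 * fp).max() < 1e-12 * np.abs(fp).max()

    def test_isotropic_u_reduces_to_scalar_debye_waller(self, p21_fixture):
        st, rset = p21_fixture
        fp = direct_structure_factors(st, rset.hkl)
        u = 0.04
        f = total_structure_factors(fp, None, ScaleModel(u_aniso=u * np.eye(3)),
                                    rset.cell, rset.hkl)
        scalar = np.exp(-2 * np.pi**2 * u * rset.s2)
        assert np.abs(f - scalar * fp).max() < 1e-12 * np.abs(fp).max()


class TestScaleEstimation:
    def test_k_overall_recovery_noise_free(self, p21_fixture):
        st, rset = p21_fixture
        fp = direct_structure_factors(st, rset.hkl)
        rset.f_obs = 0.5 * np.abs(fp)
        sc = estimate_scales(rset, fp)
        assert sc.k_overall == pytest.approx(0.5, abs=1e-6)
        assert np.abs(sc.u_aniso).max() < 1e-8

    def test_isotropic_b_recovery_in_orthorhombic_group(self):
        spec = SimulationSpec(n_residues=6, spacegroup="P 21 21 21", d_min=2.5, seed=5)
        st = make_toy_structure(spec)
        rset = simulate_observations(st, spec)
        fp = direct_structure_factors(st, rset.hkl)
        b_true = 12.0
        rset.f_obs = np.abs(fp) * np.exp(-b_true * rset.s2 / 4.0)
        sc = estimate_scales(rset, fp)
        u_expect = b_true / (8 * np.pi**2)
        assert np.abs(np.diag(sc.u_aniso) - u_expect).max() < 1e-4
        off = sc.u_aniso - np.diag(np.diag(sc.u_aniso))
        assert np.abs(off).max() < 1e-6

    def test_u_aniso_respects_crystal_symmetry(self):
        """Projection onto the symmetry-invariant subspace is built in."""
        spec = SimulationSpec(n_residues=4, spacegroup="P 41", n_atoms=30, d_min=2.5, seed=6)
        st = make_toy_structure(spec)
        rset = simulate_observations(st, spec)
        fp = direct_structure_factors(st, rset.hkl)
        rng = np.random.default_rng(3)
        rset.f_obs = np.abs(fp) * (1 + 0.05 * rng.normal(size=len(rset)))
        sc = estimate_scales(rset, fp)
        for rot in st.spacegroup.point_group_rotations:
            m = st.cell.frac_matrix.T @ rot.T @ np.linalg.inv(st.cell.frac_matrix.T)
            assert np.abs(m.T @ sc.u_aniso @ m - sc.u_aniso).max() < 1e-10

    def test_degenerate_parameters_survive_via_eigenvalue_filter(self):
        """k_overall and isotropic U are perfectly correlated on a single
        resolution shell; filtering must keep the solution finite."""
        cell = UnitCell(20, 20, 20)
        sg = SpaceGroupInfo("P 1")
        # single-|s| shell: permutations of (5,0,0)
        hkl = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5], [-5, 0, 0], [0, -5, 0],
                        [0, 0, -5], [5, 0, 0], [0, 5, 0], [0, 0, 5], [-5, 0, 0],
                        [0, -5, 0], [0, 0, -5], [5, 0, 0], [0, 5, 0], [0, 0, 5],
                        [-5, 0, 0], [0, -5, 0], [0, 0, -5], [5, 0, 0], [0, 5, 0]])
        from xtalrefine.reflections import ReflectionSet

        rset = ReflectionSet(cell=cell, spacegroup=sg, hkl=hkl,
                             f_obs=np.full(20, 8.0), sig_f=np.full(20, 0.5),
                             free=np.zeros(20, bool))
        fp = np.full(20, 10.0 + 0j)
        sc = estimate_scales(rset, fp)
        assert np.isfinite(sc.k_overall)
        assert np.isfinite(sc.u_aniso).all()
        ftot = total_structure_factors(fp, None, sc, cell, hkl)
        assert np.abs(np.abs(ftot) - 8.0).max() < 1e-6

    def test_babinet_parameters_recovered_within_one_percent(self):
        spec = SimulationSpec(n_residues=14, d_min=2.2, cell_padding=9.0, seed=3)
        st = make_toy_structure(spec)
        rset = simulate_observations(st, spec)
        fp = direct_structure_factors(st, rset.hkl)
        rset.f_obs = np.abs(fp) * babinet_factor(np.sqrt(rset.s2), 0.35, 150.0)
        sc = estimate_scales(rset, fp, use_babinet=True, use_aniso=False)
        assert sc.k_overall == pytest.approx(1.0, rel=0.01)
        assert sc.k_babinet0 == pytest.approx(0.35, rel=0.01)
        assert sc.b_babinet == pytest.approx(150.0, rel=0.01)


@pytest.fixture(scope="module")
def twin_setup():
    from xtalrefine.twin import TWIN_LAW_CATALOGUE, TwinModel

    op = np.array(TWIN_LAW_CATALOGUE["P 41"][0])
    spec = SimulationSpec(spacegroup="P 41", n_atoms=60, d_min=2.0, seed=11)
    st = make_toy_structure(spec)
    rset = simulate_observations(st, spec)
    tm = TwinModel(operators=[np.eye(3, dtype=int), op], fractions=[0.7, 0.3])
    fp = np.stack([direct_structure_factors(st, img)
                   for img in tm.domain_indices(rset.hkl)])
    return st, rset, tm, fp


class TestTwinScaling:
    def test_perfect_fraction_recovery(self, twin_setup):
        st, rset, tm, fp = twin_setup
        rset = ReflectionSetCopy(rset)
        rset.i_obs = 0.7 * np.abs(fp[0]) ** 2 + 0.3 * np.abs(fp[1]) ** 2
        rset.sig_i = np.maximum(1e-4 * rset.i_obs, 1e-6)
        _, fr = estimate_scales_twin(rset, fp, np.array([0.5, 0.5]))
        assert np.abs(fr - [0.7, 0.3]).max() < 1e-4

    def test_single_domain_reduces_to_plain_scaling(self, twin_setup):
        st, rset, tm, fp = twin_setup
        rset = ReflectionSetCopy(rset)
        rset.i_obs = 0.25 * np.abs(fp[0]) ** 2  # k_overall = 0.5 on amplitudes
        rset.sig_i = np.maximum(1e-4 * rset.i_obs, 1e-6)
        sc, fr = estimate_scales_twin(rset, fp, np.array([1.0, 0.0]))
        assert fr[0] == pytest.approx(1.0, abs=1e-6)
        assert sc.k_overall == pytest.approx(0.5, abs=1e-4)

    def test_noisy_fraction_recovery_within_band(self, twin_setup):
        st, rset, tm, fp = twin_setup
        rset = ReflectionSetCopy(rset)
        rng = np.random.default_rng(4)
        i_true = 0.6 * np.abs(fp[0]) ** 2 + 0.4 * np.abs(fp[1]) ** 2
        rset.sig_i = 0.05 * i_true
        rset.i_obs = i_true + rng.normal(size=len(i_true)) * rset.sig_i
        _, fr = estimate_scales_twin(rset, fp, np.array([0.5, 0.5]))
        assert abs(fr[1] - 0.4) < 0.05


def ReflectionSetCopy(rset):
    """Shallow working copy so class-scoped fixtures stay pristine."""
    import copy

    out = copy.copy(rset)
    out.f_obs = rset.f_obs.copy()
    out.sig_f = rset.sig_f.copy()
    return out
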