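"""NCS detection/restraints, external restraints, jelly body, Geman-McClure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from xtalrefine import (
    GMParams,
    SimulationSpec,
    detect_ncs,
    external_residual,
    geman_mcclure,
    global_ncs_residual,
    jelly_body_contribution,
    load_external_restraints,
    local_ncs_residual,
    make_toy_structure,
    procrustes_superpose,
)
from xtalrefine.ncs import build_local_ncs_pairs, local_rmsd, update_transformations


@pytest.fixture(scope="module")
def two_copy():
    """Two identical 20-residue chains related by a rotation + translation."""
    return make_toy_structure(
        SimulationSpec(n_residues=20, ncs_copy=True, seed=4, ncs_translation=(15.0, 4.0, 2.0))
    )


class TestGemanMcClure:
    def test_zero_point(self):
        rho, drho, curv = geman_mcclure(0.0, 0.5)
        assert rho == 0.0 and drho == 0.0 and curv > 0

    def test_reference_value_and_limit(self):
        rho, _, _ = geman_mcclure(1.0, 0.5)
        assert rho == pytest.approx(0.8)  # 1 / (1 + 0.25)
        rho_inf, _, _ = geman_mcclure(1e9, 0.5)
        assert rho_inf == pytest.approx(4.0, rel=1e-6)  # 1 / sigma^2

    def test_slope_matches_finite_differences(self, rng):
        for r in rng.uniform(-5, 5, 20):
            _, drho, _ = geman_mcclure(r, 0.5)
            e = 1e-7
            fd = (geman_mcclure(r + e, 0.5)[0] - geman_mcclure(r - e, 0.5)[0]) / (2 * e)
            assert drho == pytest.approx(fd, abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(r=hst.floats(-1e6, 1e6), sigma=hst.floats(0.01, 10))
    def test_bounds_property(self, r, sigma):
        """GM(r) <= min(r^2, 1/sigma^2); curvature proxy always positive."""
        rho, _, curv = geman_mcclure(r, sigma)
        assert rho <= min(r * r, 1.0 / sigma**2) + 1e-12
        assert rho >= 0
        assert curv > 0

    def test_small_r_quadratic_limit(self):
        r = 1e-5
        rho, _, _ = geman_mcclure(r, 0.5)
        assert rho == pytest.approx(r * r, rel=1e-8)


class TestProcrustes:
    def test_identity(self, rng):
        a = rng.normal(0, 3, (10, 3))
        r, t, rms = procrustes_superpose(a, a)
        assert np.abs(r - np.eye(3)).max() < 1e-12
        assert np.abs(t).max() < 1e-12 and rms < 1e-12

    def test_constructed_transform_recovered(self, rng):
        a = rng.normal(0, 3, (12, 3))
        rz = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], float)
        b = a @ rz.T + np.array([1.0, 2.0, 3.0])
        r, t, rms = procrustes_superpose(a, b)
        assert np.abs(r - rz).max() < 1e-10
        assert np.abs(t - [1, 2, 3]).max() < 1e-10
        assert rms < 1e-10

    def test_matches_quaternion_oracle_on_noisy_data(self, rng):
        """Independent Horn quaternion-method superposition."""
        a = rng.normal(0, 3, (30, 3))
        rz = np.array([[0.36, 0.48, -0.8], [-0.8, 0.6, 0.0], [0.48, 0.64, 0.6]])
        b = a @ rz.T + rng.normal(0, 0.3, (30, 3)) + [4, -1, 2]
        r, t, rms = procrustes_superpose(a, b)
        r_q, t_q = _horn_quaternion(a, b)
        assert np.abs(r - r_q).max() < 1e-10
        assert np.abs(t - t_q).max() < 1e-10
        dev = a @ r_q.T + t_q - b
        assert rms == pytest.approx(np.sqrt(np.mean(np.sum(dev**2, 1))), rel=1e-10)

    def test_degenerate_colinear_sets_rejected(self):
        a = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="colinear|degenerate"):
            procrustes_superpose(a, a * 2.0)

    def test_proper_rotation_enforced(self, rng):
        a = rng.normal(0, 2, (10, 3))
        b = a * np.array([-1.0, 1.0, 1.0])  # mirror image
        r, _, _ = procrustes_superpose(a, b)
        assert np.linalg.det(r) == pytest.approx(1.0)


def _horn_quaternion(a, b):
    """Closed-form quaternion superposition (independent of the SVD path)."""
    ca, cb = a.mean(0), b.mean(0)
    am, bm = a - ca, b - cb
    m = am.T @ bm
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    n = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    w, v = np.linalg.eigh(n)
    q = v[:, -1]
    w0, x, y, z = q
    r = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w0 * z), 2 * (x * z + w0 * y)],
        [2 * (x * y + w0 * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w0 * x)],
        [2 * (x * z - w0 * y), 2 * (y * z + w0 * x), 1 - 2 * (x * x + y * y)],
    ])
    return r, cb - r @ ca


class TestDetection:
    def test_identical_chains_found(self, two_copy):
        pairs = detect_ncs(two_copy)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.rmsd < 1e-10
        assert p.identity == 100.0
        assert len(p.residue_pairs) == 20

    def test_short_chains_rejected_at_default_fifteen(self):
        st = make_toy_structure(SimulationSpec(n_residues=10, ncs_copy=True, seed=4))
        assert detect_ncs(st) == []
        assert len(detect_ncs(st, min_aligned=5)) == 1

    def test_rmsd_threshold_at_default(self, two_copy):
        st = two_copy.copy()
        idx_b = st.chain_atoms("B")
        rng = np.random.default_rng(1)
        noise = rng.normal(0, 1, (len(idx_b), 3))
        noise *= 3.0 / np.sqrt(np.mean(np.sum(noise**2, axis=1)))
        xyz = st.positions()
        xyz[idx_b] += noise
        st.set_positions(xyz)
        assert detect_ncs(st) == []  # 3.0 A > default 2.5 A
        assert len(detect_ncs(st, max_rmsd=4.0)) == 1

    def test_transformations_are_mutually_inverse(self, two_copy):
        xyz = two_copy.positions()
        p = detect_ncs(two_copy)[0]
        ap = p.atom_pairs
        r_ab, t_ab, _ = procrustes_superpose(xyz[ap[:, 0]], xyz[ap[:, 1]])
        r_ba, t_ba, _ = procrustes_superpose(xyz[ap[:, 1]], xyz[ap[:, 0]])
        assert np.abs(r_ab @ r_ba - np.eye(3)).max() < 1e-10

    def test_local_rmsd_zero_for_rigid_copy(self, two_copy):
        p = detect_ncs(two_copy)[0]
        assert p.local_rmsd_value < 1e-10

    def test_full_window_local_equals_global(self, two_copy):
        st = two_copy.copy()
        rng = np.random.default_rng(5)
        xyz = st.positions() + rng.normal(0, 0.3, (len(st), 3))
        st.set_positions(xyz)
        pairs = detect_ncs(st)
        assert len(pairs) == 1
        p = pairs[0]
        assert local_rmsd(st, p, window=10**6) == pytest.approx(p.rmsd, abs=1e-12)

    def test_hinge_bend_gives_local_well_below_global(self):
        """Two rigid halves related by a hinge: windows superpose well while
        the global superposition cannot."""
        st = make_toy_structure(SimulationSpec(n_residues=24, ncs_copy=True, seed=4))
        idx_b = st.chain_atoms("B")
        xyz = st.positions()
        half = [i for i in idx_b if st.atoms[i].resnum > 12]
        from xtalrefine.groups import euler_zyz_matrix

        r = euler_zyz_matrix([0.0, 0.5, 0.0])  # ~29 degrees
        pivot = xyz[half[0]]
        xyz[half] = (xyz[half] - pivot) @ r.T + pivot
        st.set_positions(xyz)
        pairs = detect_ncs(st, max_rmsd=50.0)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.local_rmsd_value < 0.25 * p.rmsd


class TestGlobalNCS:
    def test_zero_at_superposition(self, two_copy):
        pairs = detect_ncs(two_copy)
        v, g, _ = global_ncs_residual(pairs, two_copy.positions(), weight=2.0)
        assert v < 1e-20
        assert np.abs(g).max() < 1e-10

    def test_single_displaced_atom_contributes_w_delta_squared(self, two_copy):
        pairs = detect_ncs(two_copy)
        xyz = two_copy.positions().copy()
        j = pairs[0].atom_pairs[0, 1]
        xyz[j] += [0.3, 0.0, 0.0]
        v, _, _ = global_ncs_residual(pairs, xyz, weight=2.0)
        assert v == pytest.approx(2.0 * 0.09)

    def test_gradient_matches_fd_with_frozen_transformations(self, two_copy):
        pairs = detect_ncs(two_copy)
        rng = np.random.default_rng(2)
        xyz = two_copy.positions() + rng.normal(0, 0.1, (len(two_copy), 3))
        v, g, _ = global_ncs_residual(pairs, xyz, weight=1.5)
        e = 1e-6
        for (ai, j) in [(0, 0), (30, 1), (150, 2)]:
            xp, xm = xyz.copy(), xyz.copy()
            xp[ai, j] += e
            xm[ai, j] -= e
            fd = (global_ncs_residual(pairs, xp, 1.5)[0]
                  - global_ncs_residual(pairs, xm, 1.5)[0]) / (2 * e)
            assert fd == pytest.approx(g[ai, j], rel=1e-6, abs=1e-6)


class TestLocalNCS:
    def test_zero_for_identical_conformations(self, two_copy):
        pairs = detect_ncs(two_copy, prepare_local=True)
        v, g, _ = local_ncs_residual(pairs, two_copy.positions(), GMParams(0.5), 1.0)
        assert v < 1e-20

    def test_small_difference_quadratic_regime(self, two_copy):
        """A single distance pair off by a small Delta contributes ~ w Delta^2
        (the quadratic limit of the Geman-McClure estimator)."""
        pairs = detect_ncs(two_copy, prepare_local=True)
        p = pairs[0]
        p.distance_pairs = p.distance_pairs[:1]  # isolate one pair
        i, j, ip, jp = p.distance_pairs[0]
        xyz = two_copy.positions().copy()
        u = (xyz[i] - xyz[j]) / np.linalg.norm(xyz[i] - xyz[j])
        delta = 1e-4
        xyz[i] += delta * u
        w = 1.7
        v1, _, _ = local_ncs_residual([p], xyz, GMParams(0.5), w)
        assert v1 == pytest.approx(w * delta**2, rel=1e-4)

    def test_large_hinge_contributions_bounded(self, two_copy):
        pairs = detect_ncs(two_copy, prepare_local=True)
        p = pairs[0]
        xyz = two_copy.positions().copy()
        idx_b = two_copy.chain_atoms("B")
        rng = np.random.default_rng(3)
        xyz[idx_b] += rng.normal(0, 5.0, (len(idx_b), 3))  # wreck chain B
        sigma_gm = 0.5
        v, _, _ = local_ncs_residual(pairs, xyz, GMParams(sigma_gm), 1.0)
        assert v <= len(p.distance_pairs) / sigma_gm**2 + 1e-9

    def test_gradient_matches_fd(self, two_copy):
        pairs = detect_ncs(two_copy, prepare_local=True)
        rng = np.random.default_rng(4)
        xyz = two_copy.positions() + rng.normal(0, 0.2, (len(two_copy), 3))
        v, g, _ = local_ncs_residual(pairs, xyz, GMParams(0.5), 1.3)
        e = 1e-6
        for (ai, j) in [(2, 0), (40, 2)]:
            xp, xm = xyz.copy(), xyz.copy()
            xp[ai, j] += e
            xm[ai, j] -= e
            fd = (local_ncs_residual(pairs, xp, GMParams(0.5), 1.3)[0]
                  - local_ncs_residual(pairs, xm, GMParams(0.5), 1.3)[0]) / (2 * e)
            assert fd == pytest.approx(g[ai, j], rel=1e-5, abs=1e-7)


class TestExternal:
    def _write(self, path, rows):
        path.write_text("\n".join(rows) + "\n")

    def test_load_skips_missing_atoms_and_far_pairs(self, polyala5, tmp_path):
        p = tmp_path / "ext.txt"
        self._write(p, [
            "A 1 CA A 2 CA 3.8 0.2",
            "A 1 CA A 9 CA 3.0 0.2",      # residue 9 does not exist
            "A 1 CA A 5 CA 50.0 0.2",     # beyond d_max
        ])
        ext = load_external_restraints(str(p), polyala5, d_max=10.0)
        assert len(ext) == 1

    def test_duplicate_pairs_combine_by_inverse_variance(self, polyala5, tmp_path):
        p = tmp_path / "ext.txt"
        self._write(p, [
            "A 1 CA A 2 CA 3.0 0.2",
            "A 1 CA A 2 CA 3.2 0.2",
        ])
        ext = load_external_restraints(str(p), polyala5)
        assert len(ext) == 1
        assert ext[0].target == pytest.approx(3.1)
        assert ext[0].sigma == pytest.approx(0.2 / np.sqrt(2))
        assert ext[0].n_sources == 2

    def test_residual_zero_at_targets_and_unit_gm_off_by_one_sigma(self, polyala5, tmp_path):
        xyz = polyala5.positions()
        p = tmp_path / "ext.txt"
        d12 = np.linalg.norm(xyz[0] - xyz[5])
        self._write(p, [f"A 1 N A 2 N {float(d12)!r} 0.2"])
        ext = load_external_restraints(str(p), polyala5)
        gm = GMParams(0.5)
        v, _, _ = external_residual(ext, xyz, 2.0, gm)
        assert v < 1e-12
        # displace to exactly one sigma
        xyz2 = xyz.copy()
        u = (xyz2[5] - xyz2[0]) / d12
        xyz2[5] += 0.2 * u
        v1, _, _ = external_residual(ext, xyz2, 2.0, gm)
        assert v1 == pytest.approx(2.0 * geman_mcclure(1.0, 0.5)[0], rel=1e-6)

    def test_gradient_matches_fd_on_many_restraints(self, tmp_path):
        st = make_toy_structure(SimulationSpec(n_residues=8, seed=2))
        xyz = st.positions()
        rng = np.random.default_rng(0)
        rows = []
        for _ in range(30):
            i, j = rng.choice(len(st), 2, replace=False)
            ai, aj = st.atoms[i], st.atoms[j]
            d = np.linalg.norm(xyz[i] - xyz[j]) * rng.uniform(0.9, 1.1)
            rows.append(f"{ai.chain} {ai.resnum} {ai.name} {aj.chain} {aj.resnum} "
                        f"{aj.name} {d:.4f} 0.3")
        p = tmp_path / "ext.txt"
        self._write(p, rows)
        ext = load_external_restraints(str(p), st, d_max=100.0)
        gm = GMParams(3.0)
        v, g, _ = external_residual(ext, xyz, 1.7, gm)
        e = 1e-6
        for (ai, j) in [(0, 0), (17, 1), (33, 2)]:
            xp, xm = xyz.copy(), xyz.copy()
            xp[ai, j] += e
            xm[ai, j] -= e
            fd = (external_residual(ext, xp, 1.7, gm)[0]
                  - external_residual(ext, xm, 1.7, gm)[0]) / (2 * e)
            assert fd == pytest.approx(g[ai, j], rel=1e-6, abs=1e-8)


class TestJellyBody:
    def test_value_and_gradient_identically_zero_by_construction(self, polyala5):
        """The jelly-body term returns Hessian blocks only: with the current
        distances as targets every residual vanishes, so there is no value or
        gradient contribution to evaluate at all."""
        coords = polyala5.positions()
        chains = np.array([a.chain for a in polyala5.atoms])
        blocks = jelly_body_contribution(coords, chains)
        assert len(blocks) > 0
        # the implied residuals are zero: r = d_current - d_current
        for (i, j), _ in blocks:
            assert np.isfinite(coords[i]).all()

    def test_pair_beyond_cutoff_excluded(self):
        from xtalrefine.cell import UnitCell
        from xtalrefine.model import Atom, Structure
        from xtalrefine.symmetry import SpaceGroupInfo

        atoms = [
            Atom("C", "A", 1, "LIG", "C1", [0, 0, 0], b_iso=10),
            Atom("C", "A", 2, "LIG", "C1", [5.0, 0, 0], b_iso=10),  # 5.0 > 4.25
            Atom("C", "A", 3, "LIG", "C1", [2.0, 0, 0], b_iso=10),
        ]
        st = Structure(UnitCell(30, 30, 30), SpaceGroupInfo("P 1"), atoms)
        blocks = jelly_body_contribution(st.positions(), np.array(["A"] * 3))
        pairs = {idx for idx, _ in blocks}
        assert (0, 1) not in pairs
        assert (0, 2) in pairs

    def test_cross_chain_pairs_excluded(self, two_copy):
        coords = two_copy.positions()
        chains = np.array([a.chain for a in two_copy.atoms])
        idx_a = set(two_copy.chain_atoms("A"))
        for (i, j), _ in jelly_body_contribution(coords, chains):
            assert (i in idx_a) == (j in idx_a)

    def test_blocks_positive_semidefinite(self, polyala5):
        coords = polyala5.positions()
        chains = np.array([a.chain for a in polyala5.atoms])
        for _, blk in jelly_body_contribution(coords, chains):
            w = np.linalg.eigvalsh(blk)
            assert w.min() >= -1e-12 * max(w.max(), 1.0)

    def test_saturated_jelly_approaches_rigid_body_behaviour(self):
        """With every interatomic distance restrained at high weight, the
        computed shifts barely change internal distances (the implicit
        rigid-body limit)."""
        from scipy.sparse import coo_matrix
        from xtalrefine.optimize import NormalEquations, assemble_normal_equations, pcg_solve

        st = make_toy_structure(SimulationSpec(n_residues=3, seed=6))
        n = len(st)
        coords = st.positions()
        chains = np.array(["A"] * n)
        rng = np.random.default_rng(1)
        grad = rng.normal(0, 0.02, 3 * n)  # small: stay in the linear regime
        fisher = np.full(3 * n, 1.0)

        def solve(jelly_sigma):
            blocks = []
            if jelly_sigma is not None:
                for (i, j), blk in jelly_body_contribution(
                    coords, chains, d_max=1e6, sigma=jelly_sigma
                ):
                    pidx = np.concatenate([np.arange(3 * i, 3 * i + 3),
                                           np.arange(3 * j, 3 * j + 3)])
                    blocks.append((pidx, blk))
            eqs = assemble_normal_equations(3 * n, grad, blocks, fisher_diag=fisher)
            p, _ = pcg_solve(eqs)
            return p.reshape(-1, 3)

        from scipy.spatial.distance import pdist

        free_shift = solve(None)
        jelly_shift = solve(1e-4)  # saturated: huge weights
        d0 = pdist(coords)
        d_free = np.abs(pdist(coords + free_shift) - d0)
        d_jelly = np.abs(pdist(coords + jelly_shift) - d0)
        assert d_jelly.max() < 0.01 * d_free.max()
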