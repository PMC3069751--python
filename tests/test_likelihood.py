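"""Maximum-likelihood targets: Rice, MLHL, SAD and the D/Sigma error model."""

import numpy as np
import pytest

from xtalrefine import (
    SimulationSpec,
    assign_resolution_bins,
    direct_structure_factors,
    estimate_d_sigma,
    generate_hkl,
    make_toy_structure,
    mlhl_nll,
    perturb_structure,
    rice_nll,
    sad_nll,
    simulate_observations,
)
from xtalrefine.cell import UnitCell
from xtalrefine.reflections import ReflectionSet, generate_free_flags
from xtalrefine.symmetry import SpaceGroupInfo


def rice_quadrature_oracle(fo, fc, d, sigma, n=8192):
    """Phase integral of the complex Gaussian of Fo given D*Fc (acentric)."""
    al = np.linspace(0, 2 * np.pi, n, endpoint=False)
    dens = (fo / (np.pi * sigma)) * np.exp(
        -np.abs(fo * np.exp(1j * al) - d * fc) ** 2 / sigma
    )
    return -np.log(dens.sum() * 2 * np.pi / n)


def centric_oracle(fo, fc_amp, d, sigma):
    """Two-point sum over the allowed phases of a centric reflection."""
    dens = (1 / np.sqrt(2 * np.pi * sigma)) * (
        np.exp(-((fo - d * fc_amp) ** 2) / (2 * sigma))
        + np.exp(-((fo + d * fc_amp) ** 2) / (2 * sigma))
    )
    return -np.log(dens)


def mlhl_quadrature_oracle(fo, fc, hl, d, sigma, n=10000):
    """Fine-grid phase integral with the HL prior reweighting the uniform
    phase measure (flat prior recovers the Rice value exactly)."""
    al = np.linspace(0, 2 * np.pi, n, endpoint=False)
    logpr = (hl[0] * np.cos(al) + hl[1] * np.sin(al)
             + hl[2] * np.cos(2 * al) + hl[3] * np.sin(2 * al))
    pr = np.exp(logpr)
    pr /= pr.sum() * 2 * np.pi / n
    joint = (fo / (np.pi * sigma)) * np.exp(
        -np.abs(fo * np.exp(1j * al) - d * fc) ** 2 / sigma
    )
    # the prior reweights the uniform phase measure: Int joint * (2 pi pr) da
    return -np.log((joint * (2 * np.pi * pr)).sum() * 2 * np.pi / n)


class TestRice:
    def test_zero_model_closed_form(self):
        v, ga, gb = rice_nll(1.0, 0j, 0.7, 1.0)
        assert v == pytest.approx(1.0 - np.log(2.0), abs=1e-12)
        assert (ga, gb) == (0.0, 0.0)

    def test_matches_phase_quadrature_oracle(self, rng):
        for _ in range(25):
            fo = rng.uniform(0.5, 30)
            fc = rng.uniform(0.1, 30) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d = rng.uniform(0.3, 1.0)
            sig = rng.uniform(0.5, 50)
            v, _, _ = rice_nll(fo, fc, d, sig)
            assert v == pytest.approx(rice_quadrature_oracle(fo, fc, d, sig), abs=1e-6)

    def test_centric_matches_two_point_oracle(self, rng):
        for _ in range(20):
            fo, amp = rng.uniform(0.5, 30, 2)
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 50)
            v, _, _ = rice_nll(fo, amp + 0j, d, sig, centric=True)
            assert v == pytest.approx(centric_oracle(fo, amp, d, sig), abs=1e-10)

    def test_gradients_match_finite_differences(self, rng):
        for _ in range(50):
            fo = rng.uniform(0.5, 30)
            fc = rng.uniform(0.5, 30) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 50)
            cen = bool(rng.random() < 0.3)
            v, ga, gb = rice_nll(fo, fc, d, sig, centric=cen)
            e = 1e-6
            fa = (rice_nll(fo, fc + e, d, sig, cen)[0] - rice_nll(fo, fc - e, d, sig, cen)[0]) / (2 * e)
            fb = (rice_nll(fo, fc + 1j * e, d, sig, cen)[0] - rice_nll(fo, fc - 1j * e, d, sig, cen)[0]) / (2 * e)
            gn = max(np.hypot(ga, gb), 1e-9)
            assert abs(fa - ga) < 1e-6 * gn + 1e-9
            assert abs(fb - gb) < 1e-6 * gn + 1e-9

    def test_no_overflow_at_huge_argument(self):
        v, ga, gb = rice_nll(1e4, 1e4 + 0j, 1.0, 0.01)  # argument 2e10/0.01 huge
        assert np.isfinite(v) and np.isfinite(ga)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            rice_nll(-1.0, 1.0 + 0j, 0.9, 1.0)

    def test_weighted_least_squares_limit(self):
        """For large D|Fo||Fc|/Sigma the Rice target behaves as the weighted
        least-squares residual (|Fo| - D|Fc|)^2 / Sigma (the Gaussian limit
        of the amplitude distribution, variance Sigma/2 per real component):
        paired perturbations give a ratio of increments -> 1 within 1%."""
        d, sig = 0.95, 1.0
        fo = 4000.0
        for fc in (3500.0, 4200.0):  # argument ~1.5e7
            v1, _, _ = rice_nll(fo, fc + 0j, d, sig)
            v2, _, _ = rice_nll(fo, fc + 2.0 + 0j, d, sig)
            wls1 = (fo - d * fc) ** 2 / sig
            wls2 = (fo - d * (fc + 2.0)) ** 2 / sig
            assert (v2 - v1) / (wls2 - wls1) == pytest.approx(1.0, abs=0.01)


class TestMLHL:
    def test_flat_prior_reduces_to_rice_acentric(self, rng):
        worst = 0.0
        for _ in range(1000):
            fo = rng.uniform(0.5, 20)
            fc = rng.uniform(0.1, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 30)
            v1, _, _ = mlhl_nll(fo, fc, np.zeros(4), d, sig)
            v0, _, _ = rice_nll(fo, fc, d, sig)
            worst = max(worst, abs(v1 - v0))
        assert worst < 1e-10

    def test_flat_prior_reduces_to_rice_centric_on_allowed_phase(self, rng):
        for _ in range(50):
            ph = rng.uniform(0, np.pi)
            fo, amp = rng.uniform(0.5, 20, 2)
            fc = amp * np.exp(1j * (ph + np.pi * (rng.random() < 0.5)))
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 30)
            v1, _, _ = mlhl_nll(fo, fc, np.zeros(4), d, sig, centric=True,
                                restricted_phase=ph)
            v0, _, _ = rice_nll(fo, fc, d, sig, centric=True)
            assert abs(v1 - v0) < 1e-10

    def test_aligned_prior_scores_better_than_antialigned(self):
        fo, amp, d, sig = 10.0, 8.0, 0.9, 5.0
        fc = amp * np.exp(1j * 0.7)
        hl_plus = np.array([10 * np.cos(0.7), 10 * np.sin(0.7), 0, 0])
        va, _, _ = mlhl_nll(fo, fc, hl_plus, d, sig)
        vb, _, _ = mlhl_nll(fo, fc, -hl_plus, d, sig)
        assert va < vb

    def test_matches_fine_grid_oracle(self, rng):
        for _ in range(20):
            fo = rng.uniform(0.5, 20)
            fc = rng.uniform(0.1, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 30)
            hl = np.concatenate([rng.normal(0, 3, 2), rng.normal(0, 1, 2)])
            v, _, _ = mlhl_nll(fo, fc, hl, d, sig)
            assert v == pytest.approx(mlhl_quadrature_oracle(fo, fc, hl, d, sig), abs=1e-8)

    def test_gradients_match_finite_differences(self, rng):
        for _ in range(20):
            fo = rng.uniform(0.5, 20)
            fc = rng.uniform(0.5, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d, sig = rng.uniform(0.3, 1.0), rng.uniform(0.5, 30)
            hl = np.concatenate([rng.normal(0, 3, 2), rng.normal(0, 1, 2)])
            v, ga, gb = mlhl_nll(fo, fc, hl, d, sig)
            e = 1e-6
            fa = (mlhl_nll(fo, fc + e, hl, d, sig)[0] - mlhl_nll(fo, fc - e, hl, d, sig)[0]) / (2 * e)
            fb = (mlhl_nll(fo, fc + 1j * e, hl, d, sig)[0] - mlhl_nll(fo, fc - 1j * e, hl, d, sig)[0]) / (2 * e)
            gn = max(np.hypot(ga, gb), 1e-9)
            assert abs(fa - ga) < 1e-5 * gn + 1e-9
            assert abs(fb - gb) < 1e-5 * gn + 1e-9

    def test_pathological_hl_magnitudes_raise(self):
        with pytest.raises(RuntimeError, match="quadrature"):
            mlhl_nll(10.0, 8.0 + 0j, np.array([0.0, 0.0, 5e4, 5e4]), 0.9, 5.0)


class TestSAD:
    def test_degenerate_point_matches_symmetric_oracle(self):
        """With no anomalous signal (F_c- = conj(F_c+), here a real F_c, and
        equal mates) the value matches an independent fine-grid double
        quadrature and the gradient has no component perpendicular to the
        no-anomalous manifold {A+ = A-, B+ = -B-}."""
        fo, fc = 10.0, 8.0 + 0j
        d, sig, rho = 0.9, 6.0, 0.8
        v, gp, gm = sad_nll(fo, fo, fc, fc, d, sig, sig, rho=rho)
        oracle = _sad_oracle(fo, fo, fc, fc, d, sig, sig, rho, n=512)
        assert v == pytest.approx(oracle, abs=1e-6)
        # normal directions of the manifold: (1,0,-1,0) and (0,1,0,1)
        assert abs(gp[0] - gm[0]) < 1e-8
        assert abs(gp[1] + gm[1]) < 1e-8

    def test_gradients_match_finite_differences(self, rng):
        for _ in range(20):
            fop, fom = rng.uniform(1, 20, 2)
            fcp = rng.uniform(0.5, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            fcm = rng.uniform(0.5, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d = rng.uniform(0.3, 1.0)
            s1, s2 = rng.uniform(1, 30, 2)
            rho = rng.uniform(0.3, 0.95)
            v, gp, gm = sad_nll(fop, fom, fcp, fcm, d, s1, s2, rho=rho)
            gn = max(np.linalg.norm(np.concatenate([gp, gm])), 1e-9)
            e = 1e-5
            for which, comp, g in [(0, 1, gp[0]), (0, 1j, gp[1]),
                                   (1, 1, gm[0]), (1, 1j, gm[1])]:
                args_p = [fcp, fcm]
                args_p[which] = args_p[which] + comp * e
                args_m = [fcp, fcm]
                args_m[which] = args_m[which] - comp * e
                vp, _, _ = sad_nll(fop, fom, args_p[0], args_p[1], d, s1, s2, rho=rho)
                vm, _, _ = sad_nll(fop, fom, args_m[0], args_m[1], d, s1, s2, rho=rho)
                assert abs((vp - vm) / (2 * e) - g) < 1e-5 * gn

    def test_friedel_relabelling_symmetry(self, rng):
        for _ in range(10):
            fop, fom = rng.uniform(1, 20, 2)
            fcp = rng.uniform(0.5, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            fcm = rng.uniform(0.5, 20) * np.exp(1j * rng.uniform(0, 2 * np.pi))
            d, s1, s2, rho = rng.uniform(0.3, 1.0), *rng.uniform(1, 30, 2), 0.7
            v1, _, _ = sad_nll(fop, fom, fcp, fcm, d, s1, s2, rho=rho)
            v2, _, _ = sad_nll(fom, fop, fcm, fcp, d, s2, s1, rho=rho)
            assert abs(v1 - v2) < 1e-12 * max(abs(v1), 1.0)


def _sad_oracle(fo1, fo2, fcp, fcm, d, s1, s2, rho, n=512):
    """Independent double phase quadrature of the 2x2 complex Gaussian."""
    c12 = rho * np.sqrt(s1 * s2)
    det = s1 * s2 - c12**2
    minv = np.array([[s2, -c12], [-c12, s1]]) / det
    mu1, mu2 = d * fcp, d * np.conj(fcm)
    a1 = np.linspace(0, 2 * np.pi, n, endpoint=False)
    o1 = fo1 * np.exp(1j * a1)[:, None]
    o2 = fo2 * np.exp(1j * a1)[None, :]
    r1, r2 = o1 - mu1, o2 - mu2
    quad = (minv[0, 0] * np.abs(r1) ** 2 + minv[1, 1] * np.abs(r2) ** 2
            + 2 * np.real(minv[0, 1] * np.conj(r1) * r2))
    w = np.exp(-(quad - quad.min()))
    log_int = -quad.min() + np.log(w.sum() * (2 * np.pi / n) ** 2)
    return -(np.log(fo1 * fo2 / (np.pi**2 * det)) + log_int - np.log((2 * np.pi) ** 2))


class TestErrorModel:
    def _synthetic_rset(self, nb, per, d_true, s_true, fc_range, seed, free_frac=0.5):
        rng = np.random.default_rng(seed)
        cell = UnitCell(40, 40, 40)
        sg = SpaceGroupInfo("P 1")
        all_h = generate_hkl(cell, sg, 1.2)
        all_h = all_h[np.argsort(cell.s_squared(all_h), kind="stable")]
        take = all_h[: nb * per]
        fc = rng.uniform(*fc_range, nb * per)
        fo = np.empty(nb * per)
        for b in range(nb):
            sl = slice(b * per, (b + 1) * per)
            re = d_true[b] * fc[sl] + rng.normal(0, np.sqrt(s_true[b] / 2), per)
            im = rng.normal(0, np.sqrt(s_true[b] / 2), per)
            fo[sl] = np.hypot(re, im)
        rset = ReflectionSet(
            cell=cell, spacegroup=sg, hkl=take, f_obs=fo,
            sig_f=np.full(nb * per, 1e-3),
            free=generate_free_flags(take, free_frac, seed=seed),
        )
        assign_resolution_bins(rset, nb)
        return rset, fc

    def test_perfect_model_limit(self, p21_fixture):
        """Fc identical to Fo with vanishing sigma_o drives D -> 1 and
        Sigma_mod -> 0 in every bin."""
        st, rset0 = p21_fixture
        import copy

        rset = copy.copy(rset0)
        fc = np.abs(direct_structure_factors(st, rset.hkl))
        rset.f_obs = fc.copy()
        rset.sig_f = np.full(len(rset), 1e-6)
        assign_resolution_bins(rset, 3)
        cov = estimate_d_sigma(rset, fc)
        assert np.all(cov.d_bins > 0.999)
        assert np.all(cov.sigma_mod_bins < 1e-4 * np.mean(fc**2))

    def test_luzzati_decay_with_resolution(self):
        """Coordinates randomized to 0.5 A rmsd: D falls monotonically with
        1/d^2 (Luzzati behaviour)."""
        spec = SimulationSpec(n_residues=10, d_min=2.0, seed=7)
        st = make_toy_structure(spec)
        rset = simulate_observations(st, spec)
        bad = perturb_structure(st, 0.5, seed=3)
        fc = np.abs(direct_structure_factors(bad, rset.hkl))
        assign_resolution_bins(rset, 3)
        cov = estimate_d_sigma(rset, fc)
        assert np.all(np.diff(cov.d_bins) < 0.0)
        assert cov.d_bins[0] > 0.85 and cov.d_bins[-1] < 0.85

    def test_parameter_recovery_from_rice_simulation(self):
        """Known per-bin (D, Sigma_mod) recovered from simulated data with
        2000 work + 2000 free reflections per bin."""
        d_true = np.array([0.95, 0.9, 0.85, 0.8])
        s_true = np.array([10.0, 20.0, 30.0, 40.0])
        rset, fc = self._synthetic_rset(4, 4000, d_true, s_true, (20, 60), seed=3)
        cov = estimate_d_sigma(rset, fc)
        assert np.mean(np.abs(cov.d_bins - d_true) / d_true) < 0.05
        assert np.mean(np.abs(cov.sigma_mod_bins - s_true) / s_true) < 0.05

    def test_starved_bins_merge(self):
        d_true = np.array([0.9, 0.9])
        s_true = np.array([20.0, 20.0])
        rset, fc = self._synthetic_rset(2, 50, d_true, s_true, (20, 60), seed=4,
                                        free_frac=0.02)
        cov = estimate_d_sigma(rset, fc)  # too few free: bins merge, no crash
        assert len(cov.d_bins) >= 1
        assert np.all(cov.d_bins <= 1.0) and np.all(cov.sigma_mod_bins > 0)

    def test_d_in_unit_interval_and_sigma_positive(self):
        d_true = np.array([0.99, 0.5])
        s_true = np.array([5.0, 200.0])
        rset, fc = self._synthetic_rset(2, 500, d_true, s_true, (5, 50), seed=5)
        cov = estimate_d_sigma(rset, fc)
        assert np.all((cov.d_bins >= 0) & (cov.d_bins <= 1))
        assert np.all(cov.sigma_mod_bins > 0)
        sig = cov.sigma_of(rset)
        assert np.all(sig > 0)
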