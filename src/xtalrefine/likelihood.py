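"""Maximum-likelihood X-ray targets: Rice, MLHL and SAD minus-log-likelihoods
with analytic derivatives, and estimation of the Luzzati D / Sigma error model
in resolution bins.

Error model
-----------
Per reflection, Sigma = epsilon * Sigma_mod(bin) + sigma_o^2, with D (in
[0, 1]) and Sigma_mod (model variance, F^2 units) estimated per resolution
bin: D over working reflections, Sigma_mod over free reflections, alternating
to convergence.  Between bin centres both are interpolated linearly in 1/d^2.

All phase integrals use periodic trapezoid quadrature (spectrally accurate
for smooth periodic integrands) with grid doubling until convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special
from scipy.optimize import minimize_scalar

from .reflections import ReflectionSet

__all__ = [
    "CovarianceModel",
    "AnomalousModel",
    "estimate_d_sigma",
    "rice_nll",
    "rice_nll_terms",
    "mlhl_nll",
    "sad_nll",
    "xray_curvature_weights",
]

log = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-12


def _log_i0(x):
    x = np.abs(x)
    return np.log(special.i0e(x)) + x


def _log_cosh(x):
    x = np.abs(x)
    return x + np.log1p(np.exp(-2.0 * x)) - np.log(2.0)


def _i1_over_i0(x):
    return special.i1e(x) / special.i0e(x)


# ---------------------------------------------------------------------------
# error model
# ---------------------------------------------------------------------------


@dataclass
class AnomalousModel:
    """Anomalous scattering corrections per heavy-atom element (electrons)."""

    corrections: dict[str, tuple[float, float]]  # element -> (f', f'')

    def __post_init__(self) -> None:
        for el, (fp, fpp) in self.corrections.items():
            if fpp < 0:
                raise ValueError(f"f'' must be >= 0 (element {el})")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {el.upper(): v for el, v in self.corrections.items()}


@dataclass
class CovarianceModel:
    """Per-bin Luzzati D and model variance Sigma_mod, interpolated in 1/d^2."""

    bin_centers_s2: np.ndarray  # (nb,)
    d_bins: np.ndarray  # (nb,), in [0, 1]
    sigma_mod_bins: np.ndarray  # (nb,), >= 0

    def d_of(self, s2: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(s2, dtype=float), self.bin_centers_s2, self.d_bins)

    def sigma_mod_of(self, s2: np.ndarray) -> np.ndarray:
        return np.interp(
            np.asarray(s2, dtype=float), self.bin_centers_s2, self.sigma_mod_bins
        )

    def sigma_of(self, rset: ReflectionSet) -> np.ndarray:
        """Effective per-reflection Sigma = eps * Sigma_mod + sigma_o^2."""
        sm = self.sigma_mod_of(rset.s2)
        return np.maximum(rset.epsilon * sm + rset.sig_f**2, SIGMA_FLOOR)

    def per_reflection(self, rset: ReflectionSet) -> tuple[np.ndarray, np.ndarray]:
        return self.d_of(rset.s2), self.sigma_of(rset)


def rice_nll_terms(f_obs, f_calc_abs, d, sigma, centric):
    """Vectorized Rice minus-log-likelihood and d/d|Fc| per reflection.

    Acentric: -log[(2|Fo|/S) exp(-(|Fo|^2 + D^2|Fc|^2)/S) I0(2 D|Fo||Fc|/S)]
    Centric:  -log[(2/(pi S))^(1/2) exp(-(|Fo|^2+D^2|Fc|^2)/(2S))
                   cosh(D|Fo||Fc|/S)]
    """
    fo = np.asarray(f_obs, dtype=float)
    if np.any(fo < 0):
        raise ValueError("observed amplitudes must be non-negative")
    fc = np.asarray(f_calc_abs, dtype=float)
    d = np.asarray(d, dtype=float)
    s = np.maximum(np.asarray(sigma, dtype=float), SIGMA_FLOOR)
    cen = np.asarray(centric, dtype=bool)

    z_ac = 2.0 * d * fo * fc / s
    nll_ac = -np.log(2.0 * fo / s) + (fo**2 + d**2 * fc**2) / s - _log_i0(z_ac)
    g_ac = 2.0 * d**2 * fc / s - (2.0 * d * fo / s) * _i1_over_i0(z_ac)

    z_c = d * fo * fc / s
    nll_c = (
        -0.5 * np.log(2.0 / (np.pi * s))
        + (fo**2 + d**2 * fc**2) / (2.0 * s)
        - _log_cosh(z_c)
    )
    g_c = d**2 * fc / s - (d * fo / s) * np.tanh(z_c)

    return np.where(cen, nll_c, nll_ac), np.where(cen, g_c, g_ac)


def rice_nll(f_obs: float, f_calc: complex, d: float, sigma: float,
             centric: bool = False) -> tuple[float, float, float]:
    """Rice minus-log-likelihood for one reflection.

    Returns (value, d/dA_c, d/dB_c) where F_c = A_c + i B_c.  The value is
    finite for arguments up to ~1e6 (Bessel/cosh evaluated in log space).
    """
    a, b = float(np.real(f_calc)), float(np.imag(f_calc))
    amp = np.hypot(a, b)
    val, g = rice_nll_terms(f_obs, amp, d, sigma, centric)
    if amp > 0:
        return float(val), float(g * a / amp), float(g * b / amp)
    return float(val), 0.0, 0.0


def xray_curvature_weights(rset: ReflectionSet, cov: CovarianceModel) -> np.ndarray:
    """Positive per-reflection curvature proxies for the Fisher-diagonal
    X-ray contribution to the normal matrix: 2 D^2/Sigma (acentric) or
    D^2/Sigma (centric), the weighted-least-squares limits of the Rice
    target."""
    d, s = cov.per_reflection(rset)
    w = 2.0 * d**2 / s
    return np.where(rset.centric, 0.5 * w, w)


# ---------------------------------------------------------------------------
# D / Sigma estimation
# ---------------------------------------------------------------------------


def _bin_nll(fo, fc, eps, sig, cen, d, sigma_mod):
    sigma = eps * sigma_mod + sig**2
    val, _ = rice_nll_terms(fo, fc, d, sigma, cen)
    return float(np.sum(val))


def estimate_d_sigma(
    rset: ReflectionSet,
    f_calc_abs: np.ndarray,
    min_free: int = 5,
    max_alternations: int = 100,
    tol: float = 1e-4,
) -> CovarianceModel:
    """Estimate per-bin D (work reflections) and Sigma_mod (free reflections),
    alternating until both changes fall below ``tol``.

    Bins with fewer than ``min_free`` free (or work) reflections are merged
    with their lower-resolution neighbour.
    """
    if rset.bin_index is None:
        raise ValueError("assign_resolution_bins must be called first")
    fc = np.abs(np.asarray(f_calc_abs))
    s2 = rset.s2

    # merge under-populated bins (scan from low to high resolution)
    raw_bins = list(range(rset.n_bins))
    groups: list[list[int]] = []
    for b in raw_bins:
        members = rset.bin_index == b
        nf = int((members & rset.free).sum())
        nw = int((members & rset.work).sum())
        if groups and (nf < min_free or nw < min_free):
            groups[-1].append(b)
            log.warning("bin %d merged with neighbour (too few reflections)", b)
        else:
            groups.append([b])
    # a leading starved group merges forward
    if len(groups) > 1:
        members = np.isin(rset.bin_index, groups[0])
        if (members & rset.free).sum() < min_free or (members & rset.work).sum() < min_free:
            groups[1] = groups[0] + groups[1]
            groups = groups[1:]

    centers, d_out, s_out = [], [], []
    for grp in groups:
        sel = np.isin(rset.bin_index, grp)
        fo_b, fc_b = rset.f_obs[sel], fc[sel]
        eps_b = rset.epsilon[sel].astype(float)
        sig_b, cen_b = rset.sig_f[sel], rset.centric[sel]
        wk, fr = rset.work[sel], rset.free[sel]
        if not fr.any():
            fr = wk  # degenerate fixture: fall back to work reflections
        scale = float(np.mean(fo_b**2)) + SIGMA_FLOOR
        d_cur = min(max(float(np.sum(fo_b * fc_b) / max(np.sum(fc_b**2), SIGMA_FLOOR)), 0.05), 1.0)
        s_cur = max(float(np.mean((fo_b - d_cur * fc_b) ** 2 / eps_b)), 1e-8 * scale)
        for _ in range(max_alternations):
            d_prev, s_prev = d_cur, s_cur
            res = minimize_scalar(
                lambda d_: _bin_nll(fo_b[wk], fc_b[wk], eps_b[wk], sig_b[wk], cen_b[wk], d_, s_cur),
                bounds=(0.0, 1.0),
                method="bounded",
                options={"xatol": 1e-6},
            )
            d_cur = float(res.x)
            res = minimize_scalar(
                lambda s_: _bin_nll(fo_b[fr], fc_b[fr], eps_b[fr], sig_b[fr], cen_b[fr], d_cur, np.exp(s_)),
                bounds=(np.log(1e-10 * scale), np.log(1e3 * scale)),
                method="bounded",
                options={"xatol": 1e-8},
            )
            s_cur = float(np.exp(res.x))
            if abs(d_cur - d_prev) < tol and abs(s_cur - s_prev) < tol * max(s_prev, SIGMA_FLOOR):
                break
        centers.append(float(np.mean(s2[sel])))
        d_out.append(d_cur)
        s_out.append(s_cur)

    order = np.argsort(centers)
    return CovarianceModel(
        bin_centers_s2=np.array(centers)[order],
        d_bins=np.array(d_out)[order],
        sigma_mod_bins=np.array(s_out)[order],
    )


# ---------------------------------------------------------------------------
# MLHL
# ---------------------------------------------------------------------------


def _phase_grid_quadrature(log_weight_fn, n0: int = 180, tol: float = 1e-8,
                           max_doublings: int = 4):
    """log of the periodic-trapezoid integral of exp(log_weight(alpha)),
    with grid doubling until the change in the log integral is < tol.
    Returns (log_integral, alphas, weights_normalized) at the final grid."""
    n = n0
    prev = None
    for _ in range(max_doublings + 1):
        alphas = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        lw = log_weight_fn(alphas)
        m = lw.max()
        val = m + np.log(np.sum(np.exp(lw - m)) * (2.0 * np.pi / n))
        if prev is not None and abs(val - prev) < tol:
            w = np.exp(lw - m)
            return val, alphas, w / w.sum()
        prev = val
        n *= 2
    raise RuntimeError(
        "phase quadrature failed to converge (pathological HL magnitudes?)"
    )


def mlhl_nll(
    f_obs: float,
    f_calc: complex,
    hl: np.ndarray,
    d: float,
    sigma: float,
    centric: bool = False,
    restricted_phase: float | None = None,
) -> tuple[float, float, float]:
    """Minus log-likelihood with a Hendrickson-Lattman phase prior.

    Acentric value:
        -log [ (|Fo|/(pi S)) Int exp(E(a)) P_pr(a) da ]
    with E(a) = (-(|Fo|^2 + D^2|Fc|^2) + 2 D |Fo| (A_c cos a + B_c sin a))/S
    and P_pr(a) = exp(A cos a + B sin a + C cos 2a + D sin 2a)/N.

    Centric value: two-term sum over the allowed phases.  With A=B=C=D=0 the
    value equals ``rice_nll`` exactly.

    Returns (value, d/dA_c, d/dB_c).
    """
    ha, hb, hc, hd = (float(x) for x in np.asarray(hl, dtype=float))
    fo = float(f_obs)
    if fo < 0:
        raise ValueError("observed amplitude must be non-negative")
    s = max(float(sigma), SIGMA_FLOOR)
    ac, bc = float(np.real(f_calc)), float(np.imag(f_calc))
    amp2 = ac * ac + bc * bc

    if centric:
        if restricted_phase is None:
            raise ValueError("centric MLHL needs the restricted phase")
        a1 = float(restricted_phase)
        alphas = np.array([a1, a1 + np.pi])
        prior = ha * np.cos(alphas) + hb * np.sin(alphas)
        prior_log_n = special.logsumexp(prior)
        # real-Gaussian exponent per allowed phase
        expo = -(
            fo**2
            + d**2 * amp2
            - 2.0 * d * fo * (ac * np.cos(alphas) + bc * np.sin(alphas))
        ) / (2.0 * s) + (prior - prior_log_n)
        m = expo.max()
        lse = m + np.log(np.exp(expo - m).sum())
        value = -0.5 * np.log(2.0 / (np.pi * s)) - lse
        w = np.exp(expo - m)
        w /= w.sum()
        ga = np.sum(w * (d**2 * ac - d * fo * np.cos(alphas)) / s)
        gb = np.sum(w * (d**2 * bc - d * fo * np.sin(alphas)) / s)
        return float(value), float(ga), float(gb)

    def log_weight(alphas):
        return (
            -(fo**2 + d**2 * amp2) / s
            + 2.0 * d * fo * (ac * np.cos(alphas) + bc * np.sin(alphas)) / s
            + ha * np.cos(alphas)
            + hb * np.sin(alphas)
            + hc * np.cos(2.0 * alphas)
            + hd * np.sin(2.0 * alphas)
        )

    def log_prior(alphas):
        return (
            ha * np.cos(alphas)
            + hb * np.sin(alphas)
            + hc * np.cos(2.0 * alphas)
            + hd * np.sin(2.0 * alphas)
        )

    log_num, alphas, w = _phase_grid_quadrature(log_weight)
    log_den, _, _ = _phase_grid_quadrature(log_prior)
    # the HL prior reweights the phase relative to the uniform measure:
    # with A=B=C=D=0 this reduces exactly to the Rice value
    value = -np.log(2.0 * fo / s) - (log_num - log_den)
    # gradient: posterior average of -dE/dFc
    ga = np.sum(w * (2.0 * d**2 * ac - 2.0 * d * fo * np.cos(alphas)) / s)
    gb = np.sum(w * (2.0 * d**2 * bc - 2.0 * d * fo * np.sin(alphas)) / s)
    return float(value), float(ga), float(gb)


# ---------------------------------------------------------------------------
# SAD
# ---------------------------------------------------------------------------


def sad_nll(
    f_obs_plus: float,
    f_obs_minus: float,
    f_calc_plus: complex,
    f_calc_minus: complex,
    d: float,
    sigma_plus: float,
    sigma_minus: float,
    rho: float = 0.9,
    n0: int = 64,
    tol: float = 1e-7,
    max_doublings: int = 4,
) -> tuple[float, np.ndarray, np.ndarray]:
    """SAD minus-log-likelihood: the joint complex Gaussian of
    (F+, conj(F-)) given (D Fc+, D conj(Fc-)) with a 2x2 Hermitian covariance
    [[S+, rho sqrt(S+ S-)], [rho sqrt(S+ S-), S-]], integrated over both
    unknown phases by nested periodic trapezoid quadrature.

    ``rho`` is the correlation of the two mates' model errors (the protein
    part is common to both Friedel mates; only the anomalous part decouples
    them).

    Returns (value, grad_plus, grad_minus) with gradients as (d/dA, d/dB)
    arrays for F_c+ and F_c- respectively.
    """
    fo1, fo2 = float(f_obs_plus), float(f_obs_minus)
    if fo1 < 0 or fo2 < 0:
        raise ValueError("observed amplitudes must be non-negative")
    s1 = max(float(sigma_plus), SIGMA_FLOOR)
    s2 = max(float(sigma_minus), SIGMA_FLOOR)
    rho = float(np.clip(rho, -0.999, 0.999))
    c12 = rho * np.sqrt(s1 * s2)
    det = s1 * s2 - c12 * c12
    minv = np.array([[s2, -c12], [-c12, s1]]) / det  # real symmetric here

    mu1 = d * complex(f_calc_plus)
    mu2 = d * np.conj(complex(f_calc_minus))

    n = n0
    prev_val = None
    for _ in range(max_doublings + 1):
        a1 = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        a2 = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        o1 = fo1 * np.exp(1j * a1)[:, None]  # (n, 1)
        o2 = fo2 * np.exp(1j * a2)[None, :]  # (1, n)
        r1 = o1 - mu1
        r2 = o2 - mu2
        quad = (
            minv[0, 0] * np.abs(r1) ** 2
            + minv[1, 1] * np.abs(r2) ** 2
            + 2.0 * np.real(minv[0, 1] * np.conj(r1) * r2)
        )
        lw = -quad
        m = lw.max()
        w = np.exp(lw - m)
        sw = w.sum()
        log_int = m + np.log(sw * (2.0 * np.pi / n) ** 2)
        value = -(
            np.log(fo1 * fo2 / (np.pi**2 * det)) + log_int - np.log((2.0 * np.pi) ** 2)
        )
        if prev_val is not None and abs(value - prev_val) < tol:
            break
        prev_val = value
        n *= 2
    # posterior-averaged gradient w.r.t. mu (Wirtinger -> real pairs)
    w = w / sw
    mr1 = minv[0, 0] * r1 + minv[0, 1] * r2  # (M r)_1 on grid
    mr2 = minv[1, 0] * r1 + minv[1, 1] * r2
    d_re_mu1 = np.sum(w * (-2.0) * np.real(mr1))
    d_im_mu1 = np.sum(w * (-2.0) * np.imag(mr1))
    d_re_mu2 = np.sum(w * (-2.0) * np.real(mr2))
    d_im_mu2 = np.sum(w * (-2.0) * np.imag(mr2))
    # V = <quad>; dV/d mu = -<dquad/dmu> with quad depending on -mu
    grad_plus = np.array([d * -d_re_mu1, d * -d_im_mu1]) * -1.0
    grad_minus = np.array([d * -d_re_mu2, d * d_im_mu2]) * -1.0
    return float(value), grad_plus, grad_minus
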