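"""Structure factors and scaling.

* Direct-summation structure factors from the atomic model (with analytic
  derivatives with respect to positions, ADPs and occupancies).
* Babinet and mask bulk-solvent models.
* Total structure factor composition and Gauss-Newton scale estimation with
  eigenvalue filtering.

The total structure factor is composed as

    F_total = k_overall * exp(-2 pi^2 s^T U_aniso s)
              * (1 - k_babinet0 exp(-B_babinet |s|^2 / 4))
              * (F_protein + k_mask exp(-B_mask |s|^2 / 4) F_mask)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cell import UnitCell
from .formfactors import FormFactorTable
from .model import Structure
from .reflections import ReflectionSet

__all__ = [
    "ScaleModel",
    "SolventMask",
    "StructureFactorDerivs",
    "direct_structure_factors",
    "structure_factor_derivs",
    "babinet_factor",
    "build_solvent_mask",
    "mask_structure_factors",
    "total_structure_factors",
    "estimate_scales",
    "estimate_scales_twin",
    "symmetry_invariant_basis",
]

log = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi

#: van der Waals radii (A) for mask construction.
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "FE": 1.50, "HG": 1.55,
}


# ---------------------------------------------------------------------------
# direct summation
# ---------------------------------------------------------------------------


@dataclass
class StructureFactorDerivs:
    """F_protein and its analytic derivatives per atom.

    Attributes
    ----------
    f : (n_refl,) complex
    d_xyz : (n_refl, n_atoms, 3) complex, d F / d x_cart (1/A)
    d_b : (n_refl, n_atoms) complex, d F / d B_iso (for isotropic atoms)
    d_occ : (n_refl, n_atoms) complex
    d_u : (n_refl, n_atoms, 6) complex or None, d F / d U components
        (U11, U22, U33, U12, U13, U23, Cartesian) for anisotropic atoms
    """

    f: np.ndarray
    d_xyz: np.ndarray
    d_b: np.ndarray
    d_occ: np.ndarray
    d_u: np.ndarray | None = None


def _atom_arrays(structure: Structure):
    xyz = structure.positions()
    occ = structure.occupancies()
    b = structure.b_values()
    elements = [a.element for a in structure.atoms]
    aniso = [a.u_aniso for a in structure.atoms]
    return xyz, occ, b, elements, aniso


def direct_structure_factors(
    structure: Structure,
    hkl: np.ndarray,
    table: FormFactorTable | None = None,
    anomalous: dict[str, tuple[float, float]] | None = None,
) -> np.ndarray:
    """F_protein(h) by direct summation over symmetry mates and atoms.

    ``anomalous`` maps element symbols to (f', f'') corrections (electrons);
    with a nonzero f'' the Friedel symmetry F(-h) = conj(F(h)) is broken, as
    it is physically.
    """
    return _direct_sum(structure, hkl, table, anomalous, derivs=False).f


def structure_factor_derivs(
    structure: Structure,
    hkl: np.ndarray,
    table: FormFactorTable | None = None,
    anomalous: dict[str, tuple[float, float]] | None = None,
) -> StructureFactorDerivs:
    """F_protein plus analytic derivatives w.r.t. x (Cartesian), B, occ, U."""
    return _direct_sum(structure, hkl, table, anomalous, derivs=True)


def _direct_sum(structure, hkl, table, anomalous, derivs):
    table = table or FormFactorTable()
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    cell = structure.cell
    xyz, occ, b_iso, elements, aniso = _atom_arrays(structure)
    n_refl, n_atoms = len(hkl), len(xyz)
    for el in set(elements):
        if el not in table:
            raise KeyError(f"no form factor tabulated for element {el!r}")

    s2 = cell.s_squared(hkl)  # |s|^2, op-invariant
    frac = cell.fractionalize(xyz)  # (n_atoms, 3)

    # per-element scattering factors (shared across ops)
    f_elem = {el: table.evaluate(el, s2) for el in set(elements)}
    fj = np.empty((n_refl, n_atoms))
    for j, el in enumerate(elements):
        fj[:, j] = f_elem[el]
    if anomalous:
        fj = fj.astype(complex)
        for el, (fp, fpp) in anomalous.items():
            corr = complex(fp, fpp)
            for j, e in enumerate(elements):
                if e == el.upper():
                    fj[:, j] = fj[:, j] + corr

    is_aniso = np.array([u is not None for u in aniso])
    t_iso = np.exp(-b_iso[None, :] * s2[:, None] / 4.0)  # used where isotropic

    f_sum = np.zeros(n_refl, dtype=complex)
    d_xyz = np.zeros((n_refl, n_atoms, 3), dtype=complex) if derivs else None
    d_b = np.zeros((n_refl, n_atoms), dtype=complex) if derivs else None
    d_occ = np.zeros((n_refl, n_atoms), dtype=complex) if derivs else None
    d_u = (
        np.zeros((n_refl, n_atoms, 6), dtype=complex)
        if derivs and is_aniso.any()
        else None
    )

    for op in structure.spacegroup.operators:
        h_eff = hkl @ op.rot  # (n_refl, 3)
        s_op = h_eff @ cell.frac_matrix  # Cartesian reciprocal vectors
        phase_arg = TWO_PI * (h_eff @ frac.T + (hkl @ op.tran)[:, None])
        phase = np.exp(1j * phase_arg)  # (n_refl, n_atoms)

        t_fac = t_iso.copy().astype(float)
        if is_aniso.any():
            for j in np.flatnonzero(is_aniso):
                u = aniso[j]
                expo = -2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", s_op, u, s_op)
                t_fac[:, j] = np.exp(expo)

        contrib = occ[None, :] * fj * t_fac * phase
        f_sum += contrib.sum(axis=1)
        if derivs:
            d_xyz += 1j * TWO_PI * s_op[:, None, :] * contrib[:, :, None]
            d_b += contrib * (-s2[:, None] / 4.0)
            with np.errstate(divide="ignore", invalid="ignore"):
                d_occ += np.where(occ[None, :] > 0, contrib / occ[None, :], 0.0)
            if d_u is not None:
                # d/dU_ab of exp(-2 pi^2 s^T U s): -2 pi^2 s_a s_b (x2 off-diag)
                ss = np.stack(
                    [
                        s_op[:, 0] ** 2,
                        s_op[:, 1] ** 2,
                        s_op[:, 2] ** 2,
                        2 * s_op[:, 0] * s_op[:, 1],
                        2 * s_op[:, 0] * s_op[:, 2],
                        2 * s_op[:, 1] * s_op[:, 2],
                    ],
                    axis=1,
                )  # (n_refl, 6)
                for j in np.flatnonzero(is_aniso):
                    d_u[:, j, :] += (
                        -2.0 * np.pi**2 * ss * contrib[:, j][:, None]
                    )
    if derivs and is_aniso.any():
        # isotropic-B derivative is meaningless for aniso atoms
        d_b[:, is_aniso] = 0.0
    if not derivs:
        return StructureFactorDerivs(f=f_sum, d_xyz=None, d_b=None, d_occ=None)
    return StructureFactorDerivs(f=f_sum, d_xyz=d_xyz, d_b=d_b, d_occ=d_occ, d_u=d_u)


# ---------------------------------------------------------------------------
# bulk solvent
# ---------------------------------------------------------------------------


def babinet_factor(s_abs, k_babinet0: float, b_babinet: float) -> np.ndarray:
    """Babinet solvent multiplier 1 - k0 exp(-B |s|^2 / 4) (applied to F)."""
    if k_babinet0 < 0 or b_babinet < 0:
        raise ValueError("Babinet parameters must be non-negative")
    s_abs = np.asarray(s_abs, dtype=float)
    return 1.0 - k_babinet0 * np.exp(-b_babinet * s_abs**2 / 4.0)


@dataclass
class SolventMask:
    """Voxel solvent/protein flags on a cell-commensurate periodic grid."""

    grid: np.ndarray  # bool, True = solvent
    cell: UnitCell
    probe_radius: float
    shrink_radius: float

    @property
    def solvent_fraction(self) -> float:
        return float(self.grid.mean())


def _periodic_label(solvent: np.ndarray) -> np.ndarray:
    """Connected-component labels (6-connectivity) under periodic boundaries."""
    labels, n = ndimage.label(solvent)
    if n <= 1:
        return labels
    # union-find merge across the three wrapped faces
    parent = list(range(n + 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for axis in range(3):
        lo = np.take(labels, 0, axis=axis)
        hi = np.take(labels, -1, axis=axis)
        both = (lo > 0) & (hi > 0)
        for a, b in zip(lo[both].ravel(), hi[both].ravel()):
            union(int(a), int(b))
    remap = np.array([find(i) for i in range(n + 1)])
    return remap[labels]


def build_solvent_mask(
    structure: Structure,
    grid_spacing: float,
    probe_radius: float = 1.0,
    shrink_radius: float = 1.1,
    d_min: float | None = None,
) -> SolventMask:
    """Flat bulk-solvent mask: protein = within (vdW + probe) of any
    symmetry-expanded atom, then shrunk back by ``shrink_radius``; interior
    solvent cavities (not periodically connected to the largest solvent
    component) are reassigned to protein.
    """
    if d_min is not None and grid_spacing > d_min / 4.0 + 1e-12:
        raise ValueError(
            f"grid spacing {grid_spacing} too coarse; use <= d_min/4 = {d_min / 4.0:.3f}"
        )
    cell = structure.cell
    dims = tuple(max(int(np.ceil(L / grid_spacing)), 4) for L in (cell.a, cell.b, cell.c))
    protein = np.zeros(dims, dtype=bool)

    if len(structure.atoms):
        # symmetry-expand atom sites (fractional, wrapped)
        frac = cell.fractionalize(structure.positions())
        sites = []
        radii = []
        for op in structure.spacegroup.operators:
            img = frac @ op.rot.T + op.tran
            sites.append(img % 1.0)
            radii.extend(VDW_RADII[a.element] + probe_radius for a in structure.atoms)
        sites = np.concatenate(sites, axis=0)
        radii = np.array(radii)

        # mark voxels within radius of each site (periodic, fractional metric)
        nx, ny, nz = dims
        for (fx, fy, fz), r in zip(sites, radii):
            # bounding box in voxel units per axis (cell may be non-orthogonal;
            # pad by the largest axis projection of r)
            pads = [
                int(np.ceil(r / (L / n))) + 1
                for L, n in zip((cell.a, cell.b, cell.c), dims)
            ]
            cx, cy, cz = int(round(fx * nx)), int(round(fy * ny)), int(round(fz * nz))
            ix = np.arange(cx - pads[0], cx + pads[0] + 1)
            iy = np.arange(cy - pads[1], cy + pads[1] + 1)
            iz = np.arange(cz - pads[2], cz + pads[2] + 1)
            gx, gy, gz = np.meshgrid(ix, iy, iz, indexing="ij")
            df = np.stack(
                [gx / nx - fx, gy / ny - fy, gz / nz - fz], axis=-1
            )
            df -= np.round(df)
            dcart = df @ cell.orth_matrix.T
            inside = np.einsum("...i,...i->...", dcart, dcart) <= r * r
            protein[gx[inside] % nx, gy[inside] % ny, gz[inside] % nz] = True

        if shrink_radius > 0 and protein.any() and not protein.all():
            # grow the solvent region back by the shrink radius (periodic
            # dilation via FFT convolution with a spherical kernel)
            protein = ~_periodic_dilate(~protein, shrink_radius, cell, dims)

    solvent = ~protein
    if solvent.any():
        labels = _periodic_label(solvent)
        if labels.max() > 1:
            counts = np.bincount(labels.ravel())
            counts[0] = 0
            keep = counts.argmax()
            solvent = labels == keep
    return SolventMask(
        grid=solvent, cell=cell, probe_radius=probe_radius, shrink_radius=shrink_radius
    )


def _periodic_dilate(mask: np.ndarray, radius: float, cell: UnitCell, dims) -> np.ndarray:
    nx, ny, nz = dims
    ix = np.fft.fftfreq(nx) * nx
    iy = np.fft.fftfreq(ny) * ny
    iz = np.fft.fftfreq(nz) * nz
    gx, gy, gz = np.meshgrid(ix / nx, iy / ny, iz / nz, indexing="ij")
    dcart = np.stack([gx, gy, gz], axis=-1) @ cell.orth_matrix.T
    kernel = (np.einsum("...i,...i->...", dcart, dcart) <= radius * radius).astype(float)
    conv = np.fft.ifftn(np.fft.fftn(mask.astype(float)) * np.fft.fftn(kernel)).real
    return conv > 0.5


def mask_structure_factors(mask: SolventMask, hkl: np.ndarray) -> np.ndarray:
    """Fourier coefficients of the unit-amplitude solvent indicator.

    F_mask(h) = (V/N) sum_x m(x) exp(+2 pi i h.x); F_mask(000) is the solvent
    fraction times the cell volume.
    """
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    coeffs = np.fft.fftn(mask.grid.astype(float))
    dims = np.array(mask.grid.shape)
    scale = mask.cell.volume / mask.grid.size
    idx = (-hkl) % dims  # +2 pi i convention
    return scale * coeffs[idx[:, 0], idx[:, 1], idx[:, 2]]


# ---------------------------------------------------------------------------
# scale model / total structure factors
# ---------------------------------------------------------------------------


@dataclass
class ScaleModel:
    """Overall scale, anisotropic scale tensor, solvent parameters, flags."""

    k_overall: float = 1.0
    u_aniso: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    k_mask: float = 0.0
    b_mask: float = 0.0
    k_babinet0: float = 0.0
    b_babinet: float = 200.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.u_aniso = np.asarray(self.u_aniso, dtype=float)
        if self.k_overall <= 0:
            raise ValueError("k_overall must be positive")
        for name in ("k_mask", "b_mask", "k_babinet0", "b_babinet"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def aniso_factor(self, s_cart: np.ndarray) -> np.ndarray:
        return np.exp(
            -2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", s_cart, self.u_aniso, s_cart)
        )

    def to_dict(self) -> dict:
        return {
            "k_overall": self.k_overall,
            "u_aniso": self.u_aniso.tolist(),
            "k_mask": self.k_mask,
            "b_mask": self.b_mask,
            "k_babinet0": self.k_babinet0,
            "b_babinet": self.b_babinet,
        }


def total_structure_factors(
    f_protein: np.ndarray,
    f_mask: np.ndarray | None,
    scale: ScaleModel,
    cell: UnitCell,
    hkl: np.ndarray,
) -> np.ndarray:
    """Compose scaled total structure factors from protein + solvent parts."""
    hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
    s_cart = cell.recip_vectors(hkl)
    s2 = np.einsum("ni,ni->n", s_cart, s_cart)
    core = np.asarray(f_protein, dtype=complex)
    if f_mask is not None and scale.k_mask != 0.0:
        core = core + scale.k_mask * np.exp(-scale.b_mask * s2 / 4.0) * np.asarray(f_mask)
    bab = babinet_factor(np.sqrt(s2), scale.k_babinet0, scale.b_babinet)
    return scale.k_overall * scale.aniso_factor(s_cart) * bab * core


def symmetry_invariant_basis(spacegroup, cell: UnitCell) -> np.ndarray:
    """Orthonormal basis (n_free, 3, 3) of symmetric tensors U with
    M^T U M = U for every point-group action M on Cartesian reciprocal
    vectors (Reynolds projection of the canonical 6-tensor basis)."""
    ainv = cell.frac_matrix  # h -> s is h @ ainv
    mats = []
    for rot in spacegroup.point_group_rotations:
        # s' = M s where M = ainv^T rot^T ainv^-T
        m = ainv.T @ rot.T @ np.linalg.inv(ainv.T)
        mats.append(m)
    basis6 = []
    for i, j in [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]:
        e = np.zeros((3, 3))
        e[i, j] = e[j, i] = 1.0
        proj = sum(m.T @ e @ m for m in mats) / len(mats)
        proj = 0.5 * (proj + proj.T)
        basis6.append(proj.ravel())
    b = np.array(basis6)
    u, sv, vt = np.linalg.svd(b, full_matrices=False)
    keep = sv > 1e-8 * sv.max()
    return vt[keep].reshape(-1, 3, 3)


def _ftotal_and_jac(params, layout, rset, f_protein, f_mask, basis, cell, hkl, s_cart, s2):
    """|F_total| and its Jacobian w.r.t. the active scale parameters."""
    k = params[layout["k"]]
    u = np.tensordot(params[layout["u"]], basis, axes=1) if len(layout["u"]) else np.zeros((3, 3))
    aniso = np.exp(-2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", s_cart, u, s_cart))
    core = np.asarray(f_protein, dtype=complex)
    dmask_k = dmask_b = None
    if layout["mask"]:
        km, bm = params[layout["mask"]]
        e = np.exp(-bm * s2 / 4.0)
        core = core + km * e * f_mask
        dmask_k = e * f_mask
        dmask_b = -km * s2 / 4.0 * e * f_mask
    bab = np.ones_like(s2)
    if layout["bab"]:
        kb, bb = params[layout["bab"]]
        eb = np.exp(-bb * s2 / 4.0)
        bab = 1.0 - kb * eb
    amp_core = np.abs(core)
    ftot = k * aniso * bab * amp_core
    cols = []
    # k_overall
    cols.append(aniso * bab * amp_core)
    # u components
    for bvec in basis[: len(layout["u"])]:
        q = np.einsum("ni,ij,nj->n", s_cart, bvec, s_cart)
        cols.append(-2.0 * np.pi**2 * q * ftot)
    with np.errstate(divide="ignore", invalid="ignore"):
        unit = np.where(amp_core > 0, 1.0 / amp_core, 0.0)
    if layout["mask"]:
        cols.append(k * aniso * bab * unit * np.real(np.conj(core) * dmask_k))
        cols.append(k * aniso * bab * unit * np.real(np.conj(core) * dmask_b))
    if layout["bab"]:
        kb, bb = params[layout["bab"]]
        eb = np.exp(-bb * s2 / 4.0)
        cols.append(k * aniso * (-eb) * amp_core)
        cols.append(k * aniso * (kb * s2 / 4.0 * eb) * amp_core)
    return ftot, np.stack(cols, axis=1), bab


def estimate_scales(
    rset: ReflectionSet,
    f_protein: np.ndarray,
    f_mask: np.ndarray | None = None,
    use_babinet: bool = False,
    use_aniso: bool = True,
    max_iter: int = 50,
    tol: float = 1e-8,
    initial: ScaleModel | None = None,
) -> ScaleModel:
    """Least-squares fit of |F_total| to |F_obs| (work reflections).

    Gauss-Newton with eigenvalue filtering (eigenvalues below 1e-6 of the
    largest are pseudo-inverted to zero); the anisotropic tensor is
    parameterized directly in the symmetry-invariant subspace.
    """
    if len(rset) < 20:
        raise ValueError("need at least 20 reflections for scaling")
    sel = rset.work
    hkl = rset.hkl[sel]
    fo = rset.f_obs[sel]
    cell = rset.cell
    s_cart = cell.recip_vectors(hkl)
    s2 = np.einsum("ni,ni->n", s_cart, s_cart)
    fp = np.asarray(f_protein)[sel]
    fm = np.asarray(f_mask)[sel] if f_mask is not None else None

    basis = symmetry_invariant_basis(rset.spacegroup, cell) if use_aniso else np.zeros((0, 3, 3))
    layout = {"k": 0, "u": [], "mask": [], "bab": []}
    p = [initial.k_overall if initial else max(float(np.dot(fo, np.abs(fp)) / max(np.dot(np.abs(fp), np.abs(fp)), 1e-30)), 1e-6)]
    for i in range(len(basis)):
        layout["u"].append(len(p))
        p.append(0.0)
    if fm is not None:
        layout["mask"] = [len(p), len(p) + 1]
        p += [initial.k_mask if initial else 0.35, initial.b_mask if initial else 50.0]
    if use_babinet:
        layout["bab"] = [len(p), len(p) + 1]
        if initial is not None:
            p += [initial.k_babinet0, initial.b_babinet]
        else:
            # coarse grid start: the (k0, B) pair is strongly correlated with
            # the overall scale, so begin from the best of a small grid
            best, best_res = (0.2, 200.0), np.inf
            amp_p = np.abs(fp)
            for k0 in (0.0, 0.2, 0.35, 0.5):
                for bb in (50.0, 100.0, 150.0, 200.0, 300.0):
                    mult = 1.0 - k0 * np.exp(-bb * s2 / 4.0)
                    model = amp_p * mult
                    k_fit = float(np.dot(fo, model) / max(np.dot(model, model), 1e-30))
                    res = float(np.sum((fo - k_fit * model) ** 2))
                    if res < best_res:
                        best, best_res = (k0, bb), res
            p += list(best)
    p = np.array(p, dtype=float)
    layout["u"] = list(layout["u"])

    def residual(params):
        ftot, jac, bab = _ftotal_and_jac(
            params, layout, rset, fp, fm, basis, cell, hkl, s_cart, s2
        )
        return fo - ftot, jac, bab

    r, jac, _ = residual(p)
    fval = float(r @ r)
    converged = False
    for _ in range(max_iter):
        a = jac.T @ jac
        g = jac.T @ r
        w, v = np.linalg.eigh(a)
        good = w > 1e-6 * w.max()
        step = v[:, good] @ ((v[:, good].T @ g) / w[good])
        accepted = False
        for _half in range(20):
            trial = p + step
            trial[layout["k"]] = max(trial[layout["k"]], 1e-8)
            if layout["mask"]:
                trial[layout["mask"][0]] = max(trial[layout["mask"][0]], 0.0)
                trial[layout["mask"][1]] = max(trial[layout["mask"][1]], 0.0)
            if layout["bab"]:
                trial[layout["bab"][0]] = max(trial[layout["bab"][0]], 0.0)
                trial[layout["bab"][1]] = max(trial[layout["bab"][1]], 0.0)
            r_t, jac_t, bab_t = residual(trial)
            f_t = float(r_t @ r_t)
            if f_t <= fval and (not layout["bab"] or bab_t.min() >= 0.0):
                p, r, jac = trial, r_t, jac_t
                accepted = True
                break
            step = 0.5 * step
        if not accepted:
            break
        if fval - f_t < tol * max(fval, 1e-30):
            fval = f_t
            converged = True
            break
        fval = f_t
    if not converged:
        log.warning("scale estimation stopped before full convergence")

    u = np.tensordot(p[layout["u"]], basis, axes=1) if len(layout["u"]) else np.zeros((3, 3))
    return ScaleModel(
        k_overall=float(p[layout["k"]]),
        u_aniso=u,
        k_mask=float(p[layout["mask"][0]]) if layout["mask"] else 0.0,
        b_mask=float(p[layout["mask"][1]]) if layout["mask"] else 0.0,
        k_babinet0=float(p[layout["bab"][0]]) if layout["bab"] else 0.0,
        b_babinet=float(p[layout["bab"][1]]) if layout["bab"] else 200.0,
        converged=converged,
    )


def estimate_scales_twin(
    rset: ReflectionSet,
    f_protein_domains: np.ndarray,
    fractions_init: np.ndarray,
    f_mask_domains: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[ScaleModel, np.ndarray]:
    """Fit observed intensities to sum_d alpha_d |F_total,d|^2.

    ``f_protein_domains`` has shape (n_domains, n_refl): the protein structure
    factors evaluated at each twin-domain image of every observed index.
    Twin fractions are projected to the simplex (>= 0, sum = 1) after each
    Gauss-Newton step; the same eigenvalue filtering as plain scaling is used.
    """
    if not rset.has_intensities:
        raise ValueError("twin scaling needs intensities")
    sel = rset.work
    io = rset.i_obs[sel]
    fp = np.asarray(f_protein_domains)[:, sel]
    nd = fp.shape[0]
    cell = rset.cell
    hkl = rset.hkl[sel]
    s_cart = cell.recip_vectors(hkl)
    s2 = np.einsum("ni,ni->n", s_cart, s_cart)

    basis = symmetry_invariant_basis(rset.spacegroup, cell)
    # parameters: log-free [k, u..., alpha_1..alpha_{nd}] (alpha projected)
    nu = len(basis)
    p = np.concatenate([[1.0], np.zeros(nu), np.asarray(fractions_init, dtype=float)])

    def unpack(params):
        k = params[0]
        u = np.tensordot(params[1 : 1 + nu], basis, axes=1)
        alpha = params[1 + nu :]
        return k, u, alpha

    def project(params):
        params = params.copy()
        params[0] = max(params[0], 1e-8)
        a = np.clip(params[1 + nu :], 0.0, None)
        ssum = a.sum()
        params[1 + nu :] = a / ssum if ssum > 0 else np.full(nd, 1.0 / nd)
        return params

    def model(params):
        k, u, alpha = unpack(params)
        aniso = np.exp(-2.0 * np.pi**2 * np.einsum("ni,ij,nj->n", s_cart, u, s_cart))
        amp2 = np.abs(fp) ** 2  # (nd, n)
        scale2 = (k * aniso) ** 2
        icalc = scale2 * (alpha @ amp2)
        jac = np.empty((len(io), len(params)))
        jac[:, 0] = 2.0 * icalc / k
        for m, bvec in enumerate(basis):
            q = np.einsum("ni,ij,nj->n", s_cart, bvec, s_cart)
            jac[:, 1 + m] = -4.0 * np.pi**2 * q * icalc
        for dcol in range(nd):
            jac[:, 1 + nu + dcol] = scale2 * amp2[dcol]
        return icalc, jac

    p = project(p)
    ic, jac = model(p)
    r = io - ic
    fval = float(r @ r)
    for _ in range(max_iter):
        a = jac.T @ jac
        g = jac.T @ r
        w, v = np.linalg.eigh(a)
        good = w > 1e-6 * w.max()
        step = v[:, good] @ ((v[:, good].T @ g) / w[good])
        accepted = False
        for _half in range(20):
            trial = project(p + step)
            ic_t, jac_t = model(trial)
            r_t = io - ic_t
            f_t = float(r_t @ r_t)
            if f_t <= fval:
                p, r, jac = trial, r_t, jac_t
                accepted = True
                break
            step = 0.5 * step
        if not accepted:
            break
        if fval - f_t < tol * max(fval, 1e-30):
            fval = f_t
            break
        fval = f_t

    k, u, alpha = unpack(p)
    if (alpha < 1e-6).sum() == len(alpha) - 1:
        log.info("all but one twin fraction driven to zero; single-domain model")
    return (
        ScaleModel(k_overall=float(k), u_aniso=u),
        alpha,
    )
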