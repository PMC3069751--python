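"""Reflection data: observed amplitudes, flags, resolution bins, R factors.

A :class:`ReflectionSet` stores one representative per reciprocal-space
asymmetric unit, as column arrays.  Friedel mates (for anomalous data),
intensities and Hendrickson-Lattman coefficients are optional columns.

The CSV interface uses the header
``H,K,L,FP,SIGFP,FREE[,FPLUS,SIGFPLUS,FMINUS,SIGFMINUS][,IOBS,SIGIOBS]
[,HLA,HLB,HLC,HLD]``; an mmCIF ``_refln`` loop with standard tag names is
also accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cell import UnitCell
from .symmetry import SpaceGroupInfo

__all__ = [
    "ReflectionSet",
    "read_reflections",
    "write_reflections",
    "generate_free_flags",
    "assign_resolution_bins",
    "compute_r_factors",
]

log = logging.getLogger(__name__)

DEFAULT_FREE_FRACTION = 0.05


@dataclass
class ReflectionSet:
    """Indexed reflection observations (one ASU representative each)."""

    cell: UnitCell
    spacegroup: SpaceGroupInfo
    hkl: np.ndarray  # (n, 3) int
    f_obs: np.ndarray  # (n,)
    sig_f: np.ndarray  # (n,)
    free: np.ndarray  # (n,) bool
    centric: np.ndarray = None  # (n,) bool
    epsilon: np.ndarray = None  # (n,) int
    d: np.ndarray = None  # (n,) A
    # anomalous (NaN where absent)
    f_plus: np.ndarray | None = None
    sig_plus: np.ndarray | None = None
    f_minus: np.ndarray | None = None
    sig_minus: np.ndarray | None = None
    # intensities
    i_obs: np.ndarray | None = None
    sig_i: np.ndarray | None = None
    # Hendrickson-Lattman coefficients (n, 4)
    hl: np.ndarray | None = None
    bin_index: np.ndarray | None = None
    n_bins: int = 0

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int).reshape(-1, 3)
        n = len(self.hkl)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        self.sig_f = np.asarray(self.sig_f, dtype=float)
        self.free = np.asarray(self.free, dtype=bool)
        if self.centric is None or self.epsilon is None:
            eps = np.empty(n, dtype=int)
            cen = np.empty(n, dtype=bool)
            for i, h in enumerate(self.hkl):
                e, c, _ = self.spacegroup.epsilon_and_centric(h)
                eps[i] = e
                cen[i] = c
            self.epsilon = eps
            self.centric = cen
        if self.d is None:
            self.d = self.cell.d_spacing(self.hkl)
        if np.any(self.sig_f <= 0):
            raise ValueError("sig_f must be positive")

    def __len__(self) -> int:
        return len(self.hkl)

    @property
    def s2(self) -> np.ndarray:
        """1/d^2 per reflection."""
        return 1.0 / self.d**2

    @property
    def work(self) -> np.ndarray:
        return ~self.free

    @property
    def has_anomalous(self) -> bool:
        return self.f_plus is not None and np.isfinite(self.f_plus).any()

    @property
    def has_intensities(self) -> bool:
        return self.i_obs is not None

    def restricted_phases(self) -> np.ndarray:
        """Restricted phase (radians, NaN for acentric) per reflection."""
        out = np.full(len(self), np.nan)
        for i, h in enumerate(self.hkl):
            _, cen, ph = self.spacegroup.epsilon_and_centric(h)
            if cen:
                out[i] = ph
        return out

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "H": self.hkl[:, 0],
                "K": self.hkl[:, 1],
                "L": self.hkl[:, 2],
                "FP": self.f_obs,
                "SIGFP": self.sig_f,
                "FREE": self.free.astype(int),
            }
        )
        if self.f_plus is not None:
            df["FPLUS"] = self.f_plus
            df["SIGFPLUS"] = self.sig_plus
            df["FMINUS"] = self.f_minus
            df["SIGFMINUS"] = self.sig_minus
        if self.i_obs is not None:
            df["IOBS"] = self.i_obs
            df["SIGIOBS"] = self.sig_i
        if self.hl is not None:
            for j, nm in enumerate(["HLA", "HLB", "HLC", "HLD"]):
                df[nm] = self.hl[:, j]
        return df


def generate_free_flags(hkl: np.ndarray, fraction: float = DEFAULT_FREE_FRACTION,
                        seed: int = 0) -> np.ndarray:
    """Deterministic free flags from a hash of (h, k, l) and the seed.

    Reproducible without storing state: the same (hkl, seed) always yields the
    same flags.
    """
    h = np.asarray(hkl, dtype=np.int64)
    mix = (
        h[:, 0] * 73856093
        ^ h[:, 1] * 19349663
        ^ h[:, 2] * 83492791
        ^ np.int64(seed) * 2654435761
    ) & 0x7FFFFFFF
    # second scrambling round for decorrelation from index parities
    mix = (mix * 2246822519 + 3266489917) & 0x7FFFFFFF
    return (mix / float(0x80000000)) < fraction


_MMCIF_TAGS = {
    "H": "index_h",
    "K": "index_k",
    "L": "index_l",
    "FP": "F_meas_au",
    "SIGFP": "F_meas_sigma_au",
    "FREE": "pdbx_r_free_flag",
    "FPLUS": "pdbx_F_plus",
    "SIGFPLUS": "pdbx_F_plus_sigma",
    "FMINUS": "pdbx_F_minus",
    "SIGFMINUS": "pdbx_F_minus_sigma",
    "IOBS": "intensity_meas",
    "SIGIOBS": "intensity_sigma",
    "HLA": "pdbx_HL_A_iso",
    "HLB": "pdbx_HL_B_iso",
    "HLC": "pdbx_HL_C_iso",
    "HLD": "pdbx_HL_D_iso",
}


def _read_mmcif_table(path: str) -> pd.DataFrame:
    import gemmi.cif as cif

    doc = cif.read(str(path))
    block = doc.sole_block()
    data = {}
    for col, tag in _MMCIF_TAGS.items():
        vals = block.find_values(f"_refln.{tag}")
        if vals:
            data[col] = [v for v in vals]
    if not data or "H" not in data:
        raise ValueError(f"{path}: no _refln loop with index_h found")
    df = pd.DataFrame(data)
    return df.apply(pd.to_numeric, errors="coerce")


def read_reflections(
    path: str,
    cell: UnitCell,
    spacegroup: SpaceGroupInfo,
    column_map: dict[str, str] | None = None,
    free_fraction: float = DEFAULT_FREE_FRACTION,
    free_seed: int = 0,
) -> ReflectionSet:
    """Read a reflection table (CSV or mmCIF) into a ReflectionSet.

    Reflections are deduplicated to one ASU representative; epsilon/centric
    flags are computed; rows with sigF <= 0 are rejected (count logged); free
    flags are generated deterministically when the column is absent.
    """
    spath = str(path)
    if spath.endswith((".cif", ".mmcif")):
        df = _read_mmcif_table(spath)
    else:
        df = pd.read_csv(spath)
        df.columns = [c.strip().upper() for c in df.columns]
        if column_map:
            df = df.rename(columns={v.upper(): k for k, v in column_map.items()})
    for req in ("H", "K", "L", "FP", "SIGFP"):
        if req not in df.columns:
            raise ValueError(f"{path}: required column {req} missing")

    bad = ~(df["SIGFP"] > 0)
    if bad.any():
        log.warning("%s: rejected %d rows with sigF <= 0", path, int(bad.sum()))
        df = df[~bad]

    hkl = df[["H", "K", "L"]].to_numpy(dtype=int)
    # map to ASU representatives and deduplicate
    asu_keys = []
    for h in hkl:
        rep, _ = spacegroup.asu_equivalent(h)
        asu_keys.append(rep)
    df = df.assign(_ASU=asu_keys)
    rows = []
    for key, grp in df.groupby("_ASU", sort=False):
        f = grp["FP"].to_numpy(dtype=float)
        s = grp["SIGFP"].to_numpy(dtype=float)
        if len(grp) > 1:
            spread = np.abs(f - f.mean()).max()
            if spread > 3.0 * s.max():
                raise ValueError(
                    f"symmetry-equivalent rows for {key} disagree beyond 3 sigma"
                )
        row = grp.iloc[0].copy()
        w = 1.0 / s**2
        row["FP"] = float((f * w).sum() / w.sum())
        row["SIGFP"] = float(1.0 / np.sqrt(w.sum()))
        row["H"], row["K"], row["L"] = key
        rows.append(row)
    df = pd.DataFrame(rows).reset_index(drop=True)
    hkl = df[["H", "K", "L"]].to_numpy(dtype=int)

    if "FREE" in df.columns and df["FREE"].notna().all():
        free = df["FREE"].to_numpy(dtype=float) > 0.5
    else:
        free = generate_free_flags(hkl, free_fraction, free_seed)

    def col(name):
        return df[name].to_numpy(dtype=float) if name in df.columns else None

    hl = None
    if all(n in df.columns for n in ("HLA", "HLB", "HLC", "HLD")):
        hl = df[["HLA", "HLB", "HLC", "HLD"]].to_numpy(dtype=float)

    rset = ReflectionSet(
        cell=cell,
        spacegroup=spacegroup,
        hkl=hkl,
        f_obs=df["FP"].to_numpy(dtype=float),
        sig_f=df["SIGFP"].to_numpy(dtype=float),
        free=free,
        f_plus=col("FPLUS"),
        sig_plus=col("SIGFPLUS"),
        f_minus=col("FMINUS"),
        sig_minus=col("SIGFMINUS"),
        i_obs=col("IOBS"),
        sig_i=col("SIGIOBS"),
        hl=hl,
    )
    if rset.hl is not None:
        # centric phase distributions have no second harmonic
        bad_cd = rset.centric & (np.abs(rset.hl[:, 2:]).max(axis=1) > 0)
        if bad_cd.any():
            log.warning(
                "forcing HL C=D=0 on %d centric reflections", int(bad_cd.sum())
            )
            rset.hl[bad_cd, 2:] = 0.0
    # centric reflections carry no independent Friedel mate
    if rset.f_plus is not None:
        both = np.isfinite(rset.f_plus) & np.isfinite(rset.f_minus)
        drop = rset.centric & both
        if drop.any():
            rset.f_minus[drop] = np.nan
            rset.sig_minus[drop] = np.nan
    return rset


def write_reflections(rset: ReflectionSet, path: str) -> None:
    rset.to_dataframe().to_csv(path, index=False, float_format="%.6g")


def assign_resolution_bins(rset: ReflectionSet, n_bins: int) -> np.ndarray:
    """Equal-count bins in 1/d^2; stores and returns the per-reflection index."""
    n = len(rset)
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds reflection count {n}")
    order = np.argsort(rset.s2, kind="stable")
    idx = np.empty(n, dtype=int)
    # equal counts, remainder spread over the first bins
    base, rem = divmod(n, n_bins)
    start = 0
    for b in range(n_bins):
        cnt = base + (1 if b < rem else 0)
        idx[order[start : start + cnt]] = b
        start += cnt
    rset.bin_index = idx
    rset.n_bins = n_bins
    return idx


def compute_r_factors(rset: ReflectionSet, f_total: np.ndarray) -> tuple[float, float]:
    """R_work and R_free (percent): sum||Fo|-|Fc|| / sum|Fo| per flag subset."""
    f_total = np.abs(np.asarray(f_total))
    out = []
    for mask in (rset.work, rset.free):
        if not mask.any():
            raise ValueError("empty work/free subset for R-factor computation")
        num = np.abs(rset.f_obs[mask] - f_total[mask]).sum()
        den = rset.f_obs[mask].sum()
        out.append(100.0 * num / den)
    return out[0], out[1]
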