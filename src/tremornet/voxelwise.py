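"""Mass-univariate statistics on paired condition maps.

Implements the per-subject On-Off difference maps, the sign-flip
permutation one-sample t-map with max-statistic family-wise error
correction, and voxel-wise simple regression of maps against a clinical
covariate with a covariate-permutation null. With n subjects and
``2**n <= n_perm`` the sign-flip null is enumerated exhaustively, making
the result exact and seed-independent; otherwise sign patterns are
sampled with the identity pattern always included, so the smallest
attainable p is ``1 / n_perm``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDesignError, GridMismatchError, InsufficientDataError
from .volumes import BrainMap

_TAILS = ("greater", "less", "two_sided")


@dataclass
class StatMap:
    """Voxel-wise statistic map with per-voxel FWE-corrected p-values."""

    stat: BrainMap               # t (or slope-t) per voxel
    p_fwe: BrainMap              # max-statistic FWE-corrected p per voxel
    n_permutations: int
    tail: str
    df: int
    exact: bool                  # full enumeration of the null?
    zero_variance_mask: np.ndarray   # voxels excluded from inference
    kind: str = "one_sample_t"

    def suprathreshold_table(self, alpha: float = 0.05) -> pd.DataFrame:
        """TSV-ready table of voxels significant at the FWE level alpha."""
        sig = self.p_fwe.data <= alpha
        sig &= self.p_fwe.mask
        idx = np.argwhere(sig)
        coords = self.stat.grid.world_coords(sig)
        return pd.DataFrame(
            {
                "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
                "x_mm": coords[:, 0], "y_mm": coords[:, 1], "z_mm": coords[:, 2],
                "t": self.stat.data[sig],
                "p_fwe": self.p_fwe.data[sig],
            }
        ).sort_values("p_fwe", kind="stable").reset_index(drop=True)

    def summary(self) -> str:
        n_sig = int(np.sum((self.p_fwe.data <= 0.05) & self.p_fwe.mask))
        mode = "exact enumeration" if self.exact else "sampled"
        return (
            f"{self.kind}: {self.stat.n_voxels} voxels tested, df={self.df}, "
            f"{self.n_permutations} permutations ({mode}), tail={self.tail}; "
            f"{n_sig} voxels with p_fwe <= 0.05; "
            f"{int(self.zero_variance_mask.sum())} zero-variance voxels excluded"
        )


def _common_stack(maps: list[BrainMap]) -> tuple[np.ndarray, BrainMap]:
    """Stack in-mask values of maps sharing one grid/mask into (n, V)."""
    first = maps[0]
    for m in maps[1:]:
        if not first.same_geometry(m):
            raise GridMismatchError("maps do not share a common grid and mask")
    return np.stack([m.values for m in maps]), first


def diff_maps(on_maps: list[BrainMap], off_maps: list[BrainMap]) -> list[BrainMap]:
    """Per-subject On - Off difference maps."""
    if len(on_maps) != len(off_maps):
        raise GridMismatchError("need equally many On and Off maps")
    out = []
    for on, off in zip(on_maps, off_maps):
        if not on.same_geometry(off):
            raise GridMismatchError("paired maps do not share grid/mask")
        out.append(on - off)
    return out


def _sign_patterns(n: int, n_perm: int, rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """(P, n) matrix of +-1 sign patterns; exact enumeration when cheap."""
    if 2**n <= n_perm:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n)) & 1)
        return signs, True
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    signs[0, :] = 1.0  # identity permutation always counted
    return signs, False


def _max_stat(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two_sided":
        return np.nanmax(np.abs(t), axis=1)
    if tail == "greater":
        return np.nanmax(t, axis=1)
    return np.nanmax(-t, axis=1)


def _observed_score(t: np.ndarray, tail: str) -> np.ndarray:
    if tail == "two_sided":
        return np.abs(t)
    if tail == "greater":
        return t
    return -t


def one_sample_perm_t(
    maps: list[BrainMap],
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "two_sided",
    chunk: int = 2048,
) -> StatMap:
    """Sign-flip permutation one-sample t-test across subjects, per voxel.

    The null hypothesis at each voxel is a symmetric distribution of the
    subject values around zero; whole subject maps are sign-flipped
    jointly, and the FWE-corrected p at a voxel is the proportion of
    permutations whose maximum statistic over the mask reaches the
    observed statistic at that voxel.

    Voxels with zero variance across subjects have no defined t and are
    excluded from inference; they are reported via ``zero_variance_mask``.
    """
    if tail not in _TAILS:
        raise DegenerateDesignError(f"tail must be one of {_TAILS}")
    if len(maps) < 3:
        raise InsufficientDataError("need at least 3 subject maps")
    x, proto = _common_stack(maps)            # (n, V)
    n = x.shape[0]
    sd = x.std(axis=0, ddof=1)
    zero_var = sd == 0
    infer = ~zero_var
    xv = x[:, infer]
    if xv.shape[1] == 0:
        raise DegenerateDesignError("all voxels have zero variance")

    t_obs = np.full(x.shape[1], np.nan)
    t_obs[infer] = xv.mean(axis=0) / (sd[infer] / np.sqrt(n))

    rng = np.random.default_rng(seed)
    signs, exact = _sign_patterns(n, n_perm, rng)
    n_total = signs.shape[0]
    ss = (xv**2).sum(axis=0)                  # invariant under sign flips
    maxstats = np.empty(n_total)
    for lo in range(0, n_total, chunk):
        s = signs[lo:lo + chunk]
        m = (s @ xv) / n
        var = (ss[None, :] - n * m**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = m / np.sqrt(var / n)
        t[var <= 0] = np.sign(m[var <= 0]) * np.inf
        maxstats[lo:lo + chunk] = _max_stat(t, tail)

    score = _observed_score(t_obs[infer], tail)
    # p = fraction of permutation maxima reaching the observed voxel score
    order = np.sort(maxstats)
    counts = n_total - np.searchsorted(order, score, side="left")
    p = counts / n_total

    full_mask = proto.mask.copy()
    stat_data = np.zeros(proto.grid.shape)
    stat_data[full_mask] = np.where(np.isnan(t_obs), 0.0, t_obs)
    p_data = np.ones(proto.grid.shape)
    pvec = np.ones(x.shape[1])
    pvec[infer] = p
    p_data[full_mask] = pvec
    zero_var_vol = np.zeros(proto.grid.shape, dtype=bool)
    zero_var_vol[full_mask] = zero_var
    infer_mask = full_mask & ~zero_var_vol

    return StatMap(
        stat=BrainMap(proto.grid, stat_data, infer_mask),
        p_fwe=BrainMap(proto.grid, np.where(infer_mask, p_data, 1.0), infer_mask),
        n_permutations=n_total,
        tail=tail,
        df=n - 1,
        exact=exact,
        zero_variance_mask=zero_var_vol,
        kind="one_sample_t",
    )


def voxelwise_regression(
    maps: list[BrainMap],
    covariate: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    tail: str = "two_sided",
) -> StatMap:
    """Per-voxel simple linear regression of maps on a subject covariate.

    The slope t-statistic (intercept included, df = n - 2) is computed at
    every voxel; the null permutes the covariate across subjects with the
    identity permutation always counted, and FWE correction uses the
    permutation distribution of the maximum statistic.
    """
    if tail not in _TAILS:
        raise DegenerateDesignError(f"tail must be one of {_TAILS}")
    c = np.asarray(covariate, dtype=float)
    if len(maps) != c.shape[0]:
        raise DegenerateDesignError("covariate length must equal the number of maps")
    n = len(maps)
    if n < 3:
        raise InsufficientDataError("need n >= 3 subjects for residual df >= 1")
    if np.ptp(c) == 0:
        raise DegenerateDesignError("covariate is constant")
    y, proto = _common_stack(maps)            # (n, V)

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=int)
    perms[0] = np.arange(n)
    for i in range(1, n_perm):
        perms[i] = rng.permutation(n)
    cmat = c[perms]                           # (P, n)
    cmat = cmat - cmat.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=0, keepdims=True)
    syy = (yc**2).sum(axis=0)                 # (V,)
    zero_var = syy == 0
    infer = ~zero_var
    ycv, syyv = yc[:, infer], syy[infer]
    scc = (cmat**2).sum(axis=1)               # (P,)
    df = n - 2

    sxy = cmat @ ycv                          # (P, V)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (scc[:, None] * syyv[None, :])
        r2 = np.clip(r2, 0.0, 1.0)
        t_all = np.sign(sxy) * np.sqrt(r2 * df / (1.0 - r2))
    t_all[np.isnan(t_all)] = 0.0
    # a perfect voxel fit (r^2 == 1) has infinite t; cap with a finite
    # sentinel so maps remain writable while p-ordering is preserved
    t_all = np.clip(t_all, -1e8, 1e8)
    t_obs = t_all[0]
    maxstats = _max_stat(t_all, tail)
    score = _observed_score(t_obs, tail)
    order = np.sort(maxstats)
    p = (n_perm - np.searchsorted(order, score, side="left")) / n_perm

    full_mask = proto.mask.copy()
    zero_var_vol = np.zeros(proto.grid.shape, dtype=bool)
    zero_var_vol[full_mask] = zero_var
    infer_mask = full_mask & ~zero_var_vol
    stat_data = np.zeros(proto.grid.shape)
    stat_data[infer_mask] = t_obs
    p_data = np.ones(proto.grid.shape)
    p_data[infer_mask] = p

    return StatMap(
        stat=BrainMap(proto.grid, stat_data, infer_mask),
        p_fwe=BrainMap(proto.grid, p_data, infer_mask),
        n_permutations=n_perm,
        tail=tail,
        df=df,
        exact=False,
        zero_variance_mask=zero_var_vol,
        kind="slope_t",
    )
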