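"""Simplified Ordinal-Trends Canonical Variates Analysis.

Finds a spatial covariance pattern whose subject-level expression shifts
consistently between the Stim-On and Stim-Off conditions, as a
multivariate cross-check of the univariate t-map. The variant here is
deliberately simple and fully specified:

1. stack the 2n condition maps and remove each subject's mean map
   (within-subject centering), so condition contrasts drive the
   decomposition;
2. principal component analysis of the centered stack, keeping the first
   ``n_components`` spatial components;
3. in component space, combine components with the unit-norm weight
   vector that maximizes the paired t-statistic of the projected On-Off
   differences — closed form ``w proportional to S_d^{-1} mean(d)`` with
   ``S_d`` the sample covariance of the component-space differences;
4. map the combined weights back to a unit-norm voxel pattern, sign-fixed
   so the mean projected difference is positive (On > Off expression);
5. bootstrap subjects (pairs, with replacement) to obtain a per-voxel
   stability z = point-estimate weight / bootstrap SD.

No Monte-Carlo significance of the ordinal trend itself is computed; the
pattern is validated downstream by spatial similarity against the
univariate t-map under the Moran-spectral-randomization null.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, GridMismatchError, InsufficientDataError
from .spatialnull import SimilarityResult, similarity_test
from .volumes import BrainMap


@dataclass
class CovariancePattern:
    """Fitted covariance pattern with expressions and bootstrap stability."""

    pattern: BrainMap                 # unit-norm voxel weights
    expression: pd.DataFrame          # columns: id, condition, expression
    n_components: int
    ordinal_violations: int
    bootstrap_z: BrainMap | None
    n_boot: int
    ridge_applied: bool

    def expression_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(on, off) expression vectors in subject order."""
        on = self.expression.query("condition == 'on'")["expression"].to_numpy()
        off = self.expression.query("condition == 'off'")["expression"].to_numpy()
        return on, off

    def summary(self) -> str:
        on, off = self.expression_matrix()
        return (
            f"OrT/CVA pattern ({self.n_components} components, "
            f"{self.n_boot} bootstrap iterations): "
            f"mean expression shift (On-Off) = {np.mean(on - off):+.4f}, "
            f"ordinal violations = {self.ordinal_violations}/{on.size}"
            + (" [ridge fallback applied]" if self.ridge_applied else "")
        )


def _fit_pattern(on: np.ndarray, off: np.ndarray, n_components: int) -> tuple[np.ndarray, bool]:
    """Core fit on value matrices (n, V); returns (unit pattern, ridge flag)."""
    n = on.shape[0]
    stack = np.concatenate([on, off], axis=0)                      # (2n, V)
    subj_mean = (on + off) / 2.0
    centered = stack - np.concatenate([subj_mean, subj_mean], axis=0)
    if np.allclose(centered, 0.0):
        raise DegenerateFitError("On == Off for every subject; no contrast to fit")
    # PCA of the centered stack: spatial components from the SVD
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-10))
    k = min(n_components, rank)
    comps = vt[:k]                                                  # (k, V)
    d = (on - off) @ comps.T                                        # (n, k)
    mean_d = d.mean(axis=0)
    if np.allclose(mean_d, 0.0):
        raise DegenerateFitError("mean component-space difference is zero")
    ridge = False
    if n - 1 >= 1:
        cov = np.cov(d, rowvar=False, ddof=1).reshape(k, k)
    else:  # pragma: no cover
        cov = np.eye(k)
    try:
        w = np.linalg.solve(cov, mean_d)
    except np.linalg.LinAlgError:
        ridge = True
        cov = cov + 1e-8 * np.trace(cov) / k * np.eye(k)
        w = np.linalg.solve(cov, mean_d)
    if not np.all(np.isfinite(w)):
        ridge = True
        cov = cov + 1e-8 * max(np.trace(cov), 1.0) / k * np.eye(k)
        w = np.linalg.solve(cov, mean_d)
    pattern = comps.T @ w                                           # (V,)
    norm = np.linalg.norm(pattern)
    if norm == 0:
        raise DegenerateFitError("degenerate zero pattern")
    pattern = pattern / norm
    # sign: mean projected On-Off difference positive
    if np.mean((on - off) @ pattern) < 0:
        pattern = -pattern
    return pattern, ridge


class OrdinalTrendsCVA:
    """Model object; ``fit`` returns a :class:`CovariancePattern`."""

    def __init__(
        self,
        on_maps: list[BrainMap],
        off_maps: list[BrainMap],
        n_components: int = 5,
        ids: list[str] | None = None,
    ):
        if len(on_maps) != len(off_maps):
            raise GridMismatchError("need paired On/Off maps")
        n = len(on_maps)
        if n < n_components + 1:
            raise InsufficientDataError(
                f"need n >= n_components + 1 subjects (n={n}, k={n_components})"
            )
        proto = on_maps[0]
        for m in list(on_maps[1:]) + list(off_maps):
            if not proto.same_geometry(m):
                raise GridMismatchError("maps do not share a common grid and mask")
        self.proto = proto
        self.on = np.stack([m.values for m in on_maps])
        self.off = np.stack([m.values for m in off_maps])
        self.n_components = n_components
        self.ids = list(ids) if ids is not None else [f"sub-{i + 1:02d}" for i in range(n)]

    def fit(self, n_boot: int = 100, seed: int | None = None) -> CovariancePattern:
        pattern, ridge = _fit_pattern(self.on, self.off, self.n_components)
        expr_on = self.on @ pattern
        expr_off = self.off @ pattern
        violations = int(np.sum(expr_on <= expr_off))
        n = self.on.shape[0]

        bz = None
        if n_boot > 0:
            rng = np.random.default_rng(seed)
            boots = np.empty((n_boot, pattern.size))
            kept = 0
            for _ in range(n_boot):
                idx = rng.integers(0, n, size=n)
                try:
                    pb, _ = _fit_pattern(self.on[idx], self.off[idx], self.n_components)
                except DegenerateFitError:
                    continue
                if pb @ pattern < 0:       # align sign to the point estimate
                    pb = -pb
                boots[kept] = pb
                kept += 1
            if kept >= 2:
                sd = boots[:kept].std(axis=0, ddof=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    zv = np.where(sd > 0, pattern / np.where(sd > 0, sd, 1.0), 0.0)
                bz = self.proto.with_values(zv)

        expr = pd.DataFrame(
            {
                "id": self.ids * 2,
                "condition": ["on"] * n + ["off"] * n,
                "expression": np.concatenate([expr_on, expr_off]),
            }
        )
        return CovariancePattern(
            pattern=self.proto.with_values(pattern),
            expression=expr,
            n_components=self.n_components,
            ordinal_violations=violations,
            bootstrap_z=bz,
            n_boot=n_boot,
            ridge_applied=ridge,
        )


def ortcva_fit(
    on_maps, off_maps, n_components: int = 5, n_boot: int = 100, seed: int | None = None
) -> CovariancePattern:
    """Functional entry point for the simplified OrT/CVA fit."""
    return OrdinalTrendsCVA(on_maps, off_maps, n_components).fit(n_boot=n_boot, seed=seed)


def pattern_vs_tmap(
    pattern: BrainMap,
    tmap: BrainMap,
    n_surr: int = 10_000,
    seed: int | None = None,
    **kwargs,
) -> tuple[SimilarityResult, SimilarityResult]:
    """Spatial similarity of the covariance pattern and the univariate
    t-map, reported with each map's surrogates in turn."""
    ra = similarity_test(pattern, tmap, n_surr=n_surr, seed=seed, permuted_side="a", **kwargs)
    rb = similarity_test(
        pattern, tmap, n_surr=n_surr,
        seed=None if seed is None else seed + 1,
        permuted_side="b", **kwargs,
    )
    return ra, rb
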