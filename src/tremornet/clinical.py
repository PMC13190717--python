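"""Clinical statistics: paired condition tests, relative improvement,
stimulation-parameter confound screening, and the amplitude-controlled
outcome regressions.

The headline quantity is the ordinary-least-squares association between
cohort-z-scored network alignment and percent tremor improvement, with
stimulation amplitude as covariate; the local counterpart regresses the
z-scored mean metabolic change inside the cohort-level stimulation-site
ROI (voxels covered by at least ``min_overlap`` patients' VTAs) on
amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    DegenerateDesignError,
    EmptyROIError,
    GridMismatchError,
    InsufficientDataError,
    StandardizationError,
    UndefinedImprovementError,
)


@dataclass
class PairedTestResult:
    """Classical paired t-test on d = off - on."""

    mean_off: float
    mean_on: float
    mean_diff: float       # off - on; positive = improvement
    mean_change: float     # on - off, the signed "absolute change"
    sem_diff: float
    t: float
    df: int
    p: float
    n: int

    def summary(self) -> str:
        return (
            f"Paired t-test (n={self.n}): Off {self.mean_off:.2f}, On {self.mean_on:.2f}, "
            f"change (On-Off) {self.mean_change:.2f} +/- {self.sem_diff:.2f} SEM, "
            f"t({self.df}) = {self.t:.2f}, two-sided p = {self.p:.3g}"
        )


@dataclass
class OutcomeRegressionResult:
    """OLS of improvement on alignment (+ covariates)."""

    r_squared: float
    f_pvalue: float
    n: int
    predictors: list[str]
    coef: dict
    tvalues: dict
    pvalues: dict
    covariate_free: "OutcomeRegressionResult | None" = None
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"OLS, n={self.n}: R^2 = {self.r_squared:.3f}, model p = {self.f_pvalue:.3g}"
        ]
        for name in self.predictors:
            lines.append(
                f"  {name}: coef {self.coef[name]:+.3f}, "
                f"t = {self.tvalues[name]:.2f}, p = {self.pvalues[name]:.3g}"
            )
        if self.covariate_free is not None:
            cf = self.covariate_free
            lines.append(
                f"  (covariate-free: R^2 = {cf.r_squared:.3f}, p = {cf.f_pvalue:.3g})"
            )
        return "\n".join(lines)


@dataclass
class RoiResult:
    """Cohort-level stimulation-site ROI and per-patient extraction."""

    mask: np.ndarray
    mean_delta: np.ndarray       # per-patient mean On-Off change in ROI
    mean_on: np.ndarray          # per-patient mean Stim-On uptake in ROI
    z_delta: np.ndarray
    min_overlap: int
    n_voxels: int


def paired_ttest(off, on, tail: str = "two_sided") -> PairedTestResult:
    """Paired t-test between Stim-Off and Stim-On scores.

    d = off - on, t = mean(d) / SEM(d), p from the t distribution with
    n - 1 degrees of freedom.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    if off.shape != on.shape or off.ndim != 1:
        raise GridMismatchError("off and on must be equal-length vectors")
    n = off.shape[0]
    if n < 2:
        raise InsufficientDataError("paired t-test needs n >= 2")
    d = off - on
    sem = d.std(ddof=1) / np.sqrt(n)
    if sem == 0:
        raise DegenerateDesignError("zero variance of paired differences")
    t = d.mean() / sem
    df = n - 1
    if tail == "two_sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif tail == "greater":
        p = stats.t.sf(t, df)
    elif tail == "less":
        p = stats.t.cdf(t, df)
    else:
        raise DegenerateDesignError(f"unknown tail {tail!r}")
    return PairedTestResult(
        mean_off=float(off.mean()), mean_on=float(on.mean()),
        mean_diff=float(d.mean()), mean_change=float(-d.mean()),
        sem_diff=float(sem), t=float(t), df=df, p=float(p), n=n,
    )


def relative_improvement(off: float, on: float) -> float:
    """Percent tremor reduction, 100 * (off - on) / off.

    Negative values (worsening) are allowed; a zero baseline is
    undefined and the patient must be excluded by the caller.
    """
    if off <= 0:
        raise UndefinedImprovementError("relative improvement undefined for off <= 0")
    return 100.0 * (off - on) / off


def cohort_improvement(off, on) -> dict:
    """Per-patient improvements plus the two cohort-level readings.

    ``mean_of_patient_percentages`` averages per-patient percentages;
    ``group_mean_ratio`` applies the percentage formula to the group
    means. Both are reported because the cohort-average reduction can be
    read either way.
    """
    off = np.asarray(off, dtype=float)
    on = np.asarray(on, dtype=float)
    per_patient = np.array([relative_improvement(o, a) for o, a in zip(off, on)])
    return {
        "per_patient": per_patient,
        "mean_of_patient_percentages": float(per_patient.mean()),
        "group_mean_ratio": relative_improvement(float(off.mean()), float(on.mean())),
        "range": (float(per_patient.min()), float(per_patient.max())),
    }


def screen_confounds(
    response,
    params: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Screen stimulation parameters as confounds of a response.

    Per parameter: Pearson r, R² and p from the univariate association;
    the variance-inflation factor from the all-parameter model; and the
    partial t / p from the joint multiple regression. A parameter is
    marked a significant independent confound when its joint-model
    partial p is below ``alpha``. Constant columns are excluded with a
    flag.
    """
    y = np.asarray(response, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise InsufficientDataError("confound screening needs n >= 4")
    if len(params) != n:
        raise DegenerateDesignError("parameter table length mismatch")
    cols = list(params.columns)
    usable = [c for c in cols if np.ptp(params[c].to_numpy(dtype=float)) > 0]
    dropped = [c for c in cols if c not in usable]
    if n < len(usable) + 2:
        raise InsufficientDataError(
            f"n={n} too small for {len(usable)} parameters plus intercept"
        )
    x_all = params[usable].to_numpy(dtype=float)
    joint = sm.OLS(y, sm.add_constant(x_all)).fit()
    rows = []
    for j, c in enumerate(usable):
        x = x_all[:, j]
        r, p_uni = stats.pearsonr(x, y)
        # VIF from regressing this parameter on the others
        others = np.delete(x_all, j, axis=1)
        if others.shape[1] > 0:
            r2_j = sm.OLS(x, sm.add_constant(others)).fit().rsquared
            vif = np.inf if r2_j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2_j)
        else:
            vif = 1.0
        rows.append(
            {
                "parameter": c,
                "pearson_r": float(r),
                "r_squared": float(r**2),
                "p_univariate": float(p_uni),
                "vif": float(vif),
                "joint_coef": float(joint.params[j + 1]),
                "joint_t": float(joint.tvalues[j + 1]),
                "joint_p": float(joint.pvalues[j + 1]),
                "significant_independent": bool(joint.pvalues[j + 1] < alpha),
                "constant_excluded": False,
            }
        )
    for c in dropped:
        rows.append(
            {
                "parameter": c, "pearson_r": np.nan, "r_squared": np.nan,
                "p_univariate": np.nan, "vif": np.nan, "joint_coef": np.nan,
                "joint_t": np.nan, "joint_p": np.nan,
                "significant_independent": False, "constant_excluded": True,
            }
        )
    return pd.DataFrame(rows)


def _ols_result(y: np.ndarray, x: pd.DataFrame) -> OutcomeRegressionResult:
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise DegenerateDesignError("rank-deficient regression design")
    fit = sm.OLS(y, design).fit()
    names = list(x.columns)
    return OutcomeRegressionResult(
        r_squared=float(fit.rsquared),
        f_pvalue=float(fit.f_pvalue),
        n=int(fit.nobs),
        predictors=names,
        coef={k: float(fit.params[k]) for k in names},
        tvalues={k: float(fit.tvalues[k]) for k in names},
        pvalues={k: float(fit.pvalues[k]) for k in names},
    )


def outcome_regression(
    improvement,
    alignment_z,
    covariates: pd.DataFrame | None = None,
) -> OutcomeRegressionResult:
    """OLS of percent improvement on z-scored alignment (+ covariates).

    The full-model R² and the alignment predictor's coefficient / t / p
    are reported; the covariate-free single-predictor model is attached
    for the paired reporting pattern (with/without amplitude).
    """
    y = np.asarray(improvement, dtype=float)
    az = np.asarray(alignment_z, dtype=float)
    if y.shape != az.shape:
        raise DegenerateDesignError("improvement and alignment lengths differ")
    x = pd.DataFrame({"alignment_z": az})
    if covariates is not None:
        if len(covariates) != y.shape[0]:
            raise DegenerateDesignError("covariate table length mismatch")
        x = pd.concat([x, covariates.reset_index(drop=True)], axis=1)
    n_pred = x.shape[1]
    if y.shape[0] < n_pred + 2:
        raise InsufficientDataError(
            f"n={y.shape[0]} too small for {n_pred} predictors"
        )
    result = _ols_result(y, x)
    if covariates is not None and covariates.shape[1] > 0:
        result.covariate_free = _ols_result(y, pd.DataFrame({"alignment_z": az}))
    return result


def vta_overlap_roi(cohort, min_overlap: int = 3) -> RoiResult:
    """Cohort-level stimulation-site ROI and per-patient uptake extraction.

    The ROI is the set of voxels covered by at least ``min_overlap``
    patients' VTAs. Per patient, the mean On-Off change (default local
    readout) and the mean Stim-On uptake inside the ROI are extracted;
    the change is z-scored across the cohort.
    """
    grid_shape = cohort.template_grid.shape
    counts = np.zeros(grid_shape, dtype=int)
    for p in cohort.patients:
        if p.vta_mask.shape != grid_shape:
            raise GridMismatchError("VTA mask on a different grid")
        counts += p.vta_mask.astype(int)
    roi = counts >= min_overlap
    roi &= cohort.analysis_mask
    if not roi.any():
        raise EmptyROIError(
            f"no voxel covered by >= {min_overlap} VTAs; lower min_overlap"
        )
    mean_delta = np.array(
        [(p.on_map.data - p.off_map.data)[roi].mean() for p in cohort.patients]
    )
    mean_on = np.array([p.on_map.data[roi].mean() for p in cohort.patients])
    sd = mean_delta.std(ddof=1)
    if sd == 0:
        raise StandardizationError("zero cohort variance of ROI uptake")
    z = (mean_delta - mean_delta.mean()) / sd
    return RoiResult(
        mask=roi, mean_delta=mean_delta, mean_on=mean_on, z_delta=z,
        min_overlap=min_overlap, n_voxels=int(roi.sum()),
    )
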