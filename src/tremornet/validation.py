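"""Statistical validation studies for the pipeline's guarantees.

Each function runs a self-contained simulation study against the
package's own synthetic-data generator and returns plain dictionaries of
the measured quantities: calibration of the spatial-null similarity test
(versus the anticonservative i.i.d.-shuffle baseline), surrogate
fidelity, family-wise error of the sign-flip permutation t-test,
recovery of the planted clinical coupling and template support, cluster
inference recovery and false-positive control, and the exact structural
identities. The acceptance script and the test suite both drive these
studies; problem sizes are chosen so the full battery runs in minutes on
one core.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import spatialnull
from .alignment import cohort_alignment
from .clinical import outcome_regression, paired_ttest, relative_improvement
from .connglm import connectivity_glm, split_signed
from .ortcva import ortcva_fit
from .simulate import (
    CohortConfig,
    default_analysis_mask,
    make_template_network,
    simulate_cohort,
    simulate_connectivity_effect,
    smooth_noise_field,
)
from .volumes import BrainMap, VolumeGrid, intensity_normalize, mirror
from .voxelwise import diff_maps, one_sample_perm_t

#: grid used for the desk-scale spatial studies (~2,400 in-mask voxels at 4 mm)
STUDY_GRID_SHAPE = (16, 18, 16)
STUDY_VOXEL_MM = 4.0


def _study_grid() -> tuple[VolumeGrid, np.ndarray]:
    grid = VolumeGrid.centered(STUDY_GRID_SHAPE, STUDY_VOXEL_MM)
    return grid, default_analysis_mask(grid)


# ---------------------------------------------------------------------------
# Worked examples from the clinical module
# ---------------------------------------------------------------------------

def paired_ttest_worked_example(mean_diff: float = 11.07, sem: float = 1.16,
                                n: int = 14) -> dict:
    """Paired t-test on a difference vector with the given mean and SEM.

    Any vector with these moments yields the same t = mean/SEM and the
    same two-sided p; a symmetric two-point construction is used.
    """
    sd = sem * np.sqrt(n)
    base = np.tile([-1.0, 1.0], n // 2 + 1)[:n]
    if n % 2:  # odd n: recenter the template before scaling
        base -= base.mean()
    d = mean_diff + base * (sd / base.std(ddof=1))
    res = paired_ttest(d, np.zeros(n))
    return {"t": res.t, "df": res.df, "p": res.p, "n": n}


def group_relative_reduction(mean_off: float = 14.79, mean_on: float = 3.71) -> dict:
    pct = relative_improvement(mean_off, mean_on)
    return {"percent": pct, "percent_rounded": float(round(pct))}


# ---------------------------------------------------------------------------
# Spatial-null calibration and surrogate fidelity
# ---------------------------------------------------------------------------

def msr_calibration_study(
    n_replicates: int = 200,
    n_surr: int = 500,
    n_naive: int = 500,
    fwhm_mm: float = 8.0,
    seed: int = 0,
) -> dict:
    """Type-I error of the MSR similarity test on independent smooth fields.

    Per replicate, two independent Gaussian random fields (smoothed to
    ``fwhm_mm``) are compared; the one-sided MSR p and the i.i.d.
    voxel-shuffle p are recorded. A calibrated test rejects at 0.05 about
    5% of the time; the shuffle null ignores spatial autocorrelation and
    rejects far more often.
    """
    grid, mask = _study_grid()
    weights = spatialnull.build_weights(grid, mask)
    basis = spatialnull.moran_eigenbasis(weights)
    rng = np.random.default_rng(seed)
    rej_msr = rej_naive = 0
    for rep in range(n_replicates):
        a = smooth_noise_field(grid, mask, fwhm_mm, 1.0, rng)
        b = smooth_noise_field(grid, mask, fwhm_mm, 1.0, rng)
        res = spatialnull.similarity_test(
            a, b, n_surr=n_surr, seed=int(rng.integers(2**31)), basis=basis
        )
        naive = spatialnull.naive_shuffle_test(
            a, b, n_perm=n_naive, seed=int(rng.integers(2**31))
        )
        rej_msr += res.p <= 0.05
        rej_naive += naive.p <= 0.05
    return {
        "n_replicates": n_replicates,
        "n_voxels": int(mask.sum()),
        "msr_rejection_rate": rej_msr / n_replicates,
        "naive_rejection_rate": rej_naive / n_replicates,
    }


def surrogate_fidelity_study(
    n_surr: int = 200, fwhm_mm: float = 8.0, seed: int = 0
) -> dict:
    """Moment and Moran-spectrum preservation of MSR surrogates."""
    grid, mask = _study_grid()
    weights = spatialnull.build_weights(grid, mask)
    basis = spatialnull.moran_eigenbasis(weights)
    rng = np.random.default_rng(seed)
    x = smooth_noise_field(grid, mask, fwhm_mm, 1.0, rng).values
    surr = spatialnull.msr_surrogates(x, basis, n_surr, seed=seed)
    i_obs = spatialnull.morans_i(x, weights)
    i_surr = float(np.mean([spatialnull.morans_i(s, weights) for s in surr]))
    return {
        "moran_i_observed": i_obs,
        "moran_i_surrogate_mean": i_surr,
        "moran_i_rel_error": abs(i_surr - i_obs) / abs(i_obs),
        "max_mean_error": float(np.abs(surr.mean(axis=1) - x.mean()).max()),
        "max_var_error": float(np.abs(surr.var(axis=1) - x.var()).max()),
        "n_surrogates": n_surr,
    }


# ---------------------------------------------------------------------------
# Sign-flip permutation t-test FWE
# ---------------------------------------------------------------------------

def signflip_fwe_study(
    n_replicates: int = 500,
    n_subjects: int = 14,
    alpha: float = 0.05,
    fwhm_mm: float = 8.0,
    seed: int = 0,
) -> dict:
    """Family-wise error of the max-statistic sign-flip t-test.

    Null Gaussian random-field cohorts (zero mean) with exhaustive
    enumeration of all 2^n sign patterns; a replicate counts as a
    family-wise false positive when any voxel reaches p_fwe <= alpha.
    """
    grid = VolumeGrid.centered((12, 14, 12), 6.0)
    mask = default_analysis_mask(grid)
    rng = np.random.default_rng(seed)
    n_fp = 0
    for rep in range(n_replicates):
        maps = [smooth_noise_field(grid, mask, fwhm_mm, 1.0, rng) for _ in range(n_subjects)]
        res = one_sample_perm_t(maps, n_perm=2**n_subjects, seed=0)
        assert res.exact
        n_fp += bool(np.any(res.p_fwe.values <= alpha))
    return {
        "n_replicates": n_replicates,
        "n_voxels": int(mask.sum()),
        "fwe_rate": n_fp / n_replicates,
        "exact_enumeration": True,
    }


# ---------------------------------------------------------------------------
# Generator-truth recovery through the full pipeline
# ---------------------------------------------------------------------------

def beta1_recovery_study(n_cohorts: int = 50, seed: int = 0) -> dict:
    """Recovery of the planted alignment-improvement coefficient.

    Per replicate cohort (default study conditions, n = 14): change maps
    -> product-sum alignment (linear in the planted gain) -> cohort
    z-scores -> OLS of the planted improvement on the z-scores. Also
    records, per cohort, whether the one-sample t-map elevates the
    planted template support above background and whether the rank-metric
    alignment correlates positively with the planted gains.
    """
    cfg = CohortConfig()
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)
    estimates = []
    spearman_positive = 0
    support_recovered = 0
    t_support_ratio = []
    for rep in range(n_cohorts):
        cohort, truth = simulate_cohort(cfg, seed=int(base + rep))
        deltas = diff_maps(
            [p.on_map for p in cohort.patients], [p.off_map for p in cohort.patients]
        )
        scores = cohort_alignment(deltas, truth.template_network, "product_sum")
        reg = outcome_regression(truth.improvement_true, scores.z)
        estimates.append(reg.coef["alignment_z"])
        rank_scores = cohort_alignment(deltas, truth.template_network, "spearman")
        spearman_positive += stats.pearsonr(
            rank_scores.z, truth.network_gain
        ).statistic > 0
        tmap = one_sample_perm_t(deltas, n_perm=1, seed=0).stat
        planted = truth.template_network.data != 0
        med_in = np.median(np.abs(tmap.data[planted & tmap.mask]))
        med_out = np.median(np.abs(tmap.data[~planted & tmap.mask]))
        t_support_ratio.append(med_in / med_out)
        support_recovered += med_in > med_out
    estimates = np.asarray(estimates)
    se = estimates.std(ddof=1) / np.sqrt(n_cohorts)
    return {
        "n_cohorts": n_cohorts,
        "beta1_planted": cfg.beta1,
        "beta1_estimate_mean": float(estimates.mean()),
        "beta1_estimate_se": float(se),
        "beta1_bias": float(estimates.mean() - cfg.beta1),
        "beta1_bias_in_se_units": float((estimates.mean() - cfg.beta1) / se),
        "spearman_gain_corr_positive_fraction": spearman_positive / n_cohorts,
        "tmap_support_recovered_fraction": support_recovered / n_cohorts,
        "tmap_support_to_background_t_ratio_median": float(np.median(t_support_ratio)),
    }


# ---------------------------------------------------------------------------
# Connectivity-GLM cluster inference
# ---------------------------------------------------------------------------

def connglm_recovery_study(
    n_replicates: int = 20, n_perm: int = 200, seed: int = 0
) -> dict:
    """Detection of a compact planted positive-connectivity effect."""
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)
    detected = 0
    for rep in range(n_replicates):
        deltas, conns, amp, region = simulate_connectivity_effect(seed=int(base + rep))
        res = connectivity_glm(deltas, conns, amp)
        cres = res.cluster_correct("pos_conn", n_perm=n_perm, seed=int(base + rep))
        region_voxels = set(map(tuple, np.argwhere(region)))
        detected += any(
            set(map(tuple, c.voxels)) & region_voxels for c in cres.significant(0.05)
        )
    return {
        "n_replicates": n_replicates,
        "detection_rate": detected / n_replicates,
    }


def connglm_null_fwe_study(
    n_replicates: int = 200, n_perm: int = 200, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Cluster-level family-wise error on matched null data."""
    base = np.random.SeedSequence(seed).generate_state(1)[0] % (2**30)
    n_fp = 0
    for rep in range(n_replicates):
        deltas, conns, amp, _ = simulate_connectivity_effect(
            effect_size=0.0, seed=int(base + rep)
        )
        res = connectivity_glm(deltas, conns, amp)
        cres = res.cluster_correct("pos_conn", n_perm=n_perm, seed=int(base + rep))
        n_fp += len(cres.significant(alpha)) > 0
    return {
        "n_replicates": n_replicates,
        "cluster_fwe_rate": n_fp / n_replicates,
    }


# ---------------------------------------------------------------------------
# OrT/CVA identity
# ---------------------------------------------------------------------------

def ortcva_identity_study(n_subjects: int = 10, seed: int = 0) -> dict:
    """Noise-free planted-pattern recovery and condition-swap antisymmetry."""
    grid, mask = _study_grid()
    rng = np.random.default_rng(seed)
    pattern = smooth_noise_field(grid, mask, 8.0, 1.0, rng).values
    pattern /= np.linalg.norm(pattern)
    proto = BrainMap(grid, np.zeros(grid.shape), mask)
    ons, offs = [], []
    for _ in range(n_subjects):
        base = smooth_noise_field(grid, mask, 8.0, 1.0, rng).values + 10.0
        c = rng.uniform(0.5, 2.0)
        offs.append(proto.with_values(base))
        ons.append(proto.with_values(base + c * pattern))
    fit = ortcva_fit(ons, offs, n_components=5, n_boot=0)
    swapped = ortcva_fit(offs, ons, n_components=5, n_boot=0)
    r = float(np.corrcoef(fit.pattern.values, pattern)[0, 1])
    return {
        "pattern_abs_correlation": abs(r),
        "ordinal_violations": fit.ordinal_violations,
        "sign_antisymmetry_max_error": float(
            np.abs(swapped.pattern.values + fit.pattern.values).max()
        ),
    }


# ---------------------------------------------------------------------------
# Exact structural identities
# ---------------------------------------------------------------------------

def structural_identity_study(seed: int = 0) -> dict:
    """Max absolute error of the exact identities the pipeline relies on."""
    grid, mask = _study_grid()
    rng = np.random.default_rng(seed)

    conn = smooth_noise_field(grid, mask, 8.0, 1.0, rng)
    pair = split_signed(conn)
    split_err = float(
        np.abs(pair.positive_part.data + pair.negative_part.data - conn.data).max()
    )

    uptake = smooth_noise_field(grid, mask, 8.0, 0.1, rng)
    uptake = uptake.with_values(uptake.values + 1.0)
    ref = mask & (rng.random(grid.shape) > 0.5)
    norm1 = intensity_normalize(uptake, ref)
    norm2 = intensity_normalize(norm1, ref)
    norm_err = float(np.abs(norm2.data - norm1.data).max())

    xcoords = grid.axis_coords(0)
    left_mask = (xcoords < 0)[:, None, None] & mask
    left = BrainMap(grid, np.where(left_mask, uptake.data, 0.0), left_mask)
    recovered = mirror(mirror(left, "left_to_right_bilateral"), "average_to_left")
    mirror_err = float(np.abs(recovered.data[left_mask] - left.data[left_mask]).max())

    template = make_template_network(
        grid,
        hubs=(((-16.0, -10.0, 14.0), 8.0, +1, 1.0), ((16.0, -10.0, 14.0), 8.0, +1, 1.0),
              ((-10.0, -22.0, -14.0), 7.0, -1, 1.0), ((10.0, -22.0, -14.0), 7.0, -1, 1.0)),
        mask=mask,
    )
    deltas = [smooth_noise_field(grid, mask, 8.0, 1.0, rng) for _ in range(8)]
    scores = cohort_alignment(deltas, template)
    z_mean_err = abs(float(scores.z.mean()))
    z_sd_err = abs(float(scores.z.std(ddof=1)) - 1.0)

    z = rng.normal(size=14)
    y = 30 + 10 * z + rng.normal(0, 8, 14)
    reg = outcome_regression(y, z)
    r = stats.pearsonr(z, y).statistic
    r2_err = abs(reg.r_squared - r**2)

    return {
        "sign_split_reconstruction_max_error": split_err,
        "intensity_normalize_idempotence_max_error": norm_err,
        "mirror_composition_max_error": mirror_err,
        "alignment_z_mean_error": z_mean_err,
        "alignment_z_sd_error": z_sd_err,
        "r_squared_vs_pearson_error": float(r2_err),
    }
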