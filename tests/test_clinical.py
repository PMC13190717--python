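"""Clinical statistics: paired test, improvement, screening, regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from tremornet import errors
from tremornet.clinical import (
    cohort_improvement,
    outcome_regression,
    paired_ttest,
    relative_improvement,
    screen_confounds,
    vta_overlap_roi,
)
from tremornet.simulate import CohortConfig, simulate_cohort
from tests.conftest import SMALL_HUBS


def t_sf_oracle(t, df):
    """Student-t upper tail via the regularized incomplete beta function,
    independent of scipy.stats.t."""
    x = df / (df + t * t)
    p_two = special.betainc(df / 2.0, 0.5, x)
    return p_two / 2.0 if t >= 0 else 1.0 - p_two / 2.0


class TestPairedTtest:
    @given(
        st.lists(st.floats(-50, 50), min_size=4, max_size=30),
        st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None)
    def test_p_matches_independent_t_cdf_oracle(self, base, salt):
        rng = np.random.default_rng(salt)
        off = np.asarray(base) + rng.normal(0, 1, len(base))
        on = rng.normal(0, 5, len(base))
        d = off - on
        if d.std(ddof=1) == 0:
            return
        res = paired_ttest(off, on)
        p_oracle = 2.0 * t_sf_oracle(abs(res.t), res.df)
        assert res.p == pytest.approx(p_oracle, abs=1e-12)
        assert res.df == len(base) - 1
        assert res.t == pytest.approx(res.mean_diff / res.sem_diff)

    def test_sign_flip_symmetry_of_two_sided_p(self, rng):
        off = rng.normal(10, 3, 12)
        on = rng.normal(5, 3, 12)
        res = paired_ttest(off, on)
        flipped = paired_ttest(on, off)
        assert flipped.p == pytest.approx(res.p)
        assert flipped.t == pytest.approx(-res.t)
        assert flipped.mean_change == pytest.approx(-res.mean_change)

    def test_identical_conditions_rejected_as_degenerate(self, rng):
        x = rng.normal(size=8)
        with pytest.raises(errors.DegenerateDesignError):
            paired_ttest(x, x)


class TestRelativeImprovement:
    def test_complete_suppression_is_hundred_percent(self):
        assert relative_improvement(12.0, 0.0) == pytest.approx(100.0)

    def test_no_change_is_zero_percent(self):
        assert relative_improvement(9.0, 9.0) == pytest.approx(0.0)

    def test_worsening_is_negative(self):
        assert relative_improvement(10.0, 15.0) == pytest.approx(-50.0)

    def test_zero_baseline_rejected(self):
        with pytest.raises(errors.UndefinedImprovementError):
            relative_improvement(0.0, 1.0)

    def test_cohort_summary_reports_both_readings(self):
        off = np.array([10.0, 20.0])
        on = np.array([5.0, 5.0])
        out = cohort_improvement(off, on)
        assert out["per_patient"] == pytest.approx([50.0, 75.0])
        assert out["mean_of_patient_percentages"] == pytest.approx(62.5)
        assert out["group_mean_ratio"] == pytest.approx(100 * (30 - 10) / 30)


class TestScreenConfounds:
    def test_planted_amplitude_confound_identified(self, rng):
        n = 40
        params = pd.DataFrame(
            {
                "amplitude": rng.uniform(1.5, 4.5, n),
                "pulse_width": rng.uniform(40, 60, n),
                "frequency": rng.uniform(130, 180, n),
            }
        )
        response = 2.0 * params["amplitude"].to_numpy()
        table = screen_confounds(response, params)
        amp = table.set_index("parameter").loc["amplitude"]
        assert amp["r_squared"] == pytest.approx(1.0, abs=1e-10)
        assert amp["significant_independent"]
        others = table.set_index("parameter").loc[["pulse_width", "frequency"]]
        assert not others["significant_independent"].any()

    def test_duplicated_parameter_columns_flag_infinite_vif(self, rng):
        n = 20
        x = rng.normal(size=n)
        params = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=n)})
        table = screen_confounds(rng.normal(size=n), params)
        assert np.isinf(table.set_index("parameter").loc["a", "vif"])
        assert np.isinf(table.set_index("parameter").loc["b", "vif"])

    def test_too_few_observations_rejected(self, rng):
        params = pd.DataFrame({"a": [1.0, 2, 3], "b": [2.0, 1, 3], "c": [1.0, 3, 2]})
        with pytest.raises(errors.InsufficientDataError):
            screen_confounds(np.array([1.0, 2, 3]), params)

    def test_constant_column_excluded_with_flag(self, rng):
        n = 12
        params = pd.DataFrame({"a": rng.normal(size=n), "b": np.full(n, 3.0)})
        table = screen_confounds(rng.normal(size=n), params).set_index("parameter")
        assert table.loc["b", "constant_excluded"]
        assert not table.loc["a", "constant_excluded"]


class TestOutcomeRegression:
    def test_exact_linear_relation_gives_unit_r_squared(self):
        z = np.array([-1.5, -0.5, 0.0, 0.5, 1.5, 2.0])
        res = outcome_regression(40 + 12 * z, z)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_single_predictor_r_squared_equals_squared_pearson(self, rng):
        z = rng.normal(size=14)
        y = 30 + 10 * z + rng.normal(0, 8, 14)
        res = outcome_regression(y, z)
        r = stats.pearsonr(z, y).statistic
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_adding_covariate_never_decreases_r_squared(self, rng):
        z = rng.normal(size=14)
        y = 30 + 10 * z + rng.normal(0, 8, 14)
        amp = rng.uniform(1.5, 4.5, 14)
        with_cov = outcome_regression(y, z, covariates=pd.DataFrame({"amplitude": amp}))
        assert with_cov.covariate_free is not None
        assert with_cov.r_squared >= with_cov.covariate_free.r_squared - 1e-12

    def test_rank_deficient_design_rejected(self, rng):
        z = rng.normal(size=10)
        with pytest.raises(errors.DegenerateDesignError):
            outcome_regression(
                rng.normal(size=10), z, covariates=pd.DataFrame({"copy": z})
            )


class TestVtaOverlapRoi:
    @staticmethod
    def cohort_with_vtas(vtas):
        cfg = CohortConfig(
            n_patients=len(vtas), shape=(16, 18, 16), voxel_size_mm=4.0,
            hubs=SMALL_HUBS, stim_centers_mm=((-8.0, -4.0, 2.0), (8.0, -4.0, 2.0)),
        )
        cohort, _ = simulate_cohort(cfg, seed=0)
        for p, v in zip(cohort.patients, vtas):
            p.vta_mask = v
        return cohort

    def test_identical_vtas_reproduce_the_common_vta(self):
        shape = (16, 18, 16)
        vta = np.zeros(shape, dtype=bool)
        vta[7:9, 8:10, 7:9] = True
        cohort = self.cohort_with_vtas([vta.copy() for _ in range(4)])
        roi = vta_overlap_roi(cohort, min_overlap=3)
        np.testing.assert_array_equal(roi.mask, vta & cohort.analysis_mask)

    def test_disjoint_vtas_give_empty_roi_error(self):
        shape = (16, 18, 16)
        vtas = []
        for i in range(4):
            v = np.zeros(shape, dtype=bool)
            v[2 * i + 4, 9, 8] = True
            vtas.append(v)
        cohort = self.cohort_with_vtas(vtas)
        with pytest.raises(errors.EmptyROIError):
            vta_overlap_roi(cohort, min_overlap=3)

    def test_nested_spheres_roi_matches_brute_force_count(self):
        from tremornet.simulate import sphere_mask

        cfg = CohortConfig(
            n_patients=3, shape=(16, 18, 16), voxel_size_mm=4.0,
            hubs=SMALL_HUBS, stim_centers_mm=((-8.0, -4.0, 2.0), (8.0, -4.0, 2.0)),
        )
        cohort, _ = simulate_cohort(cfg, seed=1)
        radii = [6.0, 10.0, 14.0]
        vtas = [sphere_mask(cohort.template_grid, (0.0, -4.0, 2.0), r) for r in radii]
        for p, v in zip(cohort.patients, vtas):
            p.vta_mask = v
        roi = vta_overlap_roi(cohort, min_overlap=3)
        # brute force: voxel-by-voxel counting oracle
        count = sum(v.astype(int) for v in vtas)
        np.testing.assert_array_equal(roi.mask, (count >= 3) & cohort.analysis_mask)
        # innermost sphere is the intersection
        np.testing.assert_array_equal(roi.mask, vtas[0] & cohort.analysis_mask)
        assert roi.z_delta.mean() == pytest.approx(0.0, abs=1e-10)
        assert roi.z_delta.std(ddof=1) == pytest.approx(1.0, abs=1e-10)
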