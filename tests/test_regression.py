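import numpy as np
import pandas as pd
import pytest

from neomux import (
    auc_aggregate,
    fit_auc_models,
    fit_density_models,
    iqr_filter,
    make_density_grid,
    strength_ttest,
)


class TestIQRFilter:
    def test_constant_vector_untouched(self):
        kept, mask = iqr_filter([3.0] * 6)
        assert kept.size == 6 and mask.all()

    def test_hand_quartile_example(self):
        kept, mask = iqr_filter([1, 2, 3, 4, 100])
        assert list(kept) == [1, 2, 3, 4]
        assert list(mask) == [True, True, True, True, False]

    def test_inlier_data_is_identity(self, rng):
        v = rng.uniform(10, 11, 50)
        kept, mask = iqr_filter(v)
        assert mask.all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            iqr_filter([1.0, 2.0, 3.0])


class TestAUC:
    def test_constant_profile(self):
        grid = make_density_grid()
        assert auc_aggregate([2.0] * 14, grid) == pytest.approx(2 * 0.65)

    def test_linear_profile_triangle_area(self):
        grid = make_density_grid()
        d = grid.as_array()
        vals = (d - 0.05) / 0.65  # 0 at 0.05, 1 at 0.70
        assert auc_aggregate(vals, grid) == pytest.approx(0.325)

    def test_single_point_grid_rejected(self):
        grid = make_density_grid(0.3, 0.3, 0.1)
        with pytest.raises(ValueError, match="single-point"):
            auc_aggregate([1.0], grid)

    def test_linear_in_values_and_refinement_invariant(self):
        coarse = make_density_grid(0.1, 0.7, 0.2)
        fine = make_density_grid(0.1, 0.7, 0.1)
        f = lambda d: 0.3 + 0.8 * d  # piecewise-linear profile
        a_coarse = auc_aggregate([f(d) for d in coarse], coarse)
        a_fine = auc_aggregate([f(d) for d in fine], fine)
        assert a_coarse == pytest.approx(a_fine)
        doubled = auc_aggregate([2 * f(d) for d in coarse], coarse)
        assert doubled == pytest.approx(2 * a_coarse)


class TestStrengthTTest:
    def test_identical_groups(self):
        t, df, p = strength_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_welch_closed_form(self):
        t, df, p = strength_ttest([1, 2, 3], [4, 5, 6])
        assert abs(t) == pytest.approx(3.674, abs=1e-3)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.0213, abs=5e-4)

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError):
            strength_ttest([1.0], [2.0, 3.0])


def _profiles(subjects, densities, beta_ga, gamma_hemi, rng,
              sd_subj=0.01, sd_eps=0.01, metric="global_efficiency",
              modality="SC"):
    """Observation table drawn from the mixed model's own process."""
    rows = []
    ga_mean = subjects["ga_birth"].mean()
    b = rng.normal(0, sd_subj, size=len(subjects))
    for i, (_, s) in enumerate(subjects.iterrows()):
        for hemi, hcode in (("L", 0), ("R", 1)):
            for d in densities:
                val = (0.5 + beta_ga * (s.ga_birth - ga_mean)
                       + gamma_hemi * hcode + b[i]
                       + rng.normal(0, sd_eps))
                rows.append((s.subject_id, modality, metric, hemi, d, val))
    return pd.DataFrame(rows, columns=[
        "subject_id", "modality", "metric", "hemisphere", "density", "value"])


def _subjects(rng, n=30):
    ga = np.concatenate([rng.uniform(37, 42, n // 2), rng.uniform(24, 36.5, n - n // 2)])
    return pd.DataFrame({
        "subject_id": [f"s{i:03d}" for i in range(n)],
        "ga_birth": ga,
    })


class TestFitDensityModels:
    def test_recovers_planted_ga_slope(self, rng):
        subjects = _subjects(rng)
        prof = _profiles(subjects, [0.2], beta_ga=0.005, gamma_hemi=0.002, rng=rng)
        res = fit_density_models(prof, subjects)
        row = res[(res.term == "ga_c")].iloc[0]
        assert row["converged"]
        assert row["estimate"] == pytest.approx(0.005, abs=3 * row["se"])
        assert row["estimate"] > 0

    def test_densities_above_cutoff_excluded(self, rng):
        subjects = _subjects(rng)
        prof = _profiles(subjects, [0.4, 0.6], beta_ga=0.0, gamma_hemi=0.0, rng=rng)
        res = fit_density_models(prof, subjects, max_density=0.5)
        assert set(res["density"]) == {0.4}

    def test_duplicated_observations_leave_estimates_unchanged(self, rng):
        subjects = _subjects(rng, n=20)
        prof = _profiles(subjects, [0.3], beta_ga=0.004, gamma_hemi=0.001, rng=rng)
        res1 = fit_density_models(prof, subjects)
        res2 = fit_density_models(
            pd.concat([prof, prof], ignore_index=True), subjects)
        for term in ("ga_c", "hemi"):
            e1 = res1[res1.term == term]["estimate"].iloc[0]
            e2 = res2[res2.term == term]["estimate"].iloc[0]
            assert e2 == pytest.approx(e1, rel=1e-3, abs=1e-6)

    def test_bh_adjustment_within_metric_family(self, rng):
        subjects = _subjects(rng)
        prof = _profiles(subjects, [0.1, 0.2, 0.3], beta_ga=0.0,
                         gamma_hemi=0.0, rng=rng)
        res = fit_density_models(prof, subjects)
        fam = res[res.term == "ga_c"]
        assert len(fam) == 3
        assert np.all(fam["p_adjusted"] >= fam["p_raw"] - 1e-12)

    def test_single_density_bh_is_identity(self, rng):
        subjects = _subjects(rng)
        prof = _profiles(subjects, [0.25], beta_ga=0.0, gamma_hemi=0.0, rng=rng)
        res = fit_density_models(prof, subjects)
        row = res[res.term == "ga_c"].iloc[0]
        assert row["p_adjusted"] == pytest.approx(row["p_raw"])

    def test_undefined_values_dropped_listwise_not_fatal(self, rng):
        subjects = _subjects(rng)
        prof = _profiles(subjects, [0.2], beta_ga=0.0, gamma_hemi=0.0, rng=rng)
        prof.loc[prof.sample(5, random_state=1).index, "value"] = np.nan
        res = fit_density_models(prof, subjects)
        assert res[res.term == "ga_c"]["n_observations"].iloc[0] <= 2 * len(subjects) - 5

    def test_permuted_ga_rarely_significant(self, rng):
        hits = 0
        reps = 25
        for r in range(reps):
            local = np.random.default_rng(900 + r)
            subjects = _subjects(local, n=24)
            prof = _profiles(subjects, [0.2], beta_ga=0.0, gamma_hemi=0.0,
                             rng=local)
            res = fit_density_models(prof, subjects)
            hits += res[res.term == "ga_c"]["p_raw"].iloc[0] < 0.05
        assert hits / reps <= 0.2  # ~alpha with binomial slack


class TestFitAUCModels:
    def test_auc_model_recovers_scaled_slope(self, rng):
        subjects = _subjects(rng)
        grid = make_density_grid(0.1, 0.7, 0.2)
        prof = _profiles(subjects, list(grid), beta_ga=0.005,
                         gamma_hemi=0.0, rng=rng)
        res = fit_auc_models(prof, subjects, grid)
        row = res[res.term == "ga_c"].iloc[0]
        assert row["density"] == "AUC"
        # AUC of a constant-in-density effect scales the slope by the span
        assert row["estimate"] == pytest.approx(0.005 * 0.6, abs=3 * row["se"])
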