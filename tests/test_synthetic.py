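"""Generator correctness: moments, survival-law agreement, bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import hemivar as hv
from hemivar.design import build_collapsed, check_identifiable
from hemivar.gompertz import gompertz_survival
from hemivar.synthetic import inject_outlier_vials, simulate_gompertz_cohort, simulate_line_effects


class TestLineEffects:
    def test_zero_variance_gives_zero_effects(self):
        eff = simulate_line_effects(50, np.zeros((2, 2)), seed=1)
        assert np.all(eff[["effect_F", "effect_M"]].to_numpy() == 0.0)

    def test_sample_covariance_recovers_G_at_large_n(self):
        # V_L values and the cross-sex correlation of the lifespan A-lines
        c = 0.50 * np.sqrt(15.00 * 17.36)
        G = np.array([[15.00, c], [c, 17.36]])
        n = 10 ** 5
        eff = simulate_line_effects(n, G, seed=2)
        S = np.cov(eff[["effect_F", "effect_M"]].to_numpy().T)
        # MC SE of a normal (co)variance estimate
        for i in range(2):
            for j in range(2):
                se = np.sqrt((G[i, i] * G[j, j] + G[i, j] ** 2) / n)
                assert abs(S[i, j] - G[i, j]) < 3 * se

    def test_perfect_correlation_is_exactly_linear(self):
        v1, v2 = 4.0, 9.0
        G = np.array([[v1, np.sqrt(v1 * v2)], [np.sqrt(v1 * v2), v2]])
        eff = simulate_line_effects(200, G, seed=3)
        ratio = eff["effect_M"] / eff["effect_F"]
        assert np.allclose(ratio, np.sqrt(v2 / v1), atol=1e-10)

    def test_non_psd_rejected_with_eigenvalue(self):
        G = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="eigenvalue"):
            simulate_line_effects(10, G, seed=4)


class TestLifespans:
    def test_zero_variance_reproduces_fixed_effects_exactly(self):
        be = {s: np.array([-2.0, 1.0, 0.5, 0.5]) for s in ("F", "M")}
        params = {ct: hv.GeneticParams(
            grand_mean={"F": 60.0, "M": 50.0}, G=np.zeros((2, 2)),
            V_V={"F": 0.0, "M": 0.0}, V_R={"F": 1e-12, "M": 1e-12},
            batch_effects=be) for ct in ("A", "X")}
        design = hv.DesignConfig(n_lines_per_type=3, n_flies_per_vial=4)
        rec = hv.simulate_lifespans(design, params, seed=5)
        for (sex, batch), grp in rec.groupby(["sex", "batch"]):
            mu = (60.0 if sex == "F" else 50.0) + be[sex][batch - 1]
            assert np.allclose(grp["lifespan_days"], mu, atol=1e-4)

    def test_moments_match_study_conditions(self, a_full_records):
        af = a_full_records[a_full_records.sex == "F"]
        n = len(af)
        vp = 15.00 + 4.78 + 73.72
        assert abs(af.lifespan_days.mean() - 64.75) < 3 * np.sqrt(vp / n)
        line_means = af.groupby("line_id")["lifespan_days"].mean()
        # var of line means ~ V_L + (V_V + V_R/50)/4; the V_L part dominates
        expected = 15.00 + (4.78 + 73.72 / 50) / 4
        se = expected * np.sqrt(2 / 39)
        assert abs(line_means.var() - expected) < 3 * se

    def test_record_count_and_vial_bookkeeping(self, small_records,
                                               small_design):
        d = small_design
        assert len(small_records) == d.n_records
        vials = small_records.groupby("vial_id")
        assert len(vials) == d.n_lines_per_type * 2 * 2 * d.n_batches
        # no vial spans two lines or sexes
        assert (vials["line_id"].nunique() == 1).all()
        assert (vials["sex"].nunique() == 1).all()

    def test_reproducible_given_seed(self, small_design, study_params):
        r1 = hv.simulate_lifespans(small_design, study_params, seed=42)
        r2 = hv.simulate_lifespans(small_design, study_params, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_single_fly_vials_flagged_non_identifiable(self, study_params):
        design = hv.DesignConfig(n_lines_per_type=4, n_flies_per_vial=1,
                                 chromosome_types=("A",))
        rec = hv.simulate_lifespans(design, study_params, seed=6)
        data = build_collapsed(rec)
        with pytest.raises(ValueError, match="non-identifiable"):
            check_identifiable(data, vial_term=True)


class TestGompertzCohort:
    def test_exponential_limit_mean(self):
        sch = simulate_gompertz_cohort(0.1, 0.0, 20000, 0.5, 400.0, seed=7)
        mids = 0.5 * (sch.boundaries[:-1] + sch.boundaries[1:])
        mean = np.dot(sch.deaths, mids) / sch.deaths.sum()
        assert sch.censored < 100
        assert abs(mean - 10.0) < 3 * 10.0 / np.sqrt(20000) + 0.25

    def test_median_matches_analytic_quantile(self):
        alpha, beta, n = 2.8e-6, 0.17, 10 ** 5
        sch = simulate_gompertz_cohort(alpha, beta, n, 0.25, 200.0, seed=8)
        cum = np.cumsum(sch.deaths)
        med_emp = sch.boundaries[1:][np.searchsorted(cum, n / 2)]
        med_true = np.log(1 - (beta / alpha) * np.log(0.5)) / beta
        # MC SE of the sample median ~ 1/(2 f(m) sqrt(n)), plus bin width
        f_m = alpha * np.exp(beta * med_true) * 0.5
        se = 1 / (2 * f_m * np.sqrt(n))
        assert abs(med_emp - med_true) < 3 * se + 0.25

    def test_degenerate_cohort_all_censored(self):
        sch = simulate_gompertz_cohort(1e-6, 0.1, 1, 2.0, 1.0, seed=9)
        assert sch.censored == 1
        assert sch.deaths.sum() == 0

    def test_survival_curve_within_dkw_band(self):
        alpha, beta, n = 1e-5, 0.12, 10 ** 5
        sch = simulate_gompertz_cohort(alpha, beta, n, 2.0, 200.0, seed=10)
        surv_emp = 1 - np.cumsum(sch.deaths) / n
        surv_true = gompertz_survival(alpha, beta, sch.boundaries[1:])
        eps = np.sqrt(np.log(2 / 0.05) / (2 * n))
        assert np.max(np.abs(surv_emp - surv_true)) < eps

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            simulate_gompertz_cohort(-1.0, 0.1, 10, 2.0, 100.0, seed=0)


class TestOutlierInjection:
    def test_fraction_zero_is_identity(self, small_records):
        out, affected = inject_outlier_vials(small_records, 0.0, 25.0, seed=1)
        assert affected == []
        pd.testing.assert_frame_equal(out, small_records)

    def test_fraction_one_hits_every_female_vial(self, small_records):
        out, affected = inject_outlier_vials(small_records, 1.0, 25.0, seed=2)
        female_vials = set(small_records.loc[small_records.sex == "F",
                                             "vial_id"])
        assert set(affected) == female_vials

    def test_shift_applied_with_floor(self, small_records):
        out, affected = inject_outlier_vials(small_records, 0.1, 25.0, seed=3)
        mask_a = out["vial_id"].isin(affected)
        before = small_records.loc[mask_a, "lifespan_days"]
        after = out.loc[mask_a, "lifespan_days"]
        assert np.allclose(after, np.clip(before - 25.0, 1.0, None))
        # untouched vials identical
        pd.testing.assert_frame_equal(out[~mask_a],
                                      small_records[~mask_a])

    def test_genetic_mode_targets_short_lived_lines(self, small_records):
        out, affected = inject_outlier_vials(
            small_records, 0.1, 25.0, seed=4, genetic_outliers=True)
        means = (small_records[small_records.sex == "F"]
                 .groupby("line_id")["lifespan_days"].mean().sort_values())
        short = set(means.index[:int(np.ceil(0.3 * len(means)))])
        hit_lines = set(out.loc[out.vial_id.isin(affected), "line_id"])
        assert hit_lines <= short
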