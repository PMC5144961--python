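"""Derived quantitative-genetic statistics and posterior summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hemivar.quantgen import (
    additive_variance,
    chain_difference,
    cv_a,
    derive_stats,
    phenotypic_variance,
    posterior_summary,
    ratio_stats,
    rmf,
    rmf_samples,
    x_linkage_proportion,
)


class TestAdditiveVariance:
    @pytest.mark.parametrize("V_L,ct,sex,expected", [
        (15.00, "autosome", "F", 30.00),   # diploid cloned set: doubled
        (6.97, "A", "F", 13.94),
        (2.28, "X", "F", 4.56),
        (8.95, "X", "M", 8.95),            # hemizygous male X: unchanged
        (0.0, "A", "M", 0.0),
    ])
    def test_conversion_rules(self, V_L, ct, sex, expected):
        assert additive_variance(V_L, ct, sex) == pytest.approx(expected)

    def test_unknown_chromosome_type_rejected(self):
        with pytest.raises(ValueError):
            additive_variance(1.0, "Y", "M")

    def test_vectorized_over_samples(self):
        out = additive_variance(np.array([1.0, 2.0]), "A", "F")
        np.testing.assert_allclose(out, [2.0, 4.0])


class TestPhenotypicVariance:
    @pytest.mark.parametrize("V_L,V_V,V_R,expected", [
        (17.36, 4.82, 89.92, 112.10),
        (2.28, 5.96, 60.95, 69.19),
        (6.97, None, 25.86, 32.83),       # aging model: no vial component
        (0.0, 0.0, 0.0, 0.0),
    ])
    def test_sums(self, V_L, V_V, V_R, expected):
        assert phenotypic_variance(V_L, V_V, V_R) == pytest.approx(expected)


class TestCVA:
    @pytest.mark.parametrize("V_A,mean,expected2dp", [
        (30.00, 64.75, 0.08),
        (8.95, 51.36, 0.06),
        (0.0, 40.0, 0.0),
    ])
    def test_values(self, V_A, mean, expected2dp):
        assert round(cv_a(V_A, mean), 2) == pytest.approx(expected2dp)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_a(1.0, 0.0)


class TestRmf:
    def test_zero_covariance_gives_zero(self):
        assert rmf(0.0, 3.0, 5.0) == 0.0

    def test_maximal_covariance_gives_one(self):
        assert rmf(np.sqrt(15.0), 3.0, 5.0) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rmf(1.0, 0.0, 5.0)

    def test_samples_dropped_and_counted(self):
        vals, dropped = rmf_samples(np.array([1.0, 1.0, 1.0]),
                                    np.array([4.0, 0.0, 4.0]),
                                    np.array([4.0, 4.0, 4.0]))
        assert dropped == 1
        np.testing.assert_allclose(vals, [0.25, 0.25])

    @given(st.floats(0.1, 50), st.floats(0.1, 50), st.floats(-1, 1))
    def test_bounded_for_psd_inputs(self, v1, v2, r):
        cov = r * np.sqrt(v1 * v2)
        assert -1.0 <= rmf(cov, v1, v2) <= 1.0 + 1e-12


class TestPosteriorSummary:
    def test_constant_vector(self):
        s = posterior_summary(np.full(100, 3.5))
        assert s["mean"] == 3.5 and s["sd"] == 0.0
        assert s["ci_low"] == s["ci_high"] == 3.5

    def test_lognormal_median_matches_analytic(self):
        rng = np.random.default_rng(61)
        mu, sig, n = 1.2, 0.8, 2000
        x = rng.lognormal(mu, sig, n)
        s = posterior_summary(x, skewed=True)
        # MC SE of the sample median of a lognormal
        med = np.exp(mu)
        f_med = np.exp(-0.5 * (0 / sig) ** 2) / (med * sig * np.sqrt(2 * np.pi))
        se = 1 / (2 * f_med * np.sqrt(n))
        assert abs(s["median"] - med) < 3 * se
        assert s["estimate"] == s["median"]

    def test_skewed_flag_resists_ratio_blowup(self):
        rng = np.random.default_rng(62)
        num = rng.normal(10, 1, 2000)
        den = np.abs(rng.normal(0.0, 0.5, 2000)) + 1e-6
        s = posterior_summary(num / den, skewed=True)
        assert np.isfinite(s["median"])
        assert s["mean"] > 2 * s["median"]  # mean inflated, median stable

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary([1.0])


class TestChainDifference:
    def test_identity_pairing_of_equal_chains_is_zero(self):
        x = np.random.default_rng(63).normal(size=500)
        d = chain_difference(x, x, permute=False)
        assert np.all(d["samples"] == 0.0)
        assert d["frac_ge_0"] == 1.0

    def test_mean_shift_recovered(self):
        rng = np.random.default_rng(64)
        a = rng.normal(1, 1, 2000)
        b = rng.normal(0, 1, 2000)
        d = chain_difference(a, b, seed=1)
        se = np.sqrt(2 / 2000)
        assert abs(d["summary"]["mean"] - 1.0) < 3 * se

    def test_null_fraction_near_half(self):
        rng = np.random.default_rng(65)
        a = rng.normal(0, 1, 2000)
        b = rng.normal(0, 1, 2000)
        d = chain_difference(a, b, seed=2)
        assert abs(d["frac_ge_0"] - 0.5) < 3 * np.sqrt(0.25 / 2000) + 0.01

    def test_unequal_lengths_resampled_with_flag(self):
        d = chain_difference(np.ones(100), np.zeros(50), seed=3)
        assert d["resampled"]
        assert d["samples"].size == 100


class TestXLinkage:
    def test_equal_constant_samples_give_half(self):
        x = np.full(100, 7.0)
        res = x_linkage_proportion(x, x)
        assert res["summary"]["mean"] == pytest.approx(0.5)

    def test_zero_x_variance_gives_zero(self):
        res = x_linkage_proportion(np.zeros(100), np.full(100, 5.0))
        assert res["summary"]["mean"] == 0.0

    def test_generative_proportion_recovered(self):
        rng = np.random.default_rng(66)
        reps_est = []
        for _ in range(10):
            va = rng.gamma(30, 1.0, 2000)          # autosomal V_A samples
            vx = rng.gamma(30, 1.0, 2000) * (0.156 / 0.844)
            reps_est.append(x_linkage_proportion(vx, va)["summary"]["mean"])
        se = np.std(reps_est, ddof=1) / np.sqrt(len(reps_est))
        assert abs(np.mean(reps_est) - 0.156) < max(3 * se, 0.01)

    def test_proportion_always_in_unit_interval(self):
        rng = np.random.default_rng(67)
        res = x_linkage_proportion(rng.gamma(2, 1, 500), rng.gamma(2, 1, 500))
        assert np.all((res["samples"] >= 0) & (res["samples"] <= 1))


class TestRatioStats:
    @staticmethod
    def _const(v):
        return np.full(400, float(v))

    def test_identical_sexes_give_unit_ratios(self):
        V_A = {(ct, s): self._const(10.0)
               for ct in ("A", "X") for s in ("F", "M")}
        CV_A = {k: self._const(0.1) for k in V_A}
        out = ratio_stats(V_A, CV_A)
        for k in ("VA_ratio_MF_A", "CVA_ratio_MF_X", "CVA_ratio_of_ratios"):
            assert out[k]["summary"]["median"] == pytest.approx(1.0)

    def test_dosage_compensation_expectation_sqrt2(self):
        # twofold male X variance, equal means, equal autosomal variances:
        # the ratio of CV ratios concentrates at sqrt(2)
        rng = np.random.default_rng(68)
        mean = 55.0
        va_f = rng.gamma(200, 0.05, 2000)
        va_m = 2.0 * rng.gamma(200, 0.05, 2000)
        va_a = rng.gamma(200, 0.05, 2000)
        V_A = {("X", "F"): va_f, ("X", "M"): va_m,
               ("A", "F"): va_a, ("A", "M"): va_a}
        CV_A = {k: np.sqrt(v) / mean for k, v in V_A.items()}
        out = ratio_stats(V_A, CV_A, seed=4)
        med = out["CVA_ratio_of_ratios"]["summary"]["median"]
        assert med == pytest.approx(np.sqrt(2), rel=0.03)

    def test_near_zero_denominators_skew_mean_above_median(self):
        rng = np.random.default_rng(69)
        small = np.abs(rng.normal(0, 0.3, 2000)) + 1e-4
        big = rng.normal(8, 1, 2000)
        V_A = {("X", "F"): small, ("X", "M"): big,
               ("A", "F"): np.full(2000, 4.0), ("A", "M"): np.full(2000, 4.0)}
        CV_A = {k: np.sqrt(np.abs(v)) / 50 for k, v in V_A.items()}
        out = ratio_stats(V_A, CV_A, seed=5)
        s = out["VA_ratio_MF_X"]["samples"]
        assert s.mean() > 2 * np.median(s)


def test_derive_stats_per_sample_identities(quick_chain, quick_chain_x):
    """V_A, V_P and CV_A summaries must come from per-sample computation,
    so their means equal the means of the recomputed per-sample vectors."""
    stats = derive_stats({"A": quick_chain, "X": quick_chain_x},
                         trait="lifespan", seed=9)
    df = quick_chain.samples
    va = 2.0 * df["V_L_F"].to_numpy()
    vp = (df["V_L_F"] + df["V_V_F"] + df["V_R_F"]).to_numpy()
    cell = stats.per_cell[("A", "F")]
    assert cell["V_A"]["mean"] == pytest.approx(va.mean())
    assert cell["V_P"]["mean"] == pytest.approx(vp.mean())
    cva = np.sqrt(va) / df["traitF"].to_numpy()
    assert cell["CV_A"]["mean"] == pytest.approx(cva.mean())
    # male X: hemizygous, no doubling
    x_cell = stats.per_cell[("X", "M")]
    assert x_cell["V_A"]["mean"] == pytest.approx(
        quick_chain_x.samples["V_L_M"].mean())
    # X-linkage proportions live in [0, 1]
    for sex in ("F", "M"):
        s = stats.contrasts[f"x_linkage_{sex}"]["samples"]
        assert np.all((s >= 0) & (s <= 1))


def test_ratio_of_ratios_scale_invariance(quick_chain, quick_chain_x):
    """Rescaling all lifespans by a constant must leave the CV ratio of
    ratios unchanged (mean-standardization contract)."""
    import copy
    s1 = derive_stats({"A": quick_chain, "X": quick_chain_x}, seed=11)
    scaled_a = copy.deepcopy(quick_chain)
    scaled_x = copy.deepcopy(quick_chain_x)
    for ch in (scaled_a, scaled_x):
        for c in ch.samples.columns:
            if c.startswith(("V_", "Cov")):
                ch.samples[c] *= 4.0       # variances scale as k^2
            elif c.startswith("trait"):
                ch.samples[c] *= 2.0       # means scale as k
    s2 = derive_stats({"A": scaled_a, "X": scaled_x}, seed=11)
    m1 = s1.contrasts["ratios"]["CVA_ratio_of_ratios"]["summary"]["median"]
    m2 = s2.contrasts["ratios"]["CVA_ratio_of_ratios"]["summary"]["median"]
    assert m1 == pytest.approx(m2, rel=1e-9)
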