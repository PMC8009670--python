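"""Estimation statistics: Hedges' g (summary and bootstrap forms),
Welch's t, regression CIs, ANCOVA and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picquant import (
    ancova_pic_conductance,
    hedges_g,
    hedges_g_from_summary,
    pca_features,
    regress_vs_age,
    regress_with_ci,
    welch_from_summary,
)
from picquant.pipeline import FEATURE_COLUMNS
from picquant.reference import ANCHOR_COMPARISONS
from picquant.stats import DegenerateSamplesError, hedges_correction


def moment_matched(mean, sd, n, rng):
    """Sample with *exact* sample mean and SD (ddof 1)."""
    z = rng.normal(size=n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


PRINTED_G = {
    "pic_amplitude_p30_p60": 1.59,
    "input_conductance_p30_p60": 1.73,
    "vthreshold_p30_p60": -1.74,
    "rmp_p30_p60": -1.24,
    "pic_onset_voltage_p30_p60": -1.83,
    "recruitment_current_p90_p120": -1.26,
    "rmp_p90_p120": 0.40,
    "nonfiring_pic_amplitude": -1.12,
}


class TestHedgesG:
    @pytest.mark.parametrize("name", sorted(ANCHOR_COMPARISONS))
    def test_published_group_summaries_reproduce(self, name):
        """g computed from published group moments matches the published
        effect size at two decimals."""
        g = hedges_g_from_summary(*ANCHOR_COMPARISONS[name])
        assert round(g, 2) == PRINTED_G[name]

    def test_identical_groups_zero(self):
        assert hedges_g_from_summary(3.0, 1.0, 10, 3.0, 1.0, 12) == 0.0

    def test_degenerate_groups_raise(self):
        with pytest.raises(DegenerateSamplesError):
            hedges_g_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)

    def test_exact_vs_approximate_correction(self):
        """The gamma-ratio and 1 - 3/(4 df - 1) corrections agree to
        3 decimals for all df >= 10."""
        for df in range(10, 200):
            exact = hedges_correction(df, "exact")
            approx = hedges_correction(df, "approx")
            assert abs(exact - approx) < 5e-4, df

    @settings(max_examples=50, deadline=None)
    @given(
        m1=st.floats(-5, 5), m2=st.floats(-5, 5),
        s1=st.floats(0.1, 3), s2=st.floats(0.1, 3),
        n1=st.integers(3, 40), n2=st.integers(3, 40),
        a=st.floats(0.1, 10), b=st.floats(-100, 100),
    )
    def test_antisymmetry_and_affine_invariance(self, m1, m2, s1, s2, n1, n2, a, b):
        g12 = hedges_g_from_summary(m1, s1, n1, m2, s2, n2)
        g21 = hedges_g_from_summary(m2, s2, n2, m1, s1, n1)
        assert g12 == pytest.approx(-g21, abs=1e-12)
        # positive affine transform of both groups leaves g unchanged
        g_t = hedges_g_from_summary(a * m1 + b, a * s1, n1, a * m2 + b, a * s2, n2)
        assert g_t == pytest.approx(g12, rel=1e-9, abs=1e-12)


class TestWelch:
    def test_published_nonfiring_statistic(self):
        t, df, p = welch_from_summary(*ANCHOR_COMPARISONS["nonfiring_pic_amplitude"])
        assert round(t, 2) == 6.81
        assert p < 1e-6

    def test_moment_matched_samples_agree_with_summary_form(self):
        rng = np.random.default_rng(0)
        x = moment_matched(2.30, 2.17, 19, rng)
        y = moment_matched(6.73, 3.28, 15, rng)
        es = hedges_g(x, y, n_boot=200, seed=1)
        assert es.g == pytest.approx(
            hedges_g_from_summary(2.30, 2.17, 19, 6.73, 3.28, 15), abs=1e-9
        )
        assert es.df_pooled == 32
        # published alongside g = 1.59 as t(32) = -4.50
        assert es.welch_t == pytest.approx(-4.50, abs=0.02)


class TestBootstrapCI:
    def test_constant_equal_samples_degenerate_interval(self):
        es = hedges_g([1.0] * 5, [1.0] * 6, n_boot=100, seed=0)
        assert es.g == 0.0
        assert es.ci_low == es.ci_high == 0.0

    def test_interval_brackets_point_estimate(self):
        rng = np.random.default_rng(2)
        es = hedges_g(rng.normal(0, 1, 19), rng.normal(1, 1, 15), n_boot=1000, seed=3)
        assert es.ci_low <= es.g <= es.ci_high
        assert es.n_boot == 1000

    def test_seeded_interval_reproducible(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 12), rng.normal(0.8, 1, 14)
        a = hedges_g(x, y, n_boot=500, seed=42)
        b = hedges_g(x, y, n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = regress_with_ci(x, 2.0 * x)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-9)

    def test_slope_ci_matches_closed_form(self):
        """statsmodels CI equals the textbook t-interval."""
        from scipy import stats as sps

        rng = np.random.default_rng(7)
        x = rng.uniform(0, 10, 25)
        y = 1.5 + 0.8 * x + rng.normal(0, 0.5, 25)
        res = regress_with_ci(x, y)
        n = x.size
        slope_hat = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        resid = y - (np.mean(y) + slope_hat * (x - np.mean(x)))
        s2 = np.sum(resid**2) / (n - 2)
        se = np.sqrt(s2 / (np.var(x, ddof=1) * (n - 1)))
        tcrit = sps.t.ppf(0.975, n - 2)
        assert res.slope == pytest.approx(slope_hat, abs=1e-10)
        assert res.ci_low == pytest.approx(slope_hat - tcrit * se, abs=1e-10)
        assert res.ci_high == pytest.approx(slope_hat + tcrit * se, abs=1e-10)

    def test_age_regression_uses_weeks(self):
        age_days = np.array([35, 42, 49, 56, 63, 70])
        y = age_days / 7.0 * 3.0  # 3 units per week
        res = regress_vs_age(age_days, y)
        assert res.slope == pytest.approx(3.0, abs=1e-9)

    def test_constant_x_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            regress_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def _ancova_table(rng, n=20, offset=0.0, slope=7.7):
    g = np.concatenate([rng.uniform(0.2, 0.7, n), rng.uniform(0.5, 1.0, n)])
    geno = ["WT"] * n + ["mSOD1"] * n
    pic = slope * g + offset * (np.arange(2 * n) >= n) + rng.normal(0, 0.4, 2 * n)
    return pd.DataFrame(
        {"input_conductance": g, "pic_amplitude_asc": pic, "genotype": geno}
    )


class TestAncova:
    def test_pure_conductance_shift_no_genotype_effect(self):
        """When both genotypes lie on one common line, the adjusted
        genotype effect is approximately zero."""
        rng = np.random.default_rng(0)
        rep = ancova_pic_conductance(_ancova_table(rng, n=60, offset=0.0))
        assert rep["model"] == "additive"
        assert rep["genotype_ci_low"] < 0 < rep["genotype_ci_high"]

    def test_known_offset_recovered_with_nominal_coverage(self):
        """The 95% CI on a planted 2 nA genotype offset covers it in at
        least 93% of seeded replicates."""
        hits = 0
        runs = 300
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            rep = ancova_pic_conductance(_ancova_table(rng, n=15, offset=2.0))
            if rep["genotype_ci_low"] <= 2.0 <= rep["genotype_ci_high"]:
                hits += 1
        assert hits / runs >= 0.93

    def test_single_genotype_rejected(self):
        rng = np.random.default_rng(1)
        t = _ancova_table(rng)
        with pytest.raises(ValueError):
            ancova_pic_conductance(t[t["genotype"] == "WT"])


def _full_table(rng, n=40):
    data = {c: rng.normal(size=n) for c in FEATURE_COLUMNS}
    data.update(
        cell_id=[f"c{i}" for i in range(n)],
        animal_id=["m"] * n,
        genotype=["WT"] * n,
        age_days=rng.integers(31, 120, n),
    )
    return pd.DataFrame(data)


class TestPCA:
    def test_rank_one_table_collapses_onto_pc1(self):
        """Cells that differ along a single latent axis (every feature an
        exact affine image of it) put all retained variance and every
        loading on PC1."""
        rng = np.random.default_rng(0)
        n = 12
        latent = rng.normal(size=n)
        df = pd.DataFrame(
            {c: (i + 1) * latent + i for i, c in enumerate(FEATURE_COLUMNS)}
        )
        res = pca_features(df, n_components=2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(res.loadings["PC1"].abs() > 0.999)

    def test_anticorrelated_blocks_separate_on_first_components(self):
        """A current-like block and an independent voltage-like block end
        up dominating different leading components."""
        rng = np.random.default_rng(3)
        n = 60
        f_cur = rng.normal(size=n)
        f_volt = rng.normal(size=n)
        # unequal block sizes keep the two leading eigenvalues apart, so
        # the components do not rotate within a near-degenerate subspace
        current_like = ["input_conductance", "pic_amplitude_asc", "pic_amplitude_desc",
                        "recruitment_current", "derecruitment_current",
                        "current_transition_spr_pr", "delta_i"]
        voltage_like = ["rmp", "vthreshold", "pic_peak_voltage", "pic_onset_voltage"]
        data = {c: rng.normal(0, 1.0, n) for c in FEATURE_COLUMNS}
        for c in current_like:
            data[c] = f_cur + rng.normal(0, 0.15, n)
        for c in voltage_like:
            data[c] = -f_volt + rng.normal(0, 0.15, n)
        df = pd.DataFrame(data)
        res = pca_features(df)
        lead = res.loadings.abs()
        pc_cur = lead.loc[current_like, ["PC1", "PC2"]].mean().idxmax()
        pc_volt = lead.loc[voltage_like, ["PC1", "PC2"]].mean().idxmax()
        assert pc_cur != pc_volt
        # within its component, each block loads strongly and coherently
        assert lead.loc[current_like, pc_cur].min() > 0.8
        assert lead.loc[voltage_like, pc_volt].min() > 0.8

    def test_ratios_sum_to_one_with_all_components(self):
        rng = np.random.default_rng(5)
        res = pca_features(_full_table(rng), n_components=len(FEATURE_COLUMNS))
        assert np.sum(res.explained_variance_ratio) == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.explained_variance_ratio) <= 1e-12)
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_zero_variance_feature_named(self):
        rng = np.random.default_rng(6)
        df = _full_table(rng)
        df["delta_f"] = 0.0
        with pytest.raises(ValueError, match="delta_f"):
            pca_features(df)

    def test_complete_case_policy_counts_dropped(self):
        rng = np.random.default_rng(8)
        df = _full_table(rng)
        df.loc[df.index[:4], "fi_gain_asc"] = np.nan
        res = pca_features(df)
        assert res.n_dropped == 4
        assert len(res.scores) == len(df) - 4
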