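"""Group statistics: t-tests, ANCOVA, partial correlation, BH-FDR."""

import numpy as np
import pandas as pd
import pytest

from fpannet.errors import DegenerateInputError
from fpannet.stats import (
    ancova_diagnosis,
    bh_fdr,
    cohort_characteristics,
    metric_correlation_table,
    metric_group_table,
    nodal_comparison,
    partial_corr,
    two_sample_t,
    two_sample_t_from_summaries,
)

# Published cohort summaries used as worked examples (mean, sd, n per group).
VIQ_SUMMARY = dict(mean_a=112.594, sd_a=14.199, n_a=69, mean_b=107.076, sd_b=13.890, n_b=119)
PIQ_SUMMARY = dict(mean_a=107.522, sd_a=15.560, n_a=69, mean_b=103.941, sd_b=14.840, n_b=119)


class TestTwoSampleT:
    def test_verbal_iq_worked_example(self):
        res = two_sample_t_from_summaries(**VIQ_SUMMARY)
        assert res.statistic == pytest.approx(2.604, abs=5e-3)
        assert res.df == (186,)
        assert res.p_raw == pytest.approx(0.010, abs=2e-3)

    def test_performance_iq_worked_example(self):
        res = two_sample_t_from_summaries(**PIQ_SUMMARY)
        assert res.statistic == pytest.approx(1.566, abs=5e-3)

    def test_raw_vectors_match_their_own_summaries(self):
        rng = np.random.default_rng(0)
        a = rng.normal(5, 2, 40)
        b = rng.normal(4, 2, 55)
        raw = two_sample_t(a, b)
        summ = two_sample_t_from_summaries(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert raw.statistic == pytest.approx(summ.statistic, abs=1e-12)
        assert raw.p_raw == pytest.approx(summ.p_raw, abs=1e-12)

    def test_matches_scipy_ttest_ind(self):
        from scipy import stats as sps

        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1.5, 45)
        res = two_sample_t(a, b)
        expected = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(expected.statistic)
        assert res.p_raw == pytest.approx(expected.pvalue)
        welch = two_sample_t(a, b, flavor="welch")
        expected_w = sps.ttest_ind(a, b, equal_var=False)
        assert welch.statistic == pytest.approx(expected_w.statistic)
        assert welch.p_raw == pytest.approx(expected_w.pvalue)

    def test_identical_groups_give_zero(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert two_sample_t(a, a).statistic == 0.0

    def test_zero_variance_both_groups_rejected(self):
        with pytest.raises(DegenerateInputError):
            two_sample_t([1.0, 1.0, 1.0], [1.0, 1.0])


def _toy_cohort(n_tdc=30, n_adhd=40, seed=0):
    rng = np.random.default_rng(seed)
    n = n_tdc + n_adhd
    return pd.DataFrame(
        {
            "subject_id": [f"s{i:03d}" for i in range(n)],
            "group": ["TDC"] * n_tdc + ["ADHD"] * n_adhd,
            "gender": rng.integers(0, 2, n),
            "viq": rng.normal(105, 12, n),
            "adhd_index": rng.normal(50, 10, n),
        }
    )


class TestAncova:
    def test_f_statistic_degrees_of_freedom(self):
        cohort = _toy_cohort(69, 119)
        y = np.random.default_rng(2).normal(size=len(cohort))
        res = ancova_diagnosis(y, cohort)
        assert res.df == (1, 184)  # n - 2 covariates - intercept - diagnosis

    def test_orthogonal_covariates_reduce_to_anova(self):
        # Covariates constructed orthogonal to both the group indicator and
        # the metric leave the diagnosis coefficient and residual sum of
        # squares unchanged; the F statistic then equals the pooled t^2 up
        # to the df ratio (n-4)/(n-2) from the extra fitted terms.
        rng = np.random.default_rng(3)
        cohort = _toy_cohort(40, 40, seed=3)
        n = len(cohort)
        y = rng.normal(size=n)
        d = (cohort["group"] == "ADHD").to_numpy(float)
        base = np.column_stack([np.ones(n), d, y])
        Z = rng.normal(size=(n, 2))
        Z -= base @ np.linalg.lstsq(base, Z, rcond=None)[0]
        cohort = cohort.assign(gender=Z[:, 0], viq=Z[:, 1])
        res = ancova_diagnosis(y, cohort)
        t = two_sample_t(y[d == 1], y[d == 0])
        assert res.statistic == pytest.approx(
            t.statistic**2 * (n - 4) / (n - 2), rel=1e-9
        )

    def test_matches_pingouin_ancova(self):
        pg = pytest.importorskip("pingouin")
        cohort = _toy_cohort(25, 35, seed=4)
        y = np.random.default_rng(4).normal(size=len(cohort))
        res = ancova_diagnosis(y, cohort)
        df = cohort.assign(y=y)
        expected = pg.ancova(data=df, dv="y", between="group", covar=["gender", "viq"])
        row = expected.loc[expected["Source"] == "group"].iloc[0]
        assert res.statistic == pytest.approx(row["F"], rel=1e-8)
        assert res.p_raw == pytest.approx(row["p_unc"], rel=1e-8)

    def test_collinear_covariates_rejected(self):
        cohort = _toy_cohort(10, 10, seed=5)
        cohort["viq"] = cohort["gender"] * 2.0
        with pytest.raises(ValueError, match="collinear|rank"):
            ancova_diagnosis(np.zeros(len(cohort)), cohort)

    def test_affine_covariate_rescaling_leaves_f_unchanged(self):
        cohort = _toy_cohort(20, 25, seed=6)
        y = np.random.default_rng(6).normal(size=len(cohort))
        f0 = ancova_diagnosis(y, cohort).statistic
        cohort2 = cohort.assign(viq=cohort["viq"] * 3.7 - 100, gender=cohort["gender"] * 2 + 1)
        assert ancova_diagnosis(y, cohort2).statistic == pytest.approx(f0, rel=1e-9)


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=50)
        y = 0.5 * x + rng.normal(size=50)
        res = partial_corr(x, y)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1])
        assert res.df == 48

    def test_identical_vectors_give_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        z = rng.normal(size=30)
        res = partial_corr(x, x.copy(), covariates=z)
        assert res.r == pytest.approx(1.0)

    def test_matches_inverse_correlation_closed_form(self):
        # First-order partial: r_xy.z = -P_xy / sqrt(P_xx P_yy) where P is
        # the inverse of the 3x3 correlation matrix of (x, y, z).
        rng = np.random.default_rng(9)
        for _ in range(20):
            z = rng.normal(size=60)
            x = 0.4 * z + rng.normal(size=60)
            y = -0.3 * z + 0.2 * x + rng.normal(size=60)
            P = np.linalg.inv(np.corrcoef(np.column_stack([x, y, z]), rowvar=False))
            expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
            got = partial_corr(x, y, covariates=z)
            assert got.r == pytest.approx(expected, abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(80, 4)), columns=["x", "y", "z1", "z2"])
        df["y"] += 0.5 * df["x"]
        res = partial_corr(df["x"], df["y"], covariates=df[["z1", "z2"]].to_numpy())
        expected = pg.partial_corr(data=df, x="x", y="y", covar=["z1", "z2"])
        assert res.r == pytest.approx(float(expected["r"].iloc[0]), abs=1e-10)
        assert res.p_raw == pytest.approx(float(expected["p_val"].iloc[0]), abs=1e-8)

    def test_constant_residuals_rejected(self):
        z = np.arange(20.0)
        with pytest.raises(DegenerateInputError):
            partial_corr(2 * z + 1, z, covariates=z)


class TestBhFdr:
    def test_single_p_unchanged(self):
        adj, rej = bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_computed_example(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_adjusted_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        adj, _ = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert (adj >= p - 1e-15).all()

    def test_q_of_one_rejects_everything(self):
        _, rej = bh_fdr([0.2, 0.9, 1.0], q=1.0)
        assert rej.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestTables:
    def test_cohort_characteristics_sign_convention(self):
        from fpannet.synth import SyntheticCohortSpec, simulate_cohort

        _, cohort, _ = simulate_cohort(
            SyntheticCohortSpec(n_tdc=60, n_adhd=90, n_timepoints=20, seed=12)
        )
        table = cohort_characteristics(cohort).set_index("variable")
        assert table.loc["viq", "t"] > 0  # controls higher verbal IQ
        assert table.loc["gender", "t"] < 0  # patients more often male
        assert table.loc["adhd_index", "t"] < 0

    def test_group_and_correlation_tables_shapes(self):
        cohort = _toy_cohort(20, 25, seed=13)
        rng = np.random.default_rng(13)
        metrics = pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "m1": rng.normal(size=len(cohort)),
                "m2": rng.normal(size=len(cohort)),
            }
        )
        g = metric_group_table(metrics, cohort)
        c = metric_correlation_table(metrics, cohort)
        assert list(g["metric"]) == ["m1", "m2"]
        assert {"F", "p_raw", "p_fdr"} <= set(g.columns)
        assert list(c["metric"]) == ["m1", "m2"]
        assert c["r"].abs().le(1).all()

    def test_nodal_comparison_recovers_planted_regions(self):
        rng = np.random.default_rng(14)
        cohort = _toy_cohort(40, 40, seed=14)
        rois = [f"roi{i:02d}" for i in range(16)]
        rows = []
        shifted = {"roi03", "roi07", "roi11"}
        for _, subj in cohort.iterrows():
            for roi in rois:
                val = rng.normal()
                if roi in shifted and subj["group"] == "ADHD":
                    val += 1.5
                rows.append({"subject_id": subj["subject_id"], "roi": roi, "ecc": val})
        table = nodal_comparison(pd.DataFrame(rows), cohort)
        assert len(table) == 16
        top3 = set(table.nsmallest(3, "p_fdr")["roi"])
        assert top3 == shifted
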