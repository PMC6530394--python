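"""Group statistics: t-tests, ANCOVA, partial correlation, FDR control.

The statistical layer mirrors a standard case-control network study:
two-sample t-tests for cohort characteristics, ANCOVA testing the diagnosis
effect on each network metric with gender and verbal IQ as covariates,
partial correlation of each metric with the symptom score controlling the
same covariates, and Benjamini-Hochberg false-discovery-rate control within
each family of tests (q < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .errors import DegenerateInputError

__all__ = [
    "GroupTestResult",
    "PartialCorrResult",
    "two_sample_t",
    "two_sample_t_from_summaries",
    "ancova_diagnosis",
    "partial_corr",
    "bh_fdr",
    "nodal_comparison",
    "metric_group_table",
    "metric_correlation_table",
    "cohort_characteristics",
]


@dataclass
class GroupTestResult:
    """One row of a group-difference table (t-test or ANCOVA F-test)."""

    metric_name: str
    statistic: float
    df: tuple
    p_raw: float
    p_fdr: float | None = None
    group_means_sds: dict | None = None
    kind: str = "t"


@dataclass
class PartialCorrResult:
    """One row of a metric-symptom partial-correlation table."""

    metric_name: str
    r: float
    df: int
    p_raw: float
    p_fdr: float | None = None


def two_sample_t_from_summaries(
    mean_a, sd_a, n_a, mean_b, sd_b, n_b, metric_name: str = "", flavor: str = "pooled"
) -> GroupTestResult:
    """Two-sample t-test from printed summary statistics.

    ``flavor='pooled'`` is the Student test with pooled variance;
    ``flavor='welch'`` uses the Welch-Satterthwaite approximation.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("both groups need n >= 2")
    if sd_a == 0 and sd_b == 0:
        raise DegenerateInputError("zero variance in both groups")
    va, vb = sd_a**2, sd_b**2
    if flavor == "pooled":
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    elif flavor == "welch":
        se2 = va / n_a + vb / n_b
        t = (mean_a - mean_b) / np.sqrt(se2)
        df = se2**2 / ((va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1))
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    p = 2.0 * sps.t.sf(abs(t), df)
    return GroupTestResult(
        metric_name=metric_name,
        statistic=float(t),
        df=(float(df),),
        p_raw=float(p),
        group_means_sds={
            "a": (float(mean_a), float(sd_a), int(n_a)),
            "b": (float(mean_b), float(sd_b), int(n_b)),
        },
        kind="t",
    )


def two_sample_t(
    values_a, values_b, metric_name: str = "", flavor: str = "pooled"
) -> GroupTestResult:
    """Two-sample t-test from raw per-subject vectors."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    return two_sample_t_from_summaries(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size,
        metric_name=metric_name, flavor=flavor,
    )


def _design_matrix(cohort: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(cohort))]
    for cov in covariates:
        if cohort[cov].isna().any():
            raise ValueError(f"covariate {cov!r} has missing values")
        cols.append(cohort[cov].to_numpy(dtype=float))
    return np.column_stack(cols)


def ancova_diagnosis(
    metric, cohort: pd.DataFrame, covariates=("gender", "viq"), metric_name: str = ""
) -> GroupTestResult:
    """ANCOVA F-test for the diagnosis effect, adjusting for covariates.

    Fits the linear model ``metric ~ 1 + diagnosis + covariates`` by OLS
    and reports the F statistic for the diagnosis term with
    ``df = (1, n - 2 - n_covariates)``; diagnosis is coded TDC = 0,
    ADHD = 1.
    """
    y = np.asarray(metric, dtype=float)
    if len(y) != len(cohort):
        raise ValueError("metric vector must align with the cohort table")
    groups = cohort["group"].unique()
    if set(groups) - {"TDC", "ADHD"}:
        raise ValueError(f"unexpected group labels {sorted(groups)}")
    diag = (cohort["group"] == "ADHD").to_numpy(dtype=float)
    X = np.column_stack([_design_matrix(cohort, covariates), diag])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design: collinear covariates")
    model = sm.OLS(y, X).fit()
    t_diag = model.tvalues[-1]
    f = float(t_diag**2)
    df = (1, int(model.df_resid))
    p = float(sps.f.sf(f, *df))
    means = {
        g: (
            float(y[cohort["group"].to_numpy() == g].mean()),
            float(y[cohort["group"].to_numpy() == g].std(ddof=1)),
            int((cohort["group"] == g).sum()),
        )
        for g in ("TDC", "ADHD")
    }
    return GroupTestResult(
        metric_name=metric_name,
        statistic=f,
        df=df,
        p_raw=p,
        group_means_sds=means,
        kind="F",
    )


def partial_corr(x, y, covariates=None, metric_name: str = "") -> PartialCorrResult:
    """Partial correlation of x and y controlling for covariates.

    Both variables are residualized on the covariates (with intercept) by
    OLS and the Pearson correlation of the residuals is reported; with no
    covariates this reduces to the plain Pearson correlation.  The p-value
    is two-sided from ``t = r sqrt(df / (1 - r^2))`` with
    ``df = n - 2 - n_covariates``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must align")
    n = x.size
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        Z = np.ones((n, 1))
        k = 0
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        k = Z.shape[1]
        Z = np.column_stack([np.ones(n), Z])
    if n <= k + 2:
        raise ValueError(f"need n > k + 2 observations, got n={n}, k={k}")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    # residuals that vanish up to numerical noise mean x or y is an exact
    # linear function of the covariates
    if rx.std() <= 1e-12 * max(1.0, x.std()) or ry.std() <= 1e-12 * max(1.0, y.std()):
        raise DegenerateInputError("constant residuals; partial correlation undefined")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df / (1 - r_clip**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return PartialCorrResult(metric_name=metric_name, r=r, df=df, p_raw=p)


def bh_fdr(p_values, q: float = 0.05):
    """Benjamini-Hochberg step-up: adjusted p-values and rejection flags at q."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, p_adj <= q


def metric_group_table(
    metrics: pd.DataFrame, cohort: pd.DataFrame, covariates=("gender", "viq"),
    q: float = 0.05,
) -> pd.DataFrame:
    """ANCOVA per metric column with BH-FDR across the table's family.

    ``metrics`` has one row per subject (aligned with ``cohort`` on
    subject_id) and one column per network metric.
    """
    merged = cohort.merge(metrics, on="subject_id", validate="one_to_one")
    metric_cols = [c for c in metrics.columns if c != "subject_id"]
    rows = []
    for col in metric_cols:
        res = ancova_diagnosis(
            merged[col], merged, covariates=covariates, metric_name=col
        )
        rows.append(
            {
                "metric": col,
                "tdc_mean": res.group_means_sds["TDC"][0],
                "tdc_sd": res.group_means_sds["TDC"][1],
                "adhd_mean": res.group_means_sds["ADHD"][0],
                "adhd_sd": res.group_means_sds["ADHD"][1],
                "F": res.statistic,
                "df1": res.df[0],
                "df2": res.df[1],
                "p_raw": res.p_raw,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"], table["significant"] = bh_fdr(table["p_raw"], q=q)
    return table


def metric_correlation_table(
    metrics: pd.DataFrame, cohort: pd.DataFrame, score_col: str = "adhd_index",
    covariates=("gender", "viq"), q: float = 0.05,
) -> pd.DataFrame:
    """Partial correlation of each metric with the symptom score, with BH-FDR."""
    merged = cohort.merge(metrics, on="subject_id", validate="one_to_one")
    Z = np.column_stack([merged[c].to_numpy(dtype=float) for c in covariates]) if covariates else None
    metric_cols = [c for c in metrics.columns if c != "subject_id"]
    rows = []
    for col in metric_cols:
        res = partial_corr(
            merged[col], merged[score_col], covariates=Z, metric_name=col
        )
        rows.append({"metric": col, "r": res.r, "df": res.df, "p_raw": res.p_raw})
    table = pd.DataFrame(rows)
    table["p_fdr"], table["significant"] = bh_fdr(table["p_raw"], q=q)
    return table


def nodal_comparison(
    nodal: pd.DataFrame, cohort: pd.DataFrame, value_col: str = "ecc",
    covariates=("gender", "viq"), q: float = 0.05,
) -> pd.DataFrame:
    """Per-region ANCOVA of a nodal metric with BH-FDR across regions.

    ``nodal`` is long-format with one row per subject x region
    (columns subject_id, roi, ``value_col``).
    """
    wide = nodal.pivot(index="subject_id", columns="roi", values=value_col).reset_index()
    merged = cohort.merge(wide, on="subject_id", validate="one_to_one")
    rois = [c for c in wide.columns if c != "subject_id"]
    rows = []
    for roi in rois:
        res = ancova_diagnosis(merged[roi], merged, covariates=covariates, metric_name=roi)
        rows.append(
            {
                "roi": roi,
                "tdc_mean": res.group_means_sds["TDC"][0],
                "tdc_sd": res.group_means_sds["TDC"][1],
                "adhd_mean": res.group_means_sds["ADHD"][0],
                "adhd_sd": res.group_means_sds["ADHD"][1],
                "F": res.statistic,
                "df1": res.df[0],
                "df2": res.df[1],
                "p_raw": res.p_raw,
            }
        )
    table = pd.DataFrame(rows)
    table["p_fdr"], table["significant"] = bh_fdr(table["p_raw"], q=q)
    return table


def cohort_characteristics(
    cohort: pd.DataFrame,
    variables=("age", "handedness", "gender", "viq", "piq", "adhd_index"),
    flavor: str = "pooled",
) -> pd.DataFrame:
    """Group-characteristic table: per-variable group mean/SD and t-test."""
    tdc = cohort[cohort["group"] == "TDC"]
    adhd = cohort[cohort["group"] == "ADHD"]
    rows = []
    for var in variables:
        # TDC minus ADHD sign convention: positive t = higher in controls.
        res = two_sample_t(tdc[var], adhd[var], metric_name=var, flavor=flavor)
        rows.append(
            {
                "variable": var,
                "tdc_mean": tdc[var].mean(),
                "tdc_sd": tdc[var].std(ddof=1),
                "adhd_mean": adhd[var].mean(),
                "adhd_sd": adhd[var].std(ddof=1),
                "t": res.statistic,
                "df": res.df[0],
                "p": res.p_raw,
            }
        )
    return pd.DataFrame(rows)
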