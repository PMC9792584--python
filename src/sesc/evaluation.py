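"""Method-agreement statistics for CoM estimators.

Per-axis RMSE against the force-platform reference, group summaries
(mean, sample SD, coefficient of variation), Pearson/Spearman correlation,
Bland–Altman agreement (fixed bias, 95% limits of agreement, bias CI,
proportional-bias regression of difference on pairwise mean), and
normality-gated two-sample comparisons.

All differences are oriented estimate − reference, so a method that
undershoots the platform reading reports a negative fixed bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RmseResult",
    "GroupSummary",
    "AgreementResult",
    "GroupComparison",
    "rmse_per_axis",
    "group_summary",
    "correlation",
    "bland_altman",
    "proportional_bias_regression",
    "compare_groups",
    "load_reference_rmse",
    "bland_altman_plot",
]


@dataclass(frozen=True)
class RmseResult:
    rmse_ap: float  # mm
    rmse_ml: float  # mm
    n: int


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float  # sample SD, n-1 denominator
    cv: float  # percent, 100*sd/mean
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """Bland–Altman agreement of one estimator against the reference (mm)."""

    fixed_bias: float
    loa_low: float
    loa_high: float
    bias_ci: tuple[float, float]
    slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    p_slope: float | None = None
    n: int = 0


@dataclass(frozen=True)
class GroupComparison:
    shapiro_p_a: float
    shapiro_p_b: float
    parametric: bool
    test_name: str
    statistic: float
    p_value: float
    degenerate: bool = False


def _as_pairs(estimates, references):
    e = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if e.shape != r.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {r.shape}")
    return e, r


def rmse_per_axis(estimates, references) -> RmseResult:
    """Root-mean-square error per horizontal axis; inputs are (n, 2) in mm."""
    e, r = _as_pairs(np.atleast_2d(estimates), np.atleast_2d(references))
    if e.shape[1] != 2:
        raise ValueError("expected (n, 2) arrays of (AP, ML) values")
    rmse = np.sqrt(np.mean((e - r) ** 2, axis=0))
    return RmseResult(float(rmse[0]), float(rmse[1]), e.shape[0])


def group_summary(values) -> GroupSummary:
    """Mean, sample SD (n−1), CV%, min, max of a list of per-subject values."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("group summary needs at least 2 values for a sample SD")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else np.inf
    return GroupSummary(mean, sd, float(cv), float(v.min()), float(v.max()), v.size)


def correlation(estimates, references, method: str = "pearson"):
    """Pearson's r or Spearman's rho with its p-value."""
    e, r = _as_pairs(estimates, references)
    if e.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(e) == 0 or np.std(r) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(e, r)
    elif method == "spearman":
        res = stats.spearmanr(e, r)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(res.statistic), float(res.pvalue)


def bland_altman(estimates, references, t_based_ci: bool = False) -> AgreementResult:
    """Fixed bias and 95% limits of agreement, bias ± 1.96·SD(differences).

    The 95% CI of the bias uses the normal approximation ±1.96·SD/√n by
    default; ``t_based_ci`` switches to the t quantile.
    """
    e, r = _as_pairs(estimates, references)
    if e.size < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = e - r
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    half = 1.96 * sd
    q = stats.t.ppf(0.975, e.size - 1) if t_based_ci else 1.96
    sem = sd / np.sqrt(e.size)
    return AgreementResult(
        fixed_bias=bias,
        loa_low=bias - half,
        loa_high=bias + half,
        bias_ci=(bias - q * sem, bias + q * sem),
        n=e.size,
    )


def proportional_bias_regression(
    estimates, references, subject_id=None, mode: str = "cluster"
) -> AgreementResult:
    """Regress difference on pairwise mean to detect a proportional bias.

    With repeated measures per subject the default uses OLS with
    cluster-robust standard errors by subject; ``mode`` may also be "ols"
    (plain) or "subject_mean" (collapse to one point per subject first).
    """
    e, r = _as_pairs(estimates, references)
    if e.size < 3:
        raise ValueError("regression needs at least 3 pairs")
    diff = e - r
    mean = (e + r) / 2.0
    if mode == "subject_mean":
        if subject_id is None:
            raise ValueError("subject_mean mode requires subject ids")
        df = pd.DataFrame({"d": diff, "m": mean, "s": np.asarray(subject_id)})
        agg = df.groupby("s").mean()
        diff, mean = agg["d"].to_numpy(), agg["m"].to_numpy()
        subject_id = None
    if np.std(mean) == 0:
        raise ValueError("slope undefined: all pairwise means are equal")
    X = sm.add_constant(mean)
    model = sm.OLS(diff, X)
    if mode == "cluster" and subject_id is not None:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": np.asarray(subject_id)})
    else:
        fit = model.fit()
    ba = bland_altman(e, r) if e.size >= 3 else None
    return AgreementResult(
        fixed_bias=ba.fixed_bias,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        bias_ci=ba.bias_ci,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_slope=float(fit.pvalues[1]),
        n=e.size,
    )


def compare_groups(a, b, paired: bool = False, alpha: float = 0.05) -> GroupComparison:
    """Two-sample location comparison with a Shapiro–Wilk normality gate.

    Both groups normal at ``alpha`` → Student's t (paired t when paired);
    otherwise Mann–Whitney U (Wilcoxon signed-rank when paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs at least 3 values")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length groups")
    if paired and np.allclose(a, b):
        return GroupComparison(1.0, 1.0, False, "wilcoxon", 0.0, 1.0, degenerate=True)

    def _shapiro_p(x):
        if np.ptp(x) == 0:
            return 0.0  # constant sample: not normal
        return float(stats.shapiro(x).pvalue)

    pa, pb = _shapiro_p(a), _shapiro_p(b)
    parametric = pa > alpha and pb > alpha
    if parametric:
        if paired:
            res = stats.ttest_rel(a, b)
            name = "paired t-test"
        else:
            res = stats.ttest_ind(a, b)
            name = "t-test"
    else:
        if paired:
            res = stats.wilcoxon(a, b)
            name = "wilcoxon"
        else:
            res = stats.mannwhitneyu(a, b)
            name = "mann-whitney"
    return GroupComparison(pa, pb, parametric, name, float(res.statistic),
                           float(res.pvalue))


def load_reference_rmse() -> pd.DataFrame:
    """Bundled per-subject published RMSE values (mm) for both cohorts.

    Columns: subject, group (fit/obese), sesc_ap_mm, sesc_ml_mm,
    segmental_ap_mm, segmental_ml_mm.
    """
    with resources.files("sesc.data").joinpath("tables_1_2_rmse.csv").open() as fh:
        return pd.read_csv(fh)


def bland_altman_plot(estimates, references, ax=None, title: str | None = None):
    """Standard Bland–Altman scatter with bias and LoA lines (matplotlib)."""
    import matplotlib.pyplot as plt

    e, r = _as_pairs(estimates, references)
    res = bland_altman(e, r)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((e + r) / 2.0, e - r, s=12, alpha=0.6)
    for y, style in ((res.fixed_bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of estimate and reference (mm)")
    ax.set_ylabel("estimate − reference (mm)")
    if title:
        ax.set_title(title)
    return ax
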