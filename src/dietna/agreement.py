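"""Method-comparison battery against the 24-h urine collection.

For each estimation method paired with the reference 24-h urinary sodium,
the battery computes: the bias (reference minus estimate) with a paired
t-test or Wilcoxon signed-rank test routed by a Lilliefors-corrected
Kolmogorov-Smirnov normality check; Pearson and Spearman correlations; the
two-way single-measure intraclass correlation (absolute-agreement or
consistency form) with an F-based 95% confidence interval and the
poor/moderate/good/excellent reliability banding; Bland-Altman limits of
agreement (mean difference +/- 1.96 x sd of differences); and the
proportional-bias regression of difference on mean. A sensitivity variant
re-runs everything on complete collections only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

#: Literal multiplier of the limits of agreement.
LOA_Z = 1.96

NORMALITY_ALPHA = 0.05

#: Wilcoxon p-values are exact up to this n (no ties/zeros), otherwise a
#: continuity-corrected normal approximation is used.
WILCOXON_EXACT_MAX_N = 25

ICC_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


@dataclass(frozen=True)
class PairedSeries:
    """Pairwise-complete reference/estimate series for one method."""

    reference: np.ndarray  # mg/day, 24-h urinary Na
    estimate: np.ndarray  # mg/day
    participant_ids: np.ndarray

    def __post_init__(self):
        ref = np.asarray(self.reference, dtype=float)
        est = np.asarray(self.estimate, dtype=float)
        ids = np.asarray(self.participant_ids)
        if not (len(ref) == len(est) == len(ids)):
            raise ValueError("reference, estimate and participant_ids must align")
        if len(ref) < 3:
            raise ValueError("paired comparison requires n >= 3")
        if np.isnan(ref).any() or np.isnan(est).any():
            raise ValueError("paired series must be pairwise complete (no NaN)")
        object.__setattr__(self, "reference", ref)
        object.__setattr__(self, "estimate", est)
        object.__setattr__(self, "participant_ids", ids)

    @property
    def n(self) -> int:
        return len(self.reference)

    @property
    def differences(self) -> np.ndarray:
        return self.reference - self.estimate


@dataclass
class MethodComparison:
    """One row of the comparison table (full precision)."""

    method_id: str
    n: int
    mean_estimate: float
    sd_estimate: float
    bias_mean: float
    bias_sd: float
    p_paired: float
    paired_test: str  # "t" | "wilcoxon"
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    icc: float
    icc_ci_low: float
    icc_ci_high: float
    icc_class: str
    icc_form: str
    loa_lower: float
    loa_upper: float
    prop_bias_slope: float
    prop_bias_p: float

    def as_dict(self) -> dict:
        return asdict(self)


def ks_normality(x) -> float:
    """Lilliefors-corrected KS p-value for normality (estimated mean/sd).

    Used only to route parametric vs non-parametric choices. n < 4 or a
    degenerate (constant) sample routes non-parametric: p = 0 with warning.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        warnings.warn("normality test needs n >= 4; routing non-parametric", stacklevel=2)
        return 0.0
    if np.ptp(x) == 0:
        return 0.0
    _, p = lilliefors(x, dist="norm")
    return float(p)


def bias_stats(s: PairedSeries) -> tuple[float, float, float, str]:
    """Mean bias, sample sd of differences and a paired-test p-value.

    The paired t-test is used when the differences pass the normality
    check, the Wilcoxon signed-rank test otherwise (exact p for small n
    without ties, normal approximation with continuity correction above).
    """
    d = s.differences
    bias_mean = float(np.mean(d))
    bias_sd = float(np.std(d, ddof=1))
    if np.ptp(d) == 0:
        if d[0] == 0:
            # identical series: nothing to test
            return bias_mean, bias_sd, 1.0, "wilcoxon"
        _, p = stats.wilcoxon(d, method="approx", correction=True)
        return bias_mean, bias_sd, float(p), "wilcoxon"
    if ks_normality(d) >= NORMALITY_ALPHA:
        _, p = stats.ttest_rel(s.reference, s.estimate)
        return bias_mean, bias_sd, float(p), "t"
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        return bias_mean, bias_sd, 1.0, "wilcoxon"
    exact = len(nonzero) <= WILCOXON_EXACT_MAX_N and len(np.unique(np.abs(nonzero))) == len(nonzero)
    _, p = stats.wilcoxon(
        nonzero, method="exact" if exact else "approx", correction=not exact
    )
    return bias_mean, bias_sd, float(p), "wilcoxon"


def correlations(s: PairedSeries) -> tuple[float, float, float, float]:
    """Pearson r and Spearman rho (average-rank ties) with p-values.

    Zero variance in either series yields NaN coefficients with a warning
    rather than a silent 0.
    """
    if np.ptp(s.reference) == 0 or np.ptp(s.estimate) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=2)
        return np.nan, np.nan, np.nan, np.nan
    pr = stats.pearsonr(s.reference, s.estimate)
    sp = stats.spearmanr(s.reference, s.estimate)
    return float(pr.statistic), float(pr.pvalue), float(sp.statistic), float(sp.pvalue)


def _icc_mean_squares(s: PairedSeries) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n x 2 (subject x method) table."""
    data = np.column_stack([s.reference, s.estimate])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(s: PairedSeries, form: str = "absolute_agreement", alpha: float = 0.05):
    """Two-way single-measure intraclass correlation with 95% CI.

    ``absolute_agreement`` is ICC(A,1) of the two-way random-effects model;
    ``consistency`` is ICC(C,1). Confidence limits follow the F-based
    formulas of McGraw & Wong. Degenerate data (all values identical)
    return icc = 1 with NaN limits.
    """
    if form not in ("absolute_agreement", "consistency"):
        raise ValueError(f"unknown ICC form {form!r}")
    if s.n < 5:
        warnings.warn("ICC confidence interval is unstable for n < 5", stacklevel=2)
    msr, msc, mse, n, k = _icc_mean_squares(s)
    if msr == 0 and msc == 0 and mse == 0:
        return 1.0, np.nan, np.nan
    if form == "consistency":
        denom = msr + (k - 1) * mse
        value = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0:
            return float(value), np.nan, np.nan
        f_obs = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + k - 1)
        upper = (fu - 1) / (fu + k - 1)
        return float(value), float(lower), float(upper)

    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    value = (msr - mse) / denom if denom != 0 else 1.0
    if mse == 0 and msc == 0:
        return float(value), np.nan, np.nan
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if not np.isfinite(a) or not np.isfinite(b):
        return float(value), np.nan, np.nan
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_star2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star2 * msr
    )
    return float(value), float(lower), float(upper)


def classify_icc(value: float) -> str:
    """Koo-Li reliability band: <0.5 poor, 0.5-0.75 moderate, 0.75-0.9
    good, >=0.9 excellent."""
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    for threshold, label in ICC_BANDS:
        if value < threshold:
            return label
    return "excellent"


def bland_altman(s: PairedSeries):
    """Bland-Altman quantities for one method.

    Returns (per-pair DataFrame with mean and difference, loa_lower,
    loa_upper, prop_bias_slope, prop_bias_p). The limits of agreement are
    mean difference +/- 1.96 x sd of differences; the proportional-bias
    slope is the OLS slope of difference on mean.
    """
    d = s.differences
    m = (s.reference + s.estimate) / 2.0
    bias_mean = float(np.mean(d))
    bias_sd = float(np.std(d, ddof=1))
    loa_lower = bias_mean - LOA_Z * bias_sd
    loa_upper = bias_mean + LOA_Z * bias_sd
    if np.ptp(m) == 0:
        slope, p = np.nan, np.nan
    else:
        res = stats.linregress(m, d)
        slope, p = float(res.slope), float(res.pvalue)
    pairs = pd.DataFrame(
        {"participant_id": s.participant_ids, "mean": m, "difference": d}
    )
    return pairs, float(loa_lower), float(loa_upper), slope, p


def loa_from_bias(bias_mean: float, bias_sd: float) -> tuple[float, float]:
    """Limits of agreement from published bias statistics."""
    return bias_mean - LOA_Z * bias_sd, bias_mean + LOA_Z * bias_sd


def compare_method(s: PairedSeries, method_id: str, icc_form: str = "absolute_agreement") -> MethodComparison:
    """Run the full battery on one paired series."""
    bias_mean, bias_sd, p_paired, test = bias_stats(s)
    pr, pr_p, rho, rho_p = correlations(s)
    icc_value, ci_lo, ci_hi = icc(s, form=icc_form)
    _, loa_lo, loa_hi, slope, slope_p = bland_altman(s)
    return MethodComparison(
        method_id=method_id,
        n=s.n,
        mean_estimate=float(np.mean(s.estimate)),
        sd_estimate=float(np.std(s.estimate, ddof=1)),
        bias_mean=bias_mean,
        bias_sd=bias_sd,
        p_paired=p_paired,
        paired_test=test,
        pearson_r=pr,
        pearson_p=pr_p,
        spearman_rho=rho,
        spearman_p=rho_p,
        icc=icc_value,
        icc_ci_low=ci_lo,
        icc_ci_high=ci_hi,
        icc_class=classify_icc(icc_value),
        icc_form=icc_form,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        prop_bias_slope=slope,
        prop_bias_p=slope_p,
    )


def paired_series(
    estimates: pd.DataFrame, method_id: str, reference_id: str = "u24"
) -> PairedSeries:
    """Build the pairwise-complete series of one method vs the reference."""
    wide = estimates.pivot_table(
        index="participant_id", columns="method_id", values="na_mg_per_day", observed=True
    )
    if reference_id not in wide.columns:
        raise ValueError(f"reference method {reference_id!r} absent from estimates")
    if method_id not in wide.columns:
        raise ValueError(f"method {method_id!r} absent from estimates")
    sub = wide[[reference_id, method_id]].dropna()
    return PairedSeries(
        reference=sub[reference_id].to_numpy(),
        estimate=sub[method_id].to_numpy(),
        participant_ids=sub.index.to_numpy(),
    )


def compare_all(
    estimates: pd.DataFrame,
    completeness: pd.Series | dict | None = None,
    sensitivity: bool = False,
    reference_id: str = "u24",
    icc_form: str = "absolute_agreement",
) -> list[MethodComparison]:
    """One MethodComparison per non-reference method.

    ``completeness`` maps participant_id to a complete-collection flag;
    with ``sensitivity=True`` incomplete-collection participants are
    dropped before any statistic is computed.
    """
    df = estimates
    if sensitivity:
        if completeness is None:
            raise ValueError("sensitivity analysis requires completeness flags")
        flags = pd.Series(completeness)
        keep = set(flags.index[flags.astype(bool)])
        df = df[df["participant_id"].isin(keep)]
    if reference_id not in set(df["method_id"].astype(str)):
        raise ValueError(f"reference method {reference_id!r} absent from estimates")
    results = []
    methods = [m for m in df["method_id"].astype(str).unique() if m != reference_id]
    # deterministic order: canonical method order first, then alphabetical
    from .score import METHOD_IDS

    rank = {m: i for i, m in enumerate(METHOD_IDS)}
    methods.sort(key=lambda m: (rank.get(m, len(rank)), m))
    for method in methods:
        s = paired_series(df, method, reference_id)
        results.append(compare_method(s, method, icc_form=icc_form))
    return results


def comparison_table(results: list[MethodComparison]) -> pd.DataFrame:
    """Full-precision comparison table, one row per method."""
    return pd.DataFrame([r.as_dict() for r in results])
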