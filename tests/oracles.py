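"""Independent brute-force oracles for the statistics and equations.

Everything here is written from first principles (sums, loops, textbook
formulas) and stays independent of the implementation paths it checks.
"""

from __future__ import annotations

import math

from scipy import stats as _st  # only for t/F tail probabilities


# ---------------------------------------------------------------------------
# basic statistics, from sums


def mean(x):
    return sum(x) / len(x)


def sample_sd(x):
    m = mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def paired_t_oracle(ref, est):
    """Paired t statistic and two-sided p, textbook formula."""
    d = [r - e for r, e in zip(ref, est)]
    n = len(d)
    t = mean(d) / (sample_sd(d) / math.sqrt(n))
    p = 2 * _st.t.sf(abs(t), n - 1)
    return t, p


def pearson_oracle(x, y):
    """Product-moment correlation and two-sided p via the t transform."""
    n = len(x)
    mx, my = mean(x), mean(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    t = r * math.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else math.inf
    p = 2 * _st.t.sf(abs(t), n - 2)
    return r, p


def average_ranks(x):
    """Average ranks with ties, by explicit sorting."""
    order = sorted(range(len(x)), key=lambda i: x[i])
    ranks = [0.0] * len(x)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and x[order[j + 1]] == x[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Rank correlation = Pearson on average ranks."""
    return pearson_oracle(average_ranks(list(x)), average_ranks(list(y)))


def ols_slope_oracle(x, y):
    """OLS slope of y on x and its two-sided p, via normal equations."""
    n = len(x)
    mx, my = mean(x), mean(y)
    sxx = sum((a - mx) ** 2 for a in x)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    slope = sxy / sxx
    intercept = my - slope * mx
    rss = sum((b - intercept - slope * a) ** 2 for a, b in zip(x, y))
    se = math.sqrt(rss / (n - 2) / sxx)
    t = slope / se
    p = 2 * _st.t.sf(abs(t), n - 2)
    return slope, p


def icc_oracle(ref, est, form):
    """Two-way single-measure ICC from an explicitly looped ANOVA table."""
    data = [[r, e] for r, e in zip(ref, est)]
    n, k = len(data), 2
    grand = mean([v for row in data for v in row])
    row_means = [mean(row) for row in data]
    col_means = [mean([row[j] for row in data]) for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_tot = sum((v - grand) ** 2 for row in data for v in row)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if form == "consistency":
        return (msr - mse) / (msr + (k - 1) * mse)
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


# ---------------------------------------------------------------------------
# independent transcription of the spot-urine conversion equations
# (second transcription, written by hand; mg/day outputs)


def _kawasaki_prcr(sex, age, weight, height):
    if sex == "M":
        return -12.63 * age + 15.12 * weight + 7.39 * height - 79.9
    return -4.72 * age + 8.58 * weight + 5.09 * height - 74.5


def kawasaki_oracle(sex, age, weight, height, spot_na, spot_creat):
    ratio = spot_na / (spot_creat * 10.0) * _kawasaki_prcr(sex, age, weight, height)
    return 16.3 * math.sqrt(ratio) * 23.0


def tanaka_oracle(sex, age, weight, height, spot_na, spot_creat):
    prcr = -2.04 * age + 14.89 * weight + 16.14 * height - 2244.45
    ratio = spot_na / (spot_creat * 10.0) * prcr
    return 21.98 * ratio**0.392 * 23.0


def intersalt_with_k_oracle(sex, age, weight, height, spot_na, spot_k, spot_creat):
    bmi = weight / (height / 100.0) ** 2
    cr = spot_creat * 10.0 / 113.12  # mg/dL -> mmol/L
    if sex == "M":
        mmol = 25.46 + 0.46 * spot_na - 2.75 * cr - 0.13 * spot_k + 4.10 * bmi + 0.26 * age
    else:
        mmol = (
            5.07 + 0.34 * spot_na - 2.16 * cr - 0.09 * spot_k + 2.39 * bmi
            + 2.35 * age - 0.03 * age**2
        )
    return max(mmol, 0.0) * 23.0


def intersalt_without_k_oracle(sex, age, weight, height, spot_na, spot_creat):
    bmi = weight / (height / 100.0) ** 2
    cr = spot_creat * 10.0 / 113.12
    if sex == "M":
        mmol = 23.51 + 0.45 * spot_na - 3.09 * cr + 4.16 * bmi + 0.22 * age
    else:
        mmol = 3.74 + 0.33 * spot_na - 2.44 * cr + 2.42 * bmi + 2.34 * age - 0.03 * age**2
    return max(mmol, 0.0) * 23.0


def mage_oracle(sex, age, weight, height, spot_na, spot_creat):
    k = 0.21 if sex == "M" else 0.18
    prcr = k * weight**1.5 * math.sqrt(height)
    return spot_na / (spot_creat * 10.0) * prcr * 23.0


def toft_oracle(sex, age, weight, height, spot_na, spot_creat):
    prcr = (24.0 if sex == "M" else 18.0) * weight
    return spot_na / (spot_creat * 10.0) * prcr * 23.0


SPOT_ORACLES = {
    "kawasaki": kawasaki_oracle,
    "tanaka": tanaka_oracle,
    "intersalt_with_k": intersalt_with_k_oracle,
    "intersalt_without_k": intersalt_without_k_oracle,
    "mage": mage_oracle,
    "toft": toft_oracle,
}
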