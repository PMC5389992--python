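"""Independent brute-force oracles, deliberately naive and separate from the
package's code paths."""
import math

import numpy as np


def walk_loglik(trials, alpha_high, alpha_low, beta, q_init=0.5,
                one_rate=False, ab_only=False):
    """Trial-by-trial log-likelihood with explicit scalar arithmetic."""
    q = {s: q_init for s in "ABCDEF"}
    pairs = {"AB": ("A", "B"), "CD": ("C", "D"), "EF": ("E", "F")}
    total = 0.0
    for row in trials.itertuples():
        if row.omitted:
            continue
        if ab_only and row.pair != "AB":
            continue
        a, b = pairs[row.pair]
        ea = math.exp(beta * q[a])
        eb = math.exp(beta * q[b])
        p_a = ea / (ea + eb)
        p = p_a if row.chosen == a else 1.0 - p_a
        total += math.log(max(p, 1e-12))
        if one_rate:
            alpha = alpha_high
        elif row.reward == 1:
            alpha = alpha_high
        else:
            alpha = alpha_low
        q[row.chosen] = q[row.chosen] + alpha * (row.reward - q[row.chosen])
    return total


def rm_anova_ss(table):
    """Sums-of-squares enumeration for a one-way within-subject design."""
    arr = np.asarray(table, dtype=float)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = sum(n * (arr[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (arr[i, :].mean() - grand) ** 2 for i in range(n))
    ss_total = sum((x - grand) ** 2 for x in arr.ravel())
    ss_resid = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    F = (ss_cond / df1) / (ss_resid / df2)
    eta = ss_cond / (ss_cond + ss_resid)
    return F, df1, df2, eta


def linear_contrast_F(table_ordered):
    """One-sample F on the (-1, 0, +1) contrast, scalar arithmetic."""
    arr = np.asarray(table_ordered, dtype=float)
    scores = [-row[0] + row[2] for row in arr]
    n = len(scores)
    mean = sum(scores) / n
    var = sum((s - mean) ** 2 for s in scores) / (n - 1)
    t = mean / math.sqrt(var / n)
    return t * t


def partial_corr_residualized(x, y, z):
    """Partial correlation on ranks by explicit residualization."""
    from scipy.stats import rankdata

    rx, ry, rz = rankdata(x), rankdata(y), rankdata(z)

    def residual(v, c):
        c1 = np.column_stack([np.ones_like(c), c])
        coef, *_ = np.linalg.lstsq(c1, v, rcond=None)
        return v - c1 @ coef

    ex, ey = residual(rx, rz), residual(ry, rz)
    return float(np.corrcoef(ex, ey)[0, 1])
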