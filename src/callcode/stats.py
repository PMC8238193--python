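"""Comparison layer: omnibus nonparametric tests, post-hoc corrections,
effect sizes, 2-D distribution tests, FDR, and permutation tests.

Kruskal-Wallis, t-tests, OLS and FDR go through scipy/statsmodels; the
Dunn-Sidak post-hoc z-tests, Cliff's delta, the Peacock all-quadrant 2-D
Kolmogorov-Smirnov test and the category-representation permutation test
are implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from scipy.special import kolmogorov
from statsmodels.stats.multitest import multipletests


@dataclass
class GroupComparison:
    labels: list
    statistic: float
    p_value: float
    #: (label_i, label_j) -> Sidak-adjusted Dunn p-value
    pairwise_p: dict
    #: (label_i, label_j) -> Cliff's delta (x=i sample, y=j sample)
    pairwise_delta: dict


def kruskal_dunn_sidak(groups: dict | list) -> GroupComparison:
    """Kruskal-Wallis omnibus test with Dunn post-hoc z-tests, Sidak-adjusted.

    ``groups`` is a mapping label -> values or a list of value arrays.
    """
    if not isinstance(groups, dict):
        groups = {i: g for i, g in enumerate(groups)}
    labels = list(groups)
    samples = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for s in samples:
        if len(s) < 2:
            raise ValueError("each group needs at least 2 values")
    H, p = sps.kruskal(*samples)

    # Dunn's z-tests on pooled mean ranks, with tie correction
    pooled = np.concatenate(samples)
    ranks = sps.rankdata(pooled)
    N = len(pooled)
    sizes = [len(s) for s in samples]
    mean_ranks, i0 = [], 0
    for n in sizes:
        mean_ranks.append(ranks[i0:i0 + n].mean())
        i0 += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (N - 1))
    m = len(labels) * (len(labels) - 1) // 2
    pairwise_p, pairwise_delta = {}, {}
    for i, j in combinations(range(len(labels)), 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1 / sizes[i] + 1 / sizes[j])
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
        p_raw = 2.0 * sps.norm.sf(abs(z))
        p_adj = 1.0 - (1.0 - min(p_raw, 1.0)) ** m
        pairwise_p[(labels[i], labels[j])] = float(p_adj)
        pairwise_delta[(labels[i], labels[j])] = cliffs_delta(
            samples[i], samples[j])
    return GroupComparison(labels=labels, statistic=float(H),
                           p_value=float(p), pairwise_p=pairwise_p,
                           pairwise_delta=pairwise_delta)


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (n_x * n_y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty input")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (len(x) * len(y)))


def _quadrant_max_diff(a: np.ndarray, b: np.ndarray,
                       points: np.ndarray) -> float:
    d = 0.0
    for px, py in points:
        for ox in (True, False):
            for oy in (True, False):
                ax = (a[:, 0] <= px) if ox else (a[:, 0] > px)
                ay = (a[:, 1] <= py) if oy else (a[:, 1] > py)
                bx = (b[:, 0] <= px) if ox else (b[:, 0] > px)
                by = (b[:, 1] <= py) if oy else (b[:, 1] > py)
                d = max(d, abs((ax & ay).mean() - (bx & by).mean()))
    return d


def ks2d_peacock(a, b) -> tuple[float, float]:
    """Peacock's two-dimensional Kolmogorov-Smirnov test.

    The statistic is the maximum discrepancy between the two empirical
    distributions over all four quadrant orientations anchored at every
    data point of both samples.  The p-value uses the asymptotic
    approximation with the correlation-based correction of the numerical
    2-D K-S literature; any multiple-comparison (Bonferroni) correction is
    left to the caller.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[0] < 5 or b.shape[0] < 5:
        raise ValueError("each sample needs at least 5 points")
    points = np.vstack([a, b])
    if np.all(points == points[0]):
        return 0.0, 1.0
    D = _quadrant_max_diff(a, b, points)
    n_eff = a.shape[0] * b.shape[0] / (a.shape[0] + b.shape[0])

    def _corr(s):
        if np.std(s[:, 0]) == 0 or np.std(s[:, 1]) == 0:
            return 0.0
        return np.corrcoef(s[:, 0], s[:, 1])[0, 1]

    r2 = 0.5 * (_corr(a) ** 2 + _corr(b) ** 2)
    denom = 1.0 + np.sqrt(max(1.0 - r2, 0.0)) * (0.25 - 0.75 / np.sqrt(n_eff))
    lam = np.sqrt(n_eff) * D / denom
    return float(D), float(min(1.0, kolmogorov(lam)))


def fdr_bh(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (rejection mask, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def permutation_category_test(responsive: np.ndarray, stages,
                              n_perm: int = 1000, seed: int = 0,
                              q: float = 0.05):
    """Two-sided permutation test for category over/under-representation.

    ``responsive`` is a (n_neurons, n_categories) boolean table; ``stages``
    labels each neuron.  The null permutes neuron -> stage assignments;
    per-cell two-sided p-values are BH-FDR corrected across all
    (stage, category) cells.  Returns (p_adj, reject, observed_counts),
    each (n_stages, n_categories).
    """
    responsive = np.asarray(responsive, dtype=bool)
    stages = np.asarray(stages)
    labels = np.unique(stages)
    if len(labels) < 2:
        raise ValueError("need at least 2 stages")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    obs = np.stack([responsive[stages == s].sum(axis=0) for s in labels])
    rng = np.random.default_rng(seed)
    null = np.zeros((n_perm,) + obs.shape)
    for i in range(n_perm):
        perm = rng.permutation(stages)
        null[i] = np.stack(
            [responsive[perm == s].sum(axis=0) for s in labels])
    p_hi = (1 + (null >= obs[None]).sum(axis=0)) / (1 + n_perm)
    p_lo = (1 + (null <= obs[None]).sum(axis=0)) / (1 + n_perm)
    p = np.minimum(1.0, 2.0 * np.minimum(p_hi, p_lo))
    reject, p_adj = fdr_bh(p.ravel(), q=q)
    return p_adj.reshape(p.shape), reject.reshape(p.shape), obs


def ancova_common_slope(y, x, groups):
    """Common-slope ANCOVA: y ~ x + group, with Tukey HSD intercept contrasts.

    Returns a dict with the group-effect F and p, the common slope, the
    adjusted group intercepts, and pairwise Tukey-adjusted p-values.
    """
    import pandas as pd
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, dtype=float),
                       "x": np.asarray(x, dtype=float),
                       "g": np.asarray(groups)})
    full = smf.ols("y ~ x + C(g)", data=df).fit()
    reduced = smf.ols("y ~ x", data=df).fit()
    from statsmodels.stats.anova import anova_lm

    tab = anova_lm(reduced, full)
    F = float(tab["F"].iloc[1])
    p = float(tab["Pr(>F)"].iloc[1])

    labels = sorted(df["g"].unique())
    slope = float(full.params["x"])
    xbar = df["x"].mean()
    adj_means = {
        g: float(df.loc[df.g == g, "y"].mean()
                 - slope * (df.loc[df.g == g, "x"].mean() - xbar))
        for g in labels}
    mse = float(full.mse_resid)
    k = len(labels)
    dfe = int(full.df_resid)
    pairwise = {}
    for g1, g2 in combinations(labels, 2):
        n1 = (df.g == g1).sum()
        n2 = (df.g == g2).sum()
        se = np.sqrt(mse * 0.5 * (1 / n1 + 1 / n2))
        qstat = abs(adj_means[g1] - adj_means[g2]) / se
        pairwise[(g1, g2)] = float(
            sps.studentized_range.sf(qstat, k, dfe))
    return {"F": F, "p": p, "slope": slope, "adjusted_means": adj_means,
            "pairwise_p": pairwise}
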