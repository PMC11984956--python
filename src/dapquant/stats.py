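"""Statistical layer: Welch's t, Fisher's exact test, nested comparisons,
Dunnett-adjusted many-to-one contrasts and ROUT outlier flagging.

Nested tests respect the replicate/cell hierarchy by operating on replicate
means — cells within a replicate are not independent samples, and pooling
them inflates significance (pseudo-replication). For balanced designs this
replicate-means reduction is equivalent to a one-level random-effects
model.

The Dunnett familywise adjustment is computed by Monte-Carlo sampling of
the null distribution of the maximum absolute t statistic under the
pooled-variance model; it is seedable and its precision scales as
1/sqrt(n_draws).

ROUT (robust outlier removal controlled by a false-discovery rate Q) is
adapted here to a single measurement column: the "regression" is the
constant model, its robust fit the median, and the robust scale the RSDR
(68.27th percentile of absolute residuals with a small-sample correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .datatypes import NestedDataset

__all__ = [
    "TestResult",
    "welch_t",
    "fisher_exact_2x2",
    "nested_t",
    "nested_anova_dunnett",
    "rout_outliers",
]


@dataclass
class TestResult:
    """Outcome of a hypothesis test."""

    name: str
    statistic: float
    df: float
    pvalue: float

    def as_dict(self) -> dict:
        return {
            "test": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p": self.pvalue,
        }


def welch_t(x, y) -> TestResult:
    """Two-sided Welch (unequal-variance) t test.

    Returns the t statistic, Welch–Satterthwaite degrees of freedom and the
    two-sided p value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult("welch_t", float(res.statistic), float(res.df), float(res.pvalue))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact test on a 2x2 table [[a, b], [c, d]].

    Two-sided p by the probability-mass convention: the sum of
    hypergeometric probabilities (margins fixed) of every table at least as
    unlikely as the observed one.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if table.sum() == 0:
        raise ValueError("table is empty")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("a margin of the table is zero")
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def nested_t(ds_a: NestedDataset, ds_b: NestedDataset) -> TestResult:
    """Nested (hierarchical) two-sample t test on replicate means.

    Pools variance across replicate means (equal-variance Student t) with
    df = n_rep_a + n_rep_b - 2.
    """
    for ds in (ds_a, ds_b):
        if ds.n_replicates < 2:
            raise ValueError("each condition needs >= 2 replicates")
    ma, mb = ds_a.replicate_means(), ds_b.replicate_means()
    df = len(ma) + len(mb) - 2
    if np.var(ma, ddof=1) == 0 and np.var(mb, ddof=1) == 0:
        # degenerate pooled variance: identical means are a null result
        if ma.mean() == mb.mean():
            return TestResult("nested_t", 0.0, float(df), 1.0)
        t = np.inf if ma.mean() > mb.mean() else -np.inf
        return TestResult("nested_t", t, float(df), 0.0)
    res = sps.ttest_ind(ma, mb, equal_var=True)
    return TestResult("nested_t", float(res.statistic), float(df), float(res.pvalue))


@dataclass
class DunnettResult:
    """Many-to-one comparisons against a shared control."""

    statistics: np.ndarray  # t per treatment
    pvalues_unadjusted: np.ndarray
    pvalues_adjusted: np.ndarray
    df: float
    f_statistic: float
    f_pvalue: float
    n_draws: int
    seed: int


def nested_anova_dunnett(
    control: NestedDataset,
    treatments: list[NestedDataset],
    n_draws: int = 100_000,
    seed: int = 0,
) -> DunnettResult:
    """Nested one-way ANOVA with Dunnett's many-to-one adjustment.

    Replicate means are the analysis units. Each treatment is compared to
    the control with a pooled-variance t statistic; the familywise-adjusted
    p value is P(max_j |T_j| >= |t_obs|) under the joint null, estimated by
    Monte-Carlo over ``n_draws`` samples of the correlated t vector
    (correlated through the shared control mean and the shared variance
    estimate). Adjusted p >= unadjusted p by construction.
    """
    if not treatments:
        raise ValueError("need at least one treatment group")
    groups = [control] + list(treatments)
    means = [g.replicate_means() for g in groups]
    ns = np.array([len(m) for m in means])
    if (ns < 2).any():
        raise ValueError("each group needs >= 2 replicates")
    k = len(treatments)
    gm = [m.mean() for m in means]
    df = int(ns.sum() - len(groups))
    ss_within = sum(((m - m.mean()) ** 2).sum() for m in means)
    s2 = ss_within / df
    if s2 == 0:
        raise ValueError("zero within-group variance on replicate means")
    # one-way ANOVA on replicate means
    grand = np.concatenate(means).mean()
    ss_between = sum(n * (g - grand) ** 2 for n, g in zip(ns, gm))
    ms_between = ss_between / (len(groups) - 1)
    f_stat = ms_between / s2
    f_p = float(sps.f.sf(f_stat, len(groups) - 1, df))

    se = np.sqrt(s2 * (1.0 / ns[1:] + 1.0 / ns[0]))
    t_obs = (np.array(gm[1:]) - gm[0]) / se
    p_unadj = 2.0 * sps.t.sf(np.abs(t_obs), df)

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(size=(n_draws, len(groups))) / np.sqrt(ns)
    w = np.sqrt(rng.chisquare(df, size=n_draws) / df)
    t_null = (z[:, 1:] - z[:, :1]) / (np.sqrt(1.0 / ns[1:] + 1.0 / ns[0]) * w[:, None])
    max_abs = np.abs(t_null).max(axis=1)
    p_adj = (1.0 + np.sum(max_abs[:, None] >= np.abs(t_obs)[None, :], axis=0)) / (
        n_draws + 1.0
    )
    p_adj = np.maximum(p_adj, p_unadj)  # MC noise guard: adjustment is monotone
    return DunnettResult(
        statistics=t_obs,
        pvalues_unadjusted=p_unadj,
        pvalues_adjusted=np.minimum(p_adj, 1.0),
        df=float(df),
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        n_draws=n_draws,
        seed=seed,
    )


def rout_outliers(values, q: float = 0.01) -> np.ndarray:
    """Flag outliers in a single measurement column by the ROUT procedure.

    Robust center = median; robust scale = RSDR, the 68.27th percentile of
    absolute residuals corrected for small n by n/(n - 1) (one fitted
    parameter). Points are tested from the most extreme inward: the j-th
    most extreme residual (j = 1, 2, ...) is flagged when its two-tailed
    t probability (df = n - 1) falls below q * (n - j + 1) / n, and testing
    stops at the first non-significant point. Returns a boolean flag array;
    no rows are removed.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise ValueError("ROUT needs n >= 3")
    if not 0.0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    resid = values - np.median(values)
    abs_resid = np.abs(resid)
    rsdr = np.percentile(abs_resid, 68.27) * n / (n - 1)
    flags = np.zeros(n, dtype=bool)
    if rsdr == 0:
        # constant data: anything off the median is an outlier
        flags[abs_resid > 0] = True
        return flags
    order = np.argsort(abs_resid)[::-1]
    t_ratio = abs_resid / rsdr
    for j, idx in enumerate(order, start=1):
        p = 2.0 * sps.t.sf(t_ratio[idx], df=n - 1)
        if p < q * (n - j + 1) / n:
            flags[idx] = True
        else:
            break
    return flags
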