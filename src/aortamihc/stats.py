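"""The study's statistical battery with explicit contracts.

Continuous non-Gaussian variables are summarized as median (IQR), compared
between two groups with the two-sided Kolmogorov–Smirnov test and between
three with the Kruskal–Wallis test followed by Bonferroni-adjusted
pairwise comparisons (adjusted p capped at 1).  Binary variables use the
Fisher exact test, correlations Kendall's tau-b (chosen for the small
group sizes) with a seeded bootstrap percentile CI, and two-observer
agreement the intraclass correlation coefficient, by default the two-way
random-effects absolute-agreement single-measures form ICC(2,1)
(ICC(3,1) available via flag).

scipy provides the test statistics and pingouin the ICC ANOVA; the
contracts — tie handling, the Bonferroni cap, degenerate-input behavior,
reproducible bootstrap — are fixed here and verified against brute-force
oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    pass


@dataclass
class GroupComparison:
    groups: tuple[str, ...]
    test: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    adjustment: str | None = None
    n_per_group: dict[str, int] = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "groups": "|".join(self.groups),
            "test": self.test,
            "statistic": self.statistic,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "adjustment": self.adjustment,
            **{f"n_{g}": n for g, n in self.n_per_group.items()},
        }


@dataclass
class CorrelationResult:
    tau: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    ci_method: str = "bootstrap percentile"

    def to_row(self) -> dict:
        return self.__dict__.copy()


def median_iqr(values) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear quantile interpolation."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise StatsError("median_iqr: empty input")
    if np.isnan(v).any():
        raise StatsError("median_iqr: input contains NaN")
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
    )


def ks_two_sample(a, b, names: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Two-sided two-sample Kolmogorov–Smirnov test (scipy's ``auto`` mode:
    exact for small samples, asymptotic otherwise)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("ks_two_sample: need n >= 2 per group")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="auto")
    return GroupComparison(
        groups=names,
        test="kolmogorov_smirnov",
        statistic=float(res.statistic),
        p_raw=float(min(res.pvalue, 1.0)),
        n_per_group={names[0]: len(a), names[1]: len(b)},
    )


def kruskal_wallis_pairwise(groups: dict[str, list | np.ndarray]) -> tuple[GroupComparison, list[GroupComparison]]:
    """Overall Kruskal–Wallis H (tie-corrected) plus all pairwise tests
    Bonferroni-adjusted by the number of pairs, capped at 1."""
    if len(groups) < 2:
        raise StatsError("kruskal_wallis_pairwise: need >= 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise StatsError(f"kruskal_wallis_pairwise: group {g!r} has n < 2")

    def _kruskal(*samples) -> tuple[float, float]:
        concat = np.concatenate(samples)
        if np.all(concat == concat[0]):
            return 0.0, 1.0  # all values identical: no evidence of difference
        h, p = sps.kruskal(*samples)
        return float(h), float(p)

    names = list(arrays)
    h, p = _kruskal(*arrays.values())
    overall = GroupComparison(
        groups=tuple(names),
        test="kruskal_wallis",
        statistic=h,
        p_raw=p,
        n_per_group={g: len(v) for g, v in arrays.items()},
    )
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    pairwise = []
    for a, b in pairs:
        h2, p2 = _kruskal(arrays[a], arrays[b])
        pairwise.append(
            GroupComparison(
                groups=(a, b),
                test="kruskal_wallis",
                statistic=h2,
                p_raw=p2,
                p_adjusted=min(1.0, p2 * len(pairs)),
                adjustment=f"bonferroni x{len(pairs)}",
                n_per_group={a: len(arrays[a]), b: len(arrays[b])},
            )
        )
    return overall, pairwise


def fisher_exact_2x2(table) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise StatsError(f"fisher_exact_2x2: expected 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise StatsError("fisher_exact_2x2: entries must be non-negative integers")
        t = t.astype(int)
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return GroupComparison(
        groups=("row1", "row2"),
        test="fisher_exact",
        statistic=float(odds),
        p_raw=float(p),
        n_per_group={"row1": int(t[0].sum()), "row2": int(t[1].sum())},
    )


def kendall_tau_ci(x, y, n_boot: int = 2000, seed: int = 0) -> CorrelationResult | None:
    """Kendall's tau-b with a seeded bootstrap percentile CI.

    Returns None when tau is undefined (a constant vector).  The p-value is
    scipy's exact/asymptotic tau null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise StatsError("kendall_tau_ci: x and y must be paired")
    if len(x) < 3:
        raise StatsError("kendall_tau_ci: need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return None
    res = sps.kendalltau(x, y)
    rng = np.random.default_rng(seed)
    taus = []
    n = len(x)
    while len(taus) < n_boot:
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if np.all(xb == xb[0]) or np.all(yb == yb[0]):
            continue  # resample with undefined tau: draw again
        tb = sps.kendalltau(xb, yb).statistic
        if not np.isnan(tb):
            taus.append(tb)
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return CorrelationResult(
        tau=float(res.statistic),
        ci_low=float(lo),
        ci_high=float(hi),
        p=float(res.pvalue),
        n=n,
    )


def icc_two_observers(ratings_a, ratings_b, form: str = "ICC2") -> tuple[float, tuple[float, float]]:
    """Intraclass correlation for two raters scoring the same subjects.

    ``form`` is ``ICC2`` (two-way random effects, absolute agreement,
    single measures; the default) or ``ICC3`` (two-way mixed, consistency).
    Identical ratings (zero total variance) return ICC = 1 by convention.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if len(a) != len(b):
        raise StatsError("icc_two_observers: ratings must be paired")
    if len(a) < 3:
        raise StatsError("icc_two_observers: need n >= 3 subjects")
    if form not in ("ICC2", "ICC3"):
        raise StatsError(f"icc_two_observers: unknown form {form!r}")
    if np.array_equal(a, b):
        return 1.0, (1.0, 1.0)

    import pingouin as pg

    n = len(a)
    df = pd.DataFrame(
        {
            "subject": np.tile(np.arange(n), 2),
            "rater": np.repeat(["a", "b"], n),
            "score": np.concatenate([a, b]),
        }
    )
    res = pg.intraclass_corr(data=df, targets="subject", raters="rater", ratings="score")
    aliases = {"ICC2": ("ICC2", "ICC(A,1)"), "ICC3": ("ICC3", "ICC(C,1)")}
    row = res[res["Type"].isin(aliases[form])].iloc[0]
    ci_col = next(c for c in res.columns if c.startswith("CI95"))
    lo, hi = row[ci_col]
    return float(row["ICC"]), (float(lo), float(hi))
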