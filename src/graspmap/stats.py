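"""Statistical tests backing the neuron classification scheme.

The one-way repeated-measures ANOVA (trials as subjects, epoch as the
within factor), its Tukey post-hoc contrasts, and the two-factor ANOVA are
implemented as explicit sum-of-squares decompositions so that every F, df
and p entering a classification decision is an auditable quantity. The
Mann-Whitney test and the chi-square test delegate to scipy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "rm_anova",
    "tukey_rm_contrasts",
    "two_way_anova",
    "mann_whitney",
]


@dataclass(frozen=True)
class TestResult:
    """One test's evidence: statistic, degrees of freedom, p, direction.

    ``direction`` is +1 / -1 / 0 for pairwise contrasts (sign of the first
    group's mean minus the second's) and 0 where direction is meaningless.
    """

    name: str
    statistic: float
    df: tuple[float, ...]
    p: float
    direction: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p out of range: {self.p}")


class DegenerateVarianceError(ValueError):
    pass


def _rm_decomposition(data: np.ndarray):
    """Sum-of-squares pieces of a one-way within-subject design.

    ``data`` is (n_subjects, k_levels). Returns (ss_level, ss_error,
    df_level, df_error, level_means, n).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 3:
        raise ValueError("need at least 3 subjects (trials)")
    grand = data.mean()
    level_means = data.mean(axis=0)
    subj_means = data.mean(axis=1)
    ss_level = n * np.sum((level_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_level - ss_subj
    return ss_level, ss_error, k - 1, (k - 1) * (n - 1), level_means, n


def rm_anova(data: np.ndarray, name: str = "rm_anova") -> TestResult:
    """One-way repeated-measures ANOVA over the columns of ``data``.

    Rows are subjects (trials), columns the within-subject levels (epochs).
    F has df (k-1, (k-1)(n-1)).
    """
    ss_level, ss_error, df1, df2, _, _ = _rm_decomposition(data)
    if ss_error <= 0:
        if ss_level <= 0:
            raise DegenerateVarianceError("no variance anywhere in the design")
        return TestResult(name, float("inf"), (df1, df2), 0.0)
    f = (ss_level / df1) / (ss_error / df2)
    return TestResult(name, float(f), (float(df1), float(df2)), float(sps.f.sf(f, df1, df2)))


def tukey_rm_contrasts(
    data: np.ndarray, labels: tuple[str, ...]
) -> dict[tuple[str, str], TestResult]:
    """Tukey HSD over the level means of a within-subject design.

    Uses the repeated-measures error term: q_ij = |m_i - m_j| /
    sqrt(MS_error / n), referred to the studentized range with k means and
    the RM error df. Direction is sign(m_i - m_j).
    """
    _, ss_error, df1, df2, means, n = _rm_decomposition(data)
    k = len(means)
    if len(labels) != k:
        raise ValueError("labels must match the number of levels")
    ms_error = ss_error / df2
    out: dict[tuple[str, str], TestResult] = {}
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if ms_error <= 0:
        for i, j in pairs:
            diff = means[i] - means[j]
            p = 0.0 if abs(diff) > 0 else 1.0
            out[(labels[i], labels[j])] = TestResult(
                f"tukey_{labels[i]}_{labels[j]}", float("inf") if p == 0 else 0.0,
                (float(k), float(df2)), p, int(np.sign(diff)),
            )
        return out
    se = np.sqrt(ms_error / n)
    qs = np.array([abs(means[i] - means[j]) / se for i, j in pairs])
    ps = sps.studentized_range.sf(qs, k, df2)
    for (i, j), q, p in zip(pairs, qs, ps):
        diff = means[i] - means[j]
        out[(labels[i], labels[j])] = TestResult(
            f"tukey_{labels[i]}_{labels[j]}",
            float(q),
            (float(k), float(df2)),
            float(min(1.0, p)),
            int(np.sign(diff)),
        )
    return out


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _effect_code(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(set(labels))
    cols = []
    for lev in levels[:-1]:
        col = np.where(labels == lev, 1.0, 0.0)
        col[labels == levels[-1]] = -1.0
        cols.append(col)
    return (np.column_stack(cols) if cols else np.empty((len(labels), 0)), levels)


def two_way_anova(
    values: np.ndarray,
    factor_a: np.ndarray,
    factor_b: np.ndarray,
    names: tuple[str, str] = ("A", "B"),
) -> dict[str, TestResult]:
    """Two-factor ANOVA with interaction (Type II sums of squares).

    Observations are treated as independent; with a balanced design this
    reduces to the classical cell-means decomposition. Returns TestResults
    keyed by the factor names and "interaction".
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factor labels must have equal length")
    Xa, lev_a = _effect_code(a)
    Xb, lev_b = _effect_code(b)
    inter = np.column_stack(
        [Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
    ) if Xa.shape[1] and Xb.shape[1] else np.empty((len(y), 0))
    one = np.ones((len(y), 1))
    X_full = np.hstack([one, Xa, Xb, inter])
    df_a, df_b = Xa.shape[1], Xb.shape[1]
    df_ab = inter.shape[1]
    df_err = len(y) - (1 + df_a + df_b + df_ab)
    if df_err <= 0:
        raise ValueError("not enough observations for the full model")
    sst = float(np.sum((y - y.mean()) ** 2))
    tol = 1e-12 * max(sst, 1.0)
    rss_full = _rss(y, X_full)
    ms_err = 0.0 if rss_full <= tol else rss_full / df_err
    # Type II: each main effect adjusted for the other main effect;
    # interaction adjusted for both.
    rss_ab_main = _rss(y, np.hstack([one, Xa, Xb]))
    ss = {
        names[0]: _rss(y, np.hstack([one, Xb])) - rss_ab_main,
        names[1]: _rss(y, np.hstack([one, Xa])) - rss_ab_main,
        "interaction": rss_ab_main - rss_full,
    }
    dfs = {names[0]: df_a, names[1]: df_b, "interaction": df_ab}
    out = {}
    for key, ss_eff in ss.items():
        d = dfs[key]
        if ms_err <= 0:
            f = float("inf") if ss_eff > tol else 0.0
            p = 0.0 if ss_eff > tol else 1.0
        else:
            f = max(0.0, ss_eff / d) / ms_err
            p = float(sps.f.sf(f, d, df_err))
        out[key] = TestResult(key, float(f), (float(d), float(df_err)), p)
    return out


def mann_whitney(
    a: np.ndarray, b: np.ndarray, name: str = "mann_whitney"
) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null distribution when the combined sample size is <= 20 and the
    data contain no ties; otherwise the normal approximation with tie
    correction (and continuity correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(a) - np.median(b)))
    return TestResult(
        name,
        float(res.statistic),
        (float(len(a)), float(len(b))),
        float(res.pvalue),
        direction,
        extra={"method": method},
    )
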