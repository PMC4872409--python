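"""One-way repeated-measures (within-subject) ANOVA and Bonferroni planned
comparisons.

The design blocks on subject: for k conditions and n subjects the total sum
of squares decomposes into treatment (between-condition), subject
(between-subject) and error (condition x subject residual) terms, with
F = MS_treatment / MS_error on (k-1, (k-1)(n-1)) degrees of freedom. No
sphericity correction is applied by default; Greenhouse-Geisser is optional.

Planned comparisons are two-sided paired t-tests with the Bonferroni
adjustment min(1, m * p), where m counts only the pre-registered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float
    ss_treatment: float
    ss_subject: float
    ss_error: float
    gg_epsilon: float | None = None  # set when sphericity-corrected

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["treatment", "subject", "error"],
                "ss": [self.ss_treatment, self.ss_subject, self.ss_error],
                "df": [self.df1, None, self.df2],
                "F": [self.F, None, None],
                "p": [self.p, None, None],
            }
        )


@dataclass
class PlannedComparison:
    cond_a: str
    cond_b: str
    mean_diff: float
    t: float
    p_raw: float
    p_adjusted: float


class IncompleteTableError(ValueError):
    """Complete within-subject tables are required; drop incomplete subjects
    (listwise removal) before analysis."""


def condition_table(df: pd.DataFrame, subject="subject", condition="condition", value="value"):
    """Pivot tidy (subject, condition, value) rows to a subjects x conditions
    matrix, enforcing completeness."""
    table = df.pivot_table(index=subject, columns=condition, values=value, aggfunc="mean")
    if table.isna().any().any():
        missing = table.isna().stack()
        bad = list(missing[missing].index)
        raise IncompleteTableError(
            f"incomplete table (missing cells: {bad}); remove those subjects entirely "
            "(listwise) before running the repeated-measures ANOVA"
        )
    return table


def rm_anova_oneway(table: pd.DataFrame | np.ndarray, use_gg: bool = False) -> AnovaResult:
    """One-way within-subjects ANOVA on a complete subjects x conditions table."""
    if isinstance(table, pd.DataFrame):
        if table.isna().any().any():
            raise IncompleteTableError(
                "incomplete table; remove subjects with missing cells (listwise)"
            )
        y = table.to_numpy(dtype=float)
    else:
        y = np.asarray(table, dtype=float)
        if np.isnan(y).any():
            raise IncompleteTableError(
                "incomplete table; remove subjects with missing cells (listwise)"
            )
    n, k = y.shape
    if k < 2 or n < 2:
        raise ValueError(f"need >=2 conditions and >=2 subjects, got {k} x {n}")
    grand = y.mean()
    cond_means = y.mean(axis=0)
    subj_means = y.mean(axis=1)
    ss_treat = n * float(((cond_means - grand) ** 2).sum())
    ss_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_total = float(((y - grand) ** 2).sum())
    ss_err = ss_total - ss_treat - ss_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    ms_treat = ss_treat / df1
    ms_err = ss_err / df2
    eps = None
    if ms_err == 0.0:
        F = 0.0 if ms_treat == 0.0 else np.inf
        p = 1.0 if ms_treat == 0.0 else 0.0
    else:
        F = ms_treat / ms_err
        if use_gg:
            eps = _gg_epsilon(y)
            p = float(spstats.f.sf(F, df1 * eps, df2 * eps))
        else:
            p = float(spstats.f.sf(F, df1, df2))
    return AnovaResult(
        F=float(F), df1=df1, df2=df2, p=p,
        ss_treatment=ss_treat, ss_subject=ss_subj, ss_error=ss_err, gg_epsilon=eps,
    )


def _gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    k = y.shape[1]
    s = np.cov(y, rowvar=False, ddof=1)
    s_c = s - s.mean(axis=0)[None, :] - s.mean(axis=1)[:, None] + s.mean()
    num = np.trace(s_c) ** 2
    den = (k - 1) * float((s_c**2).sum())
    return float(num / den) if den > 0 else 1.0


def bonferroni_planned(
    table: pd.DataFrame, comparisons: list[tuple[str, str]]
) -> list[PlannedComparison]:
    """Two-sided paired t-tests for pre-registered condition pairs.

    m = len(comparisons) is the Bonferroni family size. A pair with zero
    variance of the paired differences is degenerate: p = 1 when the mean
    difference is 0, else the limiting p = 0.
    """
    out = []
    m = len(comparisons)
    for a, b in comparisons:
        for c in (a, b):
            if c not in table.columns:
                raise KeyError(f"condition {c!r} not in table columns {list(table.columns)}")
        d = table[a].to_numpy(dtype=float) - table[b].to_numpy(dtype=float)
        mean_d = float(d.mean())
        if np.allclose(d.std(ddof=1), 0.0):
            t = 0.0 if mean_d == 0 else np.inf * np.sign(mean_d)
            p_raw = 1.0 if mean_d == 0 else 0.0
        else:
            t, p_raw = spstats.ttest_rel(table[a], table[b])
            t, p_raw = float(t), float(p_raw)
        out.append(
            PlannedComparison(
                cond_a=a, cond_b=b, mean_diff=mean_d, t=t,
                p_raw=p_raw, p_adjusted=min(1.0, m * p_raw),
            )
        )
    return out


def comparisons_frame(comparisons: list[PlannedComparison], alpha: float = 0.05) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cond_a": [c.cond_a for c in comparisons],
            "cond_b": [c.cond_b for c in comparisons],
            "mean_diff": [c.mean_diff for c in comparisons],
            "t": [c.t for c in comparisons],
            "p_raw": [c.p_raw for c in comparisons],
            "p_adjusted": [c.p_adjusted for c in comparisons],
            "significant": [c.p_adjusted < alpha for c in comparisons],
        }
    )


def baseline_drift_check(df: pd.DataFrame, subject="subject", order="session_order",
                         value="value") -> AnovaResult:
    """RM-ANOVA with session order as the within-subject factor.

    Applied to baseline-period outcomes (PPI, evoked dB, ongoing power) to
    test for habituation or sensitisation over repeated testing; degrees of
    freedom follow the table actually supplied.
    """
    table = condition_table(df, subject=subject, condition=order, value=value)
    return rm_anova_oneway(table)
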