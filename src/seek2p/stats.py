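"""Statistical reporting layer: two-way ANOVA with Sidak post-hocs,
chi-squared tests on ensemble proportions, and paired t-tests.

Thin, convention-fixing wrappers over statsmodels/scipy so every comparison
in the analysis scripts runs through one audited code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "AnovaTable",
    "two_way_anova",
    "sidak_adjust",
    "chi_squared_test",
    "paired_t",
]


@dataclass
class AnovaTable:
    """F, df and p per main effect and interaction."""

    table: pd.DataFrame  # index: factorA, factorB, interaction; cols F, df, p

    def effect(self, name: str) -> pd.Series:
        return self.table.loc[name]


def two_way_anova(
    values,
    factor_a,
    factor_b,
    repeated: bool = False,
    subject=None,
) -> AnovaTable:
    """Two-way ANOVA with interaction via the standard OLS decomposition.

    ``repeated=True`` adds the subject as a blocking factor (subject-blocked
    decomposition; no sphericity correction). Degenerate cases follow the
    conventions: an effect with zero sum of squares gets F = 0, p = 1; a
    nonzero effect over a zero residual mean square gets F = inf, p = 0.
    """
    df = pd.DataFrame(
        {"value": np.asarray(values, dtype=float), "A": factor_a, "B": factor_b}
    )
    for fac in ("A", "B"):
        if df[fac].nunique() < 2:
            raise ValueError(f"factor {fac} must have >= 2 levels")
    formula = "value ~ C(A) * C(B)"
    if repeated:
        if subject is None:
            raise ValueError("repeated-measures ANOVA needs a subject vector")
        df["subject"] = subject
        formula += " + C(subject)"
    fit = smf.ols(formula, data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=2)

    ms_res = aov.loc["Residual", "sum_sq"] / max(aov.loc["Residual", "df"], 1)
    rows = {}
    name_map = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    for src, label in name_map.items():
        ss = aov.loc[src, "sum_sq"]
        d = aov.loc[src, "df"]
        if ss <= 1e-12:
            F, p = 0.0, 1.0
        elif ms_res <= 1e-12:
            F, p = np.inf, 0.0
        else:
            F = (ss / d) / ms_res
            p = float(sps.f.sf(F, d, aov.loc["Residual", "df"]))
        rows[label] = {"F": F, "df1": d, "df2": aov.loc["Residual", "df"], "p": p}
    return AnovaTable(pd.DataFrame(rows).T[["F", "df1", "df2", "p"]])


def sidak_adjust(p_values) -> np.ndarray:
    """Sidak multiple-comparison adjustment: p_adj = 1 - (1 - p)^m."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def chi_squared_test(table) -> tuple[float, int, float]:
    """Pearson chi-squared on a groups x categories count table (no
    continuity correction); df = (rows-1)(cols-1)."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("counts must be >= 0")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal row/column")
    chi2, p, dof, _ = sps.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)


def paired_t(x, y) -> tuple[float, int, float]:
    """Two-tailed paired Student's t-test; returns (t, df, p).

    Zero-variance differences with a nonzero mean are reported with the
    infinite-t convention (p -> 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired t-test needs two equal-length samples of size >= 2")
    d = x - y
    n = d.size
    if np.std(d, ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), n - 1, float(p)
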