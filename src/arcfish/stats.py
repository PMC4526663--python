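"""Group comparisons and correlations for SiSc and densitometry tables.

Classical fixed-effects tools matching the study design: one-way ANOVA
with Fisher-LSD or Bonferroni post hocs, balanced two-way ANOVA with
interaction, Pearson correlation, and the paired t test.  p-values are
descriptive; no correction is applied across ROIs unless the
Benjamini-Hochberg helper is requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TestResult",
    "one_way_anova",
    "two_way_anova",
    "pearson",
    "paired_t",
    "bh_adjust",
]


@dataclass(frozen=True)
class TestResult:
    """One test's outcome: statistic, degrees of freedom, p, extras.

    ``terms`` (two-way ANOVA) has one row per model term; ``posthoc``
    (one-way ANOVA) has one row per pairwise comparison with raw and
    adjusted p.
    """

    name: str
    statistic: float
    df: tuple[float, float]
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    terms: Optional[pd.DataFrame] = None


def _groups(table: pd.DataFrame, factor: str, value: str) -> dict:
    if factor not in table.columns or value not in table.columns:
        raise ValueError(f"table must have columns {value!r} and {factor!r}")
    out = {}
    for level, sub in table.groupby(factor, sort=True):
        v = np.asarray(sub[value], dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in level {level!r}")
        out[level] = v
    return out


def one_way_anova(table: pd.DataFrame, factor: str, value: str = "value",
                  posthoc: str = "none") -> TestResult:
    """Classical one-way fixed-effects ANOVA with optional post hocs.

    ``posthoc``: "fisher_lsd" (pairwise t on the pooled within-group MSE,
    unadjusted), "bonferroni" (same t, p multiplied by the number of
    comparisons and capped at 1), or "none".
    """
    groups = _groups(table, factor, value)
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 factor levels")
    for level, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"level {level!r} has fewer than 2 units")
    arrays = list(groups.values())
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    F, p = sps.f_oneway(*arrays)
    df = (k - 1, n_total - k)

    ph = None
    if posthoc not in ("none", "fisher_lsd", "bonferroni"):
        raise ValueError(f"unknown posthoc {posthoc!r}")
    if posthoc != "none":
        # pooled within-group mean square (the LSD error term)
        ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
        mse = ssw / df[1]
        levels = list(groups)
        m = k * (k - 1) // 2
        rows = []
        for a, b in combinations(levels, 2):
            va, vb = groups[a], groups[b]
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            t = (va.mean() - vb.mean()) / se if se > 0 else np.inf
            p_raw = 2 * sps.t.sf(abs(t), df[1])
            p_adj = min(1.0, m * p_raw) if posthoc == "bonferroni" else p_raw
            rows.append({"comparison": f"{a} vs {b}", "t": t,
                         "p_raw": p_raw, "p_adj": p_adj})
        ph = pd.DataFrame(rows)
    return TestResult(name=f"one-way ANOVA ({factor})", statistic=float(F),
                      df=df, p_value=float(p), posthoc=ph)


def two_way_anova(table: pd.DataFrame, factor_a: str, factor_b: str,
                  value: str = "value") -> TestResult:
    """Balanced two-way fixed-effects ANOVA with interaction.

    Classical decomposition for a complete crossed design with equal cell
    sizes (>= 2 replicates per cell); unbalanced or incomplete designs
    raise.  Returns a ``terms`` table with F, df and p for both main
    effects and the interaction; the headline statistic is the
    interaction term.
    """
    for col in (factor_a, factor_b, value):
        if col not in table.columns:
            raise ValueError(f"table lacks column {col!r}")
    # a constant factor contributes no variance: the design collapses to a
    # one-way layout and the other factor's F must match one_way_anova
    if table[factor_b].nunique() == 1:
        ow = one_way_anova(table, factor_a, value=value)
        terms = pd.DataFrame([{"term": factor_a, "ss": np.nan, "df1": ow.df[0],
                               "df2": ow.df[1], "F": ow.statistic, "p": ow.p_value}])
        return TestResult(name=f"two-way ANOVA ({factor_a} x {factor_b}; "
                               f"{factor_b} constant)",
                          statistic=ow.statistic, df=ow.df, p_value=ow.p_value,
                          terms=terms)
    if table[factor_a].nunique() == 1:
        return two_way_anova(table, factor_b, factor_a, value=value)
    piv = table.groupby([factor_a, factor_b])[value]
    sizes = piv.size()
    a_levels = table[factor_a].nunique()
    b_levels = table[factor_b].nunique()
    if len(sizes) != a_levels * b_levels:
        raise ValueError("incomplete design: some factor-level cells are empty")
    if sizes.nunique() != 1:
        raise ValueError("unbalanced design not supported; equalize cell sizes")
    r = int(sizes.iloc[0])
    if r < 2:
        raise ValueError("need >= 2 replicates per cell to estimate error")

    y = np.asarray(table[value], dtype=float)
    grand = y.mean()
    cell_means = piv.mean()
    a_means = table.groupby(factor_a)[value].mean()
    b_means = table.groupby(factor_b)[value].mean()

    ss_a = r * b_levels * ((a_means - grand) ** 2).sum()
    ss_b = r * a_levels * ((b_means - grand) ** 2).sum()
    ss_cells = r * ((cell_means - grand) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((y - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells

    df_a, df_b = a_levels - 1, b_levels - 1
    df_ab = df_a * df_b
    df_err = a_levels * b_levels * (r - 1)
    rows = []
    for term, ss, dfn in ((factor_a, ss_a, df_a), (factor_b, ss_b, df_b),
                          (f"{factor_a}:{factor_b}", ss_ab, df_ab)):
        ms = ss / dfn
        mse = ss_err / df_err
        F = ms / mse if mse > 0 else (0.0 if ms == 0 else np.inf)
        p = float(sps.f.sf(F, dfn, df_err)) if np.isfinite(F) else 0.0
        rows.append({"term": term, "ss": ss, "df1": dfn, "df2": df_err, "F": F, "p": p})
    terms = pd.DataFrame(rows)
    inter = terms.iloc[2]
    return TestResult(name=f"two-way ANOVA ({factor_a} x {factor_b})",
                      statistic=float(inter["F"]), df=(float(inter["df1"]), float(inter["df2"])),
                      p_value=float(inter["p"]), terms=terms)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Sample Pearson correlation with a two-sided t-based p; returns (r, p, n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), n


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Paired t test on the within-unit differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 2:
        raise ValueError("paired t needs >= 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise ValueError("zero-variance differences: paired t undefined")
    t, p = sps.ttest_rel(x, y)
    return TestResult(name="paired t", statistic=float(t),
                      df=(float(len(x) - 1), 0.0), p_value=float(p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (opt-in across-ROI correction)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]
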