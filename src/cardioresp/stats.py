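"""Group-level statistical battery over per-subject condition means.

Mirrors the branching the study design calls for: Shapiro-Wilk normality and
Mauchly sphericity checks decide between the parametric route (one-way
repeated-measures ANOVA, Greenhouse-Geisser corrected when sphericity fails,
paired-t post hocs) and the nonparametric route (Friedman omnibus, Wilcoxon
signed-rank post hocs), always with Bonferroni correction over the
k(k-1)/2 pairwise family.  Trial-level analyses (the 2x2 half-label design
inside double-transition trials, and the first-test-trial restriction) use a
two-way fixed-effects ANOVA with pooled-SD t post hocs and the
Kruskal-Wallis test with exact rank-sum pairwise comparisons respectively.

The frequency analyses ask where in the trial taxonomy high positive RRI
velocity concentrates (per-subject rate of ``high_pos`` trials within each
half condition) and where late EI transitions concentrate across velocity
bins (rate of ``eit_half == 2nd`` within each bin).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sst


@dataclass
class TestResult:
    """One statistical test: omnibus statistic, dfs, p, and post hocs."""

    name: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    correction: str = ""
    epsilon: float | None = None
    posthoc: list[dict] = field(default_factory=list)
    notes: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "correction": self.correction,
            "epsilon": self.epsilon,
            "posthoc": self.posthoc,
            "notes": self.notes,
        }


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, p * m))


def _complete_wide(means: pd.DataFrame, value: str = "mean_z") -> pd.DataFrame:
    """Subjects x conditions matrix, complete cases only."""
    wide = means.pivot(index="subject", columns="condition", values=value)
    return wide.dropna(axis=0)


def normality_and_sphericity(wide: pd.DataFrame) -> list[TestResult]:
    """Shapiro-Wilk per condition plus the Mauchly sphericity test.

    The flags these produce drive the parametric/nonparametric branch and
    the Greenhouse-Geisser correction downstream.
    """
    out = []
    for col in wide.columns:
        x = wide[col].to_numpy()
        if np.ptp(x) == 0:
            out.append(
                TestResult(f"shapiro[{col}]", np.nan, (len(x),), np.nan, notes="constant data")
            )
            continue
        w, p = sst.shapiro(x)
        out.append(TestResult(f"shapiro[{col}]", float(w), (len(x),), float(p)))
    if wide.shape[1] >= 3:
        sph = pg.sphericity(wide)
        out.append(
            TestResult(
                "mauchly",
                float(sph.W),
                (float(sph.dof),),
                float(sph.pval),
                notes="chi2={:.4g}".format(float(sph.chi2)),
            )
        )
    return out


def is_normal(wide: pd.DataFrame, alpha: float = 0.05) -> bool:
    """True when no condition's Shapiro-Wilk test rejects at ``alpha``."""
    ps = [r.p_value for r in normality_and_sphericity(wide) if r.name.startswith("shapiro")]
    return all(np.isnan(p) or p >= alpha for p in ps)


def friedman_with_wilcoxon_posthoc(wide: pd.DataFrame, alpha: float = 0.05) -> TestResult:
    """Friedman omnibus over k >= 3 related conditions; Wilcoxon post hocs.

    Post hoc signed-rank tests over all k(k-1)/2 pairs run when the omnibus
    is significant at ``alpha``, Bonferroni-corrected by the family size.
    For k = 2 a single Wilcoxon test is returned directly.
    """
    cols = list(wide.columns)
    k = len(cols)
    if k < 2:
        raise ValueError("need at least two conditions")
    if k == 2:
        stat, p = sst.wilcoxon(wide[cols[0]], wide[cols[1]])
        return TestResult("wilcoxon", float(stat), (len(wide),), float(p))
    if all(np.allclose(wide[c], wide[cols[0]]) for c in cols):
        return TestResult("friedman", 0.0, (float(k - 1),), 1.0, notes="identical conditions")
    stat, p = sst.friedmanchisquare(*[wide[c].to_numpy() for c in cols])
    res = TestResult("friedman", float(stat), (float(k - 1),), float(p))
    if p < alpha:
        m = k * (k - 1) // 2
        for a, b in itertools.combinations(cols, 2):
            diff = wide[a].to_numpy() - wide[b].to_numpy()
            if np.allclose(diff, 0):
                res.posthoc.append(dict(pair=(a, b), statistic=np.nan, p_raw=1.0, p_bonf=1.0))
                continue
            w, pw = sst.wilcoxon(wide[a], wide[b])
            res.posthoc.append(
                dict(pair=(a, b), statistic=float(w), p_raw=float(pw), p_bonf=_bonferroni(pw, m))
            )
        res.correction = f"bonferroni m={m}"
    return res


def rm_anova_gg(wide: pd.DataFrame, alpha: float = 0.05, force_gg: bool | None = None) -> TestResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser handling.

    The GG-corrected p-value (and epsilon-deflated dfs) is reported when the
    Mauchly test rejects sphericity at ``alpha`` (or always/never when
    ``force_gg`` is set).  Paired-t post hocs with Bonferroni correction run
    when the omnibus is significant.
    """
    cols = list(wide.columns)
    k = len(cols)
    n = len(wide)
    if n < k:
        raise ValueError("need at least as many subjects as conditions")
    if all(np.allclose(wide[c], wide[cols[0]]) for c in cols):
        return TestResult(
            "rm_anova", 0.0, (float(k - 1), float((k - 1) * (n - 1))), 1.0,
            notes="identical conditions",
        )
    aov = pg.rm_anova(wide, correction=True, detailed=False)
    row = aov.iloc[0]

    def col(*names, default=np.nan):
        for nm in names:
            if nm in aov.columns:
                return row[nm]
        return default

    df1, df2 = float(row["ddof1"]), float(row["ddof2"])
    f = float(row["F"])
    eps_v = col("eps")
    eps = float(eps_v) if np.isfinite(eps_v) else None
    use_gg = force_gg
    if use_gg is None:
        use_gg = not bool(col("sphericity", default=True))
    p_gg = col("p_GG_corr", "p-GG-corr")
    if use_gg and np.isfinite(p_gg):
        e = eps if eps is not None else 1.0
        res = TestResult("rm_anova", f, (df1 * e, df2 * e), float(p_gg),
                         correction="greenhouse-geisser", epsilon=eps)
    else:
        res = TestResult("rm_anova", f, (df1, df2), float(col("p_unc", "p-unc")), epsilon=eps)
    if res.p_value < alpha:
        m = k * (k - 1) // 2
        for a, b in itertools.combinations(cols, 2):
            t, pt = sst.ttest_rel(wide[a], wide[b])
            res.posthoc.append(
                dict(pair=(a, b), statistic=float(t), p_raw=float(pt), p_bonf=_bonferroni(pt, m))
            )
        res.correction = (res.correction + "; " if res.correction else "") + f"bonferroni m={m}"
    return res


def choose_omnibus(wide: pd.DataFrame, alpha: float = 0.05) -> TestResult:
    """Shapiro-driven branch: RM-ANOVA when every condition looks normal,
    Friedman otherwise."""
    if is_normal(wide, alpha):
        return rm_anova_gg(wide, alpha)
    return friedman_with_wilcoxon_posthoc(wide, alpha)


def two_way_anova_trials(
    z: pd.Series, factor_a: pd.Series, factor_b: pd.Series, alpha: float = 0.05
) -> tuple[TestResult, TestResult]:
    """Two-way fixed-effects ANOVA on trial-level z values (2x2 half design).

    Returns one :class:`TestResult` per main effect; post hocs (pooled-SD t
    tests over the four cells, Bonferroni m=6) are attached to the first.
    Raises on empty cells.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"z": z, "a": factor_a, "b": factor_b}).dropna()
    counts = df.groupby(["a", "b"], observed=True).size()
    if len(counts) < 4 or counts.min() == 0:
        raise ValueError("two-way design has an empty cell")
    if np.ptp(df["z"].to_numpy()) == 0:
        dfr = float(len(df) - 4)
        r = TestResult("two_way_anova[A]", 0.0, (1.0, dfr), 1.0, notes="constant response")
        return r, TestResult("two_way_anova[B]", 0.0, (1.0, dfr), 1.0, notes="constant response")
    model = smf.ols("z ~ C(a) * C(b)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(model.df_resid)
    res = []
    for name, label in (("C(a)", "A"), ("C(b)", "B")):
        res.append(
            TestResult(
                f"two_way_anova[{label}]",
                float(table.loc[name, "F"]),
                (float(table.loc[name, "df"]), df_resid),
                float(table.loc[name, "PR(>F)"]),
            )
        )
    # pooled-SD pairwise t tests over the 4 cells
    cells = {f"{a}+{b}": g["z"].to_numpy() for (a, b), g in df.groupby(["a", "b"], observed=True)}
    pooled_var = float(
        sum(((v - v.mean()) ** 2).sum() for v in cells.values())
        / (len(df) - len(cells))
    )
    sp = np.sqrt(pooled_var)
    dfp = len(df) - len(cells)
    m = len(cells) * (len(cells) - 1) // 2
    for (na, va), (nb, vb) in itertools.combinations(cells.items(), 2):
        t = (va.mean() - vb.mean()) / (sp * np.sqrt(1 / len(va) + 1 / len(vb)))
        p = 2 * sst.t.sf(abs(t), dfp)
        res[0].posthoc.append(
            dict(pair=(na, nb), statistic=float(t), p_raw=float(p), p_bonf=_bonferroni(p, m))
        )
    res[0].correction = f"pooled-sd t, bonferroni m={m}"
    return res[0], res[1]


def kruskal_with_ranksum_posthoc(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> TestResult:
    """Kruskal-Wallis over trial-level values with exact rank-sum post hocs.

    Used for the first-test-trial restriction, where trials (not subject
    means) are the unit of analysis.
    """
    df = pd.DataFrame({"v": values, "g": groups}).dropna()
    labels = sorted(df["g"].unique())
    samples = [df.loc[df["g"] == lab, "v"].to_numpy() for lab in labels]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    stat, p = sst.kruskal(*samples)
    res = TestResult("kruskal", float(stat), (float(len(samples) - 1),), float(p))
    if p < alpha:
        m = len(samples) * (len(samples) - 1) // 2
        for (la, a), (lb, b) in itertools.combinations(zip(labels, samples), 2):
            method = "exact" if (len(a) <= 25 and len(b) <= 25) else "asymptotic"
            u, pu = sst.mannwhitneyu(a, b, alternative="two-sided", method=method)
            res.posthoc.append(
                dict(pair=(la, lb), statistic=float(u), p_raw=float(pu), p_bonf=_bonferroni(pu, m))
            )
        res.correction = f"rank-sum, bonferroni m={m}"
    return res


# ---------------------------------------------------------------------------
# frequency analyses


def frequency_table(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject frequency rates linking velocity bins and half conditions.

    Returns ``(by_half, by_bin)``: the rate of ``high_pos`` velocity trials
    within each half condition, and the rate of late-EI (``eit_half == 2nd``)
    trials within each velocity bin.  Denominators are recorded.
    """
    from .classify import half_condition

    t = trials.copy()
    t["half_cond"] = half_condition(t)
    rows_a = []
    sub = t[t["half_cond"].notna() & t["delta_rri_bin"].notna()]
    for (subject, cell), g in sub.groupby(["subject", "half_cond"], sort=True):
        rows_a.append(
            dict(
                subject=subject,
                condition=cell,
                rate=float((g["delta_rri_bin"] == "high_pos").mean()),
                n=int(len(g)),
            )
        )
    rows_b = []
    sub_b = t[t["delta_rri_bin"].notna()]
    for (subject, cell), g in sub_b.groupby(["subject", "delta_rri_bin"], sort=True):
        rows_b.append(
            dict(
                subject=subject,
                condition=cell,
                rate=float((g["eit_half"] == "2nd").mean()),
                n=int(len(g)),
            )
        )
    return pd.DataFrame(rows_a), pd.DataFrame(rows_b)


def frequency_analysis(trials: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Frequency tables plus their repeated-measures tests.

    Each table is pivoted to subjects x conditions (complete cases) and
    analysed by GG-aware repeated-measures ANOVA with paired-t post hocs.
    """
    by_half, by_bin = frequency_table(trials)
    out = {"by_half": by_half, "by_bin": by_bin}
    for key, tab in (("test_by_half", by_half), ("test_by_bin", by_bin)):
        wide = tab.pivot(index="subject", columns="condition", values="rate").dropna(axis=0)
        out[key] = rm_anova_gg(wide, alpha) if len(wide) >= max(3, wide.shape[1]) else None
        out[key + "_n"] = int(len(wide))
    return out
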