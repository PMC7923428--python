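"""Statistical layer: summaries, t-tests, ANOVA, Tukey HSD, Welch ANOVA.

Also packages the published per-participant fixation-duration table (total
fixation seconds per AOI within the 15 s analysis segments, split into
segments containing static vs dynamic billboards, for ten participants of
whom numbers 1 and 3 were primed on the purpose of the experiment) and
reproduces its analyses: per-column mean / sample SD / standard error for
all and for non-primed participants, paired t-tests comparing dynamic
against static segments per AOI, and the AOI time-share percentages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

AOI_COLUMNS = {
    "white_space": ("dynamic_white_space", "static_white_space"),
    "speedometer": ("dynamic_speedometer", "static_speedometer"),
    "billboard": ("dynamic_billboard", "static_billboard"),
    "speed_sign": ("dynamic_speed_sign", "static_speed_sign"),
}


@dataclass
class TestResult:
    """A test statistic with its degrees of freedom and p-value."""

    statistic: float
    df: tuple[float, ...]
    pvalue: float
    family: str
    group_means: dict = field(default_factory=dict)
    undefined: bool = False

    def __str__(self) -> str:  # e.g. "t(7) = 4.41 (p = 0.003)"
        letter = {"paired_t": "t", "welch_anova": "F", "anova": "F"}.get(
            self.family, "stat")
        dfs = ", ".join(f"{d:g}" if float(d).is_integer() else f"{d:.2f}"
                        for d in self.df)
        if self.undefined:
            return f"{letter}({dfs}) undefined"
        return f"{letter}({dfs}) = {self.statistic:.2f} (p = {self.pvalue:.3g})"


def summarize(values) -> tuple[float, float, float]:
    """Mean, sample SD (n-1 denominator) and standard error SD/sqrt(n).

    With a single value the SD and SE are unavailable (NaN).
    """
    a = np.asarray(values, dtype=float)
    if a.size < 1:
        raise ValueError("summarize requires at least one value")
    mean = float(a.mean())
    if a.size < 2:
        return mean, math.nan, math.nan
    sd = float(a.std(ddof=1))
    return mean, sd, sd / math.sqrt(a.size)


def paired_t(sample_a, sample_b) -> TestResult:
    """Paired two-sample t-test: t = mean(d) / (SD(d)/sqrt(n)), df = n-1.

    A zero difference variance yields a flagged undefined result.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("paired_t needs two equal-length samples, n >= 2")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    means = {"a": float(a.mean()), "b": float(b.mean())}
    if sd == 0:
        return TestResult(math.nan, (n - 1,), math.nan, "paired_t",
                          means, undefined=True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return TestResult(t, (n - 1,), p, "paired_t", means)


def anova_two_way(data: pd.DataFrame, value: str, factor_a: str,
                  factor_b: str) -> dict[str, TestResult]:
    """Fixed-effects two-way ANOVA with interaction on a (near-)balanced
    cell table; observations are typically per-participant cell means.

    Degrees of freedom are (levels-1) per main effect, their product for
    the interaction, and N - (cells) for the residual.  Raises on empty
    cells, naming the cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = data[[value, factor_a, factor_b]].dropna().copy()
    counts = df.groupby([factor_a, factor_b], observed=True).size()
    la = df[factor_a].nunique()
    lb = df[factor_b].nunique()
    if len(counts) < la * lb:
        have = set(counts.index)
        for a in df[factor_a].unique():
            for b in df[factor_b].unique():
                if (a, b) not in have:
                    raise ValueError(f"empty cell ({a}, {b}) in two-way ANOVA")
    df = df.rename(columns={value: "_y", factor_a: "_fa", factor_b: "_fb"})
    model = ols("_y ~ C(_fa) * C(_fb)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    df_resid = float(table.loc["Residual", "df"])
    out = {}
    for row, key in (("C(_fa)", factor_a), ("C(_fb)", factor_b),
                     ("C(_fa):C(_fb)", f"{factor_a}:{factor_b}")):
        out[key] = TestResult(float(table.loc[row, "F"]),
                              (float(table.loc[row, "df"]), df_resid),
                              float(table.loc[row, "PR(>F)"]), "anova")
    return out


@dataclass
class TukeyComparison:
    group_a: str
    group_b: str
    difference: float
    q: float
    p_adjusted: float


def tukey_hsd(means: dict[str, float], ms_error: float, df_error: float,
              group_sizes: dict[str, int]) -> list[TukeyComparison]:
    """Tukey HSD pairwise comparisons from ANOVA cell means.

    The q statistic is |diff| / sqrt(MSE/2 * (1/n_i + 1/n_j)); adjusted
    p-values come from the studentized range distribution with k groups
    and the ANOVA error degrees of freedom.  Unequal group sizes use the
    Tukey-Kramer form of the standard error.
    """
    names = sorted(means)
    k = len(names)
    if k < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = names[i], names[j]
            se = math.sqrt(ms_error / 2.0 *
                           (1.0 / group_sizes[a] + 1.0 / group_sizes[b]))
            diff = means[a] - means[b]
            q = abs(diff) / se if se > 0 else math.inf
            p = float(sps.studentized_range.sf(q, k, df_error))
            out.append(TukeyComparison(a, b, diff, q, min(max(p, 0.0), 1.0)))
    return out


def welch_anova(groups: dict[str, np.ndarray]) -> TestResult:
    """Welch's heteroscedastic one-way ANOVA.

    With weights w_i = n_i / s_i^2 and weighted grand mean m, the statistic
    is  F = [sum_i w_i (m_i - m)^2 / (k-1)] / [1 + 2(k-2)/(k^2-1) A]
    where A = sum_i (1 - w_i/sum w)^2 / (n_i - 1), with df1 = k-1 and the
    Welch-Satterthwaite df2 = (k^2 - 1) / (3 A).
    """
    names = sorted(groups)
    k = len(names)
    if k < 2:
        raise ValueError("welch_anova needs at least 2 groups")
    n = np.array([len(groups[g]) for g in names], dtype=float)
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    m = np.array([np.mean(groups[g]) for g in names])
    s2 = np.array([np.var(groups[g], ddof=1) for g in names])
    means = dict(zip(names, m.tolist()))
    if (s2 == 0).any():
        return TestResult(math.nan, (k - 1, math.nan), math.nan,
                          "welch_anova", means, undefined=True)
    w = n / s2
    mw = float((w * m).sum() / w.sum())
    a = float((((1 - w / w.sum()) ** 2) / (n - 1)).sum())
    num = float((w * (m - mw) ** 2).sum() / (k - 1))
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1) * a
    f = num / den
    df2 = (k ** 2 - 1) / (3.0 * a)
    p = float(sps.f.sf(f, k - 1, df2))
    return TestResult(f, (k - 1, df2), p, "welch_anova", means)


# ---------------------------------------------------------------------------
# Packaged fixation-duration table

def load_table3() -> pd.DataFrame:
    """The packaged per-participant fixation-duration table.

    Columns: participant, age group, driving experience (years),
    distraction count (dynamic billboards fixated after their change),
    primed flag, and total fixation seconds for dynamic/static segments
    across the four AOIs.
    """
    path = resources.files("efrp").joinpath("data/table3.csv")
    with path.open() as fh:
        return pd.read_csv(fh, dtype={"age_group": str,
                                      "driving_experience": str})


_NUMERIC = ["distraction_count",
            "dynamic_white_space", "static_white_space",
            "dynamic_speedometer", "static_speedometer",
            "dynamic_billboard", "static_billboard",
            "dynamic_speed_sign", "static_speed_sign"]


@dataclass
class Table3Report:
    """All derived quantities of the fixation-duration analysis."""

    summary_all: pd.DataFrame        # mean/sd/se rows over all participants
    summary_unprimed: pd.DataFrame   # same over non-primed participants
    t_tests: dict[str, TestResult]   # per AOI: dynamic vs static, non-primed
    percentages: dict[str, float]    # AOI share of total fixation time (%)
    increase_candidates: dict[str, float]  # labelled "average increase" defs


def reproduce_table3_report(table: pd.DataFrame | None = None) -> Table3Report:
    """Recompute every aggregate of the packaged fixation table.

    * mean / sample SD / SE per numeric column, over all ten participants
      and over the eight non-primed participants;
    * paired t-tests (dynamic vs static segment totals, non-primed) for
      billboard, speed sign and speedometer dwell;
    * AOI shares of total fixation time, computed from the non-primed
      means: share(aoi) = (dynamic mean + static mean) / grand total;
    * the two candidate definitions of the "average increase" of dynamic
      over static billboard dwell (ratio of means - 1, and difference
      relative to the dynamic mean), printed for reference only.
    """
    t = table if table is not None else load_table3()
    unprimed = t[t["primed"] == 0]

    def block(sub: pd.DataFrame) -> pd.DataFrame:
        rows = {}
        for col in _NUMERIC:
            rows[col] = summarize(sub[col].to_numpy(float))
        return pd.DataFrame(rows, index=["mean", "sd", "se"])

    t_tests = {
        aoi: paired_t(unprimed[dyn_col].to_numpy(float),
                      unprimed[stat_col].to_numpy(float))
        for aoi, (dyn_col, stat_col) in AOI_COLUMNS.items()
        if aoi != "white_space"
    }
    means_u = {col: float(unprimed[col].mean()) for col in _NUMERIC}
    aoi_sums = {aoi: means_u[d] + means_u[s]
                for aoi, (d, s) in AOI_COLUMNS.items()}
    grand = sum(aoi_sums.values())
    pct = {aoi: 100.0 * v / grand for aoi, v in aoi_sums.items()}
    pct["speed_control"] = pct["speedometer"] + pct["speed_sign"]

    bd = means_u["dynamic_billboard"]
    bs = means_u["static_billboard"]
    increase = {
        "ratio_of_means_minus_1_pct": 100.0 * (bd / bs - 1.0),
        "difference_over_dynamic_pct": 100.0 * (bd - bs) / bd,
    }
    return Table3Report(block(t), block(unprimed), t_tests, pct, increase)


def format_table3_report(report: Table3Report) -> str:
    lines = ["Fixation-duration analysis (packaged participant table)", ""]
    lines.append("Aggregates over all participants:")
    lines.append(report.summary_all.round(2).to_string())
    lines.append("")
    lines.append("Aggregates over non-primed participants:")
    lines.append(report.summary_unprimed.round(2).to_string())
    lines.append("")
    lines.append("Paired t-tests, dynamic vs static segments (non-primed):")
    for aoi, res in report.t_tests.items():
        lines.append(f"  {aoi:12s} {res}")
    lines.append("")
    lines.append("AOI share of total fixation time (non-primed means):")
    for aoi in ("white_space", "speedometer", "billboard", "speed_sign",
                "speed_control"):
        lines.append(f"  {aoi:13s} {report.percentages[aoi]:5.1f} %")
    lines.append("")
    lines.append("Candidate definitions of the dynamic-over-static billboard "
                 "dwell increase (reference only):")
    for k, v in report.increase_candidates.items():
        lines.append(f"  {k:28s} {v:5.1f} %")
    return "\n".join(lines)
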