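"""Group-comparison statistics for cuticle thickness and g_min datasets.

The battery mirrors common practice in plant ecophysiology: a two-way
factorial ANOVA (exposure site x leaf side) with Tukey HSD pairwise
comparisons and Levene / Shapiro-Wilk assumption checks on the residuals;
two-group comparisons gated by a Kolmogorov-Smirnov normality check
(t-test when normal, Mann-Whitney U otherwise); and Kruskal-Wallis across
temperature groups with a Dunn post-hoc (Holm-adjusted) rendered as a
compact letter display.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "ThicknessDataset",
    "TestReport",
    "group_summary",
    "two_way_anova_tukey",
    "compare_two_groups",
    "kruskal_wallis",
    "compact_letter_display",
]


@dataclass
class ThicknessDataset:
    """Long-format cuticle-thickness records: site (N|S), side, thickness (um)."""

    records: pd.DataFrame  # columns: site, side, thickness

    def __post_init__(self) -> None:
        required = {"site", "side", "thickness"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        if (self.records["thickness"] <= 0).any():
            raise ValueError("thickness values must be positive")

    def group_summaries(self, by=("site", "side")) -> pd.DataFrame:
        return group_summary(self.records, "thickness", list(by))


@dataclass
class TestReport:
    """Outcome of one statistical procedure."""

    test_name: str
    statistic: float
    p_value: float
    group_summaries: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "test_name": self.test_name,
            "statistic": self.statistic,
            "p_value": self.p_value,
        }
        if self.group_summaries is not None:
            out["group_summaries"] = self.group_summaries.to_dict(orient="records")
        if self.pairwise is not None:
            out["pairwise"] = self.pairwise.to_dict(orient="records")
        out.update(
            {k: v for k, v in self.details.items() if not isinstance(v, pd.DataFrame)}
        )
        return out


def group_summary(df: pd.DataFrame, value: str, by: list[str]) -> pd.DataFrame:
    """Mean, SD, n, SE and 95% t-based CI per group."""
    rows = []
    for keys, sub in df.groupby(by, observed=True):
        if not isinstance(keys, tuple):
            keys = (keys,)
        v = sub[value].to_numpy(dtype=float)
        n = len(v)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if n > 1 else 0.0
        se = sd / np.sqrt(n) if n > 0 else np.nan
        tcrit = sps.t.ppf(0.975, n - 1) if n > 1 else np.nan
        rows.append(
            dict(zip(by, keys))
            | {
                "mean": mean,
                "sd": sd,
                "n": n,
                "se": se,
                "ci_lower": mean - tcrit * se if n > 1 else np.nan,
                "ci_upper": mean + tcrit * se if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-way ANOVA + Tukey HSD
# ---------------------------------------------------------------------------

def two_way_anova_tukey(
    data: ThicknessDataset, alpha: float = 0.05
) -> TestReport:
    """Factorial ANOVA (site, side, interaction) with Tukey HSD post-hoc.

    Type-II sums of squares (equivalent to the classical decomposition for
    balanced designs).  Levene's test across the four cells and the
    Shapiro-Wilk test on the residuals are reported alongside.  Tukey HSD is
    run on the four site:side cell means.
    """
    df = data.records.copy()
    cells = df.groupby(["site", "side"], observed=True).size()
    if (cells < 2).any() or len(cells) < 2:
        raise ValueError("each site x side cell needs at least 2 observations")

    model = smf.ols("thickness ~ C(site) * C(side)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    cell_label = df["site"].astype(str) + ":" + df["side"].astype(str)
    groups = [g["thickness"].to_numpy() for _, g in df.groupby(cell_label)]
    levene_stat, levene_p = sps.levene(*groups)
    shapiro_stat, shapiro_p = sps.shapiro(model.resid)

    tukey = pairwise_tukeyhsd(df["thickness"].to_numpy(), cell_label.to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(
        columns={
            "group1": "group_a",
            "group2": "group_b",
            "meandiff": "difference",
            "p-adj": "p_adjusted",
            "lower": "ci_lower",
            "upper": "ci_upper",
        }
    )

    f_site = float(table.loc["C(site)", "F"])
    p_site = float(table.loc["C(site)", "PR(>F)"])
    return TestReport(
        test_name="two_way_anova_tukey",
        statistic=f_site,
        p_value=p_site,
        group_summaries=data.group_summaries(),
        pairwise=pairwise,
        details={
            "anova_table": table,
            "F_site": f_site,
            "p_site": p_site,
            "F_side": float(table.loc["C(side)", "F"]),
            "p_side": float(table.loc["C(side)", "PR(>F)"]),
            "F_interaction": float(table.loc["C(site):C(side)", "F"]),
            "p_interaction": float(table.loc["C(site):C(side)", "PR(>F)"]),
            "levene_statistic": float(levene_stat),
            "levene_p": float(levene_p),
            "shapiro_statistic": float(shapiro_stat),
            "shapiro_p": float(shapiro_p),
        },
    )


# ---------------------------------------------------------------------------
# Two-group comparison with normality gate
# ---------------------------------------------------------------------------

def compare_two_groups(
    a, b, alpha_normality: float = 0.05, labels: tuple[str, str] = ("a", "b")
) -> TestReport:
    """t-test or Mann-Whitney U, gated by a KS normality check per group.

    Each group is tested against a normal distribution with its own sample
    mean and SD (Kolmogorov-Smirnov); when either group departs from
    normality (or is degenerate), the rank test is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")

    def _normalish(x: np.ndarray) -> bool:
        sd = x.std(ddof=1)
        if sd == 0:
            return False
        _, p = sps.kstest(x, "norm", args=(x.mean(), sd))
        return p >= alpha_normality

    normal = _normalish(a) and _normalish(b)
    if normal:
        stat, p = sps.ttest_ind(a, b, equal_var=False)
        name = "welch_t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"

    df = pd.DataFrame(
        {"group": np.r_[[labels[0]] * len(a), [labels[1]] * len(b)], "value": np.r_[a, b]}
    )
    return TestReport(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        group_summaries=group_summary(df, "value", ["group"]),
        details={"normality_assumed": normal},
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis with Dunn post-hoc letters
# ---------------------------------------------------------------------------

def _dunn_holm(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based pairwise z tests with Holm adjustment."""
    labels = list(groups)
    all_values = np.concatenate([groups[g] for g in labels])
    n = len(all_values)
    ranks = sps.rankdata(all_values)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    pos = 0
    for g in labels:
        m = len(groups[g])
        mean_rank[g] = float(ranks[pos : pos + m].mean())
        sizes[g] = m
        pos += m
    # tie correction for the variance of rank sums
    _, counts = np.unique(all_values, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (12.0 * (n - 1)) if n > 1 else 0.0

    rows = []
    for ga, gb in itertools.combinations(labels, 2):
        se = np.sqrt(
            (n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[ga] + 1.0 / sizes[gb])
        )
        z = (mean_rank[ga] - mean_rank[gb]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append({"group_a": ga, "group_b": gb, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    # Holm step-down
    order = np.argsort(df["p_raw"].to_numpy())
    m = len(df)
    adj = np.empty(m)
    running = 0.0
    for rank_i, idx in enumerate(order):
        val = (m - rank_i) * df["p_raw"].iloc[idx]
        running = max(running, val)
        adj[idx] = min(1.0, running)
    df["p_adjusted"] = adj
    return df


def compact_letter_display(
    labels: list[str], pairwise: pd.DataFrame, alpha: float = 0.05
) -> dict[str, str]:
    """Assign shared lowercase letters to groups not significantly different.

    Insertion algorithm over the adjusted-p matrix: groups connected by
    p >= alpha share a letter; any pair with p < alpha never shares one.
    """
    differ = {
        frozenset((r["group_a"], r["group_b"])): r["p_adjusted"] < alpha
        for _, r in pairwise.iterrows()
    }

    def conflict(group: str, letter_set: set[str]) -> bool:
        return any(differ.get(frozenset((group, other)), False) for other in letter_set)

    letter_sets: list[set[str]] = []
    for g in labels:
        placed = False
        for s in letter_sets:
            if not conflict(g, s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorption: every group joins every set it does not conflict with
    for s in letter_sets:
        for g in labels:
            if g not in s and not conflict(g, s):
                s.add(g)
    # drop redundant sets (subsets of another)
    keep = []
    for i, s in enumerate(letter_sets):
        if not any(s < t for j, t in enumerate(letter_sets) if j != i):
            keep.append(s)
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in labels}
    for letter, s in zip(letters, keep):
        for g in labels:
            if g in s:
                out[g] += letter
    return out


def kruskal_wallis(
    groups: dict[str, np.ndarray] | list[np.ndarray], alpha: float = 0.05
) -> TestReport:
    """Kruskal-Wallis H (tie-corrected) with Dunn/Holm letters.

    ``groups`` maps labels to samples, e.g. exposure temperature to g_min
    values from one site.
    """
    if not isinstance(groups, dict):
        groups = {str(i): np.asarray(g) for i, g in enumerate(groups)}
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2 or any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    all_vals = np.concatenate(list(groups.values()))
    if np.all(all_vals == all_vals[0]):
        raise ValueError("all observations tied across all groups")

    stat, p = sps.kruskal(*groups.values())
    pairwise = _dunn_holm(groups)
    letters = compact_letter_display(list(groups), pairwise, alpha=alpha)

    df = pd.DataFrame(
        {
            "group": np.concatenate([[k] * len(v) for k, v in groups.items()]),
            "value": all_vals,
        }
    )
    summaries = group_summary(df, "value", ["group"])
    summaries["letters"] = summaries["group"].map(letters)
    return TestReport(
        test_name="kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        group_summaries=summaries,
        pairwise=pairwise,
        details={"letters": letters},
    )
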