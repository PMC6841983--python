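"""Group comparisons: t-tests, one-way and two-way ANOVA with Tukey HSD.

The comparisons mirror the study design for regional microvascular
morphometry: an independent-samples t-test contrasts the two retinal
regions within the healthy group; one-way ANOVA with Tukey post-hoc
compares diagnostic groups on whole-retina metrics; two-way ANOVA
(region × diagnosis, Type II sums of squares on the balanced layout)
with Tukey over the six cell means resolves regional remodelling
patterns.  Post-hoc results are summarized as a compact letter display:
groups sharing a letter are not significantly different.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DesignError

METRIC_COLUMNS = ("db", "lambda_mean", "density_pct")


@dataclass(frozen=True)
class PosthocPair:
    a: str
    b: str
    p_adj: float
    significant: bool


@dataclass
class ComparisonResult:
    design: str  # "ttest" | "anova1" | "anova2"
    metric: str
    levels: list[str]
    means: dict[str, float]
    sds: dict[str, float]
    ns: dict[str, int]
    statistic: float
    p_value: float
    effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    posthoc: list[PosthocPair] = field(default_factory=list)
    letters: dict[str, str] = field(default_factory=dict)


def _summaries(df: pd.DataFrame, by: pd.Series, metric: str):
    levels = list(dict.fromkeys(by))
    means = {lv: float(df.loc[by == lv, metric].mean()) for lv in levels}
    sds = {lv: float(df.loc[by == lv, metric].std(ddof=1)) for lv in levels}
    ns = {lv: int((by == lv).sum()) for lv in levels}
    return levels, means, sds, ns


def compact_letter_display(
    levels: list[str], means: dict[str, float], sig_pairs: set[frozenset[str]]
) -> dict[str, str]:
    """Greedy insert-and-absorb compact letter display.

    Levels are processed in descending-mean order; the result is a
    deterministic function of the means and the significance matrix.
    Levels sharing a letter are not significantly different.
    """
    order = sorted(levels, key=lambda lv: (-means[lv], lv))
    columns: list[set[str]] = [set(order)]
    for a, b in combinations(order, 2):
        if frozenset((a, b)) not in sig_pairs:
            continue
        new_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_columns.append(col - {a})
                new_columns.append(col - {b})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, duplicates, and strict subsets of another column
        columns = []
        for col in new_columns:
            if not col or col in columns:
                continue
            if any(col < other for other in new_columns):
                continue
            columns.append(col)
    # letters in order of each column's best-ranked member
    columns.sort(key=lambda col: min(order.index(lv) for lv in col))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {lv: "" for lv in order}
    for i, col in enumerate(columns):
        for lv in order:
            if lv in col:
                letters[lv] += alphabet[i % len(alphabet)]
    return letters


def _tukey(values: np.ndarray, labels: np.ndarray, alpha: float) -> list[PosthocPair]:
    """Tukey HSD over group labels, robust to zero residual variance."""
    levels = list(dict.fromkeys(labels))
    groups = {lv: values[labels == lv] for lv in levels}
    mse = float(
        np.sum([np.sum((g - g.mean()) ** 2) for g in groups.values()])
        / max(sum(len(g) for g in groups.values()) - len(levels), 1)
    )
    pairs: list[PosthocPair] = []
    if mse <= 0:
        for a, b in combinations(levels, 2):
            same = np.isclose(groups[a].mean(), groups[b].mean())
            pairs.append(PosthocPair(str(a), str(b), 1.0 if same else 0.0, not same))
        return pairs
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    for (a, b), p, rej in zip(
        combinations(res.groupsunique, 2), res.pvalues, res.reject
    ):
        pairs.append(PosthocPair(str(a), str(b), float(p), bool(rej)))
    return pairs


def _finalize_posthoc(
    result: ComparisonResult, values: np.ndarray, labels: np.ndarray, alpha: float
) -> None:
    result.posthoc = _tukey(values, labels, alpha)
    sig = {frozenset((p.a, p.b)) for p in result.posthoc if p.significant}
    result.letters = compact_letter_display(result.levels, result.means, sig)


def region_ttest(
    records: pd.DataFrame, metric: str, equal_var: bool = True
) -> ComparisonResult:
    """Two-tailed independent-samples t-test between two region levels.

    ``equal_var=True`` gives the classical pooled-variance Student form;
    ``False`` gives Welch's correction.
    """
    regions = records["region"]
    levels = sorted(regions.unique())
    if len(levels) != 2:
        raise DesignError(f"t-test needs exactly 2 region levels, got {levels}")
    a = records.loc[regions == levels[0], metric].to_numpy(dtype=float)
    b = records.loc[regions == levels[1], metric].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise DesignError("each region needs n >= 2")
    if np.ptp(np.concatenate([a, b])) == 0:
        t, p = 0.0, 1.0
    else:
        t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    levels_s, means, sds, ns = _summaries(records, regions, metric)
    return ComparisonResult(
        design="ttest",
        metric=metric,
        levels=[str(lv) for lv in levels],
        means={str(k): v for k, v in means.items()},
        sds={str(k): v for k, v in sds.items()},
        ns={str(k): v for k, v in ns.items()},
        statistic=float(t),
        p_value=float(p),
    )


def _f_oneway_robust(groups: list[np.ndarray]) -> tuple[float, float]:
    grand = np.concatenate(groups)
    ss_within = float(np.sum([np.sum((g - g.mean()) ** 2) for g in groups]))
    ss_between = float(np.sum([len(g) * (g.mean() - grand.mean()) ** 2 for g in groups]))
    if ss_within <= 0:
        return (0.0, 1.0) if ss_between <= 1e-12 else (np.inf, 0.0)
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def anova_oneway(
    records: pd.DataFrame, metric: str, alpha: float = 0.05
) -> ComparisonResult:
    """One-way ANOVA over ``group`` with Tukey HSD and compact letters."""
    by = records["group"]
    levels = sorted(by.unique())
    if len(levels) < 2:
        raise DesignError(f"one-way ANOVA needs >= 2 groups, got {levels}")
    groups = [records.loc[by == lv, metric].to_numpy(dtype=float) for lv in levels]
    if any(len(g) < 2 for g in groups):
        raise DesignError("every group needs n >= 2")
    f, p = _f_oneway_robust(groups)
    _, means, sds, ns = _summaries(records, by, metric)
    result = ComparisonResult(
        design="anova1",
        metric=metric,
        levels=[str(lv) for lv in levels],
        means={str(k): v for k, v in means.items()},
        sds={str(k): v for k, v in sds.items()},
        ns={str(k): v for k, v in ns.items()},
        statistic=f,
        p_value=p,
        effects={"group": (f, p)},
    )
    _finalize_posthoc(
        result, records[metric].to_numpy(dtype=float), by.to_numpy(), alpha
    )
    return result


def anova_twoway(
    records: pd.DataFrame,
    metric: str,
    alpha: float = 0.05,
    posthoc: bool = True,
) -> ComparisonResult:
    """Two-way ANOVA (region × group) with Tukey HSD over the cell means.

    Requires the full crossed layout with n >= 2 per cell.  Type II sums
    of squares are used (identical to Type I/III on a balanced design).
    The headline statistic and p-value belong to the interaction; the main
    effects are reported in ``effects``.  Cells are labelled
    ``"<region>:<group>"`` in the post-hoc table and letter display.
    """
    regions = sorted(records["region"].unique())
    groups = sorted(records["group"].unique())
    if len(regions) < 2 or len(groups) < 2:
        raise DesignError("two-way ANOVA needs >= 2 levels on both factors")
    for r in regions:
        for g in groups:
            n = len(records[(records["region"] == r) & (records["group"] == g)])
            if n < 2:
                raise DesignError(f"cell ({r}, {g}) has n={n} < 2")
    values = records[metric].to_numpy(dtype=float)
    cell = (records["region"].astype(str) + ":" + records["group"].astype(str)).to_numpy()
    if np.ptp(values) == 0:
        effects = {"region": (0.0, 1.0), "group": (0.0, 1.0), "interaction": (0.0, 1.0)}
        f_int, p_int = 0.0, 1.0
    else:
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        data = records[["region", "group", metric]].rename(columns={metric: "y"})
        model = smf.ols("y ~ C(region) * C(group)", data=data).fit()
        table = anova_lm(model, typ=2)
        effects = {
            "region": (float(table.loc["C(region)", "F"]), float(table.loc["C(region)", "PR(>F)"])),
            "group": (float(table.loc["C(group)", "F"]), float(table.loc["C(group)", "PR(>F)"])),
            "interaction": (
                float(table.loc["C(region):C(group)", "F"]),
                float(table.loc["C(region):C(group)", "PR(>F)"]),
            ),
        }
        f_int, p_int = effects["interaction"]
    levels = list(dict.fromkeys(cell))
    means = {lv: float(values[cell == lv].mean()) for lv in levels}
    sds = {lv: float(np.std(values[cell == lv], ddof=1)) for lv in levels}
    ns = {lv: int((cell == lv).sum()) for lv in levels}
    result = ComparisonResult(
        design="anova2",
        metric=metric,
        levels=levels,
        means=means,
        sds=sds,
        ns=ns,
        statistic=f_int,
        p_value=p_int,
        effects=effects,
    )
    if posthoc:
        _finalize_posthoc(result, values, cell, alpha)
    return result


def comparison_to_rows(result: ComparisonResult) -> list[dict]:
    """Flatten a ComparisonResult into tidy CSV-ready rows."""
    rows = []
    for lv in result.levels:
        rows.append(
            {
                "design": result.design,
                "metric": result.metric,
                "kind": "level",
                "name": lv,
                "mean": result.means[lv],
                "sd": result.sds[lv],
                "n": result.ns[lv],
                "statistic": "",
                "p": "",
                "letters": result.letters.get(lv, ""),
            }
        )
    effects = result.effects or {result.design: (result.statistic, result.p_value)}
    for name, (f, p) in effects.items():
        rows.append(
            {
                "design": result.design,
                "metric": result.metric,
                "kind": "effect",
                "name": name,
                "mean": "",
                "sd": "",
                "n": "",
                "statistic": f,
                "p": p,
                "letters": "",
            }
        )
    if result.design == "ttest":
        rows.append(
            {
                "design": result.design,
                "metric": result.metric,
                "kind": "effect",
                "name": "t",
                "mean": "",
                "sd": "",
                "n": "",
                "statistic": result.statistic,
                "p": result.p_value,
                "letters": "",
            }
        )
    for pair in result.posthoc:
        rows.append(
            {
                "design": result.design,
                "metric": result.metric,
                "kind": "posthoc",
                "name": f"{pair.a} vs {pair.b}",
                "mean": "",
                "sd": "",
                "n": "",
                "statistic": "",
                "p": pair.p_adj,
                "letters": "*" if pair.significant else "",
            }
        )
    return rows
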