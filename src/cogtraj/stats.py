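"""Nonparametric group comparisons for biomarkers and risk factors.

Continuous variables are compared with the Wilcoxon rank-sum test (two
groups) or the Kruskal-Wallis test (more than two); binary factors with
Fisher's exact test (two groups) and categorical factors with the Pearson
chi-square test (multiple groups). All tests are two-sided with a 0.05
significance threshold; Benjamini-Hochberg adjustment is available but off by
default. Per-visit trajectory summaries report mean, SD, n and the 95%
confidence half-width of the mean.

The test engines are scipy's; this module fixes the conventions (midrank
ties, tie-corrected normal approximation without continuity correction so the
two-group Kruskal-Wallis agrees with the rank-sum test, exact enumeration for
small untied samples) and returns a uniform result record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "GroupComparisonResult",
    "wilcoxon_rank_sum",
    "kruskal_wallis",
    "fisher_exact",
    "chi_square",
    "trajectory_summary",
    "compare_all",
]


@dataclass
class GroupComparisonResult:
    variable: str
    test: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    effect_summary: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


def wilcoxon_rank_sum(
    x, y, variable: str = "", alternative: str = "two-sided"
) -> GroupComparisonResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Exact enumeration when the combined sample has at most 10 untied values;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so the two-group Kruskal-Wallis test agrees with it).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 10 and not ties) else "asymptotic"
    res = sst.mannwhitneyu(x, y, alternative=alternative, method=method,
                           use_continuity=False)
    return GroupComparisonResult(
        variable=variable,
        test=f"wilcoxon_rank_sum[{method}]",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=(x.size, y.size),
        effect_summary={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
    )


def kruskal_wallis(groups, variable: str = "") -> GroupComparisonResult:
    """Kruskal-Wallis H test with tie correction; p from chi-square, g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    pooled = np.concatenate(groups)
    if np.unique(pooled).size == 1:
        return GroupComparisonResult(
            variable=variable, test="kruskal_wallis", statistic=0.0, p_value=1.0,
            group_sizes=tuple(g.size for g in groups),
            effect_summary={"medians": [float(np.median(g)) for g in groups]},
        )
    res = sst.kruskal(*groups)
    return GroupComparisonResult(
        variable=variable,
        test="kruskal_wallis",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        group_sizes=tuple(g.size for g in groups),
        effect_summary={"medians": [float(np.median(g)) for g in groups]},
    )


def fisher_exact(table_2x2, variable: str = "") -> GroupComparisonResult:
    """Fisher's exact test; two-sided p by hypergeometric probability mass.

    A zero margin makes the odds ratio undefined; p = 1 with a flag.
    """
    t = np.asarray(table_2x2)
    if t.shape != (2, 2) or (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
            raise ValueError("fisher_exact needs a 2x2 table of non-negative integers")
        t = t.astype(int)
    sizes = tuple(int(s) for s in t.sum(axis=1))
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return GroupComparisonResult(
            variable=variable, test="fisher_exact", statistic=float("nan"), p_value=1.0,
            group_sizes=sizes, warnings=["zero margin: odds ratio undefined"],
            effect_summary={"odds_ratio": float("nan")},
        )
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]) if t[0, 1] * t[1, 0] > 0 else float("inf")
    res = sst.fisher_exact(t, alternative="two-sided")
    return GroupComparisonResult(
        variable=variable,
        test="fisher_exact",
        statistic=float(odds),
        p_value=float(res.pvalue),
        group_sizes=sizes,
        effect_summary={
            "odds_ratio": float(odds),
            "proportions": [t[0, 0] / sizes[0], t[1, 0] / sizes[1]],
        },
    )


def chi_square(table, variable: str = "") -> GroupComparisonResult:
    """Pearson chi-square test of independence on an r x c count table
    ((r-1)(c-1) df, no Yates correction); warns when an expected count < 5."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("chi_square needs a 2-d table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError(
            "zero row/column margin; collapse empty categories before testing"
        )
    stat, p, dof, expected = sst.chi2_contingency(t, correction=False)
    notes = []
    if (expected < 5).any():
        notes.append(f"{int((expected < 5).sum())} cells with expected count < 5")
    return GroupComparisonResult(
        variable=variable,
        test="chi_square",
        statistic=float(stat),
        p_value=float(p),
        group_sizes=tuple(int(s) for s in t.sum(axis=1)),
        effect_summary={"dof": int(dof)},
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# trajectory summaries


def trajectory_summary(values: pd.DataFrame) -> pd.DataFrame:
    """Per (group, visit) mean, SD, n and the 95% CI half-width of the mean
    (1.96 * SD / sqrt(n); undefined at n = 1).

    ``values`` needs columns group, visit_index, value.
    """
    rows = []
    for (group, visit), grp in values.groupby(["group", "visit_index"]):
        v = grp["value"].to_numpy(dtype=float)
        n = v.size
        sd = float(np.std(v, ddof=1)) if n > 1 else float("nan")
        rows.append({
            "group": group,
            "visit_index": visit,
            "mean": float(v.mean()),
            "sd": sd,
            "n": n,
            "ci_halfwidth": 1.96 * sd / np.sqrt(n) if n > 1 else float("nan"),
        })
    return pd.DataFrame(rows).sort_values(["group", "visit_index"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# batch comparisons


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    return sst.false_discovery_control(p, method="bh")


def compare_all(
    features: pd.DataFrame,
    labels: pd.Series,
    categorical: set[str] | None = None,
    merge_map: dict | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Compare every variable across the labeled groups.

    ``features``: long table (participant_id, variable, value); values may be
    numeric or category strings. ``labels``: participant -> group. With
    ``merge_map`` (e.g. {"low": [...], "high": [...]}) groups are first merged
    to two classes, switching the test family to Wilcoxon / Fisher; otherwise
    continuous variables get Kruskal-Wallis and categorical ones chi-square.
    """
    labels = labels.copy()
    if merge_map is not None:
        reverse = {g: cls for cls, gs in merge_map.items() for g in gs}
        labels = labels.map(reverse)
        if labels.isna().any():
            raise ValueError("merge map does not cover all group labels")
    df = features.merge(labels.rename("group"), left_on="participant_id",
                        right_index=True, how="inner")
    categorical = categorical or set()
    two_groups = labels.nunique() == 2
    group_order = sorted(labels.unique())

    results = []
    for var, grp in df.groupby("variable", sort=True):
        grp = grp.dropna(subset=["value"])
        numeric = pd.to_numeric(grp["value"], errors="coerce")
        is_cat = var in categorical or numeric.isna().any()
        if not is_cat:
            grp = grp.assign(value=numeric)
        try:
            if is_cat:
                counts = pd.crosstab(grp["group"], grp["value"]).reindex(group_order)
                if two_groups and counts.shape[1] == 2:
                    res = fisher_exact(counts.to_numpy(), variable=var)
                else:
                    res = chi_square(counts.to_numpy(), variable=var)
            else:
                samples = [g["value"].to_numpy(dtype=float)
                           for _, g in grp.groupby("group")]
                if two_groups:
                    res = wilcoxon_rank_sum(samples[0], samples[1], variable=var)
                else:
                    res = kruskal_wallis(samples, variable=var)
        except ValueError as exc:
            results.append({"variable": var, "test": "skipped", "statistic": np.nan,
                            "p_value": np.nan, "note": str(exc)})
            continue
        results.append({
            "variable": var,
            "test": res.test,
            "statistic": res.statistic,
            "p_value": res.p_value,
            "significant": res.significant,
            "note": "; ".join(res.warnings),
        })
    out = pd.DataFrame(results)
    if bh_adjust and not out.empty:
        ok = out["p_value"].notna()
        out.loc[ok, "p_bh"] = _bh_adjust(out.loc[ok, "p_value"].to_numpy())
        out["significant_bh"] = out.get("p_bh", np.nan) < 0.05
    return out
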