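"""Comparative-Ct qPCR quantification and group comparisons.

Relative expression per subject is 2^(-dCt) with dCt = mean target Ct minus
mean reference-gene Ct. Group fold-changes are ratios of geometric means
(equivalent to 2^(-ddCt) on mean dCt values) reported on the +/-1 signed
convention: no values inside (-1, 1), a 3.3-fold decrease prints as -3.3.
The Long/Short ratio summarizes, per group, the arithmetic mean and sample
SD of the per-subject ratio of the two splice-variant expressions.

Expression data are compared with nonparametric tests — Mann-Whitney U for
two unpaired groups, Wilcoxon signed-rank for paired within-subject
contrasts (Long vs Short), Kruskal-Wallis with Dunn/Bonferroni post hoc for
three groups — with a Kolmogorov-Smirnov normality screen reported for
information only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CtRecord",
    "ExpressionPanel",
    "GroupComparison",
    "RatioSummary",
    "delta_ct",
    "relative_expression",
    "build_panel",
    "group_fold_change",
    "long_short_ratio",
    "compare_groups",
    "dunn_posthoc",
]


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    group: str  # CTR | CAD | AMI
    target: str  # long | short | reference
    ct_replicates: tuple[float, ...]

    def __post_init__(self):
        if not self.ct_replicates:
            raise ValueError("need >= 1 Ct replicate")
        if not all(0 < c < 45 for c in self.ct_replicates):
            raise ValueError(f"{self.sample_id}/{self.target}: Ct outside (0, 45)")

    @property
    def ct_mean(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass
class ExpressionPanel:
    """Per-sample relative expression of the long and short splice variants."""

    data: pd.DataFrame  # columns: sample_id, group, long_expr, short_expr

    def __post_init__(self):
        required = {"sample_id", "group", "long_expr", "short_expr"}
        if not required <= set(self.data.columns):
            raise ValueError(f"panel needs columns {sorted(required)}")
        if (self.data[["long_expr", "short_expr"]] <= 0).any().any():
            raise ValueError("expression must be > 0")

    def group_values(self, group: str, target: str) -> np.ndarray:
        col = f"{target}_expr"
        return self.data.loc[self.data["group"] == group, col].to_numpy(float)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.data["group"]))


@dataclass(frozen=True)
class GroupComparison:
    contrast: tuple[str, str]  # (group_a, group_b)
    signed_fc: float
    p_value: float
    test_name: str


@dataclass(frozen=True)
class RatioSummary:
    per_group: dict[str, tuple[float, float]]  # group -> (mean, sample SD)


# ----------------------------------------------------------------------
def delta_ct(ct_target: float, ct_reference: float) -> float:
    """dCt = target Ct - reference-gene Ct."""
    return ct_target - ct_reference


def relative_expression(dct: float) -> float:
    """Comparative-Ct relative expression, 2^(-dCt)."""
    return 2.0 ** (-dct)


def read_ct_csv(path: str) -> list[CtRecord]:
    """Long-format CSV: sample_id, group, target, ct_rep1..ct_repK."""
    df = pd.read_csv(path)
    rep_cols = [c for c in df.columns if c.startswith("ct_rep")]
    if not rep_cols:
        raise ValueError("no ct_rep* columns found")
    return [
        CtRecord(
            str(row["sample_id"]), row["group"], row["target"],
            tuple(float(row[c]) for c in rep_cols if pd.notna(row[c])),
        )
        for _, row in df.iterrows()
    ]


def build_panel(
    records: list[CtRecord],
    long_target: str = "long",
    short_target: str = "short",
    reference_target: str = "reference",
) -> ExpressionPanel:
    """Collapse replicate Cts (arithmetic mean), normalize against the
    reference gene, and return per-sample 2^(-dCt) expressions."""
    by_sample: dict[str, dict[str, CtRecord]] = {}
    groups: dict[str, str] = {}
    for rec in records:
        by_sample.setdefault(rec.sample_id, {})[rec.target] = rec
        groups[rec.sample_id] = rec.group
    rows = []
    for sid, targets in by_sample.items():
        missing = {long_target, short_target, reference_target} - set(targets)
        if missing:
            raise ValueError(f"sample {sid} lacks target(s) {sorted(missing)}")
        ref = targets[reference_target].ct_mean
        rows.append(
            {
                "sample_id": sid,
                "group": groups[sid],
                "long_expr": relative_expression(delta_ct(targets[long_target].ct_mean, ref)),
                "short_expr": relative_expression(delta_ct(targets[short_target].ct_mean, ref)),
            }
        )
    return ExpressionPanel(pd.DataFrame(rows))


# ----------------------------------------------------------------------
def group_fold_change(
    expr_a: np.ndarray, expr_b: np.ndarray, aggregation: str = "geometric"
) -> float:
    """Signed fold-change of group a over group b.

    r = mean(a)/mean(b) with geometric means by default (arithmetic behind
    the flag); reported as r when r >= 1, else -1/r, so magnitudes are
    always >= 1.
    """
    a = np.asarray(expr_a, float)
    b = np.asarray(expr_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("expression values must be > 0")
    if aggregation == "geometric":
        r = math.exp(np.mean(np.log(a)) - np.mean(np.log(b)))
    elif aggregation == "arithmetic":
        r = a.mean() / b.mean()
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    return r if r >= 1 else -1.0 / r


def long_short_ratio(panel: ExpressionPanel) -> RatioSummary:
    """Per-group arithmetic mean and sample SD of per-subject long/short."""
    ratios = panel.data["long_expr"] / panel.data["short_expr"]
    if not np.isfinite(ratios).all():
        raise ValueError("zero short expression")
    out = {}
    for grp in panel.groups:
        vals = ratios[panel.data["group"] == grp]
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out[grp] = (float(vals.mean()), sd)
    return RatioSummary(out)


# ----------------------------------------------------------------------
def _ks_normality(values: np.ndarray) -> float:
    """One-sample KS p-value against a normal fit (advisory only)."""
    v = np.asarray(values, float)
    if v.std(ddof=1) == 0:
        return 0.0
    return float(stats.kstest(v, "norm", args=(v.mean(), v.std(ddof=1))).pvalue)


def dunn_posthoc(values_by_group: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based post hoc after Kruskal-Wallis, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with T = sum(t^3 - t) over tie groups; two-sided p multiplied by the
    number of pairwise comparisons and capped at 1.
    """
    names = list(values_by_group)
    pooled = np.concatenate([np.asarray(values_by_group[g], float) for g in names])
    ranks = stats.rankdata(pooled)
    n_total = len(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    i = 0
    for g in names:
        n = len(values_by_group[g])
        mean_rank[g] = float(ranks[i : i + n].mean())
        sizes[g] = n
        i += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    n_pairs = len(names) * (len(names) - 1) // 2
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(base_var * (1.0 / sizes[a] + 1.0 / sizes[b]))
            if se == 0:
                out[(a, b)] = 1.0
                continue
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            out[(a, b)] = min(1.0, p * n_pairs)
    return out


def compare_groups(
    values_by_group: dict[str, np.ndarray], mode: str
) -> dict:
    """Nonparametric group comparison per study conventions.

    Returns a dict with ``test_name``, ``p_value``, ``statistic``,
    ``normality_p`` (per-group KS screen, advisory), and for ``k_groups``
    additionally ``posthoc`` (Dunn/Bonferroni pairwise p-values).
    """
    groups = {g: np.asarray(v, float) for g, v in values_by_group.items()}
    for g, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {g!r} needs >= 2 values")
    normality = {g: _ks_normality(v) for g, v in groups.items()}

    if mode == "two_unpaired":
        if len(groups) != 2:
            raise ValueError("two_unpaired needs exactly 2 groups")
        x, y = groups.values()
        exact_ok = min(len(x), len(y)) <= 8 and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
        )
        return {
            "test_name": "mann-whitney",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "normality_p": normality,
        }
    if mode == "two_paired":
        if len(groups) != 2:
            raise ValueError("two_paired needs exactly 2 groups")
        x, y = groups.values()
        if len(x) != len(y):
            raise ValueError("paired mode requires equal-length matched vectors")
        if np.all(x == y):
            return {
                "test_name": "wilcoxon", "statistic": 0.0, "p_value": 1.0,
                "normality_p": normality,
            }
        res = stats.wilcoxon(x, y, alternative="two-sided")
        return {
            "test_name": "wilcoxon",
            "statistic": float(res.statistic),
            "p_value": float(res.pvalue),
            "normality_p": normality,
        }
    if mode == "k_groups":
        if len(groups) < 3:
            raise ValueError("k_groups needs >= 3 groups")
        vals = list(groups.values())
        if all(np.array_equal(vals[0], v) for v in vals[1:]) or len(
            np.unique(np.concatenate(vals))
        ) == 1:
            p, stat = 1.0, 0.0
        else:
            res = stats.kruskal(*vals)
            p, stat = float(res.pvalue), float(res.statistic)
        return {
            "test_name": "kruskal-wallis",
            "statistic": stat,
            "p_value": p,
            "posthoc": dunn_posthoc(groups),
            "normality_p": normality,
        }
    raise ValueError(f"unknown mode {mode!r}")


def group_comparisons_table(
    panel: ExpressionPanel, target: str, contrasts: list[tuple[str, str]]
) -> list[GroupComparison]:
    """Pairwise signed fold-changes with Mann-Whitney p per contrast."""
    out = []
    for a, b in contrasts:
        va, vb = panel.group_values(a, target), panel.group_values(b, target)
        fc = group_fold_change(va, vb)
        res = compare_groups({a: va, b: vb}, "two_unpaired")
        out.append(GroupComparison((a, b), fc, res["p_value"], res["test_name"]))
    return out
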