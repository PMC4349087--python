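"""Nonparametric immune-vs-control group comparisons.

Mann-Whitney U tests compare divergence statistics between independent
immune and control gene sets; paired Wilcoxon signed-rank tests compare
diversity statistics between immune genes and their position-matched
controls. Statistic conventions follow R's ``wilcox.test``: the reported U
is R's W (rank sum of the first sample minus n1(n1+1)/2, with midranks for
ties) and V is the sum of ranks of positive paired differences with zero
differences dropped. Exact p-values are used for tie-free samples up to a
combined size of 25; otherwise a normal approximation with tie and
continuity corrections applies.

P-value computation is delegated to scipy; the statistics themselves are
computed here so the R conventions hold regardless of scipy's return value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

EXACT_LIMIT = 25


@dataclass
class RankTestResult:
    statistic: float  # U (Mann-Whitney, R's W) or V (Wilcoxon signed rank)
    n1: int
    n2: int  # equals n1 (number of pairs) for the signed-rank test
    p_two_sided: float
    method: str  # "exact" or "normal-approx-with-ties"


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test with R's W statistic convention."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: x.size].sum()
    u = r1 - x.size * (x.size + 1) / 2.0
    ties = np.unique(pooled).size < pooled.size
    if not ties and x.size + y.size <= EXACT_LIMIT:
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
        method = "normal-approx-with-ties"
    return RankTestResult(float(u), int(x.size), int(y.size), p, method)


def wilcoxon_signed_rank(x, y) -> RankTestResult:
    """Two-sided paired Wilcoxon signed-rank test, V = rank sum of positive diffs.

    Zero differences are dropped (R's default); raises
    :class:`UndefinedStatisticError` when every difference is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("samples must be paired and non-empty")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedStatisticError("all paired differences are zero; V undefined")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    ties = np.unique(np.abs(d)).size < d.size
    if not ties and d.size <= EXACT_LIMIT:
        res = stats.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method="exact")
        method = "exact"
    else:
        res = stats.wilcoxon(
            d, zero_method="wilcox", alternative="two-sided", method="approx", correction=True
        )
        method = "normal-approx-with-ties"
    return RankTestResult(v, int(d.size), int(d.size), float(res.pvalue), method)


def build_pairs(summaries: pd.DataFrame, pathway: str | None = None) -> pd.DataFrame:
    """Immune/control pairing table for the paired Wilcoxon tests.

    Each immune locus with a ``paired_control`` contributes one pair; shared
    controls appear once per immune gene they are matched to, and immune loci
    without a position control are excluded. ``pathway`` optionally restricts
    to one pathway's immune genes.
    """
    immune = summaries[summaries["group"] == "immune"]
    if pathway is not None:
        immune = immune[immune["pathway"] == pathway]
    by_id = summaries.set_index("locus_id")
    rows = []
    for _, row in immune.iterrows():
        ctrl = row.get("paired_control")
        if ctrl is None or (isinstance(ctrl, float) and np.isnan(ctrl)) or ctrl == "":
            continue
        if ctrl not in by_id.index:
            continue
        rows.append({"immune_locus": row["locus_id"], "control_locus": ctrl})
    return pd.DataFrame(rows)


def compare_groups(
    summaries: pd.DataFrame,
    divergence_stats: tuple[str, ...] = ("K_total", "K_S", "K_A", "ka_ks"),
    diversity_stats: tuple[str, ...] = ("pi_total", "pi_s", "pi_a", "tajima_d"),
    pathway: str | None = None,
    control_loci: list[str] | None = None,
) -> pd.DataFrame:
    """Immune-vs-control test battery over a locus summary table.

    Divergence statistics use unpaired Mann-Whitney U on the immune vs
    control gene sets (``control_loci`` can widen the control set for
    pathway-level runs where a shared control serves several pathways);
    diversity statistics use the paired Wilcoxon over matched pairs.
    """
    immune = summaries[summaries["group"] == "immune"]
    if pathway is not None:
        immune = immune[immune["pathway"] == pathway]
    if control_loci is not None:
        control = summaries[summaries["locus_id"].isin(control_loci)]
    else:
        control = summaries[summaries["group"] == "control"]
    by_id = summaries.set_index("locus_id")
    pairs = build_pairs(summaries, pathway=pathway)
    rows = []
    for stat in divergence_stats:
        xs = immune[stat].dropna().to_numpy()
        ys = control[stat].dropna().to_numpy()
        if xs.size == 0 or ys.size == 0:
            continue
        res = mann_whitney_u(xs, ys)
        rows.append(
            {
                "statistic_name": stat, "test": "mann_whitney_u",
                "immune_mean": float(xs.mean()), "control_mean": float(ys.mean()),
                "statistic": res.statistic, "p": res.p_two_sided, "method": res.method,
                "n_immune": res.n1, "n_control": res.n2,
            }
        )
    for stat in diversity_stats:
        if pairs.empty:
            break
        xs = by_id.loc[pairs["immune_locus"], stat].to_numpy(dtype=float)
        ys = by_id.loc[pairs["control_locus"], stat].to_numpy(dtype=float)
        keep = ~(np.isnan(xs) | np.isnan(ys))
        if keep.sum() == 0:
            continue
        try:
            res = wilcoxon_signed_rank(xs[keep], ys[keep])
        except UndefinedStatisticError:
            continue
        rows.append(
            {
                "statistic_name": stat, "test": "wilcoxon_signed_rank",
                "immune_mean": float(xs[keep].mean()), "control_mean": float(ys[keep].mean()),
                "statistic": res.statistic, "p": res.p_two_sided, "method": res.method,
                "n_immune": res.n1, "n_control": res.n2,
            }
        )
    return pd.DataFrame(rows)
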