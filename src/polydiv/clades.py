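"""Haplotype-clade detection and balanced-polymorphism diagnostics.

Given a locus alignment, this module builds a neighbor-joining tree of the
alleles, calls the two-clade partition (the internal bipartition maximizing
the between/within mean-distance ratio, with user override), quantifies it
by bootstrap support, lists fixed differences between clades, computes
per-clade diversity summaries, and computes Nei's Dxy within and between
groups of sequences (clades, or clade-by-species subsets). Elevated
between-clade, cross-species Dxy relative to within-clade Dxy indicates a
polymorphism older than the species split — the signature of an ancient
balanced polymorphism.

Distances use the p-distance or its Jukes-Cantor correction (JC69 default);
clade recovery, not branch-length fidelity, is the analysis-critical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .errors import UndefinedStatisticError
from .popstats import LocusSummary, jc_correct, locus_summary
from .seqdata import MISSING, LocusAlignment, encode


def _seq_matrix(seqs: list[str]) -> np.ndarray:
    return np.vstack([encode(s) for s in seqs])


def distance_matrix(
    seqs: list[str], ids: list[str], model: str = "jc69"
) -> DistanceMatrix:
    """Pairwise distance matrix (p-distance or JC69) with pairwise deletion."""
    if model not in ("jc69", "p"):
        raise ValueError("model must be 'jc69' or 'p'")
    m = _seq_matrix(seqs)
    n = len(seqs)
    out = np.zeros((n, n))
    valid = m != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            shared = valid[i] & valid[j]
            ns = int(shared.sum())
            if ns == 0:
                raise UndefinedStatisticError(f"no shared sites between {ids[i]} and {ids[j]}")
            p = float((m[i, shared] != m[j, shared]).sum()) / ns
            d = jc_correct(p) if model == "jc69" else p
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor-joining tree with branch lengths."""
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    return nj(dm)


def tree_bipartitions(tree: TreeNode, taxa: set[str] | None = None) -> set[frozenset[str]]:
    """Non-trivial splits of an (unrooted) tree, each as the side not
    containing the lexicographically smallest taxon."""
    taxa = taxa or {t.name for t in tree.tips()}
    ref = min(taxa)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref in side:
            side = frozenset(taxa - side)
        if 1 < len(side) < len(taxa) - 1:
            splits.add(side)
    return splits


@dataclass
class CladePartition:
    """Two-clade assignment of alleles with its supporting statistics."""

    assignments: dict[str, str]  # allele id -> clade label ("A"/"B")
    support: float | None = None  # bootstrap proportion of the A|B split
    ratio: float | None = None  # between/within mean distance ratio of the split
    fixed_differences: list[tuple[int, str, str]] = field(default_factory=list)
    clade_summaries: dict[str, LocusSummary] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return [a for a, c in self.assignments.items() if c == label]

    @property
    def labels(self) -> list[str]:
        return sorted(set(self.assignments.values()))


def call_clades(
    aln: LocusAlignment,
    model: str = "jc69",
    override: dict[str, str] | None = None,
) -> CladePartition:
    """Call the two-clade partition of the ingroup alleles.

    The partition is the NJ-tree internal bipartition maximizing the ratio of
    mean between-clade to mean within-clade distance; ``override`` supplies a
    manual assignment instead. Clade "A" is the side containing the
    lexicographically smallest allele id.
    """
    ids = list(aln.ingroup_ids)
    if override is not None:
        return CladePartition(assignments=dict(override))
    dm = distance_matrix(aln.ingroup_seqs, ids, model=model)
    tree = nj_tree(dm)
    taxa = set(ids)
    best_split = None
    best_ratio = -math.inf
    dists = dm.data
    index = {t: i for i, t in enumerate(dm.ids)}
    for split in sorted(tree_bipartitions(tree, taxa), key=sorted):
        side1 = [index[t] for t in split]
        side2 = [index[t] for t in taxa - split]
        between = dists[np.ix_(side1, side2)].mean()
        # pooled (pair-count weighted) within-distance: a tiny tight clade
        # cannot dominate the denominator
        within_pairs: list[float] = []
        for side in (side1, side2):
            if len(side) > 1:
                block = dists[np.ix_(side, side)]
                within_pairs.extend(block[np.triu_indices(len(side), k=1)].tolist())
        within = float(np.mean(within_pairs)) if within_pairs else 0.0
        ratio = between / within if within > 0 else math.inf
        if ratio > best_ratio:
            best_ratio = ratio
            best_split = split
    if best_split is None:
        raise UndefinedStatisticError(f"{aln.locus_id}: no internal bipartition found")
    smallest = min(ids)
    side_a = (taxa - best_split) if smallest not in best_split else set(best_split)
    assignments = {i: ("A" if i in side_a else "B") for i in ids}
    return CladePartition(
        assignments=assignments,
        ratio=None if math.isinf(best_ratio) else float(best_ratio),
    )


def bootstrap_support(
    aln: LocusAlignment,
    partition: CladePartition,
    replicates: int = 1000,
    seed: int = 0,
    model: str = "jc69",
) -> float:
    """Fraction of site-resampled NJ trees containing the clade bipartition."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids = list(aln.ingroup_ids)
    taxa = set(ids)
    ref = min(taxa)
    labels = partition.labels
    if len(labels) != 2:
        raise ValueError("bootstrap support requires a two-clade partition")
    side = set(partition.members(labels[0]))
    target = frozenset(taxa - side if ref in side else side)
    m = _seq_matrix(aln.ingroup_seqs)
    rng = np.random.default_rng(seed)
    L = m.shape[1]
    hits = 0
    for _ in range(replicates):
        cols = rng.integers(0, L, size=L)
        boot = m[:, cols]
        n = len(ids)
        out = np.zeros((n, n))
        valid = boot != MISSING
        for i in range(n):
            diff = (boot[i] != boot) & valid[i] & valid
            shared = (valid[i] & valid).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = diff.sum(axis=1) / shared
            p = np.nan_to_num(p)
            if model == "jc69":
                p = np.clip(p, 0.0, 0.7499)
                out[i] = -0.75 * np.log1p(-4.0 * p / 3.0)
            else:
                out[i] = p
        out = (out + out.T) / 2.0
        np.fill_diagonal(out, 0.0)
        tree = nj(DistanceMatrix(out, ids))
        if target in tree_bipartitions(tree, taxa):
            hits += 1
    return hits / replicates


def fixed_differences(
    aln: LocusAlignment, partition: CladePartition
) -> tuple[list[tuple[int, str, str]], dict]:
    """Columns fixed between the two clades, plus a positional summary.

    A column qualifies when each clade is monomorphic among its non-missing
    states and the two clades share no state (N/gap treated as missing and
    does not break fixation). Returns ``(diffs, summary)`` where each diff is
    ``(column, clade-A state, clade-B state)`` in 0-based coordinates and the
    summary reports the spanned interval in 1-based inclusive coordinates.
    """
    labels = partition.labels
    if len(labels) != 2:
        raise ValueError("fixed differences require exactly two clades")
    ids_a, ids_b = partition.members(labels[0]), partition.members(labels[1])
    if not ids_a or not ids_b:
        raise ValueError("both clades must be non-empty")
    index = {sid: k for k, sid in enumerate(aln.ingroup_ids)}
    m = _seq_matrix(aln.ingroup_seqs)
    rows_a = m[[index[i] for i in ids_a]]
    rows_b = m[[index[i] for i in ids_b]]
    diffs: list[tuple[int, str, str]] = []
    for col in range(aln.length):
        sa = set(rows_a[:, col].tolist()) - {MISSING}
        sb = set(rows_b[:, col].tolist()) - {MISSING}
        if len(sa) == 1 and len(sb) == 1 and sa != sb:
            base_a = "ACGT"[sa.pop()]
            base_b = "ACGT"[sb.pop()]
            diffs.append((col, base_a, base_b))
    summary = {
        "count": len(diffs),
        "first": diffs[0][0] + 1 if diffs else None,
        "last": diffs[-1][0] + 1 if diffs else None,
    }
    return diffs, summary


def dxy(
    group1: list[str], group2: list[str], columns: np.ndarray | slice | None = None
) -> float:
    """Nei's Dxy: mean per-site difference proportion over all cross-group pairs.

    ``columns`` optionally restricts to a site filter (boolean mask or slice);
    shared non-missing sites are determined per pair (pairwise deletion).
    """
    if not group1 or not group2:
        raise ValueError("both groups must be non-empty")
    m1 = _seq_matrix(group1)
    m2 = _seq_matrix(group2)
    if columns is not None:
        m1 = m1[:, columns]
        m2 = m2[:, columns]
    v1 = m1 != MISSING
    v2 = m2 != MISSING
    vals = []
    for i in range(m1.shape[0]):
        shared = v1[i] & v2
        ns = shared.sum(axis=1)
        if np.any(ns == 0):
            raise UndefinedStatisticError("a sequence pair shares zero included sites")
        diffs = ((m1[i] != m2) & shared).sum(axis=1)
        vals.extend((diffs / ns).tolist())
    return float(np.mean(vals))


def clade_summary(aln: LocusAlignment, partition: CladePartition) -> dict[str, LocusSummary]:
    """Per-clade diversity summaries (the clade-wise statistics table).

    Within-clade diversity is expected to drop relative to the pooled sample
    roughly in proportion to clade frequency (clades at 50% imply an ~50%
    reduction under neutral equilibrium) because conditioning on a clade
    halves the effective population size behind the coalescent. Singleton
    clades report diversity statistics as absent.
    """
    out: dict[str, LocusSummary] = {}
    for label in partition.labels:
        members = partition.members(label)
        if len(members) < 2:
            out[label] = LocusSummary(
                locus_id=f"{aln.locus_id}:{label}", n=len(members), S=0,
                pi_total=None, pi_s=None, pi_a=None, theta_w=None, tajima_d=None,
                K_total=None, K_S=None, K_A=None, ka_ks=None,
            )
            continue
        sub = aln.subset(members, locus_id=f"{aln.locus_id}:{label}")
        out[label] = locus_summary(sub)
    return out


def dxy_table(
    groups: dict[str, list[str]], columns: np.ndarray | slice | None = None
) -> pd.DataFrame:
    """All pairwise (including self) Dxy values among named sequence groups.

    Self comparisons report within-group π (mean pairwise difference of
    distinct pairs), matching the convention Dxy(g, g) = π_g.
    """
    names = list(groups)
    rows = []
    for i, g1 in enumerate(names):
        for g2 in names[i:]:
            if g1 == g2:
                seqs = groups[g1]
                if len(seqs) < 2:
                    value = math.nan
                else:
                    m = _seq_matrix(seqs)
                    if columns is not None:
                        m = m[:, columns]
                    valid = m != MISSING
                    vals = []
                    for a in range(len(seqs)):
                        for b in range(a + 1, len(seqs)):
                            shared = valid[a] & valid[b]
                            ns = int(shared.sum())
                            if ns == 0:
                                raise UndefinedStatisticError("pair shares zero sites")
                            vals.append(float((m[a, shared] != m[b, shared]).sum()) / ns)
                    value = float(np.mean(vals))
            else:
                value = dxy(groups[g1], groups[g2], columns)
            rows.append({"group1": g1, "group2": g2, "dxy": value})
    return pd.DataFrame(rows)
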