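"""Per-locus diversity and divergence statistics and sliding-window scans.

Implements average pairwise diversity (π, and πs/πa restricted to
synonymous/nonsynonymous sites), Watterson's θ, Tajima's D on silent sites,
Jukes-Cantor-corrected divergence to the outgroup (K, K_A, K_S) with
Nei-Gojobori site denominators, per-group averages, and the 200 bp / 25 bp
sliding-window Tajima's D scan used to localize balanced polymorphisms.

"Silent" sites are synonymous coding positions plus usable noncoding
positions. Statistics that are undefined for an input (zero denominator,
no segregating sites) are reported as ``None`` and propagate as NaN in
tabular output — never as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import codon_path_diffs, is_stop
from .errors import SaturationError, UndefinedStatisticError
from .seqdata import (
    MISSING,
    NONCODING,
    NONSYNONYMOUS,
    SYNONYMOUS,
    LocusAlignment,
    SiteClassTable,
    classify_sites,
    decode,
)

SITE_SETS = ("all", "synonymous", "nonsynonymous", "silent", "noncoding")


def harmonic(n: int, power: int = 1) -> float:
    """Σ_{j=1..n-1} 1/j**power — the a1 (power=1) and a2 (power=2) constants."""
    return sum(1.0 / j**power for j in range(1, n))


def site_mask(table: SiteClassTable, site_set: str) -> np.ndarray:
    """Boolean column mask selecting the numerator sites for a site set."""
    classes = np.asarray(table.classes)
    if site_set == "all":
        return table.retained.copy()
    if site_set == "synonymous":
        return classes == SYNONYMOUS
    if site_set == "nonsynonymous":
        return classes == NONSYNONYMOUS
    if site_set == "silent":
        return (classes == NONCODING) | (classes == SYNONYMOUS)
    if site_set == "noncoding":
        return classes == NONCODING
    raise ValueError(f"unknown site set {site_set!r}; expected one of {SITE_SETS}")


def site_count(table: SiteClassTable, site_set: str) -> float:
    """Fractional site-opportunity denominator for a site set."""
    if site_set == "all":
        return float(table.retained.sum())
    if site_set == "synonymous":
        return table.syn_sites
    if site_set == "nonsynonymous":
        return table.nonsyn_sites
    if site_set == "silent":
        return table.silent_sites
    if site_set == "noncoding":
        return table.noncoding_sites
    raise ValueError(f"unknown site set {site_set!r}")


def _pair_diff_stats(matrix: np.ndarray, mask: np.ndarray) -> tuple[float, int]:
    """(mean pairwise difference count, segregating-site count) on masked columns.

    Assumes complete deletion (no missing data inside the mask).
    """
    n = matrix.shape[0]
    sub = matrix[:, mask]
    counts = np.vstack([(sub == b).sum(axis=0) for b in range(4)])
    diff_pairs = (n * n - (counts**2).sum(axis=0)) / 2.0
    total_pairs = n * (n - 1) / 2.0
    seg = int(((counts > 0).sum(axis=0) > 1).sum())
    return float(diff_pairs.sum() / total_pairs), seg


def pairwise_diversity(
    aln: LocusAlignment, site_set: str = "all", table: SiteClassTable | None = None
) -> float | None:
    """Per-site average pairwise diversity π on the chosen site set.

    Returns ``None`` when the site-opportunity denominator is zero.
    """
    table = table or classify_sites(aln)
    denom = site_count(table, site_set)
    if denom <= 0:
        return None
    mean_diffs, _ = _pair_diff_stats(aln.ingroup_matrix(), site_mask(table, site_set))
    return mean_diffs / denom


def segregating_sites(
    aln: LocusAlignment, site_set: str = "all", table: SiteClassTable | None = None
) -> int:
    table = table or classify_sites(aln)
    _, seg = _pair_diff_stats(aln.ingroup_matrix(), site_mask(table, site_set))
    return seg


def watterson_theta(S: int, n: int, L: float) -> float:
    """Watterson's estimator per site: θ_W = S / (a_n · L)."""
    if n < 2:
        raise UndefinedStatisticError("Watterson's theta requires n >= 2")
    if L <= 0:
        raise UndefinedStatisticError("Watterson's theta requires L > 0")
    return S / (harmonic(n) * L)


def tajima_d_from_counts(mean_pairwise: float, S: int, n: int) -> float | None:
    """Tajima's D from the total mean pairwise difference count and S.

    Uses the standard n-dependent constants (Tajima 1989). Returns ``None``
    when S = 0 (the statistic is undefined, not zero).
    """
    if S == 0:
        return None
    a1 = harmonic(n, 1)
    a2 = harmonic(n, 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return (mean_pairwise - S / a1) / math.sqrt(var)


def tajimas_d(
    aln: LocusAlignment, site_set: str = "silent", table: SiteClassTable | None = None
) -> float | None:
    """Tajima's D on the chosen site set (silent sites by default)."""
    table = table or classify_sites(aln)
    mean_diffs, S = _pair_diff_stats(aln.ingroup_matrix(), site_mask(table, site_set))
    return tajima_d_from_counts(mean_diffs, S, aln.n)


@dataclass
class WindowRecord:
    start: int  # 0-based half-open alignment coordinates
    end: int
    silent_sites: float
    S: int
    tajima_d: float | None


@dataclass
class WindowScan:
    window: int
    step: int
    records: list[WindowRecord] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": [r.start + 1 for r in self.records],  # 1-based in reports
                "end": [r.end for r in self.records],
                "silent_sites": [r.silent_sites for r in self.records],
                "S": [r.S for r in self.records],
                "tajima_d": [r.tajima_d if r.tajima_d is not None else np.nan for r in self.records],
            }
        )


def sliding_tajimas_d(
    aln: LocusAlignment,
    window: int = 200,
    step: int = 25,
    min_S: int = 3,
    site_set: str = "silent",
    table: SiteClassTable | None = None,
) -> WindowScan:
    """Sliding-window Tajima's D on silent sites (200 bp window, 25 bp step).

    Windows with fewer than ``min_S`` segregating sites report the statistic
    as absent. A window longer than the alignment degrades to a single
    whole-alignment window with a warning.
    """
    if not (window >= step >= 1):
        raise ValueError("require window >= step >= 1")
    table = table or classify_sites(aln)
    L = aln.length
    if window > L:
        warnings.warn(
            f"{aln.locus_id}: window {window} exceeds alignment length {L}; "
            "using a single whole-alignment window"
        )
        window = L
    matrix = aln.ingroup_matrix()
    mask = site_mask(table, site_set)
    scan = WindowScan(window=window, step=step)
    for start in range(0, L - window + 1, step):
        end = start + window
        wmask = mask.copy()
        wmask[:start] = False
        wmask[end:] = False
        mean_diffs, S = _pair_diff_stats(matrix, wmask)
        d = tajima_d_from_counts(mean_diffs, S, aln.n) if S >= min_S else None
        silent = float(table.silent_fraction[start:end].sum())
        scan.records.append(WindowRecord(start, end, silent, S, d))
    return scan


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance −(3/4)·ln(1 − 4p/3) for a raw difference proportion."""
    if p < 0:
        raise ValueError("negative difference proportion")
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p:.3f} >= 0.75 saturates the JC correction")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def _coding_diffs_vs_outgroup(aln: LocusAlignment, table: SiteClassTable) -> tuple[float, float]:
    """Mean per-allele (synonymous, nonsynonymous) pathway difference counts vs outgroup."""
    out_codes = np.asarray([ord(c) for c in aln.outgroup_seq], dtype=np.uint16)
    syn_sum = 0.0
    nonsyn_sum = 0.0
    for seq in aln.ingroup_seqs:
        for cols3 in table.codon_columns:
            c_in = seq[cols3[0]] + seq[cols3[1]] + seq[cols3[2]]
            c_out = "".join(chr(out_codes[c]) for c in cols3)
            if is_stop(c_in) or is_stop(c_out):
                continue  # rare allele-level stop: skip the codon for this pair
            s, a = codon_path_diffs(c_in, c_out)
            syn_sum += s
            nonsyn_sum += a
    n = aln.n
    return syn_sum / n, nonsyn_sum / n


def jc_corrected_divergence(
    aln: LocusAlignment, site_set: str = "all", table: SiteClassTable | None = None
) -> float | None:
    """Per-site JC-corrected divergence K to the outgroup on the chosen site set.

    The raw proportion p averages each ingroup allele against the outgroup;
    for synonymous/nonsynonymous sets the difference counts come from
    Nei-Gojobori pathway averaging over codons and the denominators are the
    fractional site opportunities. Raises :class:`SaturationError` at
    p >= 0.75; returns ``None`` when the denominator is zero.
    """
    table = table or classify_sites(aln)
    denom = site_count(table, site_set)
    if denom <= 0:
        return None
    matrix = aln.ingroup_matrix()
    out_row = np.asarray(
        [0 if b == "A" else 1 if b == "C" else 2 if b == "G" else 3 if b == "T" else MISSING
         for b in aln.outgroup_seq],
        dtype=np.uint8,
    )
    if site_set in ("all", "noncoding"):
        mask = site_mask(table, site_set)
        diffs = (matrix[:, mask] != out_row[mask]).sum(axis=1)
        p = float(diffs.mean()) / denom
        return jc_correct(p)
    syn_d, nonsyn_d = _coding_diffs_vs_outgroup(aln, table)
    if site_set == "synonymous":
        return jc_correct(syn_d / denom)
    if site_set == "nonsynonymous":
        return jc_correct(nonsyn_d / denom)
    if site_set == "silent":
        mask = site_mask(table, "noncoding")
        nonc = float((matrix[:, mask] != out_row[mask]).sum(axis=1).mean())
        return jc_correct((syn_d + nonc) / denom)
    raise ValueError(f"unknown site set {site_set!r}")


@dataclass
class LocusSummary:
    """One row of per-locus statistics (the per-gene summary table)."""

    locus_id: str
    n: int
    S: int
    pi_total: float | None
    pi_s: float | None
    pi_a: float | None
    theta_w: float | None  # per silent site
    tajima_d: float | None
    K_total: float | None
    K_S: float | None
    K_A: float | None
    ka_ks: float | None
    group: str = "control"
    pathway: str | None = None
    chromosome: str = ""
    paired_control: str | None = None

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        for k, v in d.items():
            if v is None and k not in ("pathway", "paired_control"):
                d[k] = np.nan
        return d


def locus_summary(aln: LocusAlignment, table: SiteClassTable | None = None) -> LocusSummary:
    """All per-locus statistics for one alignment."""
    table = table or classify_sites(aln)
    matrix = aln.ingroup_matrix()
    _, S_all = _pair_diff_stats(matrix, site_mask(table, "all"))
    _, S_silent = _pair_diff_stats(matrix, site_mask(table, "silent"))
    theta = (
        watterson_theta(S_silent, aln.n, table.silent_sites) if table.silent_sites > 0 else None
    )

    def _k(site_set: str) -> float | None:
        # saturated divergence is reported absent in summary tables
        try:
            return jc_corrected_divergence(aln, site_set, table)
        except SaturationError:
            return None

    K_S = _k("synonymous")
    K_A = _k("nonsynonymous")
    ka_ks = None
    if K_S is not None and K_A is not None and K_S > 0:
        ka_ks = K_A / K_S
    return LocusSummary(
        locus_id=aln.locus_id,
        n=aln.n,
        S=S_all,
        pi_total=pairwise_diversity(aln, "all", table),
        pi_s=pairwise_diversity(aln, "synonymous", table),
        pi_a=pairwise_diversity(aln, "nonsynonymous", table),
        theta_w=theta,
        tajima_d=tajimas_d(aln, "silent", table),
        K_total=_k("all"),
        K_S=K_S,
        K_A=K_A,
        ka_ks=ka_ks,
        group=aln.group_label,
        pathway=aln.pathway_label,
        chromosome=aln.chromosome_label,
        paired_control=aln.paired_control_id,
    )


def summarize_loci(alns: list[LocusAlignment]) -> pd.DataFrame:
    """Per-locus summary table (one row per locus)."""
    return pd.DataFrame([locus_summary(a).as_dict() for a in alns])


STAT_COLUMNS = ["pi_total", "pi_s", "pi_a", "theta_w", "tajima_d", "K_total", "K_S", "K_A", "ka_ks"]


def group_means(
    summaries: pd.DataFrame, group_col: str = "group", loci: list[str] | None = None
) -> pd.DataFrame:
    """Unweighted per-group means of per-gene statistics.

    K_A/K_S is averaged as the mean of per-gene ratios (not the ratio of
    means); per-gene undefined statistics are skipped with their count
    reported in an ``n_<stat>`` column.
    """
    df = summaries if loci is None else summaries[summaries["locus_id"].isin(loci)]
    if df.empty or df[group_col].nunique() == 0:
        raise ValueError("no loci to average")
    cols = [c for c in STAT_COLUMNS if c in df.columns]
    grouped = df.groupby(group_col)
    out = grouped[cols].mean()
    out.insert(0, "n_loci", grouped.size())
    for c in cols:
        out[f"n_{c}"] = grouped[c].count()
    return out.reset_index()
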