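"""Coalescent synthetic-data generator.

Produces per-locus multi-FASTA alignments (plus machine-readable truth
records) under the statistical structures the analysis assumes:

* ``simulate_neutral_locus`` — Hudson-style neutral coalescent with
  infinite-sites mutations at per-site rate θ and an outgroup diverging T
  2N-generations ago (with an Exp(1) ancestral-coalescent tail, so that the
  expected per-site one-allele-vs-outgroup divergence is θ·(T+1), matching
  the HKA divergence expectation at k = 1).
* ``simulate_coding_locus`` — adds codon structure: synonymous and
  noncoding mutations arise at the neutral rate, nonsynonymous
  polymorphisms are thinned by the locus constraint f, and nonsynonymous
  fixed differences arise at rate λ·L_nonsyn·f/(1−α) with λ = θ·T, so the
  emitted counts follow the multilocus MK model exactly. At most one
  mutation is placed per codon, which keeps the synonymous/nonsynonymous
  classification of every change unambiguous and the truth counts exactly
  recoverable from the alignment.
* ``simulate_balanced_locus`` — an ancient two-clade balanced polymorphism
  segregating in several descendant species: within-clade coalescents run
  at clade-frequency-scaled effective size, species merge at the species
  split time, and the two clade ancestral lineages join at depth τ; a
  clade-defining block carries a configured number of diagnostic fixed
  differences. Non-block sites follow a single clade-free genealogy — a
  deliberate stand-in for recombination decay of the haplotype block.

Time is measured in 2N-generation units throughout. All randomness flows
from the configured seed; identical seeds give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .codons import (
    SENSE_CODONS,
    count_syn_nonsyn_sites,
    nonsynonymous_changes,
    synonymous_changes,
)
from .seqdata import LocusAlignment, manifest_entry_for, write_locus_fasta, write_manifest

BASES = "ACGT"


# ---------------------------------------------------------------------------
# genealogy machinery


@dataclass
class Genealogy:
    """Binary coalescent tree: nodes 0..n_tips-1 are tips, root has parent -1."""

    times: np.ndarray
    parents: np.ndarray
    n_tips: int
    tip_labels: list[str]

    @property
    def n_nodes(self) -> int:
        return len(self.times)

    @property
    def root(self) -> int:
        return int(np.where(self.parents < 0)[0][0])

    @property
    def root_time(self) -> float:
        return float(self.times[self.root])

    def branch_lengths(self) -> np.ndarray:
        out = np.zeros(self.n_nodes)
        for i in range(self.n_nodes):
            p = self.parents[i]
            if p >= 0:
                out[i] = self.times[p] - self.times[i]
        return out

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tips_under(self, node: int) -> list[int]:
        children: dict[int, list[int]] = {}
        for i, p in enumerate(self.parents):
            if p >= 0:
                children.setdefault(int(p), []).append(i)
        stack = [node]
        tips = []
        while stack:
            cur = stack.pop()
            if cur < self.n_tips:
                tips.append(cur)
            else:
                stack.extend(children.get(cur, []))
        return sorted(tips)

    def mrca(self, tips: list[int]) -> int:
        """Most recent common ancestor of a tip set."""
        paths = []
        for t in tips:
            path = []
            cur = t
            while cur >= 0:
                path.append(cur)
                cur = int(self.parents[cur])
            paths.append(set(path))
        common = set.intersection(*paths)
        return min(common, key=lambda n: self.times[n])


def structured_coalescent(
    rng: np.random.Generator,
    tips_by_pop: dict[str, list[str]],
    scales: dict[str, float],
    merges: list[tuple[float, list[str], str]],
    final_scale: float = 1.0,
) -> Genealogy:
    """Coalescent with piecewise population structure.

    ``tips_by_pop`` maps population labels to tip labels (all tips at time
    0); coalescence in population p proceeds at rate C(k,2)/scale(p);
    ``merges`` are (time, source populations, destination population)
    events. After the last merge the process must be able to reach a single
    lineage (destination scale defaults to ``final_scale`` when the
    destination is a new population).
    """
    tip_labels = [t for pop in tips_by_pop for t in tips_by_pop[pop]]
    n_tips = len(tip_labels)
    label_index = {t: i for i, t in enumerate(tip_labels)}
    times = [0.0] * n_tips
    parents = [-1] * n_tips
    active: dict[str, list[int]] = {
        pop: [label_index[t] for t in tips] for pop, tips in tips_by_pop.items()
    }
    scales = dict(scales)
    pending = sorted(merges, key=lambda m: m[0])
    t = 0.0
    while sum(len(v) for v in active.values()) > 1:
        rates = {
            pop: (len(lin) * (len(lin) - 1) / 2.0) / scales.get(pop, final_scale)
            for pop, lin in active.items()
            if len(lin) >= 2
        }
        total_rate = sum(rates.values())
        t_next = t + rng.exponential(1.0 / total_rate) if total_rate > 0 else np.inf
        if pending and pending[0][0] <= t_next:
            t, sources, dest = pending[0][0], pending[0][1], pending[0][2]
            pending = pending[1:]
            moved = []
            for src in sources:
                moved.extend(active.pop(src, []))
            active.setdefault(dest, []).extend(moved)
            scales.setdefault(dest, final_scale)
            continue
        if not np.isfinite(t_next):
            raise RuntimeError("coalescent cannot complete: isolated lineages remain")
        t = t_next
        pops = list(rates)
        weights = np.array([rates[p] for p in pops])
        pop = pops[rng.choice(len(pops), p=weights / weights.sum())]
        lin = active[pop]
        i, j = rng.choice(len(lin), size=2, replace=False)
        a, b = lin[i], lin[j]
        node = len(times)
        times.append(t)
        parents.append(-1)
        parents[a] = node
        parents[b] = node
        active[pop] = [x for x in lin if x not in (a, b)] + [node]
    return Genealogy(
        times=np.array(times), parents=np.array(parents), n_tips=n_tips, tip_labels=tip_labels
    )


def kingman_tree(rng: np.random.Generator, labels: list[str]) -> Genealogy:
    """Single-population neutral coalescent."""
    return structured_coalescent(rng, {"pop": labels}, {"pop": 1.0}, [])


def drop_mutations(gen: Genealogy, n_mut: int, rng: np.random.Generator) -> list[list[int]]:
    """Place mutations on branches ∝ length; return the carrier tip sets."""
    lengths = gen.branch_lengths()
    probs = lengths / lengths.sum()
    carriers = []
    for node in rng.choice(gen.n_nodes, size=n_mut, p=probs):
        carriers.append(gen.tips_under(int(node)))
    return carriers


class _ColumnPool:
    """Draws distinct alignment columns (infinite-sites collision redraw)."""

    def __init__(self, columns: np.ndarray, rng: np.random.Generator):
        self._free = list(map(int, columns))
        rng.shuffle(self._free)

    def draw(self) -> int:
        if not self._free:
            raise RuntimeError("infinite-sites assumption violated: no free columns left")
        return self._free.pop()


# ---------------------------------------------------------------------------
# truth records


@dataclass
class SimTruth:
    """Generator ground truth for one locus, verifiable from the alignment."""

    locus_id: str
    seed: int
    counts: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)  # 0-based alignment columns
    clades: dict = field(default_factory=dict)  # allele id -> clade label

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# neutral locus


def _random_seq(rng: np.random.Generator, length: int) -> list[str]:
    return [BASES[i] for i in rng.integers(0, 4, size=length)]


def _apply(seqs: dict[str, list[str]], ids: list[str], col: int, base: str) -> None:
    for sid in ids:
        seqs[sid][col] = base


def simulate_neutral_locus(
    n: int = 20,
    theta: float = 0.01,
    T: float = 1.3,
    length: int = 1000,
    seed: int = 0,
    locus_id: str = "neutral",
    group: str = "control",
) -> tuple[LocusAlignment, SimTruth]:
    """Neutral noncoding locus with outgroup divergence T (2N units)."""
    rng = np.random.default_rng(seed)
    labels = [f"a{i:02d}" for i in range(n)]
    gen = kingman_tree(rng, labels)
    ancestral = _random_seq(rng, length)
    seqs = {lab: ancestral.copy() for lab in labels}
    outgroup = ancestral.copy()

    S = rng.poisson(theta * length * gen.total_branch_length / 2.0)
    S = min(S, length)
    pool = _ColumnPool(np.arange(length), rng)
    poly_cols = []
    for carriers in drop_mutations(gen, S, rng):
        col = pool.draw()
        alt = rng.choice([b for b in BASES if b != ancestral[col]])
        _apply(seqs, [labels[i] for i in carriers], col, alt)
        poly_cols.append(col)

    extra = rng.exponential(1.0)
    stem = max(T - gen.root_time, 0.0) + extra
    n_out = rng.poisson(theta * length * (T + extra) / 2.0)
    n_stem = rng.poisson(theta * length * stem / 2.0)
    fixed_cols = []
    for _ in range(int(n_out)):
        col = pool.draw()
        outgroup[col] = rng.choice([b for b in BASES if b != ancestral[col]])
        fixed_cols.append(col)
    for _ in range(int(n_stem)):
        col = pool.draw()
        alt = rng.choice([b for b in BASES if b != ancestral[col]])
        _apply(seqs, labels, col, alt)
        fixed_cols.append(col)

    aln = LocusAlignment(
        locus_id=locus_id,
        ingroup_ids=labels,
        ingroup_seqs=["".join(seqs[lab]) for lab in labels],
        outgroup_id="outgroup",
        outgroup_seq="".join(outgroup),
        coding_segments=[],
        group_label=group,
    )
    truth = SimTruth(
        locus_id=locus_id,
        seed=seed,
        counts={"S": int(S), "fixed": len(fixed_cols)},
        positions={"polymorphic": sorted(poly_cols), "fixed": sorted(fixed_cols)},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# coding locus


@dataclass
class CodingLocusConfig:
    """Study-scale defaults: ~1.8 kb loci, 70% coding, silent θ ≈ 2.6%,
    outgroup divergence tuned so synonymous divergence is ≈ 6%."""

    locus_id: str = "locus"
    n: int = 20
    length: int = 1800
    coding_fraction: float = 0.7
    theta: float = 0.026  # per neutral (silent) site
    T: float = 1.3
    f: float = 0.12  # selective constraint on nonsynonymous sites
    alpha: float = 0.0  # adaptive fraction of nonsynonymous fixations
    group: str = "control"
    pathway: str | None = None
    paired_control: str | None = None
    chromosome: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha >= 1.0:
            raise ValueError("alpha must be < 1")
        if not (0.0 <= self.coding_fraction <= 1.0):
            raise ValueError("coding_fraction must be in [0, 1]")
        if self.f < 0:
            raise ValueError("f must be >= 0")


def simulate_coding_locus(config: CodingLocusConfig) -> tuple[LocusAlignment, SimTruth]:
    """Coding locus under the multilocus MK generative model.

    Synonymous/noncoding mutations arise at the neutral rate; nonsynonymous
    polymorphisms are thinned by f; nonsynonymous fixations arise at rate
    λ·L_nonsyn·f/(1−α) with λ = θ·T. Fixed differences are applied to the
    outgroup sequence (direction is irrelevant to every downstream count).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    coding_len = int(cfg.length * cfg.coding_fraction) // 3 * 3
    n_codons = coding_len // 3
    labels = [f"a{i:02d}" for i in range(cfg.n)]

    codon_idx = rng.integers(0, len(SENSE_CODONS), size=n_codons)
    codons = [SENSE_CODONS[i] for i in codon_idx]
    ancestral = list("".join(codons)) + _random_seq(rng, cfg.length - coding_len)
    seqs = {lab: ancestral.copy() for lab in labels}
    outgroup = ancestral.copy()

    L_syn = sum(count_syn_nonsyn_sites(c)[0] for c in codons)
    L_nonsyn = sum(count_syn_nonsyn_sites(c)[1] for c in codons)
    L_nc = cfg.length - coding_len
    gen = kingman_tree(rng, labels)
    half_len = gen.total_branch_length / 2.0
    lam = cfg.theta * cfg.T

    n_syn_p = rng.poisson(cfg.theta * L_syn * half_len)
    n_non_p = rng.poisson(cfg.theta * L_nonsyn * cfg.f * half_len)
    n_nc_p = rng.poisson(cfg.theta * L_nc * half_len)
    n_syn_f = rng.poisson(lam * L_syn)
    n_non_f = rng.poisson(lam * L_nonsyn * cfg.f / (1.0 - cfg.alpha))
    n_nc_f = rng.poisson(lam * L_nc)

    free_codons = list(range(n_codons))
    rng.shuffle(free_codons)
    nc_pool = _ColumnPool(np.arange(coding_len, cfg.length), rng)

    def draw_coding_change(kind: str) -> tuple[int, str]:
        """(alignment column, alternative base) for a fresh codon; one per codon."""
        while free_codons:
            ci = free_codons.pop()
            changes = (
                synonymous_changes(codons[ci]) if kind == "syn" else nonsynonymous_changes(codons[ci])
            )
            if not changes:
                continue
            pos, alt = changes[rng.integers(0, len(changes))]
            return ci * 3 + pos, alt
        raise RuntimeError("ran out of codons for mutations; locus too short for these rates")

    positions: dict[str, list[int]] = {k: [] for k in
                                       ("Ps", "Pn", "Ds", "Dn", "nc_poly", "nc_fixed")}
    carrier_sets = drop_mutations(gen, n_syn_p + n_non_p + n_nc_p, rng)
    ptr = 0
    for kind, count in (("syn", n_syn_p), ("nonsyn", n_non_p)):
        for _ in range(int(count)):
            col, alt = draw_coding_change("syn" if kind == "syn" else "nonsyn")
            tips = carrier_sets[ptr]
            ptr += 1
            _apply(seqs, [labels[i] for i in tips], col, alt)
            positions["Ps" if kind == "syn" else "Pn"].append(col)
    for _ in range(int(n_nc_p)):
        col = nc_pool.draw()
        alt = rng.choice([b for b in BASES if b != ancestral[col]])
        tips = carrier_sets[ptr]
        ptr += 1
        _apply(seqs, [labels[i] for i in tips], col, alt)
        positions["nc_poly"].append(col)
    for kind, count, key in (("syn", n_syn_f, "Ds"), ("nonsyn", n_non_f, "Dn")):
        for _ in range(int(count)):
            col, alt = draw_coding_change(kind)
            outgroup[col] = alt
            positions[key].append(col)
    for _ in range(int(n_nc_f)):
        col = nc_pool.draw()
        outgroup[col] = rng.choice([b for b in BASES if b != ancestral[col]])
        positions["nc_fixed"].append(col)

    aln = LocusAlignment(
        locus_id=cfg.locus_id,
        ingroup_ids=labels,
        ingroup_seqs=["".join(seqs[lab]) for lab in labels],
        outgroup_id="outgroup",
        outgroup_seq="".join(outgroup),
        coding_segments=[(0, coding_len, 0)] if coding_len else [],
        group_label=cfg.group,
        pathway_label=cfg.pathway,
        paired_control_id=cfg.paired_control,
        chromosome_label=cfg.chromosome,
    )
    truth = SimTruth(
        locus_id=cfg.locus_id,
        seed=cfg.seed,
        counts={
            "Ps": int(n_syn_p), "Pn": int(n_non_p), "Ds": int(n_syn_f), "Dn": int(n_non_f),
            "nc_poly": int(n_nc_p), "nc_fixed": int(n_nc_f),
            "L_syn": L_syn, "L_nonsyn": L_nonsyn, "L_noncoding": L_nc,
        },
        positions={k: sorted(v) for k, v in positions.items()},
    )
    return aln, truth


# ---------------------------------------------------------------------------
# balanced polymorphism locus


@dataclass
class BalancedConfig:
    """An ancient balanced polymorphism shared across descendant species.

    Defaults model a ~1 kb locus whose 5' 350 bp block carries 11 diagnostic
    fixed differences between clades segregating at 50%, a clade split 5×
    older than the species split, and an outgroup at T = 6 (2N units).
    """

    locus_id: str = "balanced"
    length: int = 1000
    block: tuple[int, int] = (0, 350)  # 0-based half-open
    n_fixed: int = 11
    tau: float = 5.0  # clade split depth, 2N units
    species_split: float = 1.0
    T_outgroup: float = 6.0
    clade_freqs: tuple[float, float] = (0.5, 0.5)
    n_species: int = 3
    n_focal: int = 20
    n_other: int = 10
    theta: float = 0.015
    recomb_chunk: int = 100  # non-block genealogy decorrelation length, bp
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.clade_freqs) - 1.0) > 1e-9:
            raise ValueError("clade frequencies must sum to 1")
        if not (0 <= self.block[0] < self.block[1] <= self.length):
            raise ValueError("block must lie inside the locus")
        if self.n_species >= 1 and self.tau <= self.species_split and self.n_species > 1:
            raise ValueError("clade split tau must predate the species split")


def _compose(gen_a: Genealogy, gen_b: Genealogy, join_time: float) -> Genealogy:
    """Join two genealogies under a common root at ``join_time``."""
    na, nb = gen_a.n_nodes, gen_b.n_nodes
    n_tips = gen_a.n_tips + gen_b.n_tips
    # re-index: tips of A, tips of B, internals of A, internals of B, root
    map_a = {i: i if i < gen_a.n_tips else gen_a.n_tips + gen_b.n_tips + (i - gen_a.n_tips)
             for i in range(na)}
    off_b_int = n_tips + (na - gen_a.n_tips)
    map_b = {i: gen_a.n_tips + i if i < gen_b.n_tips else off_b_int + (i - gen_b.n_tips)
             for i in range(nb)}
    total = na + nb + 1
    times = np.zeros(total)
    parents = np.full(total, -1)
    root = total - 1
    times[root] = join_time
    for old, new in map_a.items():
        times[new] = gen_a.times[old]
        p = gen_a.parents[old]
        parents[new] = map_a[int(p)] if p >= 0 else root
    for old, new in map_b.items():
        times[new] = gen_b.times[old]
        p = gen_b.parents[old]
        parents[new] = map_b[int(p)] if p >= 0 else root
    return Genealogy(
        times=times, parents=parents, n_tips=n_tips,
        tip_labels=gen_a.tip_labels + gen_b.tip_labels,
    )


def simulate_balanced_locus(
    config: BalancedConfig,
) -> tuple[dict[str, LocusAlignment], SimTruth]:
    """Trans-species balanced polymorphism with a clade-defining block.

    Returns one alignment per species (``sp1`` is the focal species; every
    alignment shares the same outgroup sequence) plus the truth record with
    clade assignments and diagnostic positions.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    n_by_species = {s: (cfg.n_focal if i == 0 else cfg.n_other) for i, s in enumerate(species)}

    clade_of: dict[str, str] = {}
    tips_by_sp_clade: dict[str, dict[str, list[str]]] = {"A": {}, "B": {}}
    for s in species:
        n = n_by_species[s]
        n_a = int(round(cfg.clade_freqs[0] * n))
        labels = [f"{s}_{k:02d}" for k in range(n)]
        tips_by_sp_clade["A"][s] = labels[:n_a]
        tips_by_sp_clade["B"][s] = labels[n_a:]
        for lab in labels[:n_a]:
            clade_of[lab] = "A"
        for lab in labels[n_a:]:
            clade_of[lab] = "B"

    def clade_tree(clade: str, freq: float) -> Genealogy | None:
        pops = {s: tips for s, tips in tips_by_sp_clade[clade].items() if tips}
        if not pops:
            return None
        merges = []
        if len(pops) > 1:
            merges = [(cfg.species_split, list(pops), f"anc_{clade}")]
        return structured_coalescent(
            rng, pops, {p: freq for p in pops}, merges, final_scale=freq
        )

    # block genealogy: per-clade trees joined at (at least) tau
    gen_a = clade_tree("A", cfg.clade_freqs[0])
    gen_b = clade_tree("B", cfg.clade_freqs[1])
    if gen_a is not None and gen_b is not None:
        join = max(cfg.tau, gen_a.root_time, gen_b.root_time)
        block_gen = _compose(gen_a, gen_b, join)
        b_root_new = block_gen.mrca(
            [block_gen.tip_labels.index(t) for c in tips_by_sp_clade["B"].values() for t in c]
        )
    else:
        block_gen = gen_a if gen_a is not None else gen_b
        b_root_new = None

    # non-block region: species structure only, clades ignored. Recombination
    # decay is approximated by independent genealogies per ~200 bp chunk,
    # which keeps within-clade distances concentrated near their mean the
    # way freely recombining flanking sequence would.
    all_tips = {s: tips_by_sp_clade["A"][s] + tips_by_sp_clade["B"][s] for s in species}

    def species_tree() -> Genealogy:
        nb_merges = [(cfg.species_split, species, "anc")] if len(species) > 1 else []
        return structured_coalescent(rng, all_tips, {s: 1.0 for s in species}, nb_merges)

    ancestral = _random_seq(rng, cfg.length)
    seqs = {lab: ancestral.copy() for lab in clade_of}
    outgroup = ancestral.copy()
    b0, b1 = cfg.block
    block_cols = np.arange(b0, b1)
    nonblock_cols = np.concatenate([np.arange(0, b0), np.arange(b1, cfg.length)])
    block_pool = _ColumnPool(block_cols, rng)
    nonblock_pool = _ColumnPool(nonblock_cols, rng)

    # diagnostic fixed differences: derived in every clade-B allele
    diagnostic = []
    b_tips = [t for c in tips_by_sp_clade["B"].values() for t in c]
    for _ in range(cfg.n_fixed if b_tips else 0):
        col = block_pool.draw()
        alt = rng.choice([b for b in BASES if b != ancestral[col]])
        _apply(seqs, b_tips, col, alt)
        diagnostic.append(col)

    def scatter(gen: Genealogy, pool: _ColumnPool, n_sites: int) -> list[int]:
        n_mut = rng.poisson(cfg.theta * n_sites * gen.total_branch_length / 2.0)
        n_mut = min(n_mut, len(pool._free))
        cols = []
        for carriers in drop_mutations(gen, n_mut, rng):
            col = pool.draw()
            alt = rng.choice([b for b in BASES if b != ancestral[col]])
            _apply(seqs, [gen.tip_labels[i] for i in carriers], col, alt)
            cols.append(col)
        return cols

    block_poly = scatter(block_gen, block_pool, len(block_cols))
    nonblock_poly: list[int] = []
    n_nonblock = len(nonblock_cols)
    if n_nonblock:
        n_chunks = max(1, round(n_nonblock / cfg.recomb_chunk))
        chunk_sizes = [n_nonblock // n_chunks] * n_chunks
        for i in range(n_nonblock % n_chunks):
            chunk_sizes[i] += 1
        for size in chunk_sizes:
            nonblock_poly.extend(scatter(species_tree(), nonblock_pool, size))

    # outgroup divergence lumped onto the outgroup branch
    n_out = rng.poisson(cfg.theta * cfg.length * cfg.T_outgroup)
    out_cols = []
    used = set(diagnostic) | set(block_poly) | set(nonblock_poly)
    free = [c for c in range(cfg.length) if c not in used]
    rng.shuffle(free)
    for _ in range(min(int(n_out), len(free))):
        col = free.pop()
        outgroup[col] = rng.choice([b for b in BASES if b != ancestral[col]])
        out_cols.append(col)

    alignments = {}
    for s in species:
        labels = all_tips[s]
        alignments[s] = LocusAlignment(
            locus_id=f"{cfg.locus_id}_{s}",
            ingroup_ids=labels,
            ingroup_seqs=["".join(seqs[lab]) for lab in labels],
            outgroup_id="outgroup",
            outgroup_seq="".join(outgroup),
            coding_segments=[],
            group_label="immune",
        )
    truth = SimTruth(
        locus_id=cfg.locus_id,
        seed=cfg.seed,
        counts={
            "diagnostic_fixed": len(diagnostic),
            "block_poly": len(block_poly),
            "nonblock_poly": len(nonblock_poly),
            "outgroup": len(out_cols),
        },
        positions={
            "diagnostic": sorted(diagnostic),
            "block": [b0, b1],
        },
        clades=dict(clade_of),
    )
    return alignments, truth


# ---------------------------------------------------------------------------
# multi-locus datasets


@dataclass
class DatasetConfig:
    """Study-shape dataset: 20 immune genes (8 Imd, 7 Toll, 5 other) and 17
    position-matched controls, with one unpaired immune locus and two
    controls shared between immune-gene pairs."""

    n_immune: int = 20
    n_control: int = 17
    n_alleles: int = 20
    length: int = 1800
    coding_fraction: float = 0.7
    theta: float = 0.026
    T: float = 1.3
    f_immune: tuple[float, float] = (2.0, 9.4)  # Beta(a, b): mean ≈ 0.175
    f_control: tuple[float, float] = (2.0, 24.0)  # mean ≈ 0.077
    alpha_immune: float = 0.0
    alpha_control: float = 0.0
    seed: int = 0


def _pathway_labels(n_immune: int) -> list[str | None]:
    out: list[str | None] = []
    for i in range(n_immune):
        if i < 8:
            out.append("Imd")
        elif i < 15:
            out.append("Toll")
        else:
            out.append(None)
    return out


def simulate_dataset(
    config: DatasetConfig | None = None, seed: int | None = None
) -> tuple[list[LocusAlignment], list[SimTruth]]:
    """Simulate a full immune/control multilocus dataset.

    Pairing layout: immune locus i is matched to control i for i < n_control
    − 1; the last two immune loci reuse the last two controls (the shared
    controls of the study design) and one immune locus stays unpaired.
    """
    cfg = config or DatasetConfig()
    if seed is not None:
        cfg = DatasetConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)
    pathways = _pathway_labels(cfg.n_immune)
    control_ids = [f"CTR{j + 1:02d}" for j in range(cfg.n_control)]
    alns, truths = [], []

    # pairing: immune 0..n_control-1 -> control j; the overflow immune loci
    # reuse the first controls (shared); the very last immune locus unpaired.
    paired: list[str | None] = []
    for i in range(cfg.n_immune):
        if i < cfg.n_control:
            paired.append(control_ids[i])
        elif i < cfg.n_immune - 1:
            paired.append(control_ids[i - cfg.n_control])
        else:
            paired.append(None)

    chroms = ["2L", "2R", "3L", "3R", "X"]
    for i in range(cfg.n_immune):
        sub = int(rng.integers(0, 2**31 - 1))
        f = float(rng.beta(*cfg.f_immune))
        a, t = simulate_coding_locus(
            CodingLocusConfig(
                locus_id=f"IMM{i + 1:02d}",
                n=cfg.n_alleles,
                length=cfg.length,
                coding_fraction=cfg.coding_fraction,
                theta=cfg.theta,
                T=cfg.T,
                f=f,
                alpha=cfg.alpha_immune,
                group="immune",
                pathway=pathways[i],
                paired_control=paired[i],
                chromosome=chroms[i % len(chroms)],
                seed=sub,
            )
        )
        alns.append(a)
        truths.append(t)
    for j in range(cfg.n_control):
        sub = int(rng.integers(0, 2**31 - 1))
        f = float(rng.beta(*cfg.f_control))
        a, t = simulate_coding_locus(
            CodingLocusConfig(
                locus_id=control_ids[j],
                n=cfg.n_alleles,
                length=cfg.length,
                coding_fraction=cfg.coding_fraction,
                theta=cfg.theta,
                T=cfg.T,
                f=f,
                alpha=cfg.alpha_control,
                group="control",
                pathway=None,
                chromosome=chroms[j % len(chroms)],
                seed=sub,
            )
        )
        alns.append(a)
        truths.append(t)
    return alns, truths


def write_dataset(
    outdir: str | Path,
    alignments: list[LocusAlignment],
    truths: list[SimTruth] | None = None,
) -> Path:
    """Write a dataset directory: per-locus FASTA, JSON manifest, truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for aln in alignments:
        fname = f"{aln.locus_id}.fasta"
        write_locus_fasta(outdir / fname, aln)
        entries.append(manifest_entry_for(aln, fname))
    write_manifest(outdir / "manifest.json", entries)
    if truths is not None:
        (outdir / "truth.json").write_text(
            json.dumps([t.as_dict() for t in truths], indent=1) + "\n"
        )
    return outdir / "manifest.json"
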