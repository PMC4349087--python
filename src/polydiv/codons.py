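"""Standard genetic code utilities and Nei-Gojobori codon counting.

Site opportunities (how many of a codon's positions are synonymous vs
nonsynonymous "sites") and pathway-averaged difference counts between two
codons follow Nei & Gojobori (1986) unweighted counting under the standard
genetic code. Single-base changes that would create a stop codon are
excluded from the per-position site denominator, so a codon adjacent to a
stop contributes slightly less than 3 sites in total.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations

from Bio.Data.CodonTable import standard_dna_table

from .errors import AnnotationError

BASES = "ACGT"

#: codon -> single-letter amino acid, stop codons absent
GENETIC_CODE: dict[str, str] = dict(standard_dna_table.forward_table)
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(GENETIC_CODE))


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate_codon(codon: str) -> str | None:
    """Amino acid for ``codon``, or ``None`` for a stop codon."""
    if codon in STOP_CODONS:
        return None
    try:
        return GENETIC_CODE[codon]
    except KeyError:
        raise AnnotationError(f"not a valid codon: {codon!r}") from None


@lru_cache(maxsize=None)
def count_syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Nei-Gojobori synonymous/nonsynonymous site counts for one codon.

    Each position contributes (synonymous changes)/3 synonymous sites and
    (nonsynonymous changes)/3 nonsynonymous sites, where changes to stop
    codons count toward neither; a position with a stop neighbour therefore
    contributes less than one site in total.

    Raises
    ------
    AnnotationError
        If ``codon`` is a stop codon or not a valid DNA triplet.
    """
    if is_stop(codon):
        raise AnnotationError(f"stop codon has no site counts: {codon}")
    aa = translate_codon(codon)
    syn = 0.0
    nonsyn = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
    return syn, nonsyn


def is_synonymous_change(codon: str, pos: int, alt: str) -> bool:
    """Whether replacing position ``pos`` of ``codon`` with ``alt`` is synonymous.

    A change creating a stop codon is treated as nonsynonymous (an observed
    premature stop is a radical protein change).
    """
    mutant = codon[:pos] + alt + codon[pos + 1 :]
    if is_stop(mutant):
        return False
    return translate_codon(mutant) == translate_codon(codon)


@lru_cache(maxsize=None)
def codon_path_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons.

    Codons differing at k positions are compared along all k! mutational
    orderings; orderings that pass through a stop codon are discarded and the
    difference counts averaged over the remaining ones. If every ordering is
    blocked by a stop, each differing position is classified independently in
    the context of ``codon1``.
    """
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid = []
    for order in permutations(diff_pos):
        current = codon1
        syn = 0
        nonsyn = 0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon2[pos] + current[pos + 1 :]
            if is_stop(nxt):
                blocked = True
                break
            if translate_codon(nxt) == translate_codon(current):
                syn += 1
            else:
                nonsyn += 1
            current = nxt
        if not blocked:
            valid.append((syn, nonsyn))
    if not valid:
        syn = sum(is_synonymous_change(codon1, p, codon2[p]) for p in diff_pos)
        return float(syn), float(len(diff_pos) - syn)
    syn = sum(v[0] for v in valid) / len(valid)
    nonsyn = sum(v[1] for v in valid) / len(valid)
    return syn, nonsyn


@lru_cache(maxsize=None)
def synonymous_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """All (position, alternative base) synonymous single-base changes."""
    return tuple(
        (pos, alt)
        for pos in range(3)
        for alt in BASES
        if alt != codon[pos] and not is_stop(codon[:pos] + alt + codon[pos + 1 :])
        and is_synonymous_change(codon, pos, alt)
    )


@lru_cache(maxsize=None)
def nonsynonymous_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """All (position, alternative base) nonsynonymous, non-stop changes."""
    return tuple(
        (pos, alt)
        for pos in range(3)
        for alt in BASES
        if alt != codon[pos] and not is_stop(codon[:pos] + alt + codon[pos + 1 :])
        and not is_synonymous_change(codon, pos, alt)
    )


@lru_cache(maxsize=None)
def ng_sites_by_position(codon: str) -> tuple[tuple[float, float], ...]:
    """Per-position (synonymous, nonsynonymous) Nei-Gojobori site contributions.

    Each position contributes (changes of that kind)/3, with changes to stop
    codons contributing to neither; summing over the three positions gives
    :func:`count_syn_nonsyn_sites`.
    """
    aa = translate_codon(codon)
    if aa is None:
        raise AnnotationError(f"stop codon: {codon}")
    out = []
    for pos in range(3):
        syn = 0.0
        nonsyn = 0.0
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1 :]
            if is_stop(mutant):
                continue
            if GENETIC_CODE[mutant] == aa:
                syn += 1.0 / 3.0
            else:
                nonsyn += 1.0 / 3.0
        out.append((syn, nonsyn))
    return tuple(out)
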