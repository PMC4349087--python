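"""Per-locus alignment containers, manifest IO, and site classification.

A locus is represented by a :class:`LocusAlignment`: an aligned set of
ingroup alleles plus one outgroup sequence, with coding segments annotated in
alignment coordinates. :func:`classify_sites` assigns every alignment column
a site class and computes the fractional synonymous/nonsynonymous site
opportunities (Nei-Gojobori counting on the ingroup consensus) that serve as
denominators for diversity and divergence statistics.

Coordinates are 0-based half-open internally; the manifest dialect uses
1-based inclusive coordinates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codons import count_syn_nonsyn_sites, is_stop, is_synonymous_change, ng_sites_by_position
from .errors import AlignmentError, AnnotationError, ManifestError

VALID_CHARS = frozenset("ACGTN-")

# byte encoding for alignment matrices
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 255, "-": 255}
_DECODE = np.full(256, b"N"[0], dtype=np.uint8)
for _b, _c in zip("ACGT", range(4)):
    _DECODE[_c] = ord(_b)
MISSING = 255

# site classes
NONCODING = "noncoding"
SYNONYMOUS = "synonymous_position"
NONSYNONYMOUS = "nonsynonymous_position"
MIXED = "mixed"
EXCLUDED = "excluded"


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A,C,G,T -> 0..3; N,- -> 255)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    out = np.full(arr.shape, MISSING, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    return out


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass
class LocusAlignment:
    """Aligned ingroup alleles plus one outgroup sequence for a single locus."""

    locus_id: str
    ingroup_ids: list[str]
    ingroup_seqs: list[str]
    outgroup_id: str
    outgroup_seq: str
    coding_segments: list[tuple[int, int, int]] = field(default_factory=list)
    chromosome_label: str = ""
    group_label: str = "control"
    pathway_label: str | None = None
    paired_control_id: str | None = None

    def __post_init__(self) -> None:
        self.ingroup_seqs = [s.upper() for s in self.ingroup_seqs]
        self.outgroup_seq = self.outgroup_seq.upper()
        if len(self.ingroup_ids) != len(self.ingroup_seqs):
            raise AlignmentError(f"{self.locus_id}: ids/sequences length mismatch")
        if self.n < 2:
            raise AlignmentError(f"{self.locus_id}: need at least 2 ingroup alleles")
        lengths = {len(s) for s in self.ingroup_seqs} | {len(self.outgroup_seq)}
        if len(lengths) != 1:
            raise AlignmentError(f"{self.locus_id}: sequences have unequal lengths {sorted(lengths)}")
        if self.length < 1:
            raise AlignmentError(f"{self.locus_id}: empty alignment")
        for sid, seq in zip(self.ingroup_ids + [self.outgroup_id], self.ingroup_seqs + [self.outgroup_seq]):
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(f"{self.locus_id}/{sid}: illegal characters {sorted(bad)}")
        segs = sorted(self.coding_segments)
        for (s1, e1, _), (s2, e2, _) in zip(segs, segs[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.locus_id}: overlapping coding segments")
        for s, e, f in segs:
            if not (0 <= s < e <= self.length) or f not in (0, 1, 2):
                raise AnnotationError(f"{self.locus_id}: bad coding segment ({s},{e},{f})")
        self.coding_segments = segs

    @property
    def n(self) -> int:
        return len(self.ingroup_seqs)

    @property
    def length(self) -> int:
        return len(self.outgroup_seq)

    def ingroup_matrix(self) -> np.ndarray:
        return np.vstack([encode(s) for s in self.ingroup_seqs])

    def full_matrix(self) -> np.ndarray:
        """Ingroup rows followed by the outgroup row."""
        return np.vstack([encode(s) for s in self.ingroup_seqs] + [encode(self.outgroup_seq)])

    def subset(self, ids: Sequence[str], locus_id: str | None = None) -> "LocusAlignment":
        """New alignment restricted to the given ingroup allele ids (order preserved)."""
        index = {i: k for k, i in enumerate(self.ingroup_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise AlignmentError(f"{self.locus_id}: unknown allele ids {missing}")
        return LocusAlignment(
            locus_id=locus_id or self.locus_id,
            ingroup_ids=list(ids),
            ingroup_seqs=[self.ingroup_seqs[index[i]] for i in ids],
            outgroup_id=self.outgroup_id,
            outgroup_seq=self.outgroup_seq,
            coding_segments=list(self.coding_segments),
            chromosome_label=self.chromosome_label,
            group_label=self.group_label,
            pathway_label=self.pathway_label,
            paired_control_id=self.paired_control_id,
        )


@dataclass
class SiteClassTable:
    """Per-column site classes and per-locus site-opportunity totals."""

    classes: list[str]
    retained: np.ndarray  # bool per column (passes complete deletion)
    silent_fraction: np.ndarray  # per-column silent site contribution
    syn_sites: float  # L_syn
    nonsyn_sites: float  # L_nonsyn
    silent_sites: float  # L_silent = L_syn + usable noncoding columns
    noncoding_sites: float
    codon_columns: list[tuple[int, int, int]]  # alignment columns of each analyzable codon
    consensus_codons: list[str]
    column_codon: dict[int, tuple[int, int]]  # column -> (codon index, position in codon)

    @property
    def n_codons(self) -> int:
        return len(self.codon_columns)


def _coding_columns(aln: LocusAlignment) -> list[int]:
    cols: list[int] = []
    for s, e, _ in aln.coding_segments:
        cols.extend(range(s, e))
    if aln.coding_segments:
        frame = aln.coding_segments[0][2]
        cols = cols[frame:]
    return cols


def consensus_codes(matrix: np.ndarray) -> np.ndarray:
    """Majority-rule consensus (ties -> smallest base code) per column; 255 if all missing."""
    n, L = matrix.shape
    out = np.full(L, MISSING, dtype=np.uint8)
    counts = np.zeros((4, L), dtype=np.int64)
    for b in range(4):
        counts[b] = (matrix == b).sum(axis=0)
    any_valid = counts.sum(axis=0) > 0
    out[any_valid] = counts[:, any_valid].argmax(axis=0)
    return out


def classify_sites(
    aln: LocusAlignment,
    on_internal_stop: str = "error",
) -> SiteClassTable:
    """Classify every column and compute Nei-Gojobori site-opportunity totals.

    Complete deletion: any column with a gap or N in any sequence (ingroup or
    outgroup) is excluded from every total. Codons are built by concatenating
    the coding segments (honouring the first segment's frame offset) and
    dropping trailing partial codons; a codon is analyzable only if all three
    of its columns are retained and its ingroup consensus is not a stop.

    Segregating coding columns are classed by the observed changes relative
    to the consensus codon: all synonymous -> ``synonymous_position``, all
    nonsynonymous -> ``nonsynonymous_position``, both -> ``mixed`` (excluded
    from synonymous/nonsynonymous numerators). Monomorphic coding columns are
    classed by their majority mutational opportunity; this choice only
    affects labels, not any statistic, since monomorphic columns carry no
    differences.

    Parameters
    ----------
    on_internal_stop:
        ``"error"`` raises :class:`AnnotationError` when the consensus coding
        sequence contains a stop before its final codon; ``"warn"`` (or
        ``"ignore"``) drops the stop codon and continues.
    """
    if on_internal_stop not in ("error", "warn", "ignore"):
        raise ValueError("on_internal_stop must be 'error', 'warn' or 'ignore'")
    matrix = aln.full_matrix()
    ingroup = matrix[:-1]
    L = aln.length
    retained = ~(matrix == MISSING).any(axis=0)

    classes = [EXCLUDED] * L
    for col in range(L):
        if retained[col]:
            classes[col] = NONCODING
    silent_fraction = np.zeros(L, dtype=float)
    silent_fraction[retained] = 1.0

    coding_cols = _coding_columns(aln)
    # mark every coding column non-silent until (re)assigned through its codon
    for col in coding_cols:
        if retained[col]:
            classes[col] = MIXED
            silent_fraction[col] = 0.0

    cons = consensus_codes(ingroup)
    codon_columns: list[tuple[int, int, int]] = []
    consensus_codons: list[str] = []
    column_codon: dict[int, tuple[int, int]] = {}

    triplets = [tuple(coding_cols[i : i + 3]) for i in range(0, len(coding_cols) - 2, 3)]
    stop_seen_before_end = False
    for t_idx, cols3 in enumerate(triplets):
        if not all(retained[c] for c in cols3):
            continue
        codon = decode(cons[list(cols3)])
        if is_stop(codon):
            if t_idx < len(triplets) - 1:
                stop_seen_before_end = True
            continue
        codon_columns.append(cols3)  # type: ignore[arg-type]
        consensus_codons.append(codon)
    if stop_seen_before_end and on_internal_stop == "error":
        raise AnnotationError(f"{aln.locus_id}: internal stop codon in consensus coding sequence")

    syn_total = 0.0
    nonsyn_total = 0.0
    for c_idx, (cols3, codon) in enumerate(zip(codon_columns, consensus_codons)):
        s, a = count_syn_nonsyn_sites(codon)
        syn_total += s
        nonsyn_total += a
        per_pos = ng_sites_by_position(codon)
        for pos, col in enumerate(cols3):
            column_codon[col] = (c_idx, pos)
            silent_fraction[col] = per_pos[pos][0]
            states = np.unique(ingroup[:, col])
            states = states[states != MISSING]
            ref = codon[pos]
            observed_alts = [b for b in "ACGT" if _CODE[b] in states and b != ref]
            if observed_alts:
                flags = [is_synonymous_change(codon, pos, alt) for alt in observed_alts]
                if all(flags):
                    classes[col] = SYNONYMOUS
                elif not any(flags):
                    classes[col] = NONSYNONYMOUS
                else:
                    classes[col] = MIXED
            else:
                s_pos, a_pos = per_pos[pos]
                classes[col] = SYNONYMOUS if s_pos >= a_pos and s_pos > 0 else NONSYNONYMOUS

    noncoding_sites = float(sum(1 for c in range(L) if classes[c] == NONCODING))
    return SiteClassTable(
        classes=classes,
        retained=retained,
        silent_fraction=silent_fraction,
        syn_sites=syn_total,
        nonsyn_sites=nonsyn_total,
        silent_sites=syn_total + noncoding_sites,
        noncoding_sites=noncoding_sites,
        codon_columns=codon_columns,
        consensus_codons=consensus_codons,
        column_codon=column_codon,
    )


# ---------------------------------------------------------------------------
# manifest + FASTA IO


def _parse_segments(value, length_hint: int | None = None) -> list[tuple[int, int, int]]:
    """Parse manifest coding segments (1-based inclusive) to 0-based half-open."""
    if value in (None, "", []):
        return []
    if isinstance(value, str):
        parts = []
        for chunk in value.split(";"):
            chunk = chunk.strip()
            if not chunk:
                continue
            frame = 0
            if ":" in chunk:
                chunk, frame_s = chunk.split(":")
                frame = int(frame_s)
            start_s, end_s = chunk.split("-")
            parts.append((int(start_s), int(end_s), frame))
        value = parts
    out = []
    for seg in value:
        if len(seg) == 2:
            start, end = seg
            frame = 0
        else:
            start, end, frame = seg
        out.append((int(start) - 1, int(end), int(frame)))
    return out


def read_manifest(path: str | Path) -> list[dict]:
    """Read a JSON or TSV locus manifest into a list of entry dicts.

    Each entry has keys: ``locus_id, file, outgroup, coding_segments, group,
    pathway, paired_control, chromosome`` (missing optional keys filled with
    defaults). Coding segments use 1-based inclusive coordinates with an
    optional ``:frame`` suffix in the TSV dialect.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            entries = list(csv.DictReader(fh, delimiter="\t"))
    out = []
    for raw in entries:
        if "locus_id" not in raw or "file" not in raw or "outgroup" not in raw:
            raise ManifestError(f"manifest entry missing required keys: {raw}")
        out.append(
            {
                "locus_id": raw["locus_id"],
                "file": raw["file"],
                "outgroup": raw["outgroup"],
                "coding_segments": raw.get("coding_segments") or [],
                "group": raw.get("group") or "control",
                "pathway": raw.get("pathway") or None,
                "paired_control": raw.get("paired_control") or None,
                "chromosome": raw.get("chromosome") or "",
            }
        )
    return out


def read_locus_fasta(path: str | Path, manifest_entry: dict) -> LocusAlignment:
    """Read one locus multi-FASTA and validate it against its manifest entry."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no FASTA records")
    outgroup_id = manifest_entry["outgroup"]
    ingroup_ids, ingroup_seqs = [], []
    outgroup_seq = None
    for rec in records:
        if rec.id == outgroup_id:
            if outgroup_seq is not None:
                raise ManifestError(f"{path}: outgroup id {outgroup_id!r} appears twice")
            outgroup_seq = str(rec.seq).upper()
        else:
            ingroup_ids.append(rec.id)
            ingroup_seqs.append(str(rec.seq).upper())
    if outgroup_seq is None:
        raise ManifestError(f"{path}: outgroup record {outgroup_id!r} not found")
    return LocusAlignment(
        locus_id=manifest_entry["locus_id"],
        ingroup_ids=ingroup_ids,
        ingroup_seqs=ingroup_seqs,
        outgroup_id=outgroup_id,
        outgroup_seq=outgroup_seq,
        coding_segments=_parse_segments(manifest_entry.get("coding_segments")),
        chromosome_label=manifest_entry.get("chromosome", ""),
        group_label=manifest_entry.get("group", "control"),
        pathway_label=manifest_entry.get("pathway"),
        paired_control_id=manifest_entry.get("paired_control"),
    )


def load_dataset(manifest_path: str | Path) -> list[LocusAlignment]:
    """Load all loci listed in a manifest; FASTA paths resolve relative to it."""
    manifest_path = Path(manifest_path)
    out = []
    seen = set()
    for entry in read_manifest(manifest_path):
        if entry["locus_id"] in seen:
            raise ManifestError(f"duplicate locus_id {entry['locus_id']!r}")
        seen.add(entry["locus_id"])
        fasta = Path(entry["file"])
        if not fasta.is_absolute():
            fasta = manifest_path.parent / fasta
        out.append(read_locus_fasta(fasta, entry))
    return out


def write_locus_fasta(path: str | Path, aln: LocusAlignment) -> None:
    records = [
        SeqRecord(Seq(seq), id=sid, description="")
        for sid, seq in zip(aln.ingroup_ids, aln.ingroup_seqs)
    ]
    records.append(SeqRecord(Seq(aln.outgroup_seq), id=aln.outgroup_id, description=""))
    SeqIO.write(records, str(path), "fasta")


def manifest_entry_for(aln: LocusAlignment, file_name: str) -> dict:
    """Manifest entry (1-based inclusive segment coordinates) for an alignment."""
    return {
        "locus_id": aln.locus_id,
        "file": file_name,
        "outgroup": aln.outgroup_id,
        "coding_segments": [[s + 1, e, f] for s, e, f in aln.coding_segments],
        "group": aln.group_label,
        "pathway": aln.pathway_label,
        "paired_control": aln.paired_control_id,
        "chromosome": aln.chromosome_label,
    }


def write_manifest(path: str | Path, entries: Iterable[dict]) -> None:
    Path(path).write_text(json.dumps(list(entries), indent=1) + "\n")
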