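"""Shared fixtures and alignment builders for the test suite."""

from __future__ import annotations

import pytest

from polydiv.seqdata import LocusAlignment


def make_alignment(
    ingroup: list[str],
    outgroup: str,
    coding: list[tuple[int, int, int]] | None = None,
    locus_id: str = "toy",
    **kwargs,
) -> LocusAlignment:
    """Toy alignment with auto-generated allele ids."""
    return LocusAlignment(
        locus_id=locus_id,
        ingroup_ids=[f"a{i:02d}" for i in range(len(ingroup))],
        ingroup_seqs=list(ingroup),
        outgroup_id="out",
        outgroup_seq=outgroup,
        coding_segments=coding or [],
        **kwargs,
    )


@pytest.fixture
def toy_noncoding():
    """4 alleles, 10 noncoding sites: one singleton and one 2:2 site."""
    return make_alignment(
        [
            "AAAAAAAAAA",
            "AAAAAAAAAT",
            "AACAAAAAAA",
            "AACAAAAAAT",
        ],
        "AAAAAAAAAA",
    )
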