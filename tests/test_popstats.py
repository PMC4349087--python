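"""Diversity/divergence statistics against brute-force and closed-form oracles."""

import math

import numpy as np
import pytest

from polydiv.errors import SaturationError
from polydiv.popstats import (
    group_means,
    harmonic,
    jc_correct,
    jc_corrected_divergence,
    locus_summary,
    pairwise_diversity,
    sliding_tajimas_d,
    summarize_loci,
    tajimas_d,
    watterson_theta,
)
from polydiv.seqdata import classify_sites
from polydiv.simulate import simulate_dataset, DatasetConfig

from conftest import make_alignment


def brute_force_pi(seqs: list[str]) -> float:
    """Mean pairwise difference count over all pairs (noncoding alignment)."""
    n = len(seqs)
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(a != b for a, b in zip(seqs[i], seqs[j]))
    return total / (n * (n - 1) / 2)


class TestPairwiseDiversity:
    def test_two_sequences_three_of_hundred(self):
        s1 = "A" * 100
        s2 = "T" * 3 + "A" * 97
        aln = make_alignment([s1, s2], s1)
        assert pairwise_diversity(aln, "all") == pytest.approx(0.03)

    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT" * 5] * 4, "ACGT" * 5)
        assert pairwise_diversity(aln, "all") == 0.0

    def test_matches_brute_force_over_six_pairs(self, toy_noncoding):
        expected = brute_force_pi(toy_noncoding.ingroup_seqs) / toy_noncoding.length
        assert pairwise_diversity(toy_noncoding, "all") == pytest.approx(expected)

    def test_zero_denominator_returns_none(self, toy_noncoding):
        assert pairwise_diversity(toy_noncoding, "synonymous") is None


class TestWatterson:
    def test_no_segregating_sites(self):
        assert watterson_theta(0, 10, 100) == 0.0

    def test_two_alleles(self):
        assert watterson_theta(5, 2, 100) == pytest.approx(0.05)

    def test_direct_harmonic_sum(self):
        a10 = sum(1 / j for j in range(1, 10))
        assert watterson_theta(7, 10, 350) == pytest.approx(7 / (a10 * 350))


def oracle_tajima_d(seqs: list[str]) -> float:
    """Independent transcription of the 1989 formulas."""
    n = len(seqs)
    L = len(seqs[0])
    S = sum(1 for col in range(L) if len({s[col] for s in seqs}) > 1)
    Pi = brute_force_pi(seqs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (Pi - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        aln = make_alignment(["AAAA"] * 4, "AAAA")
        assert tajimas_d(aln, "all") is None
        assert tajimas_d(aln, "silent") is None

    def test_matches_independent_formula_transcription(self, toy_noncoding):
        expected = oracle_tajima_d(toy_noncoding.ingroup_seqs)
        assert tajimas_d(toy_noncoding, "silent") == pytest.approx(expected)

    def test_larger_alignment_against_oracle(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=40)) for _ in range(6)]
        # make most columns shared to have realistic S
        base = seqs[0]
        seqs = [base[:30] + s[30:] for s in seqs]
        aln = make_alignment(seqs, base)
        assert tajimas_d(aln, "silent") == pytest.approx(oracle_tajima_d(seqs))


class TestSlidingWindows:
    def test_uniform_alignment_all_windows_undefined(self):
        aln = make_alignment(["A" * 300] * 4, "A" * 300)
        scan = sliding_tajimas_d(aln, window=200, step=25)
        assert all(r.tajima_d is None for r in scan.records)

    def test_whole_locus_window_equals_whole_locus_d(self, toy_noncoding):
        scan = sliding_tajimas_d(
            toy_noncoding, window=toy_noncoding.length, step=toy_noncoding.length, min_S=1
        )
        assert len(scan.records) == 1
        assert scan.records[0].tajima_d == pytest.approx(tajimas_d(toy_noncoding, "silent"))

    def test_oversized_window_degrades_with_warning(self, toy_noncoding):
        with pytest.warns(UserWarning):
            scan = sliding_tajimas_d(toy_noncoding, window=500, step=25, min_S=1)
        assert len(scan.records) == 1


class TestDivergence:
    def test_identical_outgroup_zero(self):
        aln = make_alignment(["ACGT" * 25] * 3, "ACGT" * 25)
        assert jc_corrected_divergence(aln, "all") == 0.0

    def test_closed_form_evaluation(self):
        assert jc_correct(0.03) == pytest.approx(-0.75 * math.log(0.96))

    def test_jc_monotone_and_asymptotically_linear(self):
        ps = np.linspace(0.001, 0.5, 50)
        ks = [jc_correct(p) for p in ps]
        assert all(k2 > k1 for k1, k2 in zip(ks, ks[1:]))
        assert jc_correct(1e-6) == pytest.approx(1e-6, rel=1e-3)

    def test_saturation_error(self):
        with pytest.raises(SaturationError):
            jc_correct(0.76)

    def test_toy_codon_divergence_matches_hand_computation(self):
        # 10 codons, one synonymous (TTT->TTC) and one nonsynonymous
        # (AAA->GAA, Lys->Glu) outgroup difference
        ing = "ATGTTTGGGCCCAAACTGGAATACCGATTG"
        out = "ATGTTCGGGCCCGAACTGGAATACCGATTG"
        aln = make_alignment([ing, ing], out, coding=[(0, 30, 0)])
        t = classify_sites(aln)
        ks = jc_corrected_divergence(aln, "synonymous", t)
        ka = jc_corrected_divergence(aln, "nonsynonymous", t)
        assert ks == pytest.approx(jc_correct(1.0 / t.syn_sites))
        assert ka == pytest.approx(jc_correct(1.0 / t.nonsyn_sites))


class TestGroupMeans:
    def test_mean_of_ratios_not_ratio_of_means(self):
        alns, _ = simulate_dataset(DatasetConfig(n_immune=2, n_control=2, n_alleles=4,
                                                 length=600, seed=3))
        df = summarize_loci(alns)
        df.loc[df.index[:2], "ka_ks"] = [0.1, 0.3]
        out = group_means(df[df["group"] == "immune"])
        assert out["ka_ks"].iloc[0] == pytest.approx(0.2)

    def test_single_locus_group_mean_equals_locus(self):
        alns, _ = simulate_dataset(DatasetConfig(n_immune=1, n_control=1, n_alleles=4,
                                                 length=600, seed=3))
        df = summarize_loci(alns)
        out = group_means(df)
        imm = out[out["group"] == "immune"]
        assert imm["pi_total"].iloc[0] == pytest.approx(
            df[df["group"] == "immune"]["pi_total"].iloc[0]
        )

    def test_spreadsheet_style_recomputation(self):
        alns, _ = simulate_dataset(DatasetConfig(n_immune=4, n_control=3, n_alleles=6,
                                                 length=600, seed=8))
        df = summarize_loci(alns)
        out = group_means(df)
        for g in ("immune", "control"):
            sub = df[df["group"] == g]
            row = out[out["group"] == g].iloc[0]
            assert row["K_A"] == pytest.approx(sub["K_A"].mean())
            assert row["pi_s"] == pytest.approx(sub["pi_s"].mean())


def test_locus_summary_pi_zero_implies_no_segregation():
    aln = make_alignment(["ACGT" * 10] * 5, "ACGT" * 10)
    s = locus_summary(aln)
    assert s.pi_total == 0.0
    assert s.S == 0
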