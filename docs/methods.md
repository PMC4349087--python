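# Methods

This note records the models implemented in `polydiv`, the numerical and
design choices made where several reasonable options existed, what the
synthetic-data generator does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Site classification and counting

Coordinates are 0-based half-open internally and 1-based inclusive in the
manifest dialect and all reports.

**Missing data.** Complete deletion is applied throughout: any column with a
gap or `N` in any sequence (ingroup or outgroup) is excluded from every
numerator and denominator. Pairwise deletion is used only where a statistic
is intrinsically pairwise (the distance matrices behind NJ trees and Dxy).

**Codons.** Coding segments are concatenated in order, the first segment's
frame offset is honoured, and trailing partial codons are dropped. A codon
is analyzable when all three of its columns survive deletion and its
ingroup majority-rule consensus is not a stop. An internal stop in the
consensus raises an error by default (configurable to warn and drop the
codon), since it usually signals a mis-specified reading frame.

**Nei–Gojobori counting.** Synonymous/nonsynonymous site opportunities use
unweighted Nei–Gojobori (1986) counting under the standard genetic code:
each codon position contributes (synonymous changes)/3 and (nonsynonymous
changes)/3, with changes to stop codons excluded from the per-position
denominator, so codons adjacent to stops contribute slightly fewer than 3
sites. Site opportunities are computed on the ingroup consensus coding
sequence — a deterministic, record-order-invariant choice; DnaSP instead
averages per-sequence counts, which differs negligibly at within-species
divergence levels. Difference counts between codons differing at several
positions are averaged over all mutational orderings that avoid stop
codons; if every ordering is blocked, positions are classified
independently in the first codon's context.

**Column classes.** A segregating coding column is `synonymous_position` if
every observed change (relative to the consensus codon) is synonymous,
`nonsynonymous_position` if every change is nonsynonymous, and `mixed`
otherwise; mixed columns are excluded from the πs/πa numerators. Monomorphic
coding columns are labelled by their majority mutational opportunity — this
affects only labels, never statistics, because monomorphic columns carry no
differences. "Silent" sites are synonymous coding positions plus usable
noncoding positions.

## Per-locus statistics

π is the mean over all n(n−1)/2 ingroup pairs of per-site differences on
the chosen site set; the denominators for πs/πa/π_silent are the fractional
Nei–Gojobori opportunities. Tajima's D follows the 1989 formulas with the
variance constants computed from the post-deletion allele count n; it is
reported as absent (never 0) when S = 0. Sliding windows default to 200 bp
with a 25 bp step on silent sites and suppress the statistic below
`min_S = 3` segregating sites — a guard against meaningless values in
near-invariant windows; both are configurable.

Divergence averages each ingroup allele against the outgroup and applies
the Jukes–Cantor correction K = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 raises a
saturation error in direct calls and is reported as absent in summary
tables. K_A/K_S is reported absent when K_S = 0, and group averages use the
mean of per-gene ratios, not the ratio of group means. All group means are
unweighted arithmetic means over genes, with per-statistic counts of
skipped (undefined) loci.

## Multilocus MK framework

Counts are modelled as independent Poissons with means E[Ps] = θ·L_syn,
E[Pn] = θ·L_nonsyn·f, E[Ds] = λ·L_syn, E[Dn] = λ·L_nonsyn·f/(1−α); θ and λ
are shared across loci, the constraint f is free per locus, and α is fixed
at 0 (M0), shared (M1), or per group (M2). This is one concrete choice
among algebraically equivalent parameterizations of MKtest-style models; it
supports negative α (segregating deleterious variants inflating Pn) and its
sign convention is pinned by simulation tests. Given (θ, λ, α) the
constraints have the closed form f̂ = (Pn+Dn)/(L_nonsyn·(θ + λ/(1−α))) and
are profiled out; the remaining 2–4 parameters are optimised by Nelder–Mead
in log space (α via log β, β = 1−α > 0) from 5 seeded restarts around
moment estimates. LRT statistics are clipped at 0 against optimizer noise.

AICc uses n_obs = 4·(number of loci) count cells. The parameter count is
n_loci + 2 + (0, 1, 2) for M0/M1/M2. Published tables of comparable
analyses do not document their AICc sample size or parameter bookkeeping,
so AICc values are comparable within a `polydiv` analysis, not across
software; likelihood-ratio statistics and Akaike weights computed from any
consistent AICc set are software-independent arithmetic and are verified as
such in the tests.

## Multilocus HKA

Each locus contributes S ~ Poisson(k·θ·L·a(n)) and
D ~ Poisson(θ·L·(T + (1+k)/2)), with a(n) the harmonic number, T the
divergence time in 2N-generation units, and the (1+k)/2 term carrying
ancestral polymorphism. This is one concrete rendering of the
Wright–Charlesworth maximum-likelihood HKA; it is validated by internal
parameter recovery (k = 0.2 planted at 1 of 30 loci is recovered within
[0.1, 0.4] in ≥ 90% of replicates) and by null calibration of the LRT, not
against any external per-locus dataset. θ_i is profiled per locus in closed
form; T and the candidate k's are optimised in log space with restarts. At
the null MLE the moment conditions Σ(S−Ê[S]) = 0 and Σ(D−Ê[D]) = 0 hold,
which the tests assert.

Divergence counts taken from alignments use the first ingroup allele versus
the outgroup (the single-sequence convention of the classical HKA input);
X-linked θ scaling is not applied automatically — a per-locus θ multiplier
hook exists, default 1, because the analyses this package mirrors report
X/autosome differences descriptively without correcting for them. Whether
any particular published run normalised locus lengths identically is
unknowable; HKA conclusions here should rest on the package's own fits.

## Clade diagnostics

Distances are JC69-corrected p-distances by default (p-distance available).
MEGA-style maximum-composite-likelihood distances are deliberately not
implemented: clade recovery, not branch-length fidelity, is the
analysis-critical output, and on within-species data the two are nearly
affine. Trees come from scikit-bio's Saitou–Nei neighbor joining.

The automatic two-clade call selects the NJ internal bipartition maximizing
mean between-clade distance over the pooled (pair-count-weighted) mean
within-clade distance; pooling prevents a tiny near-identical allele pair
from dominating the denominator. A manual override is available, matching
the by-inspection practice of the field. Clade "A" is the side containing
the lexicographically smallest allele id. Bootstrap support is the fraction
of column-resampled NJ trees containing the called bipartition, seeded and
reproducible.

A fixed difference between clades is a column where each clade is
monomorphic among its non-missing states and the clades share no state;
missing data does not break fixation. Dxy is the mean over cross-group
pairs of per-site differences (pairwise deletion per pair), and
Dxy(g, g) = within-group π. Within-clade diversity is expected to be
reduced relative to the pooled sample roughly in proportion to clade
frequency — clades segregating at 50% imply ≈ 50% within-clade π — because
conditioning on a clade scales the effective population size behind the
coalescent; Tajima's D, being a normalized contrast of two such estimators,
is not shifted by that scaling.

## Rank tests

Statistics follow R's `wilcox.test` conventions: U is R's W (rank sum of
the first sample minus n1(n1+1)/2, midranks for ties) and V is the sum of
ranks of positive paired differences with zeros dropped. Exact p-values are
used for tie-free samples with combined size ≤ 25, otherwise a normal
approximation with tie and continuity corrections (p-values delegated to
scipy; statistics computed here). Pairing for the signed-rank test comes
from the manifest's `paired_control` field: a control shared by two focal
genes enters once per pair, and focal genes without a position control are
excluded from paired tests. In pathway-level comparisons the control set is
the position-matched controls of that pathway's genes, so a shared control
re-enters each pathway's analysis. No multiple-testing correction is
applied, matching the analysis design this package mirrors.

## Synthetic-data generator

Time is in units of 2N generations; θ is per site. The coalescent engine
supports piecewise population structure (per-population scales, timed
merges) and is exercised against closed forms: E[T_MRCA] = 2(1−1/n),
E[S] = θ·L·a_n, E[π] = θ per site, mean Tajima's D ≈ 0.

**Outgroup.** The outgroup lineage splits at T with an Exp(1) ancestral
coalescent tail on both sides, so the expected one-allele-vs-outgroup
divergence is θL(T+1), consistent with the HKA divergence expectation at
k = 1. In the balanced scenario the two ancestral branches are lumped onto
the outgroup branch, which is observationally equivalent for every
statistic computed here.

**Coding loci.** The ancestral sequence is random sense codons plus random
noncoding sequence. Synonymous and noncoding polymorphisms arise at the
neutral rate on the genealogy; nonsynonymous polymorphisms are thinned by
f; fixed differences are drawn directly as Poisson counts at λ = θ·T per
neutral site (nonsynonymous at λ·L_nonsyn·f/(1−α)) and applied to the
outgroup sequence — direction is irrelevant to every downstream count. At
most one mutation is placed per codon, so the synonymous/nonsynonymous
identity of every change is context-unambiguous and the generator's truth
counts are exactly recoverable by `build_mk_table`, which the tests assert
per locus. The cost is the absence of multi-hit codons, a negligible
feature at the simulated divergences.

**Study-shape dataset.** Defaults are the conditions of the motivating
study design: 20 immune (8 Imd, 7 Toll, 5 other) and 17 control loci, one
focal locus unpaired and two controls shared between focal pairs, 20
alleles per locus, 1.8 kb loci with 70% coding, silent θ = 0.026 (giving
πs ≈ 2.6% and total π ≈ 1.4%), T = 1.3 (K_S ≈ 6%), constraint f drawn
Beta(2, 9.4) for immune loci (mean 0.175) and Beta(2, 24) for controls
(mean 0.077) so the groups differ in constraint but not adaptation
(α = 0 in both). Reduced X-chromosome diversity is *not* emulated;
chromosome labels are cosmetic.

**Balanced polymorphism.** Two allelic classes joined at depth τ = 5, three
descendant species splitting at 1.0 (so the clade split is 5× the species
divergence), clade frequencies 0.5/0.5, a 1 kb locus whose first 350 bp
form the clade-defining block carrying 11 diagnostic fixed differences,
θ = 0.015, outgroup at T = 6, 20 focal plus 10 alleles per other species.
Within-clade coalescence runs at clade-frequency-scaled effective size. The
block region follows a single non-recombining genealogy; non-block sequence
approximates recombination decay with independent species-structured
genealogies per 100 bp chunk. The chunk length is a discretization-fidelity
parameter of the approximation, not a biological condition: at coarse
chunking the approximation's own genealogical variance occasionally
produces within-clade distances rivalling cross-clade ones (an artifact no
freely recombining flank would show), while results are stable from 100 bp
downward. The balanced locus is modelled as noncoding sequence, since its
diagnostics (π, D, Dxy, clades) do not involve codon structure.

What passing the balanced-scenario tests shows: the analysis stack recovers
planted clades, localizes positive Tajima's D to the block, and reproduces
the between-vs-within-clade cross-species Dxy contrast under the stated
model. What it does not show: robustness to gene conversion, to unequal
clade frequencies drifting over time, or to genuine recombination within
the block — none of which the generator emulates. Cross-species clade Dxy
in the acceptance checks is computed over the block region, mirroring the
comparative amplicons that cover the clade-defining 5' region in real
datasets; whole-locus Dxy dilutes the contrast by the shared flanking
genealogy.

## Problem sizes in the shipped checks

The test suite and acceptance script use 1000 neutral calibration
replicates; 200 replicates for MK type-I error (40 loci at study-scale
counts), HKA k-recovery (30 loci) and the balanced-scenario Dxy/π-ratio
properties; 40 replicates per α value for bias checks; and 400 bootstrap
replicates on a subset of balanced datasets. These sizes give Monte-Carlo
error comfortably inside the asserted bands while keeping the default runs
quick; production analyses should use the 1000-replicate bootstrap default.

## Known limitations

- No recombination-aware variance corrections in HKA or the MK framework.
- No frequency-filtered MK variants or DFE-based α estimators.
- No Fu & Li / Fay & Wu statistics, linkage statistics, or recombination
  estimation.
- The clade caller targets exactly two clades; more complex haplotype
  structure needs the manual override.
- Alignments are taken as given: no realignment, ORF discovery, or
  sequence retrieval.
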