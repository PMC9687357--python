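# Methods

## Scope and model

`mitoeditkit` treats a plant mitogenome as a single circular "master circle"
(MC) sequence with a flat gene table. Three analyses hang off that
coordinate authority:

1. **Editing-site calling.** C-to-U editing is observed as a C(genome)/
   T(cDNA) substitution in a CDS-vs-cDNA comparison. The model is binary
   per site (edited in the assembled transcript or not); partial editing
   fractions are out of scope because the input is assembled cDNA, not
   read-level RNA-seq.
2. **Codon-usage consequences.** Edits are applied in silico and codons are
   compared pairwise. Because editing substitutes within codons and never
   inserts or deletes, the 64-codon delta vector is zero-sum by
   construction — that invariant is asserted, not assumed.
3. **Conformation evidence.** Loop-out recombination between two identical
   direct repeats (copies A and B, flanks FR1|LDR|FR2 and FR3|LDR|FR4 on
   the MC) excises the inter-repeat arc with one copy. The products are
   deterministic: sc2 = copy A + inner arc (junction FR3-LDR-FR2), sc1 =
   copy B + outer arc (junction FR1-LDR-FR4), and |sc1| + |sc2| = |MC|.
   The subcircle names follow the junction-type convention (type 3 reads
   belong to SC1, type 4 to SC2); which arc each name lands on therefore
   depends on repeat placement, not on size.

## Coordinates and degenerate inputs

All user-facing coordinates are 1-based inclusive. A feature whose end
exceeds the sequence length is legal on a circular molecule and is split
into two in-range segments in coding order (for minus-strand genes the wrap
piece leads); linear sequences reject it. N bases are carried through
sequences but excluded from every GC numerator and denominator, and codons
containing N (or a trailing incomplete frame) are excluded from all codon
counts with an exclusion tally. Translation uses the standard genetic code
(plant mitochondria retain it; the editing-created ACG→AUG starts and
CAA→UAA stops are consistent with table 1), and internal stops are rendered
as `*` rather than truncating — the effects module needs to see them.

## Alignment and calling parameters

Global affine alignment (Biopython `PairwiseAligner`): match +2, mismatch
−3, gap open −5, gap extend −2. A CDS/cDNA pairing is usable at identity
≥ 0.90 over aligned bases and CDS coverage ≥ 0.50; this tolerates the few
percent of mismatch that heavy editing produces while rejecting paralogous
transcripts. Mismatch columns within `gap_margin` = 3 columns of any indel
are masked (indel shadows are the dominant false-call source). With
multiple transcripts per gene, sites are called per transcript and merged
by strict majority (> 50% of usable transcripts), with the support count
kept per site. On a minus-strand gene the coding-strand C→U event is
reported at its genome coordinate as G→A, with the coding-strand identity
retained.

## Codon-usage indices

GCk is the G+C fraction among non-N bases at codon position k over complete
codons; GC12 is the mean of GC1 and GC2. GC3s covers third positions of all
codons except the three stops, AUG and UGG — the only codons without
synonymous third-position freedom; 2-, 3-, 4- and 6-fold families all
contribute.

ENC is Wright's Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆ with per-family
homozygosity F̂ = (nΣp̂² − 1)/(n − 1), families with n < 2 excluded from
class means, the (F̄₂+F̄₄)/2 fallback when isoleucine (the lone 3-fold
family) is absent, and the value clamped to [20, 61]. If a 2-, 4- or 6-fold
class is empty, or a class mean is non-positive, ENC is undefined with the
reason attached; published ENC implementations differ in unstated details,
so decimal-for-decimal parity with any particular tool is not claimed —
correctness is instead checked against an independent brute-force
implementation of the same formula. The expected-ENC reference curve is
2 + s + 29/(s² + (1−s)²).

The neutrality fit is ordinary least squares of GC12 on GC3 (that
regression direction is fixed), requiring ≥ 3 genes and nonzero GC3
variance; |slope| is reported as the mutation–selection equilibrium
coefficient and 100·|slope| as the mutation contribution in percent.

## Repeat finding and read typing

Direct-repeat discovery is exact-match only (the loop-out substrate is a
pair of *identical* repeats): seed k-mers (k = min(min_len, 32)) are
extended to maximal runs per diagonal on the doubled sequence when
circular, deduplicated, and pairs whose copies overlap on the circle
(tandem periods) are excluded; abutting copies are kept. Inverted repeats
are reported separately on request. Output is verified in tests against a
quadratic all-diagonal scan.

Read typing anchors the `min_anchor` (default 100 bp) repeat-proximal edge
of one upstream flank (FR1/FR3) and one downstream flank (FR2/FR4) in the
read via infix edit-distance search (edlib), in both read orientations. A
type is assigned when exactly one junction arrangement matches with the two
anchors separated by approximately the repeat length (±25% + 50 bp, an
indel allowance); anything else is ambiguous. The anchor edit tolerance is
15% of the anchor span: at a 5% long-read error rate a 100-bp anchor
carries ~5 expected edits, and a 10% cap would reject ~1.4% of true anchors
(P[Poisson(5) > 10]) — enough to drop two-anchor agreement below 99% — while
15% keeps the rejection probability near 3·10⁻⁵ and random flank matches
remain unreachable (expected edit distance ~75%). Flank size defaults to
1,000 bp, matching standard practice of examining 1-kb flanking regions.

## Synthetic data: what it emulates, what it does not

The generator plants the structures the analyses detect, with defaults at
realistic scale for a small plant mitogenome: 50-kb circle, 20 genes
(300–1500 bp, both strands, uniform sense-codon composition so ENC/GC of
fixtures is analytically predictable), ~16 editing sites per gene (the
genome-wide density of ~500 sites over ~31 genes), codon-position weights
(0.3012, 0.6378, 0.0610) reflecting the observed 2nd > 1st >> 3rd bias, a
5,222-bp repeat pair, eight transcripts per gene, and 8 ± 1.5 kb reads at
5% error (substitution:insertion:deletion 60:20:20, a generic long-read
profile) mixed 60/25/15 across MC/SC1/SC2.

Site planting draws the codon-position class first and then searches for a
valid C within the class, so stop-creating rejections (disabled edits
unless `allow_stop_gain`) do not skew the realized position spectrum; a
class can still exhaust in short genes at extreme densities, which is why
recovery tests run at realistic density. Every fixture carries a
self-consistency check (planted sites applied to planted CDSs reproduce the
stored edited sequences) and is byte-deterministic per seed.

Passing on this generator shows coordinate bookkeeping, accounting
identities and classifier behaviour are correct under the stated error
model. It does not show robustness to real-data pathologies the generator
deliberately omits: uneven coverage, chimeric reads, non-uniform error
profiles, paralogous gene families, partial editing, or
annotation errors beyond the stale-site guard.

## Problem sizes and numerical choices

Tests run the editing-recovery property on 50 seeded 9-kb/4-gene fixtures,
length conservation on 500 random repeat placements, the neutrality
zero-slope coverage on 200 replicates of 30 genes, and the full pipeline on
one 50-kb/20-gene/2,000-read fixture — sizes chosen to exercise every code
path at desk scale. Binomial 95% half-widths are used for all stochastic
recovery assertions; exact equality is asserted for accounting identities
(zero-sum, flow conservation, truth recovery on error-free input).
Tie-break conventions: conversion rows sort nonsynonymous-first by
descending count; repeat pairs sort longest-first; the canonical repeat
pair stores the smaller start as copy A.

## Known limitations

- The editing caller assumes one locus per gene id; multi-copy genes with
  divergent paralogs should be split upstream.
- ENC is undefined (with reason) rather than approximated for genes missing
  whole degeneracy classes — common below ~50 codons.
- Repeat finding is exact-match; near-identical repeat pairs (which also
  recombine in vivo) are out of scope.
- Boundary typing reports read counts only; it makes no claim about
  conformation stoichiometry, and a read spanning two junctions (possible
  for very close repeat copies) is deliberately left ambiguous.
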