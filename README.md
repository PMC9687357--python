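# mitoeditkit

Analysis toolkit for circular plant mitochondrial genomes, built around the
comparative workflow used for the *Sedum plumbizincicola* master circle
(GenBank OP588116): C-to-U RNA-editing site calling from CDS/cDNA
comparison, codon-level accounting of editing consequences, codon-usage
selection indices, and repeat-mediated loop-out isoform evidence from long
reads. A synthetic-data generator with full ground truth makes the whole
pipeline testable offline.

## Who this is for

Organelle genomicists who have a mitogenome assembly, per-gene cDNA
(assembled transcript) sequences, and optionally long reads, and want
reproducible answers to four questions:

1. **Where is the transcript edited?** In plant mitochondria, cytidine
   deamination converts C to U post-transcriptionally, so cDNA reads T where
   the genome reads C. `mitoeditkit` globally aligns each coding sequence to
   its cDNA (affine gaps), masks indel shadows, and emits each C(CDS)/T(cDNA)
   column as an editing site with CDS, codon and genome coordinates. Reverse
   U-to-C candidates are tallied separately, never merged.
2. **What does editing do to the proteome?** Applying the sites in silico
   gives the amino-acid conversion spectrum (with its synonymous /
   nonsynonymous split), the 64-codon usage table before editing with signed
   deltas after (zero-sum by construction), and editing-created start
   (ACG→AUG) and stop codons.
3. **Mutation or selection?** Per-gene GC1/GC2/GC3/GC12/GC3s, Wright's
   effective number of codons `Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, the
   no-selection reference curve `ENC_exp = 2 + s + 29/(s² + (1−s)²)` over
   GC3s, and the neutrality plot: OLS of GC12 on GC3, whose absolute slope
   is the mutation–selection equilibrium coefficient (1 = pure mutational
   drift, 0 = complete selective constraint on positions 1–2).
4. **Does the genome exist as one circle or several?** A pair of identical
   large direct repeats (LDRs) can loop out two subgenomic circles whose
   lengths sum to the master circle's. Labelling the repeat flanks
   FR1|LDR|FR2 and FR3|LDR|FR4, long reads anchored across a junction are
   typed 1 (FR1-LDR-FR2) or 2 (FR3-LDR-FR4) for the master circle, 3
   (FR1-LDR-FR4) for SC1, 4 (FR3-LDR-FR2) for SC2; joint observation of all
   four types evidences coexisting conformations.

## Worked example

Generate a synthetic 50-kb circular genome (20 genes on both strands,
planted C-to-U sites with the canonical 2nd > 1st >> 3rd codon-position
bias, one 5,222-bp direct-repeat pair, 2,000 noisy long reads from the
MC/SC1/SC2 mixture), then run the full pipeline:

```bash
mitoeditkit simulate --seed 42 --out-dir fixture/
mitoeditkit run-all \
    --genome fixture/genome.fasta --annotation fixture/genome.gff3 \
    --cdna fixture/cdna.fasta --reads fixture/reads.fasta \
    --out results/ --repeat-min-len 1000
```

The summary JSON printed at the end includes (seed 42):

```json
{
  "n_editing_sites": 327,
  "position_fractions_pct": [29.36, 63.3, 7.34],
  "total_codons_changed": 322,
  "n_nonsynonymous": 279,
  "n_synonymous": 43,
  "delta_zero_sum": 0,
  "isoforms": {
    "sc1_length": 31593, "sc2_length": 18407,
    "all_four_types": true
  }
}
```

Reading this: 327 editing sites were called (exactly the planted truth set —
the caller is exact on error-free cDNA) with the configured position bias
recovered, they changed 322 codons
(some codons carry two sites), the codon-usage deltas sum to zero as they
must, and the two loop-out subcircles conserve the 50,000-bp master length
while all four boundary junction types were seen in the reads, evidencing
the three coexisting conformations. Per-site, per-codon and per-gene detail
lands in `results/*.tsv` (editing sites, conversion table, usage deltas,
codon stats, neutrality points, ENC–GC3s plot data, boundary calls).

On the published *S. plumbizincicola* accounting (embedded in
`mitoeditkit.datasets` as raw counts), the builders reproduce the genome's
reported totals: 496 changed codons (474 nonsynonymous / 22 synonymous),
Ser→Leu at 22.98%, a net gain of 211 leucine codons consistent between the
conversion flows and the usage deltas, and the 156,162 bp + 55,997 bp
loop-out decomposition of the 212,159-bp master circle.

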