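"""Published reference tables for the *Sedum plumbizincicola* mitogenome.

Two small published accounting tables for the S. plumbizincicola master
circle (GenBank OP588116) are embedded here as plain TSV text: the
amino-acid conversion spectrum caused by C-to-U RNA editing in its 31
protein-coding genes, and the codon-usage table before editing with the
per-codon changes after. They serve as desk-scale inputs: the package's
builders recompute every derived quantity (totals, ratios, the
synonymous/nonsynonymous split, per-amino-acid codon flux) from the raw
counts rather than trusting any printed summary.

Amino acids use three-letter names; codons are RNA (U) alphabet. The
``printed_*`` columns keep the rounded percentages as published, for
cross-checks against recomputation.
"""

from __future__ import annotations

import io

import pandas as pd

from mitoeditkit.editing_effects import ConversionTable, CodonUsageDelta

#: amino-acid conversion counts over all changed codons (OP588116 PCGs)
SEDUM_AA_CONVERSIONS_TSV = """\
aa_from	aa_to	count	printed_ratio_pct
Ser	Leu	114	22.98
Pro	Leu	112	22.58
Ser	Phe	73	14.72
Pro	Ser	42	8.47
Arg	Cys	37	7.46
Arg	Trp	32	6.45
His	Tyr	21	4.23
Leu	Phe	15	3.02
Thr	Ile	9	1.81
Ala	Val	6	1.21
Thr	Met	6	1.21
Pro	Phe	6	1.21
Gln	Termination	1	0.20
Leu	Leu	6	1.21
Phe	Phe	5	1.01
Ile	Ile	3	0.60
Tyr	Tyr	3	0.60
Pro	Pro	2	0.40
Val	Val	2	0.40
Ser	Ser	1	0.20
"""

#: codon usage before RNA editing and signed per-codon change after
SEDUM_CODON_USAGE_TSV = """\
amino_acid	codon	count_before	printed_ratio_pct	delta_count	printed_delta_ratio_pct
Ala	GCA	151	1.65	-1	-0.01
Ala	GCC	126	1.38	-1	-0.01
Ala	GCG	74	0.81	-3	-0.03
Ala	GCU	248	2.71	-1	-0.01
Arg	AGA	115	1.26	0	0
Arg	AGG	66	0.72	0	0
Arg	CGU	128	1.40	-28	-0.31
Arg	CGC	58	0.63	-9	-0.10
Arg	CGA	119	1.30	0	0
Arg	CGG	85	0.93	-32	-0.35
Asn	AAC	81	0.88	0	0
Asn	AAU	203	2.22	0	0
Asp	GAC	90	0.98	0	0
Asp	GAU	202	2.20	0	0
Cys	UGC	56	0.61	9	0.10
Cys	UGU	79	0.86	28	0.31
Gln	CAA	206	2.25	-1	-0.01
Gln	CAG	57	0.62	0	0
Glu	GAA	253	2.76	0	0
Glu	GAG	111	1.21	0	0
Gly	GGA	240	2.62	0	0
Gly	GGC	89	0.97	0	0
Gly	GGG	123	1.34	0	0
Gly	GGU	212	2.31	0	0
His	CAC	42	0.46	-6	-0.07
His	CAU	175	1.91	-15	-0.16
Ile	AUA	202	2.20	4	0.04
Ile	AUC	194	2.12	-2	-0.02
Ile	AUU	333	3.63	7	0.08
Leu	CUA	131	1.43	34	0.37
Leu	CUC	98	1.07	4	0.04
Leu	CUG	88	0.96	32	0.35
Leu	CUU	205	2.24	20	0.22
Leu	UUA	250	2.73	75	0.82
Leu	UUG	183	2.00	46	0.50
Lys	AAA	233	2.54	0	0
Lys	AAG	125	1.36	0	0
Met	AUG	244	2.66	6	0.07
Phe	UUC	247	2.70	25	0.27
Phe	UUU	348	3.80	69	0.75
Pro	CCA	144	1.57	-45	-0.49
Pro	CCC	118	1.29	-26	-0.28
Pro	CCG	87	0.95	-41	-0.45
Pro	CCU	184	2.01	-48	-0.52
Ser	AGC	89	0.97	0	0
Ser	AGU	149	1.63	0	0
Ser	UCA	175	1.91	-64	-0.70
Ser	UCC	133	1.45	-15	-0.16
Ser	UCG	110	1.20	-38	-0.41
Ser	UCU	189	2.06	-28	-0.31
Thr	ACA	117	1.28	-4	-0.04
Thr	ACC	123	1.34	-1	-0.01
Thr	ACG	72	0.79	-6	-0.07
Thr	ACU	157	1.71	-4	-0.04
Trp	UGG	141	1.54	32	0.35
Tyr	UAC	69	0.75	3	0.03
Tyr	UAU	226	2.47	18	0.20
Val	GUA	172	1.88	1	0.01
Val	GUC	103	1.12	-1	-0.01
Val	GUG	127	1.39	3	0.03
Val	GUU	178	1.94	3	0.03
Termination	UAA	19	0.21	1	0.01
Termination	UAG	6	0.07	0	0
Termination	UGA	5	0.05	0	0
"""


def sedum_conversion_counts() -> pd.DataFrame:
    """Published conversion counts as a DataFrame (raw inputs)."""
    return pd.read_csv(io.StringIO(SEDUM_AA_CONVERSIONS_TSV), sep="\t")


def sedum_conversion_table() -> ConversionTable:
    """ConversionTable rebuilt from the published raw counts."""
    df = sedum_conversion_counts()
    return ConversionTable.from_counts(
        list(df[["aa_from", "aa_to", "count"]].itertuples(index=False, name=None))
    )


def sedum_codon_usage() -> pd.DataFrame:
    """Published per-codon usage and deltas as a DataFrame (raw inputs)."""
    return pd.read_csv(io.StringIO(SEDUM_CODON_USAGE_TSV), sep="\t")


def sedum_codon_usage_delta() -> CodonUsageDelta:
    """CodonUsageDelta rebuilt from the published raw counts."""
    df = sedum_codon_usage()
    return CodonUsageDelta.from_counts(
        dict(zip(df["codon"], df["count_before"])),
        dict(zip(df["codon"], df["delta_count"])),
    )
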