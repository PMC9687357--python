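"""C-to-U RNA-editing site calling from CDS/cDNA comparison.

In plant mitochondria, cytidine deamination edits transcripts so that cDNA
reads T where the genome reads C. Comparing each protein-coding gene's CDS
with its assembled cDNA therefore exposes editing sites as C(CDS)/T(cDNA)
mismatch columns in a global alignment. Columns near indels are masked (an
alignment gap shifts the register and fakes substitutions), and reverse
U-to-C candidates are tallied separately so they are never silently folded
into the forward count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

from Bio import Align

from mitoeditkit.seq_model import CodingSequence, translate_str


class AlignmentError(ValueError):
    """Empty input or an alignment that fails the pairing thresholds."""


@dataclass
class AlignParams:
    """Alignment scoring and acceptance thresholds for CDS/cDNA pairing.

    Defaults tolerate editing-induced mismatches (a few percent of bases)
    while rejecting paralogous transcripts: affine gap model with
    match +2 / mismatch -3 / open -5 / extend -2, accepted when identity
    >= 0.90 over aligned bases and >= 0.50 of the CDS is covered.
    ``gap_margin`` masks calls within that many columns of any indel.
    """

    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -5.0
    gap_extend: float = -2.0
    min_identity: float = 0.90
    min_coverage: float = 0.50
    gap_margin: int = 3


@dataclass
class PairwiseAlignment:
    gene_id: str
    aligned_cds: str
    aligned_cdna: str
    identity: float
    coverage: float
    usable: bool = True
    reason: str = ""

    def __post_init__(self):
        if len(self.aligned_cds) != len(self.aligned_cdna):
            raise AlignmentError("gapped strings differ in length")


@dataclass
class EditingSite:
    """One called C-to-U event with CDS, codon and genome coordinates.

    ``ref``/``alt`` are coding-strand identities (always C -> U for a
    forward site); on a minus-strand gene the same event appears on the
    genome forward strand as G -> A, exposed via ``genome_ref``/``genome_alt``.
    """

    gene_id: str
    cds_pos: int
    codon_index: int
    codon_pos: int
    genome_pos: int
    strand: str
    codon_before: str
    codon_after: str
    ref: str = "C"
    alt: str = "U"
    n_support: int = 1

    def __post_init__(self):
        assert self.codon_pos == (self.cds_pos - 1) % 3 + 1
        assert self.codon_before[self.codon_pos - 1] == "C"
        assert self.codon_after[self.codon_pos - 1] in "TU"

    @property
    def genome_ref(self) -> str:
        return "C" if self.strand == "+" else "G"

    @property
    def genome_alt(self) -> str:
        return "T" if self.strand == "+" else "A"

    @property
    def aa_before(self) -> str:
        return translate_str(self.codon_before)

    @property
    def aa_after(self) -> str:
        return translate_str(self.codon_after.replace("U", "T"))

    def key(self) -> tuple[str, int]:
        return (self.gene_id, self.cds_pos)


@dataclass
class CallResult:
    """Sites from one CDS/cDNA comparison; iterates over the C-to-U calls."""

    sites: list[EditingSite]
    u_to_c: list[tuple[int, str, str]]  # (cds_pos, cds_base, cdna_base)
    n_masked_near_gaps: int = 0

    def __iter__(self) -> Iterator[EditingSite]:
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


@dataclass
class PositionDistribution:
    """Codon-position spectrum of a site set (counts and fractions at 1/2/3)."""

    counts: tuple[int, int, int]
    fractions: tuple[float, float, float] | None

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def defined(self) -> bool:
        return self.fractions is not None


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def align_cds_to_cdna(
    cds: CodingSequence | str,
    cdna: str,
    params: AlignParams | None = None,
    gene_id: str | None = None,
) -> PairwiseAlignment:
    """Globally align a CDS to its cDNA and grade the pairing.

    Identity is computed over columns where both sequences have a base;
    coverage is the fraction of CDS bases aligned to cDNA bases. A pairing
    below the thresholds is returned flagged unusable rather than raising,
    so callers can report it.
    """
    params = params or AlignParams()
    cds_seq = cds.na_seq if isinstance(cds, CodingSequence) else cds
    gid = gene_id or (cds.gene_id if isinstance(cds, CodingSequence) else "")
    if not cds_seq or not cdna:
        raise AlignmentError(f"{gid}: empty sequence input")
    cdna = cdna.upper().replace("U", "T")
    aln = _make_aligner(params).align(cds_seq, cdna)[0]
    a, b = str(aln[0]), str(aln[1])
    both = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    identity = matches / both if both else 0.0
    coverage = both / len(cds_seq)
    usable = identity >= params.min_identity and coverage >= params.min_coverage
    reason = ""
    if not usable:
        reason = (
            f"identity {identity:.3f} / coverage {coverage:.3f} below thresholds "
            f"({params.min_identity}, {params.min_coverage})"
        )
    return PairwiseAlignment(gid, a, b, identity, coverage, usable, reason)


def call_editing_sites(
    aln: PairwiseAlignment,
    cds: CodingSequence,
    params: AlignParams | None = None,
) -> CallResult:
    """Emit C(CDS)/T(cDNA) mismatch columns as editing sites.

    Sites within ``gap_margin`` columns of any alignment gap are suppressed
    (counted in ``n_masked_near_gaps``); reverse T(CDS)/C(cDNA) candidates
    are listed under ``u_to_c``. Sites whose codon is incomplete at the CDS
    3' end are not callable and are skipped.
    """
    params = params or AlignParams()
    if not aln.usable:
        raise AlignmentError(f"{aln.gene_id}: unusable alignment ({aln.reason})")
    a, b = aln.aligned_cds, aln.aligned_cdna
    gap_cols = [i for i, (x, y) in enumerate(zip(a, b)) if x == "-" or y == "-"]

    def near_gap(col: int) -> bool:
        return any(abs(col - g) < params.gap_margin for g in gap_cols)

    sites: list[EditingSite] = []
    u_to_c: list[tuple[int, str, str]] = []
    masked = 0
    cds_pos = 0
    n_codons = len(cds.na_seq) // 3
    for col, (x, y) in enumerate(zip(a, b)):
        if x != "-":
            cds_pos += 1
        if x == "-" or y == "-" or x == y:
            continue
        if x == "C" and y == "T":
            if near_gap(col):
                masked += 1
                continue
            codon_index = (cds_pos - 1) // 3 + 1
            if codon_index > n_codons:
                continue
            codon_pos = (cds_pos - 1) % 3 + 1
            codon = cds.na_seq[(codon_index - 1) * 3 : codon_index * 3]
            after = codon[: codon_pos - 1] + "T" + codon[codon_pos:]
            sites.append(
                EditingSite(
                    gene_id=cds.gene_id,
                    cds_pos=cds_pos,
                    codon_index=codon_index,
                    codon_pos=codon_pos,
                    genome_pos=cds.genome_map[cds_pos - 1],
                    strand=cds.strand,
                    codon_before=codon,
                    codon_after=after,
                )
            )
        elif x == "T" and y == "C" and not near_gap(col):
            u_to_c.append((cds_pos, x, y))
    return CallResult(sites=sites, u_to_c=u_to_c, n_masked_near_gaps=masked)


def merge_transcript_calls(
    per_transcript: Sequence[CallResult | Sequence[EditingSite]],
) -> list[EditingSite]:
    """Majority-merge sites called from multiple transcripts of one gene.

    A site is kept when present in more than half of the usable transcripts;
    the merged record carries the support count.
    """
    n = len(per_transcript)
    if n == 0:
        return []
    tally: dict[tuple[str, int], list[EditingSite]] = {}
    for calls in per_transcript:
        for site in calls:
            tally.setdefault(site.key(), []).append(site)
    merged = [
        replace(hits[0], n_support=len(hits))
        for hits in tally.values()
        if len(hits) > n / 2
    ]
    merged.sort(key=lambda s: (s.gene_id, s.cds_pos))
    return merged


def summarize_site_positions(sites: Sequence[EditingSite]) -> PositionDistribution:
    """Count sites by codon position (1/2/3) and report fractions.

    An empty site set yields zero counts with fractions flagged undefined.
    """
    counts = [0, 0, 0]
    for s in sites:
        counts[s.codon_pos - 1] += 1
    total = sum(counts)
    fractions = tuple(c / total for c in counts) if total else None
    return PositionDistribution(counts=tuple(counts), fractions=fractions)
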