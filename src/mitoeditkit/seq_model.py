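"""Genome and gene-model data types with circular-coordinate arithmetic.

Plant mitogenomes are conventionally represented as a single circular
"master circle" sequence. Genes may span the arbitrary linearization origin,
so every coordinate operation here is origin-aware: an annotated interval
whose end exceeds the sequence length is legal on a circular molecule and is
normalized into two in-range segments. All user-facing coordinates are
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

GENE_KINDS = ("PCG", "tRNA", "rRNA", "ORF", "pseudogene")
CODING_KINDS = ("PCG", "ORF")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeError(ValueError):
    """Invalid genome, annotation or coordinate request."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: ordered coding-order segments on one strand.

    ``segments`` are (start, end, strand) triples, 1-based inclusive, listed
    in CDS order (first segment holds the 5' end of the coding sequence).
    ``end`` may exceed the genome length to denote an origin-spanning
    segment on a circular sequence.
    """

    gene_id: str
    segments: tuple[tuple[int, int, str], ...]
    kind: str = "PCG"

    def __post_init__(self):
        if self.kind not in GENE_KINDS:
            raise GenomeError(f"{self.gene_id}: unknown gene kind {self.kind!r}")
        if not self.segments:
            raise GenomeError(f"{self.gene_id}: gene model has no segments")
        strands = {s[2] for s in self.segments}
        if not strands <= {"+", "-"}:
            raise GenomeError(f"{self.gene_id}: unknown strand symbol in {strands}")
        if len(strands) != 1:
            raise GenomeError(f"{self.gene_id}: mixed strands within one gene")
        for start, end, _ in self.segments:
            if start < 1 or end < start:
                raise GenomeError(
                    f"{self.gene_id}: bad segment coordinates ({start}, {end})"
                )
        if self.length == 0:
            raise GenomeError(f"{self.gene_id}: zero-length gene model")

    @property
    def strand(self) -> str:
        return self.segments[0][2]

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end, _ in self.segments)

    def normalized(self, genome_length: int, circular: bool) -> "GeneModel":
        """Split any out-of-range segment across the origin.

        On a circular genome a segment with ``end > genome_length`` wraps and
        becomes two segments; on a linear genome it is an error.
        """
        out: list[tuple[int, int, str]] = []
        for start, end, strand in self.segments:
            if start > genome_length:
                raise GenomeError(
                    f"{self.gene_id}: segment start {start} beyond sequence "
                    f"length {genome_length}"
                )
            if end > genome_length:
                if not circular:
                    raise GenomeError(
                        f"{self.gene_id}: segment end {end} beyond length "
                        f"{genome_length} on a linear sequence"
                    )
                if end - start + 1 > genome_length:
                    raise GenomeError(
                        f"{self.gene_id}: segment longer than the genome"
                    )
                # coding order: the low-coordinate wrap piece follows the
                # high piece on '+', and precedes it on '-' only in genome
                # terms — coding order is preserved by keeping genomic order
                # here and letting extraction reverse minus-strand genes.
                out.append((start, genome_length, strand))
                out.append((1, end - genome_length, strand))
            else:
                out.append((start, end, strand))
        if self.strand == "-" and len(out) != len(self.segments):
            # For a minus-strand wrapped segment the 5' end of the CDS lies
            # on the low-coordinate piece; genomic-order pieces must be
            # swapped to stay in CDS order.
            fixed: list[tuple[int, int, str]] = []
            i = 0
            for start, end, strand in self.segments:
                if end > genome_length:
                    fixed.append((1, end - genome_length, strand))
                    fixed.append((start, genome_length, strand))
                else:
                    fixed.append((start, end, strand))
            out = fixed
        return GeneModel(self.gene_id, tuple(out), self.kind)


@dataclass
class AnnotatedGenome:
    """A (possibly circular) genome sequence plus its gene models.

    The coordinate authority for every downstream module.
    """

    id: str
    sequence: str
    circular: bool = True
    features: list[GeneModel] = field(default_factory=list)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise GenomeError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        self.features = [
            f.normalized(len(self.sequence), self.circular) for f in self.features
        ]

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, gene_id: str) -> GeneModel:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise GenomeError(f"unknown gene {gene_id!r}")

    def fetch(self, start: int, end: int) -> str:
        """1-based inclusive substring; wraps across the origin if circular."""
        n = len(self.sequence)
        if start < 1 or end < start:
            raise GenomeError(f"bad coordinates ({start}, {end})")
        if end <= n:
            return self.sequence[start - 1 : end]
        if not self.circular:
            raise GenomeError(f"coordinates ({start}, {end}) beyond linear sequence")
        if end - start + 1 > n:
            raise GenomeError("request longer than the genome")
        return self.sequence[start - 1 :] + self.sequence[: end - n]


@dataclass
class CodingSequence:
    """A coding-strand CDS with its per-base genome coordinate map.

    ``genome_map[i]`` is the 1-based genome position of CDS base ``i``
    (0-based); ``strand`` applies to the whole gene. The map is injective by
    construction.
    """

    gene_id: str
    na_seq: str
    genome_map: tuple[int, ...]
    strand: str
    complete: bool = False

    def __len__(self) -> int:
        return len(self.na_seq)


def load_genome(
    fasta_path: str | Path,
    annotation_path: str | Path,
    circular: bool = True,
) -> AnnotatedGenome:
    """Read a single-record genome FASTA plus its annotation.

    The annotation may be GFF3 (``.gff``/``.gff3``) or a 5-column TSV
    (gene_id, start, end, strand, kind); multi-segment genes repeat the
    gene_id on consecutive rows in CDS order. Origin-spanning features
    (end > sequence length) are accepted only on circular sequences.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise GenomeError(
            f"{fasta_path}: expected exactly one genome record, found {len(records)}"
        )
    rec = records[0]
    annotation_path = Path(annotation_path)
    if annotation_path.suffix.lower() in (".gff", ".gff3"):
        features = _read_gff3(annotation_path, rec.id)
    else:
        features = _read_gene_table(annotation_path)
    return AnnotatedGenome(
        id=rec.id, sequence=str(rec.seq), circular=circular, features=features
    )


_GFF_KIND = {
    "cds": "PCG",
    "gene": "PCG",
    "trna": "tRNA",
    "rrna": "rRNA",
    "orf": "ORF",
    "pseudogene": "pseudogene",
}


def _read_gff3(path: Path, seqid: str) -> list[GeneModel]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise GenomeError(f"{path}: malformed GFF3 line: {line!r}")
            if cols[0] != seqid:
                raise GenomeError(
                    f"{path}: feature on {cols[0]!r} but genome record is {seqid!r}"
                )
            ftype = cols[2].lower()
            if ftype not in _GFF_KIND:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            gid = attrs.get("Parent") or attrs.get("ID") or attrs.get("gene_id")
            if gid is None:
                raise GenomeError(f"{path}: feature without ID/Parent: {line!r}")
            kind = attrs.get("gene_kind", _GFF_KIND[ftype])
            g = groups.setdefault(gid, {"kind": kind, "segments": [], "from_cds": False})
            if gid not in order:
                order.append(gid)
            seg = (int(cols[3]), int(cols[4]), cols[6])
            if ftype == "cds":
                if not g["from_cds"]:
                    g["segments"] = []  # CDS rows supersede the gene outline
                    g["from_cds"] = True
                g["segments"].append(seg)
                g["kind"] = kind
            elif not g["from_cds"]:
                g["segments"].append(seg)
                g["kind"] = kind
    features = []
    for gid in order:
        g = groups[gid]
        segs = g["segments"]
        if segs and segs[0][2] == "-" and len(segs) > 1:
            segs = sorted(segs, key=lambda s: -s[0])
        features.append(GeneModel(gid, tuple(segs), g["kind"]))
    return features


def _read_gene_table(path: Path) -> list[GeneModel]:
    groups: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "gene_id":
                continue
            if len(cols) != 5:
                raise GenomeError(f"{path}: expected 5 columns, got {len(cols)}")
            gid, start, end, strand, kind = cols
            g = groups.setdefault(gid, {"kind": kind, "segments": []})
            g["segments"].append((int(start), int(end), strand))
            if gid not in order:
                order.append(gid)
    return [
        GeneModel(gid, tuple(groups[gid]["segments"]), groups[gid]["kind"])
        for gid in order
    ]


def extract_cds(genome: AnnotatedGenome, gene_id: str) -> CodingSequence:
    """Extract the coding-strand sequence of a PCG/ORF with its genome map.

    Minus-strand genes are reverse-complemented; the genome map records, for
    each CDS base, the genome coordinate it derives from.
    """
    gene = genome.feature(gene_id)
    if gene.kind not in CODING_KINDS:
        raise GenomeError(
            f"{gene_id}: kind {gene.kind} is not a coding gene (PCG/ORF)"
        )
    n = len(genome.sequence)
    seq_parts: list[str] = []
    coords: list[int] = []
    for start, end, strand in gene.segments:
        if end > n:
            raise GenomeError(f"{gene_id}: unnormalized segment ({start}, {end})")
        piece = genome.sequence[start - 1 : end]
        if strand == "+":
            seq_parts.append(piece)
            coords.extend(range(start, end + 1))
        else:
            seq_parts.append(reverse_complement(piece))
            coords.extend(range(end, start - 1, -1))
    na = "".join(seq_parts)
    if not na:
        raise GenomeError(f"{gene_id}: zero-length CDS")
    if len(set(coords)) != len(coords):
        raise GenomeError(f"{gene_id}: overlapping segments (non-injective map)")
    prot = translate_str(na) if len(na) >= 3 else ""
    complete = len(na) % 3 == 0 and "*" not in prot[:-1]
    return CodingSequence(
        gene_id=gene_id,
        na_seq=na,
        genome_map=tuple(coords),
        strand=gene.strand,
        complete=complete,
    )


def translate_str(na_seq: str) -> str:
    """Translate complete codons with the standard code; internal stops as '*'."""
    if len(na_seq) < 3:
        raise GenomeError("sequence shorter than one codon")
    trimmed = na_seq[: len(na_seq) - len(na_seq) % 3]
    return str(Seq(trimmed).translate(table=1))


def translate(cds: CodingSequence | str) -> str:
    """Protein sequence of a CDS (one letter per complete codon).

    Internal stop codons are rendered as ``*`` and left in place rather than
    truncating the translation — editing analysis needs to see them.
    """
    na = cds if isinstance(cds, str) else cds.na_seq
    return translate_str(na)
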