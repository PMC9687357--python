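"""Synthetic circular mitogenomes with planted ground truth.

The generator emulates the observable structure the analysis modules
consume: a circular genome carrying protein-coding genes on both strands,
planted C-to-U editing sites whose codon-position spectrum follows the
strong 2nd > 1st >> 3rd bias of plant mitochondrial editing, one pair of
identical large direct repeats, and long reads drawn from a mixture of the
master-circle and the two loop-out subcircle conformations with a
configurable error rate. Every random choice flows from ``SimConfig.seed``
and is recorded in a ``SimTruth`` object, so callers can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np

from mitoeditkit.seq_model import (
    AnnotatedGenome,
    CodingSequence,
    GeneModel,
    extract_cds,
    reverse_complement,
    translate_str,
)
from mitoeditkit.editing_caller import EditingSite
from mitoeditkit.editing_effects import apply_edits
from mitoeditkit.recombination import ConformationSet, RepeatPair

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_STOPS = ("TAA", "TAG", "TGA")


class SimulationError(ValueError):
    """Infeasible configuration (e.g. genes do not fit the genome)."""


@dataclass
class SimConfig:
    """Generator configuration; defaults mirror a small plant mitogenome.

    ``edit_rate`` is the expected number of planted sites per gene (about
    16, the genome-wide density of ~508 sites over 31 genes);
    ``position_weights`` is the codon-position bias of plant mitochondrial
    C-to-U editing (2nd > 1st >> 3rd). The repeat defaults to the 5222-bp
    LDR scale. Long reads default to an 8 +/- 1.5 kb corrected-ONT-like
    length at 5% error, mixed 60/25/15 across MC/SC1/SC2.
    """

    genome_length: int = 50_000
    n_genes: int = 20
    gene_length: tuple[int, int] = (300, 1500)
    edit_rate: float = 16.0
    position_weights: tuple[float, float, float] = (0.3012, 0.6378, 0.0610)
    repeat_length: int = 5222
    repeat_spacers: tuple[int, int] | None = None
    n_transcripts: int = 8
    transcript_dropout: float = 0.0
    n_reads: int = 2000
    read_length_mean: float = 8000.0
    read_length_sd: float = 1500.0
    read_length_min: int = 500
    read_error_rate: float = 0.05
    mixture: tuple[float, float, float] = (0.6, 0.25, 0.15)
    allow_stop_gain: bool = False
    min_intergenic: int = 50
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.position_weights) - 1) > 1e-9:
            raise SimulationError("position_weights must sum to 1")
        if abs(sum(self.mixture) - 1) > 1e-9:
            raise SimulationError("mixture must sum to 1")
        for p in (*self.position_weights, *self.mixture,
                  self.transcript_dropout, self.read_error_rate):
            if not 0 <= p <= 1:
                raise SimulationError(f"probability {p} outside [0, 1]")


@dataclass
class ReadLabel:
    read_id: str
    template: str  # mc | sc1 | sc2
    start: int  # 0-based on the template
    length: int
    flipped: bool
    junction: int | None  # boundary type fully spanned, if any


@dataclass
class SimTruth:
    """Ground truth for one simulated fixture."""

    genome_id: str
    repeat_pair: RepeatPair | None
    gene_models: list[GeneModel] = field(default_factory=list)
    cds: dict[str, str] = field(default_factory=dict)
    sites: dict[str, list[EditingSite]] = field(default_factory=dict)
    edited: dict[str, str] = field(default_factory=dict)
    read_labels: list[ReadLabel] = field(default_factory=list)

    def all_sites(self) -> list[EditingSite]:
        return [s for sites in self.sites.values() for s in sites]

    def verify_consistency(self) -> bool:
        """Planted sites applied to planted CDSs reproduce the edited truth."""
        for gid, seq in self.cds.items():
            if apply_edits(seq, self.sites.get(gid, [])) != self.edited.get(gid, seq):
                return False
        return True


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_gene(rng: np.random.Generator, length: int) -> str:
    """ATG + uniform sense codons + TAA; length is rounded to codons >= 9."""
    n_codons = max(length // 3, 3)
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in body) + "TAA"


def simulate_genome(config: SimConfig) -> tuple[AnnotatedGenome, SimTruth]:
    """Build a circular genome with planted genes and one direct-repeat pair.

    Layout: copy A of the repeat at position 1, the inner arc, copy B, the
    outer arc; genes are packed into the two arcs on random strands with at
    least ``min_intergenic`` bases between them. Raises on infeasible
    packing. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    rep_len = config.repeat_length
    if config.repeat_spacers is not None:
        inner, outer = config.repeat_spacers
        total = 2 * rep_len + inner + outer
    else:
        total = config.genome_length
        nonrep = total - 2 * rep_len
        if nonrep < 2:
            raise SimulationError("genome too short for two repeat copies")
        inner = nonrep // 3
        outer = nonrep - inner
    repeat = _random_seq(rng, rep_len) if rep_len else ""

    lengths = [
        3 * int(rng.integers(config.gene_length[0] // 3, config.gene_length[1] // 3 + 1))
        for _ in range(config.n_genes)
    ]
    gap = config.min_intergenic
    # split genes across the two arcs proportionally, then pack greedily
    arcs = {"inner": inner, "outer": outer}
    assignment: dict[str, list[int]] = {"inner": [], "outer": []}
    load = {"inner": gap, "outer": gap}
    for gi in sorted(range(config.n_genes), key=lambda i: -lengths[i]):
        arc = min(arcs, key=lambda a: (load[a] + lengths[gi] + gap) / max(arcs[a], 1))
        assignment[arc].append(gi)
        load[arc] += lengths[gi] + gap
    for arc in arcs:
        if load[arc] > arcs[arc]:
            raise SimulationError(
                f"infeasible packing: {load[arc]} bp of genes+gaps into a "
                f"{arcs[arc]} bp arc"
            )

    arc_seqs: dict[str, list[str]] = {}
    models: list[GeneModel] = []
    cds_truth: dict[str, str] = {}
    arc_offsets = {"inner": rep_len, "outer": 2 * rep_len + inner}
    for arc, arc_len in arcs.items():
        chunks: list[str] = []
        cursor = 0
        order = sorted(assignment[arc], key=lambda i: rng.random())
        slack = arcs[arc] - load[arc]
        for gi in order:
            extra = int(rng.integers(0, max(slack // (len(order) + 1), 1) + 1))
            pad = gap + extra
            chunks.append(_random_seq(rng, pad))
            cursor += pad
            gene_seq = _random_gene(rng, lengths[gi])
            strand = "+" if rng.random() < 0.5 else "-"
            start = arc_offsets[arc] + cursor + 1  # 1-based genome coord
            end = start + len(gene_seq) - 1
            models.append(
                GeneModel(f"gene{gi:03d}", ((start, end, strand),), "PCG")
            )
            cds_truth[f"gene{gi:03d}"] = gene_seq
            chunks.append(
                gene_seq if strand == "+" else reverse_complement(gene_seq)
            )
            cursor += len(gene_seq)
        chunks.append(_random_seq(rng, arc_len - cursor))
        arc_seqs[arc] = chunks

    sequence = (
        repeat
        + "".join(arc_seqs["inner"])
        + repeat
        + "".join(arc_seqs["outer"])
    )
    assert len(sequence) == total
    models.sort(key=lambda m: m.segments[0][0])
    genome = AnnotatedGenome(
        id="synthetic_mc", sequence=sequence, circular=True, features=models
    )
    pair = (
        RepeatPair(length=rep_len, copyA_start=1, copyB_start=rep_len + inner + 1)
        if rep_len
        else None
    )
    truth = SimTruth(
        genome_id=genome.id, repeat_pair=pair, gene_models=models, cds=cds_truth
    )
    # sanity: extraction reproduces the planted coding sequences
    for gid, seq in cds_truth.items():
        assert extract_cds(genome, gid).na_seq == seq
    return genome, truth


def plant_edits(
    genome: AnnotatedGenome, truth: SimTruth, config: SimConfig
) -> dict[str, list[str]]:
    """Plant C-to-U sites per gene and emit the per-transcript cDNA set.

    Site counts are Poisson(edit_rate) per gene; codon positions follow
    ``position_weights`` (resampled among non-exhausted classes); edits that
    would create a premature stop are resampled unless ``allow_stop_gain``.
    With ``transcript_dropout`` > 0 each transcript independently reverts
    each site with that probability, exercising majority merging.
    Updates ``truth.sites``/``truth.edited`` and returns gene -> transcripts.
    """
    rng = np.random.default_rng([config.seed, 202])
    cdnas: dict[str, list[str]] = {}
    for model in truth.gene_models:
        gid = model.gene_id
        cds = extract_cds(genome, gid)
        seq = list(cds.na_seq)
        n_codons = len(seq) // 3
        by_pos: dict[int, list[int]] = {1: [], 2: [], 3: []}
        for i, base in enumerate(seq):
            if base == "C" and (i // 3) < n_codons:
                by_pos[(i % 3) + 1].append(i)
        n_sites = int(rng.poisson(config.edit_rate))
        sites: list[EditingSite] = []
        for _ in range(n_sites):
            # draw the codon-position class first, then search for a valid
            # candidate within it, so stop-creating rejections do not skew
            # the realized position spectrum away from the weights
            idx = None
            while idx is None:
                avail = [p for p in (1, 2, 3) if by_pos[p]]
                if not avail:
                    break
                w = np.array([config.position_weights[p - 1] for p in avail])
                if w.sum() == 0:
                    w = np.ones(len(avail), dtype=float)
                p = int(rng.choice(avail, p=w / w.sum()))
                while by_pos[p]:
                    cand = by_pos[p].pop(int(rng.integers(len(by_pos[p]))))
                    ci_ = cand // 3
                    codon_now = "".join(seq[ci_ * 3 : ci_ * 3 + 3])
                    codon_new = (
                        codon_now[: cand % 3] + "T" + codon_now[cand % 3 + 1 :]
                    )
                    if codon_new in _STOPS and not config.allow_stop_gain:
                        continue  # permanently discard this candidate
                    idx = cand
                    break
            if idx is None:
                break
            ci = idx // 3
            codon_before = "".join(
                cds.na_seq[ci * 3 : ci * 3 + 3]
            )
            after = codon_before[: idx % 3] + "T" + codon_before[idx % 3 + 1 :]
            seq[idx] = "T"
            p = (idx % 3) + 1
            sites.append(
                EditingSite(
                    gene_id=gid,
                    cds_pos=idx + 1,
                    codon_index=ci + 1,
                    codon_pos=p,
                    genome_pos=cds.genome_map[idx],
                    strand=cds.strand,
                    codon_before=codon_before,
                    codon_after=after,
                )
            )
        sites.sort(key=lambda s: s.cds_pos)
        edited = "".join(seq)
        truth.sites[gid] = sites
        truth.edited[gid] = edited
        transcripts: list[str] = []
        for _ in range(config.n_transcripts):
            t = list(edited)
            for s in sites:
                if rng.random() < config.transcript_dropout:
                    t[s.cds_pos - 1] = "C"
            transcripts.append("".join(t))
        cdnas[gid] = transcripts
    assert truth.verify_consistency()
    return cdnas


def _apply_read_errors(
    rng: np.random.Generator, seq: str, error_rate: float
) -> str:
    """Uniform errors at ``error_rate``, split 60:20:20 sub:ins:del."""
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    if len(hits) == 0:
        return seq
    kinds = rng.choice(3, size=len(hits), p=[0.6, 0.2, 0.2])
    out: list[str] = []
    prev = 0
    for pos, kind in zip(hits, kinds):
        out.append(seq[prev:pos])
        if kind == 0:  # substitution to a different base
            choices = [b for b in "ACGT" if b != seq[pos]]
            out.append(choices[int(rng.integers(3))])
            prev = pos + 1
        elif kind == 1:  # insertion before the base
            out.append("ACGT"[int(rng.integers(4))])
            prev = pos
        else:  # deletion
            prev = pos + 1
    out.append(seq[prev:])
    return "".join(out)


def _spanned_junction(
    template: str, start: int, length: int, conf: ConformationSet, margin: int
) -> int | None:
    """Boundary type whose full repeat+margin arc the read covers, if any."""
    rep_len = len(conf.repeat)
    n = len(conf.template(template))
    arc_len = rep_len + 2 * margin
    if template == "mc":
        a0 = conf.pair.copyA_start - 1
        b0 = conf.pair.copyB_start - 1
        junctions = [(1, (a0 - margin) % n), (2, (b0 - margin) % n)]
    else:
        junctions = [(3 if template == "sc1" else 4, (-margin) % n)]
    for btype, u in junctions:
        if arc_len <= length and (u - start) % n + arc_len <= length:
            return btype
    return None


def simulate_long_reads(
    conformations: ConformationSet,
    config: SimConfig,
    label_margin: int = 100,
) -> tuple[list[tuple[str, str]], list[ReadLabel]]:
    """Sample long reads from the MC/SC1/SC2 mixture with uniform errors.

    Reads start uniformly on their circular template; lengths are normal
    (mean, sd) clipped below at ``read_length_min`` and above at the
    template length (with a warning when clipping occurs). Half the reads
    are reverse-complemented. Labels record template, coordinates and the
    boundary type fully spanned with ``label_margin`` flank bases, if any.
    """
    rng = np.random.default_rng([config.seed, 303])
    names = ["mc", "sc1", "sc2"]
    reads: list[tuple[str, str]] = []
    labels: list[ReadLabel] = []
    clipped = False
    for i in range(config.n_reads):
        template = names[int(rng.choice(3, p=list(config.mixture)))]
        tseq = conformations.template(template)
        n = len(tseq)
        want = int(rng.normal(config.read_length_mean, config.read_length_sd))
        length = max(config.read_length_min, want)
        if length > n:
            clipped = True
            length = n
        start = int(rng.integers(n))
        frag = tseq[start:] + tseq[: max(0, start + length - n)]
        frag = frag[:length] if start + length > n else tseq[start : start + length]
        junction = _spanned_junction(template, start, length, conformations, label_margin)
        flipped = bool(rng.random() < 0.5)
        seq = _apply_read_errors(rng, frag, config.read_error_rate)
        if flipped:
            seq = reverse_complement(seq)
        rid = f"read{i:05d}"
        reads.append((rid, seq))
        labels.append(
            ReadLabel(
                read_id=rid, template=template, start=start, length=length,
                flipped=flipped, junction=junction,
            )
        )
    if clipped:
        warnings.warn(
            "requested read length exceeds a template length; reads clipped",
            stacklevel=2,
        )
    return reads, labels


# ---------------------------------------------------------------------------
# text-format emission

def write_fasta(path: str | Path, records: Sequence[tuple[str, str]], width: int = 70):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(path: str | Path, genome: AnnotatedGenome):
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for gene in genome.features:
            for start, end, strand in gene.segments:
                fh.write(
                    f"{genome.id}\tmitoeditkit\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                    f"ID={gene.gene_id};gene_kind={gene.kind}\n"
                )


def write_truth_sites_tsv(path: str | Path, truth: SimTruth):
    cols = (
        "gene_id\tcds_pos\tcodon_index\tcodon_pos\tgenome_pos\tstrand\t"
        "codon_before\tcodon_after\n"
    )
    with open(path, "w") as fh:
        fh.write(cols)
        for s in truth.all_sites():
            fh.write(
                f"{s.gene_id}\t{s.cds_pos}\t{s.codon_index}\t{s.codon_pos}\t"
                f"{s.genome_pos}\t{s.strand}\t{s.codon_before}\t{s.codon_after}\n"
            )


def write_read_labels_tsv(path: str | Path, labels: Sequence[ReadLabel]):
    with open(path, "w") as fh:
        fh.write("read_id\ttemplate\tstart\tlength\tflipped\tjunction\n")
        for l in labels:
            fh.write(
                f"{l.read_id}\t{l.template}\t{l.start}\t{l.length}\t"
                f"{int(l.flipped)}\t{l.junction if l.junction else ''}\n"
            )


def emit_fixture(out_dir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate a complete fixture on disk: genome, annotation, cDNAs,
    reads and truth tables. Returns the path map."""
    from mitoeditkit.recombination import loop_out

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome, truth = simulate_genome(config)
    cdnas = plant_edits(genome, truth, config)
    paths = {
        "genome": out / "genome.fasta",
        "annotation": out / "genome.gff3",
        "cdna": out / "cdna.fasta",
        "reads": out / "reads.fasta",
        "truth_sites": out / "truth_sites.tsv",
        "truth_reads": out / "truth_read_labels.tsv",
    }
    write_fasta(paths["genome"], [(genome.id, genome.sequence)])
    write_gff3(paths["annotation"], genome)
    cdna_records = [
        (f"{gid}.t{i + 1}", seq)
        for gid, transcripts in cdnas.items()
        for i, seq in enumerate(transcripts)
    ]
    write_fasta(paths["cdna"], cdna_records)
    write_truth_sites_tsv(paths["truth_sites"], truth)
    if truth.repeat_pair is not None and config.n_reads > 0:
        conf = loop_out(genome, truth.repeat_pair)
        reads, labels = simulate_long_reads(conf, config)
        write_fasta(paths["reads"], reads)
        write_read_labels_tsv(paths["truth_reads"], labels)
    return paths
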