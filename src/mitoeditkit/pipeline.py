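"""End-to-end orchestration: inputs -> tables -> summary JSON.

Runs the editing caller over every coding gene with matched transcripts,
applies the calls, renders the conversion / codon-usage / start-stop
accounting, computes per-gene codon statistics and the before/after
neutrality fits, and (when long reads are supplied) the repeat loop-out
isoform evidence. Every table is TSV with a header row; the summary JSON
is key-sorted and stable across reruns with the same config.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from mitoeditkit.seq_model import AnnotatedGenome, extract_cds, load_genome, CODING_KINDS
from mitoeditkit.editing_caller import (
    AlignParams,
    align_cds_to_cdna,
    call_editing_sites,
    merge_transcript_calls,
    summarize_site_positions,
)
from mitoeditkit.editing_effects import (
    apply_edits,
    classify_conversions,
    codon_usage_delta,
    detect_start_stop_gain,
)
from mitoeditkit.codon_stats import (
    compute_codon_stats,
    enc_expected,
    neutrality_fit,
    CodonStatsError,
)
from mitoeditkit.recombination import (
    classify_boundary_read,
    conformation_evidence,
    find_direct_repeats,
    loop_out,
)
from mitoeditkit.synthetic_data import write_fasta

log = logging.getLogger("mitoeditkit")


@dataclass
class RunConfig:
    """Effective pipeline configuration; serialized alongside the outputs."""

    genome: str
    annotation: str
    cdna: str
    out_dir: str
    reads: str | None = None
    circular: bool = True
    min_identity: float = 0.90
    min_coverage: float = 0.50
    gap_margin: int = 3
    repeat_min_len: int = 1000
    flank_size: int = 1000
    min_anchor: int = 100
    seed: int = 0
    verbosity: str = "INFO"


class PipelineError(RuntimeError):
    """A module failure annotated with the module and offending record."""


def _read_transcripts(path: str) -> dict[str, list[str]]:
    """cDNA FASTA grouped by gene id; '.t<N>' suffixes mark transcripts."""
    groups: dict[str, list[str]] = {}
    for rec in SeqIO.parse(path, "fasta"):
        gid = rec.id.rsplit(".t", 1)[0] if ".t" in rec.id else rec.id
        groups.setdefault(gid, []).append(str(rec.seq).upper())
    return groups


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the summary dict it also writes."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.verbosity.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for path in (config.genome, config.annotation, config.cdna, config.reads):
        if path is not None and not Path(path).exists():
            raise PipelineError(f"input file not found: {path}")

    try:
        genome = load_genome(config.genome, config.annotation, circular=config.circular)
    except Exception as e:
        raise PipelineError(f"seq_model: {e}") from e
    transcripts = _read_transcripts(config.cdna)
    params = AlignParams(
        min_identity=config.min_identity,
        min_coverage=config.min_coverage,
        gap_margin=config.gap_margin,
    )

    cds_by_gene = {}
    merged_sites = {}
    unusable: list[str] = []
    n_u_to_c = 0
    for gene in genome.features:
        if gene.kind not in CODING_KINDS or gene.gene_id not in transcripts:
            continue
        try:
            cds = extract_cds(genome, gene.gene_id)
            per_transcript = []
            for t in transcripts[gene.gene_id]:
                aln = align_cds_to_cdna(cds, t, params)
                if not aln.usable:
                    unusable.append(f"{gene.gene_id}: {aln.reason}")
                    continue
                result = call_editing_sites(aln, cds, params)
                n_u_to_c += len(result.u_to_c)
                per_transcript.append(result)
            cds_by_gene[gene.gene_id] = cds
            merged_sites[gene.gene_id] = merge_transcript_calls(per_transcript)
        except Exception as e:
            raise PipelineError(f"editing_caller: {gene.gene_id}: {e}") from e

    all_sites = [s for sites in merged_sites.values() for s in sites]
    dist = summarize_site_positions(all_sites)

    before = [cds_by_gene[g] for g in sorted(cds_by_gene)]
    after = [
        apply_edits(cds_by_gene[g], merged_sites[g]) for g in sorted(cds_by_gene)
    ]
    conversions = classify_conversions(before, after)
    usage = codon_usage_delta(before, after)
    events = [
        ev
        for g in sorted(cds_by_gene)
        for ev in detect_start_stop_gain(
            cds_by_gene[g], apply_edits(cds_by_gene[g], merged_sites[g]), g
        )
    ]

    stats_before = [compute_codon_stats(c) for c in before]
    stats_after = [compute_codon_stats(c) for c in after]
    fits = {}
    for label, stats in (("before", stats_before), ("after", stats_after)):
        try:
            fits[label] = neutrality_fit(stats)
        except CodonStatsError as e:
            log.warning("neutrality fit (%s) skipped: %s", label, e)
            fits[label] = None

    _write_sites_tsv(out / "editing_sites.tsv", merged_sites)
    _write_distribution_tsv(out / "position_distribution.tsv", dist)
    conversions.to_dataframe().to_csv(out / "conversion_table.tsv", sep="\t", index=False)
    usage.to_dataframe().to_csv(out / "codon_usage_delta.tsv", sep="\t", index=False)
    _write_events_tsv(out / "start_stop_events.tsv", events)
    _write_stats_tsv(out / "codon_stats_before.tsv", stats_before)
    _write_stats_tsv(out / "codon_stats_after.tsv", stats_after)
    _write_plot_data(out, stats_before, stats_after, fits)

    isoforms = None
    if config.reads is not None:
        isoforms = _isoform_analysis(genome, config, out)

    summary = {
        "n_genes_analyzed": len(cds_by_gene),
        "n_unusable_alignments": len(unusable),
        "n_editing_sites": len(all_sites),
        "n_u_to_c_candidates": n_u_to_c,
        "position_counts": list(dist.counts),
        "position_fractions_pct": (
            [round(100 * f, 2) for f in dist.fractions] if dist.defined else None
        ),
        "total_codons_changed": conversions.total_codons_changed,
        "n_nonsynonymous": conversions.n_nonsynonymous,
        "n_synonymous": conversions.n_synonymous,
        "total_codons_before": usage.total_before,
        "delta_zero_sum": sum(usage.delta_count.values()),
        "n_start_gain": sum(1 for e in events if e.kind == "start_gain"),
        "n_stop_gain": sum(1 for e in events if e.kind == "stop_gain"),
        "neutrality": {
            label: (
                None
                if fit is None
                else {
                    "abs_slope": round(fit.abs_slope, 5),
                    "intercept": round(fit.intercept, 5),
                    "r2": round(fit.r2, 5),
                    "mutation_contribution_pct": round(
                        fit.mutation_contribution_pct, 3
                    ),
                    "n": fit.n,
                }
            )
            for label, fit in fits.items()
        },
        "isoforms": isoforms,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "effective_config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    return summary


def _isoform_analysis(genome: AnnotatedGenome, config: RunConfig, out: Path):
    try:
        pairs = find_direct_repeats(genome, min_len=max(config.repeat_min_len, 20))
        if not pairs:
            return {"repeat_found": False}
        conf = loop_out(genome, pairs[0], flank_size=config.flank_size)
    except Exception as e:
        raise PipelineError(f"recombination: {e}") from e
    calls = []
    with open(out / "boundary_calls.tsv", "w") as fh:
        fh.write("read_id\ttype\tanchor_up\tanchor_down\tedits\n")
        for rec in SeqIO.parse(config.reads, _reads_format(config.reads)):
            call = classify_boundary_read(
                str(rec.seq), conf, min_anchor=config.min_anchor
            )
            call.read_id = rec.id
            calls.append(call)
            fh.write(
                f"{call.read_id}\t{call.btype}\t{call.anchor_up}\t"
                f"{call.anchor_down}\t{call.edits}\n"
            )
    evidence = conformation_evidence(calls)
    write_fasta(
        out / "conformations.fasta",
        [("mc", conf.mc.sequence), ("sc1", conf.sc1), ("sc2", conf.sc2)],
    )
    return {
        "repeat_found": True,
        "repeat_length": conf.pair.length,
        "mc_length": len(conf.mc.sequence),
        "sc1_length": len(conf.sc1),
        "sc2_length": len(conf.sc2),
        "boundary_counts": {str(k): v for k, v in evidence.counts.items()},
        "n_ambiguous": evidence.n_ambiguous,
        "all_four_types": evidence.all_four_types,
    }


def _reads_format(path: str) -> str:
    p = str(path).lower()
    return "fastq" if p.endswith((".fastq", ".fq")) else "fasta"


def _write_sites_tsv(path: Path, merged_sites: dict):
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tgenome_pos\tstrand\tcds_pos\tcodon_index\tcodon_pos\t"
            "codon_before\tcodon_after\taa_before\taa_after\tn_transcripts_support\n"
        )
        for gid in sorted(merged_sites):
            for s in merged_sites[gid]:
                fh.write(
                    f"{s.gene_id}\t{s.genome_pos}\t{s.strand}\t{s.cds_pos}\t"
                    f"{s.codon_index}\t{s.codon_pos}\t{s.codon_before}\t"
                    f"{s.codon_after}\t{s.aa_before}\t{s.aa_after}\t{s.n_support}\n"
                )


def _write_distribution_tsv(path: Path, dist):
    with open(path, "w") as fh:
        fh.write("codon_pos\tcount\tfraction\n")
        for i, c in enumerate(dist.counts, start=1):
            frac = f"{dist.fractions[i - 1]:.6f}" if dist.defined else "NA"
            fh.write(f"{i}\t{c}\t{frac}\n")


def _write_events_tsv(path: Path, events):
    with open(path, "w") as fh:
        fh.write("gene_id\tkind\tcodon_index\tcodon_before\tcodon_after\ttruncation\n")
        for e in events:
            fh.write(
                f"{e.gene_id}\t{e.kind}\t{e.codon_index}\t{e.codon_before}\t"
                f"{e.codon_after}\t{int(e.truncation)}\n"
            )


def _write_stats_tsv(path: Path, stats):
    with open(path, "w") as fh:
        fh.write("gene_id\tn_codons\tgc1\tgc2\tgc3\tgc12\tgc3s\tenc\tenc_reason\n")
        for s in stats:
            gc3s_s = f"{s.gc3s:.6f}" if s.gc3s is not None else "NA"
            enc_s = f"{s.enc:.4f}" if s.enc is not None else "NA"
            fh.write(
                f"{s.gene_id}\t{s.n_codons}\t{s.gc1:.6f}\t{s.gc2:.6f}\t"
                f"{s.gc3:.6f}\t{s.gc12:.6f}\t{gc3s_s}\t{enc_s}\t{s.enc_reason}\n"
            )


def _write_plot_data(out: Path, stats_before, stats_after, fits):
    with open(out / "enc_gc3s_plot.tsv", "w") as fh:
        fh.write("series\tgc3s\tenc\n")
        for x in np.arange(0, 1.0001, 0.01):
            fh.write(f"expected\t{x:.2f}\t{enc_expected(float(x)):.4f}\n")
        for label, stats in (("before", stats_before), ("after", stats_after)):
            for s in stats:
                if s.gc3s is not None and s.enc is not None:
                    fh.write(f"{label}\t{s.gc3s:.6f}\t{s.enc:.4f}\n")
    with open(out / "neutrality_points.tsv", "w") as fh:
        fh.write("series\tgc3\tgc12\n")
        for label, stats in (("before", stats_before), ("after", stats_after)):
            for s in stats:
                fh.write(f"{label}\t{s.gc3:.6f}\t{s.gc12:.6f}\n")
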