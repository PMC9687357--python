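"""In-silico application of C-to-U edits and their codon-level accounting.

Applying the called sites to the CDS set yields the "after editing"
sequences; comparing codon-by-codon gives (i) the amino-acid conversion
spectrum with its synonymous/nonsynonymous split, (ii) the before/after
codon-usage table with signed deltas (zero-sum by construction: editing
substitutes within codons, never changes their number), and (iii)
editing-created start (ACG -> AUG) and stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from mitoeditkit.seq_model import CodingSequence, translate_str
from mitoeditkit.editing_caller import EditingSite

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    "*": "Termination", "X": "Unknown",
}

RNA_CODONS = tuple(
    a + b + c for a in "UCAG" for b in "UCAG" for c in "UCAG"
)
STOP_CODONS_RNA = ("UAA", "UAG", "UGA")


class EditApplicationError(ValueError):
    """A site does not match the sequence it is applied to."""


def _seq_of(x: CodingSequence | str) -> str:
    return x.na_seq if isinstance(x, CodingSequence) else x


def _rna(codon: str) -> str:
    return codon.replace("T", "U")


def aa3(aa1: str) -> str:
    """Three-letter (or 'Termination') name of a one-letter amino acid."""
    return _AA3[aa1]


def apply_edits(
    cds: CodingSequence | str, sites: Iterable[EditingSite]
) -> CodingSequence | str:
    """Return a copy of the CDS with each site's C replaced by T.

    A site pointing at a non-C base signals a stale annotation and raises.
    """
    seq = list(_seq_of(cds))
    for site in sites:
        pos = site.cds_pos
        if pos < 1 or pos > len(seq):
            raise EditApplicationError(
                f"{site.gene_id}: site position {pos} outside CDS"
            )
        if seq[pos - 1] != "C":
            raise EditApplicationError(
                f"{site.gene_id}: position {pos} is {seq[pos - 1]}, not C "
                "(stale annotation?)"
            )
        seq[pos - 1] = "T"
    edited = "".join(seq)
    if isinstance(cds, CodingSequence):
        return CodingSequence(
            gene_id=cds.gene_id,
            na_seq=edited,
            genome_map=cds.genome_map,
            strand=cds.strand,
            complete=cds.complete,
        )
    return edited


@dataclass
class ConversionRow:
    aa_from: str
    aa_to: str
    count: int
    ratio: float
    synonymous: bool


@dataclass
class ConversionTable:
    """Amino-acid conversion spectrum over all changed codons.

    One row per observed (aa_from, aa_to) pair; a codon edited at two
    positions counts once, classified by its full before -> after change.
    """

    rows: list[ConversionRow]
    total_codons_changed: int
    n_nonsynonymous: int
    n_synonymous: int
    n_excluded: int = 0

    @classmethod
    def from_counts(
        cls, counts: Iterable[tuple[str, str, int]], n_excluded: int = 0
    ) -> "ConversionTable":
        """Build the table from (aa_from, aa_to, count) triples.

        Amino acids are three-letter names ('Ser', 'Termination', ...).
        Totals, ratios and the synonymous split are recomputed here, never
        taken on trust from the caller.
        """
        items = list(counts)
        total = sum(c for _, _, c in items)
        rows = [
            ConversionRow(
                aa_from=f,
                aa_to=t,
                count=c,
                ratio=c / total if total else 0.0,
                synonymous=(f == t),
            )
            for f, t, c in items
        ]
        rows.sort(key=lambda r: (r.synonymous, -r.count, r.aa_from, r.aa_to))
        return cls(
            rows=rows,
            total_codons_changed=total,
            n_nonsynonymous=sum(r.count for r in rows if not r.synonymous),
            n_synonymous=sum(r.count for r in rows if r.synonymous),
            n_excluded=n_excluded,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "aa_conversion": f"{r.aa_from} -> {r.aa_to}",
                    "count": r.count,
                    "ratio_pct": 100.0 * r.ratio,
                    "conversion_type": "Synonymous" if r.synonymous else "Nonsynonymous",
                }
                for r in self.rows
            ]
        )


def _changed_codons(
    cds_set: Sequence[CodingSequence | str],
    edited_set: Sequence[CodingSequence | str],
) -> tuple[list[tuple[str, str]], int]:
    """(before, after) codon pairs that differ, plus the N/incomplete tally."""
    if len(cds_set) != len(edited_set):
        raise EditApplicationError("before/after sets differ in size")
    changed: list[tuple[str, str]] = []
    excluded = 0
    for before, after in zip(cds_set, edited_set):
        b, a = _seq_of(before), _seq_of(after)
        if len(b) != len(a):
            gid = before.gene_id if isinstance(before, CodingSequence) else "?"
            raise EditApplicationError(f"{gid}: before/after length mismatch")
        excluded += (1 if len(b) % 3 else 0)
        for i in range(0, len(b) - len(b) % 3, 3):
            cb, ca = b[i : i + 3], a[i : i + 3]
            if "N" in cb or "N" in ca:
                excluded += 1
                continue
            if cb != ca:
                changed.append((cb, ca))
    return changed, excluded


def classify_conversions(
    cds_set: Sequence[CodingSequence | str],
    edited_set: Sequence[CodingSequence | str],
) -> ConversionTable:
    """Tabulate amino-acid conversions over all changed codons."""
    changed, excluded = _changed_codons(cds_set, edited_set)
    counts: dict[tuple[str, str], int] = {}
    for cb, ca in changed:
        pair = (aa3(translate_str(cb)), aa3(translate_str(ca)))
        counts[pair] = counts.get(pair, 0) + 1
    return ConversionTable.from_counts(
        [(f, t, c) for (f, t), c in counts.items()], n_excluded=excluded
    )


@dataclass
class CodonUsageDelta:
    """Per-codon usage before editing and its signed change after.

    Keys are RNA codons (UUU ... GGG, 64 entries); ratios are fractions of
    ``total_before``. Deltas sum to zero over the 64 codons.
    """

    count_before: dict[str, int]
    delta_count: dict[str, int]
    total_before: int
    n_excluded: int = 0

    @classmethod
    def from_counts(
        cls,
        count_before: dict[str, int],
        delta_count: dict[str, int],
        n_excluded: int = 0,
    ) -> "CodonUsageDelta":
        before = {c: int(count_before.get(c, 0)) for c in RNA_CODONS}
        delta = {c: int(delta_count.get(c, 0)) for c in RNA_CODONS}
        return cls(
            count_before=before,
            delta_count=delta,
            total_before=sum(before.values()),
            n_excluded=n_excluded,
        )

    def ratio_before(self, codon: str) -> float:
        return self.count_before[codon] / self.total_before if self.total_before else 0.0

    def delta_ratio(self, codon: str) -> float:
        return self.delta_count[codon] / self.total_before if self.total_before else 0.0

    def net_amino_acid_change(self, aa_one_letter: str) -> int:
        """Net change in the number of codons encoding one amino acid."""
        return sum(
            d
            for codon, d in self.delta_count.items()
            if translate_str(codon.replace("U", "T")) == aa_one_letter
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for codon in RNA_CODONS:
            rows.append(
                {
                    "amino_acid": aa3(translate_str(codon.replace("U", "T"))),
                    "codon": codon,
                    "count_before": self.count_before[codon],
                    "ratio_before_pct": 100.0 * self.ratio_before(codon),
                    "delta_count": self.delta_count[codon],
                    "delta_ratio_pct": 100.0 * self.delta_ratio(codon),
                }
            )
        return pd.DataFrame(rows)


def codon_usage_delta(
    cds_set: Sequence[CodingSequence | str],
    edited_set: Sequence[CodingSequence | str],
) -> CodonUsageDelta:
    """Codon counts over all genes before editing and the per-codon deltas.

    Counts cover every complete, N-free codon (stop codons included);
    excluded codons are tallied.
    """
    if len(cds_set) != len(edited_set):
        raise EditApplicationError("before/after sets differ in size")
    before_counts: dict[str, int] = {}
    after_counts: dict[str, int] = {}
    excluded = 0
    for before, after in zip(cds_set, edited_set):
        b, a = _seq_of(before), _seq_of(after)
        if len(b) != len(a):
            raise EditApplicationError("before/after length mismatch")
        for i in range(0, len(b) - len(b) % 3, 3):
            cb, ca = _rna(b[i : i + 3]), _rna(a[i : i + 3])
            if "N" in cb or "N" in ca:
                excluded += 1
                continue
            before_counts[cb] = before_counts.get(cb, 0) + 1
            after_counts[ca] = after_counts.get(ca, 0) + 1
    delta = {
        c: after_counts.get(c, 0) - before_counts.get(c, 0) for c in RNA_CODONS
    }
    return CodonUsageDelta.from_counts(before_counts, delta, n_excluded=excluded)


@dataclass
class StartStopEvent:
    gene_id: str
    kind: str  # start_gain | stop_gain
    codon_index: int
    codon_before: str  # RNA alphabet
    codon_after: str
    truncation: bool = False  # stop gained before the terminal codon


def detect_start_stop_gain(
    cds: CodingSequence | str,
    edited: CodingSequence | str,
    gene_id: str = "",
) -> list[StartStopEvent]:
    """Find editing-created initiation and termination codons.

    A start gain is codon 1 changing ACG -> AUG; a stop gain is any codon
    becoming UAA/UAG/UGA. A stop gained before the terminal codon truncates
    the protein and is flagged as such.
    """
    b, a = _seq_of(cds), _seq_of(edited)
    gid = gene_id or (cds.gene_id if isinstance(cds, CodingSequence) else "")
    if len(b) != len(a):
        raise EditApplicationError(f"{gid}: before/after length mismatch")
    events: list[StartStopEvent] = []
    n_codons = len(b) // 3
    for idx in range(1, n_codons + 1):
        cb = _rna(b[(idx - 1) * 3 : idx * 3])
        ca = _rna(a[(idx - 1) * 3 : idx * 3])
        if cb == ca:
            continue
        if idx == 1 and cb == "ACG" and ca == "AUG":
            events.append(StartStopEvent(gid, "start_gain", 1, cb, ca))
        if ca in STOP_CODONS_RNA and cb not in STOP_CODONS_RNA:
            events.append(
                StartStopEvent(
                    gid, "stop_gain", idx, cb, ca, truncation=(idx < n_codons)
                )
            )
    return events
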