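"""Direct-repeat discovery, loop-out decomposition and long-read evidence.

A pair of identical large direct repeats (LDRs) on a circular master
mitogenome (MC) can recombine intramolecularly and "loop out" two
subgenomic circles (SCs) whose lengths sum to the master's. Labelling the
1-kb flanking regions of the two repeat copies FR1|LDR|FR2 and FR3|LDR|FR4
on the MC, the four possible flank-repeat-flank junctions discriminate the
conformations: type 1 (FR1-LDR-FR2) and type 2 (FR3-LDR-FR4) occur on the
MC, type 3 (FR1-LDR-FR4) on SC1 and type 4 (FR3-LDR-FR2) on SC2. Long reads
anchored on both flanks across a junction therefore vote for a
conformation, and joint observation of all four types evidences their
coexistence in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import edlib

from mitoeditkit.seq_model import AnnotatedGenome, reverse_complement


class RecombinationError(ValueError):
    """Invalid repeat pair or conformation request."""


@dataclass(frozen=True)
class RepeatPair:
    """An exact same-orientation repeated pair on the (circular) genome."""

    length: int
    copyA_start: int  # 1-based
    copyB_start: int  # 1-based
    identity: float = 1.0

    def intervals_mod(self, n: int) -> tuple[set[int], set[int]]:
        a = {(self.copyA_start - 1 + k) % n for k in range(self.length)}
        b = {(self.copyB_start - 1 + k) % n for k in range(self.length)}
        return a, b


def _maximal_pairs_on(text: str, n_total: int, min_len: int, circular: bool):
    """Seed-and-extend maximal exact pair discovery on ``text``.

    ``text`` is the doubled sequence for circular genomes; seeds are
    restricted to the first ``n_total`` positions and deduplicated per
    diagonal so each maximal run is extended once.
    """
    k = min(min_len, 32)
    index: dict[str, list[int]] = {}
    for i in range(n_total):
        index.setdefault(text[i : i + k], []).append(i)
    seen_diag: dict[int, list[tuple[int, int]]] = {}
    results: set[tuple[int, int, int]] = set()
    m = len(text)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                d = j - i
                if d == 0 or (circular and d >= n_total):
                    continue
                covered = seen_diag.get(d, [])
                if any(lo <= i < hi for lo, hi in covered):
                    continue
                # extend left
                li, lj = i, j
                while li > 0 and lj > 0 and text[li - 1] == text[lj - 1]:
                    li -= 1
                    lj -= 1
                # extend right
                length = k
                while (
                    lj + length < m
                    and length < n_total
                    and text[li + length] == text[lj + length]
                ):
                    length += 1
                seen_diag.setdefault(d, []).append((li, li + length))
                if length >= min_len:
                    results.add((li, lj, length))
    return results


def find_direct_repeats(
    genome: AnnotatedGenome | str,
    min_len: int = 20,
    include_inverted: bool = False,
    circular: bool | None = None,
) -> list[RepeatPair]:
    """All maximal exact direct-repeat pairs of length >= min_len, longest first.

    Repeats are searched on the circularized sequence when the genome is
    circular, so pairs spanning the linearization origin are found. Pairs
    whose two copies overlap on the circle (tandem periods shorter than the
    repeat) are not reported; abutting copies are. Inverted repeats are
    appended (strand-reversed second copy) only when requested.
    """
    if min_len < 20:
        raise RecombinationError("min_len must be >= 20")
    if isinstance(genome, AnnotatedGenome):
        seq = genome.sequence
        circ = genome.circular if circular is None else circular
    else:
        seq = genome.upper()
        circ = bool(circular)
    n = len(seq)
    text = seq + seq if circ else seq
    raw = _maximal_pairs_on(text, n, min_len, circ)
    pairs: set[tuple[int, int, int]] = set()
    for i, j, length in raw:
        if length > n:
            length = n
        a, b = i % n, j % n
        lo, hi = min(a, b), max(a, b)
        pairs.add((lo, hi, length))
    out: list[RepeatPair] = []
    for lo, hi, length in pairs:
        pair = RepeatPair(length=length, copyA_start=lo + 1, copyB_start=hi + 1)
        ia, ib = pair.intervals_mod(n)
        if ia & ib:
            continue  # tandem overlap; not a loop-out substrate
        out.append(pair)
    out.sort(key=lambda p: (-p.length, p.copyA_start, p.copyB_start))
    if include_inverted:
        out.extend(_inverted_pairs(seq, n, min_len, circ))
    return out


def _inverted_pairs(seq: str, n: int, min_len: int, circ: bool) -> list["InvertedRepeatPair"]:
    text = seq + seq if circ else seq
    rc = reverse_complement(text)
    k = min(min_len, 32)
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(text[i : i + k], []).append(i)
    found: set[tuple[int, int, int]] = set()
    m = len(text)
    for j in range(len(rc) - k + 1):
        kmer = rc[j : j + k]
        if kmer not in index:
            continue
        # position j in rc corresponds to forward start m - j - k
        for i in index[kmer]:
            li, lj = i, j
            while li > 0 and lj > 0 and text[li - 1] == rc[lj - 1]:
                li -= 1
                lj -= 1
            length = k
            while lj + length < m and length < n and text[li + length] == rc[lj + length]:
                length += 1
            fwd2 = (m - (lj + length)) % n
            a, b = li % n, fwd2
            if a == b:
                continue
            lo, hi = min(a, b), max(a, b)
            found.add((lo, hi, length))
    return [
        InvertedRepeatPair(length=L, copyA_start=lo + 1, copyB_start=hi + 1)
        for lo, hi, L in sorted(found, key=lambda t: -t[2])
        if L >= min_len
    ]


@dataclass(frozen=True)
class InvertedRepeatPair(RepeatPair):
    orientation: str = "inverted"


def _fetch_circ(seq: str, start0: int, length: int) -> str:
    n = len(seq)
    start0 %= n
    if length > n:
        raise RecombinationError("request longer than the genome")
    end = start0 + length
    if end <= n:
        return seq[start0:end]
    return seq[start0:] + seq[: end - n]


@dataclass
class ConformationSet:
    """Master circle, its two loop-out subcircles, and the four flanks.

    ``sc1`` carries the FR1-LDR-FR4 junction, ``sc2`` the FR3-LDR-FR2
    junction; len(sc1) + len(sc2) == len(mc) and each subcircle contains
    exactly one full repeat copy.
    """

    mc: AnnotatedGenome
    sc1: str
    sc2: str
    repeat: str
    flanks: dict[int, str]  # 1..4 -> flank sequence (flank_size bp each)
    flank_size: int
    pair: RepeatPair

    def junction(self, btype: int) -> str:
        """Reference FRx-LDR-FRy sequence for a boundary type 1-4."""
        up, dn = {1: (1, 2), 2: (3, 4), 3: (1, 4), 4: (3, 2)}[btype]
        return self.flanks[up] + self.repeat + self.flanks[dn]

    def template(self, name: str) -> str:
        return {"mc": self.mc.sequence, "sc1": self.sc1, "sc2": self.sc2}[name]


def loop_out(
    mc: AnnotatedGenome, pair: RepeatPair, flank_size: int = 1000
) -> ConformationSet:
    """Decompose the master circle into its two loop-out subcircles.

    Recombination between the two identical repeat copies excises the arc
    between them together with one copy (sc2 = copyA + inner arc, junction
    FR3-LDR-FR2) and leaves the complementary circle (sc1 = copyB + outer
    arc, junction FR1-LDR-FR4). FR1/FR2 flank copy A and FR3/FR4 flank
    copy B on the master circle, ``flank_size`` bases each.
    """
    seq = mc.sequence
    n = len(seq)
    a0, b0 = pair.copyA_start - 1, pair.copyB_start - 1
    if a0 > b0:
        a0, b0 = b0, a0
    L = pair.length
    copy_a = _fetch_circ(seq, a0, L)
    copy_b = _fetch_circ(seq, b0, L)
    if copy_a != copy_b:
        raise RecombinationError("repeat copies are not identical")
    ia, ib = RepeatPair(L, a0 + 1, b0 + 1).intervals_mod(n)
    if ia & ib:
        raise RecombinationError("repeat copies overlap on the circle")
    sc2 = _fetch_circ(seq, a0, b0 - a0)
    sc1 = _fetch_circ(seq, b0, n - (b0 - a0))
    flanks = {
        1: _fetch_circ(seq, a0 - flank_size, flank_size),
        2: _fetch_circ(seq, a0 + L, flank_size),
        3: _fetch_circ(seq, b0 - flank_size, flank_size),
        4: _fetch_circ(seq, b0 + L, flank_size),
    }
    return ConformationSet(
        mc=mc, sc1=sc1, sc2=sc2, repeat=copy_a, flanks=flanks,
        flank_size=flank_size, pair=RepeatPair(L, a0 + 1, b0 + 1),
    )


@dataclass
class BoundaryCall:
    """Boundary-type assignment for one long read."""

    read_id: str
    btype: int | str  # 1|2|3|4 or "ambiguous"
    anchor_up: int = 0  # matched bases on the upstream flank
    anchor_down: int = 0
    edits: int = 0


_TYPE_ANCHORS = {1: (1, 2), 2: (3, 4), 3: (1, 4), 4: (3, 2)}


def _best_hits(query: str, target: str, k: int) -> list[tuple[int, int, int]]:
    """edlib infix hits of query in target: (start, end, edits), best score."""
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0:
        return []
    return [(s, e, res["editDistance"]) for s, e in res["locations"]]


def classify_boundary_read(
    read: str,
    conformations: ConformationSet,
    min_anchor: int = 100,
    max_edit_frac: float = 0.15,
) -> BoundaryCall | None:
    """Assign a read to boundary type 1-4, or "ambiguous".

    A read is typed when it anchors with >= min_anchor bases on the repeat-
    proximal edge of one upstream flank and one downstream flank, in that
    order, separated by approximately the repeat length (the read crosses
    the whole LDR). Anchoring tolerates ``max_edit_frac`` edits over the
    anchor span; both read orientations are tried. Reads matching no type,
    or more than one, are ambiguous.
    """
    read = read.upper()
    if len(read) <= min_anchor:
        return BoundaryCall(read_id="", btype="ambiguous")
    rep_len = len(conformations.repeat)
    k = int(max_edit_frac * min_anchor)
    gap_tol = int(0.25 * rep_len) + 50
    anchors_up = {
        f: conformations.flanks[f][-min_anchor:] for f in (1, 3)
    }
    anchors_dn = {
        f: conformations.flanks[f][:min_anchor] for f in (2, 4)
    }
    matches: list[tuple[int, int, int, int]] = []  # (btype, span_up, span_dn, edits)
    for oriented in (read, reverse_complement(read)):
        up_hits = {f: _best_hits(a, oriented, k) for f, a in anchors_up.items()}
        dn_hits = {f: _best_hits(a, oriented, k) for f, a in anchors_dn.items()}
        for btype, (fu, fd) in _TYPE_ANCHORS.items():
            for us, ue, uev in up_hits.get(fu, []):
                for ds, de, dev in dn_hits.get(fd, []):
                    gap = ds - ue - 1
                    if abs(gap - rep_len) <= gap_tol:
                        matches.append(
                            (btype, ue - us + 1, de - ds + 1, uev + dev)
                        )
    types = {m[0] for m in matches}
    if len(types) != 1:
        return BoundaryCall(read_id="", btype="ambiguous")
    best = min(matches, key=lambda m: m[3])
    return BoundaryCall(
        read_id="", btype=best[0], anchor_up=best[1], anchor_down=best[2],
        edits=best[3],
    )


@dataclass
class ConformationEvidence:
    """Per-boundary-type read counts and the coexistence verdict."""

    counts: dict[int, int]
    n_ambiguous: int

    @property
    def all_four_types(self) -> bool:
        return all(self.counts.get(t, 0) > 0 for t in (1, 2, 3, 4))

    @property
    def total_typed(self) -> int:
        return sum(self.counts.values())


def conformation_evidence(calls: Sequence[BoundaryCall]) -> ConformationEvidence:
    """Summarize boundary calls: counts per type and whether all four
    junction types were observed together (the coexistence criterion for
    MC + SC1 + SC2)."""
    counts = {1: 0, 2: 0, 3: 0, 4: 0}
    ambiguous = 0
    for c in calls:
        if isinstance(c.btype, int):
            counts[c.btype] += 1
        else:
            ambiguous += 1
    return ConformationEvidence(counts=counts, n_ambiguous=ambiguous)
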