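"""Codon-usage selection indices: GC by codon position, GC3s, Wright's ENC,
the ENC-GC3s expected curve, and the neutrality-plot regression.

The neutrality plot regresses GC12 (mean GC at codon positions 1-2) on GC3;
its absolute slope is read as the mutation-selection equilibrium
coefficient: 1 under complete mutational bias (positions drift together),
0 under complete selective constraint on positions 1-2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from mitoeditkit.seq_model import CodingSequence, translate_str

#: synonymous family per amino acid under the standard code (stops excluded)
_FAMILY_SIZE = {
    "F": 2, "L": 6, "S": 6, "Y": 2, "C": 2, "W": 1, "P": 4, "H": 2,
    "Q": 2, "R": 6, "I": 3, "M": 1, "T": 4, "N": 2, "K": 2, "V": 4,
    "A": 4, "D": 2, "E": 2, "G": 4,
}
_STOPS_DNA = {"TAA", "TAG", "TGA"}
_CLASS_FAMILY_COUNT = {2: 9, 3: 1, 4: 5, 6: 3}

ENC_MIN, ENC_MAX = 20.0, 61.0


class CodonStatsError(ValueError):
    """No computable codons for the requested statistic."""


class EncUndefinedError(CodonStatsError):
    """ENC has no defined value for this gene (reason in the message)."""


def _codons(seq: CodingSequence | str) -> list[str]:
    s = seq.na_seq if isinstance(seq, CodingSequence) else seq
    s = s.upper().replace("U", "T")
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def gc_fractions(cds: CodingSequence | str) -> tuple[float, float, float, float]:
    """(gc1, gc2, gc3, gc12) over all complete codons; N bases excluded."""
    codons = _codons(cds)
    if not codons:
        raise CodonStatsError("no complete codons")
    gc = []
    for k in range(3):
        bases = [c[k] for c in codons if c[k] != "N"]
        if not bases:
            raise CodonStatsError(f"no non-N bases at codon position {k + 1}")
        gc.append(sum(b in "GC" for b in bases) / len(bases))
    return gc[0], gc[1], gc[2], (gc[0] + gc[1]) / 2


def gc3s(cds: CodingSequence | str) -> float:
    """GC fraction at synonymously variable third positions.

    Codons excluded: the three stops, AUG (Met) and UGG (Trp) — the only
    codons whose third position cannot vary synonymously.
    """
    codons = [
        c
        for c in _codons(cds)
        if c not in _STOPS_DNA and c not in ("ATG", "TGG") and "N" not in c
    ]
    if not codons:
        raise CodonStatsError("no synonymously variable codons (only Met/Trp/stops)")
    thirds = [c[2] for c in codons]
    return sum(b in "GC" for b in thirds) / len(thirds)


def _family_homozygosity(counts: Sequence[int]) -> float | None:
    """Wright's F-hat = (n * sum(p^2) - 1) / (n - 1); undefined at n < 2."""
    n = sum(counts)
    if n < 2:
        return None
    p2 = sum((c / n) ** 2 for c in counts)
    return (n * p2 - 1) / (n - 1)


def enc(cds: CodingSequence | str) -> float:
    """Wright's effective number of codons (Nc), clamped to [20, 61].

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, where Fk averages the per-family
    codon homozygosity over the amino acids with k synonymous codons
    (families with fewer than two codons observed are left out of the
    average). When isoleucine (the lone 3-fold family) is absent, F3 falls
    back to (F2 + F4)/2; a missing 2-, 4- or 6-fold class leaves ENC
    undefined.
    """
    per_family: dict[str, dict[str, int]] = {}
    for codon in _codons(cds):
        if codon in _STOPS_DNA or "N" in codon:
            continue
        aa = translate_str(codon)
        per_family.setdefault(aa, {})[codon] = per_family.get(aa, {}).get(codon, 0) + 1
    if not per_family:
        raise EncUndefinedError("no sense codons")
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, usage in per_family.items():
        k = _FAMILY_SIZE[aa]
        if k == 1:
            continue
        f = _family_homozygosity(list(usage.values()))
        if f is not None:
            class_f[k].append(f)
    fbar: dict[int, float] = {}
    for k, fs in class_f.items():
        if fs:
            fbar[k] = float(np.mean(fs))
    if 3 not in fbar and 2 in fbar and 4 in fbar:
        fbar[3] = (fbar[2] + fbar[4]) / 2
    missing = [k for k in (2, 3, 4, 6) if k not in fbar]
    if missing:
        raise EncUndefinedError(
            f"no observed family in degeneracy class(es) {missing}"
        )
    zero = [k for k in (2, 3, 4, 6) if fbar[k] <= 0]
    if zero:
        raise EncUndefinedError(
            f"zero mean homozygosity in degeneracy class(es) {zero}"
        )
    nc = 2 + sum(
        _CLASS_FAMILY_COUNT[k] / fbar[k] for k in (2, 3, 4, 6)
    )
    return float(min(max(nc, ENC_MIN), ENC_MAX))


def enc_expected(gc3s_value: float) -> float:
    """Expected ENC under mutation pressure alone at a given GC3s.

    ENC_expected = 2 + s + 29 / (s^2 + (1 - s)^2), the no-selection
    reference curve of the ENC-GC3s plot.
    """
    s = float(gc3s_value)
    if not 0.0 <= s <= 1.0:
        raise CodonStatsError(f"GC3s {s} outside [0, 1]")
    return 2 + s + 29 / (s * s + (1 - s) * (1 - s))


@dataclass
class CodonStats:
    """Per-gene codon-usage indices; ``enc`` is None when undefined."""

    gene_id: str
    n_codons: int
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float | None
    enc: float | None
    enc_reason: str = ""


def compute_codon_stats(cds: CodingSequence | str, gene_id: str = "") -> CodonStats:
    gid = gene_id or (cds.gene_id if isinstance(cds, CodingSequence) else "")
    g1, g2, g3, g12 = gc_fractions(cds)
    try:
        s3 = gc3s(cds)
    except CodonStatsError:
        s3 = None
    try:
        nc: float | None = enc(cds)
        reason = ""
    except EncUndefinedError as e:
        nc, reason = None, str(e)
    return CodonStats(
        gene_id=gid,
        n_codons=len(_codons(cds)),
        gc1=g1, gc2=g2, gc3=g3, gc12=g12,
        gc3s=s3, enc=nc, enc_reason=reason,
    )


@dataclass
class NeutralityFit:
    """OLS fit of GC12 on GC3 over genes; |slope| is the mutation-selection
    equilibrium coefficient (mutation contribution = 100 * |slope| %)."""

    points: list[tuple[float, float]]
    slope: float
    intercept: float
    r2: float
    stderr: float

    @property
    def abs_slope(self) -> float:
        return abs(self.slope)

    @property
    def mutation_contribution_pct(self) -> float:
        return 100.0 * self.abs_slope

    @property
    def n(self) -> int:
        return len(self.points)


def neutrality_fit(
    stats: Sequence[CodonStats] | Sequence[tuple[float, float]],
) -> NeutralityFit:
    """Fit the neutrality plot from per-gene stats or raw (gc3, gc12) pairs."""
    points = [
        (s.gc3, s.gc12) if isinstance(s, CodonStats) else (float(s[0]), float(s[1]))
        for s in stats
    ]
    if len(points) < 3:
        raise CodonStatsError(f"need >= 3 genes for a fit, got {len(points)}")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    if np.allclose(x, x[0]):
        raise CodonStatsError("degenerate fit: GC3 has zero variance")
    res = sps.linregress(x, y)
    return NeutralityFit(
        points=points,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        stderr=float(res.stderr),
    )
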