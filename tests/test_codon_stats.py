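"""GC statistics, Wright's ENC, the expected curve, neutrality regression."""

import itertools

import numpy as np
import pytest

from mitoeditkit.codon_stats import (
    CodonStatsError,
    EncUndefinedError,
    compute_codon_stats,
    enc,
    enc_expected,
    gc3s,
    gc_fractions,
    neutrality_fit,
)
from mitoeditkit.seq_model import translate_str

SENSE = [
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]


def brute_force_enc(seq: str) -> float:
    """Independent implementation of Wright's Nc, written from the formula.

    F-hat per amino acid = (n * sum p^2 - 1)/(n - 1) for n >= 2; class means
    over the 2/3/4/6-fold degeneracy families; Nc = 2 + 9/F2 + 1/F3 + 5/F4
    + 3/F6 with the (F2+F4)/2 fallback for a missing 3-fold class.
    """
    codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
    by_aa: dict[str, dict[str, int]] = {}
    family = {}
    for c in ("".join(t) for t in itertools.product("ACGT", repeat=3)):
        aa = translate_str(c)
        if aa != "*":
            family[aa] = family.get(aa, 0) + 1
    for c in codons:
        if "N" in c or translate_str(c) == "*":
            continue
        aa = translate_str(c)
        by_aa.setdefault(aa, {})
        by_aa[aa][c] = by_aa[aa].get(c, 0) + 1
    fs: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, usage in by_aa.items():
        k = family[aa]
        if k == 1:
            continue
        n = sum(usage.values())
        if n < 2:
            continue
        fhat = (n * sum((v / n) ** 2 for v in usage.values()) - 1) / (n - 1)
        fs[k].append(fhat)
    means = {k: sum(v) / len(v) for k, v in fs.items() if v}
    if 3 not in means and 2 in means and 4 in means:
        means[3] = (means[2] + means[4]) / 2
    if any(k not in means or means[k] <= 0 for k in (2, 3, 4, 6)):
        raise ValueError("undefined")
    nc = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(max(nc, 20.0), 61.0)


class TestGcFractions:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("GCGCGC", (1.0, 1.0, 1.0, 1.0)),
            ("ATAATA", (0.0, 0.0, 0.0, 0.0)),
            ("ATGGCC", (0.5, 0.5, 1.0, 0.5)),
        ],
    )
    def test_hand_counts(self, seq, expected):
        assert gc_fractions(seq) == pytest.approx(expected)

    def test_n_bases_excluded(self):
        # N at position 3 of the second codon: only the first codon's G counts
        assert gc_fractions("ATGACN")[2] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(CodonStatsError):
            gc_fractions("AT")


class TestGc3s:
    def test_only_met_trp_undefined(self):
        with pytest.raises(CodonStatsError):
            gc3s("ATGTGG")

    @pytest.mark.parametrize("seq,expected", [("TTTTTC", 0.5), ("GCCGCA", 0.5)])
    def test_hand_counts(self, seq, expected):
        assert gc3s(seq) == pytest.approx(expected)

    def test_stops_excluded(self):
        # TAA third position would be A; excluded, leaving GCC -> 1.0
        assert gc3s("GCCTAA") == 1.0


class TestEnc:
    def test_uniform_usage_hits_upper_limit(self):
        seq = "".join(SENSE * 30)
        assert enc(seq) == pytest.approx(61.0)

    def test_one_codon_per_amino_acid_hits_lower_limit(self):
        one_each = sorted({translate_str(c): c for c in SENSE}.values())
        seq = "".join(c * 25 for c in one_each)
        assert enc(seq) == pytest.approx(20.0)

    def test_matches_brute_force_oracle_on_random_genes(self, rng):
        for _ in range(25):
            n = int(rng.integers(60, 1500))
            seq = "".join(rng.choice(SENSE, size=n))
            try:
                expected = brute_force_enc(seq)
            except ValueError:
                with pytest.raises(EncUndefinedError):
                    enc(seq)
                continue
            assert enc(seq) == pytest.approx(expected, abs=1e-9)

    def test_synonym_relabeling_invariance(self, rng):
        """ENC depends only on per-family count multisets, not on which
        synonymous codon carries each count."""
        from mitoeditkit.seq_model import translate_str as tr

        fam: dict[str, list[str]] = {}
        for c in SENSE:
            fam.setdefault(tr(c), []).append(c)
        seq = "".join(rng.choice(SENSE, size=800))
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        relabeled = []
        perm = {}
        for aa, codon_list in fam.items():
            shuffled = list(codon_list)
            rng.shuffle(shuffled)
            perm.update(dict(zip(codon_list, shuffled)))
        for c in codons:
            relabeled.append(perm[c])
        assert enc(seq) == pytest.approx(enc("".join(relabeled)))

    def test_concentration_decreases_enc(self, rng):
        """Concentrating one family's usage onto fewer codons never raises ENC."""
        codons = list(rng.choice(SENSE, size=1200))
        before = enc("".join(codons))
        remap = {"GCC": "GCA", "GCG": "GCA", "GCT": "GCA"}  # alanine family
        concentrated = "".join(remap.get(c, c) for c in codons)
        assert enc(concentrated) <= before + 1e-9

    def test_stop_only_undefined(self):
        with pytest.raises(EncUndefinedError):
            enc("TAATAGTGA")


class TestEncExpected:
    @pytest.mark.parametrize("s,expected", [(0.5, 60.5), (0.0, 31.0), (1.0, 32.0)])
    def test_curve_values(self, s, expected):
        assert enc_expected(s) == pytest.approx(expected)

    def test_symmetric_about_half(self):
        for s in np.linspace(0, 0.5, 21):
            left, right = enc_expected(s), enc_expected(1 - s)
            # the curve's rational part is symmetric; the +s term adds 1-2s
            assert right - left == pytest.approx(1 - 2 * s)

    def test_out_of_range_rejected(self):
        with pytest.raises(CodonStatsError):
            enc_expected(1.2)


class TestNeutralityFit:
    def test_diagonal_slope_one(self):
        pts = [(0.2, 0.2), (0.4, 0.4), (0.6, 0.6), (0.8, 0.8)]
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.mutation_contribution_pct == pytest.approx(100.0)

    def test_flat_slope_zero(self):
        fit = neutrality_fit([(0.3, 0.5), (0.4, 0.5), (0.5, 0.5)])
        assert fit.slope == pytest.approx(0.0)

    def test_matches_closed_form_ols(self):
        pts = [(0.30, 0.42), (0.45, 0.47), (0.62, 0.55)]
        x = np.array([p[0] for p in pts])
        y = np.array([p[1] for p in pts])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(slope)
        assert fit.intercept == pytest.approx(intercept)

    def test_too_few_points_rejected(self):
        with pytest.raises(CodonStatsError):
            neutrality_fit([(0.1, 0.2), (0.2, 0.3)])

    def test_degenerate_x_rejected(self):
        with pytest.raises(CodonStatsError, match="variance"):
            neutrality_fit([(0.4, 0.2), (0.4, 0.3), (0.4, 0.4)])

    def test_independent_gc12_gc3_slope_near_zero(self):
        """With GC12 independent of GC3 the fitted slope's own 95% CI covers
        zero in at least ~90% of seeded replicates."""
        rng = np.random.default_rng(2024)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            gc3 = rng.uniform(0.2, 0.6, size=25)
            gc12 = rng.normal(0.45, 0.03, size=25)
            fit = neutrality_fit(list(zip(gc3, gc12)))
            if abs(fit.slope) <= 1.96 * fit.stderr:
                covered += 1
        assert covered >= 0.90 * n_rep


class TestComputeCodonStats:
    def test_undefined_enc_carries_reason(self):
        stats = compute_codon_stats("ATGTGGATG", gene_id="tiny")
        assert stats.enc is None
        assert stats.enc_reason
        assert stats.gc3s is None

    def test_gc12_is_mean_of_gc1_gc2(self, rng):
        seq = "".join(rng.choice(SENSE, size=200))
        s = compute_codon_stats(seq)
        assert s.gc12 == pytest.approx((s.gc1 + s.gc2) / 2)
        if s.enc is not None:
            assert 20.0 <= s.enc <= 61.0
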