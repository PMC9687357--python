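"""Repeat discovery, loop-out decomposition, read boundary typing."""

import numpy as np
import pytest

from mitoeditkit.recombination import (
    RecombinationError,
    RepeatPair,
    classify_boundary_read,
    conformation_evidence,
    find_direct_repeats,
    loop_out,
    BoundaryCall,
)
from mitoeditkit.seq_model import AnnotatedGenome, reverse_complement


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def brute_force_direct_repeats(seq: str, min_len: int):
    """Quadratic diagonal-scan oracle for maximal exact direct pairs on a
    linear sequence; same overlap filtering as the library."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    found = set()
    for d in range(1, n):
        eq = arr[: n - d] == arr[d:]
        idx = np.flatnonzero(eq)
        if len(idx) == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for s, e in zip(starts, ends):
            run_start, run_len = int(idx[s]), int(idx[e] - idx[s] + 1)
            if run_len >= min_len and run_len <= d:  # non-overlapping copies
                found.add((run_start + 1, run_start + d + 1, run_len))
    return found


class TestFindDirectRepeats:
    def test_planted_repeat_found(self, rng):
        unit = _random_seq(rng, 600)
        seq = (
            _random_seq(rng, 2000) + unit + _random_seq(rng, 3000)
            + unit + _random_seq(rng, 1500)
        )
        pairs = find_direct_repeats(seq, min_len=200, circular=True)
        assert len(pairs) == 1
        assert pairs[0].length >= 600  # chance extension at the edges allowed
        assert pairs[0].copyB_start - pairs[0].copyA_start == 3600

    def test_random_sequence_has_no_long_repeats(self, rng):
        seq = _random_seq(rng, 100_000)
        assert find_direct_repeats(seq, min_len=50, circular=True) == []

    def test_adjacent_copies_abut(self, rng):
        unit = _random_seq(rng, 1000)
        # boundary bases chosen so the maximal match cannot extend by chance
        prefix = _random_seq(rng, 499) + ("A" if unit[-1] != "A" else "C")
        suffix = ("A" if unit[0] != "A" else "C") + _random_seq(rng, 499)
        seq = prefix + unit + unit + suffix
        pairs = find_direct_repeats(seq, min_len=500, circular=False)
        assert len(pairs) == 1
        p = pairs[0]
        assert p.copyB_start == p.copyA_start + p.length

    def test_origin_spanning_repeat_found_on_circle(self, rng):
        unit = _random_seq(rng, 400)
        # one copy crosses the linearization origin
        seq = unit[250:] + _random_seq(rng, 2000) + unit + _random_seq(rng, 1000) + unit[:250]
        pairs = find_direct_repeats(seq, min_len=300, circular=True)
        assert any(p.length >= 400 for p in pairs)

    def test_min_len_floor(self, rng):
        with pytest.raises(RecombinationError):
            find_direct_repeats(_random_seq(rng, 100), min_len=10)

    def test_matches_brute_force_oracle(self, rng):
        """Seed-and-extend output equals the quadratic all-diagonal scan."""
        for trial in range(5):
            parts = [_random_seq(rng, 700)]
            for _ in range(3):
                unit = _random_seq(rng, int(rng.integers(40, 150)))
                parts += [unit, _random_seq(rng, 300), unit]
            parts.append(_random_seq(rng, 400))
            seq = "".join(parts)[:3000]
            expected = brute_force_direct_repeats(seq, 30)
            got = {
                (p.copyA_start, p.copyB_start, p.length)
                for p in find_direct_repeats(seq, min_len=30, circular=False)
            }
            assert got == expected

    def test_inverted_repeats_reported_separately(self, rng):
        unit = _random_seq(rng, 300)
        seq = (
            _random_seq(rng, 500) + unit + _random_seq(rng, 800)
            + reverse_complement(unit) + _random_seq(rng, 500)
        )
        direct = find_direct_repeats(seq, min_len=100, circular=False)
        assert direct == []
        with_inv = find_direct_repeats(
            seq, min_len=100, circular=False, include_inverted=True
        )
        assert any(getattr(p, "orientation", "") == "inverted" for p in with_inv)


class TestLoopOut:
    def _genome(self, rng, total, rep_len, inner_gap):
        """Circle: [copyA][inner_gap][copyB][rest]."""
        unit = _random_seq(rng, rep_len)
        rest = total - 2 * rep_len - inner_gap
        seq = unit + _random_seq(rng, inner_gap) + unit + _random_seq(rng, rest)
        genome = AnnotatedGenome("mc", seq, circular=True)
        pair = RepeatPair(rep_len, 1, rep_len + inner_gap + 1)
        return genome, pair

    def test_published_scale_lengths(self, rng):
        """212,159-bp master circle with 5,222-bp repeats placed so one
        product is 55,997 bp: the other must be 156,162 bp."""
        genome, pair = self._genome(rng, 212_159, 5_222, 55_997 - 5_222)
        conf = loop_out(genome, pair)
        assert len(conf.sc2) == 55_997
        assert len(conf.sc1) == 156_162
        assert len(conf.sc1) + len(conf.sc2) == 212_159

    def test_symmetric_toy_circle(self, rng):
        genome, pair = self._genome(rng, 1_000, 100, 400)
        conf = loop_out(genome, pair, flank_size=50)
        assert len(conf.sc1) == len(conf.sc2) == 500

    def test_abutting_copies_degenerate_product(self, rng):
        genome, pair = self._genome(rng, 2_000, 300, 0)
        conf = loop_out(genome, pair, flank_size=100)
        assert conf.sc2 == conf.repeat

    def test_each_subcircle_contains_one_copy(self, rng):
        genome, pair = self._genome(rng, 5_000, 400, 1_200)
        conf = loop_out(genome, pair)
        assert conf.sc1.count(conf.repeat) == 1
        assert conf.sc2.count(conf.repeat) == 1

    def test_overlapping_copies_rejected(self, rng):
        seq = _random_seq(rng, 1_000)
        genome = AnnotatedGenome("mc", seq, circular=True)
        with pytest.raises(RecombinationError):
            loop_out(genome, RepeatPair(200, 1, 101))

    def test_non_identical_copies_rejected(self, rng):
        seq = _random_seq(rng, 2_000)
        genome = AnnotatedGenome("mc", seq, circular=True)
        with pytest.raises(RecombinationError, match="identical"):
            loop_out(genome, RepeatPair(100, 1, 1_001))

    def test_length_conservation_random_fixtures(self, rng):
        for _ in range(100):
            rep_len = int(rng.integers(100, 400))
            inner = int(rng.integers(0, 800))
            rest = int(rng.integers(200, 1_000))
            genome, pair = self._genome(rng, 2 * rep_len + inner + rest, rep_len, inner)
            conf = loop_out(genome, pair, flank_size=64)
            assert len(conf.sc1) + len(conf.sc2) == len(genome.sequence)


class TestBoundaryClassification:
    @pytest.fixture
    def conf(self, rng):
        genome, pair = TestLoopOut()._genome(rng, 12_000, 900, 3_000)
        return loop_out(genome, pair, flank_size=400)

    def test_error_free_junction_reads(self, conf):
        for btype in (1, 2, 3, 4):
            read = conf.junction(btype)
            call = classify_boundary_read(read, conf, min_anchor=100)
            assert call.btype == btype, f"junction {btype} mistyped as {call.btype}"

    def test_reverse_complement_read_typed(self, conf):
        call = classify_boundary_read(
            reverse_complement(conf.junction(3)), conf, min_anchor=100
        )
        assert call.btype == 3

    def test_read_inside_repeat_is_ambiguous(self, conf):
        call = classify_boundary_read(conf.repeat, conf, min_anchor=100)
        assert call.btype == "ambiguous"

    def test_round_trip_simulated_conformation_reads(self, rng):
        """Error-free reads across a subcircle junction are always typed for
        that subcircle, never for the master circle, and vice versa."""
        for _ in range(25):
            rep_len = int(rng.integers(250, 500))
            inner = int(rng.integers(600, 1_500))
            rest = int(rng.integers(800, 2_000))
            genome, pair = TestLoopOut()._genome(
                rng, 2 * rep_len + inner + rest, rep_len, inner
            )
            conf = loop_out(genome, pair, flank_size=200)
            for btype in (1, 2, 3, 4):
                call = classify_boundary_read(conf.junction(btype), conf, min_anchor=80)
                assert call.btype == btype

    def test_noisy_reads_mostly_recovered(self, rng):
        from mitoeditkit.synthetic_data import SimConfig, simulate_long_reads

        genome, pair = TestLoopOut()._genome(rng, 20_000, 1_200, 6_000)
        conf = loop_out(genome, pair, flank_size=1_000)
        cfg = SimConfig(
            genome_length=20_000, n_genes=0, repeat_length=1_200,
            n_reads=300, read_length_mean=5_000, read_length_sd=800,
            read_error_rate=0.05, seed=3,
        )
        reads, labels = simulate_long_reads(conf, cfg)
        checked = agreed = 0
        for (rid, seq), label in zip(reads, labels):
            call = classify_boundary_read(seq, conf)
            if label.junction is not None:
                checked += 1
                agreed += call.btype == label.junction
        assert checked >= 20
        assert agreed / checked >= 0.99


class TestConformationEvidence:
    def _call(self, t):
        return BoundaryCall(read_id="r", btype=t)

    def test_all_four_types_coexistence(self):
        ev = conformation_evidence([self._call(t) for t in (1, 2, 3, 4, 2, "ambiguous")])
        assert ev.all_four_types
        assert ev.counts == {1: 1, 2: 2, 3: 1, 4: 1}
        assert ev.n_ambiguous == 1

    def test_master_circle_only(self):
        ev = conformation_evidence([self._call(t) for t in (1, 2, 1)])
        assert not ev.all_four_types

    def test_empty(self):
        ev = conformation_evidence([])
        assert not ev.all_four_types
        assert ev.total_typed == 0
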