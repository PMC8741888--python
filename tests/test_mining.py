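"""Perfect/compound repeat mining and the single-SSR candidate filter."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ssrmarkers import (
    DEFAULT_MIN_REPEATS,
    PipelineConfig,
    Read,
    filter_candidates,
    find_perfect_ssrs,
    join_compound,
)

from _oracles import brute_join, brute_ssr_hits


def _rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _plant(rng, n=300, max_runs=3):
    """Random sequence with a few planted repeat runs."""
    seq = list(_rand_dna(rng, n))
    for _ in range(rng.randint(0, max_runs)):
        u = rng.randint(1, 6)
        unit = _rand_dna(rng, u)
        k = rng.randint(3, 14)
        pos = rng.randrange(0, n - u * k + 1)
        seq[pos : pos + u * k] = unit * k
    return "".join(seq)


def _as_tuples(hits):
    return [(h.unit, h.unit_len, h.repeats, h.start, h.end) for h in hits]


def _clean_dna(rng, n, not_last=""):
    """Random DNA containing no detectable repeat, optionally with a
    constrained final base (to avoid extending an adjacent run)."""
    while True:
        s = _rand_dna(rng, n)
        if find_perfect_ssrs(s, DEFAULT_MIN_REPEATS):
            continue
        if not_last and s[-1] in not_last:
            continue
        return s


class TestFindPerfect:
    def test_mononucleotide_run(self):
        hits = find_perfect_ssrs("A" * 12, DEFAULT_MIN_REPEATS)
        assert _as_tuples(hits) == [("A", 1, 12, 0, 12)]
        assert hits[0].type == "p1"

    def test_primitivity_no_double_report(self):
        hits = find_perfect_ssrs("AC" * 6, DEFAULT_MIN_REPEATS)
        assert _as_tuples(hits) == [("AC", 2, 6, 0, 12)]
        # no additional p4 "ACAC" hit
        assert all(h.unit_len == 2 for h in hits)

    def test_flank_lengths(self):
        rng = random.Random(12)
        left = _clean_dna(rng, 20, not_last="C")
        right = _clean_dna(rng, 30)
        seq = left + "AC" * 8 + right
        hits = [h for h in find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS) if h.unit_len == 2]
        (h,) = hits
        assert (h.left_flank_len, h.right_flank_len) == (20, 30)
        assert h.left_flank_len == h.start
        assert h.right_flank_len == len(seq) - h.end

    def test_n_breaks_runs(self):
        assert find_perfect_ssrs("A" * 6 + "N" + "A" * 6, DEFAULT_MIN_REPEATS) == []

    def test_matches_brute_oracle_on_planted_sequences(self):
        rng = random.Random(99)
        for _ in range(150):
            seq = _plant(rng)
            got = _as_tuples(find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS))
            assert got == brute_ssr_hits(seq, DEFAULT_MIN_REPEATS)

    @given(st.text(alphabet="ACGTN", min_size=0, max_size=120))
    def test_matches_brute_oracle_random(self, seq):
        got = _as_tuples(find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS))
        assert got == brute_ssr_hits(seq, DEFAULT_MIN_REPEATS)


class TestJoinCompound:
    def test_adjacent_runs_make_c(self):
        rng = random.Random(21)
        left = _clean_dna(rng, 30, not_last="C")
        right = _clean_dna(rng, 30)
        seq = left + "AC" * 6 + "AG" * 6 + right
        hits = find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS)
        joined = join_compound(hits, max_gap=100)
        assert len(joined) == 1
        h = joined[0]
        assert h.type == "c"
        assert h.unit == "AC-AG"
        assert (h.start, h.end) == (30, 30 + 24)
        assert h.label == "(AC)6-(AG)6"

    def test_small_gap_makes_c_star(self):
        rng = random.Random(22)
        left = _clean_dna(rng, 30, not_last="C")
        right = _clean_dna(rng, 30)
        seq = left + "AC" * 6 + "GTA" + "AG" * 6 + right
        hits = find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS)
        joined = join_compound(hits, max_gap=100)
        assert len(joined) == 1
        assert joined[0].type == "c*"
        assert joined[0].end - joined[0].start == 12 + 3 + 12

    def test_distant_runs_unchanged(self):
        rng = random.Random(23)
        left = _clean_dna(rng, 10, not_last="C")
        middle = _clean_dna(rng, 150, not_last="G")
        right = _clean_dna(rng, 10)
        seq = left + "AC" * 6 + middle + "AG" * 6 + right
        hits = find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS)
        assert len(hits) == 2
        joined = join_compound(hits, max_gap=100)
        assert [h.type for h in joined] == ["p2", "p2"]

    def test_matches_definition_oracle(self):
        rng = random.Random(7)
        for _ in range(100):
            seq = _plant(rng, n=260, max_runs=4)
            hits = find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS)
            joined = join_compound(hits, max_gap=40)
            expected = brute_join(
                [(h.unit, h.unit_len, h.repeats, h.start, h.end) for h in hits], 40
            )
            assert [(h.unit, h.type, h.start, h.end) for h in joined] == expected

    def test_span_conservation(self):
        """Compound flank fields still partition the sequence length."""
        rng = random.Random(24)
        seq = _clean_dna(rng, 30, not_last="C") + "AC" * 6 + "AG" * 6 + _clean_dna(rng, 30)
        (h,) = join_compound(find_perfect_ssrs(seq, DEFAULT_MIN_REPEATS), 100)
        assert h.left_flank_len == h.start
        assert h.right_flank_len == len(seq) - h.end


def _read(bases):
    return Read(id="x", bases=bases, quals=[40] * len(bases))


class TestFilterCandidates:
    def _seq220(self):
        rng = random.Random(0)
        left = _clean_dna(rng, 60, not_last="C")
        right = _clean_dna(rng, 144)
        seq = left + "AC" * 8 + right
        assert len(seq) == 220
        return seq

    def test_passes_with_sufficient_flanks(self):
        cfg = PipelineConfig(min_flank_len=50)
        seq = self._seq220()
        hits = find_perfect_ssrs(seq, cfg.min_repeats)
        decision = filter_candidates(_read(seq), hits, cfg)
        assert decision.passed
        assert decision.hit.unit == "AC"

    def test_rejected_when_flank_too_short(self):
        cfg = PipelineConfig(min_flank_len=75)
        seq = self._seq220()
        hits = find_perfect_ssrs(seq, cfg.min_repeats)
        decision = filter_candidates(_read(seq), hits, cfg)
        assert not decision.passed
        assert decision.reason == "no_ssr"

    def test_two_qualifying_hits_rejected_multi(self):
        rng = random.Random(1)
        seq = (
            _clean_dna(rng, 60, not_last="C")
            + "AC" * 8
            + _clean_dna(rng, 150, not_last="G")  # farther than the compound gap
            + "AG" * 7
            + _clean_dna(rng, 60)
        )
        cfg = PipelineConfig(min_flank_len=20)
        hits = join_compound(find_perfect_ssrs(seq, cfg.min_repeats), cfg.compound_max_gap)
        decision = filter_candidates(_read(seq), hits, cfg)
        assert decision.reason == "multi_ssr"

    def test_excluded_type_is_ignored(self):
        cfg = PipelineConfig(min_flank_len=20, excluded_ssr_types={"p2"})
        seq = self._seq220()
        hits = find_perfect_ssrs(seq, cfg.min_repeats)
        assert filter_candidates(_read(seq), hits, cfg).reason == "no_ssr"

    def test_min_flank_monotonicity(self):
        """Raising the flank requirement never lets more sequences pass."""
        rng = random.Random(17)
        seqs = [_plant(rng, n=280) for _ in range(120)]
        passed = []
        for mfl in (0, 25, 50, 75, 100):
            cfg = PipelineConfig(min_flank_len=mfl)
            n = 0
            for s in seqs:
                hits = join_compound(
                    find_perfect_ssrs(s, cfg.min_repeats), cfg.compound_max_gap
                )
                if filter_candidates(_read(s), hits, cfg).passed:
                    n += 1
            passed.append(n)
        assert passed == sorted(passed, reverse=True)
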