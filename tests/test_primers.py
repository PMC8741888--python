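"""Melting temperature, candidate enumeration, pairing and ranking."""

import random

import pytest

from ssrmarkers import (
    PipelineConfig,
    PrimerParams,
    enumerate_candidates,
    melting_temperature,
    pair_and_rank,
    render_records,
    validate_pairs,
)
from ssrmarkers.dna import gc_fraction, max_homopolymer, revcomp
from ssrmarkers.loci import Locus
from ssrmarkers.mining import SSRHit
from ssrmarkers.primers import _self_complementarity, design_for_locus

from _oracles import exhaustive_pair_ranking


def _rand_dna(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


def _rand_oligo(rng, n):
    while True:
        s = _rand_dna(rng, n)
        if s != revcomp(s):  # stay off the self-complementary special case
            return s


class TestMeltingTemperature:
    def test_agrees_with_reference_implementation(self):
        """Within 0.5 C of an independent unified nearest-neighbor
        implementation at 50 nM oligo / 50 mM monovalent."""
        from Bio.SeqUtils import MeltingTemp as mt

        rng = random.Random(0)
        for _ in range(60):
            s = _rand_oligo(rng, rng.randint(18, 27))
            ref = mt.Tm_NN(s, nn_table=mt.DNA_NN3, dnac1=25, dnac2=25, Na=50, saltcorr=5)
            assert abs(melting_temperature(s) - ref) <= 0.5

    def test_at_rich_melts_below_gc_rich(self):
        assert melting_temperature("AT" * 10) < melting_temperature("GC" * 10)

    def test_monotone_in_gc_stacks(self):
        tms = [melting_temperature("GC" * n) for n in range(6, 15)]
        assert tms == sorted(tms)

    @pytest.mark.parametrize("bad", ["ACGTACGT", "A" * 37, "ACGTACGTACGN"])
    def test_input_validation(self, bad):
        with pytest.raises(ValueError):
            melting_temperature(bad)


class TestEnumerate:
    def test_pure_a_template_has_no_candidates(self):
        assert (
            enumerate_candidates("A" * 80, (0, 80), "forward", PrimerParams()) == []
        )

    def test_matches_brute_force_predicates(self):
        """Candidate set equals a direct scan applying the same bounds."""
        rng = random.Random(1)
        params = PrimerParams()
        for _ in range(10):
            template = _rand_dna(rng, 60)
            got = {
                (c.start, c.length)
                for c in enumerate_candidates(template, (0, 60), "forward", params)
            }
            expected = set()
            for length in range(params.size_min, params.size_max + 1):
                for s in range(0, 60 - length + 1):
                    seq = template[s : s + length]
                    if not params.gc_min <= gc_fraction(seq) <= params.gc_max:
                        continue
                    if max_homopolymer(seq) > params.max_homopolymer:
                        continue
                    if _self_complementarity(seq) > params.max_self_comp:
                        continue
                    if not (
                        params.tm_min
                        <= melting_temperature(seq)
                        <= params.tm_max
                    ):
                        continue
                    expected.add((s, length))
            assert got == expected

    def test_reverse_candidates_are_reverse_complements(self):
        rng = random.Random(2)
        template = _rand_dna(rng, 80)
        for c in enumerate_candidates(template, (0, 80), "reverse", PrimerParams()):
            assert c.seq == revcomp(template[c.start : c.start + c.length])

    def test_avoid_primer_in_ssr_excludes_overlaps(self):
        rng = random.Random(3)
        template = _rand_dna(rng, 70) + "AC" * 10 + _rand_dna(rng, 70)
        span = (70, 90)
        for orientation in ("forward", "reverse"):
            for c in enumerate_candidates(
                template, (0, len(template)), orientation, PrimerParams(),
                ssr_span=span, avoid_primer_in_ssr=True,
            ):
                a, b = c.footprint
                assert b <= span[0] or a >= span[1]


def _mklocus(template, span, number=1):
    u = 2
    hit = SSRHit(
        unit=template[span[0] : span[0] + u],
        unit_len=u,
        repeats=(span[1] - span[0]) // u,
        start=span[0],
        end=span[1],
        type="p2",
        left_flank_len=span[0],
        right_flank_len=len(template) - span[1],
    )
    return Locus(
        locus_number=number,
        motif_unit=hit.unit,
        unit_len=u,
        allele_lengths=[len(template)],
        observed=4,
        range_min=len(template) - 6,
        range_max=len(template) + 6,
        potential=7,
        representative_seq=template,
        representative_hit=hit,
    )


class TestPairAndRank:
    def _candidates(self, seed=4, flank=90):
        rng = random.Random(seed)
        template = _rand_dna(rng, flank) + "AC" * 10 + _rand_dna(rng, flank)
        span = (flank, flank + 20)
        params = PrimerParams()
        fwd = enumerate_candidates(template, (0, len(template)), "forward", params)
        rev = enumerate_candidates(template, (0, len(template)), "reverse", params)
        return template, span, params, fwd, rev

    def test_order_matches_exhaustive_oracle(self):
        template, span, params, fwd, rev = self._candidates()
        got = pair_and_rank(fwd, rev, span, params, (100, 300), max_diff_tm=2.0)
        oracle = exhaustive_pair_ranking(fwd, rev, span, params, (100, 300), 2.0)
        assert len(got) == min(params.num_return, len(oracle))
        for pair, exp in zip(got, oracle):
            assert (pair.fwd.seq, pair.rev.seq) == (exp[3], exp[4])
            assert pair.penalty == pytest.approx(exp[0])

    def test_no_tm_compatible_pair_gives_empty(self):
        template, span, params, fwd, rev = self._candidates()
        got = pair_and_rank(fwd, rev, span, params, (100, 300), max_diff_tm=0.0)
        oracle = exhaustive_pair_ranking(fwd, rev, span, params, (100, 300), 0.0)
        assert (got == []) == (oracle == [])

    def test_single_feasible_combination_is_best(self):
        template, span, params, fwd, rev = self._candidates()
        all_pairs = pair_and_rank(fwd, rev, span, params, (100, 300), 2.0)
        assert all_pairs[0].is_best
        assert all(not p.is_best for p in all_pairs[1:])

    def test_widening_max_diff_tm_grows_feasible_set(self):
        template, span, params, fwd, rev = self._candidates()
        sizes = [
            len(exhaustive_pair_ranking(fwd, rev, span, params, (100, 300), d))
            for d in (0.1, 0.5, 1.0, 2.0, 5.0)
        ]
        assert sizes == sorted(sizes)

    def test_emitted_pairs_pass_validator(self):
        template, span, params, fwd, rev = self._candidates()
        pairs = pair_and_rank(fwd, rev, span, params, (100, 300), 0.5)
        assert validate_pairs(pairs, span, (100, 300), 0.5) == []


class TestRender:
    def test_ids_and_best_flag(self):
        rng = random.Random(8)
        template = _rand_dna(rng, 90) + "AC" * 10 + _rand_dna(rng, 90)
        locus = _mklocus(template, (90, 110), number=8)
        cfg = PipelineConfig(max_diff_tm=2.0)
        pairs = design_for_locus(locus, cfg)
        assert len(pairs) >= 2
        records = render_records(locus, pairs, "Mk")
        assert [r.id for r in records][:2] == ["Mk8-1", "Mk8-2"]
        assert [r.best_flag for r in records].count("|BEST|") == 1
        assert records[0].best_flag == "|BEST|"
        for r in records:
            assert r.alleles_observed == locus.observed
            assert r.alleles_potential == locus.potential
            assert r.motif == locus.representative_hit.label

    def test_zero_pairs_zero_records(self):
        locus = _mklocus("ACGT" * 60, (100, 120))
        assert render_records(locus, [], "X") == []
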