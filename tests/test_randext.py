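"""RandExt: Shannon diversity, divergence rule, filtering, grid scan."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from termflex.io import Genome, Read
from termflex.mapper import revcomp
from termflex.randext import (ExtensionGroup, RandExtParams, flank_diverges,
                              grid_scan, kmer_occurrences, run_randext,
                              randext_filter, shannon_index)


def _read(seq, id="r"):
    return Read(id=id, seq=seq)


class TestShannon:
    def test_single_unique_sequence_is_zero(self):
        assert shannon_index({"AAAA": 57}) == 0.0

    def test_uniform_four_is_ln4(self):
        counts = {s: 1 for s in ("AAAA", "CCCC", "GGGG", "TTTT")}
        assert shannon_index(counts) == pytest.approx(math.log(4), abs=1e-12)

    def test_skewed_distribution(self):
        # -(1/2 ln 1/2 + 1/4 ln 1/4 + 1/4 ln 1/4)
        h = shannon_index({"x": 2, "y": 1, "z": 1})
        assert h == pytest.approx(1.0397207708399179, abs=1e-12)

    def test_uniform_64_is_ln64(self):
        counts = {f"s{i}": 1 for i in range(64)}
        assert shannon_index(counts) == pytest.approx(math.log(64), abs=1e-12)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            shannon_index({})

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1,
                    max_size=30))
    def test_agrees_with_brute_force(self, counts):
        table = {f"s{i}": c for i, c in enumerate(counts)}
        total = sum(counts)
        expected = -sum((c / total) * math.log(c / total) for c in counts)
        assert shannon_index(table) == pytest.approx(expected, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=20), min_size=2,
                    max_size=20))
    def test_merging_two_uniques_never_increases_h(self, counts):
        table = {f"s{i}": c for i, c in enumerate(counts)}
        merged = dict(list(table.items())[:-2])
        a, b = list(table.items())[-2:]
        merged["ab"] = a[1] + b[1]
        assert shannon_index(merged) <= shannon_index(table) + 1e-12

    def test_uniform_is_maximal(self):
        uniform = {f"s{i}": 3 for i in range(10)}
        skewed = {f"s{i}": c for i, c in enumerate([21] + [1] * 9)}
        assert shannon_index(uniform) == pytest.approx(math.log(10), abs=1e-12)
        assert shannon_index(skewed) < math.log(10)


class TestFlankDiverges:
    @pytest.mark.parametrize("ext,cont,expected", [
        ("ACGT", "TGCA", True),    # L=4, 0 matches: complete divergence
        ("ACGT", "ACCA", False),   # L=4, 1 match
        ("ACGTAC", "ACGCCT", False),  # L=6, 3 matches > L-4
        ("AAAAAA", "AACCCC", True),   # L=6, 2 matches = L-4
    ])
    def test_rule(self, ext, cont, expected):
        assert flank_diverges(ext, cont) is expected

    def test_truncated_continuation_counts_missing_as_mismatch(self):
        # genome-end continuation of 2 bases: the 4 missing positions are
        # mismatches, so 2 positional matches = L-4 still diverges ...
        assert flank_diverges("ACGTAA", "AC") is True
        # ... while a truncated continuation cannot rescue extra matches
        assert flank_diverges("ACGT", "ACG") is False  # 3 matches > 0

    def test_continuation_longer_than_flank_errors(self):
        with pytest.raises(ValueError):
            flank_diverges("ACGT", "ACGTA")

    def test_exhaustive_l4_against_mismatch_oracle(self):
        import itertools
        for ext in itertools.product("ACGT", repeat=4):
            for cont in itertools.product("AC", repeat=4):
                e, c = "".join(ext), "".join(cont)
                matches = sum(a == b for a, b in zip(e, c))
                assert flank_diverges(e, c) is (matches == 0)


class TestKmerOccurrences:
    def test_both_strand_positions(self, tiny_genome):
        # GCGT at 1-based 3 on plus; its revcomp ACGC maps minus at 6
        assert kmer_occurrences("GCGT", tiny_genome) == [(3, "+")]
        assert kmer_occurrences("ACGC", tiny_genome) == [(6, "-")]


@pytest.fixture
def genome():
    from termflex.simulate import SimConfig, make_genome
    return make_genome(SimConfig(seed=3, genome_length=2000))


def _params(k=13, L=4):
    return RandExtParams(k=k, L=L)


class TestFilter:
    def test_fully_genomic_read_removed(self, genome):
        read = _read(genome.seq[100:117])  # 17 = 13 + 4
        assert randext_filter([read], genome, _params()) == []

    def test_read_with_foreign_kmer_removed(self, genome):
        seq = "A" * 13 + "CGTA"
        assert "A" * 13 not in genome.seq and "T" * 13 not in genome.seq
        assert randext_filter([_read(seq)], genome, _params()) == []

    def test_divergent_flank_qualifies(self, genome):
        kmer = genome.seq[100:113]
        cont = genome.seq[113:117]
        ext = "".join(next(b for b in "ACGT" if b != c) for c in cont)
        reads = [_read(kmer + ext)]
        out = run_randext(reads, genome, _params())
        assert (101, "+") in out
        assert out[(101, "+")].counts == {kmer + ext: 1}

    def test_adapter_remnant_trimmed_defensively(self, genome):
        from termflex.preprocess import DEFAULT_ADAPTER_PREFIX
        kmer = genome.seq[100:113]
        cont = genome.seq[113:117]
        ext = "".join(next(b for b in "ACGT" if b != c) for c in cont)
        reads = [_read(kmer + ext + DEFAULT_ADAPTER_PREFIX + "GG")]
        out = run_randext(reads, genome, _params())
        assert (101, "+") in out


class TestAttribution:
    def _two_locus_genome(self):
        # identical 13-mer planted at two loci with different continuations
        core = "ACGTACGTACGTT"
        filler1 = "GGGGCCCC"
        g = "TTTT" + core + "AAAA" + "CCGG" * 3 + core + "GGCC" + "T" * 8
        return Genome(id="two", seq=g), core

    def test_attributed_to_every_divergent_occurrence(self):
        g, core = self._two_locus_genome()
        read = _read(core + "TTTT")  # diverges from both continuations?
        occ = kmer_occurrences(core, g)
        assert len(occ) == 2
        out = run_randext([read], g, _params())
        # verify against the divergence rule occurrence by occurrence
        from termflex.randext import continuation_after
        expected = [o for o in occ
                    if flank_diverges("TTTT", continuation_after(g, *o, 13, 4))]
        assert sorted(out.keys()) == sorted(expected)
        if len(expected) == 2:
            assert all(grp.cross_contributed for grp in out.values())


class TestGridScan:
    def test_single_combination_equals_single_run(self, genome):
        kmer = genome.seq[100:113]
        cont = genome.seq[113:117]
        ext = "".join(next(b for b in "ACGT" if b != c) for c in cont)
        reads = [_read(kmer + ext, id=f"r{i}") for i in range(3)]
        profile = grid_scan(reads, genome, [13], [4])
        single = run_randext(reads, genome, _params())
        assert set(profile.positions) == set(single)
        key = (101, "+")
        assert profile.positions[key].max_H == pytest.approx(single[key].H)
        assert (profile.positions[key].best_k, profile.positions[key].best_L) == (13, 4)

    def test_flagging_above_threshold(self):
        grp = ExtensionGroup(1, "+", 13, 4,
                             counts={f"s{i}": 1 for i in range(16)})
        assert grp.H == pytest.approx(math.log(16))
        assert grp.H > 2.0

    def test_no_qualifying_reads_gives_empty_profile(self, genome):
        profile = grid_scan([], genome, [13], [4])
        assert profile.positions == {}

    def test_empty_grid_errors(self, genome):
        with pytest.raises(ValueError):
            grid_scan([], genome, [], [])

    def test_raising_threshold_never_enlarges_flagged_set(self, genome, rng):
        kmer = genome.seq[200:213]
        reads = []
        for i in range(60):
            ext = "".join(rng.choice(list("ACGT"), size=4))
            reads.append(_read(kmer + ext, id=f"r{i}"))
        flagged_sets = []
        for thr in (1.0, 2.0, 3.0):
            prof = grid_scan(reads, genome, [13], [4], h_threshold=thr)
            flagged_sets.append({(p.genome_pos, p.strand)
                                 for p in prof.flagged()})
        assert flagged_sets[2] <= flagged_sets[1] <= flagged_sets[0]
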