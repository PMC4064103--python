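import random

import pytest

from hierfold import (
    RnaSequence,
    SecondaryStructure,
    StructureError,
    crosses,
    find_bands,
    is_density_two,
    is_pseudoknot_free,
    layers,
    parse_structure,
    write_structure,
)
from hierfold.fixtures import generate_fixtures
from hierfold.structures import BasePair, read_bpseq, read_ct


class TestRnaSequence:
    def test_normalises_lowercase(self):
        assert RnaSequence("acgu").bases == "ACGU"

    @pytest.mark.parametrize("bad", ["ACGT", "ACGN", "", "AC GU"])
    def test_rejects_invalid(self, bad):
        with pytest.raises(StructureError):
            RnaSequence(bad)

    def test_canonical_pairs(self):
        seq = RnaSequence("GUAC")
        assert seq.can_pair(1, 4)  # G-C
        assert seq.can_pair(1, 2)  # G-U wobble
        assert seq.can_pair(2, 3)  # U-A
        assert not seq.can_pair(3, 4)  # A-C is not canonical

    def test_one_partner_invariant(self):
        with pytest.raises(StructureError):
            SecondaryStructure([(1, 5), (1, 7)])
        with pytest.raises(StructureError):
            SecondaryStructure([(2, 5), (5, 9)])


class TestCrossing:
    def test_crossing_definition(self):
        assert crosses(BasePair(1, 10), BasePair(5, 15))
        assert not crosses(BasePair(2, 8), BasePair(3, 7))  # nested
        assert not crosses(BasePair(2, 8), BasePair(9, 12))  # disjoint

    def test_symmetric_irreflexive(self):
        rng = random.Random(0)
        for _ in range(200):
            p = BasePair.make(rng.randint(1, 20), rng.randint(21, 40))
            q = BasePair.make(rng.randint(1, 20), rng.randint(21, 40))
            assert crosses(p, q) == crosses(q, p)
            assert not crosses(p, p)

    def test_pk_free_matches_all_pairs_check(self):
        rng = random.Random(1)
        for _ in range(100):
            pairs = []
            used = set()
            for _ in range(rng.randint(0, 8)):
                i, j = sorted(rng.sample(range(1, 40), 2))
                if i != j and not {i, j} & used:
                    used |= {i, j}
                    pairs.append((i, j))
            s = SecondaryStructure(pairs)
            brute = not any(
                crosses(p, q)
                for a, p in enumerate(s.pairs)
                for q in s.pairs[a + 1 :]
            )
            assert is_pseudoknot_free(s) == brute


class TestDensityTwo:
    def test_pk_free_is_density_two(self):
        s = SecondaryStructure([(1, 7), (2, 6)])
        assert is_pseudoknot_free(s)
        assert is_density_two(s)

    def test_h_type_is_density_two(self):
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        assert not is_pseudoknot_free(s)
        assert is_density_two(s)

    def test_three_mutually_crossing_rejected(self):
        s = SecondaryStructure([(1, 30), (10, 40), (20, 50)])
        assert not is_density_two(s)
        with pytest.raises(StructureError):
            layers(s)

    def test_layers_are_pk_free(self):
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14), (20, 30)])
        a, b = layers(s)
        assert is_pseudoknot_free(a) and is_pseudoknot_free(b)
        assert a.union(b) == s


class TestBands:
    def test_pk_free_has_no_bands(self):
        assert find_bands(SecondaryStructure([(1, 7), (2, 6)])) == []

    def test_h_type_two_bands(self):
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        bands = find_bands(s)
        assert len(bands) == 2
        assert {tuple(b.outer) for b in bands} == {(1, 10), (5, 15)}

    def test_kissing_chain_bands_partition_crossing_pairs(self):
        # three stems, middle crossing both: one band per stem
        s = SecondaryStructure(
            [(1, 14), (2, 13), (6, 24), (7, 23), (17, 30), (18, 29)]
        )
        bands = find_bands(s)
        assert len(bands) == 3
        band_pairs = [p for b in bands for p in b.pairs]
        assert sorted(band_pairs) == sorted(s.pairs)  # disjoint partition
        for band in bands:
            (lo1, hi1), (lo2, hi2) = band.intervals
            assert lo1 <= hi1 < lo2 <= hi2

    def test_band_error_outside_class(self):
        with pytest.raises(StructureError):
            find_bands(SecondaryStructure([(1, 30), (10, 40), (20, 50)]))


class TestNotationIO:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("((...))", {(1, 7), (2, 6)}),
            (".......", set()),
            ("((..[[..))..]]", {(1, 10), (2, 9), (5, 14), (6, 13)}),
        ],
    )
    def test_parse(self, text, expected):
        assert set(map(tuple, parse_structure(text, len(text)).pairs)) == expected

    def test_parse_errors(self):
        with pytest.raises(StructureError, match="position 3"):
            parse_structure("..)", 3)
        with pytest.raises(StructureError, match="never closed"):
            parse_structure("(..", 3)
        with pytest.raises(StructureError, match="length"):
            parse_structure("(...)", 7)

    def test_write_simple(self):
        assert write_structure(SecondaryStructure([(1, 7), (2, 6)]), 7) == "((...))"
        assert write_structure(SecondaryStructure(), 4) == "...."

    def test_crossing_pairs_get_distinct_families(self):
        s = SecondaryStructure([(1, 10), (2, 9), (5, 15), (6, 14)])
        text = write_structure(s, 16)
        assert text == "((..[[..))...]]."

    def test_round_trip_random_density2(self):
        rng = random.Random(7)
        fixtures = generate_fixtures(60, (20, 60), rng=rng)
        count = 0
        for f in fixtures:
            n = f.sequence.n
            assert parse_structure(write_structure(f.reference, n), n) == f.reference
            count += 1
        # plus random pseudoknot-free structures
        for _ in range(200):
            pairs = []
            used = set()
            stack = []
            for pos in range(1, rng.randint(10, 60)):
                r = rng.random()
                if r < 0.3:
                    stack.append(pos)
                elif r < 0.5 and stack:
                    pairs.append((stack.pop(), pos))
            s = SecondaryStructure(pairs)
            n = max([60] + [p[1] for p in pairs])
            assert parse_structure(write_structure(s, n), n) == s
            count += 1
        assert count >= 260


class TestFileFormats:
    def test_ct_round_trip(self, tmp_path):
        path = tmp_path / "x.ct"
        path.write_text(
            "5 energy = 0\n"
            "1 G 0 2 5 1\n2 A 1 3 0 2\n3 A 2 4 0 3\n4 A 3 5 0 4\n5 C 4 0 1 5\n"
        )
        seq, s = read_ct(str(path))
        assert seq.bases == "GAAAC"
        assert set(map(tuple, s.pairs)) == {(1, 5)}

    def test_bpseq(self, tmp_path):
        path = tmp_path / "x.bpseq"
        path.write_text("1 G 5\n2 A 0\n3 A 0\n4 A 0\n5 C 1\n")
        seq, s = read_bpseq(str(path))
        assert seq.bases == "GAAAC"
        assert set(map(tuple, s.pairs)) == {(1, 5)}

    def test_ct_malformed(self, tmp_path):
        path = tmp_path / "bad.ct"
        path.write_text("2\n1 G 0 2 2 1\n")
        with pytest.raises(StructureError):
            read_ct(str(path))


class TestProperties:
    """Invariant checks over generated structures (derandomised)."""

    from hypothesis import given, settings, strategies as st_

    pair_lists = st_.lists(
        st_.tuples(st_.integers(1, 30), st_.integers(31, 60)), max_size=10
    )

    @given(pairs=pair_lists)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_each_index_has_at_most_one_partner(self, pairs):
        try:
            s = SecondaryStructure(pairs)
        except StructureError:
            return  # duplicate-endpoint inputs are correctly rejected
        seen = {}
        for p in s.pairs:
            for x in (p.i, p.j):
                assert seen.setdefault(x, p) == p

    @given(pairs=pair_lists)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_write_parse_round_trip(self, pairs):
        try:
            s = SecondaryStructure(pairs)
            text = write_structure(s, 60)
        except StructureError:
            return  # needs more bracket families than available, or invalid
        assert parse_structure(text, 60) == s

    @given(pairs=pair_lists)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_pk_free_implies_density_two(self, pairs):
        try:
            s = SecondaryStructure(pairs)
        except StructureError:
            return
        if is_pseudoknot_free(s):
            assert is_density_two(s)


def test_non_canonical_rejected_strict_and_warned_permissive():
    seq = RnaSequence("GGAAACC")
    s = SecondaryStructure([(1, 6), (2, 3)])  # (2,3) G-A is non-canonical
    with pytest.raises(StructureError):
        s.check_canonical(seq)
    with pytest.warns(UserWarning):
        s.check_canonical(seq, permissive=True)
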