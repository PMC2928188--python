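"""GENEPOP round trips, allele tallies and syntenic-pair enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mscan.genotype_io import (
    GenepopParseError,
    GenotypeDataset,
    LocusInfo,
    MarkerMap,
    allele_counts,
    enumerate_syntenic_pairs,
    read_genepop,
    read_marker_map,
    write_genepop,
    write_marker_map,
)


def _write(tmp_path, text):
    p = tmp_path / "data.gen"
    p.write_text(text)
    return p


class TestReadGenepop:
    def test_two_digit_encoding(self, tmp_path):
        p = _write(tmp_path, "title\nlocA\nlocB\nPOP\nind1, 0101 0203\n")
        ds = read_genepop(p)
        assert ds.loci == ["locA", "locB"]
        assert tuple(ds.genotypes[0][0, 0]) == (1, 1)
        assert tuple(ds.genotypes[0][0, 1]) == (2, 3)

    def test_missing_token(self, tmp_path):
        p = _write(tmp_path, "t\nA\nPOP\ni1, 0000\ni2, 0102\n")
        ds = read_genepop(p)
        assert tuple(ds.genotypes[0][0, 0]) == (0, 0)

    def test_comma_separated_loci_and_pop_case(self, tmp_path):
        p = _write(tmp_path, "t\nA, B\npop\ni1, 001002 003003\nPop\nj1, 001001 002002\n")
        ds = read_genepop(p)
        assert ds.loci == ["A", "B"]
        assert ds.n_populations == 2
        assert tuple(ds.genotypes[0][0, 0]) == (1, 2)

    def test_wrong_locus_count_errors(self, tmp_path):
        p = _write(tmp_path, "t\nA\nB\nPOP\ni1, 0101\n")
        with pytest.raises(GenepopParseError, match="expected 2"):
            read_genepop(p)

    def test_malformed_token_names_line(self, tmp_path):
        p = _write(tmp_path, "t\nA\nPOP\ni1, 01x2\n")
        with pytest.raises(GenepopParseError, match="line 4"):
            read_genepop(p)

    def test_no_populations_errors(self, tmp_path):
        p = _write(tmp_path, "t\nA\n")
        with pytest.raises(GenepopParseError, match="POP"):
            read_genepop(p)


class TestWriteGenepop:
    def test_width_rule_and_overflow(self, tmp_path):
        g = np.array([[[999, 1]]])
        ds = GenotypeDataset(populations=["p"], loci=["A"], genotypes=[g])
        out = tmp_path / "o.gen"
        write_genepop(ds, out, digits=3)
        assert "999001" in out.read_text()
        with pytest.raises(ValueError, match="not representable"):
            write_genepop(ds, out, digits=2)

    def test_empty_population_roundtrip(self, tmp_path):
        ds = GenotypeDataset(
            populations=["p1", "p2"], loci=["A"],
            genotypes=[np.array([[[1, 2]]]), np.empty((0, 1, 2), dtype=int)])
        out = tmp_path / "o.gen"
        write_genepop(ds, out)
        back = read_genepop(out)
        assert back.n_individuals == [1, 0]


@st.composite
def datasets(draw):
    n_loci = draw(st.integers(1, 4))
    n_pops = draw(st.integers(1, 3))
    genotypes = []
    for _ in range(n_pops):
        n = draw(st.integers(0, 5))
        g = draw(st.lists(
            st.lists(st.tuples(st.integers(0, 99), st.integers(0, 99)),
                     min_size=n_loci, max_size=n_loci),
            min_size=n, max_size=n))
        arr = np.array(g, dtype=np.int64).reshape(n, n_loci, 2)
        # GENEPOP ties both copies of a missing genotype together
        miss = (arr == 0).any(axis=2)
        arr[miss] = 0
        genotypes.append(arr)
    return GenotypeDataset(
        populations=[f"p{i}" for i in range(n_pops)],
        loci=[f"L{i}" for i in range(n_loci)],
        genotypes=genotypes)


@given(datasets())
@settings(max_examples=30, deadline=None)
def test_roundtrip_identity(tmp_path_factory, ds):
    out = tmp_path_factory.mktemp("gp") / "rt.gen"
    write_genepop(ds, out, digits=2)
    back = read_genepop(out)
    assert back.loci == ds.loci
    assert [g.shape for g in back.genotypes] == [g.shape for g in ds.genotypes]
    for a, b in zip(back.genotypes, ds.genotypes):
        assert np.array_equal(np.sort(a, 2), np.sort(b, 2))


class TestAlleleCounts:
    def test_direct_tally(self):
        g = np.array([[[1, 1]], [[1, 2]], [[0, 0]]])
        ds = GenotypeDataset(populations=["p"], loci=["A"], genotypes=[g])
        tab = allele_counts(ds, "A")
        assert tab.counts[0] == {1: 3, 2: 1}
        assert tab.n_pop == [4]

    def test_all_missing(self):
        g = np.zeros((3, 1, 2), dtype=int)
        ds = GenotypeDataset(populations=["p"], loci=["A"], genotypes=[g])
        tab = allele_counts(ds, "A")
        assert tab.counts[0] == {}
        assert tab.n_pop == [0]

    def test_unknown_locus(self):
        ds = GenotypeDataset(populations=["p"], loci=["A"],
                             genotypes=[np.ones((1, 1, 2), dtype=int)])
        with pytest.raises(KeyError):
            allele_counts(ds, "missing")

    def test_matches_naive_tally_and_pop_reorder(self, neutral_small):
        ds = neutral_small
        for loc in ds.loci[:5]:
            tab = allele_counts(ds, loc)
            li = ds.locus_index(loc)
            for p, g in enumerate(ds.genotypes):
                naive = {}
                for ind in g[:, li, :]:
                    for a in ind:
                        if a != 0:
                            naive[int(a)] = naive.get(int(a), 0) + 1
                assert tab.counts[p] == naive
            total = sum(tab.n_pop)
            rev = ds.subset_populations(list(reversed(ds.populations)))
            assert sum(allele_counts(rev, loc).n_pop) == total


class TestMarkerMap:
    def test_interval_normalized(self):
        li = LocusInfo("X", "1", 200, 100)
        assert (li.start_bp, li.end_bp) == (100, 200)
        assert li.midpoint == 150

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            MarkerMap([LocusInfo("X"), LocusInfo("X")])

    def test_tsv_roundtrip(self, tmp_path):
        mm = MarkerMap([LocusInfo("A", "1", 10, 20), LocusInfo("B", "NA")])
        p = tmp_path / "map.tsv"
        write_marker_map(mm, p)
        back = read_marker_map(p)
        assert back.names == ["A", "B"]
        assert back["B"].start_bp is None


class TestSyntenicPairs:
    def test_counts_match_brute_force(self, study_fixture):
        _, mmap = study_fixture
        pairs = enumerate_syntenic_pairs(mmap)
        by_chrom = {}
        for l in mmap:
            if l.chromosome != "NA":
                by_chrom.setdefault(l.chromosome, []).append(l.name)
        brute = sum(
            len(list(itertools.combinations(v, 2))) for v in by_chrom.values())
        assert len(pairs) == brute

    def test_reference_map_pair_counts(self, study_fixture):
        _, mmap = study_fixture
        pairs = enumerate_syntenic_pairs(mmap)
        assert sum(p[2] == "1" for p in pairs) == 21
        assert sum(p[2] == "20" for p in pairs) == 120

    def test_single_locus_chromosome(self):
        mm = MarkerMap([LocusInfo("A", "5", 1, 2), LocusInfo("B", "NA")])
        assert enumerate_syntenic_pairs(mm) == []
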