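import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tifa import genome_io
from tifa.genome_io import (
    GeneRecord, InsertionRecord, assign_sites_to_genes, canonical_motif,
    combine_samples, enumerate_motif_classes, filter_insertions,
    find_ta_sites, fractional_position, read_genome, revcomp,
)


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


class TestReadGenome:
    def test_identity(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("chr circular", "ACTAGT")])
        seq, circular = read_genome(p)
        assert seq == "ACTAGT" and circular

    def test_lowercase_uppercased_and_linear(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("chr", "actagt")])
        seq, circular = read_genome(p)
        assert seq == "ACTAGT" and not circular

    def test_multiple_records_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        write_fasta(p, [("a", "ACGT"), ("b", "ACGT")])
        with pytest.raises(ValueError, match="record"):
            read_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_genome(p)


class TestFindTASites:
    def test_single_site_with_context(self):
        sites = find_ta_sites("GGTACC", circular=False)
        assert len(sites) == 1
        assert sites[0].position == 2 and sites[0].context6 == "GGTACC"

    def test_overlapping_occurrences(self):
        sites = find_ta_sites("TATATA", circular=False)
        assert [s.position for s in sites] == [0, 2, 4]
        # edge sites of a linear genome have N-padded context -> excluded
        assert sites[0].excluded and sites[0].exclude_reason == "context"
        assert not sites[1].excluded

    def test_circular_context_wraps(self):
        sites = find_ta_sites("TAGGGG", circular=True)
        assert len(sites) == 1
        assert sites[0].position == 0 and sites[0].context6 == "GGTAGG"
        assert not sites[0].excluded

    @given(st.text(alphabet="ACGT", min_size=2, max_size=300))
    def test_count_matches_regex_oracle(self, seq):
        expected = len(re.findall("(?=TA)", seq))
        assert len(find_ta_sites(seq, circular=False)) == expected


class TestCanonicalMotif:
    @pytest.mark.parametrize("palindrome", ["GTTAAC", "AATATT"])
    def test_palindromes_map_to_themselves(self, palindrome):
        assert canonical_motif(palindrome) == palindrome

    def test_strand_pair_shares_class(self):
        assert canonical_motif("TATATG") == canonical_motif("CATATA")
        assert canonical_motif("TATATG") == "CATATA"  # lexicographic min

    def test_non_ta_center_rejected(self):
        with pytest.raises(ValueError):
            canonical_motif("GGCCGG")

    def test_partition_of_all_contexts(self):
        """Every TA-centred 6-mer maps to exactly one of 136 classes."""
        import itertools

        classes = set(enumerate_motif_classes())
        assert len(classes) == 136
        palindromic = [c for c in classes if revcomp(c) == c]
        assert len(palindromic) == 16
        for a, b, c, d in itertools.product("ACGT", repeat=4):
            ctx = a + b + "TA" + c + d
            m = canonical_motif(ctx)
            assert m in classes
            assert canonical_motif(revcomp(ctx)) == m
            assert canonical_motif(m) == m  # idempotent


class TestAssignSites:
    def make(self, seq, genes, circular=True):
        sites = find_ta_sites(seq, circular)
        assign_sites_to_genes(genes, sites, len(seq))
        return sites

    def test_overlap_sites_excluded(self):
        seq = "G" * 20 + "TA" + "G" * 78  # site at 20
        genes = [GeneRecord("a", 10, 30, "+"), GeneRecord("b", 25, 60, "+"),
                 GeneRecord("c", 15, 24, "+")]
        sites = self.make(seq, genes)
        assert sites[0].excluded and sites[0].exclude_reason == "overlap"
        assert all(20 not in g.core_ta_sites for g in genes)

    def test_terminal_two_percent_trimmed(self):
        # 100-nt plus-strand gene: a site at fractional position 0.99 is
        # non-core, one at 0.50 is core
        seq = "G" * 50 + "TA" + "G" * 47 + "TAG"
        genes = [GeneRecord("a", 0, 100, "+")]
        sites = self.make(seq, genes, circular=False)
        positions = {s.position: i for i, s in enumerate(sites)}
        assert positions[50] in genes[0].core_ta_sites
        assert positions[99] in genes[0].ta_sites
        assert positions[99] not in genes[0].core_ta_sites

    def test_minus_strand_trims_low_coordinates(self):
        seq = "TA" + "G" * 96 + "TA"
        genes = [GeneRecord("a", 0, 100, "-")]
        sites = self.make(seq, genes, circular=False)
        by_pos = {sites[i].position: i for i in genes[0].ta_sites}
        # genomic start = 3' end on the minus strand
        assert by_pos[0] not in genes[0].core_ta_sites
        assert by_pos[98] in genes[0].core_ta_sites

    def test_origin_wrapping_gene(self):
        seq = "GGTAGG" + "C" * 88 + "GGGTAG"  # sites at 2 and 91+? -> 2, 92
        genes = [GeneRecord("w", 90, 10, "+")]  # wraps the origin
        sites = self.make(seq, genes)
        member_pos = {sites[i].position for i in genes[0].ta_sites}
        assert 2 in member_pos
        assert fractional_position(genes[0], 2, len(seq)) == pytest.approx(
            (100 - 90 + 2) / 20)


class TestFilterAndCombine:
    def setup_method(self):
        self.seq = "GGTACCGGGGTAGGGGGGGG"  # TA sites at 2 and 10
        self.sites = find_ta_sites(self.seq, circular=False)

    def rec(self, pos, unique=True, reads=(10, 0, 0, 0)):
        return InsertionRecord(pos, unique, np.array(reads))

    def test_discard_reasons(self):
        records = [
            self.rec(2),                           # retained
            self.rec(10, reads=(4, 1, 1, 1)),      # low count (7 total)
            self.rec(5),                           # non-TA
            self.rec(2, unique=False),             # non-unique
        ]
        retained, report = filter_insertions(records, self.sites, self.seq)
        assert report == {"input": 4, "retained": 1, "non_unique": 1,
                          "non_ta": 1, "low_count": 1}
        assert report["input"] - report["retained"] == sum(
            report[k] for k in ("non_unique", "non_ta", "low_count"))

    def test_minus_strand_position_collapses(self):
        # a record at the A of the TA maps to the same site
        retained, _ = filter_insertions([self.rec(3)], self.sites, self.seq)
        assert retained[0][0] == 0
        assert self.sites[retained[0][0]].position == 2

    def test_position_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            filter_insertions([self.rec(99)], self.sites, self.seq)

    def test_combine_is_union_across_samples(self):
        records = [
            InsertionRecord(2, True, np.array([0, 0, 10, 0])),  # sample 3 only
            InsertionRecord(10, True, np.array([10, 0, 0, 0])),
        ]
        retained, _ = filter_insertions(records, self.sites, self.seq)
        n = combine_samples(retained, self.sites)
        assert n == 2
        assert self.sites[0].inserted and self.sites[1].inserted

    def test_disjoint_sample_sets_add(self):
        seq = ("GTA" * 15) + "GGGGG"  # 15 TA sites
        sites = find_ta_sites(seq, circular=False)
        recs = [InsertionRecord(1 + 3 * i, True,
                                np.array([10, 0, 0, 0]) if i < 10
                                else np.array([0, 10, 0, 0]))
                for i in range(15)]
        retained, _ = filter_insertions(recs, sites, seq)
        assert combine_samples(retained, sites) == 15

    def test_filtering_idempotent(self):
        records = [self.rec(2), self.rec(10, reads=(4, 1, 1, 1)), self.rec(5)]
        retained, _ = filter_insertions(records, self.sites, self.seq)
        again, report2 = filter_insertions([r for _, r in retained],
                                           self.sites, self.seq)
        assert [i for i, _ in again] == [i for i, _ in retained]
        assert report2["retained"] == report2["input"]


def test_planted_non_ta_fraction_recovered(small_library):
    """The filter's non-TA discard fraction matches the generator's 5%."""
    _, records, truth, ds = small_library
    frac = ds.filter_report["non_ta"] / ds.filter_report["input"]
    assert truth["non_ta_rate"] == 0.05
    assert 0.03 < frac < 0.08


def test_roundtrip_io(tmp_path, small_library):
    art, records, _, _ = small_library
    genome_io.write_genome(tmp_path / "g.fa", art.seq, circular=True)
    seq, circ = genome_io.read_genome(tmp_path / "g.fa")
    assert seq == art.seq and circ

    genome_io.write_genes(tmp_path / "genes.tsv", art.genes)
    genes = genome_io.read_genes(tmp_path / "genes.tsv")
    assert [(g.locus_id, g.start, g.end, g.strand) for g in genes] == \
           [(g.locus_id, g.start, g.end, g.strand) for g in art.genes]

    genome_io.write_insertions(tmp_path / "ins.tsv", records[:50])
    back = genome_io.read_insertions(tmp_path / "ins.tsv")
    assert [(r.position, r.unique, r.read_counts.tolist()) for r in back] == \
           [(r.position, r.unique, r.read_counts.tolist()) for r in records[:50]]
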