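"""Genome container, context classification, and functional regions."""

import gzip

import numpy as np
import pytest
from hypothesis import given, strategies as st

import windmr as w
from windmr.genome import FastaFormatError, _subtract

H = set("ACT")  # the non-G bases


def brute_force_context(trinuc: str) -> str | None:
    """Definitional classifier from a plus-strand 3-mer starting with C."""
    if trinuc[0] != "C":
        return None
    if trinuc[1] == "G":
        return "CG"
    if trinuc[1] in H and trinuc[2] == "G":
        return "CHG"
    if trinuc[1] in H and trinuc[2] in H:
        return "CHH"
    return None  # N involved


class TestLoadFasta:
    def test_case_normalized_and_lengths(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nac\ngt\n")
        g = w.load_fasta(p)
        assert g.chrom_seq["chr1"] == "ACGT"
        assert g.chrom_len["chr1"] == 4

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "g.fa.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(">c\nACGTN\n")
        assert w.load_fasta(p).chrom_seq["c"] == "ACGTN"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(FastaFormatError):
            w.load_fasta(p)

    def test_duplicate_records_error(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(FastaFormatError, match="duplicate"):
            w.load_fasta(p)

    def test_bad_alphabet_errors(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">a\nACXT\n")
        with pytest.raises(FastaFormatError, match="non-nucleotide"):
            w.load_fasta(p)

    def test_roundtrip(self, tmp_path, tiny_genome):
        p = tmp_path / "rt.fa"
        w.write_fasta(tiny_genome, p, width=7)
        back = w.load_fasta(p)
        assert back.chrom_seq == tiny_genome.chrom_seq
        assert back.chrom_names == tiny_genome.chrom_names


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", "CG"),
            ("CAG", 0, "+", "CHG"),
            ("CCGG", 3, "-", "CHG"),
            ("CCTA", 1, "+", "CHH"),
            ("CG", 0, "+", "CG"),  # CG needs only one downstream base
            ("CG", 1, "-", "CG"),
            ("CAN", 0, "+", None),  # N in context
            ("CA", 0, "+", None),  # runs off the chromosome
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        g = w.GenomeSequence({"c": seq})
        assert w.classify_context(g, "c", pos, strand) == expected

    def test_not_cytosine_errors(self):
        g = w.GenomeSequence({"c": "ACGT"})
        with pytest.raises(ValueError, match="not C"):
            w.classify_context(g, "c", 0, "+")
        with pytest.raises(ValueError):
            w.classify_context(g, "c", 1, "-")  # ref C, no cytosine on minus

    def test_agrees_with_brute_force_table_both_strands(self):
        """All 64 trinucleotides, classified on + directly and on − via RC."""
        comp = str.maketrans("ACGT", "TGCA")
        for b1 in "ACGT":
            for b2 in "ACGT":
                for b3 in "ACGT":
                    tri = b1 + b2 + b3
                    if tri[0] != "C":
                        continue
                    expected = brute_force_context(tri)
                    # plus strand: pad so the 3-mer starts at pos 1
                    g = w.GenomeSequence({"c": "A" + tri + "A"})
                    assert w.classify_context(g, "c", 1, "+") == expected, tri
                    # minus strand: the same 3-mer embedded as its reverse
                    # complement; its cytosine becomes the G at position 3
                    rc = tri.translate(comp)[::-1]
                    g2 = w.GenomeSequence({"c": "A" + rc + "A"})
                    assert w.classify_context(g2, "c", 3, "-") == expected, tri


class TestEnumerateCytosines:
    def test_cg_dinucleotide_both_strands(self):
        g = w.GenomeSequence({"c": "CG"})
        df = w.enumerate_cytosines(g)
        assert list(map(tuple, df[["pos", "strand", "context"]].to_numpy())) == [
            (0, "+", "CG"),
            (1, "-", "CG"),
        ]

    def test_no_cytosines(self):
        assert len(w.enumerate_cytosines(w.GenomeSequence({"c": "AAAA"}))) == 0

    def test_n_adjacent_dropped(self):
        assert len(w.enumerate_cytosines(w.GenomeSequence({"c": "CN"}))) == 0

    def test_agrees_with_scalar_classifier(self, tiny_genome):
        df = w.enumerate_cytosines(tiny_genome)
        seen = set()
        for row in df.itertuples(index=False):
            key = (row.chrom, row.pos, row.strand)
            assert key not in seen  # each site exactly once
            seen.add(key)
            assert w.classify_context(tiny_genome, row.chrom, row.pos, row.strand) == row.context
        # and nothing classifiable is missing
        for chrom in tiny_genome.chrom_names:
            seq = tiny_genome.chrom_seq[chrom]
            for pos, base in enumerate(seq):
                for strand, ref in (("+", "C"), ("-", "G")):
                    if base == ref:
                        ctx = w.classify_context(tiny_genome, chrom, pos, strand)
                        assert ((chrom, pos, strand) in seen) == (ctx is not None)

    @given(st.text(alphabet="ACGT", min_size=2, max_size=300))
    def test_cg_palindromy(self, seq):
        """Without N, CG sites pair across strands: equal counts per strand."""
        df = w.enumerate_cytosines(w.GenomeSequence({"c": seq}))
        cg = df[df["context"] == "CG"]
        assert (cg["strand"] == "+").sum() == (cg["strand"] == "-").sum()

    def test_coordinate_order(self, tiny_genome):
        df = w.enumerate_cytosines(tiny_genome)
        for _, grp in df.groupby("chrom", observed=True):
            assert grp["pos"].is_monotonic_increasing


def _gene(chrom="chr1", start=5000, end=8000, strand="+"):
    body = w.GenomicInterval(chrom, start, end, strand)
    return w.GeneModel("g1", body, exons=[body])


class TestFunctionalRegions:
    def test_plus_strand_promoter(self):
        regions = dict(w.build_functional_regions(_gene(strand="+"), 2000))
        assert (regions["promoter"].start, regions["promoter"].end) == (3000, 5000)

    def test_minus_strand_promoter_reflected(self):
        regions = dict(w.build_functional_regions(_gene(strand="-"), 2000, chrom_len=20000))
        assert (regions["promoter"].start, regions["promoter"].end) == (8000, 10000)

    def test_promoter_clipped_at_chromosome_start(self):
        regions = dict(w.build_functional_regions(_gene(start=500, end=2500), 2000))
        assert (regions["promoter"].start, regions["promoter"].end) == (0, 500)

    def test_regions_disjoint_and_cover_promoter_and_body(self, small_sim):
        genome = small_sim["genome"]
        for gene in small_sim["genes"]:
            regions = w.build_functional_regions(gene, 2000, genome.chrom_len[gene.body.chrom])
            covered = np.zeros(genome.chrom_len[gene.body.chrom], dtype=int)
            for _, iv in regions:
                covered[iv.start : iv.end] += 1
            assert covered.max() <= 1, f"{gene.gene_id}: overlapping functional regions"
            prom = dict(regions)["promoter"]
            body = gene.body
            expected = np.zeros_like(covered)
            expected[prom.start : prom.end] = 1
            expected[body.start : body.end] = 1
            assert np.array_equal(covered > 0, expected > 0)

    def test_interval_subtraction(self):
        iv = w.GenomicInterval("c", 0, 100)
        cuts = [w.GenomicInterval("c", 10, 20), w.GenomicInterval("c", 50, 100)]
        out = [(p.start, p.end) for p in _subtract(iv, cuts)]
        assert out == [(0, 10), (20, 50)]


class TestGff3Roundtrip:
    def test_genes_and_tes_survive(self, small_sim, tmp_path):
        path = tmp_path / "ann.gff3"
        w.write_gff3(small_sim["genes"], small_sim["tes"], path)
        genes, tes = w.read_gff3(path)
        assert len(genes) == len(small_sim["genes"])
        assert len(tes) == len(small_sim["tes"])
        orig = {g.gene_id: g for g in small_sim["genes"]}
        for g in genes:
            o = orig[g.gene_id]
            assert (g.body.start, g.body.end, g.body.strand) == (
                o.body.start, o.body.end, o.body.strand)
            assert [(e.start, e.end) for e in g.exons] == [(e.start, e.end) for e in o.exons]
            assert [(u.start, u.end) for u in g.utr5] == [(u.start, u.end) for u in o.utr5]
        orig_te = {t.te_id: t for t in small_sim["tes"]}
        for t in tes:
            o = orig_te[t.te_id]
            assert (t.location.start, t.location.end, t.family) == (
                o.location.start, o.location.end, o.family)
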