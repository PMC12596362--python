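"""Genome/annotation I/O, feature extraction and windowed-track behaviour."""

import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genokit import genome_io


DNA = st.text(alphabet="ACGTacgt", min_size=1, max_size=200)


class TestLoadGenome:
    def test_lengths_and_region(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"chr1": "ACGTACGT" * 5}))
        assert g.lengths == {"chr1": 40}
        assert g.region("chr1", 0, 5) == "ACGTA"

    def test_region_out_of_bounds(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"chr1": "ACGTACGT"}))
        with pytest.raises(ValueError):
            g.region("chr1", 0, 9)
        with pytest.raises(ValueError):
            g.region("chr1", 5, 5)

    def test_duplicate_headers_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">chr1\nACGT\n>chr1\nGGCC\n")
        with pytest.raises(ValueError, match="chr1"):
            genome_io.load_genome(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            genome_io.load_genome(p)

    def test_header_token_before_whitespace(self, tmp_path):
        p = tmp_path / "desc.fa"
        p.write_text(">chr1 some description\nACGTACGT\n")
        g = genome_io.load_genome(p)
        assert g.contigs() == ["chr1"]


class TestParseGff:
    def test_coordinate_conversion_and_utr_inference(self, tiny_gff):
        genes = {g.gene_id: g for g in genome_io.parse_gff(tiny_gff)}
        plus = genes["gplus"].transcripts[0]
        assert plus.utr5_segments == [(10, 15)]
        assert plus.cds_segments == [(15, 35)]
        assert plus.utr3_segments == [(35, 40)]

    def test_minus_strand_utr_orientation(self, tiny_gff):
        genes = {g.gene_id: g for g in genome_io.parse_gff(tiny_gff)}
        minus = genes["gminus"].transcripts[0]
        assert minus.utr5_segments == [(35, 40)]
        assert minus.utr3_segments == [(10, 15)]

    def test_unlinked_children_warn_and_skip(self, tmp_path, caplog):
        p = tmp_path / "orphan.gff3"
        p.write_text(
            "chr1\ts\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            "chr1\ts\tgene\t60\t90\t.\t+\t.\tID=g2\n"
            "chr1\ts\tmRNA\t1\t50\t.\t+\t.\tID=t9;Parent=ghost\n"
        )
        with caplog.at_level(logging.WARNING):
            genes = genome_io.parse_gff(p)
        assert len(genes) == 2
        assert all(not g.transcripts for g in genes)
        assert any("unknown Parent" in r.message for r in caplog.records)

    def test_start_after_end_raises_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("chr1\ts\tgene\t50\t10\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match=":1:"):
            genome_io.parse_gff(p)


class TestFeatureTypes:
    def test_types_in_order_of_first_appearance(self, tiny_gff):
        assert genome_io.iter_feature_types(tiny_gff) == ["gene", "mRNA", "exon", "CDS"]

    def test_lncrna_rows_detected(self, tmp_path):
        p = tmp_path / "nc.gff3"
        p.write_text(
            "chr1\ts\tgene\t1\t50\t.\t+\t.\tID=g1\n"
            "chr1\ts\tlncRNA\t60\t90\t.\t+\t.\tID=n1\n"
        )
        assert "lncRNA" in genome_io.list_feature_types(p)

    def test_empty_annotation(self, tmp_path):
        p = tmp_path / "empty.gff3"
        p.write_text("##gff-version 3\n")
        assert genome_io.list_feature_types(p) == set()


class TestExtractFeature:
    def test_plus_strand_cds_roundtrip(self, tiny_genome, tiny_gff):
        genes = {g.gene_id: g for g in genome_io.parse_gff(tiny_gff)}
        rid, seq = genome_io.extract_feature(genes["gplus"], tiny_genome, "cds")
        assert rid == "gplus|cds"
        assert seq == tiny_genome.region("chr1", 15, 35)

    def test_minus_strand_is_revcomp_of_ascending_concatenation(
        self, tiny_genome, tiny_gff
    ):
        genes = {g.gene_id: g for g in genome_io.parse_gff(tiny_gff)}
        _, seq = genome_io.extract_feature(genes["gminus"], tiny_genome, "cds")
        planted = tiny_genome.region("chr2", 15, 35)
        # independent string oracle: complement map + reversed()
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        assert seq == "".join(comp[c] for c in reversed(planted))

    def test_promoter_truncated_at_contig_edge(self, tiny_genome, tiny_gff):
        genes = {g.gene_id: g for g in genome_io.parse_gff(tiny_gff)}
        _, seq = genome_io.extract_feature(
            genes["gplus"], tiny_genome, "promoter", promoter_len=100
        )
        assert len(seq) == 10  # gene starts at 10; only 10 bp upstream exist

    def test_missing_kind_collected_in_batch(self, tiny_genome, tmp_path):
        p = tmp_path / "nocds.gff3"
        p.write_text(
            "chr1\ts\tgene\t11\t40\t.\t+\t.\tID=g1\n"
            "chr1\ts\tmRNA\t11\t40\t.\t+\t.\tID=g1_t;Parent=g1\n"
            "chr1\ts\texon\t11\t40\t.\t+\t.\tID=g1_t.e;Parent=g1_t\n"
        )
        genes = genome_io.parse_gff(p)
        records, errors = genome_io.extract_features_batch(genes, tiny_genome, "cds")
        assert records == [] and len(errors) == 1


class TestRevcompTranslate:
    @pytest.mark.parametrize(
        "seq,expected", [("ACGT", "ACGT"), ("AAACCC", "GGGTTT"), ("ANRY", "RYNT")]
    )
    def test_revcomp_examples(self, seq, expected):
        assert genome_io.revcomp(seq) == expected

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(DNA)
    def test_revcomp_involution(self, seq):
        assert genome_io.revcomp(genome_io.revcomp(seq)) == seq

    def test_revcomp_rejects_non_iupac(self):
        with pytest.raises(ValueError, match="position 2"):
            genome_io.revcomp("AC!T")

    @pytest.mark.parametrize(
        "cds,protein", [("ATGAAATAG", "MK"), ("ATGGCC", "MA"), ("ATGTAAATG", "M")]
    )
    def test_translate_examples(self, cds, protein):
        assert genome_io.translate(cds) == protein

    def test_translate_partial_codon_warns(self, caplog):
        with caplog.at_level(logging.WARNING):
            assert genome_io.translate("ATGGCCA") == "MA"
        assert any("multiple of 3" in r.message for r in caplog.records)

    def test_translate_too_short(self):
        with pytest.raises(ValueError):
            genome_io.translate("AT")


class TestWindowedTracks:
    def test_gc_values(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"c": "GGCCATAT"}))
        vals = [t.value for t in genome_io.windowed_tracks(g, "gc", 4)]
        assert vals == [1.0, 0.0]

    def test_all_n_window_flagged_zero(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"c": "NNNNACGT"}))
        tracks = genome_io.windowed_tracks(g, "gc", 4)
        assert tracks[0].value == 0.0 and tracks[0].flag == "all_N"

    def test_overlapping_motif_counted(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"c": "ATATAT"}))
        tracks = genome_io.windowed_tracks(g, "kmer", 6, motif="AT")
        # brute-force scan oracle over every start position
        seq = "ATATAT"
        expect = sum(1 for i in range(len(seq)) if seq[i : i + 2] == "AT")
        assert tracks[0].value == expect == 3

    def test_tiling_covers_contig(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"c": "ACGTACGTAC"}))
        tracks = genome_io.windowed_tracks(g, "gc", 4)
        assert [(t.start, t.end) for t in tracks] == [(0, 4), (4, 8), (8, 10)]
        assert sum(t.end - t.start for t in tracks) == 10

    def test_k_larger_than_window_rejected(self, tmp_fasta):
        g = genome_io.load_genome(tmp_fasta({"c": "ACGTACGT"}))
        with pytest.raises(ValueError):
            genome_io.windowed_tracks(g, "kmer", 3, motif="ACGTA")

    def test_gene_density_by_start_coordinate(self, tmp_fasta, tiny_gff):
        g = genome_io.load_genome(
            tmp_fasta({"chr1": "A" * 60, "chr2": "A" * 60}, "two.fa")
        )
        ann = genome_io.parse_gff(tiny_gff)
        tracks = genome_io.windowed_tracks(g, "gene_density", 20, annotation=ann)
        by_window = {(t.seqid, t.start): t.value for t in tracks}
        assert by_window[("chr1", 0)] == 1.0  # gene starts at 10
        assert by_window[("chr1", 20)] == 0.0


class TestSeqStats:
    def test_n50_by_exhaustive_definition(self, tmp_fasta):
        s = genome_io.seq_stats(tmp_fasta({"a": "ACGT", "b": "ACGTAC"}))
        lengths = [4, 6]
        # oracle: largest L in the length set whose >=L contigs hold half the bases
        total = sum(lengths)
        oracle = max(
            L for L in set(lengths) if sum(x for x in lengths if x >= L) * 2 >= total
        )
        assert s.n_records == 2 and s.total_bp == 10
        assert s.n50 == oracle == 6

    def test_single_record(self, tmp_fasta):
        assert genome_io.seq_stats(tmp_fasta({"a": "ACGTACG"})).n50 == 7

    def test_fastq_detected(self, tmp_path):
        p = tmp_path / "r.fq"
        p.write_text("@r1\nACGT\n+\nIIII\n")
        s = genome_io.seq_stats(p)
        assert s.fmt == "fastq" and s.total_bp == 4

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            genome_io.seq_stats(p)
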