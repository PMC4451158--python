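import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from its2barcode import (
    HeaderSchema,
    Region,
    SeqRecord,
    ValidationError,
    annotate_regions,
    gc_percent,
    read_fasta,
    region_stats,
    revcomp,
    trim_primers,
    write_fasta,
)
from its2barcode.errors import (
    FastaParseError,
    PrimerGeometryError,
    PrimerNotFoundError,
    TooShortError,
    UndefinedGCError,
)
from its2barcode.seqio import DEFAULT_FWD_PRIMER, DEFAULT_REV_PRIMER


class TestFastaIO:
    def test_single_record_identity(self, tmp_path):
        p = tmp_path / "one.fasta"
        p.write_text(">S1|Ferula_sinkiangensis\nACGT\n")
        records = read_fasta(p)
        assert records == [SeqRecord("S1", "Ferula_sinkiangensis", "ACGT")]

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        assert read_fasta(p) == []

    def test_round_trip_preserves_sequences_and_labels(self, tmp_path):
        records = [
            SeqRecord("A1", "Alpha_sp", "ACGT" * 30),
            SeqRecord("B1", "Beta_sp", "TTGGCCAA" * 10),
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        assert read_fasta(p) == records

    def test_lowercase_input_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">S1|Sp_x\nacgt\n")
        assert read_fasta(p)[0].sequence == "ACGT"

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">S1|Sp_x\nACGT\n>S1|Sp_y\nACGT\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_fasta(p)

    def test_malformed_fasta_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text("ACGT\n>S1|Sp_x\nACGT\n")
        with pytest.raises(FastaParseError, match="line 1"):
            read_fasta(p)

    def test_header_schema_delimiter(self, tmp_path):
        p = tmp_path / "schema.fasta"
        p.write_text(">Genus_sp;S9\nACGT\n")
        rec = read_fasta(p, HeaderSchema(delimiter=";", sample_field=1, species_field=0))[0]
        assert (rec.sample_id, rec.species) == ("S9", "Genus_sp")


class TestPrimerTrimming:
    CORE = "GGGG"

    def _amplicon(self, fwd=DEFAULT_FWD_PRIMER, rev=DEFAULT_REV_PRIMER, core=CORE):
        return SeqRecord("q", "Sp_x", fwd + core + revcomp(rev))

    def test_exact_flanks_excised(self):
        assert trim_primers(self._amplicon(), max_mismatch=0).sequence == self.CORE

    def test_one_substitution_in_forward_primer_tolerated(self):
        fwd = DEFAULT_FWD_PRIMER
        mutated = fwd[:5] + ("C" if fwd[5] != "C" else "G") + fwd[6:]
        rec = SeqRecord("q", "Sp_x", mutated + self.CORE + revcomp(DEFAULT_REV_PRIMER))
        with pytest.raises(PrimerNotFoundError, match="forward"):
            trim_primers(rec, max_mismatch=0)
        assert trim_primers(rec, max_mismatch=1).sequence == self.CORE

    def test_missing_reverse_primer_raises(self):
        rec = SeqRecord("q", "Sp_x", DEFAULT_FWD_PRIMER + "GGGGCCCCTTTTAAAAGGGGCC")
        with pytest.raises(PrimerNotFoundError, match="reverse"):
            trim_primers(rec, max_mismatch=0)

    def test_out_of_order_primers_raise_geometry_error(self):
        rec = SeqRecord("q", "Sp_x", revcomp(DEFAULT_REV_PRIMER) + self.CORE + DEFAULT_FWD_PRIMER)
        with pytest.raises(PrimerGeometryError):
            trim_primers(rec, max_mismatch=0)

    def test_sense_strand_3prime_notation_also_matches(self):
        # reverse primer written 3'->5' on the sense strand: its sense-strand
        # text is the plain complement of the printed string
        complement = revcomp(DEFAULT_REV_PRIMER[::-1])
        rec = SeqRecord("q", "Sp_x", DEFAULT_FWD_PRIMER + self.CORE + complement)
        assert trim_primers(rec, max_mismatch=0).sequence == self.CORE


class TestRegionAnnotation:
    @pytest.mark.parametrize("length,its2_len", [(451, 226), (455, 230)])
    def test_fixed_flanks(self, length, its2_len):
        rec = SeqRecord("q", "Sp_x", "ACGT" * 114)  # 456 bp
        rec = rec.with_sequence(rec.sequence[:length])
        ann = annotate_regions(rec)
        assert ann.p58s == (1, 85)
        assert ann.its2[1] - ann.its2[0] == its2_len
        assert ann.p28s[1] - ann.p28s[0] == 141

    def test_too_short_is_an_error(self):
        rec = SeqRecord("q", "Sp_x", "A" * 450)
        with pytest.raises(TooShortError):
            annotate_regions(rec)

    def test_planted_core_recovered_after_trim(self):
        core = ("ACGT" * 60)[:230]
        amplicon = (
            DEFAULT_FWD_PRIMER
            + "G" * 84
            + core
            + "C" * 141
            + revcomp(DEFAULT_REV_PRIMER)
        )
        rec = trim_primers(SeqRecord("q", "Sp_x", amplicon), max_mismatch=0)
        ann = annotate_regions(rec)
        assert ann.extract(rec.sequence, Region.ITS2) == core


class TestGC:
    @pytest.mark.parametrize("seq,expected", [("GGCC", 100.0), ("ATAT", 0.0), ("ATGC", 50.0)])
    def test_known_values(self, seq, expected):
        assert gc_percent(seq) == expected

    def test_ambiguity_codes_excluded(self):
        assert gc_percent("GNGN") == 100.0

    def test_all_ambiguous_region_is_undefined(self):
        with pytest.raises(UndefinedGCError):
            gc_percent("NNNN")

    def test_region_stats_cover_all_regions(self):
        rec = SeqRecord("q", "Sp_x", "ACGT" * 114)  # 456 bp
        stats = region_stats(rec, annotate_regions(rec))
        assert [s.region for s in stats] == [Region.FULL, Region.P58S, Region.ITS2, Region.P28S]
        assert all(0 <= s.gc_percent <= 100 for s in stats)
        assert sum(s.length_bp for s in stats[1:]) == stats[0].length_bp

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_gc_of_at_relabel_is_complementary(self, seq):
        # relabeling A<->G and T<->C swaps the GC and AT pools exactly
        relabeled = seq.translate(str.maketrans("AGTC", "GACT"))
        assert gc_percent(seq) + gc_percent(relabeled) == pytest.approx(100.0)
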