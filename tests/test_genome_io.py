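"""Genome and metadata I/O: round-trips, coordinate conventions, validation."""

import pytest

from nitriscan.genome_io import (EmptyGenomeError, GenomeIOError, GenomeRecord,
                                 OrfFeature, Replicon, StrainMetadata,
                                 read_genbank, read_gff_fasta, read_metadata,
                                 write_genbank, write_gff_fasta)


def _tiny_record():
    # 3 CDS on one replicon; middle one on the minus strand
    seq = "TTT" + "ATGAAATGA" + "GG" + "TCATTTCAT" + "C" + "ATGGGCTAA" + "AA"
    orfs = [
        OrfFeature("chr", 0, 4, 12, "+", "ATGAAATGA", "MK", label="one"),
        OrfFeature("chr", 1, 15, 23, "-", "ATGAAATGA", "MK", label="two"),
        OrfFeature("chr", 2, 25, 33, "+", "ATGGGCTAA", "MG", label="three"),
    ]
    return GenomeRecord("T1", "AOB", "marine", [Replicon("chr", seq)], orfs)


class TestGenBank:
    def test_roundtrip_identity(self, implanted_genome, tmp_path):
        genome, _ = implanted_genome
        path = tmp_path / "g.gbk"
        write_genbank(genome, str(path))
        back = read_genbank(str(path))
        assert back.strain_id == genome.strain_id
        assert back.guild == genome.guild and back.habitat == genome.habitat
        assert len(back.orfs) == len(genome.orfs)
        for a, b in zip(genome.orfs, back.orfs):
            assert (a.start, a.end, a.strand, a.nt_seq, a.aa_seq) == \
                   (b.start, b.end, b.strand, b.nt_seq, b.aa_seq)
        assert back.genome_gc == pytest.approx(genome.genome_gc, abs=1e-12)

    def test_ordinals_follow_file_order(self, tmp_path):
        rec = _tiny_record()
        path = tmp_path / "t.gbk"
        write_genbank(rec, str(path))
        back = read_genbank(str(path))
        assert [o.ordinal for o in back.orfs] == [0, 1, 2]
        assert [o.label for o in back.orfs] == ["one", "two", "three"]

    def test_minus_strand_is_reverse_complement(self, tmp_path):
        rec = _tiny_record()
        path = tmp_path / "t.gbk"
        write_genbank(rec, str(path))
        back = read_genbank(str(path))
        minus = back.orfs[1]
        genomic_slice = back.replicons[0].seq[minus.start - 1: minus.end]
        assert genomic_slice == "TCATTTCAT"
        assert minus.nt_seq == "ATGAAATGA"  # revcomp of the slice

    def test_zero_cds_rejected(self, tmp_path):
        path = tmp_path / "empty.gbk"
        path.write_text(
            "LOCUS       empty  6 bp  DNA linear  01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "ORIGIN\n        1 acgtac\n//\n")
        with pytest.raises(EmptyGenomeError):
            read_genbank(str(path))


class TestGffFasta:
    def test_coordinate_passthrough(self, tmp_path):
        (tmp_path / "a.gff").write_text(
            "##gff-version 3\nchr\tx\tCDS\t4\t9\t.\t+\t0\tID=c1\n")
        (tmp_path / "a.fa").write_text(">chr\nTTTATGTGAAAC\n")
        rec = read_gff_fasta(str(tmp_path / "a.gff"), str(tmp_path / "a.fa"))
        assert rec.orfs[0].start == 4 and rec.orfs[0].end == 9
        assert rec.orfs[0].nt_seq == "ATGTGA"

    def test_out_of_bounds_cds_rejected(self, tmp_path):
        (tmp_path / "a.gff").write_text(
            "##gff-version 3\nchr\tx\tCDS\t4\t40\t.\t+\t0\tID=c1\n")
        (tmp_path / "a.fa").write_text(">chr\nTTTATGTGAAAC\n")
        with pytest.raises(GenomeIOError):
            read_gff_fasta(str(tmp_path / "a.gff"), str(tmp_path / "a.fa"))

    def test_unknown_seqid_rejected(self, tmp_path):
        (tmp_path / "a.gff").write_text(
            "##gff-version 3\nplasmid\tx\tCDS\t1\t6\t.\t+\t0\tID=c1\n")
        (tmp_path / "a.fa").write_text(">chr\nTTTATGTGAAAC\n")
        with pytest.raises(GenomeIOError):
            read_gff_fasta(str(tmp_path / "a.gff"), str(tmp_path / "a.fa"))

    def test_dual_encoding_agreement(self, implanted_genome, tmp_path):
        """GenBank and GFF3+FASTA encodings of one genome parse identically."""
        genome, _ = implanted_genome
        write_genbank(genome, str(tmp_path / "g.gbk"))
        write_gff_fasta(genome, str(tmp_path / "g.gff"), str(tmp_path / "g.fa"))
        a = read_genbank(str(tmp_path / "g.gbk"))
        b = read_gff_fasta(str(tmp_path / "g.gff"), str(tmp_path / "g.fa"),
                           strain_id=genome.strain_id)
        assert [(o.start, o.end, o.strand, o.nt_seq) for o in a.orfs] == \
               [(o.start, o.end, o.strand, o.nt_seq) for o in b.orfs]
        assert a.genome_gc == pytest.approx(b.genome_gc, abs=1e-12)


class TestMetadata:
    def test_parse_dimensions(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("strain_id,guild,habitat,shape,widths,lengths\n"
                        "S1,AOA,marine,sphere,0.5;0.7,\n")
        recs = read_metadata(str(path))
        assert recs[0].widths == [0.5, 0.7] and recs[0].lengths == []

    def test_rod_without_length_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("strain_id,guild,habitat,shape,widths,lengths\n"
                        "S1,AOB,marine,rod,0.5,\n")
        with pytest.raises(ValueError):
            read_metadata(str(path))

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("strain_id,guild,habitat,widths,lengths\n"
                        "S1,AOA,marine,0.5,\n")
        with pytest.raises(GenomeIOError):
            read_metadata(str(path))

    def test_unknown_guild_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("strain_id,guild,habitat,shape,widths,lengths\n"
                        "S1,XXX,marine,sphere,0.5,\n")
        with pytest.raises(ValueError):
            read_metadata(str(path))

    def test_guild_group_sizes(self, tmp_path):
        """A 70-row panel with the survey's guild split parses to 46/10/12/2."""
        rows = ["strain_id,guild,habitat,shape,widths,lengths"]
        split = [("AOA", 46), ("AOB", 10), ("NOB", 12), ("comammox", 2)]
        i = 0
        for guild, n in split:
            for _ in range(n):
                rows.append(f"S{i},{guild},marine,sphere,0.5,")
                i += 1
        path = tmp_path / "m.csv"
        path.write_text("\n".join(rows) + "\n")
        recs = read_metadata(str(path))
        assert len(recs) == 70
        counts = {}
        for r in recs:
            counts[r.guild] = counts.get(r.guild, 0) + 1
        assert counts == {"AOA": 46, "AOB": 10, "NOB": 12, "comammox": 2}


def test_validate_catches_sparse_ordinals():
    rec = _tiny_record()
    rec.orfs[2].ordinal = 5
    with pytest.raises(GenomeIOError):
        rec.validate()
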