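import pysam
import pytest

from splicebin.align import (
    AlignmentError,
    AlignmentRecord,
    align_chunk,
    build_index,
    concatenate_sample,
    parse_cigar,
    toy_align,
    verify_equivalence,
    write_sam,
)
from splicebin.chunking import ReadChunk, ReadPair
from splicebin.fasta import revcomp


def make_pair(read_id, seq1, seq2):
    return ReadPair(read_id, seq1, "I" * len(seq1), seq2, "I" * len(seq2))


class TestBuildIndex:
    def test_repeated_kmer_offsets(self):
        index = build_index({"c": "ACGTACGT"}, k=4)
        assert index.kmer_map["ACGT"] == [("c", 0), ("c", 4)]

    def test_full_length_kmer(self):
        index = build_index({"c": "ACGTACGT"}, k=8)
        assert index.kmer_map["ACGTACGT"] == [("c", 0)]

    def test_every_genomic_kmer_present(self):
        seq = "ACGTTGCAAGGT"
        index = build_index({"c": seq}, k=5)
        for i in range(len(seq) - 4):
            assert ("c", i) in index.kmer_map[seq[i : i + 5]]

    def test_k_longer_than_chromosome(self):
        with pytest.raises(AlignmentError, match="exceeds length"):
            build_index({"c": "ACGT"}, k=8)

    def test_invalid_characters(self):
        with pytest.raises(AlignmentError, match="invalid"):
            build_index({"c": "ACGTXACGT"}, k=4)


@pytest.fixture(scope="module")
def junction_genome():
    # exon1 [0,60) + intron [60,140) + exon2 [140,200); GT..AG motifs
    import numpy as np

    rng = np.random.default_rng(42)
    bases = "ACGT"
    seq = list(rng.choice(list(bases), size=200))
    seq[60], seq[61] = "G", "T"
    seq[138], seq[139] = "A", "G"
    # break split-point ambiguity at the junction
    if seq[140] == seq[60]:
        seq[140] = "C"
    if seq[59] == seq[139]:
        seq[59] = "C"
    return {"chrJ": "".join(seq)}


class TestToyAlign:
    def test_exonic_read_identity_placement(self, junction_genome):
        genome = junction_genome
        index = build_index(genome, k=10)
        read = genome["chrJ"][5:45]
        recs = toy_align(make_pair("r1", read, revcomp(read)), index)
        assert recs[0].pos == 6 and recs[0].cigar_string == "40M"
        assert recs[1].pos == 6 and recs[1].cigar_string == "40M"
        assert recs[1].is_reverse and not recs[0].is_reverse

    def test_junction_read_split_cigar(self, junction_genome):
        genome = junction_genome
        index = build_index(genome, k=10)
        # 40 bases from the left exon, 20 from the right: 40M80N20M
        read = genome["chrJ"][20:60] + genome["chrJ"][140:160]
        recs = toy_align(make_pair("r1", read, revcomp(read)), index)
        assert recs[0].pos == 21
        assert recs[0].cigar_string == "40M80N20M"

    def test_all_n_read_unmapped(self, junction_genome):
        index = build_index(junction_genome, k=10)
        recs = toy_align(make_pair("r1", "N" * 40, "N" * 40), index)
        assert not recs[0].is_mapped and not recs[1].is_mapped
        assert recs[0].chrom is None and recs[0].pos == 0

    def test_record_conservation_two_per_pair(self, junction_genome):
        index = build_index(junction_genome, k=10)
        chunk = ReadChunk("s", 0, [make_pair(f"r{i}", "N" * 30, "N" * 30) for i in range(4)])
        assert len(align_chunk(chunk, index).records) == 8


class TestAlignChunk:
    def test_empty_chunk(self, tiny_index):
        assert align_chunk(ReadChunk("s", 0, []), tiny_index).records == []

    def test_determinism_byte_identical(self, tiny_truth, tiny_index, tmp_path):
        pairs = [
            make_pair(p.truth.read_id, p.mate1_seq, p.mate2_seq)
            for p in next(iter(tiny_truth.samples.values()))[:20]
        ]
        chunk = ReadChunk("s", 0, pairs)
        paths = []
        for i in range(2):
            result = align_chunk(chunk, tiny_index)
            path = tmp_path / f"run{i}.sam"
            write_sam(result.records, str(path), tiny_truth.genome)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_mapped_plus_unmapped_equals_two_per_pair(self, tiny_truth, tiny_index):
        pairs = [
            make_pair(p.truth.read_id, p.mate1_seq, p.mate2_seq)
            for p in next(iter(tiny_truth.samples.values()))[:50]
        ]
        result = align_chunk(ReadChunk("s", 0, pairs), tiny_index)
        assert len(result.records) == 2 * len(pairs)


def write_chunk_sams(records_per_chunk, genome, tmp_path):
    paths = {}
    for idx, records in enumerate(records_per_chunk):
        path = tmp_path / f"chunk{idx}.sam"
        write_sam(records, str(path), genome)
        paths[idx] = str(path)
    return paths


def body_lines(path):
    with open(path) as fh:
        return [ln for ln in fh if not ln.startswith("@")]


class TestConcatenateSample:
    GENOME = {"c": "ACGTACGTACGTACGTACGT"}

    def recs(self, n, tag):
        return [
            AlignmentRecord(f"{tag}{i}", 0, "c", 1 + i, (("M", 4),), "ACGT", "IIII")
            for i in range(n)
        ]

    def test_count_conservation(self, tmp_path):
        chunks = [self.recs(8, "a"), self.recs(8, "b"), self.recs(4, "c")]
        paths = write_chunk_sams(chunks, self.GENOME, tmp_path)
        out = concatenate_sample("s", paths, str(tmp_path / "out.sam"))
        assert len(body_lines(out)) == 20

    def test_single_chunk_record_identical(self, tmp_path):
        records = self.recs(5, "a")
        paths = write_chunk_sams([records], self.GENOME, tmp_path)
        chunk_body = body_lines(paths[0])
        out = concatenate_sample("s", paths, str(tmp_path / "out.sam"), delete_chunks=False)
        assert body_lines(out) == chunk_body

    def test_missing_chunk_error_names_index(self, tmp_path):
        paths = write_chunk_sams([self.recs(2, "a"), self.recs(2, "b"), self.recs(2, "c")],
                                 self.GENOME, tmp_path)
        del paths[1]
        with pytest.raises(AlignmentError, match=r"\[1\]"):
            concatenate_sample("s", paths, str(tmp_path / "out.sam"))

    def test_pg_lines_dropped_and_chunks_deleted(self, tmp_path):
        import os

        paths = write_chunk_sams([self.recs(2, "a"), self.recs(2, "b")], self.GENOME, tmp_path)
        kept = dict(paths)
        out = concatenate_sample("s", paths, str(tmp_path / "out.sam"))
        header = [ln for ln in open(out) if ln.startswith("@")]
        assert not any(ln.startswith(("@PG", "@CO")) for ln in header)
        assert any(ln.startswith("@SQ") for ln in header)
        assert all(not os.path.exists(p) for p in kept.values())

    def test_output_is_valid_sam_for_pysam(self, tmp_path):
        paths = write_chunk_sams([self.recs(3, "a")], self.GENOME, tmp_path)
        out = concatenate_sample("s", paths, str(tmp_path / "out.sam"))
        with pysam.AlignmentFile(out, "r") as fh:
            assert sum(1 for _ in fh) == 3


class TestVerifyEquivalence:
    GENOME = {"c": "ACGTACGTACGTACGTACGT"}

    def _write(self, records, tmp_path, name, program="splicebin"):
        path = tmp_path / name
        write_sam(records, str(path), self.GENOME, program=program)
        return str(path)

    def recs(self):
        return [
            AlignmentRecord(f"r{i}", 0, "c", 1 + i, (("M", 4),), "ACGT", "IIII")
            for i in range(6)
        ]

    def test_file_vs_itself(self, tmp_path):
        path = self._write(self.recs(), tmp_path, "a.sam")
        assert verify_equivalence(path, path)

    def test_reordered_records_equivalent(self, tmp_path):
        records = self.recs()
        a = self._write(records, tmp_path, "a.sam")
        b = self._write(list(reversed(records)), tmp_path, "b.sam")
        assert verify_equivalence(a, b)

    def test_pg_difference_ignored(self, tmp_path):
        a = self._write(self.recs(), tmp_path, "a.sam", program="toolA")
        b = self._write(self.recs(), tmp_path, "b.sam", program=None)
        assert verify_equivalence(a, b)

    def test_perturbed_position_reported(self, tmp_path):
        records = self.recs()
        a = self._write(records, tmp_path, "a.sam")
        perturbed = records[:2] + [
            AlignmentRecord("r2", 0, "c", records[2].pos + 1, (("M", 4),), "ACGT", "IIII")
        ] + records[3:]
        b = self._write(perturbed, tmp_path, "b.sam")
        result = verify_equivalence(a, b)
        assert not result
        assert result.first_divergence is not None
        assert "r2" in str(result.first_divergence)

    def test_unparseable_file(self, tmp_path):
        bad = tmp_path / "bad.sam"
        bad.write_text("this is not a sam file\n\x00")
        good = self._write(self.recs(), tmp_path, "a.sam")
        with pytest.raises(AlignmentError):
            verify_equivalence(str(bad), good)


class TestSamRoundTrip:
    def test_record_line_round_trip(self):
        rec = AlignmentRecord("r1", 83, "chr1", 1234, parse_cigar("10M50N90M"), "*", "*")
        assert AlignmentRecord.from_sam_line(rec.to_sam_line()) == rec

    def test_parse_cigar_rejects_garbage(self):
        with pytest.raises(AlignmentError):
            parse_cigar("10X")
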