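import logging

import pytest

from splicebin.align import AlignmentRecord, parse_cigar
from splicebin.assembly import (
    AssemblyError,
    AssemblyParams,
    assemble_bin,
    assemble_pooled,
    collect_transcripts,
    extract_evidence,
    filter_annotation_for_bin,
    junction_strand,
)
from splicebin.binning import BinName, BinScheme
from splicebin.gtf import Annotation, Transcript


def rec(pos, cigar, qname="r", chrom="chr1", flag=0):
    return AlignmentRecord(qname, flag, chrom, pos, parse_cigar(cigar))


def tx(tid, chrom, exons, strand="+", gid=None):
    return Transcript(tid, gid or tid, chrom, strand, tuple(exons))


class TestFilterAnnotationForBin:
    ANNOTATION = Annotation([
        tx("a", "chr1", ((1, 100),)),
        tx("b", "chr1", ((201, 300),)),
        tx("c", "chr2", ((1, 100),)),
        tx("d", "chr2", ((201, 300),)),
        tx("e", "chr2", ((401, 500),)),
    ])

    def test_selects_bin_chromosome(self):
        partial = filter_annotation_for_bin(self.ANNOTATION, BinName("chr1", 0))
        assert [t.transcript_id for t in partial] == ["a", "b"]

    def test_absent_chromosome_empty(self):
        assert len(filter_annotation_for_bin(self.ANNOTATION, BinName("chr9", 0))) == 0

    def test_single_chromosome_identity(self):
        single = Annotation([tx("a", "chr1", ((1, 100),))])
        assert filter_annotation_for_bin(single, BinName("chr1", 3)).transcripts == single.transcripts


class TestExtractEvidence:
    SEQ = "A" * 500

    def test_stacked_reads_counted(self):
        records = [rec(101, "50M", qname=f"r{i}") for i in range(3)]
        coverage, junctions = extract_evidence(records, self.SEQ)
        assert (coverage[100:150] == 3).all()
        assert coverage[:100].sum() == 0 and coverage[150:].sum() == 0
        assert junctions == {}

    def test_junction_from_n_op(self):
        coverage, junctions = extract_evidence([rec(1, "10M100N10M")], self.SEQ)
        assert set(junctions) == {(10, 110)}
        assert junctions[(10, 110)].support == 1
        assert (coverage[0:10] == 1).all() and (coverage[110:120] == 1).all()
        assert coverage[10:110].sum() == 0

    def test_empty_records(self):
        coverage, junctions = extract_evidence([], self.SEQ)
        assert coverage.sum() == 0 and junctions == {}

    def test_record_past_chromosome_end(self):
        with pytest.raises(AssemblyError, match="past chromosome end"):
            extract_evidence([rec(490, "50M")], self.SEQ)

    def test_multi_chromosome_rejected(self):
        with pytest.raises(AssemblyError, match="multiple chromosomes"):
            extract_evidence([rec(1, "10M"), rec(1, "10M", chrom="chr2")], self.SEQ)

    @pytest.mark.parametrize(
        "intron_seq,expected",
        [("GT" + "A" * 20 + "AG", "+"), ("CT" + "A" * 20 + "AC", "-"), ("AA" + "A" * 20 + "AA", ".")],
    )
    def test_junction_strand_motifs(self, intron_seq, expected):
        seq = "C" * 10 + intron_seq + "C" * 10
        assert junction_strand(seq, 10, 10 + len(intron_seq)) == expected


def spliced_gene_records(depth=5):
    """Reads over a two-exon gene: exons [101,200], [301,400], GT..AG intron."""
    records = []
    for i in range(depth):
        records.append(rec(101, "100M", qname=f"L{i}"))
        records.append(rec(151, "50M100N50M", qname=f"J{i}"))
        records.append(rec(301, "100M", qname=f"R{i}"))
    return sorted(records, key=lambda r: r.pos)


@pytest.fixture()
def gene_genome():
    seq = list("A" * 600)
    seq[200:202] = "GT"
    seq[298:300] = "AG"
    return {"chr1": "".join(seq)}


class TestAssembleBin:
    def test_single_isoform_recovered(self, gene_genome):
        transcripts = assemble_bin(spliced_gene_records(), gene_genome)
        assert len(transcripts) == 1
        t = transcripts[0]
        assert t.exons == ((101, 200), (301, 400))
        assert t.introns == ((201, 300),)
        assert t.strand == "+"

    def test_minus_motif_sets_strand(self, gene_genome):
        genome = {"chr1": gene_genome["chr1"][:200] + "CT" + gene_genome["chr1"][202:298] + "AC"
                  + gene_genome["chr1"][300:]}
        t = assemble_bin(spliced_gene_records(), genome)[0]
        assert t.strand == "-"

    def test_coverage_below_min_cov_empty(self, gene_genome):
        transcripts = assemble_bin(
            spliced_gene_records(depth=2), gene_genome, AssemblyParams(min_cov=10.0)
        )
        assert transcripts == []

    def test_junction_support_threshold(self, gene_genome):
        records = sorted(
            [rec(101, "100M", qname=f"L{i}") for i in range(5)]
            + [rec(151, "50M100N50M", qname="J0")]
            + [rec(301, "100M", qname=f"R{i}") for i in range(5)],
            key=lambda r: r.pos,
        )
        transcripts = assemble_bin(records, gene_genome, AssemblyParams(min_junction_support=2))
        # junction too weak: no spliced call; fragments with dangling
        # junction boundaries must not become spurious singles
        assert all(t.introns != ((201, 300),) for t in transcripts)

    def test_unspliced_fragment_single_exon_unknown_strand(self, gene_genome):
        records = [rec(101, "100M", qname=f"r{i}") for i in range(3)]
        transcripts = assemble_bin(records, gene_genome)
        assert len(transcripts) == 1
        assert transcripts[0].exons == ((101, 200),)
        assert transcripts[0].strand == "."

    def test_empty_records(self, gene_genome):
        assert assemble_bin([], gene_genome) == []

    def test_multi_chromosome_rejected(self, gene_genome):
        genome = dict(gene_genome, chr2="A" * 600)
        records = [rec(1, "10M"), rec(1, "10M", chrom="chr2")]
        with pytest.raises(AssemblyError):
            assemble_bin(sorted(records, key=lambda r: r.chrom or ""), genome)

    def test_deterministic_output(self, gene_genome):
        a = assemble_bin(spliced_gene_records(), gene_genome)
        b = assemble_bin(spliced_gene_records(), gene_genome)
        assert a == b

    def test_path_cap_warns_not_reorders(self, gene_genome, caplog):
        # two alternative introns sharing a donor: 2 maximal paths, cap at 1
        seq = list("A" * 800)
        seq[200:202] = "GT"
        seq[298:300] = "AG"
        seq[398:400] = "AG"
        genome = {"chr1": "".join(seq)}
        records = sorted(
            [rec(101, "100M", qname=f"a{i}") for i in range(3)]
            + [rec(151, "50M100N50M", qname=f"b{i}") for i in range(3)]
            + [rec(151, "50M200N50M", qname=f"c{i}") for i in range(3)]
            + [rec(301, "100M", qname=f"d{i}") for i in range(3)]
            + [rec(401, "100M", qname=f"e{i}") for i in range(3)],
            key=lambda r: r.pos,
        )
        with caplog.at_level(logging.WARNING):
            capped = assemble_bin(records, genome, AssemblyParams(max_paths_per_component=1))
        assert len([t for t in capped if t.is_multi_exon]) == 1
        assert any("path cap" in message for message in caplog.messages)
        full = assemble_bin(records, genome, AssemblyParams(max_paths_per_component=64))
        # capped output is a prefix of the full enumeration, never a reordering
        assert [t.exons for t in capped if t.is_multi_exon] == [
            t.exons for t in full if t.is_multi_exon
        ][:1]


class TestGuidedMode:
    def test_reference_with_supported_introns_emitted_verbatim(self, gene_genome):
        ref = Annotation([tx("ref.t1", "chr1", ((95, 200), (301, 410)))])
        transcripts = assemble_bin(spliced_gene_records(), gene_genome, partial_annotation=ref)
        assert transcripts[0].transcript_id == "ref.t1"
        assert transcripts[0].exons == ((95, 200), (301, 410))
        assert transcripts[0].source == "reference"
        # the de novo path with the same chain is suppressed
        assert sum(1 for t in transcripts if t.introns == ((201, 300),)) == 1

    def test_reference_with_unsupported_introns_not_emitted(self, gene_genome):
        ref = Annotation([tx("ref.t1", "chr1", ((95, 150), (451, 520)))])
        transcripts = assemble_bin(spliced_gene_records(), gene_genome, partial_annotation=ref)
        assert all(t.transcript_id != "ref.t1" for t in transcripts)

    def test_guided_superset_of_denovo_chains(self, tiny_mapped, tiny_truth):
        denovo = assemble_pooled(tiny_mapped, tiny_truth.genome)
        guided = assemble_pooled(
            tiny_mapped, tiny_truth.genome, partial_annotation=tiny_truth.annotation
        )
        denovo_chains = {(t.chrom, t.introns) for t in denovo if t.is_multi_exon}
        guided_chains = {(t.chrom, t.introns) for t in guided if t.is_multi_exon}
        assert denovo_chains <= guided_chains


class TestCollectTranscripts:
    def test_bin_order_not_completion_order(self):
        t0 = tx("a", "chr1", ((1, 50),))
        t1 = tx("b", "chr1", ((101, 150),))
        per_bin = {BinName("chr1", 1): [t1], BinName("chr1", 0): [t0]}
        assert collect_transcripts(per_bin) == [t0, t1]

    def test_empty_bins(self):
        assert collect_transcripts({}) == []
        assert collect_transcripts({BinName("chr1", 0): []}) == []

    def test_overlap_duplicates_retained(self):
        dup0 = tx("a", "chr1", ((1, 50),))
        dup1 = tx("b", "chr1", ((1, 50),))
        per_bin = {BinName("chr1", 0): [dup0], BinName("chr1", 1): [dup1]}
        assert len(collect_transcripts(per_bin)) == 2


class TestBinnedAssemblyBoundaries:
    def test_transcript_in_overlap_assembled_by_both_bins(self):
        # gene spans [301,440], wholly inside the bin0/bin1 overlap [250,450):
        # S=250, V=200 gives bin0=[0,450), bin1=[250,600)
        seq = list("A" * 600)
        seq[340:342] = "GT"
        seq[398:400] = "AG"
        genome = {"chr1": "".join(seq)}
        records = sorted(
            [rec(301, "40M", qname=f"L{i}") for i in range(4)]
            + [rec(321, "20M60N20M", qname=f"J{i}") for i in range(4)]
            + [rec(401, "40M", qname=f"R{i}") for i in range(4)],
            key=lambda r: r.pos,
        )
        scheme = BinScheme(bin_size=250, overlap=200, chrom_lengths={"chr1": 600})
        out = {}
        for name in (BinName("chr1", 0), BinName("chr1", 1)):
            bs, be = scheme.interval(name)
            in_bin = [r for r in records
                      if r.pos - 1 < be and r.pos - 1 + r.reference_length() > bs]
            out[name] = assemble_bin(in_bin, genome, origin_bin=name, scheme=scheme)
        assert len(out[BinName("chr1", 0)]) == 1
        assert len(out[BinName("chr1", 1)]) == 1
        assert out[BinName("chr1", 0)][0].exons == out[BinName("chr1", 1)][0].exons
        assert out[BinName("chr1", 0)][0].origin_bin == "chr1:0"

    def test_partial_evidence_transcripts_dropped(self, gene_genome):
        # bin1 core starts inside the gene: its evidence is incomplete and
        # must produce nothing (bin0 sees the full gene)
        scheme = BinScheme(bin_size=350, overlap=100, chrom_lengths={"chr1": 600})
        records = spliced_gene_records()
        name = BinName("chr1", 1)
        bs, be = scheme.interval(name)
        in_bin = [r for r in records
                  if r.pos - 1 < be and r.pos - 1 + r.reference_length() > bs]
        assert in_bin  # the gene does leak into bin 1
        assert assemble_bin(in_bin, gene_genome, origin_bin=name, scheme=scheme) == []
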