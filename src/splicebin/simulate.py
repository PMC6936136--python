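"""Seeded generator of a small genome, multi-isoform annotation and paired reads.

The generator produces data with the properties the rest of the pipeline's
guarantees are stated over: genes are placed non-overlapping with >= 1 kb
gaps, every intron carries the canonical splice motif on its gene's strand
(GT..AG forward, CT..AC reverse genomic) so junction strand inference works,
and in disjoint-isoform mode isoforms of a gene share no exons or junctions.
Zero-error reads are exact substrings (or reverse complements) of their
spliced transcript, every read pair's true genomic placement (position,
CIGAR, orientation) is recorded in a truth table, and all output is a pure
function of the seed.

The exon bases flanking each intron are additionally constrained so the
splice junction admits exactly one exact split point: the first exonic base
after an intron never equals the first intron base, and the last exonic
base before an intron never equals the last intron base. Without this, a
junction-spanning read has two equally exact placements and no aligner can
recover the annotated chain deterministically.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import yaml

from splicebin.fasta import revcomp, write_fasta
from splicebin.gtf import Annotation, Transcript, write_gtf

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    n_chromosomes: int = 1
    chrom_length: int = 200_000
    n_genes: int = 10
    isoforms_per_gene: int = 1
    exons_per_transcript: tuple[int, int] = (2, 4)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (60, 200)
    read_length: int = 100
    reads_per_transcript: int = 1000
    fragment_mean: float = 250.0
    fragment_sd: float = 25.0
    error_rate: float = 0.0
    seed: int = 0
    n_samples: int = 1
    disjoint_isoforms: bool = True
    gene_gap: int = 1000
    isoform_gap: int = 500

    def validate(self) -> None:
        if self.exon_length[0] < self.read_length:
            raise SimulationError(
                f"minimum exon length {self.exon_length[0]} must be >= read length "
                f"{self.read_length}"
            )
        if self.intron_length[0] < 4:
            raise SimulationError("minimum intron length must be >= 4 (room for splice motifs)")
        if self.gene_gap < 1000:
            raise SimulationError("gene gap must be >= 1000 bp")
        for lo, hi in (self.exons_per_transcript, self.exon_length, self.intron_length):
            if lo > hi or lo < 1:
                raise SimulationError(f"bad range ({lo}, {hi})")
        if not 0.0 <= self.error_rate < 1.0:
            raise SimulationError(f"error rate {self.error_rate} outside [0, 1)")
        if min(self.n_chromosomes, self.n_genes, self.isoforms_per_gene, self.n_samples) < 1:
            raise SimulationError("counts must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SimulationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exons_per_transcript", "exon_length", "intron_length"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class MateTruth:
    chrom: str
    pos: int  # 1-based leftmost
    strand: str
    cigar: str


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    sample: str
    transcript_id: str
    fragment_start: int  # transcript-relative, 0-based
    fragment_length: int
    mate1: MateTruth
    mate2: MateTruth


@dataclass(frozen=True)
class SimulatedPair:
    truth: ReadTruth
    mate1_seq: str
    mate2_seq: str


@dataclass
class GroundTruth:
    genome: dict[str, str]
    annotation: Annotation
    samples: dict[str, list[SimulatedPair]] = field(default_factory=dict)


def _transcript_structure(
    rng: np.random.Generator, config: SimConfig
) -> tuple[list[int], list[int]]:
    n_exons = int(rng.integers(config.exons_per_transcript[0], config.exons_per_transcript[1] + 1))
    exon_lens = [
        int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        for _ in range(n_exons)
    ]
    intron_lens = [
        int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
        for _ in range(n_exons - 1)
    ]
    return exon_lens, intron_lens


def _inject_motifs(
    chrom_arr: np.ndarray, introns0: list[tuple[int, int]], strand: str, rng: np.random.Generator
) -> None:
    """Write splice motifs and break split-point ambiguity at each junction."""
    donor_motif, acceptor_motif = (b"GT", b"AG") if strand == "+" else (b"CT", b"AC")
    for d, a in introns0:  # 0-based half-open intron [d, a)
        chrom_arr[d : d + 2] = np.frombuffer(donor_motif, dtype=np.uint8)
        chrom_arr[a - 2 : a] = np.frombuffer(acceptor_motif, dtype=np.uint8)
        for pos, banned in ((a, chrom_arr[d]), (d - 1, chrom_arr[a - 1])):
            if chrom_arr[pos] == banned:
                choices = _BASES[_BASES != banned]
                chrom_arr[pos] = choices[int(rng.integers(len(choices)))]


def simulate_genome_and_annotation(config: SimConfig) -> GroundTruth:
    """Generate the genome and annotation halves of the ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    arrays = {
        name: _BASES[rng.integers(0, 4, size=config.chrom_length)].copy()
        for name in chrom_names
    }
    cursors = {name: config.gene_gap for name in chrom_names}
    transcripts: list[Transcript] = []
    pending_motifs: list[tuple[str, list[tuple[int, int]], str]] = []
    for gi in range(config.n_genes):
        chrom = chrom_names[gi % config.n_chromosomes]
        strand = "+" if rng.integers(2) == 0 else "-"
        gene_id = f"g{gi + 1:03d}"
        isoform_structures = [
            _transcript_structure(rng, config) for _ in range(config.isoforms_per_gene)
        ]
        cursor = cursors[chrom]
        gene_start = cursor
        for k, (exon_lens, intron_lens) in enumerate(isoform_structures):
            if config.disjoint_isoforms and k > 0:
                cursor += config.isoform_gap
            exons0: list[tuple[int, int]] = []
            pos = cursor if config.disjoint_isoforms or k == 0 else gene_start
            iso_start = pos
            for j, elen in enumerate(exon_lens):
                exons0.append((pos, pos + elen))
                pos += elen
                if j < len(intron_lens):
                    pos += intron_lens[j]
            introns0 = [(exons0[j][1], exons0[j + 1][0]) for j in range(len(exons0) - 1)]
            pending_motifs.append((chrom, introns0, strand))
            transcripts.append(
                Transcript(
                    transcript_id=f"{gene_id}.t{k + 1}",
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    exons=tuple((s + 1, e) for s, e in exons0),
                    source="reference",
                )
            )
            if config.disjoint_isoforms:
                cursor = pos
            else:
                cursor = max(cursor, pos)
        extra = int(rng.integers(0, 500))
        cursors[chrom] = cursor + config.gene_gap + extra
        if cursors[chrom] > config.chrom_length - config.gene_gap:
            # conservative requirement estimate: current usage scaled to all genes
            per_gene = (cursors[chrom] - config.gene_gap) // max(1, gi // config.n_chromosomes + 1)
            genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
            required = per_gene * genes_per_chrom + 2 * config.gene_gap
            raise SimulationError(
                f"chromosome length {config.chrom_length} too short for configuration; "
                f"requires at least ~{required} bp per chromosome"
            )
    for chrom, introns0, strand in pending_motifs:
        _inject_motifs(arrays[chrom], introns0, strand, rng)
    genome = {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    return GroundTruth(genome=genome, annotation=Annotation(transcripts))


def spliced_sequence(genome: dict[str, str], transcript: Transcript) -> str:
    seq = "".join(genome[transcript.chrom][s - 1 : e] for s, e in transcript.exons)
    return revcomp(seq) if transcript.strand == "-" else seq


def _transcript_interval_to_genome(
    transcript: Transcript, t_start: int, t_end: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval to ascending genomic 0-based intervals."""
    length = sum(e - s + 1 for s, e in transcript.exons)
    if transcript.strand == "-":
        t_start, t_end = length - t_end, length - t_start
    segments: list[tuple[int, int]] = []
    offset = 0
    for s, e in transcript.exons:
        exon_len = e - s + 1
        lo = max(t_start, offset)
        hi = min(t_end, offset + exon_len)
        if lo < hi:
            segments.append((s - 1 + (lo - offset), s - 1 + (hi - offset)))
        offset += exon_len
    return segments


def _segments_to_cigar(segments: list[tuple[int, int]]) -> str:
    parts = []
    for i, (s, e) in enumerate(segments):
        if i:
            parts.append(f"{s - segments[i - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _mate_truth(transcript: Transcript, t_start: int, t_end: int, is_mate1: bool) -> MateTruth:
    segments = _transcript_interval_to_genome(transcript, t_start, t_end)
    forward = (transcript.strand != "-") == is_mate1
    return MateTruth(
        chrom=transcript.chrom,
        pos=segments[0][0] + 1,
        strand="+" if forward else "-",
        cigar=_segments_to_cigar(segments),
    )


def _inject_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[int(rng.integers(len(choices)))]
    return arr.tobytes().decode("ascii")


def simulate_reads(truth: GroundTruth, config: SimConfig) -> GroundTruth:
    """Draw paired reads for each transcript and fill in the truth table.

    Fragment start positions are uniform along the spliced sequence; mates
    of ``read_length`` are taken from the fragment ends with mate2 reverse
    complemented. Transcripts are partitioned round-robin across samples.
    Transcripts shorter than the minimum fragment are skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    sample_names = [f"sample_{i + 1:02d}" for i in range(config.n_samples)]
    samples: dict[str, list[SimulatedPair]] = {name: [] for name in sample_names}
    for ti, transcript in enumerate(truth.annotation):
        sample = sample_names[ti % config.n_samples]
        spliced = spliced_sequence(truth.genome, transcript)
        length = len(spliced)
        if length < config.read_length:
            logger.warning(
                "transcript %s shorter than a read (%d bp); skipped",
                transcript.transcript_id,
                length,
            )
            continue
        n = config.reads_per_transcript
        frag_lens = np.clip(
            np.rint(rng.normal(config.fragment_mean, config.fragment_sd, size=n)).astype(int),
            config.read_length,
            length,
        )
        starts = (rng.random(n) * (length - frag_lens + 1)).astype(int)
        for i in range(n):
            fs, fl = int(starts[i]), int(frag_lens[i])
            mate1 = spliced[fs : fs + config.read_length]
            mate2 = revcomp(spliced[fs + fl - config.read_length : fs + fl])
            if config.error_rate > 0:
                mate1 = _inject_errors(mate1, config.error_rate, rng)
                mate2 = _inject_errors(mate2, config.error_rate, rng)
            read_id = f"{transcript.transcript_id}_{i + 1:06d}"
            samples[sample].append(
                SimulatedPair(
                    truth=ReadTruth(
                        read_id=read_id,
                        sample=sample,
                        transcript_id=transcript.transcript_id,
                        fragment_start=fs,
                        fragment_length=fl,
                        mate1=_mate_truth(transcript, fs, fs + config.read_length, True),
                        mate2=_mate_truth(transcript, fs + fl - config.read_length, fs + fl, False),
                    ),
                    mate1_seq=mate1,
                    mate2_seq=mate2,
                )
            )
    truth.samples = samples
    return truth


def iter_fastq_records(
    pairs: list[SimulatedPair], mate: int
) -> Iterator[tuple[str, str, str]]:
    for pair in pairs:
        seq = pair.mate1_seq if mate == 1 else pair.mate2_seq
        yield f"@{pair.truth.read_id}/{mate}", seq, "I" * len(seq)


def write_truth_table(truth: GroundTruth, path: str) -> str:
    columns = (
        "sample", "read_id", "transcript_id", "fragment_start", "fragment_length",
        "mate1_chrom", "mate1_pos", "mate1_strand", "mate1_cigar",
        "mate2_chrom", "mate2_pos", "mate2_strand", "mate2_cigar",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for sample in truth.samples:
            for pair in truth.samples[sample]:
                t = pair.truth
                fh.write(
                    "\t".join(
                        map(
                            str,
                            (
                                t.sample, t.read_id, t.transcript_id,
                                t.fragment_start, t.fragment_length,
                                t.mate1.chrom, t.mate1.pos, t.mate1.strand, t.mate1.cigar,
                                t.mate2.chrom, t.mate2.pos, t.mate2.strand, t.mate2.cigar,
                            ),
                        )
                    )
                    + "\n"
                )
    return path


def write_outputs(truth: GroundTruth, out_dir: str, compress: bool = True) -> dict[str, object]:
    """Write genome FASTA, annotation GTF, per-sample FASTQ pairs and truth table."""
    from splicebin.chunking import write_fastq

    os.makedirs(out_dir, exist_ok=True)
    genome_path = os.path.join(out_dir, "genome.fasta")
    write_fasta(truth.genome, genome_path)
    annotation_path = os.path.join(out_dir, "annotation.gtf")
    write_gtf(truth.annotation, annotation_path)
    suffix = ".fastq.gz" if compress else ".fastq"
    fastq_paths: dict[str, tuple[str, str]] = {}
    for sample, pairs in truth.samples.items():
        p1 = os.path.join(out_dir, f"{sample}_1{suffix}")
        p2 = os.path.join(out_dir, f"{sample}_2{suffix}")
        write_fastq(iter_fastq_records(pairs, 1), p1, compress=compress)
        write_fastq(iter_fastq_records(pairs, 2), p2, compress=compress)
        fastq_paths[sample] = (p1, p2)
    truth_path = write_truth_table(truth, os.path.join(out_dir, "truth.tsv"))
    manifest_path = os.path.join(out_dir, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        for sample, (p1, p2) in fastq_paths.items():
            fh.write(f"{sample}\t{p1}\t{p2}\n")
    return {
        "genome": genome_path,
        "annotation": annotation_path,
        "fastq": fastq_paths,
        "truth_table": truth_path,
        "manifest": manifest_path,
    }
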