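"""Chunk alignment, per-sample concatenation and the sequential-equivalence verifier.

The built-in ("toy") aligner is a deterministic two-seed exact matcher that
supports contiguous alignments and alignments spanning a single intron. Its
purpose is to make the chunked pipeline's equivalence guarantees testable
without external binaries: given identical input bytes it always produces
identical output, regardless of chunking, worker count or task order.
Candidate placements are tried in (chromosome, coordinate, '+' before '-')
order and the first placement that matches the genome exactly wins.

External aligner adapters (STAR / HISAT2 command templates) are provided as
untested hooks only.
"""

from __future__ import annotations

import os
import subprocess
from dataclasses import dataclass, field
from typing import Callable, Iterable

import pysam

from splicebin.chunking import ReadChunk, ReadPair
from splicebin.fasta import revcomp

# SAM flag bits used by the pipeline.
FLAG_PAIRED = 0x1
FLAG_UNMAPPED = 0x4
FLAG_MATE_UNMAPPED = 0x8
FLAG_REVERSE = 0x10
FLAG_MATE_REVERSE = 0x20
FLAG_MATE1 = 0x40
FLAG_MATE2 = 0x80

_CIGAR_CONSUMES_REF = frozenset("MDN")
_CIGAR_OPS = frozenset("MIDNS")


class AlignmentError(ValueError):
    pass


def parse_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    if cigar == "*":
        return ()
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS and num:
            ops.append((ch, int(num)))
            num = ""
        else:
            raise AlignmentError(f"bad CIGAR string {cigar!r}")
    if num:
        raise AlignmentError(f"bad CIGAR string {cigar!r}")
    return tuple(ops)


def cigar_to_string(cigar: tuple[tuple[str, int], ...]) -> str:
    if not cigar:
        return "*"
    return "".join(f"{n}{op}" for op, n in cigar)


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment record: the unit shuffled between pipeline stages.

    ``pos`` is the 1-based leftmost reference coordinate (0 for unmapped
    records, which also leave ``chrom`` unset).
    """

    qname: str
    flag: int
    chrom: str | None
    pos: int
    cigar: tuple[tuple[str, int], ...]
    seq: str = "*"
    qual: str = "*"
    mapq: int = 255

    @property
    def is_mapped(self) -> bool:
        return not self.flag & FLAG_UNMAPPED

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    @property
    def cigar_string(self) -> str:
        return cigar_to_string(self.cigar)

    def reference_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _CIGAR_CONSUMES_REF)

    def to_sam_line(self) -> str:
        rname = self.chrom if self.chrom is not None else "*"
        mapq = self.mapq if self.is_mapped else 0
        return "\t".join(
            (
                self.qname,
                str(self.flag),
                rname,
                str(self.pos),
                str(mapq),
                self.cigar_string,
                "*",
                "0",
                "0",
                self.seq,
                self.qual,
            )
        )

    @classmethod
    def from_sam_line(cls, line: str) -> "AlignmentRecord":
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise AlignmentError(f"SAM line has {len(fields)} fields, expected >= 11")
        qname, flag, rname, pos, mapq, cigar = fields[:6]
        seq, qual = fields[9], fields[10]
        chrom = None if rname == "*" else rname
        return cls(
            qname=qname,
            flag=int(flag),
            chrom=chrom,
            pos=int(pos),
            cigar=parse_cigar(cigar),
            seq=seq,
            qual=qual,
            mapq=int(mapq),
        )


@dataclass
class AlignerIndex:
    """Exact k-mer index of the forward genome used by the built-in aligner.

    Reverse-strand placements are found by querying the reverse complement
    of the read, so only forward-strand k-mer occurrences are stored.
    """

    genome: dict[str, str]
    k: int
    kmer_map: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)


def build_index(genome: dict[str, str], k: int) -> AlignerIndex:
    """Index every genomic k-mer; occurrence lists are coordinate-sorted."""
    if k <= 0:
        raise AlignmentError(f"k must be positive, got {k}")
    seen: set[str] = set()
    for name, seq in genome.items():
        if name in seen:
            raise AlignmentError(f"duplicate chromosome name {name!r}")
        seen.add(name)
        if len(seq) < k:
            raise AlignmentError(
                f"k={k} exceeds length {len(seq)} of chromosome {name!r}"
            )
        bad = set(seq) - set("ACGTN")
        if bad:
            raise AlignmentError(f"chromosome {name!r} contains invalid characters {sorted(bad)}")
    kmer_map: dict[str, list[tuple[str, int]]] = {}
    for name in genome:  # dict order is input order; appends stay sorted per chrom
        seq = genome[name]
        for i in range(len(seq) - k + 1):
            kmer_map.setdefault(seq[i : i + k], []).append((name, i))
    return AlignerIndex(genome=dict(genome), k=k, kmer_map=kmer_map)


def _place_mate(seq: str, index: AlignerIndex) -> tuple[str, int, str, tuple[tuple[str, int], ...]] | None:
    """Best deterministic placement of one mate, or None if unalignable.

    Two-seed search: the first and last k bases are looked up exactly; seed
    pairs on the same chromosome and strand with non-negative inner distance
    yield either a contiguous candidate or a single-intron candidate whose
    split point is found by scanning for the prefix+suffix exact match.
    """
    k = index.k
    n = len(seq)
    if n < k:
        return None
    candidates: list[tuple[str, int, int, str, str]] = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        hits1 = index.kmer_map.get(oriented[:k])
        hits2 = index.kmer_map.get(oriented[-k:])
        if not hits1 or not hits2:
            continue
        by_chrom: dict[str, list[int]] = {}
        for chrom, off in hits2:
            by_chrom.setdefault(chrom, []).append(off)
        for chrom, p1 in hits1:
            for p2 in by_chrom.get(chrom, ()):
                gap = p2 - p1 - (n - k)
                if gap >= 0:
                    candidates.append((chrom, p1, gap, strand, oriented))
    # Deterministic tie-break: (chrom, coordinate, '+' before '-', gap).
    candidates.sort(key=lambda c: (c[0], c[1], c[3] != "+", c[2]))
    for chrom, p1, gap, strand, oriented in candidates:
        ref = index.genome[chrom]
        if p1 + n + gap > len(ref):
            continue
        if gap == 0:
            if ref[p1 : p1 + n] == oriented:
                return chrom, p1, strand, (("M", n),)
        else:
            for split in range(k, n - k + 1):
                if (
                    ref[p1 : p1 + split] == oriented[:split]
                    and ref[p1 + split + gap : p1 + n + gap] == oriented[split:]
                ):
                    return chrom, p1, strand, (("M", split), ("N", gap), ("M", n - split))
    return None


def toy_align(pair: ReadPair, index: AlignerIndex) -> list[AlignmentRecord]:
    """Align both mates of a pair; unalignable mates become unmapped records."""
    placements = [
        _place_mate(pair.mate1_seq, index),
        _place_mate(pair.mate2_seq, index),
    ]
    records = []
    for mate_bit, placement, seq, qual in (
        (FLAG_MATE1, placements[0], pair.mate1_seq, pair.mate1_qual),
        (FLAG_MATE2, placements[1], pair.mate2_seq, pair.mate2_qual),
    ):
        other = placements[1] if mate_bit == FLAG_MATE1 else placements[0]
        flag = FLAG_PAIRED | mate_bit
        if other is None:
            flag |= FLAG_MATE_UNMAPPED
        elif other[2] == "-":
            flag |= FLAG_MATE_REVERSE
        if placement is None:
            records.append(
                AlignmentRecord(pair.read_id, flag | FLAG_UNMAPPED, None, 0, (), seq, qual, mapq=0)
            )
            continue
        chrom, p0, strand, cigar = placement
        if strand == "-":
            flag |= FLAG_REVERSE
            seq = revcomp(seq)
            qual = qual[::-1]
        records.append(AlignmentRecord(pair.read_id, flag, chrom, p0 + 1, cigar, seq, qual))
    return records


AlignFunc = Callable[[ReadPair, AlignerIndex], list[AlignmentRecord]]


@dataclass
class AlignerAdapter:
    """Contract for pluggable aligners.

    Deterministic adapters must produce identical record sets for identical
    chunk bytes and index; the chunked pipeline's equivalence guarantee only
    holds for deterministic adapters.
    """

    name: str
    deterministic: bool
    align_pair: AlignFunc | None = None
    command_template: str | None = None


BUILTIN_ADAPTER = AlignerAdapter(name="builtin", deterministic=True, align_pair=toy_align)

# Untested hooks: templates receive {index}, {fastq1}, {fastq2}, {out_prefix}.
STAR_ADAPTER = AlignerAdapter(
    name="star",
    deterministic=True,
    command_template=(
        "STAR --genomeDir {index} --readFilesIn {fastq1} {fastq2} "
        "--outSAMtype BAM Unsorted --outFileNamePrefix {out_prefix}"
    ),
)
HISAT2_ADAPTER = AlignerAdapter(
    name="hisat2",
    deterministic=True,  # requires transcriptome-mapping-only operation for determinism
    command_template="hisat2 --tmo -x {index} -1 {fastq1} -2 {fastq2} -S {out_prefix}.sam",
)

ADAPTERS = {a.name: a for a in (BUILTIN_ADAPTER, STAR_ADAPTER, HISAT2_ADAPTER)}


def run_external_adapter(
    adapter: AlignerAdapter, index_path: str, fastq1: str, fastq2: str, out_prefix: str
) -> None:  # pragma: no cover - hook for external binaries
    if adapter.command_template is None:
        raise AlignmentError(f"adapter {adapter.name!r} has no command template")
    cmd = adapter.command_template.format(
        index=index_path, fastq1=fastq1, fastq2=fastq2, out_prefix=out_prefix
    )
    subprocess.run(cmd, shell=True, check=True)


@dataclass
class ChunkAlignment:
    sample_name: str
    chunk_index: int
    records: list[AlignmentRecord]


class ChunkAlignmentError(RuntimeError):
    """Adapter failure carrying the chunk identity so the task can be retried."""

    def __init__(self, sample_name: str, chunk_index: int, cause: Exception):
        super().__init__(f"alignment of {sample_name} chunk {chunk_index} failed: {cause}")
        self.sample_name = sample_name
        self.chunk_index = chunk_index


def align_chunk(
    chunk: ReadChunk,
    index: AlignerIndex,
    adapter: AlignerAdapter = BUILTIN_ADAPTER,
) -> ChunkAlignment:
    """Align one chunk; record order is input pair order, mate1 before mate2."""
    if adapter.align_pair is None:
        raise AlignmentError(
            f"adapter {adapter.name!r} is an external hook and cannot run in-process"
        )
    records: list[AlignmentRecord] = []
    try:
        for pair in chunk.pairs:
            records.extend(adapter.align_pair(pair, index))
    except Exception as exc:  # pragma: no cover - defensive
        raise ChunkAlignmentError(chunk.sample_name, chunk.chunk_index, exc) from exc
    return ChunkAlignment(chunk.sample_name, chunk.chunk_index, records)


def sam_header_lines(genome: dict[str, str], program: str | None = "splicebin") -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in genome.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    if program:
        lines.append(f"@PG\tID:{program}\tPN:{program}")
    return lines


def write_sam(
    records: Iterable[AlignmentRecord], path: str, genome: dict[str, str], program: str | None = "splicebin"
) -> str:
    with open(path, "w") as fh:
        for line in sam_header_lines(genome, program):
            fh.write(line + "\n")
        for record in records:
            fh.write(record.to_sam_line() + "\n")
    return path


def _normalize_header(lines: list[str]) -> list[str]:
    """Drop @PG and @CO lines: run-specific, not part of the record contract."""
    return [ln for ln in lines if not ln.startswith(("@PG", "@CO"))]


def concatenate_sample(
    sample_name: str,
    chunk_paths: dict[int, str],
    out_path: str,
    delete_chunks: bool = True,
) -> str:
    """Concatenate per-chunk SAM files into one per-sample alignment file.

    The header is taken from chunk 0 with @PG/@CO lines dropped; body lines
    follow in chunk-index order. Chunks are copied in one at a time and
    deleted immediately after use, so peak temporary disk usage is bounded
    by one chunk plus the accumulated output, never by the sum of all
    unconcatenated chunks.
    """
    if not chunk_paths:
        raise AlignmentError(f"sample {sample_name}: no chunk outputs to concatenate")
    indices = sorted(chunk_paths)
    missing = sorted(set(range(indices[-1] + 1)) - set(indices))
    if missing:
        raise AlignmentError(f"sample {sample_name}: missing chunk indices {missing}")
    with open(out_path, "w") as out:
        for i, idx in enumerate(indices):
            with open(chunk_paths[idx]) as chunk_fh:
                for line in chunk_fh:
                    if line.startswith("@"):
                        if i == 0 and not line.startswith(("@PG", "@CO")):
                            out.write(line)
                        continue
                    out.write(line)
            if delete_chunks:
                os.unlink(chunk_paths[idx])
    return out_path


def _load_sam_for_diff(path: str) -> tuple[list[str], list[tuple]]:
    """Read a SAM file into (normalized header lines, sortable record keys)."""
    header_lines: list[str] = []
    keys: list[tuple] = []
    try:
        with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
            header_lines = _normalize_header(str(fh.header).rstrip("\n").split("\n"))
            for rec in fh:
                keys.append(
                    (
                        rec.query_name or "",
                        rec.flag,
                        rec.reference_name or "*",
                        rec.reference_start + 1 if rec.reference_start is not None else 0,
                        rec.cigarstring or "*",
                        rec.query_sequence or "*",
                        rec.qual or "*",
                    )
                )
    except (OSError, ValueError) as exc:
        raise AlignmentError(f"cannot parse alignment file {path}: {exc}") from exc
    return header_lines, keys


@dataclass
class EquivalenceResult:
    equivalent: bool
    detail: str | None = None
    first_divergence: tuple | None = None

    def __bool__(self) -> bool:
        return self.equivalent


def verify_equivalence(file_a: str, file_b: str) -> EquivalenceResult:
    """Name-sorted record-set comparison of two alignment files.

    Records are sorted by a total, deterministic key (name, flags, chrom,
    pos, cigar, seq, qual); headers are compared only after @PG/@CO
    normalization. Returns the first divergent record on failure.
    """
    header_a, recs_a = _load_sam_for_diff(file_a)
    header_b, recs_b = _load_sam_for_diff(file_b)
    if header_a != header_b:
        return EquivalenceResult(False, detail="headers differ after PG/CO normalization")
    recs_a.sort()
    recs_b.sort()
    if recs_a == recs_b:
        return EquivalenceResult(True)
    for i, (ra, rb) in enumerate(zip(recs_a, recs_b)):
        if ra != rb:
            return EquivalenceResult(
                False,
                detail=f"record {i} differs: {ra} vs {rb}",
                first_divergence=(ra, rb),
            )
    longer, which = (recs_a, file_a) if len(recs_a) > len(recs_b) else (recs_b, file_b)
    extra = longer[min(len(recs_a), len(recs_b))]
    return EquivalenceResult(
        False,
        detail=f"extra record in {which}: {extra}",
        first_divergence=(extra,),
    )
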