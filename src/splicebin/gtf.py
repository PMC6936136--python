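"""Transcript / annotation model and GTF I/O.

Transcripts are strand-aware chains of non-overlapping exon intervals in
1-based inclusive coordinates, grouped into gene loci. The writer emits one
``transcript`` feature line followed by its ``exon`` lines with ``gene_id``,
``transcript_id`` and (when set) ``origin_bin`` attributes; the reader
inverts this losslessly, which the merge stage relies on.

The reader/writer pair is deliberately self-contained: the pipeline's
determinism contract requires byte-stable output (fixed attribute order,
fixed float-free columns), which rules out round-tripping through a
database-backed GFF library.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

VALID_STRANDS = ("+", "-", ".")

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class GtfError(ValueError):
    pass


@dataclass(frozen=True)
class Transcript:
    """An exon-interval chain; exons are 1-based inclusive and ascending."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source: str = "assembled"  # one of: assembled, reference, merged
    origin_bin: str | None = None

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """1-based inclusive intron intervals between consecutive exons."""
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return self.introns

    @property
    def structure_key(self) -> tuple:
        return (self.chrom, self.strand, self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    def validate(self) -> None:
        if not self.exons:
            raise GtfError(f"transcript {self.transcript_id!r} has no exons")
        if self.strand not in VALID_STRANDS:
            raise GtfError(f"transcript {self.transcript_id!r}: bad strand {self.strand!r}")
        prev_end: int | None = None
        for start, end in self.exons:
            if start < 1 or end < start:
                raise GtfError(
                    f"transcript {self.transcript_id!r}: bad exon interval ({start}, {end})"
                )
            if prev_end is not None and start <= prev_end + 1:
                raise GtfError(
                    f"transcript {self.transcript_id!r}: exons out of order or overlapping "
                    f"at ({start}, {end})"
                )
            prev_end = end


@dataclass
class Annotation:
    """A flat, ordered collection of transcripts."""

    transcripts: list[Transcript] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts)

    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(t.chrom for t in self.transcripts)
        return list(seen)

    def filter_chrom(self, chrom: str) -> "Annotation":
        return Annotation([t for t in self.transcripts if t.chrom == chrom])

    def by_id(self) -> dict[str, Transcript]:
        return {t.transcript_id: t for t in self.transcripts}

    def sorted(self) -> "Annotation":
        return Annotation(
            sorted(self.transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
        )


def _format_attributes(transcript: Transcript) -> str:
    parts = [
        f'gene_id "{transcript.gene_id}"',
        f'transcript_id "{transcript.transcript_id}"',
    ]
    if transcript.origin_bin is not None:
        parts.append(f'origin_bin "{transcript.origin_bin}"')
    return "; ".join(parts) + ";"


def transcript_to_gtf_lines(transcript: Transcript) -> Iterator[str]:
    attrs = _format_attributes(transcript)
    common = (transcript.chrom, transcript.source)
    yield "\t".join(
        (*common, "transcript", str(transcript.start), str(transcript.end), ".",
         transcript.strand, ".", attrs)
    )
    for start, end in transcript.exons:
        yield "\t".join(
            (*common, "exon", str(start), str(end), ".", transcript.strand, ".", attrs)
        )


def write_gtf(annotation: Annotation | Iterable[Transcript], path: str) -> str:
    transcripts = list(annotation)
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for transcript in transcripts:
            for line in transcript_to_gtf_lines(transcript):
                fh.write(line + "\n")
    return path


def parse_gtf_lines(lines: Iterable[str]) -> Annotation:
    # exon rows are grouped by transcript_id; a transcript feature row only
    # contributes metadata (source column, origin_bin attribute).
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(lines, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GtfError(f"line {lineno}: expected 9 tab-separated columns")
        chrom, source, feature, start, end, _score, strand, _frame, attr_text = fields
        if feature not in ("transcript", "exon"):
            continue
        attrs = dict(_ATTR_RE.findall(attr_text))
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id", tid)
        if tid is None:
            raise GtfError(f"line {lineno}: missing transcript_id attribute")
        if tid not in meta:
            order.append(tid)
            meta[tid] = {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "source": source,
                "origin_bin": attrs.get("origin_bin"),
            }
        if feature == "exon":
            exons.setdefault(tid, []).append((int(start), int(end)))
    transcripts = []
    for tid in order:
        info = meta[tid]
        exon_list = sorted(exons.get(tid, []))
        if not exon_list:
            raise GtfError(f"transcript {tid!r} has no exon features")
        transcripts.append(
            Transcript(
                transcript_id=tid,
                gene_id=info["gene_id"],
                chrom=info["chrom"],
                strand=info["strand"],
                exons=tuple(exon_list),
                source=info["source"],
                origin_bin=info["origin_bin"],
            )
        )
    return Annotation(transcripts)


def read_gtf(path: str) -> Annotation:
    with open(path) as fh:
        return parse_gtf_lines(fh)


def retag(transcript: Transcript, **changes) -> Transcript:
    return replace(transcript, **changes)
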