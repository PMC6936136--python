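"""Bin-overlap redundancy removal and merging with a reference annotation.

Adjacent bins share an overlap region, so a transcript located inside that
region is assembled identically by both bins. Unlike a generic GTF merge —
which treats such exact duplicates as novel isoforms and inflates the
transcript count — the redundancy here is removed explicitly, before
merging, by keeping exactly one copy of each identical exon structure (the
copy from the lowest-ordered origin bin).
"""

from __future__ import annotations

from typing import Iterable, Sequence

from splicebin.binning import BinName
from splicebin.gtf import Annotation, Transcript, retag, write_gtf

SINGLE_EXON_OVERLAP = 0.8  # reciprocal overlap of the longer transcript


class MergeError(ValueError):
    pass


def _origin_order(transcript: Transcript) -> tuple:
    if transcript.origin_bin is None:
        return ("", -1)
    name = BinName.parse(transcript.origin_bin)
    return (name.chrom, name.index)


def remove_bin_redundancy(transcripts: Sequence[Transcript]) -> list[Transcript]:
    """Keep one transcript per identical (chrom, strand, exon chain) structure.

    The survivor is the copy from the lowest-ordered origin bin; input order
    is otherwise preserved. Idempotent, and never drops the last copy of a
    structure.
    """
    best: dict[tuple, Transcript] = {}
    for transcript in transcripts:
        key = transcript.structure_key
        held = best.get(key)
        if held is None or _origin_order(transcript) < _origin_order(held):
            best[key] = transcript
    kept = set(map(id, best.values()))
    return [t for t in transcripts if id(t) in kept]


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _single_exon_match(query: Transcript, ref: Transcript) -> bool:
    """>= 80% overlap relative to the longer of the two single-exon transcripts."""
    qs, qe = query.exons[0]
    rs, re_ = ref.exons[0]
    overlap = min(qe, re_) - max(qs, rs) + 1
    if overlap <= 0:
        return False
    longer = max(qe - qs + 1, re_ - rs + 1)
    return overlap * 5 >= longer * 4  # exact integer form of overlap/longer >= 0.8


def merge_with_reference(
    assembled: Iterable[Transcript], reference: Annotation
) -> Annotation:
    """Merge assembled transcripts into the reference annotation.

    Every reference transcript is kept unchanged. An assembled multi-exon
    transcript is absorbed when a reference transcript shares its
    (chromosome, strand, intron chain); an assembled single-exon transcript
    is absorbed by a same-strand (or unknown-strand) reference single-exon
    transcript at >= 80% reciprocal overlap of the longer. Everything else
    is added as novel with fresh ids, attached to an overlapping same-strand
    reference gene when one exists. Output is sorted by
    (chrom, start, transcript_id).
    """
    ref_transcripts = list(reference)
    for t in ref_transcripts:
        t.validate()

    chain_index: dict[tuple, list[str]] = {}
    single_index: dict[str, list[Transcript]] = {}
    gene_extent: dict[str, tuple[str, str, int, int]] = {}
    for t in ref_transcripts:
        if t.is_multi_exon:
            chain_index.setdefault((t.chrom, t.introns), []).append(t.strand)
        else:
            single_index.setdefault(t.chrom, []).append(t)
        chrom, strand, lo, hi = gene_extent.get(t.gene_id, (t.chrom, t.strand, t.start, t.end))
        gene_extent[t.gene_id] = (chrom, strand, min(lo, t.start), max(hi, t.end))

    novel: list[Transcript] = []
    for t in assembled:
        t.validate()
        if t.is_multi_exon:
            strands = chain_index.get((t.chrom, t.introns), [])
            if any(_strands_compatible(t.strand, s) for s in strands):
                continue  # absorbed
        else:
            if any(
                _strands_compatible(t.strand, r.strand) and _single_exon_match(t, r)
                for r in single_index.get(t.chrom, [])
            ):
                continue  # absorbed
        novel.append(t)

    novel.sort(key=lambda t: (t.chrom, t.start, t.end, t.exons, t.strand))
    merged: list[Transcript] = [t for t in ref_transcripts]
    new_gene_counter = 0
    for i, t in enumerate(novel, 1):
        gene_id = None
        for gid, (chrom, strand, lo, hi) in gene_extent.items():
            if chrom == t.chrom and _strands_compatible(t.strand, strand):
                if t.start <= hi and t.end >= lo:
                    gene_id = gid
                    break
        if gene_id is None:
            new_gene_counter += 1
            gene_id = f"novel_gene_{new_gene_counter:05d}"
        merged.append(
            retag(
                t,
                transcript_id=f"novel_{i:05d}",
                gene_id=gene_id,
                source="merged",
            )
        )
    return Annotation(merged).sorted()


def write_updated_annotation(merged: Annotation, destination: str) -> str:
    """Write the merged annotation as GTF; round-trips losslessly."""
    try:
        return write_gtf(merged, destination)
    except OSError as exc:
        raise MergeError(f"cannot write annotation to {destination!r}: {exc}") from exc
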