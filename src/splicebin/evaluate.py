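"""Six-level sensitivity/precision comparison of a query annotation to a reference.

Levels: base, exon, intron, intron chain, transcript, locus. Sensitivity is
matched reference features over total reference features; precision is
matched query features over total query features. Matching rules:

* base — exonic base positions (union over transcripts, strand-agnostic);
* exon / intron — distinct exact intervals (strand-agnostic);
* intron chain — distinct full ordered chains, strands compatible
  (identical, or one side unknown);
* transcript — a multi-exon transcript matches iff a reference transcript
  carries the same intron chain; a single-exon transcript matches iff it has
  >= 80% reciprocal overlap (of the longer) with a reference single-exon
  transcript. The query side counts transcript *records* but an exact
  duplicate structure is only credited once, so redundant copies lower
  precision; the chain level counts distinct chains.
* locus — transcripts clustered by exonic overlap (single linkage); a
  reference locus is matched iff it contains a matched reference
  transcript, a query locus is correct iff it contains a matched query
  transcript.

Ratios with empty denominators are reported as undefined (``None`` /
``"NA"``), never as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from splicebin.gtf import Annotation, Transcript

LEVELS = ("base", "exon", "intron", "intron_chain", "transcript", "locus")

_LEVEL_LABELS = {
    "base": "Base",
    "exon": "Exon",
    "intron": "Intron",
    "intron_chain": "Intron Chain",
    "transcript": "Transcript",
    "locus": "Locus",
}
_LABEL_LEVELS = {v: k for k, v in _LEVEL_LABELS.items()}


@dataclass(frozen=True)
class LevelStats:
    matched_ref: int
    ref_total: int
    matched_query: int
    query_total: int

    @property
    def sensitivity(self) -> float | None:
        if self.ref_total == 0:
            return None
        return 100.0 * self.matched_ref / self.ref_total

    @property
    def precision(self) -> float | None:
        if self.query_total == 0:
            return None
        return 100.0 * self.matched_query / self.query_total


@dataclass
class EvalReport:
    levels: dict[str, LevelStats]

    def sensitivity(self, level: str) -> float | None:
        return self.levels[level].sensitivity

    def precision(self, level: str) -> float | None:
        return self.levels[level].precision

    def to_dict(self) -> dict:
        return {
            level: {
                "sensitivity": stats.sensitivity,
                "precision": stats.precision,
                "matched_ref": stats.matched_ref,
                "reference_total": stats.ref_total,
                "matched_query": stats.matched_query,
                "query_total": stats.query_total,
            }
            for level, stats in self.levels.items()
        }


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of 1-based inclusive intervals as a sorted disjoint list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _interval_total(intervals: Sequence[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in intervals)


def _intersection_total(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo <= hi:
            total += hi - lo + 1
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _exonic_union_by_chrom(annotation: Annotation) -> dict[str, list[tuple[int, int]]]:
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in annotation:
        per_chrom.setdefault(t.chrom, []).extend(t.exons)
    return {chrom: _merge_intervals(ivs) for chrom, ivs in per_chrom.items()}


def _base_stats(query: Annotation, reference: Annotation) -> LevelStats:
    q_union = _exonic_union_by_chrom(query)
    r_union = _exonic_union_by_chrom(reference)
    q_total = sum(_interval_total(ivs) for ivs in q_union.values())
    r_total = sum(_interval_total(ivs) for ivs in r_union.values())
    shared = sum(
        _intersection_total(q_union[c], r_union[c]) for c in q_union.keys() & r_union.keys()
    )
    return LevelStats(shared, r_total, shared, q_total)


def _interval_set_stats(
    query_items: set, reference_items: set
) -> LevelStats:
    shared = len(query_items & reference_items)
    return LevelStats(shared, len(reference_items), shared, len(query_items))


def _strands_compatible(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def _chain_key(t: Transcript) -> tuple:
    return (t.chrom, t.introns)


def _chain_stats(query: Annotation, reference: Annotation) -> LevelStats:
    q_chains = {(t.chrom, t.strand, t.introns) for t in query if t.is_multi_exon}
    r_chains = {(t.chrom, t.strand, t.introns) for t in reference if t.is_multi_exon}
    q_by_key: dict[tuple, set[str]] = {}
    for chrom, strand, introns in q_chains:
        q_by_key.setdefault((chrom, introns), set()).add(strand)
    r_by_key: dict[tuple, set[str]] = {}
    for chrom, strand, introns in r_chains:
        r_by_key.setdefault((chrom, introns), set()).add(strand)
    matched_ref = sum(
        1
        for chrom, strand, introns in r_chains
        if any(_strands_compatible(strand, s) for s in q_by_key.get((chrom, introns), ()))
    )
    matched_query = sum(
        1
        for chrom, strand, introns in q_chains
        if any(_strands_compatible(strand, s) for s in r_by_key.get((chrom, introns), ()))
    )
    return LevelStats(matched_ref, len(r_chains), matched_query, len(q_chains))


def single_exon_overlap_fraction(a: Transcript, b: Transcript) -> float:
    """Overlap length over the longer of two single-exon transcripts."""
    (as_, ae), (bs, be) = a.exons[0], b.exons[0]
    overlap = min(ae, be) - max(as_, bs) + 1
    if overlap <= 0:
        return 0.0
    return overlap / max(ae - as_ + 1, be - bs + 1)


def transcripts_match(query: Transcript, ref: Transcript) -> bool:
    """The transcript-level matching rule (chain identity or 80% single-exon)."""
    if query.chrom != ref.chrom or not _strands_compatible(query.strand, ref.strand):
        return False
    if query.is_multi_exon or ref.is_multi_exon:
        return (
            query.is_multi_exon
            and ref.is_multi_exon
            and query.introns == ref.introns
        )
    (qs, qe), (rs, re_) = query.exons[0], ref.exons[0]
    overlap = min(qe, re_) - max(qs, rs) + 1
    if overlap <= 0:
        return False
    longer = max(qe - qs + 1, re_ - rs + 1)
    return overlap * 5 >= longer * 4


def _transcript_matches(
    query: Annotation, reference: Annotation
) -> tuple[list[bool], list[bool]]:
    """Per-record match flags for (query records, reference records)."""
    ref_by_chrom: dict[str, list[Transcript]] = {}
    for t in reference:
        ref_by_chrom.setdefault(t.chrom, []).append(t)
    q_matched = []
    r_matched_ids: set[int] = set()
    for q in query:
        hit = False
        for i, r in enumerate(reference):
            if transcripts_match(q, r):
                hit = True
                r_matched_ids.add(i)
        q_matched.append(hit)
    r_matched = [i in r_matched_ids for i in range(len(reference.transcripts))]
    return q_matched, r_matched


def _transcript_stats(
    query: Annotation, q_matched: Sequence[bool], reference: Annotation, r_matched: Sequence[bool]
) -> LevelStats:
    # Credit each exact query structure once: extra identical copies are
    # redundant records and count against precision.
    seen: set[tuple] = set()
    matched_query = 0
    for t, hit in zip(query, q_matched):
        if hit and t.structure_key not in seen:
            seen.add(t.structure_key)
            matched_query += 1
    return LevelStats(sum(r_matched), len(reference), matched_query, len(query))


def _cluster_loci(annotation: Annotation) -> list[list[int]]:
    """Single-linkage clusters of transcript indices by exonic overlap."""
    events: list[tuple[str, int, int, int]] = []
    for idx, t in enumerate(annotation):
        for s, e in t.exons:
            events.append((t.chrom, s, e, idx))
    events.sort()
    parent = list(range(len(annotation.transcripts)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    active_chrom: str | None = None
    active: list[tuple[int, int]] = []  # (end, idx) of intervals still open
    for chrom, s, e, idx in events:
        if chrom != active_chrom:
            active_chrom, active = chrom, []
        active = [(end, other) for end, other in active if end >= s]
        for _end, other in active:
            union(idx, other)
        active.append((e, idx))
    clusters: dict[int, list[int]] = {}
    for idx in range(len(annotation.transcripts)):
        clusters.setdefault(find(idx), []).append(idx)
    return list(clusters.values())


def _locus_stats(
    query: Annotation, q_matched: Sequence[bool], reference: Annotation, r_matched: Sequence[bool]
) -> LevelStats:
    r_loci = _cluster_loci(reference)
    q_loci = _cluster_loci(query)
    matched_ref = sum(1 for locus in r_loci if any(r_matched[i] for i in locus))
    matched_query = sum(1 for locus in q_loci if any(q_matched[i] for i in locus))
    return LevelStats(matched_ref, len(r_loci), matched_query, len(q_loci))


def compare(query: Annotation, reference: Annotation) -> EvalReport:
    """Six-level sensitivity/precision report of query against reference."""
    exon_stats = _interval_set_stats(
        {(t.chrom, s, e) for t in query for s, e in t.exons},
        {(t.chrom, s, e) for t in reference for s, e in t.exons},
    )
    intron_stats = _interval_set_stats(
        {(t.chrom, s, e) for t in query for s, e in t.introns},
        {(t.chrom, s, e) for t in reference for s, e in t.introns},
    )
    q_matched, r_matched = _transcript_matches(query, reference)
    return EvalReport(
        levels={
            "base": _base_stats(query, reference),
            "exon": exon_stats,
            "intron": intron_stats,
            "intron_chain": _chain_stats(query, reference),
            "transcript": _transcript_stats(query, q_matched, reference, r_matched),
            "locus": _locus_stats(query, q_matched, reference, r_matched),
        }
    )


def _format_cell(value: float | None) -> str:
    return "NA" if value is None else f"{value:.1f}"


def report_to_text(report: EvalReport) -> str:
    """Six-row table of sensitivity/precision percentages, one decimal place."""
    lines = [f"{'Feature':<14}{'Sensitivity (%)':>17}{'Precision (%)':>15}"]
    for level in LEVELS:
        stats = report.levels[level]
        lines.append(
            f"{_LEVEL_LABELS[level]:<14}"
            f"{_format_cell(stats.sensitivity):>17}"
            f"{_format_cell(stats.precision):>15}"
        )
    return "\n".join(lines) + "\n"


def parse_report_text(text: str) -> dict[str, tuple[float | None, float | None]]:
    """Invert :func:`report_to_text` (values rounded to one decimal)."""
    values: dict[str, tuple[float | None, float | None]] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        label = line[:14].strip()
        cells = line[14:].split()
        if label not in _LABEL_LEVELS or len(cells) != 2:
            raise ValueError(f"unparseable report line {line!r}")
        sens, prec = (None if c == "NA" else float(c) for c in cells)
        values[_LABEL_LEVELS[label]] = (sens, prec)
    return values


def report_to_tsv(report: EvalReport) -> str:
    lines = ["level\tsensitivity\tprecision\tmatched_ref\treference_total\tmatched_query\tquery_total"]
    for level in LEVELS:
        s = report.levels[level]
        lines.append(
            "\t".join(
                (
                    level,
                    _format_cell(s.sensitivity),
                    _format_cell(s.precision),
                    str(s.matched_ref),
                    str(s.ref_total),
                    str(s.matched_query),
                    str(s.query_total),
                )
            )
        )
    return "\n".join(lines) + "\n"
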