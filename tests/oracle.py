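"""Independent naive oracles used to cross-check the package implementations.

Everything here is deliberately brute-force (position sets, all-pairs loops,
fixed-point clustering) and shares no code with the implementations it
checks.
"""

from __future__ import annotations

import numpy as np

from splicebin.gtf import Annotation, Transcript


# ---------------------------------------------------------------------------
# naive six-level evaluator


def _compatible(a: str, b: str) -> bool:
    return a == b or "." in (a, b)


def _tx_match(q: Transcript, r: Transcript) -> bool:
    if q.chrom != r.chrom or not _compatible(q.strand, r.strand):
        return False
    if len(q.exons) > 1 or len(r.exons) > 1:
        return len(q.exons) > 1 and len(r.exons) > 1 and q.introns == r.introns
    positions_q = set(range(q.exons[0][0], q.exons[0][1] + 1))
    positions_r = set(range(r.exons[0][0], r.exons[0][1] + 1))
    overlap = len(positions_q & positions_r)
    longer = max(len(positions_q), len(positions_r))
    return overlap / longer >= 0.8


def _naive_loci(transcripts: list[Transcript]) -> list[set[int]]:
    clusters: list[tuple[set[int], set[tuple[str, int]]]] = []
    for idx, t in enumerate(transcripts):
        bases = {(t.chrom, p) for s, e in t.exons for p in range(s, e + 1)}
        clusters.append(({idx}, bases))
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                if clusters[i][1] & clusters[j][1]:
                    clusters[i] = (
                        clusters[i][0] | clusters[j][0],
                        clusters[i][1] | clusters[j][1],
                    )
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return [members for members, _ in clusters]


def naive_compare(query: Annotation, reference: Annotation) -> dict[str, dict]:
    """All-pairs O(n^2) re-derivation of the six-level report counts."""
    q = list(query)
    r = list(reference)

    q_bases = {(t.chrom, p) for t in q for s, e in t.exons for p in range(s, e + 1)}
    r_bases = {(t.chrom, p) for t in r for s, e in t.exons for p in range(s, e + 1)}

    q_exons = {(t.chrom, s, e) for t in q for s, e in t.exons}
    r_exons = {(t.chrom, s, e) for t in r for s, e in t.exons}
    q_introns = {(t.chrom, s, e) for t in q for s, e in t.introns}
    r_introns = {(t.chrom, s, e) for t in r for s, e in t.introns}

    q_chains = {(t.chrom, t.strand, t.introns) for t in q if len(t.exons) > 1}
    r_chains = {(t.chrom, t.strand, t.introns) for t in r if len(t.exons) > 1}
    matched_r_chains = sum(
        1
        for (rc, rs, ri) in r_chains
        if any(qc == rc and qi == ri and _compatible(qs, rs) for (qc, qs, qi) in q_chains)
    )
    matched_q_chains = sum(
        1
        for (qc, qs, qi) in q_chains
        if any(qc == rc and qi == ri and _compatible(qs, rs) for (rc, rs, ri) in r_chains)
    )

    q_hit = [any(_tx_match(t, rt) for rt in r) for t in q]
    r_hit = [any(_tx_match(qt, t) for qt in q) for t in r]
    seen_structures = set()
    matched_q_tx = 0
    for t, hit in zip(q, q_hit):
        key = (t.chrom, t.strand, t.exons)
        if hit and key not in seen_structures:
            seen_structures.add(key)
            matched_q_tx += 1

    r_loci = _naive_loci(r)
    q_loci = _naive_loci(q)

    return {
        "base": {
            "matched_ref": len(q_bases & r_bases),
            "ref_total": len(r_bases),
            "matched_query": len(q_bases & r_bases),
            "query_total": len(q_bases),
        },
        "exon": {
            "matched_ref": len(q_exons & r_exons),
            "ref_total": len(r_exons),
            "matched_query": len(q_exons & r_exons),
            "query_total": len(q_exons),
        },
        "intron": {
            "matched_ref": len(q_introns & r_introns),
            "ref_total": len(r_introns),
            "matched_query": len(q_introns & r_introns),
            "query_total": len(q_introns),
        },
        "intron_chain": {
            "matched_ref": matched_r_chains,
            "ref_total": len(r_chains),
            "matched_query": matched_q_chains,
            "query_total": len(q_chains),
        },
        "transcript": {
            "matched_ref": sum(r_hit),
            "ref_total": len(r),
            "matched_query": matched_q_tx,
            "query_total": len(q),
        },
        "locus": {
            "matched_ref": sum(1 for locus in r_loci if any(r_hit[i] for i in locus)),
            "ref_total": len(r_loci),
            "matched_query": sum(1 for locus in q_loci if any(q_hit[i] for i in locus)),
            "query_total": len(q_loci),
        },
    }


def random_annotation(
    rng: np.random.Generator, max_transcripts: int = 6, ensure_multi_exon: bool = False
) -> Annotation:
    """Small random annotation with frequent overlaps between draws."""
    transcripts = []
    n = int(rng.integers(1, max_transcripts + 1))
    for i in range(n):
        chrom = f"chr{int(rng.integers(1, 3))}"
        strand = ["+", "-", "."][int(rng.integers(3))]
        n_exons = int(rng.integers(2 if ensure_multi_exon and i == 0 else 1, 4))
        pos = int(rng.integers(1, 1500))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(10, 200))
            exons.append((pos, pos + length - 1))
            pos += length + int(rng.integers(5, 100))
        transcripts.append(
            Transcript(
                transcript_id=f"rt{i}",
                gene_id=f"rg{i}",
                chrom=chrom,
                strand=strand,
                exons=tuple(exons),
            )
        )
    return Annotation(transcripts)


# ---------------------------------------------------------------------------
# brute-force bin assignment


def brute_force_bins(span: tuple[int, int], bin_size: int, overlap: int, chrom_len: int) -> list[int]:
    """All bin indices whose interval intersects the span, by direct scan."""
    import math

    n_bins = max(1, math.ceil(chrom_len / bin_size))
    hits = []
    for i in range(n_bins):
        b_start = i * bin_size
        b_end = min((i + 1) * bin_size + overlap, chrom_len)
        if b_start < span[1] and span[0] < b_end:
            hits.append(i)
    return hits
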