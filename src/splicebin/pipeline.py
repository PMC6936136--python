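"""End-to-end drivers for alignment mode and assembly mode.

Parallelism is a pool of independent tasks over chunks or bins whose results
are merged in key order, so every output is invariant under worker count and
task completion order. The pipeline itself uses no randomness. Stage
boundaries exchange serialized files under the work directory and each
completed stage leaves a ``.done`` marker with its input/output counts, so a
crashed run resumes from the last completed stage and conservation
invariants are auditable after the fact.
"""

from __future__ import annotations

import json
import logging
import os
import random
import shutil
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, fields
from typing import Callable, Sequence, TypeVar

import yaml

from splicebin import align as al
from splicebin import assembly as asm
from splicebin import binning as bn
from splicebin.chunking import ReadChunk, SampleManifest, split_sample, write_chunk
from splicebin.evaluate import EvalReport, compare, report_to_text, report_to_tsv
from splicebin.fasta import load_fasta
from splicebin.gtf import read_gtf, write_gtf
from splicebin.merge import merge_with_reference, remove_bin_redundancy, write_updated_annotation

logger = logging.getLogger(__name__)

T = TypeVar("T")
R = TypeVar("R")

OVERSIZED_BIN_REMEDIATIONS = (
    "split the samples into smaller batches and merge the per-batch assemblies",
    "increase the memory available to each worker",
    "run alignment-only mode first, then assemble the merged per-sample alignments",
)


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    chunk_size: int = 65536
    k: int = 25
    bin_size: int = bn.DEFAULT_BIN_SIZE
    bin_overlap: int = bn.DEFAULT_BIN_OVERLAP
    workers: int = 1
    aligner: str = "builtin"
    min_cov: float = 1.0
    min_junction_support: int = 1
    max_paths_per_component: int = 64
    max_records_per_bin: int | None = None
    guided: bool = False
    run_comparison: bool = False
    shuffle_tasks_seed: int | None = None  # test hook: scheduling order must not matter

    def assembly_params(self) -> asm.AssemblyParams:
        return asm.AssemblyParams(
            min_cov=self.min_cov,
            min_junction_support=self.min_junction_support,
            max_paths_per_component=self.max_paths_per_component,
        )

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def run_tasks(
    fn: Callable[[T], R], items: Sequence[T], workers: int, shuffle_seed: int | None = None
) -> list[R]:
    """Run independent tasks and return results in input order.

    ``shuffle_seed`` scrambles submission order (a test hook proving that
    scheduling order cannot influence output).
    """
    order = list(range(len(items)))
    if shuffle_seed is not None:
        random.Random(shuffle_seed).shuffle(order)
    results: list = [None] * len(items)
    if workers <= 1:
        for i in order:
            results[i] = fn(items[i])
        return results
    with ThreadPoolExecutor(max_workers=workers) as pool:
        futures = {pool.submit(fn, items[i]): i for i in order}
        for future, i in futures.items():
            results[i] = future.result()
    return results


def _stage_marker(work_dir: str, stage: str) -> str:
    return os.path.join(work_dir, f"stage_{stage}.done")


def _stage_done(work_dir: str, stage: str) -> bool:
    return os.path.exists(_stage_marker(work_dir, stage))


def _mark_stage(work_dir: str, stage: str, counts: dict) -> None:
    logger.info("stage %s complete: %s", stage, counts)
    with open(_stage_marker(work_dir, stage), "w") as fh:
        json.dump({"stage": stage, **counts}, fh)


def _split_all(
    manifests: Sequence[SampleManifest], config: PipelineConfig, chunk_dir: str
) -> dict[str, list[str]]:
    os.makedirs(chunk_dir, exist_ok=True)
    paths: dict[str, list[str]] = {}
    for manifest in manifests:
        chunks = split_sample(manifest, config.chunk_size)
        paths[manifest.sample_name] = [write_chunk(c, chunk_dir) for c in chunks]
    return paths


def _align_chunks(
    chunks: Sequence[ReadChunk], index: al.AlignerIndex, config: PipelineConfig
) -> list[al.ChunkAlignment]:
    adapter = al.ADAPTERS[config.aligner]
    if not adapter.deterministic:
        raise PipelineError(f"adapter {adapter.name!r} is not deterministic")
    return run_tasks(
        lambda chunk: al.align_chunk(chunk, index, adapter),
        chunks,
        config.workers,
        config.shuffle_tasks_seed,
    )


def run_alignment_mode(
    manifests: Sequence[SampleManifest],
    genome_path: str,
    config: PipelineConfig,
    out_dir: str,
) -> dict[str, str]:
    """Chunk, align and concatenate every sample; one SAM file per sample.

    Output is invariant under worker count and scheduling order. A chunk
    failure aborts that sample and leaves a resumable state file naming the
    chunks already aligned.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome = load_fasta(genome_path)
    index = al.build_index(genome, config.k)
    tmp_dir = os.path.join(out_dir, "tmp_chunks")
    os.makedirs(tmp_dir, exist_ok=True)
    outputs: dict[str, str] = {}
    failures: list[str] = []
    for manifest in manifests:
        chunks = split_sample(manifest, config.chunk_size)
        sample = manifest.sample_name
        out_path = os.path.join(out_dir, f"{sample}.sam")
        if not chunks:
            al.write_sam([], out_path, genome, program=None)
            outputs[sample] = out_path
            continue
        chunk_paths: dict[int, str] = {}
        try:
            aligned = _align_chunks(chunks, index, config)
            for result in aligned:
                path = os.path.join(tmp_dir, f"{sample}.chunk{result.chunk_index}.sam")
                al.write_sam(result.records, path, genome)
                chunk_paths[result.chunk_index] = path
            al.concatenate_sample(sample, chunk_paths, out_path)
            outputs[sample] = out_path
        except Exception as exc:
            state_path = os.path.join(out_dir, f"{sample}.state.json")
            with open(state_path, "w") as fh:
                json.dump(
                    {
                        "sample": sample,
                        "completed_chunks": sorted(chunk_paths),
                        "total_chunks": len(chunks),
                        "error": str(exc),
                    },
                    fh,
                )
            logger.error("sample %s failed: %s (state in %s)", sample, exc, state_path)
            failures.append(sample)
    shutil.rmtree(tmp_dir, ignore_errors=True)
    if failures:
        raise PipelineError(f"alignment failed for samples: {failures}")
    return outputs


@dataclass
class AssemblyModeResult:
    assembled_path: str
    updated_path: str | None
    report: EvalReport | None
    work_dir: str
    outputs: dict[str, str] = field(default_factory=dict)


def run_assembly_mode(
    manifests: Sequence[SampleManifest],
    genome_path: str,
    config: PipelineConfig,
    out_dir: str,
    reference_annotation_path: str | None = None,
) -> AssemblyModeResult:
    """Chunk -> align -> bin -> assemble -> dedup -> merge -> (optional) compare.

    Reads from all samples are pooled before binning. Without a reference
    annotation the merge step is skipped and the raw deduplicated assembly
    is emitted. The final GTF is deterministic under parallelism.
    """
    os.makedirs(out_dir, exist_ok=True)
    genome = load_fasta(genome_path)
    reference = read_gtf(reference_annotation_path) if reference_annotation_path else None
    scheme = bn.BinScheme(
        bin_size=config.bin_size,
        overlap=config.bin_overlap,
        chrom_lengths={name: len(seq) for name, seq in genome.items()},
    )

    bins_dir = os.path.join(out_dir, "bins")
    if not _stage_done(out_dir, "binning"):
        index = al.build_index(genome, config.k)
        all_chunks: list[ReadChunk] = []
        for manifest in manifests:
            all_chunks.extend(split_sample(manifest, config.chunk_size))
        aligned = _align_chunks(all_chunks, index, config)
        n_records = sum(len(c.records) for c in aligned)
        emissions: list[tuple[bn.BinName, al.AlignmentRecord]] = []
        for chunk_result in aligned:
            emissions.extend(bn.emit_binned(chunk_result.records, scheme))
        groups = bn.partition_records(emissions)
        os.makedirs(bins_dir, exist_ok=True)
        for name, records in groups.items():
            path = os.path.join(bins_dir, f"{name.chrom}__{name.index}.sam")
            with open(path, "w") as fh:
                for record in records:
                    fh.write(record.to_sam_line() + "\n")
        _mark_stage(
            out_dir,
            "binning",
            {
                "aligned_records": n_records,
                "binned_emissions": len(emissions),
                "bins": len(groups),
            },
        )

    assembled_path = os.path.join(out_dir, "assembled.gtf")
    if not _stage_done(out_dir, "assembly"):
        bin_files = sorted(os.listdir(bins_dir))
        params = config.assembly_params()

        def assemble_one(file_name: str) -> tuple[bn.BinName, list]:
            chrom, _, idx = file_name[: -len(".sam")].rpartition("__")
            name = bn.BinName(chrom, int(idx))
            with open(os.path.join(bins_dir, file_name)) as fh:
                records = [al.AlignmentRecord.from_sam_line(line) for line in fh]
            if config.max_records_per_bin is not None and len(records) > config.max_records_per_bin:
                remedies = "; ".join(OVERSIZED_BIN_REMEDIATIONS)
                raise PipelineError(
                    f"bin {name} holds {len(records)} records, above the configured cap "
                    f"{config.max_records_per_bin}. Possible remediations: {remedies}"
                )
            partial = (
                asm.filter_annotation_for_bin(reference, name)
                if (config.guided and reference is not None)
                else None
            )
            transcripts = asm.assemble_bin(
                records, genome, params, partial, origin_bin=name, scheme=scheme
            )
            return name, transcripts

        results = run_tasks(
            assemble_one, bin_files, config.workers, config.shuffle_tasks_seed
        )
        per_bin = dict(results)
        collected = asm.collect_transcripts(per_bin)
        deduped = remove_bin_redundancy(collected)
        write_gtf(deduped, assembled_path)
        _mark_stage(
            out_dir,
            "assembly",
            {"collected": len(collected), "deduplicated": len(deduped)},
        )

    updated_path: str | None = None
    if reference is not None:
        updated_path = os.path.join(out_dir, "updated.gtf")
        if not _stage_done(out_dir, "merge"):
            assembled = read_gtf(assembled_path)
            merged = merge_with_reference(assembled.transcripts, reference)
            write_updated_annotation(merged, updated_path)
            _mark_stage(out_dir, "merge", {"merged": len(merged)})

    report: EvalReport | None = None
    outputs: dict[str, str] = {"assembled": assembled_path}
    if updated_path:
        outputs["updated"] = updated_path
    if config.run_comparison and reference is not None and updated_path:
        merged = read_gtf(updated_path)
        report = compare(merged, reference)
        report_txt = os.path.join(out_dir, "comparison.txt")
        with open(report_txt, "w") as fh:
            fh.write(report_to_text(report))
        report_tsv = os.path.join(out_dir, "comparison.tsv")
        with open(report_tsv, "w") as fh:
            fh.write(report_to_tsv(report))
        outputs["comparison"] = report_txt
    return AssemblyModeResult(
        assembled_path=assembled_path,
        updated_path=updated_path,
        report=report,
        work_dir=out_dir,
        outputs=outputs,
    )
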