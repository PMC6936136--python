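import os
import sys

import pytest

sys.path.insert(0, os.path.dirname(__file__))

from splicebin.align import build_index, toy_align
from splicebin.chunking import ReadPair, load_manifest
from splicebin.simulate import (
    SimConfig,
    simulate_genome_and_annotation,
    simulate_reads,
    write_outputs,
)

TINY_CONFIG = SimConfig(
    n_chromosomes=1,
    chrom_length=60_000,
    n_genes=4,
    isoforms_per_gene=2,
    exons_per_transcript=(2, 3),
    exon_length=(120, 200),
    intron_length=(60, 120),
    reads_per_transcript=120,
    seed=11,
    n_samples=2,
)


@pytest.fixture(scope="session")
def tiny_truth():
    return simulate_reads(simulate_genome_and_annotation(TINY_CONFIG), TINY_CONFIG)


@pytest.fixture(scope="session")
def tiny_index(tiny_truth):
    return build_index(tiny_truth.genome, k=25)


@pytest.fixture(scope="session")
def tiny_outputs(tiny_truth, tmp_path_factory):
    out_dir = tmp_path_factory.mktemp("sim")
    return write_outputs(tiny_truth, str(out_dir), compress=True)


@pytest.fixture(scope="session")
def tiny_manifests(tiny_outputs):
    return load_manifest(tiny_outputs["manifest"])


@pytest.fixture(scope="session")
def tiny_aligned(tiny_truth, tiny_index):
    """All samples' records aligned single-pass, keyed by sample."""
    per_sample = {}
    for sample, pairs in tiny_truth.samples.items():
        records = []
        for p in pairs:
            rp = ReadPair(
                p.truth.read_id,
                p.mate1_seq,
                "I" * len(p.mate1_seq),
                p.mate2_seq,
                "I" * len(p.mate2_seq),
            )
            records.extend(toy_align(rp, tiny_index))
        per_sample[sample] = records
    return per_sample


@pytest.fixture(scope="session")
def tiny_mapped(tiny_aligned):
    return [r for records in tiny_aligned.values() for r in records if r.is_mapped]
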