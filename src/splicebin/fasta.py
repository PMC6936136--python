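"""FASTA I/O helpers built on Biopython."""

from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def load_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into an ordered chrom -> uppercase sequence map."""
    genome: dict[str, str] = {}
    for record in SeqIO.parse(path, "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name {record.id!r} in {path}")
        genome[record.id] = str(record.seq).upper()
    return genome


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")
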