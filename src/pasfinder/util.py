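"""Small sequence and file helpers shared across the pipeline."""

from __future__ import annotations

from typing import Dict, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str) -> Dict[str, str]:
    """Load a FASTA file into a {name: sequence} dict (uppercased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str) -> Iterable[SeqRecord]:
    return SeqIO.parse(path, "fastq")


def write_fastq(records: Iterable[SeqRecord], path: str) -> int:
    return SeqIO.write(records, path, "fastq")


def make_read(read_id: str, seq: str, qual: int = 40) -> SeqRecord:
    """Build a FASTQ-ready record with a flat quality string."""
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [qual] * len(seq)
    return rec
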