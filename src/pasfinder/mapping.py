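"""Alignment records for trimmed reads: SAM ingestion and a naive test mapper.

In production the trimmed polyadenylated reads are aligned by an external
aligner and imported from SAM/BAM; only uniquely mapped reads proceed to
cleavage-site inference.  For self-contained tests this module also provides
an exhaustive seed-and-extend mapper over small genomes (pigeonhole split of
the read into ``max_mismatches + 1`` chunks; a hit with at most that many
substitutions must match one chunk exactly).  Coordinates are 0-based
half-open internally; SAM's 1-based convention is converted at the boundary.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pysam
from Bio.SeqRecord import SeqRecord

from .tails import TailCall
from .util import revcomp

SEED_K = 10


@dataclass(frozen=True)
class AlignmentRecord:
    """One placement of a trimmed read on the genome.

    ``unique`` is True only when exactly one best-scoring locus exists.
    ``tail_side``/``tail_base`` carry the read-relative tail geometry from
    the originating :class:`~pasfinder.tails.TailCall`.
    """

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    n_mismatches: int
    unique: bool
    tail_side: Optional[str] = None
    tail_base: Optional[str] = None


class GenomeIndex:
    """Exact k-mer index over a small genome, for the naive mapper."""

    def __init__(self, genome: Mapping[str, str], k: int = SEED_K):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self.index: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((chrom, i))

    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def naive_map(
    reads: Iterable[SeqRecord],
    genome: Mapping[str, str] | GenomeIndex,
    max_mismatches: int = 1,
    tail_calls: Optional[Mapping[str, TailCall]] = None,
) -> List[AlignmentRecord]:
    """Exhaustively place each read on both strands with <= ``max_mismatches``.

    Returns one record per best-scoring locus (minimal mismatch count);
    every record of a read with more than one best locus carries
    ``unique=False``.  Reads longer than the genome, or without any
    qualifying locus, yield no records.
    """
    idx = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    k = idx.k
    out: List[AlignmentRecord] = []
    for rec in reads:
        seq = str(rec.seq).upper()
        n = len(seq)
        if n < k:
            continue
        hits: Dict[Tuple[str, int, str], int] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            n_chunks = max_mismatches + 1
            chunk = n // n_chunks
            offsets = (
                [i * chunk for i in range(n_chunks)] if chunk >= k else range(0, n - k + 1)
            )
            for off in offsets:
                for chrom, pos in idx.index.get(s[off : off + k], ()):
                    start = pos - off
                    if start < 0 or start + n > len(idx.genome[chrom]):
                        continue
                    key = (chrom, start, strand)
                    if key in hits:
                        continue
                    mm = _count_mismatches(
                        s, idx.genome[chrom][start : start + n], max_mismatches
                    )
                    if mm <= max_mismatches:
                        hits[key] = mm
        if not hits:
            continue
        best = min(hits.values())
        loci = sorted(key for key, mm in hits.items() if mm == best)
        tc = tail_calls.get(rec.id) if tail_calls else None
        for chrom, start, strand in loci:
            out.append(
                AlignmentRecord(
                    read_id=rec.id,
                    chrom=chrom,
                    start=start,
                    end=start + n,
                    strand=strand,
                    n_mismatches=hits[(chrom, start, strand)],
                    unique=len(loci) == 1,
                    tail_side=tc.side if tc else None,
                    tail_base=tc.base if tc else None,
                )
            )
    return out


def write_sam(
    records: Sequence[AlignmentRecord],
    chrom_lengths: Mapping[str, int],
    path: str,
) -> None:
    """Serialize alignment records as SAM.

    The first record of each read id is written as primary; further loci are
    flagged secondary (0x100).  NM holds the mismatch count and NH the
    number of reported loci, so uniqueness survives a round trip.
    """
    chroms = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    per_read: Dict[str, List[AlignmentRecord]] = defaultdict(list)
    order: List[str] = []
    for r in records:
        if r.read_id not in per_read:
            order.append(r.read_id)
        per_read[r.read_id].append(r)
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rid in order:
            group = per_read[rid]
            for i, r in enumerate(group):
                seg = pysam.AlignedSegment(fh.header)
                seg.query_name = r.read_id
                seg.flag = (0x10 if r.strand == "-" else 0) | (0x100 if i > 0 else 0)
                seg.reference_id = chroms.index(r.chrom)
                seg.reference_start = r.start
                seg.mapping_quality = 255 if r.unique else 0
                seg.cigarstring = f"{r.end - r.start}M"
                seg.set_tag("NM", r.n_mismatches)
                seg.set_tag("NH", len(group))
                fh.write(seg)


def import_alignments(
    path: str,
    tail_calls: Mapping[str, TailCall],
) -> Tuple[List[AlignmentRecord], Dict[str, int]]:
    """Load primary alignments of tail-called reads from SAM/BAM.

    Only primary, mapped, non-supplementary records of reads present in the
    tail-call table are returned.  A read is non-unique when the file holds
    secondary records for its id or an NH tag above 1; such records are
    returned with ``unique=False`` and must be excluded from PAS calling.
    Diagnostics count unmapped/secondary/supplementary records and reads
    missing from the tail-call table.
    """
    diagnostics = {
        "unmapped": 0,
        "secondary": 0,
        "supplementary": 0,
        "missing_tailcall": 0,
        "imported": 0,
    }
    multi: set = set()
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        alns = list(fh)
    for a in alns:
        if a.is_secondary:
            multi.add(a.query_name)
    out: List[AlignmentRecord] = []
    for a in alns:
        if a.is_unmapped:
            diagnostics["unmapped"] += 1
            continue
        if a.is_secondary:
            diagnostics["secondary"] += 1
            continue
        if a.is_supplementary:
            diagnostics["supplementary"] += 1
            continue
        tc = tail_calls.get(a.query_name)
        if tc is None:
            diagnostics["missing_tailcall"] += 1
            continue
        nh = a.get_tag("NH") if a.has_tag("NH") else 1
        unique = a.query_name not in multi and nh <= 1
        out.append(
            AlignmentRecord(
                read_id=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_end,
                strand="-" if a.is_reverse else "+",
                n_mismatches=a.get_tag("NM") if a.has_tag("NM") else 0,
                unique=unique,
                tail_side=tc.side,
                tail_base=tc.base,
            )
        )
        diagnostics["imported"] += 1
    return out, diagnostics


def attach_tail_calls(
    records: Sequence[AlignmentRecord], tail_calls: Mapping[str, TailCall]
) -> List[AlignmentRecord]:
    """Return copies of ``records`` with tail metadata filled from the table."""
    out = []
    for r in records:
        tc = tail_calls.get(r.read_id)
        if tc is not None:
            r = replace(r, tail_side=tc.side, tail_base=tc.base)
        out.append(r)
    return out
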