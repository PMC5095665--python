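"""Synthetic genomes, gene models and tailed RNA-seq reads with known truth.

Every downstream stage of the polyadenylation-site (PAS) pipeline is tested
against data produced here: a random genome with planted A/T-rich decoy loci
(internal-priming bait), gene models with 1-6 known PAS per gene placed
downstream of the stop codon at configurable spacing, and FASTQ reads whose
poly(A)/(T) tails are appended after the templated cleavage base.

Two properties make exact end-to-end recovery checks possible:

* accidental homopolymers in the random background are broken so that no
  A or T run of >= 7 nt exists outside the planted decoys — true PAS are
  therefore never hit by the internal-priming filter;
* decoy reads are genomic copies ending inside a planted A-run (or starting
  inside a T-run), so the tail detector accepts them and only the
  internal-priming filter can remove them.

All randomness flows from a single integer seed; regenerating with the same
seed yields byte-identical FASTA/GTF/FASTQ output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .util import make_read, revcomp, write_fastq

_BASES = np.array(["A", "C", "G", "T"])


class PlacementError(ValueError):
    """Requested decoys or genes cannot be placed in the genome."""


@dataclass(frozen=True)
class DecoyLocus:
    """A planted genomic A- or T-run that mimics an internal-priming site."""

    chrom: str
    start: int  # 0-based
    end: int  # half-open
    base: str  # "A" | "T"

    @property
    def strand(self) -> str:
        # an A-run misleads oligo-dT priming on the + strand, a T-run on -
        return "+" if self.base == "A" else "-"


@dataclass
class GeneTruth:
    """Ground-truth structure of one synthetic gene.

    ``pas_positions`` hold the genomic coordinate (0-based) of the last
    transcribed base for each PAS, ordered in transcription direction.
    ``pas_weights`` map sample id -> per-PAS expression proportions
    (summing to 1).
    """

    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # 0-based half-open, sorted by coordinate
    cds: List[Tuple[int, int]]
    stop_codon: Tuple[int, int]
    stop_last: int  # last stop-codon base in transcription direction
    pas_positions: List[int]
    pas_weights: Dict[str, List[float]] = field(default_factory=dict)
    tail_length_mean: float = 15.0

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)


@dataclass
class SyntheticTruth:
    """Complete ground truth for one synthetic dataset."""

    genome_id: str
    genome: Dict[str, str]
    genes: List[GeneTruth]
    decoy_loci: List[DecoyLocus]
    seed: int


def _break_homopolymers(codes: np.ndarray, rng: np.random.Generator, max_run: int = 6) -> None:
    """Substitute every ``max_run+1``-th base of long runs, in place.

    After this pass no homopolymer exceeds ``max_run`` nt (a substitution can
    at worst seed a new run of ``max_run + 1`` by merging with a neighbour,
    still far below the 9-nt internal-priming threshold).
    """
    n = len(codes)
    if n < 2:
        return
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate([[0], change])
    run_id = np.zeros(n, dtype=np.int64)
    run_id[change] = 1
    run_id = np.cumsum(run_id)
    offset = np.arange(n) - starts[run_id]
    hits = np.flatnonzero((offset > 0) & (offset % max_run == 0))
    if len(hits) == 0:
        return
    shift = rng.integers(1, 4, size=len(hits))
    codes[hits] = (codes[hits] + shift) % 4


def generate_genome(
    length: int,
    gc_fraction: float = 0.5,
    n_decoys: int = 0,
    seed: int = 0,
    chrom: str = "chr1",
    decoy_run_range: Tuple[int, int] = (10, 14),
    edge_margin: int = 200,
) -> Tuple[str, List[DecoyLocus]]:
    """Random genome with ``n_decoys`` planted non-overlapping A/T runs.

    The background sequence is i.i.d. with the requested GC fraction, then
    scrubbed of accidental homopolymers (see :func:`_break_homopolymers`).
    Each decoy is a run of 10-14 identical A or T bases at a recorded,
    non-overlapping position at least ``edge_margin`` nt from either end.

    Raises :class:`PlacementError` when the decoys cannot be placed.
    """
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p_at = (1.0 - gc_fraction) / 2.0
    p_gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    _break_homopolymers(codes, rng)

    decoys: List[DecoyLocus] = []
    if n_decoys > 0:
        gap = 30
        run_max = decoy_run_range[1]
        usable = length - 2 * edge_margin
        if usable < n_decoys * (run_max + gap):
            raise PlacementError(
                f"cannot place {n_decoys} decoy runs in a {length}-nt genome"
            )
        placed: List[Tuple[int, int]] = []
        attempts = 0
        max_attempts = 1000 * n_decoys
        while len(decoys) < n_decoys:
            if attempts >= max_attempts:
                raise PlacementError(
                    f"failed to place {n_decoys} non-overlapping decoys "
                    f"after {max_attempts} attempts"
                )
            attempts += 1
            run_len = int(rng.integers(decoy_run_range[0], decoy_run_range[1] + 1))
            pos = int(rng.integers(edge_margin, length - edge_margin - run_len))
            lo, hi = pos - gap, pos + run_len + gap
            if any(not (hi <= s or lo >= e) for s, e in placed):
                continue
            base = "A" if rng.random() < 0.5 else "T"
            codes[pos : pos + run_len] = 0 if base == "A" else 3
            placed.append((lo, hi))
            decoys.append(DecoyLocus(chrom=chrom, start=pos, end=pos + run_len, base=base))
        decoys.sort(key=lambda d: d.start)
    return "".join(_BASES[codes]), decoys


def _draw(rng: np.random.Generator, spec: Union[int, Tuple[int, int]]) -> int:
    if isinstance(spec, tuple):
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def generate_gene_models(
    genome: str,
    decoys: Sequence[DecoyLocus],
    n_genes: int,
    pas_per_gene: Union[int, Tuple[int, int]] = (1, 6),
    utr_pas_spacing: Union[int, Tuple[int, int]] = 300,
    seed: int = 0,
    chrom: str = "chr1",
    sample_ids: Sequence[str] = ("sample1",),
    tail_length_mean: float = 15.0,
) -> Tuple[List[GeneTruth], str]:
    """Place two-exon protein-coding genes and their PAS on the genome.

    Each gene has a 150-nt first exon, a 120-nt intron and a second exon
    holding 150 nt of CDS, the stop codon and a 3'UTR sized to fit its PAS.
    PAS positions follow the stop codon at distances drawn from
    ``utr_pas_spacing`` (an int for constant spacing or an inclusive
    ``(lo, hi)`` range); the same distribution spaces adjacent PAS, so the
    stop-to-first-PAS and adjacent-PAS distance statistics have a known
    target.  Genes avoid decoy neighbourhoods entirely so that no true PAS
    can be flagged by the internal-priming filter.

    Returns the gene truth list and the Ensembl-dialect GTF text
    (gene/transcript/exon/CDS/stop_codon records, 1-based inclusive).
    """
    rng = np.random.default_rng(seed)
    exon1_len, intron_len, cds2_len = 150, 120, 150
    edge = 250
    utr_tail_margin = 60
    blocked = sorted((d.start - 80, d.end + 80) for d in decoys)

    genes: List[GeneTruth] = []
    cursor = edge
    for i in range(n_genes):
        k = _draw(rng, pas_per_gene)
        if not 1 <= k <= 6:
            raise ValueError("pas_per_gene must draw values in 1..6")
        spacings = [_draw(rng, utr_pas_spacing) for _ in range(k)]
        utr_len = sum(spacings) + utr_tail_margin
        gene_len = exon1_len + intron_len + cds2_len + 3 + utr_len
        # skip decoy neighbourhoods
        moved = True
        while moved:
            moved = False
            for lo, hi in blocked:
                if not (cursor + gene_len <= lo or cursor >= hi):
                    cursor = hi
                    moved = True
        if cursor + gene_len + edge > len(genome):
            raise PlacementError(
                f"genome of {len(genome)} nt too short for {n_genes} genes "
                f"(placed {i})"
            )
        g, e = cursor, cursor + gene_len
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            exons = [(g, g + exon1_len), (g + exon1_len + intron_len, e)]
            cds = [
                (g, g + exon1_len),
                (g + exon1_len + intron_len, g + exon1_len + intron_len + cds2_len),
            ]
            stop = (cds[1][1], cds[1][1] + 3)
            stop_last = stop[1] - 1
            pas = list(stop_last + np.cumsum(spacings))
        else:
            exons = [(g, e - exon1_len - intron_len), (e - exon1_len, e)]
            cds = [
                (e - exon1_len - intron_len - cds2_len, e - exon1_len - intron_len),
                (e - exon1_len, e),
            ]
            stop = (cds[0][0] - 3, cds[0][0])
            stop_last = stop[0]
            pas = list(stop_last - np.cumsum(spacings))
        weights = {s: [1.0 / k] * k for s in sample_ids}
        genes.append(
            GeneTruth(
                gene_id=f"G{i:04d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                stop_codon=stop,
                stop_last=stop_last,
                pas_positions=[int(p) for p in pas],
                pas_weights=weights,
                tail_length_mean=tail_length_mean,
            )
        )
        cursor = e + int(rng.integers(200, 500))
    return genes, genes_to_gtf(genes)


def genes_to_gtf(genes: Sequence[GeneTruth]) -> str:
    """Serialize gene truths as Ensembl-dialect GTF (1-based inclusive)."""
    lines: List[str] = []

    def row(chrom, feature, start0, end0, strand, attrs):
        lines.append(
            "\t".join(
                [
                    chrom,
                    "pasfinder_synthetic",
                    feature,
                    str(start0 + 1),
                    str(end0),
                    ".",
                    strand,
                    "0" if feature == "CDS" else ".",
                    attrs,
                ]
            )
        )

    for gene in genes:
        gid = f'gene_id "{gene.gene_id}";'
        tid = f'{gid} transcript_id "{gene.gene_id}.t1";'
        row(gene.chrom, "gene", gene.start, gene.end, gene.strand,
            f'{gid} gene_biotype "protein_coding";')
        row(gene.chrom, "transcript", gene.start, gene.end, gene.strand, tid)
        for s, e in gene.exons:
            row(gene.chrom, "exon", s, e, gene.strand, tid)
        for s, e in gene.cds:
            row(gene.chrom, "CDS", s, e, gene.strand, tid)
        row(gene.chrom, "stop_codon", gene.stop_codon[0], gene.stop_codon[1],
            gene.strand, tid)
    return "\n".join(lines) + "\n"


@dataclass
class SimulatedReads:
    """FASTQ records plus the read-level truth table."""

    paired: bool
    records: List  # unpaired reads, or mate-2 ("sense") reads when paired
    mate1: Optional[List]  # reverse-complement mates when paired
    truth: pd.DataFrame

    @property
    def n_reads(self) -> int:
        return len(self.records)

    def write(self, path: str, path2: Optional[str] = None) -> None:
        if self.paired:
            if path2 is None:
                raise ValueError("paired output needs two FASTQ paths")
            write_fastq(self.mate1, path)
            write_fastq(self.records, path2)
        else:
            write_fastq(self.records, path)

    def write_truth(self, path: str) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hit:
        choices = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode()


def simulate_reads(
    truth: SyntheticTruth,
    reads_per_pas: int = 5,
    read_length: int = 50,
    tail_length: int = 15,
    error_rate: float = 0.0,
    library: str = "nss",
    paired: bool = False,
    n_decoy_reads: int = 0,
    seed: int = 0,
    pas_read_counts: Optional[Dict[Tuple[str, int], int]] = None,
) -> SimulatedReads:
    """Simulate tailed reads for every PAS plus internal-priming decoy reads.

    Each PAS read consists of the ``read_length - tail_length`` genomic bases
    ending at the cleavage site (in mRNA sense) followed by a non-templated
    poly(A) tail of ``tail_length`` nt; substitution errors are applied
    uniformly at ``error_rate`` per base.  Decoy reads are pure genomic
    copies ending inside a planted A-run (or starting inside a T-run) and
    carry no added tail.  ``pas_read_counts`` may override the per-PAS read
    count keyed by ``(gene_id, pas_index)``.

    Orientation: non-strand-specific unpaired reads are emitted in a random
    orientation (sense, ending in poly(A), or antisense, starting with
    poly(T)); paired and strand-specific libraries emit mate 1 as the
    antisense copy and mate 2 as the sense copy, matching oligo-dT library
    geometry.
    """
    if library not in ("nss", "ss"):
        raise ValueError("library must be 'nss' or 'ss'")
    if tail_length < 10:
        warnings.warn(
            "tail_length < 10 nt: simulated tails are below the detection "
            "threshold and reads will be classified as non-polyadenylated",
            stacklevel=2,
        )
    body_len = read_length - tail_length
    if body_len < 1:
        raise ValueError("read_length must exceed tail_length")
    rng = np.random.default_rng(seed)
    records: List = []
    mate1: List = []
    rows: List[dict] = []

    def emit(read_id: str, sense: str, row: dict) -> None:
        sense = _apply_errors(sense, rng, error_rate)
        if paired:
            mate1.append(make_read(read_id, revcomp(sense)))
            records.append(make_read(read_id, sense))
        elif library == "ss":
            records.append(make_read(read_id, sense))
        else:
            if rng.random() < 0.5:
                records.append(make_read(read_id, revcomp(sense)))
            else:
                records.append(make_read(read_id, sense))
        rows.append(row)

    for gene in truth.genes:
        seq = truth.genome[gene.chrom]
        for pi, pos in enumerate(gene.pas_positions):
            count = (
                pas_read_counts.get((gene.gene_id, pi), reads_per_pas)
                if pas_read_counts
                else reads_per_pas
            )
            for r in range(count):
                if gene.strand == "+":
                    body = seq[pos - body_len + 1 : pos + 1]
                else:
                    body = revcomp(seq[pos : pos + body_len])
                sense = body + "A" * tail_length
                rid = f"{gene.gene_id}|pas{pi}|r{r:04d}"
                emit(
                    rid,
                    sense,
                    {
                        "read_id": rid,
                        "source": "pas",
                        "gene_id": gene.gene_id,
                        "pas_index": pi,
                        "chrom": gene.chrom,
                        "position": pos,
                        "strand": gene.strand,
                    },
                )

    if n_decoy_reads > 0:
        if not truth.decoy_loci:
            raise ValueError("decoy reads requested but truth has no decoy loci")
        for r in range(n_decoy_reads):
            d = truth.decoy_loci[r % len(truth.decoy_loci)]
            seq = truth.genome[d.chrom]
            run_len = d.end - d.start
            t = int(rng.integers(10, min(run_len, read_length - 10) + 1))
            if d.base == "A":
                end = d.start + t
                sense = seq[end - read_length : end]
            else:
                start = d.end - t
                sense = revcomp(seq[start : start + read_length])
            rid = f"decoy|d{truth.decoy_loci.index(d):03d}|r{r:04d}"
            emit(
                rid,
                sense,
                {
                    "read_id": rid,
                    "source": "decoy",
                    "gene_id": "",
                    "pas_index": -1,
                    "chrom": d.chrom,
                    "position": d.start,
                    "strand": d.strand,
                },
            )

    truth_df = pd.DataFrame(
        rows,
        columns=["read_id", "source", "gene_id", "pas_index", "chrom", "position", "strand"],
    )
    return SimulatedReads(
        paired=paired, records=records, mate1=mate1 if paired else None, truth=truth_df
    )


def _harden_tail_boundaries(
    seq: str, genes: Sequence[GeneTruth], rng: np.random.Generator, zone: int = 12
) -> str:
    """Remove tail-base ambiguity immediately upstream of each planted PAS.

    A cleavage site whose upstream transcript sequence is A-rich cannot be
    trimmed exactly: the appended tail merges with templated adenosines and
    the inferred site drifts upstream.  Substituting C/G for any A (T on the
    minus strand) in the ``zone`` nt ending at the cleavage base makes the
    tail/body boundary unambiguous under the 10%-mismatch run definition,
    so error-free reads recover every planted position exactly.  C/G
    substitutions cannot seed new A/T homopolymers.
    """
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for gene in genes:
        for pos in gene.pas_positions:
            if gene.strand == "+":
                lo, hi, bad = max(0, pos - zone + 1), pos + 1, b"A"
            else:
                lo, hi, bad = pos, min(len(arr), pos + zone), b"T"
            for i in range(lo, hi):
                if arr[i] == bad:
                    arr[i] = b"C" if rng.random() < 0.5 else b"G"
    return arr.tobytes().decode()


def make_dataset(
    genome_length: int = 100_000,
    n_genes: int = 10,
    n_decoys: int = 5,
    pas_per_gene: Union[int, Tuple[int, int]] = (1, 6),
    utr_pas_spacing: Union[int, Tuple[int, int]] = 300,
    gc_fraction: float = 0.5,
    seed: int = 0,
    chrom: str = "chr1",
    sample_ids: Sequence[str] = ("sample1",),
) -> Tuple[SyntheticTruth, str]:
    """Convenience constructor: genome + decoys + gene models in one call.

    Returns the :class:`SyntheticTruth` and the GTF text.  Genome and gene
    placement use decorrelated child seeds derived from ``seed``.
    """
    seq, decoys = generate_genome(
        genome_length, gc_fraction=gc_fraction, n_decoys=n_decoys, seed=seed, chrom=chrom
    )
    genes, gtf = generate_gene_models(
        seq,
        decoys,
        n_genes=n_genes,
        pas_per_gene=pas_per_gene,
        utr_pas_spacing=utr_pas_spacing,
        seed=seed + 1,
        chrom=chrom,
        sample_ids=sample_ids,
    )
    seq = _harden_tail_boundaries(seq, genes, np.random.default_rng(seed + 2))
    truth = SyntheticTruth(
        genome_id=f"synthetic-{seed}",
        genome={chrom: seq},
        genes=genes,
        decoy_loci=decoys,
        seed=seed,
    )
    return truth, gtf
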