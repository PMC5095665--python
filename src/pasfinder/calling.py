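"""Cleavage-site inference, internal-priming filtering and PAS cluster calling.

Alignments of tail-trimmed reads pinpoint the cleavage position of the
source mRNA: the genomic base adjacent to the (removed) poly(A) tail, on the
tail side of the alignment.  Putative sites whose downstream genomic
sequence is A/T-rich are internal-priming artifacts (oligo-dT annealed to a
templated A-run rather than a real tail) and are removed.  Surviving sites
on one strand within a small genomic window form a cluster reflecting 3'-end
heterogeneity; the best-supported member of each cluster is its positive
(representative) PAS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .mapping import AlignmentRecord
from .tails import SIDE_3, SIDE_5
from .util import revcomp


@dataclass(frozen=True)
class CallingParameters:
    """Thresholds for site filtering and clustering.

    cluster_window:
        maximum gap (nt) between consecutive sites of one cluster
        (default 20; the boundary is inclusive, gap <= window).
    min_site_reads:
        minimum supporting reads for a site to be a positive-PAS candidate
        (default 3).
    ip_window:
        length (nt) of the downstream genomic window scanned for
        internal-priming evidence (default 20).
    ip_run:
        homopolymer run length (nt) that triggers the internal-priming flag
        (default 9).
    """

    cluster_window: int = 20
    min_site_reads: int = 3
    ip_window: int = 20
    ip_run: int = 9

    def __post_init__(self) -> None:
        for name in ("cluster_window", "min_site_reads", "ip_window", "ip_run"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


DEFAULT_PARAMS = CallingParameters()


@dataclass(frozen=True)
class CleavageSite:
    """A genomic position + strand where a transcript 3' end is inferred.

    ``position`` is the 0-based coordinate of the last transcribed base;
    ``strand`` is the transcription strand of the source mRNA.
    """

    chrom: str
    position: int
    strand: str
    read_count: int = 1
    internal_priming: bool = False


@dataclass
class PASCluster:
    """A strand-consistent group of nearby cleavage sites."""

    chrom: str
    strand: str
    sites: List[CleavageSite] = field(default_factory=list)
    positive_site: Optional[CleavageSite] = None

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def total_reads(self) -> int:
        return sum(s.read_count for s in self.sites)

    @property
    def start(self) -> int:
        return min(s.position for s in self.sites)

    @property
    def end(self) -> int:
        return max(s.position for s in self.sites) + 1


def infer_cleavage_sites(
    alignments: Iterable[AlignmentRecord],
) -> Tuple[List[CleavageSite], Dict[str, int]]:
    """Derive cleavage sites from tail-annotated alignments.

    The read-relative tail geometry plus the aligned strand determine the
    transcript strand and cleavage base:

    * tail at read 3' as A, aligned ``+``  -> site at ``end - 1``, strand ``+``
    * tail at read 3' as A, aligned ``-``  -> site at ``start``, strand ``-``
    * tail at read 5' as T, aligned ``+``  -> site at ``start``, strand ``-``
    * tail at read 5' as T, aligned ``-``  -> site at ``end - 1``, strand ``+``

    Any other combination (5' A-runs / 3' T-runs, which cannot arise from a
    poly(A) tail) is rejected and counted, as are non-unique alignments and
    records lacking tail metadata.  Sites at the same (chrom, position,
    strand) are merged with summed read counts.
    """
    counts: Dict[Tuple[str, int, str], int] = {}
    diagnostics = {"used": 0, "non_unique": 0, "no_tail_metadata": 0, "inconsistent_tail": 0}
    for rec in alignments:
        if not rec.unique:
            diagnostics["non_unique"] += 1
            continue
        if rec.tail_side is None or rec.tail_base is None:
            diagnostics["no_tail_metadata"] += 1
            continue
        combo = (rec.tail_side, rec.tail_base, rec.strand)
        if combo in ((SIDE_3, "A", "+"), (SIDE_5, "T", "-")):
            key = (rec.chrom, rec.end - 1, "+")
        elif combo in ((SIDE_3, "A", "-"), (SIDE_5, "T", "+")):
            key = (rec.chrom, rec.start, "-")
        else:
            diagnostics["inconsistent_tail"] += 1
            continue
        counts[key] = counts.get(key, 0) + 1
        diagnostics["used"] += 1
    sites = [
        CleavageSite(chrom=c, position=p, strand=s, read_count=n)
        for (c, p, s), n in sorted(counts.items())
    ]
    return sites, diagnostics


def _has_run(window: str, run: int, bases: str = "AT") -> bool:
    for b in bases:
        if b * run in window:
            return True
    return False


def filter_internal_priming(
    sites: Sequence[CleavageSite],
    genome: Mapping[str, str],
    params: CallingParameters = DEFAULT_PARAMS,
) -> List[CleavageSite]:
    """Flag sites whose downstream genomic window is A/T homopolymeric.

    The window of ``ip_window`` nt immediately downstream of the cleavage
    base in transcription direction is read in transcription orientation
    (reverse complement for ``-`` strand sites); a run of at least
    ``ip_run`` consecutive A or T flags the site.  Windows truncated at
    chromosome ends are scanned as-is.  Flagged sites must be excluded from
    clustering and positive calling.
    """
    out: List[CleavageSite] = []
    for site in sites:
        if site.chrom not in genome:
            raise KeyError(f"chromosome {site.chrom!r} absent from genome")
        seq = genome[site.chrom]
        if site.strand == "+":
            window = seq[site.position + 1 : site.position + 1 + params.ip_window]
        else:
            window = revcomp(seq[max(0, site.position - params.ip_window) : site.position])
        out.append(replace(site, internal_priming=_has_run(window, params.ip_run)))
    return out


def cluster_sites(
    sites: Iterable[CleavageSite],
    params: CallingParameters = DEFAULT_PARAMS,
) -> List[PASCluster]:
    """Single-linkage chaining of same-strand sites within ``cluster_window``.

    Internal-priming-flagged sites are excluded.  A new cluster starts when
    the gap to the previous retained site on the same chrom/strand exceeds
    the window; clusters are maximal and invariant to input order.
    """
    kept = sorted(
        (s for s in sites if not s.internal_priming),
        key=lambda s: (s.chrom, s.strand, s.position),
    )
    clusters: List[PASCluster] = []
    for site in kept:
        if (
            clusters
            and clusters[-1].chrom == site.chrom
            and clusters[-1].strand == site.strand
            and site.position - clusters[-1].sites[-1].position <= params.cluster_window
        ):
            clusters[-1].sites.append(site)
        else:
            clusters.append(PASCluster(chrom=site.chrom, strand=site.strand, sites=[site]))
    return clusters


def call_positive_pas(
    cluster: PASCluster, params: CallingParameters = DEFAULT_PARAMS
) -> PASCluster:
    """Pick the cluster's representative PAS.

    Member sites below ``min_site_reads`` supporting reads are dropped from
    candidacy; among the rest the maximal read count wins, ties broken
    toward the 3'-most position in transcription direction.  A cluster with
    no candidate keeps ``positive_site = None``.
    """
    candidates = [s for s in cluster.sites if s.read_count >= params.min_site_reads]
    if not candidates:
        cluster.positive_site = None
        return cluster
    direction = 1 if cluster.strand == "+" else -1
    cluster.positive_site = max(
        candidates, key=lambda s: (s.read_count, direction * s.position)
    )
    return cluster


def call_all(
    sites: Sequence[CleavageSite],
    genome: Mapping[str, str],
    params: CallingParameters = DEFAULT_PARAMS,
) -> List[PASCluster]:
    """Filter, cluster and call positives in one pass."""
    flagged = filter_internal_priming(sites, genome, params)
    clusters = cluster_sites(flagged, params)
    return [call_positive_pas(c, params) for c in clusters]


def positive_sites(clusters: Iterable[PASCluster]) -> List[CleavageSite]:
    return [c.positive_site for c in clusters if c.positive_site is not None]


def heterogeneity_profile(clusters: Sequence[PASCluster]) -> Dict[str, float]:
    """Fraction of clusters with one, two, or more than two member sites."""
    if not clusters:
        raise ValueError("no clusters given")
    n = len(clusters)
    one = sum(1 for c in clusters if c.n_sites == 1)
    two = sum(1 for c in clusters if c.n_sites == 2)
    return {"1": one / n, "2": two / n, ">2": (n - one - two) / n}


def write_positive_bed(clusters: Sequence[PASCluster], path: str) -> None:
    """BED6 of positive PAS (0-based; name = cluster id; score = reads)."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            s = c.positive_site
            if s is None:
                continue
            fh.write(
                f"{s.chrom}\t{s.position}\t{s.position + 1}\tcluster{i:06d}\t"
                f"{s.read_count}\t{s.strand}\n"
            )


def write_site_table(clusters: Sequence[PASCluster], all_sites: Sequence[CleavageSite], path: str) -> None:
    """TSV of every putative site with flags (position reported 1-based)."""
    membership: Dict[Tuple[str, int, str], Tuple[int, bool]] = {}
    for i, c in enumerate(clusters):
        for s in c.sites:
            positive = c.positive_site is not None and s.position == c.positive_site.position
            membership[(s.chrom, s.position, s.strand)] = (i, positive)
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\treads\tinternal_priming\tcluster_id\tpositive\n")
        for s in all_sites:
            cid, pos_flag = membership.get((s.chrom, s.position, s.strand), (-1, False))
            fh.write(
                f"{s.chrom}\t{s.position + 1}\t{s.strand}\t{s.read_count}\t"
                f"{int(s.internal_priming)}\t{cid}\t{int(pos_flag)}\n"
            )
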