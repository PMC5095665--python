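"""Assignment of PAS to gene features and APA distribution statistics.

Positive PAS are assigned to annotated genes (Ensembl-dialect GTF) on the
same strand, with category precedence 3'UTR > ORF > intron across all
overlapping transcripts; a PAS overlapping no same-strand gene span is
intergenic.  3'UTRs are derived as the exonic sequence downstream of the
stop codon in transcription direction.  Distance statistics (stop codon to
first 3'UTR PAS; adjacent PAS per gene) are genomic distances in
transcription direction.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils
import pandas as pd

from .calling import CleavageSite

Interval = Tuple[int, int]  # 0-based half-open


@dataclass
class TranscriptModel:
    transcript_id: str
    exons: List[Interval]
    cds: List[Interval]
    stop_codon: Optional[Interval] = None
    utr3: List[Interval] = field(default_factory=list)


@dataclass
class GeneModel:
    """Gene structure with derived 3'UTR intervals.

    ``stop_last`` is the genomic coordinate of the last stop-codon base in
    transcription direction (None for non-coding genes); distances to PAS
    are measured from it.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: List[TranscriptModel] = field(default_factory=list)
    stop_last: Optional[int] = None

    def utr3_intervals(self) -> List[Interval]:
        return [iv for t in self.transcripts for iv in t.utr3]

    def cds_intervals(self) -> List[Interval]:
        out = [iv for t in self.transcripts for iv in t.cds]
        out += [t.stop_codon for t in self.transcripts if t.stop_codon is not None]
        return out

    def exon_intervals(self) -> List[Interval]:
        return [iv for t in self.transcripts for iv in t.exons]


@dataclass(frozen=True)
class PASAnnotation:
    pas: CleavageSite
    category: str  # "3UTR" | "ORF" | "intron" | "intergenic"
    gene_id: Optional[str] = None
    distance_to_stop: Optional[int] = None


def _derive_utr3(exons: List[Interval], stop_last: int, strand: str) -> List[Interval]:
    """Exonic intervals strictly downstream of the stop codon."""
    utr: List[Interval] = []
    for s, e in exons:
        if strand == "+":
            lo = max(s, stop_last + 1)
            if lo < e:
                utr.append((lo, e))
        else:
            hi = min(e, stop_last)
            if s < hi:
                utr.append((s, hi))
    return utr


def load_gene_models(gtf_path: str) -> Tuple[List[GeneModel], Dict[str, int]]:
    """Parse a GTF into GeneModels with derived 3'UTRs.

    Transcripts lacking CDS contribute exon/intron structure only.
    Transcripts whose CDS falls outside their exons are skipped with a
    counted diagnostic.  When a stop_codon feature is absent but CDS is
    present, the stop codon is assumed to occupy the 3 nt immediately
    following the CDS in transcription direction (Ensembl CDS excludes the
    stop codon).
    """
    db = gffutils.create_db(
        gtf_path,
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    diagnostics = {"transcripts": 0, "skipped_inconsistent": 0}
    models: List[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gm = GeneModel(
            gene_id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            start=gene.start - 1,
            end=gene.end,
        )
        for tr in db.children(gene, featuretype="transcript"):
            diagnostics["transcripts"] += 1
            exons = sorted((f.start - 1, f.end) for f in db.children(tr, featuretype="exon"))
            cds = sorted((f.start - 1, f.end) for f in db.children(tr, featuretype="CDS"))
            stops = sorted(
                (f.start - 1, f.end) for f in db.children(tr, featuretype="stop_codon")
            )
            if cds and not all(
                any(s >= es and e <= ee for es, ee in exons) for s, e in cds
            ):
                diagnostics["skipped_inconsistent"] += 1
                continue
            tm = TranscriptModel(transcript_id=tr.id, exons=exons, cds=cds)
            if stops:
                tm.stop_codon = (stops[0][0], stops[-1][1])
            if cds:
                if tm.stop_codon is not None:
                    stop_last = tm.stop_codon[1] - 1 if gm.strand == "+" else tm.stop_codon[0]
                else:
                    stop_last = cds[-1][1] + 2 if gm.strand == "+" else cds[0][0] - 3
                tm.utr3 = _derive_utr3(exons, stop_last, gm.strand)
                if gm.stop_last is None or (
                    # most downstream stop across isoforms defines the gene's
                    stop_last > gm.stop_last
                    if gm.strand == "+"
                    else stop_last < gm.stop_last
                ):
                    gm.stop_last = stop_last
            tm_exists = tm.exons or tm.cds
            if tm_exists:
                gm.transcripts.append(tm)
        models.append(gm)
    return models, diagnostics


def _in_any(pos: int, intervals: Sequence[Interval]) -> bool:
    return any(s <= pos < e for s, e in intervals)


def annotate_pas(
    pas_list: Sequence[CleavageSite], models: Sequence[GeneModel]
) -> List[PASAnnotation]:
    """Assign each PAS to a category and (for genic PAS) a gene.

    Precedence across all overlapping same-strand transcripts is
    3'UTR > ORF > intron; exonic positions upstream of the CDS fall through
    to the intron (generic intragenic) category.  When several genes
    qualify at the same precedence, the one whose stop codon is nearest is
    chosen.
    """
    rank = {"3UTR": 0, "ORF": 1, "intron": 2}
    out: List[PASAnnotation] = []
    for pas in pas_list:
        hits: List[Tuple[int, int, str, GeneModel]] = []
        for gm in models:
            if gm.chrom != pas.chrom or gm.strand != pas.strand:
                continue
            if not gm.start <= pas.position < gm.end:
                continue
            if _in_any(pas.position, gm.utr3_intervals()):
                cat = "3UTR"
            elif _in_any(pas.position, gm.cds_intervals()):
                cat = "ORF"
            else:
                cat = "intron"
            stop_dist = (
                abs(pas.position - gm.stop_last) if gm.stop_last is not None else 10**12
            )
            hits.append((rank[cat], stop_dist, cat, gm))
        if not hits:
            out.append(PASAnnotation(pas=pas, category="intergenic"))
            continue
        hits.sort(key=lambda h: (h[0], h[1], h[3].gene_id))
        _, _, cat, gm = hits[0]
        dist = None
        if cat == "3UTR" and gm.stop_last is not None:
            dist = (
                pas.position - gm.stop_last
                if gm.strand == "+"
                else gm.stop_last - pas.position
            )
        out.append(PASAnnotation(pas=pas, category=cat, gene_id=gm.gene_id, distance_to_stop=dist))
    return out


def apa_summary(
    annotations: Sequence[PASAnnotation],
) -> Tuple[pd.DataFrame, Dict[str, float]]:
    """Per-gene PAS counts and aggregate APA fractions.

    A gene shows alternative polyadenylation (APA) when it carries two or
    more PAS.  The aggregate reports the APA fraction over all PAS-bearing
    genes and, restricted to 3'UTR PAS, over genes with at least one
    3'UTR PAS.
    """
    genic = [a for a in annotations if a.gene_id is not None]
    if not genic:
        raise ValueError("no genic PAS annotations")
    rows: Dict[str, Dict[str, int]] = {}
    for a in genic:
        row = rows.setdefault(a.gene_id, {"n_pas": 0, "n_utr3_pas": 0})
        row["n_pas"] += 1
        if a.category == "3UTR":
            row["n_utr3_pas"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    df.index.name = "gene_id"
    df["apa"] = df["n_pas"] >= 2
    utr_genes = df[df["n_utr3_pas"] >= 1]
    summary = {
        "n_genes": float(len(df)),
        "apa_fraction": float(df["apa"].mean()),
        "apa_fraction_3utr": float((utr_genes["n_utr3_pas"] >= 2).mean())
        if len(utr_genes)
        else float("nan"),
    }
    return df, summary


def distance_statistics(
    annotations: Sequence[PASAnnotation], models: Sequence[GeneModel]
) -> Dict[str, object]:
    """Stop-to-first-PAS and adjacent-PAS distance distributions.

    The "first PAS" of a gene is its 3'UTR PAS nearest the stop codon;
    adjacent distances are computed between consecutive PAS of one gene
    sorted in transcription direction, both over all genic PAS and
    restricted to 3'UTR PAS.  Genes with fewer than two PAS contribute no
    adjacent distances.
    """
    strand_of = {m.gene_id: m.strand for m in models}
    by_gene: Dict[str, List[PASAnnotation]] = {}
    for a in annotations:
        if a.gene_id is not None:
            by_gene.setdefault(a.gene_id, []).append(a)
    stop_to_first: List[int] = []
    adjacent_all: List[int] = []
    adjacent_utr3: List[int] = []
    order_rows: List[dict] = []
    for gene_id, anns in sorted(by_gene.items()):
        reverse = strand_of.get(gene_id) == "-"
        positions = sorted((a.pas.position for a in anns), reverse=reverse)
        adjacent_all.extend(abs(b - a) for a, b in zip(positions, positions[1:]))
        utr = sorted(
            (a for a in anns if a.category == "3UTR"),
            key=lambda a: a.distance_to_stop,
        )
        if utr:
            stop_to_first.append(utr[0].distance_to_stop)
            for order, a in enumerate(utr, start=1):
                order_rows.append(
                    {"gene_id": gene_id, "pas_order": order, "distance_to_stop": a.distance_to_stop}
                )
        upos = [a.pas.position for a in utr]
        adjacent_utr3.extend(abs(b - a) for a, b in zip(upos, upos[1:]))
    return {
        "stop_to_first": stop_to_first,
        "adjacent_all": adjacent_all,
        "adjacent_utr3": adjacent_utr3,
        "median_stop_to_first": statistics.median(stop_to_first) if stop_to_first else None,
        "median_adjacent_all": statistics.median(adjacent_all) if adjacent_all else None,
        "median_adjacent_utr3": statistics.median(adjacent_utr3) if adjacent_utr3 else None,
        "pas_order_table": pd.DataFrame(
            order_rows, columns=["gene_id", "pas_order", "distance_to_stop"]
        ),
    }


def write_annotations(annotations: Sequence[PASAnnotation], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tposition\tstrand\treads\tcategory\tgene_id\tdistance_to_stop\n")
        for a in annotations:
            fh.write(
                f"{a.pas.chrom}\t{a.pas.position + 1}\t{a.pas.strand}\t"
                f"{a.pas.read_count}\t{a.category}\t{a.gene_id or '.'}\t"
                f"{a.distance_to_stop if a.distance_to_stop is not None else '.'}\n"
            )
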