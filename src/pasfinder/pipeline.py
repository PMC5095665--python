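"""End-to-end orchestration: simulate -> findtail -> map -> callpas -> annotate.

The pipeline chains the library stages over one sample, writing each
stage's artifact (FASTA/GTF/FASTQ/TSV/SAM/BED) plus a plain-text run report
with the surviving-item count after every stage.  Multi-sample usage and
differential analysis operate on the per-sample outputs via
:mod:`pasfinder.usage` (CLI subcommands ``usage`` and ``diff``).

Configuration is a flat ``key = value`` text file; unset keys keep the
pipeline's standard defaults (min_run=10, mismatch_frac=0.10,
min_trimmed_len=20, ip_run=9, ip_window=20, cluster_window=20,
min_site_reads=3, scale=1e8, fdr=0.05, min_lfc=1).  Identical config and
inputs reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

from . import annotation, calling, mapping, synthetic, tails, util


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All stage parameters with their standard defaults."""

    seed: int = 0
    library: str = "nss"  # "nss" | "ss"
    paired: bool = False
    single_end_rule: str = ""  # "" | "mate1" | "mate2" (ss unpaired only)

    # inputs (ignored when simulate is true)
    genome_fasta: str = ""
    gtf: str = ""
    fastq: str = ""
    fastq2: str = ""
    alignments: str = ""  # pre-computed SAM of trimmed reads

    # synthetic-data stage
    simulate: bool = False
    genome_length: int = 100_000
    n_genes: int = 10
    n_decoys: int = 5
    pas_per_gene: str = "1-6"
    utr_pas_spacing: str = "300"
    reads_per_pas: int = 5
    read_length: int = 50
    tail_length: int = 15
    error_rate: float = 0.0
    n_decoy_reads: int = 10

    # tail extraction
    min_run: int = 10
    mismatch_frac: float = 0.10
    min_trimmed_len: int = 20

    # mapping
    max_mismatches: int = 1

    # PAS calling
    cluster_window: int = 20
    min_site_reads: int = 3
    ip_window: int = 20
    ip_run: int = 9

    # usage analysis defaults (used by the usage/diff subcommands)
    scale: float = 1e8
    fdr: float = 0.05
    min_lfc: float = 1.0
    dispersion: str = "common"
    fixed_disp: float = 0.1

    def tail_params(self) -> tails.TailParameters:
        return tails.TailParameters(
            min_run=self.min_run,
            mismatch_fraction=self.mismatch_frac,
            min_trimmed_length=self.min_trimmed_len,
            library_mode=self.library,
        )

    def calling_params(self) -> calling.CallingParameters:
        return calling.CallingParameters(
            cluster_window=self.cluster_window,
            min_site_reads=self.min_site_reads,
            ip_window=self.ip_window,
            ip_run=self.ip_run,
        )

    def to_file(self, path: str) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_dict(cls, values: Dict[str, str]) -> "PipelineConfig":
        unknown = set(values) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise PipelineError(f"config: unknown keys {sorted(unknown)}")
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name not in values:
                continue
            raw = str(values[f.name])
            if isinstance(f.default, bool):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif isinstance(f.default, int):
                kwargs[f.name] = int(raw)
            elif isinstance(f.default, float):
                kwargs[f.name] = float(raw)
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        values: Dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                values[key.strip()] = value.strip()
        values.update({k: str(v) for k, v in overrides.items()})
        return cls.from_dict(values)


def _parse_range(spec: str) -> "int | Tuple[int, int]":
    if "-" in spec:
        lo, hi = spec.split("-", 1)
        return (int(lo), int(hi))
    return int(spec)


def run_pipeline(config: PipelineConfig, outdir: str) -> Dict[str, object]:
    """Execute the staged pipeline and return the run report as a dict.

    Artifacts land in ``outdir``; the report (also written to
    ``report.txt``) records the surviving-item counts after every stage:
    candidate polyadenylated reads -> trimmed retained -> uniquely mapped
    -> post-internal-priming sites -> clusters -> positive PAS.
    """
    os.makedirs(outdir, exist_ok=True)
    report: Dict[str, object] = {}

    # --- stage 0: inputs or simulation -------------------------------------
    truth = None
    if config.simulate:
        truth, gtf_text = synthetic.make_dataset(
            genome_length=config.genome_length,
            n_genes=config.n_genes,
            n_decoys=config.n_decoys,
            pas_per_gene=_parse_range(config.pas_per_gene),
            utr_pas_spacing=_parse_range(config.utr_pas_spacing),
            seed=config.seed,
        )
        genome = truth.genome
        gtf_path = os.path.join(outdir, "genes.gtf")
        with open(gtf_path, "w") as fh:
            fh.write(gtf_text)
        util.write_fasta(genome, os.path.join(outdir, "genome.fa"))
        sim = synthetic.simulate_reads(
            truth,
            reads_per_pas=config.reads_per_pas,
            read_length=config.read_length,
            tail_length=config.tail_length,
            error_rate=config.error_rate,
            library=config.library,
            paired=config.paired,
            n_decoy_reads=config.n_decoy_reads,
            seed=config.seed + 2,
        )
        sim.write_truth(os.path.join(outdir, "truth.tsv"))
        if config.paired:
            sim.write(os.path.join(outdir, "reads_1.fastq"), os.path.join(outdir, "reads_2.fastq"))
            read_sets = [(sim.mate1, 1), (sim.records, 2)]
        else:
            sim.write(os.path.join(outdir, "reads.fastq"))
            read_sets = [(sim.records, None)]
        report["input_reads"] = sim.n_reads
    else:
        if not config.genome_fasta or not os.path.exists(config.genome_fasta):
            raise PipelineError("config: genome_fasta missing or not found")
        if not config.fastq or not os.path.exists(config.fastq):
            raise PipelineError("config: fastq missing or not found")
        genome = util.read_fasta(config.genome_fasta)
        gtf_path = config.gtf
        reads1 = list(util.read_fastq(config.fastq))
        if config.paired:
            if not config.fastq2:
                raise PipelineError("config: paired input needs fastq2")
            reads2 = list(util.read_fastq(config.fastq2))
            read_sets = [(reads1, 1), (reads2, 2)]
        else:
            read_sets = [(reads1, None)]
        report["input_reads"] = sum(len(r) for r, _ in read_sets)

    # --- stage 1: tail detection and trimming -------------------------------
    params = config.tail_params()
    trimmed = []
    calls: Dict[str, tails.TailCall] = {}
    stats_total = {"total": 0, "candidate": 0, "ambiguous": 0, "too_short": 0, "retained": 0}
    for records, mate in read_sets:
        t, c, st = tails.extract_polyadenylated(
            records,
            params,
            mate=mate,
            single_end_rule=config.single_end_rule or None,
        )
        trimmed.extend(t)
        calls.update(c)
        for k in stats_total:
            stats_total[k] += st[k]
    util.write_fastq(trimmed, os.path.join(outdir, "trimmed.fastq"))
    tails.write_tailcalls(
        sorted(calls.values(), key=lambda c: c.read_id),
        os.path.join(outdir, "tailcalls.tsv"),
    )
    report["candidate_polyadenylated"] = stats_total["candidate"]
    report["trimmed_retained"] = stats_total["retained"]

    # --- stage 2: mapping ----------------------------------------------------
    if config.alignments:
        records, diag = mapping.import_alignments(config.alignments, calls)
    else:
        records = mapping.naive_map(
            trimmed, genome, max_mismatches=config.max_mismatches, tail_calls=calls
        )
        mapping.write_sam(
            records,
            {c: len(s) for c, s in genome.items()},
            os.path.join(outdir, "alignments.sam"),
        )
    unique = [r for r in records if r.unique]
    report["uniquely_mapped"] = len(unique)

    # --- stage 3-5: sites, internal-priming filter, clusters, positives -----
    cparams = config.calling_params()
    sites, site_diag = calling.infer_cleavage_sites(unique)
    report["putative_sites"] = len(sites)
    flagged = calling.filter_internal_priming(sites, genome, cparams)
    surviving = [s for s in flagged if not s.internal_priming]
    report["sites_after_ip_filter"] = len(surviving)
    clusters = calling.cluster_sites(flagged, cparams)
    clusters = [calling.call_positive_pas(c, cparams) for c in clusters]
    report["clusters"] = len(clusters)
    positives = calling.positive_sites(clusters)
    report["positive_pas"] = len(positives)
    calling.write_site_table(clusters, flagged, os.path.join(outdir, "sites.tsv"))
    calling.write_positive_bed(clusters, os.path.join(outdir, "positive_pas.bed"))

    # --- stage 6: annotation -------------------------------------------------
    if gtf_path and os.path.exists(gtf_path):
        models, _ = annotation.load_gene_models(gtf_path)
        annotations = annotation.annotate_pas(positives, models)
        annotation.write_annotations(annotations, os.path.join(outdir, "annotations.tsv"))
        cats = {}
        for a in annotations:
            cats[a.category] = cats.get(a.category, 0) + 1
        report["pas_categories"] = dict(sorted(cats.items()))
        if any(a.gene_id is not None for a in annotations):
            per_gene, summary = annotation.apa_summary(annotations)
            per_gene.to_csv(os.path.join(outdir, "apa_summary.tsv"), sep="\t")
            report["apa_fraction"] = round(summary["apa_fraction"], 6)
            dist = annotation.distance_statistics(annotations, models)
            report["median_stop_to_first"] = dist["median_stop_to_first"]
            report["median_adjacent_all"] = dist["median_adjacent_all"]

    with open(os.path.join(outdir, "report.txt"), "w") as fh:
        for key, value in report.items():
            fh.write(f"{key}\t{value}\n")
    return report
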