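"""GTF parsing, PAS category assignment and distance statistics."""

import pytest

from pasfinder.annotation import (
    annotate_pas,
    apa_summary,
    distance_statistics,
    load_gene_models,
)
from pasfinder.calling import CleavageSite


def pas(position, strand="+", chrom="chr1"):
    return CleavageSite(chrom, position, strand, read_count=5)


GTF_PLUS = """\
chr1\ttest\tgene\t1001\t3000\t.\t+\t.\tgene_id "gA";
chr1\ttest\ttranscript\t1001\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t1001\t1200\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\texon\t1501\t3000\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tCDS\t1001\t1200\t.\t+\t0\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tCDS\t1501\t1700\t.\t+\t0\tgene_id "gA"; transcript_id "gA.t1";
chr1\ttest\tstop_codon\t1701\t1703\t.\t+\t.\tgene_id "gA"; transcript_id "gA.t1";
"""


@pytest.fixture()
def plus_gene(tmp_path):
    p = tmp_path / "plus.gtf"
    p.write_text(GTF_PLUS)
    models, _ = load_gene_models(str(p))
    return models


class TestLoadGeneModels:
    def test_utr3_derivation_plus_strand(self, plus_gene):
        (m,) = plus_gene
        # stop codon ends at 0-based 1702; 3'UTR = exonic (1703, 3000]
        assert m.stop_last == 1702
        assert m.transcripts[0].utr3 == [(1703, 3000)]

    def test_transcript_without_cds_contributes_structure_only(self, tmp_path):
        gtf = (
            'chr1\tt\tgene\t101\t400\t.\t+\t.\tgene_id "gN";\n'
            'chr1\tt\ttranscript\t101\t400\t.\t+\t.\tgene_id "gN"; transcript_id "gN.t1";\n'
            'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "gN"; transcript_id "gN.t1";\n'
            'chr1\tt\texon\t301\t400\t.\t+\t.\tgene_id "gN"; transcript_id "gN.t1";\n'
        )
        p = tmp_path / "nc.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        (m,) = models
        assert m.stop_last is None
        assert m.transcripts[0].utr3 == []
        assert len(m.transcripts[0].exons) == 2

    def test_cds_outside_exons_skips_transcript(self, tmp_path):
        gtf = (
            'chr1\tt\tgene\t101\t400\t.\t+\t.\tgene_id "gB";\n'
            'chr1\tt\ttranscript\t101\t400\t.\t+\t.\tgene_id "gB"; transcript_id "gB.t1";\n'
            'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "gB"; transcript_id "gB.t1";\n'
            'chr1\tt\tCDS\t251\t350\t.\t+\t0\tgene_id "gB"; transcript_id "gB.t1";\n'
        )
        p = tmp_path / "bad.gtf"
        p.write_text(gtf)
        models, diag = load_gene_models(str(p))
        assert diag["skipped_inconsistent"] == 1
        assert models[0].transcripts == []

    def test_stop_codon_derived_from_cds_when_absent(self, tmp_path):
        gtf = "".join(
            line for line in GTF_PLUS.splitlines(keepends=True) if "stop_codon" not in line
        )
        p = tmp_path / "nostop.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        assert models[0].stop_last == 1702


class TestAnnotatePas:
    def test_categories_partition_pas_set(self, plus_gene):
        positions = [1800, 1100, 1300, 5000, 1600]
        anns = annotate_pas([pas(p) for p in positions], plus_gene)
        cats = [a.category for a in anns]
        assert cats == ["3UTR", "ORF", "intron", "intergenic", "ORF"]
        assert len(anns) == len(positions)

    def test_distance_to_stop_only_for_utr3(self, plus_gene):
        anns = annotate_pas([pas(2002), pas(1100)], plus_gene)
        assert anns[0].distance_to_stop == 300
        assert anns[1].distance_to_stop is None

    def test_opposite_strand_gene_is_intergenic(self, plus_gene):
        (a,) = annotate_pas([pas(1800, strand="-")], plus_gene)
        assert a.category == "intergenic" and a.gene_id is None

    def test_precedence_cds_over_intron_across_isoforms(self, tmp_path):
        # isoform t1 has an intron over [201, 300]; isoform t2 has CDS there
        gtf = (
            'chr1\tt\tgene\t101\t400\t.\t+\t.\tgene_id "gC";\n'
            'chr1\tt\ttranscript\t101\t400\t.\t+\t.\tgene_id "gC"; transcript_id "t1";\n'
            'chr1\tt\texon\t101\t200\t.\t+\t.\tgene_id "gC"; transcript_id "t1";\n'
            'chr1\tt\texon\t301\t400\t.\t+\t.\tgene_id "gC"; transcript_id "t1";\n'
            'chr1\tt\ttranscript\t101\t400\t.\t+\t.\tgene_id "gC"; transcript_id "t2";\n'
            'chr1\tt\texon\t101\t400\t.\t+\t.\tgene_id "gC"; transcript_id "t2";\n'
            'chr1\tt\tCDS\t101\t340\t.\t+\t0\tgene_id "gC"; transcript_id "t2";\n'
        )
        p = tmp_path / "iso.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        (a,) = annotate_pas([pas(250)], models)
        assert a.category == "ORF"

    def test_synthetic_truth_pas_all_annotate_as_utr3(self, small_dataset, tmp_path):
        truth, gtf = small_dataset
        p = tmp_path / "genes.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        sites = [
            CleavageSite(g.chrom, position, g.strand, 5)
            for g in truth.genes
            for position in g.pas_positions
        ]
        anns = annotate_pas(sites, models)
        assert all(a.category == "3UTR" for a in anns)
        by_gene_pos = {
            (g.gene_id, position): abs(position - g.stop_last)
            for g in truth.genes
            for position in g.pas_positions
        }
        for a in anns:
            assert a.distance_to_stop == by_gene_pos[(a.gene_id, a.pas.position)]


class TestSummaries:
    def make_annotations(self, models):
        return annotate_pas([pas(1800), pas(2100), pas(1100)], models)

    def test_apa_summary_counts(self, plus_gene):
        df, summary = apa_summary(self.make_annotations(plus_gene))
        assert df.loc["gA", "n_pas"] == 3
        assert df.loc["gA", "n_utr3_pas"] == 2
        assert summary["apa_fraction"] == 1.0

    def test_apa_fraction_half(self, plus_gene, tmp_path):
        gtf2 = GTF_PLUS.replace("gA", "gB").replace("chr1", "chr2")
        p = tmp_path / "two.gtf"
        p.write_text(GTF_PLUS + gtf2)
        models, _ = load_gene_models(str(p))
        anns = annotate_pas([pas(1800), pas(2100), pas(1800, chrom="chr2")], models)
        _, summary = apa_summary(anns)
        assert summary["apa_fraction"] == 0.5

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            apa_summary([])

    def test_distance_statistics_plus_strand(self, plus_gene):
        anns = annotate_pas([pas(2002), pas(2302)], plus_gene)
        stats = distance_statistics(anns, plus_gene)
        assert stats["stop_to_first"] == [300]
        assert stats["adjacent_all"] == [300]
        assert stats["median_stop_to_first"] == 300

    def test_distance_statistics_minus_strand_symmetric(self, tmp_path):
        # mirror geometry: stop at 0-based 2000, PASs at 1700 and 1400 (-)
        gtf = (
            'chr1\tt\tgene\t1001\t3000\t.\t-\t.\tgene_id "gM";\n'
            'chr1\tt\ttranscript\t1001\t3000\t.\t-\t.\tgene_id "gM"; transcript_id "m.t1";\n'
            'chr1\tt\texon\t1001\t3000\t.\t-\t.\tgene_id "gM"; transcript_id "m.t1";\n'
            'chr1\tt\tCDS\t2004\t3000\t.\t-\t0\tgene_id "gM"; transcript_id "m.t1";\n'
            'chr1\tt\tstop_codon\t2001\t2003\t.\t-\t.\tgene_id "gM"; transcript_id "m.t1";\n'
        )
        p = tmp_path / "minus.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        anns = annotate_pas([pas(1700, "-"), pas(1400, "-")], models)
        stats = distance_statistics(anns, models)
        assert stats["stop_to_first"] == [300]
        assert stats["adjacent_all"] == [300]

    def test_constant_spacing_median_exact(self, tmp_path):
        from pasfinder import synthetic

        truth, gtf = synthetic.make_dataset(
            genome_length=120_000, n_genes=8, n_decoys=0,
            pas_per_gene=3, utr_pas_spacing=300, seed=2,
        )
        p = tmp_path / "genes.gtf"
        p.write_text(gtf)
        models, _ = load_gene_models(str(p))
        sites = [
            CleavageSite(g.chrom, position, g.strand, 5)
            for g in truth.genes
            for position in g.pas_positions
        ]
        stats = distance_statistics(annotate_pas(sites, models), models)
        assert stats["median_stop_to_first"] == 300
        assert stats["median_adjacent_all"] == 300
        assert stats["median_adjacent_utr3"] == 300
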