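"""Cleavage-site inference, internal-priming filter, clustering, positives."""

import numpy as np
import pytest

from pasfinder.calling import (
    CallingParameters,
    CleavageSite,
    call_positive_pas,
    cluster_sites,
    filter_internal_priming,
    heterogeneity_profile,
    infer_cleavage_sites,
)
from pasfinder.mapping import AlignmentRecord


def aln(read_id="r", start=100, end=130, strand="+", side="3prime", base="A", unique=True):
    return AlignmentRecord(
        read_id=read_id,
        chrom="chr1",
        start=start,
        end=end,
        strand=strand,
        n_mismatches=0,
        unique=unique,
        tail_side=side,
        tail_base=base,
    )


def site(position, strand="+", reads=1, ip=False):
    return CleavageSite("chr1", position, strand, reads, ip)


class TestInferCleavageSites:
    @pytest.mark.parametrize(
        "side,base,strand,expected",
        [
            ("3prime", "A", "+", (129, "+")),
            ("3prime", "A", "-", (100, "-")),
            ("5prime", "T", "+", (100, "-")),
            ("5prime", "T", "-", (129, "+")),
        ],
    )
    def test_orientation_table(self, side, base, strand, expected):
        sites, _ = infer_cleavage_sites([aln(side=side, base=base, strand=strand)])
        assert [(s.position, s.strand) for s in sites] == [expected]

    @pytest.mark.parametrize("side,base", [("5prime", "A"), ("3prime", "T")])
    def test_non_polya_geometries_rejected(self, side, base):
        """5' A-runs and 3' T-runs cannot arise from a poly(A) tail."""
        for strand in "+-":
            sites, diag = infer_cleavage_sites([aln(side=side, base=base, strand=strand)])
            assert sites == [] and diag["inconsistent_tail"] == 1

    def test_same_position_reads_merge(self):
        sites, _ = infer_cleavage_sites([aln("r1"), aln("r2")])
        assert len(sites) == 1 and sites[0].read_count == 2

    def test_non_unique_alignments_skipped(self):
        sites, diag = infer_cleavage_sites([aln(unique=False)])
        assert sites == [] and diag["non_unique"] == 1


class TestInternalPrimingFilter:
    def make_genome(self, downstream, site_pos=99):
        # site at 99 on +: downstream window is [100, 120)
        prefix = "CGCGCGCGCG" * 10
        return {"chr1": prefix[: site_pos + 1] + downstream + "CG" * 40}

    def test_nine_consecutive_a_downstream_flags_site(self):
        genome = self.make_genome("AAAAAAAAACGTACGTACGT")
        (flagged,) = filter_internal_priming([site(99)], genome)
        assert flagged.internal_priming

    def test_eight_consecutive_a_downstream_does_not_flag(self):
        genome = self.make_genome("AAAAAAAACGTACGTACGTA")
        (flagged,) = filter_internal_priming([site(99)], genome)
        assert not flagged.internal_priming

    def test_t_runs_also_trigger(self):
        genome = self.make_genome("TTTTTTTTTCGTACGTACGT")
        (flagged,) = filter_internal_priming([site(99)], genome)
        assert flagged.internal_priming

    def test_minus_strand_scans_upstream_in_genome_coordinates(self):
        # - strand site at 120: transcription-direction downstream is [100, 120)
        genome = self.make_genome("TTTTTTTTTCGTACGTACGT")
        (flagged,) = filter_internal_priming([site(120, strand="-")], genome)
        assert flagged.internal_priming

    def test_window_truncated_at_chromosome_end(self):
        genome = {"chr1": "CG" * 50 + "AAAA"}
        (flagged,) = filter_internal_priming([site(99)], genome)
        assert not flagged.internal_priming

    def test_missing_chromosome_is_hard_error(self):
        with pytest.raises(KeyError):
            filter_internal_priming([CleavageSite("chrX", 10, "+", 1)], {"chr1": "ACGT"})

    def test_synthetic_decoys_flagged_and_true_pas_clean(self, small_dataset, small_reads):
        from pasfinder import mapping, tails

        truth, _ = small_dataset
        trimmed, calls, _ = tails.extract_polyadenylated(small_reads.records)
        recs = mapping.naive_map(trimmed, truth.genome, tail_calls=calls)
        sites, _ = infer_cleavage_sites([r for r in recs if r.unique])
        flagged = filter_internal_priming(sites, truth.genome)
        true_positions = {(p, g.strand) for g in truth.genes for p in g.pas_positions}
        for s in flagged:
            if (s.position, s.strand) in true_positions:
                assert not s.internal_priming
            else:
                assert s.internal_priming  # decoy-derived site


def brute_force_clusters(sites, window):
    """Transitive-closure oracle: union positions within `window` on one
    chrom/strand, independent of the sweep implementation."""
    groups = []
    for s in sites:
        merged = [g for g in groups if any(
            x.chrom == s.chrom and x.strand == s.strand and abs(x.position - s.position) <= window
            for x in g
        )]
        newg = {s}
        for g in merged:
            newg |= g
            groups.remove(g)
        groups.append(newg)
    # transitive closure via repeated merging
    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    a.chrom == b.chrom and a.strand == b.strand and abs(a.position - b.position) <= window
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] |= groups[j]
                    del groups[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset((s.chrom, s.position, s.strand) for s in g) for g in groups}


class TestClusterSites:
    def test_gap_rule(self):
        clusters = cluster_sites([site(100), site(115), site(140)])
        assert [[s.position for s in c.sites] for c in clusters] == [[100, 115], [140]]

    def test_gap_exactly_twenty_joins(self):
        clusters = cluster_sites([site(100), site(120)])
        assert len(clusters) == 1

    def test_single_site_singleton(self):
        clusters = cluster_sites([site(100)])
        assert len(clusters) == 1 and clusters[0].n_sites == 1

    def test_strands_never_mix(self):
        clusters = cluster_sites([site(100, "+"), site(105, "-")])
        assert len(clusters) == 2

    def test_flagged_sites_excluded(self):
        clusters = cluster_sites([site(100), site(105, ip=True)])
        assert len(clusters) == 1 and clusters[0].n_sites == 1

    def test_matches_transitive_closure_oracle_and_order_invariance(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            sites = [
                site(int(rng.integers(0, 500)), rng.choice(["+", "-"]))
                for _ in range(int(rng.integers(2, 100)))
            ]
            # deduplicate positions per strand (merge rule upstream)
            seen = {}
            for s in sites:
                seen[(s.chrom, s.position, s.strand)] = s
            sites = list(seen.values())
            expected = brute_force_clusters(sites, 20)
            got = {
                frozenset((s.chrom, s.position, s.strand) for s in c.sites)
                for c in cluster_sites(sites)
            }
            assert got == expected
            shuffled = list(sites)
            rng.shuffle(shuffled)
            got2 = {
                frozenset((s.chrom, s.position, s.strand) for s in c.sites)
                for c in cluster_sites(shuffled)
            }
            assert got2 == expected

    def test_total_reads_conserved(self):
        clusters = cluster_sites([site(100, reads=2), site(110, reads=5)])
        assert clusters[0].total_reads == 7


class TestCallPositive:
    def test_max_read_count_wins(self):
        (c,) = cluster_sites([site(100, reads=2), site(105, reads=7), site(110, reads=3)])
        assert call_positive_pas(c).positive_site.position == 105

    def test_below_three_reads_no_positive(self):
        (c,) = cluster_sites([site(100, reads=2), site(105, reads=2)])
        assert call_positive_pas(c).positive_site is None

    def test_exactly_three_reads_retained(self):
        (c,) = cluster_sites([site(100, reads=3)])
        assert call_positive_pas(c).positive_site is not None

    @pytest.mark.parametrize("strand,winner", [("+", 110), ("-", 100)])
    def test_tie_breaks_to_three_prime_most(self, strand, winner):
        (c,) = cluster_sites([site(100, strand, 5), site(110, strand, 5)])
        assert call_positive_pas(c).positive_site.position == winner

    def test_raising_min_site_reads_never_increases_positives(self):
        rng = np.random.default_rng(23)
        sites = [
            site(int(p), reads=int(r))
            for p, r in zip(rng.integers(0, 2000, 60), rng.integers(1, 8, 60))
        ]
        seen = {}
        for s in sites:
            seen[s.position] = s
        sites = list(seen.values())
        previous = None
        for threshold in (1, 2, 3, 5, 8):
            params = CallingParameters(min_site_reads=threshold)
            n = sum(
                1
                for c in cluster_sites(sites, params)
                if call_positive_pas(c, params).positive_site is not None
            )
            if previous is not None:
                assert n <= previous
            previous = n


class TestHeterogeneity:
    def test_profile_fractions(self):
        clusters = []
        for n in (1, 1, 1, 2, 3):
            clusters.extend(cluster_sites([site(1000 * len(clusters) + 10 * i) for i in range(n)]))
        profile = heterogeneity_profile(clusters)
        assert profile == {"1": 0.6, "2": 0.2, ">2": 0.2}
        assert abs(sum(profile.values()) - 1.0) < 1e-12

    def test_all_singletons(self):
        clusters = cluster_sites([site(100), site(500), site(900)])
        assert heterogeneity_profile(clusters) == {"1": 1.0, "2": 0.0, ">2": 0.0}

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            heterogeneity_profile([])

    def test_jitter_model_matches_designed_singleton_fraction(self):
        """Sites drawn with a known per-PAS jitter produce the expected
        share of single-site clusters (independent binomial model)."""
        rng = np.random.default_rng(31)
        p_extra = 0.3  # chance a PAS locus gains a second end 5 nt away
        n_loci = 4000
        sites = []
        extra = rng.random(n_loci) < p_extra
        for i in range(n_loci):
            base = 100 + 1000 * i
            sites.append(site(base, reads=5))
            if extra[i]:
                sites.append(site(base + 5, reads=2))
        profile = heterogeneity_profile(cluster_sites(sites))
        se = (p_extra * (1 - p_extra) / n_loci) ** 0.5
        assert abs(profile["1"] - (1 - p_extra)) < 4 * se
        assert profile[">2"] == 0.0
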