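# Methods

This note documents the models, rules and numerical choices behind
`pasfinder`, in the order the pipeline applies them, followed by an account
of the synthetic-data generator and the limitations of both.

## Tail detection

A candidate polyadenylated read is one that failed genome alignment but
starts or ends with a poly(T)/poly(A) homopolymer. "A run of at least 10 nt
with 10% mismatch" admits several formalizations; the one used here is:

> the **longest end-anchored window** whose non-tail-base count is at most
> `floor(mismatch_fraction × window_length)`, whose outermost (terminal)
> base is the tail base, and whose innermost base is the tail base (a run
> never ends on a mismatch). `N` counts as a mismatch. The window must be
> at least `min_run` nt.

This definition is deterministic, independent of scan direction, and
checkable against an exhaustive enumeration of terminal substrings (the
test suite and the acceptance script both run that oracle on 10,000 random
reads). Taking the *longest* qualifying window rather than the minimal one
means a tail such as `…A C AAAAAAAAAA` is reported as a 12-nt run with one
mismatch: the mismatch budget is spent absorbing adjacent A-context, which
is the behaviour wanted for trimming (the alternative leaves templated-A
ambiguity in the read body).

Library geometry: in non-strand-specific mode all four (end, base)
configurations are tested and a read qualifying at **both** ends is
excluded as ambiguous, since one read cannot evidence two cleavage events.
In strand-specific mode only mate 1/5′ poly(T) and mate 2/3′ poly(A) are
tested; unpaired strand-specific input requires an explicit
`single_end_rule`.

Parameters (defaults): `min_run = 10` nt, `mismatch_fraction = 0.10`,
`min_trimmed_length = 20` nt. Trimming removes exactly the called run;
bodies shorter than 20 nt are discarded.

## Mapping and uniqueness

Internally all coordinates are 0-based half-open; SAM's 1-based convention
is converted at the boundary. In production the trimmed bodies are aligned
by an external aligner and imported from SAM/BAM. A read is treated as
**uniquely mapped** when the file contains no secondary record for its id
and any NH tag is ≤ 1; how multi-mapping is reported is aligner
configuration, so this contract is deliberately explicit rather than
inferred from scores.

The built-in test mapper indexes every genomic 10-mer and places each read
by the pigeonhole principle: with at most *m* substitutions, one of *m*+1
non-overlapping read chunks must match exactly. Every candidate offset on
both strands is verified by direct comparison, all best-scoring loci are
reported, and `unique` is true only when exactly one best locus exists.
This is an exhaustive search (it provably finds all loci within the
mismatch budget), intended for test-scale genomes of a few Mb.

## Cleavage-site inference

The cleavage position is the last transcribed base, recovered from the
tail side of the alignment:

| tail (read-relative) | aligned strand | site | transcript strand |
|---|---|---|---|
| 3′ poly(A) | + | `end − 1` | + |
| 3′ poly(A) | − | `start`   | − |
| 5′ poly(T) | + | `start`   | − |
| 5′ poly(T) | − | `end − 1` | + |

The remaining combinations (5′ poly(A), 3′ poly(T)) cannot arise from a
poly(A) tail in any sequencing orientation — they are genomic homopolymers
or artifacts — and are rejected with a counted diagnostic. Sites at the
same (chrom, position, strand) merge with summed read counts.

## Internal-priming filter

Oligo-dT can prime on genomically templated A-rich stretches inside a
transcript, producing reads that look polyadenylated. A putative site is
flagged when the `ip_window = 20` nt immediately downstream of the
cleavage base, read in transcription orientation, contains
`ip_run = 9` or more consecutive A **or** T. Both bases trigger the filter
(only A-runs model canonical oligo-dT mispriming; the symmetric T rule is
kept for fidelity to the established filtering convention). Windows
truncated at chromosome ends are scanned as-is. Only the run length is a
field-standard constant; the 20-nt window length is this package's
explicit, flag-settable choice.

## Clustering and positive calling

Cleavage sites show 3′-end heterogeneity, so same-strand sites are chained
by single linkage: a new cluster starts when the gap to the previous site
exceeds `cluster_window = 20` nt (inclusive boundary: a gap of exactly
20 nt joins). Within a cluster, sites with fewer than `min_site_reads = 3`
supporting reads are dropped from candidacy; the remaining site with the
highest read count is the **positive PAS**, ties broken toward the 3′-most
position in transcription direction (a deterministic rule biased toward
the distal-cleavage convention). The read threshold applies per site, not
to cluster totals. Clusters with no candidate produce no positive PAS but
still appear in the site table.

## Annotation and distance statistics

3′UTRs are derived from GTF models as the exonic sequence strictly
downstream of the stop codon in transcription direction (when a
`stop_codon` feature is absent, the stop codon is assumed to occupy the
3 nt following the CDS, matching Ensembl's CDS convention). A PAS is
assigned only to same-strand genes whose span contains it, with category
precedence **3′UTR > ORF > intron** across all overlapping transcripts —
the precedence puts the APA-relevant category first; exonic positions
upstream of the CDS fall through to the generic intragenic (intron)
category. When several genes qualify at the same precedence the gene with
the nearest stop codon wins. The four categories partition the PAS set.

Distances (stop codon → first 3′UTR PAS; adjacent PAS per gene) are
**genomic** distances in transcription direction, not spliced distances;
at desk scale the generator places all PAS in a single 3′UTR exon, where
the two coincide.

## Usage quantification and differential testing

Usage of a PAS in a sample is `count × 10⁸ / total polyadenylated reads`,
where a read counts toward a PAS when its cleavage position falls within
the PAS cluster's span on the same strand — the span rule, rather than
exact positive-site identity, because per-sample reads show the same end
heterogeneity the clusters were built from.

Differential usage between two groups uses a conditional NB exact test on
the group sums: with `S₁ ~ NB(mean s·M₁/(M₁+M₂), size n₁/φ)` and `S₂`
analogous (sums of per-sample NB counts with library-size offsets `M_g`),
the two-sided p-value is the total conditional probability, given
`S₁+S₂ = s`, of outcomes no more likely than the observed split. Zero
dispersion reduces exactly to the binomial split. Dispersion `φ` is
estimated by the method of moments on counts adjusted to a common library
size (`φ = (var − μ)/μ²` pooled within groups):

* `common` — the ratio of summed numerators to summed denominators across
  all PAS (far more stable than averaging noisy per-PAS ratios; with
  n = 5 per group, per-PAS moment estimates have only ~8 df);
* `tagwise` — per-PAS estimates shrunk toward the common value,
  `φᵢ' = w·φ_common + (1−w)·φᵢ` with `shrink_weight w = 0.5` by default;
* `fixed` — a user-set value (default 0.1), required for designs without
  replicates where dispersion is unidentifiable.

Negative moment estimates are clamped to 0 (Poisson) with a diagnostic.
P-values are Benjamini–Hochberg adjusted; significance requires
FDR < 0.05 **and** |log2FC| ≥ 1. The fold change is computed on mean
normalized usage with a pseudocount of 0.5 normalized units to avoid
infinities at zero counts. This is an in-package test in the spirit of
count-based differential tools; it is simulation-validated (type-I error
within sampling error of nominal at 1,000 null PAS with n = 5 per group;
≥ 80% power over 200 replicates for a 4-fold difference at dispersion
0.1), not a numerical reimplementation of any external package.

## The synthetic-data generator

The generator exists so that every stage has exact ground truth:

* **Genome** — i.i.d. bases at the requested GC fraction. Accidental
  homopolymers are broken (every 7th base of a run substituted), so no
  A/T run of ≥ 9 nt exists outside planted decoys and a true PAS can never
  trip the internal-priming filter. Decoys are planted runs of 10–14 A or
  T at recorded, non-overlapping positions — at least 10 nt so that decoy
  reads clear the read-level tail threshold and only the genomic filter
  can remove them.
* **Gene models** — two-exon protein-coding genes (150-nt exon 1, 120-nt
  intron, 150-nt CDS in exon 2) with 1–6 PAS placed downstream of the stop
  codon at spacings drawn from a configurable constant or uniform range;
  the same draw spaces stop→first-PAS and adjacent PAS, giving the
  distance statistics a known target. Genes avoid decoy neighbourhoods.
* **Reads** — each PAS read is the genomic body ending at the cleavage
  base plus a non-templated poly(A) tail (appended *after* the templated
  cleavage base, matching the site definition); decoy reads are pure
  genomic copies ending inside a planted run. Substitution errors are
  uniform per base. A 12-nt zone upstream of each planted PAS is
  "hardened" (A→C/G in mRNA sense) so the tail/body boundary is
  unambiguous under the longest-window rule and error-free recovery is
  exact to the base.
* Truth tables are TSV sidecars keyed by read id; FASTQ stays standard.
  All randomness flows from one integer seed and regeneration is
  byte-identical.

What the generator does **not** emulate: realistic expression levels,
spliced reads across the PAS-bearing exon, position-specific quality/error
models, adapter contamination, or genomes with repeat structure. Passing
the recovery tests therefore demonstrates the correctness of the
*rules* — detection, trimming geometry, orientation logic, filtering,
clustering, thresholds — not performance on repetitive or noisy real data,
where alignment uniqueness and sequencing error dominate.

## Problem sizes and numerical choices

The bundled verification runs use a ~1 Mb genome with 50 genes (about 175
PAS) and 5 reads per PAS for end-to-end recovery, 15 genes at constant
300-nt spacing for the distance statistics, 1,000 PAS × 5+5 samples for
null calibration and 200 replicates for power — sizes chosen so the whole
suite completes in well under a minute while every count involved stays
large enough for the stated tolerances. The NB exact test enumerates the
full conditional support (group sums at these depths are a few thousand);
p-values use log-space pmf evaluation, and the observed-probability
comparison uses a 1e-10 relative tolerance to make ties robust to
floating-point noise. Dispersions below 1e-12 switch to the exact binomial
limit.

## Known limitations

* Spliced alignment is out of scope for the test mapper; reads spanning
  exon junctions require an external spliced aligner.
* The annotation step assigns a PAS to one gene and one category; genuinely
  overlapping genes at equal precedence are resolved by stop-codon
  proximity, which is a convention, not biology.
* Stop-to-PAS distances are genomic; for genes with introns in the 3′UTR
  the spliced distance would differ.
* The differential test conditions on group sums with an equal-mean
  library-size split; strongly unbalanced library sizes within a group are
  handled only through the offset in the conditional mean, not per-sample.
* No poly(A)-signal motif model (AAUAAA variants) is used anywhere; calls
  rest on read evidence and the internal-priming filter alone.
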