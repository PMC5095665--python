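"""PAS usage quantification and differential-usage testing.

Usage of a PAS in a sample is the number of polyadenylated reads whose
inferred cleavage position falls in the PAS cluster's span, normalized to
the sample's total polyadenylated reads and rescaled by 1e8.

Differential usage between two groups is assessed with a conditional
negative-binomial (NB) exact test on the group count sums with library-size
offsets.  Dispersion is estimated by the method of moments on
library-size-adjusted counts, either as a single common value across PAS,
as a tagwise value shrunk toward the common one, or fixed by the user for
designs without replicates (where dispersion is unidentifiable).  P-values
are Benjamini-Hochberg adjusted; a PAS is significant when FDR and absolute
log2 fold change clear their thresholds (defaults 0.05 and 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import CleavageSite, PASCluster

DEFAULT_SCALE = 1e8


@dataclass
class UsageTable:
    """PAS x sample polyadenylated-read counts with normalization metadata."""

    counts: pd.DataFrame  # integer counts, index = pas id, columns = samples
    sample_totals: pd.Series  # total polyadenylated reads per sample
    scale: float = DEFAULT_SCALE

    @property
    def normalized(self) -> pd.DataFrame:
        """count * scale / sample_total, exactly."""
        return self.counts * self.scale / self.sample_totals

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)


def count_usage(
    clusters: Sequence[PASCluster],
    per_sample_sites: Mapping[str, Sequence[CleavageSite]],
    scale: float = DEFAULT_SCALE,
    sample_totals: Optional[Mapping[str, int]] = None,
) -> Tuple[UsageTable, Dict[str, int]]:
    """Count each sample's cleavage-site reads against the positive PAS set.

    A read supports a PAS when its cleavage position falls within the PAS
    cluster's span (inclusive of both boundary member sites) on the same
    strand; end heterogeneity within a cluster therefore counts toward its
    PAS.  Sample totals default to the sum of all of the sample's site
    reads (its total polyadenylated reads).  Samples with a zero total are
    rejected with a diagnostic.
    """
    called = [(i, c) for i, c in enumerate(clusters) if c.positive_site is not None]
    pas_ids = [f"cluster{i:06d}" for i, _ in called]
    diagnostics = {"rejected_samples": 0}
    data: Dict[str, List[int]] = {}
    totals: Dict[str, int] = {}
    for sample, sites in per_sample_sites.items():
        total = (
            int(sample_totals[sample])
            if sample_totals is not None
            else sum(s.read_count for s in sites)
        )
        if total <= 0:
            diagnostics["rejected_samples"] += 1
            continue
        col = []
        for _, cluster in called:
            n = sum(
                s.read_count
                for s in sites
                if s.chrom == cluster.chrom
                and s.strand == cluster.strand
                and cluster.start <= s.position < cluster.end
            )
            col.append(n)
        data[sample] = col
        totals[sample] = total
    counts = pd.DataFrame(data, index=pas_ids)
    table = UsageTable(counts=counts, sample_totals=pd.Series(totals), scale=scale)
    return table, diagnostics


def _moment_dispersions(
    adj: pd.DataFrame, group_cols: Sequence[Sequence[str]]
) -> Tuple[np.ndarray, float, int]:
    """Method-of-moments dispersion on library-size-adjusted counts.

    For NB counts, var = mu + phi * mu^2, so phi = (var - mu) / mu^2 with
    within-group means and variances pooled across groups.  Returns the
    per-PAS estimates (for tagwise shrinkage), the common estimate (ratio
    of summed numerators to summed denominators across PAS, which is far
    more stable than averaging noisy per-PAS ratios), and the number of
    negative per-PAS estimates clamped to 0 (Poisson).
    """
    n_pas = len(adj)
    num = np.zeros(n_pas)
    den = np.zeros(n_pas)
    for cols in group_cols:
        sub = adj[list(cols)].to_numpy(dtype=float)
        if sub.shape[1] < 2:
            continue
        mu = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        num += (sub.shape[1] - 1) * (var - mu)
        den += (sub.shape[1] - 1) * mu**2
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    common = float(max(num.sum() / den.sum(), 0.0)) if den.sum() > 0 else 0.0
    clamped = int(np.sum(phi < 0))
    return np.clip(phi, 0.0, None), common, clamped


def _nb_exact_pvalue(s1: int, s2: int, m_frac: float, r1: float, r2: float) -> float:
    """Two-sided conditional exact test for S1 given S1 + S2 = s.

    S1 ~ NB(mean = s * m_frac, size = r1) and S2 ~ NB(mean = s * (1 -
    m_frac), size = r2) independently under the null; p is the total
    conditional probability of outcomes no more likely than the observed
    one.  Infinite sizes (zero dispersion) reduce to the exact binomial
    split.
    """
    s = s1 + s2
    if s == 0:
        return 1.0
    if not np.isfinite(r1) or not np.isfinite(r2):
        pmf = stats.binom.pmf(np.arange(s + 1), s, m_frac)
    else:
        m1 = s * m_frac
        m2 = s - m1
        p1 = r1 / (r1 + m1)
        p2 = r2 / (r2 + m2)
        k = np.arange(s + 1)
        logpmf = stats.nbinom.logpmf(k, r1, p1) + stats.nbinom.logpmf(s - k, r2, p2)
        logpmf -= logpmf.max()
        pmf = np.exp(logpmf)
    total = pmf.sum()
    if total <= 0:
        return 1.0
    observed = pmf[s1]
    return float(pmf[pmf <= observed * (1 + 1e-10)].sum() / total)


def differential_usage(
    table: UsageTable,
    groups: Mapping[str, str],
    dispersion: str = "common",
    fixed_disp: float = 0.1,
    shrink_weight: float = 0.5,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
    pseudocount: float = 0.5,
    group_order: Optional[Sequence[str]] = None,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """NB exact test of per-PAS usage between two groups.

    ``groups`` maps sample -> group label (exactly two labels).  The fold
    change is ``log2((mean usage in first group + pseudocount) / (mean
    usage in second group + pseudocount))`` on the normalized scale, with
    the group order taken from ``group_order`` or sorted labels.

    Dispersion modes: ``common`` (single pooled moment estimate across
    PAS), ``tagwise`` (per-PAS estimates
    shrunk toward the common value with weight ``shrink_weight`` on the
    common component), ``fixed`` (user-set value, required for
    no-replicate designs).
    """
    if dispersion not in ("common", "tagwise", "fixed"):
        raise ValueError("dispersion must be 'common', 'tagwise' or 'fixed'")
    labels = group_order or sorted(set(groups.values()))
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    g1_cols = [s for s in table.samples if groups.get(s) == labels[0]]
    g2_cols = [s for s in table.samples if groups.get(s) == labels[1]]
    if not g1_cols or not g2_cols:
        raise ValueError("each group needs at least one sample")
    lib = table.sample_totals
    m1_tot, m2_tot = lib[g1_cols].sum(), lib[g2_cols].sum()
    if m1_tot <= 0 or m2_tot <= 0:
        raise ValueError("a group has all-zero library totals")

    diagnostics = {"clamped_dispersions": 0}
    # counts adjusted to a common library size for moment estimation
    common_lib = float(np.exp(np.log(lib.astype(float)).mean()))
    adj = table.counts * common_lib / lib
    if dispersion == "fixed":
        phi = np.full(len(table.counts), float(fixed_disp))
    else:
        phi_tag, phi_common, clamped = _moment_dispersions(adj, [g1_cols, g2_cols])
        diagnostics["clamped_dispersions"] = clamped
        if dispersion == "common":
            phi = np.full(len(table.counts), phi_common)
        else:
            phi = shrink_weight * phi_common + (1.0 - shrink_weight) * phi_tag

    norm = table.normalized
    mean1 = norm[g1_cols].mean(axis=1).to_numpy()
    mean2 = norm[g2_cols].mean(axis=1).to_numpy()
    lfc = np.log2((mean1 + pseudocount) / (mean2 + pseudocount))
    m_frac = float(m1_tot / (m1_tot + m2_tot))
    s1 = table.counts[g1_cols].sum(axis=1).to_numpy()
    s2 = table.counts[g2_cols].sum(axis=1).to_numpy()
    pvals = np.empty(len(table.counts))
    for i in range(len(pvals)):
        if phi[i] <= 1e-12:
            r1 = r2 = np.inf
        else:
            r1 = len(g1_cols) / phi[i]
            r2 = len(g2_cols) / phi[i]
        pvals[i] = _nb_exact_pvalue(int(s1[i]), int(s2[i]), m_frac, r1, r2)
    fdr = multipletests(pvals, method="fdr_bh")[1]
    result = pd.DataFrame(
        {
            "pas": table.counts.index,
            f"mean_{labels[0]}": mean1,
            f"mean_{labels[1]}": mean2,
            "log2FC": lfc,
            "dispersion": phi,
            "pvalue": pvals,
            "FDR": fdr,
        }
    ).set_index("pas")
    result["significant"] = (result["FDR"] < fdr_threshold) & (
        result["log2FC"].abs() >= lfc_threshold
    )
    return result, diagnostics


def compare_pas_sets(
    pas_sets: Mapping[str, Sequence[PASCluster]],
) -> pd.DataFrame:
    """Overlap table of positive-PAS sets across sample groups.

    Two PAS from different groups are the same locus when their cluster
    spans overlap on the same chrom and strand.  Overlapping spans (across
    all groups) are merged into loci; each locus contributes one count to
    the combination of groups it appears in.  Returns a table with one row
    per observed combination plus per-group totals.
    """
    if len(pas_sets) < 2:
        raise ValueError("need at least two PAS sets")
    events: List[Tuple[str, str, int, int, str]] = []
    for name, clusters in pas_sets.items():
        for c in clusters:
            if c.positive_site is None:
                continue
            events.append((c.chrom, c.strand, c.start, c.end, name))
    events.sort()
    combos: Dict[frozenset, int] = {}
    i = 0
    while i < len(events):
        chrom, strand, start, end, name = events[i]
        members = {name}
        j = i + 1
        while j < len(events) and events[j][0] == chrom and events[j][1] == strand and events[j][2] <= end:
            end = max(end, events[j][3])
            members.add(events[j][4])
            j += 1
        key = frozenset(members)
        combos[key] = combos.get(key, 0) + 1
        i = j
    rows = [
        {"groups": "+".join(sorted(k)), "n_groups": len(k), "count": v}
        for k, v in sorted(combos.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["groups", "n_groups", "count"])
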