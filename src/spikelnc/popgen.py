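"""Population-genetic characterization of lncRNA/mRNA features.

Nucleotide diversity follows the VCFtools windowed-pi convention: per-site
pi is the unbiased heterozygosity (n/(n-1)) * 2p(1-p) over the non-missing
allele count n, and a window's pi is the per-site sum divided by the window
span in bp.  Fst is the Weir-Cockerham (1984) two-population estimator with
ratio-of-sums aggregation (VCFtools' weighted Fst).  Haplotype tables are
built from phased genotype strings only; the within-group haplotype with
frequency strictly above 50% is that group's major haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from spikelnc.models import MISSING, GenomicInterval, VariantPanel

log = logging.getLogger(__name__)

#: Lineage transitions along which diversity shifts are reported:
#: wild -> domesticated einkorn; wild -> domesticated emmer -> durum;
#: landrace -> cultivar bread wheat.
DEFAULT_LINEAGE_EDGES = (
    ("A1", "A2"),
    ("AB1", "AB2"),
    ("AB2", "AB3"),
    ("ABD1", "ABD2"),
)


@dataclass
class DiversityResult:
    scope: str
    group: str
    pi: float
    n_sites: int
    n_chromosomes: float
    interval: Optional[GenomicInterval] = None


@dataclass
class FstResult:
    group_a: str
    group_b: str
    fst: float
    n_sites: int
    mean_site_fst: float = float("nan")
    negative_flagged: bool = False


@dataclass
class HaplotypeTable:
    feature_id: str
    site_order: list[int]  # positions (0-based) of the sites used
    group_frequencies: dict[str, dict[str, float]]  # group -> haplotype -> freq
    major: dict[str, Optional[str]] = field(default_factory=dict)
    excluded_samples: dict[str, int] = field(default_factory=dict)


def _per_site_pi(dosages: np.ndarray) -> tuple[float, int]:
    """Unbiased per-site pi from a 1-D dosage vector; (pi, n alleles used)."""
    d = dosages[dosages != MISSING]
    n = 2 * len(d)
    if n < 2:
        return float("nan"), n
    p = d.sum() / n
    return (n / (n - 1)) * 2.0 * p * (1.0 - p), n


def nucleotide_diversity(
    panel: VariantPanel,
    group: str,
    windows: Optional[Iterable[tuple[GenomicInterval, str]]] = None,
    window_size: int = 50_000,
    min_alleles: int = 4,
    denominator: str = "span",
) -> list[DiversityResult]:
    """Windowed or per-feature nucleotide diversity for one group.

    ``windows`` may be explicit (interval, name) pairs (per-feature mode);
    otherwise the panel's chromosomes are tiled with ``window_size`` bp
    windows.  Sites where the group has fewer than ``min_alleles``
    non-missing alleles are skipped.  ``denominator`` is "span" (VCFtools
    convention, pi per bp of window) or "sites" (mean per-site pi).
    """
    cols = panel.group_members(group)
    if len(cols) < 2:
        raise ValueError(f"group {group} has < 2 samples")
    if windows is None:
        windows = []
        for chrom in sorted({s.interval.chrom for s in panel.sites}):
            last = max(
                s.interval.end for s in panel.sites if s.interval.chrom == chrom
            )
            for start in range(0, last, window_size):
                iv = GenomicInterval(chrom, start, start + window_size)
                windows.append((iv, f"{chrom}:{start}-{start + window_size}"))
    geno = panel.genotypes[:, cols]
    out = []
    for iv, name in windows:
        idx = panel.sites_in(iv)
        total = 0.0
        used = 0
        n_sum = 0.0
        for i in idx:
            pi_i, n = _per_site_pi(geno[i])
            if n < min_alleles or np.isnan(pi_i):
                continue
            total += pi_i
            used += 1
            n_sum += n
        if used == 0:
            continue
        denom = iv.span if denominator == "span" else used
        out.append(
            DiversityResult(
                scope=name,
                group=group,
                pi=total / denom,
                n_sites=used,
                n_chromosomes=n_sum / used,
                interval=iv,
            )
        )
    return out


def wc_fst_components(
    dos_a: np.ndarray, dos_b: np.ndarray
) -> tuple[float, float, float]:
    """Weir-Cockerham (1984) variance components (a, b, c) for one bi-allelic
    site and two populations, from diploid dosage vectors (missing = -1)."""
    comp = []
    for d in (dos_a, dos_b):
        d = d[d != MISSING]
        if len(d) == 0:
            return np.nan, np.nan, np.nan
        n_i = float(len(d))
        p_i = d.sum() / (2 * n_i)
        h_i = np.mean(d == 1)  # observed heterozygote frequency
        comp.append((n_i, p_i, h_i))
    (n1, p1, h1), (n2, p2, h2) = comp
    r = 2.0
    n_bar = (n1 + n2) / r
    if n_bar <= 1:
        return np.nan, np.nan, np.nan
    n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4.0)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2.0
    return a, b, c


def pairwise_fst(panel: VariantPanel, group_a: str, group_b: str) -> FstResult:
    """Weighted (ratio-of-sums) Weir-Cockerham Fst between two groups.

    Sites monomorphic across both groups are excluded.  Small negative
    estimates are preserved (clamped at -0.05) and flagged.
    """
    ca, cb = panel.group_members(group_a), panel.group_members(group_b)
    if len(ca) < 2 or len(cb) < 2:
        raise ValueError("both groups need >= 2 samples")
    num = den = 0.0
    site_vals = []
    for i in range(panel.n_sites):
        da, db = panel.genotypes[i, ca], panel.genotypes[i, cb]
        both = np.concatenate([da[da != MISSING], db[db != MISSING]])
        if len(both) == 0 or both.min() == both.max() == 0 or (both.min() == both.max() == 2):
            continue  # monomorphic in the pooled pair (or hom-alt fixed)
        a, b, c = wc_fst_components(da, db)
        if np.isnan(a):
            continue
        num += a
        den += a + b + c
        if a + b + c != 0:
            site_vals.append(a / (a + b + c))
    if den == 0:
        raise ValueError(
            f"no usable polymorphic sites between {group_a} and {group_b}"
        )
    fst = num / den
    flagged = fst < 0
    fst = max(fst, -0.05)
    return FstResult(
        group_a=group_a,
        group_b=group_b,
        fst=float(fst),
        n_sites=len(site_vals),
        mean_site_fst=float(np.mean(site_vals)) if site_vals else float("nan"),
        negative_flagged=flagged,
    )


def snp_density(
    panel: VariantPanel, features: Iterable[tuple[GenomicInterval, str]]
) -> pd.DataFrame:
    """SNPs per kb inside each feature interval (half-open counting)."""
    rows = []
    for iv, name in features:
        n = len(panel.sites_in(iv))
        rows.append(
            {"feature": name, "chrom": iv.chrom, "n_snps": n, "snps_per_kb": n / (iv.span / 1000.0)}
        )
    return pd.DataFrame(rows, columns=["feature", "chrom", "n_snps", "snps_per_kb"])


def haplotypes(
    panel: VariantPanel,
    feature: GenomicInterval,
    feature_id: str,
    groups: Optional[Iterable[str]] = None,
) -> HaplotypeTable:
    """Per-group haplotype strings (nucleotide letters, sites in positional
    order) with frequencies; the major haplotype is the one with within-group
    frequency strictly > 50%.

    A chromosome copy contributes only when every site has a phase-resolved
    allele (phased call or homozygote); samples failing that at any site are
    excluded from the feature's table with a per-group count.  No statistical
    phasing is attempted.
    """
    idx = panel.sites_in(feature)
    if len(idx) == 0:
        raise ValueError(f"{feature_id}: no panel sites inside feature")
    if panel.haplotypes is None:
        raise ValueError("panel has no phase information")
    if groups is None:
        groups = sorted(set(panel.sample_groups.values()))
    letters = {
        i: (panel.sites[i].ref, panel.sites[i].alt) for i in idx
    }
    table = HaplotypeTable(
        feature_id=feature_id,
        site_order=[panel.sites[i].interval.start for i in idx],
        group_frequencies={},
    )
    for g in groups:
        cols = panel.group_members(g)
        counts: dict[str, int] = {}
        excluded = 0
        for j in cols:
            alleles = panel.haplotypes[idx, j, :]  # (n_sites, 2)
            if (alleles == MISSING).any():
                excluded += 1
                continue
            for copy in (0, 1):
                hap = "".join(letters[i][alleles[k, copy]] for k, i in enumerate(idx))
                counts[hap] = counts.get(hap, 0) + 1
        total = sum(counts.values())
        freqs = {h: c / total for h, c in counts.items()} if total else {}
        table.group_frequencies[g] = freqs
        table.excluded_samples[g] = excluded
        major = None
        for h, f in sorted(freqs.items()):
            if f > 0.5:
                major = h
        table.major[g] = major
    return table


def diversity_shift(
    pi_by_group: dict[str, float],
    lineage_edges: Iterable[tuple[str, str]] = DEFAULT_LINEAGE_EDGES,
) -> pd.DataFrame:
    """Signed diversity change along each lineage edge.

    sign = sign(pi_child - pi_parent); ratio = pi_child / pi_parent; a ratio
    below 1 flags a bottleneck on that transition.
    """
    rows = []
    for parent, child in lineage_edges:
        if parent not in pi_by_group or child not in pi_by_group:
            raise ValueError(f"missing group in pi table: {parent} or {child}")
        pp, pc = pi_by_group[parent], pi_by_group[child]
        ratio = pc / pp if pp > 0 else float("inf")
        rows.append(
            {
                "parent": parent,
                "child": child,
                "sign": "-" if pc < pp else ("+" if pc > pp else "0"),
                "ratio": ratio,
                "bottleneck": ratio < 1,
            }
        )
    return pd.DataFrame(rows, columns=["parent", "child", "sign", "ratio", "bottleneck"])
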