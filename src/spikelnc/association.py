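"""Trait association and co-localization.

Per-SNP scan with a population-structure-aware linear model (phenotype ~
dosage + top genotype principal components), a 1/Ne significance threshold
(Ne = effective number of independent tests), LD r² utilities, a 5 Mb
candidate window around passing SNPs, and interval co-localization with an
exact two-sided Fisher enrichment test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from spikelnc.models import GenomicInterval

log = logging.getLogger(__name__)


@dataclass
class AssociationHit:
    site: GenomicInterval
    trait: str
    effect: float
    p_value: float
    passes_threshold: bool
    snp_id: str = ""


@dataclass
class CandidateAssignment:
    feature_id: str
    hit: AssociationHit
    distance: float
    window: int


def _pc_covariates(dosage: np.ndarray, n_pcs: int) -> np.ndarray:
    """Top principal components of the centered sample x SNP dosage matrix."""
    x = dosage - dosage.mean(axis=0, keepdims=True)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    u, s, _ = np.linalg.svd(x / sd, full_matrices=False)
    return u[:, :n_pcs] * s[:n_pcs]


def gwas_scan(
    genotypes: pd.DataFrame,
    phenotype: pd.Series,
    trait: str = "trait",
    positions: Optional[pd.DataFrame] = None,
    n_pcs: int = 3,
    maf_min: float = 0.05,
    ne: Optional[int] = None,
) -> list[AssociationHit]:
    """Structure-adjusted per-SNP linear-model scan.

    ``genotypes``: samples x SNPs dosage frame; ``positions``: optional frame
    indexed by SNP id with chrom/pos columns.  Phenotype and covariates are
    residualized on (intercept + PCs); per-SNP slope and two-sided t-test
    p-value use n - 2 - n_pcs residual degrees of freedom.  The significance
    threshold is 1/Ne with Ne defaulting to the post-filter SNP count.
    """
    common = [s for s in genotypes.index if s in phenotype.index]
    if len(common) < 30:
        raise ValueError("need >= 30 overlapping samples")
    y = phenotype.loc[common].values.astype(float)
    if np.ptp(y) == 0:
        raise ValueError("phenotype has zero variance")
    geno = genotypes.loc[common]
    x = geno.values.astype(float)
    n = len(common)

    freq = x.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = maf >= maf_min
    dropped = int((~keep).sum())
    if dropped:
        log.info("gwas_scan: %d SNPs removed by MAF >= %.3g filter", dropped, maf_min)
    x = x[:, keep]
    snp_ids = list(geno.columns[keep])
    if x.shape[1] == 0:
        raise ValueError("no SNPs left after MAF filter")

    pcs = _pc_covariates(x, min(n_pcs, n - 3)) if n_pcs > 0 else np.empty((n, 0))
    cov = np.column_stack([np.ones(n), pcs])
    # residualize phenotype and every dosage vector on the covariates
    beta_cov, *_ = np.linalg.lstsq(cov, y, rcond=None)
    ry = y - cov @ beta_cov
    bx, *_ = np.linalg.lstsq(cov, x, rcond=None)
    rx = x - cov @ bx

    ssx = (rx**2).sum(axis=0)
    ssx[ssx == 0] = np.nan  # monomorphic after residualization
    slope = (rx * ry[:, None]).sum(axis=0) / ssx
    df = n - 2 - pcs.shape[1]
    resid = ry[:, None] - rx * slope
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(sigma2 / ssx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = slope / se
    from scipy import stats

    pvals = 2 * stats.t.sf(np.abs(tstat), df)

    ne_eff = ne if ne is not None else int(np.isfinite(pvals).sum())
    threshold = 1.0 / ne_eff
    hits = []
    for j, sid in enumerate(snp_ids):
        if not np.isfinite(pvals[j]):
            continue
        if positions is not None and sid in positions.index:
            row = positions.loc[sid]
            iv = GenomicInterval(str(row["chrom"]), int(row["pos"]), int(row["pos"]) + 1)
        else:
            iv = GenomicInterval("un", j, j + 1)
        hits.append(
            AssociationHit(
                site=iv,
                trait=trait,
                effect=float(slope[j]),
                p_value=float(pvals[j]),
                passes_threshold=bool(pvals[j] < threshold),
                snp_id=sid,
            )
        )
    return hits


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite (genotype-based) LD: squared Pearson correlation of dosages."""
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def ld_decay(
    genotypes: pd.DataFrame,
    positions: pd.DataFrame,
    max_dist: int = 10_000_000,
    n_bins: int = 20,
    r2_drop: float = 0.2,
) -> pd.DataFrame:
    """Distance-binned mean r² between same-chromosome SNP pairs, with the
    first bin whose mean r² falls below ``r2_drop`` flagged as the decay
    distance."""
    x = genotypes.values.astype(float)
    ids = list(genotypes.columns)
    keep = [j for j in range(x.shape[1]) if np.ptp(x[:, j]) > 0]
    edges = np.linspace(0, max_dist, n_bins + 1)
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    pos = positions
    for ai in range(len(keep)):
        j = keep[ai]
        pj = pos.loc[ids[j]]
        for bi in range(ai + 1, len(keep)):
            k = keep[bi]
            pk = pos.loc[ids[k]]
            if pj["chrom"] != pk["chrom"]:
                continue
            d = abs(int(pj["pos"]) - int(pk["pos"]))
            if d >= max_dist:
                continue
            b = min(int(d / max_dist * n_bins), n_bins - 1)
            sums[b] += ld_r2(x[:, j], x[:, k])
            counts[b] += 1
    rows = []
    decay_found = False
    for b in range(n_bins):
        mean_r2 = sums[b] / counts[b] if counts[b] else float("nan")
        below = (not decay_found) and counts[b] > 0 and mean_r2 < r2_drop
        if below:
            decay_found = True
        rows.append(
            {
                "dist_lo": int(edges[b]),
                "dist_hi": int(edges[b + 1]),
                "n_pairs": int(counts[b]),
                "mean_r2": mean_r2,
                "decay_bin": below,
            }
        )
    return pd.DataFrame(rows)


def assign_candidates(
    hits: Iterable[AssociationHit],
    features: Iterable[tuple[GenomicInterval, str]],
    window: int = 5_000_000,
) -> list[CandidateAssignment]:
    """Features within ``window`` bp (nearest edge) of any threshold-passing
    SNP, annotated with the distance to that SNP."""
    features = sorted(features, key=lambda f: (f[0].chrom, f[0].start, f[1]))
    out = []
    for iv, name in features:
        for h in hits:
            if not h.passes_threshold:
                continue
            d = iv.gap_to(h.site)
            if d <= window:
                out.append(CandidateAssignment(name, h, d, window))
    return out


def colocalize(
    features: Iterable[tuple[GenomicInterval, str]],
    interval_sets: dict[str, list[tuple[GenomicInterval, str]]],
) -> pd.DataFrame:
    """Any-base overlap table between features and named interval sets
    (QTL, introgression regions), half-open semantics."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for set_name, ivs in interval_sets.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv, name in ivs:
            per_chrom.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, name)
        trees[set_name] = per_chrom
    rows = []
    for iv, fname in features:
        for set_name, per_chrom in trees.items():
            tree = per_chrom.get(iv.chrom)
            overlaps = sorted(o.data for o in tree.overlap(iv.start, iv.end)) if tree else []
            rows.append(
                {
                    "feature": fname,
                    "set": set_name,
                    "n_overlaps": len(overlaps),
                    "regions": ",".join(overlaps),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "set", "n_overlaps", "regions"])


def fisher_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p for the 2x2 table [[a, b], [c, d]]:
    the sum of hypergeometric probabilities of all tables with the same
    margins whose probability does not exceed the observed table's."""
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    r1, c1 = a + b, a + c

    def log_prob(x: int) -> float:
        # P(X = x) for X ~ Hypergeom(n, r1, c1)
        return (
            math.lgamma(r1 + 1)
            - math.lgamma(x + 1)
            - math.lgamma(r1 - x + 1)
            + math.lgamma(n - r1 + 1)
            - math.lgamma(c1 - x + 1)
            - math.lgamma(n - r1 - (c1 - x) + 1)
            - (math.lgamma(n + 1) - math.lgamma(c1 + 1) - math.lgamma(n - c1 + 1))
        )

    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    obs = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= obs + 1e-9:  # relative tolerance for float ties
            total += math.exp(lp)
    return min(total, 1.0)
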