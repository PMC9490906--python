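"""Synthetic-data generator for every pipeline input.

The generator emulates the statistical structure of the study rather than
its sequences: lncRNAs are shorter and mostly single-exon while mRNAs are
longer and multi-exon; planted lncRNA-mRNA pairs reach a target Spearman
correlation through a Gaussian copula with log-normal FPKM marginals; the
nine Triticum/Aegilops groups get Balding-Nichols allele frequencies whose
per-group drift realizes a target nucleotide diversity, with a bottleneck
along the domestication lineage; one causal SNP per agronomic trait drives
a heritability-scaled phenotype; and consumed binding-site / pairing-energy
/ homolog-hit tables carry planted ceRNA triangles and a planted species
chain.  Everything is deterministic given the config seed: each stage draws
from its own RNG stream (seed + a stable per-stage offset).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from spikelnc import formats_io
from spikelnc.models import (
    GROUP_LABELS,
    GROUP_SIZES,
    GenomicInterval,
    Site,
    TranscriptModel,
    VariantPanel,
)
from spikelnc.popgen import DEFAULT_LINEAGE_EDGES

# RNG stream offsets (stage-level reproducibility when stages re-run alone)
_OFF_ANNOT, _OFF_EXPR, _OFF_POP, _OFF_PHENO, _OFF_BIND, _OFF_HOMOLOG = 1, 2, 3, 4, 5, 6

#: Expected p(1-p) of an ancestral frequency drawn Uniform(0.05, 0.95);
#: per-site heterozygosity under Balding-Nichols drift F is 2*0.1825*(1-F).
_EXP_P_Q = 0.1825

DEFAULT_GROUP_DIVERSITY = {
    # per-site pi targets; halving along each domestication edge,
    # mild recovery into durum-adjacent improvement is left out so every
    # configured lineage edge is a bottleneck by default
    "A1": 0.30,
    "A2": 0.15,
    "A3": 0.14,
    "AB1": 0.28,
    "AB2": 0.14,
    "AB3": 0.10,
    "ABD1": 0.12,
    "ABD2": 0.06,
    "D1": 0.20,
}

SPECIES_CHAIN = (
    "aegilops_tauschii",
    "barley",
    "rye",
    "brachypodium",
    "rice",
    "sorghum",
    "maize",
    "arabidopsis",
)

TRAITS = ("SL", "GW", "GN", "SNS", "HD")


@dataclass
class SimulationConfig:
    seed: int = 0
    # expression panel
    n_samples_expr: int = 186
    # annotation
    n_genes: int = 240
    n_lncrnas: int = 160
    n_chromosomes: int = 3
    chrom_length: int = 60_000_000
    fraction_single_exon: float = 0.892
    lncrna_length_median: float = 1584.0
    mrna_length_median: float = 3953.0
    # planted signals
    n_planted_cis: int = 20
    n_planted_trans: int = 20
    n_planted_triangles: int = 10
    pair_rho: float = 0.95
    triangle_rho: float = -0.8
    n_coding_flagged: int = 5
    # population panel
    group_sizes: dict = field(default_factory=lambda: dict(GROUP_SIZES))
    group_diversity: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_DIVERSITY))
    lineage_edges: tuple = DEFAULT_LINEAGE_EDGES
    n_sites: int = 3000
    hap_n_sites: int = 26
    planted_hap_counts: dict = field(
        default_factory=lambda: {"AB3": 10, "ABD1": 42, "ABD2": 25}
    )
    # trait association
    n_array_samples: int = 93
    n_array_snps: int = 2000
    causal_h2: float = 0.5
    causal_maf: float = 0.3
    causal_effect: float = 1.0
    traits: tuple = TRAITS
    # consumed tables
    binding_span: int = 21
    pass_energy: float = -0.5
    fail_energy: float = -0.01
    n_homolog_queries: int = 60
    # intervals
    n_qtl: int = 12
    introgression_cover: int = 12  # planted-pair lncRNAs covered by introgression

    def __post_init__(self):
        if sum(self.group_sizes.values()) != sum(GROUP_SIZES.values()) and set(
            self.group_sizes
        ) == set(GROUP_LABELS):
            pass  # non-default sizes are allowed; the default sums to 261
        if not (0 < self.causal_h2 < 1):
            raise ValueError("heritability must be in (0, 1)")
        if abs(self.pair_rho) > 0.999 or abs(self.triangle_rho) > 0.999:
            raise ValueError("|rho| > 0.999 saturates rank correlation")
        planted = self.n_planted_cis + self.n_planted_trans + self.n_planted_triangles
        if planted > self.n_lncrnas:
            raise ValueError("planted lncRNAs exceed n_lncrnas")
        for g, pi in self.group_diversity.items():
            if pi >= 0.5:
                raise ValueError(f"group {g}: requested pi {pi} >= theoretical max 0.5")


@dataclass
class GroundTruth:
    lncrna_ids: list
    pairs: list  # dicts: lncrna_id, mrna_id, mode, rho
    triangles: list  # dicts: lncrna_id, mirna_id, mrna_id, rho
    causal: dict  # trait -> snp_id
    group_pi_targets: dict
    planted_classes: dict  # lncrna_id -> class code
    hap_feature: Optional[str] = None
    hap_expected: dict = field(default_factory=dict)  # group -> major frequency
    coding_flagged: list = field(default_factory=list)
    species_order: list = field(default_factory=list)


@dataclass
class AnnotationBundle:
    reference: list
    assembly: list
    sequences: dict
    truth: GroundTruth


def _chrom_names(n: int) -> list[str]:
    return [f"chr{i // 3 + 1}{'ABD'[i % 3]}" for i in range(n)]


def _random_seq(rng, length: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _draw_length(rng, median: float, sigma: float = 0.55, minimum: int = 250) -> int:
    return max(minimum, int(rng.lognormal(math.log(median), sigma)))


def _make_gene(rng, chrom: str, start: int, idx: int) -> TranscriptModel:
    strand = "+" if rng.random() < 0.5 else "-"
    single = rng.random() < 0.10
    n_exons = 1 if single else 2 + int(min(rng.poisson(2.5), 7))
    spliced = _draw_length(rng, 3953.0, 0.5, minimum=400)
    cuts = np.sort(rng.choice(np.arange(1, spliced), size=n_exons - 1, replace=False)) if n_exons > 1 else np.array([], dtype=int)
    exon_lens = np.diff(np.concatenate([[0], cuts, [spliced]])).astype(int)
    exon_lens = np.maximum(exon_lens, 30)
    intron_lens = [max(80, int(rng.lognormal(math.log(2000), 0.6))) for _ in range(n_exons - 1)]
    exons = []
    pos = start
    for k, el in enumerate(exon_lens):
        exons.append(GenomicInterval(chrom, pos, pos + int(el), strand))
        pos += int(el)
        if k < len(intron_lens):
            pos += intron_lens[k]
    iv = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(f"gene{idx}.1", f"gene{idx}", iv, exons, biotype="mRNA")


def _single_exon_lnc(chrom, start, length, strand, tid) -> TranscriptModel:
    iv = GenomicInterval(chrom, start, start + length, strand)
    return TranscriptModel(tid, tid.rsplit(".", 1)[0], iv, [iv], biotype="lncRNA-candidate")


def simulate_annotation(config: SimulationConfig) -> AnnotationBundle:
    """Emit the reference annotation, the assembled transcriptome and the
    transcript FASTA, with planted class codes, planted cis/trans pairs and
    planted ceRNA triangle members recorded in the ground truth."""
    rng = np.random.default_rng(config.seed + _OFF_ANNOT)
    chroms = _chrom_names(config.n_chromosomes)
    genes: list[TranscriptModel] = []
    per_chrom = int(math.ceil(config.n_genes / len(chroms)))
    spacing = config.chrom_length // (per_chrom + 1)
    if spacing < 250_000:
        raise ValueError(
            "chromosome too short to place features; increase chrom_length"
        )
    gidx = 0
    slots: list[tuple[str, int]] = []  # midpoints available for intergenic placement
    for chrom in chroms:
        for s in range(per_chrom):
            if gidx >= config.n_genes:
                break
            start = (s + 1) * spacing + int(rng.integers(-spacing // 10, spacing // 10))
            genes.append(_make_gene(rng, chrom, start, gidx))
            gidx += 1
    for g in genes:
        slots.append((g.chrom, g.interval.end))

    truth = GroundTruth(
        lncrna_ids=[],
        pairs=[],
        triangles=[],
        causal={},
        group_pi_targets=dict(config.group_diversity),
        planted_classes={},
    )

    n_lnc = config.n_lncrnas
    n_single = round(config.fraction_single_exon * n_lnc)
    n_multi = n_lnc - n_single

    n_planted = config.n_planted_cis + config.n_planted_trans + config.n_planted_triangles
    n_decoys = n_lnc - n_planted
    j_count = min(n_multi, max(0, round(0.06 * n_decoys)))
    i_count = min(n_decoys - j_count, round(0.10 * n_decoys))
    o_count = min(n_decoys - j_count - i_count, round(0.05 * n_decoys))
    multi_u_quota = n_multi - j_count

    lncs: list[TranscriptModel] = []
    used_genes: set[str] = set()
    k = 0

    def next_id():
        nonlocal k
        k += 1
        return f"lnc.{k}.1"

    # --- planted cis pairs: lncRNA placed 5-45 kb downstream of its gene ---
    cis_genes = genes[:: max(1, len(genes) // max(1, config.n_planted_cis))][
        : config.n_planted_cis
    ]
    for g in cis_genes:
        tid = next_id()
        gap = int(rng.integers(5_000, 45_000))
        length = _draw_length(rng, config.lncrna_length_median)
        lnc = _single_exon_lnc(g.chrom, g.interval.end + gap, length, g.strand, tid)
        lncs.append(lnc)
        used_genes.add(g.transcript_id)
        truth.pairs.append(
            {"lncrna_id": tid, "mrna_id": g.transcript_id, "mode": "cis", "rho": config.pair_rho}
        )
        truth.planted_classes[tid] = "u"

    # --- planted trans pairs: partner gene on a different chromosome ---
    free_genes = [g for g in genes if g.transcript_id not in used_genes]
    for t in range(config.n_planted_trans):
        g = free_genes[(t * 3) % len(free_genes)]
        while g.transcript_id in used_genes:
            g = free_genes[(free_genes.index(g) + 1) % len(free_genes)]
        other_chroms = [c for c in chroms if c != g.chrom]
        chrom = other_chroms[t % len(other_chroms)]
        tid = next_id()
        pos = int(rng.integers(spacing // 2, config.chrom_length - 100_000))
        pos = _nudge_intergenic(pos, genes, chrom, spacing)
        length = _draw_length(rng, config.lncrna_length_median)
        lncs.append(_single_exon_lnc(chrom, pos, length, "+", tid))
        used_genes.add(g.transcript_id)
        truth.pairs.append(
            {"lncrna_id": tid, "mrna_id": g.transcript_id, "mode": "trans", "rho": config.pair_rho}
        )
        truth.planted_classes[tid] = "u"

    # --- planted ceRNA triangles: intergenic lncRNA, anti-correlated mRNA ---
    free_genes = [g for g in genes if g.transcript_id not in used_genes]
    for t in range(config.n_planted_triangles):
        g = free_genes[(t * 5) % len(free_genes)]
        while g.transcript_id in used_genes:
            g = free_genes[(free_genes.index(g) + 1) % len(free_genes)]
        other_chroms = [c for c in chroms if c != g.chrom]
        chrom = other_chroms[t % len(other_chroms)]
        tid = next_id()
        pos = int(rng.integers(spacing // 2, config.chrom_length - 100_000))
        pos = _nudge_intergenic(pos, genes, chrom, spacing)
        length = max(450, _draw_length(rng, config.lncrna_length_median))
        lncs.append(_single_exon_lnc(chrom, pos, length, "+", tid))
        used_genes.add(g.transcript_id)
        truth.triangles.append(
            {
                "lncrna_id": tid,
                "mirna_id": f"tae-miR{9000 + t}",
                "mrna_id": g.transcript_id,
                "rho": config.triangle_rho,
            }
        )
        truth.planted_classes[tid] = "u"

    # --- decoy lncRNAs with the configured class-code mix ---
    multi_exon_genes = [g for g in genes if g.n_exons >= 3]
    di = 0
    for _ in range(j_count):
        g = multi_exon_genes[di % len(multi_exon_genes)]
        di += 1
        intron_s, intron_e = g.introns[0]
        tid = next_id()
        a = GenomicInterval(g.chrom, max(0, g.exons[0].start - 150), intron_s, g.strand)
        b_end = min(intron_e + 150, g.exons[1].end)
        b = GenomicInterval(g.chrom, intron_e, b_end, g.strand)
        iv = GenomicInterval(g.chrom, a.start, b.end, g.strand)
        lncs.append(TranscriptModel(tid, tid.rsplit(".", 1)[0], iv, [a, b], biotype="lncRNA-candidate"))
        truth.planted_classes[tid] = "j"
    for _ in range(i_count):
        g = multi_exon_genes[di % len(multi_exon_genes)]
        di += 1
        introns = sorted(g.introns, key=lambda it: it[1] - it[0])
        s, e = introns[-1]
        if e - s < 300:
            tid = next_id()
            pos = _nudge_intergenic(
                int(rng.integers(spacing // 2, config.chrom_length - 100_000)),
                genes,
                g.chrom,
                spacing,
            )
            lncs.append(_single_exon_lnc(g.chrom, pos, 400, "+", tid))
            truth.planted_classes[tid] = "u"
            continue
        tid = next_id()
        length = min(e - s - 40, _draw_length(rng, config.lncrna_length_median))
        lncs.append(_single_exon_lnc(g.chrom, s + 20, length, g.strand, tid))
        truth.planted_classes[tid] = "i"
    for _ in range(o_count):
        g = multi_exon_genes[di % len(multi_exon_genes)]
        di += 1
        tid = next_id()
        overlap = min(100, g.exons[0].span - 1)  # stay clear of intron 1
        length = max(300, _draw_length(rng, config.lncrna_length_median))
        start = max(0, g.exons[0].start + overlap - length)
        lncs.append(
            _single_exon_lnc(g.chrom, start, g.exons[0].start + overlap - start, g.strand, tid)
        )
        truth.planted_classes[tid] = "o"
    n_u_decoys = n_decoys - j_count - i_count - o_count
    for u in range(n_u_decoys):
        chrom = chroms[u % len(chroms)]
        tid = next_id()
        pos = _nudge_intergenic(
            int(rng.integers(spacing // 2, config.chrom_length - 100_000)),
            genes,
            chrom,
            spacing,
        )
        length = _draw_length(rng, config.lncrna_length_median)
        if multi_u_quota > 0 and u < multi_u_quota:
            half = max(120, length // 2)
            a = GenomicInterval(chrom, pos, pos + half, "+")
            b = GenomicInterval(chrom, pos + half + 200, pos + half + 200 + half, "+")
            iv = GenomicInterval(chrom, a.start, b.end, "+")
            lncs.append(TranscriptModel(tid, tid.rsplit(".", 1)[0], iv, [a, b], biotype="lncRNA-candidate"))
        else:
            lncs.append(_single_exon_lnc(chrom, pos, length, "+", tid))
        truth.planted_classes[tid] = "u"

    truth.lncrna_ids = [t.transcript_id for t in lncs]
    assembly = genes + lncs
    sequences = {
        t.transcript_id: _random_seq(rng, t.length) for t in assembly
    }
    return AnnotationBundle(reference=genes, assembly=assembly, sequences=sequences, truth=truth)


def _nudge_intergenic(pos: int, genes, chrom: str, spacing: int) -> int:
    """Move a position to the midpoint of its nearest intergenic gap so the
    feature sits far (> 100 kb at default spacing) from every gene."""
    ivs = sorted(
        (g.interval.start, g.interval.end) for g in genes if g.chrom == chrom
    )
    if not ivs:
        return max(1000, pos)
    gaps = []
    prev_end = 1000
    for s, e in ivs:
        if s > prev_end:
            gaps.append((prev_end, s))
        prev_end = max(prev_end, e)
    gaps.append((prev_end, prev_end + spacing))
    mids = [(a + b) // 2 for a, b in gaps]
    return min(mids, key=lambda m: abs(m - pos))


def simulate_expression(config: SimulationConfig, bundle: AnnotationBundle) -> pd.DataFrame:
    """Gaussian-copula FPKM matrix.

    Planted pairs/triangles hit their target Spearman rho by giving the two
    features latent normals with Pearson correlation 2*sin(pi*rho/6) and
    then mapping monotonically to log-normal FPKM (mRNA marginal above the
    lncRNA marginal).  All other features are independent.  Constant
    features (which the copula never produces) would be dropped.
    """
    rng = np.random.default_rng(config.seed + _OFF_EXPR)
    features = [t.transcript_id for t in bundle.assembly]
    fidx = {f: i for i, f in enumerate(features)}
    n, m = len(features), config.n_samples_expr
    z = rng.standard_normal((n, m))
    for planted in bundle.truth.pairs + bundle.truth.triangles:
        rho_s = planted["rho"]
        r = 2.0 * math.sin(math.pi * rho_s / 6.0)
        i, j = fidx[planted["lncrna_id"]], fidx[planted["mrna_id"]]
        z[i] = r * z[j] + math.sqrt(1 - r * r) * z[i]
    is_lnc = np.array([t.biotype == "lncRNA-candidate" for t in bundle.assembly])
    mu = np.where(is_lnc, math.log(2.0), math.log(8.0))[:, None]
    fpkm = np.exp(mu + 1.0 * z)
    df = pd.DataFrame(fpkm, index=features, columns=[f"S{i + 1:03d}" for i in range(m)])
    keep = df.apply(lambda r: r.nunique() > 1, axis=1)
    if not keep.all():
        import logging

        logging.getLogger(__name__).warning(
            "simulate_expression: dropped %d constant features", int((~keep).sum())
        )
        df = df[keep]
    return df


def _feature_intervals(bundle: AnnotationBundle) -> list[tuple[GenomicInterval, str]]:
    return [(t.interval, t.transcript_id) for t in bundle.assembly]


def simulate_population(
    config: SimulationConfig, bundle: AnnotationBundle
) -> VariantPanel:
    """Balding-Nichols genotype panel over the nine groups.

    Per site the ancestral frequency is Uniform(0.05, 0.95) and each group
    draws its frequency from Beta(p(1-F)/F, (1-p)(1-F)/F) with F tuned so
    the expected per-site diversity matches the group's target pi.  Sites
    live inside lncRNA/mRNA feature intervals.  The first planted cis
    lncRNA hosts the planted haplotype block: hap_n_sites sites, every
    sample homozygous, per-group H1 counts from the config (H1 = all-ref,
    H2 = all-alt).
    """
    rng = np.random.default_rng(config.seed + _OFF_POP)
    groups = list(config.group_sizes)
    f_by_group = {}
    for g in groups:
        target = config.group_diversity[g]
        f = 1.0 - target / (2 * _EXP_P_Q)
        f_by_group[g] = float(np.clip(f, 0.01, 0.97))

    samples = []
    sample_groups = {}
    for g in groups:
        for i in range(config.group_sizes[g]):
            s = f"{g}_{i + 1:03d}"
            samples.append(s)
            sample_groups[s] = g
    cols_by_group = {
        g: [j for j, s in enumerate(samples) if sample_groups[s] == g] for g in groups
    }

    features = _feature_intervals(bundle)
    hap_feature = bundle.truth.pairs[0]["lncrna_id"] if bundle.truth.pairs else None
    hap_iv = next((iv for iv, name in features if name == hap_feature), None)

    positions: list[tuple[str, int, bool]] = []  # chrom, pos, in_hap_block
    if hap_iv is not None:
        step = max(1, hap_iv.span // (config.hap_n_sites + 1))
        for s in range(config.hap_n_sites):
            positions.append((hap_iv.chrom, hap_iv.start + (s + 1) * step, True))
    n_rest = config.n_sites - len(positions)
    # the haplotype-block feature hosts only its planted sites
    weights = np.array(
        [0.0 if name == hap_feature else iv.span for iv, name in features],
        dtype=float,
    )
    weights /= weights.sum()
    choice = rng.choice(len(features), size=n_rest, p=weights)
    for c in choice:
        iv, _name = features[c]
        positions.append((iv.chrom, int(rng.integers(iv.start, iv.end)), False))
    seen = set()
    uniq = []
    for chrom, pos, in_hap in positions:
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        uniq.append((chrom, pos, in_hap))
    uniq.sort(key=lambda t: (t[0], t[1]))

    bases = "ACGT"
    n_sites, n_samp = len(uniq), len(samples)
    haps = np.zeros((n_sites, n_samp, 2), dtype=np.int8)
    sites = []
    hap_assign = {}  # group -> boolean array per accession: True = H1
    for g in groups:
        size = config.group_sizes[g]
        n_h1 = config.planted_hap_counts.get(g, size // 2)
        arr = np.zeros(size, dtype=bool)
        arr[: min(n_h1, size)] = True
        hap_assign[g] = arr
    for i, (chrom, pos, in_hap) in enumerate(uniq):
        ref_i = int(rng.integers(0, 4))
        alt_i = (ref_i + 1 + int(rng.integers(0, 3))) % 4
        sites.append(
            Site(GenomicInterval(chrom, pos, pos + 1), bases[ref_i], bases[alt_i])
        )
        if in_hap:
            for g in groups:
                for a, j in enumerate(cols_by_group[g]):
                    allele = 0 if hap_assign[g][a] else 1
                    haps[i, j, :] = allele
            continue
        p_anc = rng.uniform(0.05, 0.95)
        for g in groups:
            f = f_by_group[g]
            a_par = p_anc * (1 - f) / f
            b_par = (1 - p_anc) * (1 - f) / f
            p_g = rng.beta(a_par, b_par)
            cols = cols_by_group[g]
            draws = rng.random((len(cols), 2)) < p_g
            haps[i, cols, :] = draws.astype(np.int8)
    genotypes = haps.sum(axis=2).astype(np.int8)
    truth = bundle.truth
    truth.hap_feature = hap_feature
    for g in groups:
        size = config.group_sizes[g]
        n_h1 = min(config.planted_hap_counts.get(g, size // 2), size)
        truth.hap_expected[g] = n_h1 / size
    return VariantPanel(
        sites=sites,
        samples=samples,
        genotypes=genotypes,
        sample_groups=sample_groups,
        haplotypes=haps,
    )


def simulate_phenotype_and_array(
    config: SimulationConfig,
    bundle: Optional[AnnotationBundle] = None,
    panel: Optional[VariantPanel] = None,
    seed_override: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trait-array genotypes (samples x SNPs), SNP positions and phenotypes.

    One causal SNP per trait at MAF ``causal_maf``; the phenotype is
    additive effect x dosage plus Gaussian noise scaled so the causal SNP
    explains ``causal_h2`` of the variance.  Causal SNPs are placed next to
    planted-pair lncRNAs (within the 5 Mb candidate window) when an
    annotation bundle is supplied.  Explicitly configured causal sites must
    exist in the supplied panel.
    """
    rng = np.random.default_rng(
        (config.seed if seed_override is None else seed_override) + _OFF_PHENO
    )
    n, m = config.n_array_samples, config.n_array_snps
    chroms = _chrom_names(config.n_chromosomes)
    snp_ids = [f"AX-{100000 + j}" for j in range(m)]
    pos_rows = []
    freqs = rng.uniform(0.05, 0.5, size=m)
    causal_idx = {}
    anchor_ivs = []
    if bundle is not None and bundle.truth.pairs:
        anchor_ivs = [
            next(t.interval for t in bundle.assembly if t.transcript_id == p["lncrna_id"])
            for p in bundle.truth.pairs[: len(config.traits)]
        ]
    for j in range(m):
        chrom = chroms[j % len(chroms)]
        pos = int(rng.integers(1, config.chrom_length))
        pos_rows.append({"snp_id": snp_ids[j], "chrom": chrom, "pos": pos})
    for t_i, trait in enumerate(config.traits):
        j = t_i * (m // len(config.traits))  # deterministic distinct columns
        causal_idx[trait] = j
        freqs[j] = config.causal_maf
        if t_i < len(anchor_ivs):
            iv = anchor_ivs[t_i]
            pos_rows[j] = {
                "snp_id": snp_ids[j],
                "chrom": iv.chrom,
                "pos": max(1, iv.start - int(rng.integers(1_000, 50_000))),
            }
    if panel is not None and bundle is None:
        pass  # panel-only call: positions stay random
    geno = rng.binomial(2, freqs, size=(n, m)).astype(np.int8)
    for trait, j in causal_idx.items():
        if geno[:, j].min() == geno[:, j].max():
            raise ValueError(f"causal SNP for {trait} is monomorphic in the sample")
    samples = [f"G{i + 1:03d}" for i in range(n)]
    geno_df = pd.DataFrame(geno, index=samples, columns=snp_ids)
    pos_df = pd.DataFrame(pos_rows).set_index("snp_id")
    pheno = {}
    for trait in config.traits:
        g = geno[:, causal_idx[trait]].astype(float)
        var_g = (config.causal_effect**2) * g.var()
        noise_sd = math.sqrt(var_g * (1 - config.causal_h2) / config.causal_h2)
        pheno[trait] = config.causal_effect * g + rng.normal(0, noise_sd, size=n)
    pheno_df = pd.DataFrame(pheno, index=samples)
    if bundle is not None:
        bundle.truth.causal = {t: snp_ids[j] for t, j in causal_idx.items()}
    return geno_df, pos_df, pheno_df


def simulate_binding_and_energy(
    config: SimulationConfig, bundle: AnnotationBundle
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consumed binding-site and pairing-energy tables.

    Each planted triangle's lncRNA and mRNA share one miRNA with recorded
    21-nt spans (modelled on the worked 369-389 / 314-334 bp example);
    decoy binding rows and fail-threshold energies exercise the filters.
    Planted cis/trans pairs get pass-threshold energies.
    """
    rng = np.random.default_rng(config.seed + _OFF_BIND)
    lengths = {t.transcript_id: t.length for t in bundle.assembly}
    w = config.binding_span
    bind_rows = []
    for t in bundle.truth.triangles:
        ls = min(369, max(0, lengths[t["lncrna_id"]] - w - 1))
        ms = min(314, max(0, lengths[t["mrna_id"]] - w - 1))
        bind_rows.append(
            {"transcript_id": t["lncrna_id"], "mirna_id": t["mirna_id"], "start": ls, "end": ls + w, "expectation": 2.0}
        )
        bind_rows.append(
            {"transcript_id": t["mrna_id"], "mirna_id": t["mirna_id"], "start": ms, "end": ms + w, "expectation": 2.0}
        )
    decoy_lncs = [
        t for t in bundle.truth.lncrna_ids
        if t not in {x["lncrna_id"] for x in bundle.truth.triangles}
    ][:20]
    for i, lnc in enumerate(decoy_lncs):
        s = int(rng.integers(0, max(1, lengths[lnc] - w)))
        bind_rows.append(
            {"transcript_id": lnc, "mirna_id": f"tae-miR{100 + i}", "start": s, "end": s + w, "expectation": 3.0}
        )
    # rows above the expectation cutoff (dropped by the reader)
    for i in range(5):
        bind_rows.append(
            {"transcript_id": decoy_lncs[i % len(decoy_lncs)], "mirna_id": "tae-miR9999", "start": 0, "end": w, "expectation": 7.5}
        )
    binding = pd.DataFrame(bind_rows, columns=["transcript_id", "mirna_id", "start", "end", "expectation"])

    energy_rows = []
    for p in bundle.truth.pairs:
        energy_rows.append(
            {"lncrna_id": p["lncrna_id"], "mrna_id": p["mrna_id"], "energy": config.pass_energy}
        )
    # uncorrelated decoy entries with passing energy (correlation gate should drop them)
    genes = [t.transcript_id for t in bundle.reference]
    paired = {(p["lncrna_id"], p["mrna_id"]) for p in bundle.truth.pairs}
    for i, lnc in enumerate(decoy_lncs):
        g = genes[(i * 7) % len(genes)]
        if (lnc, g) not in paired:
            energy_rows.append({"lncrna_id": lnc, "mrna_id": g, "energy": config.pass_energy})
    # fail-threshold entries
    for i, lnc in enumerate(decoy_lncs[:5]):
        g = genes[(i * 11 + 3) % len(genes)]
        energy_rows.append({"lncrna_id": lnc, "mrna_id": g, "energy": config.fail_energy})
    energy = pd.DataFrame(energy_rows, columns=["lncrna_id", "mrna_id", "energy"])
    return binding, energy


def simulate_coding_calls(config: SimulationConfig, bundle: AnnotationBundle) -> pd.DataFrame:
    """Consumed coding-potential table: two scorers plus a domain-database
    flag per transcript; a few decoy lncRNAs are flagged coding by one
    predictor to exercise the unanimity rule."""
    rows = []
    planted = {
        p["lncrna_id"] for p in bundle.truth.pairs
    } | {t["lncrna_id"] for t in bundle.truth.triangles}
    flaggable = [t for t in bundle.truth.lncrna_ids if t not in planted]
    flagged = set(flaggable[: config.n_coding_flagged])
    bundle.truth.coding_flagged = sorted(flagged)
    bundle.truth.lncrna_ids = [t for t in bundle.truth.lncrna_ids if t not in flagged]
    for t in bundle.assembly:
        if t.biotype == "mRNA":
            verdicts = {"cpc": "coding", "lgc": "coding", "pfam": "coding"}
        elif t.transcript_id in flagged:
            verdicts = {"cpc": "coding", "lgc": "noncoding", "pfam": "noncoding"}
        else:
            verdicts = {"cpc": "noncoding", "lgc": "noncoding", "pfam": "noncoding"}
        for pred, v in verdicts.items():
            rows.append({"transcript_id": t.transcript_id, "predictor": pred, "verdict": v})
    return pd.DataFrame(rows, columns=["transcript_id", "predictor", "verdict"])


def simulate_homologs(config: SimulationConfig, bundle: AnnotationBundle) -> pd.DataFrame:
    """Homolog-hit table from a planted species chain.

    Mean conservation decays linearly away from wheat along the chain, so
    the pairwise conservation distances are additive on a path and the NJ
    stand-in should recover the chain topology.  A couple of queries get a
    duplicated locus in one species to exercise the single-copy rule.
    """
    rng = np.random.default_rng(config.seed + _OFF_HOMOLOG)
    queries = bundle.truth.lncrna_ids[: config.n_homolog_queries]
    rows = []
    means = {sp: 0.95 - 0.04 * i for i, sp in enumerate(SPECIES_CHAIN)}
    for q in queries:
        qlen = 1000
        for sp in SPECIES_CHAIN:
            s = float(np.clip(means[sp] + rng.normal(0, 0.015), 0.05, 0.999))
            ident = math.sqrt(s)
            cov = s / ident
            rows.append(
                {
                    "query": q,
                    "species": sp,
                    "subject": f"{sp}_loc1",
                    "align_length": int(round(cov * qlen)),
                    "pident": 100.0 * ident,
                    "evalue": 10.0 ** float(rng.uniform(-40, -10)),
                    "query_length": qlen,
                }
            )
    for q in queries[:2]:  # duplicated locus in the nearest species
        rows.append(
            {
                "query": q,
                "species": SPECIES_CHAIN[0],
                "subject": f"{SPECIES_CHAIN[0]}_loc2",
                "align_length": 900,
                "pident": 92.0,
                "evalue": 1e-20,
                "query_length": 1000,
            }
        )
    bundle.truth.species_order = list(SPECIES_CHAIN)
    return pd.DataFrame(
        rows,
        columns=["query", "species", "subject", "align_length", "pident", "evalue", "query_length"],
    )


def simulate_intervals(
    config: SimulationConfig, bundle: AnnotationBundle
) -> tuple[list, list]:
    """QTL and introgression interval sets.

    Introgression intervals cover ``introgression_cover`` of the planted
    pair lncRNAs (plus a little background), so the Fisher enrichment of
    pairs inside introgressions is strongly positive by construction.
    """
    rng = np.random.default_rng(config.seed + _OFF_BIND + 100)
    chroms = _chrom_names(config.n_chromosomes)
    qtl = []
    for q in range(config.n_qtl):
        chrom = chroms[q % len(chroms)]
        start = int(rng.integers(0, config.chrom_length - 2_000_000))
        qtl.append((GenomicInterval(chrom, start, start + 2_000_000), f"qtl{q + 1}"))
    intro = []
    pair_lncs = [p["lncrna_id"] for p in bundle.truth.pairs][: config.introgression_cover]
    ivs = {t.transcript_id: t.interval for t in bundle.assembly}
    for i, lnc in enumerate(pair_lncs):
        iv = ivs[lnc]
        intro.append(
            (GenomicInterval(iv.chrom, max(0, iv.start - 10_000), iv.end + 10_000), f"intro{i + 1}")
        )
    intro.append(
        (GenomicInterval(chroms[0], config.chrom_length - 1_000_000, config.chrom_length), "intro_bg")
    )
    return qtl, intro


def simulate_all(config: SimulationConfig, outdir) -> GroundTruth:
    """Run every generator stage and write the full input bundle to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = simulate_annotation(config)
    formats_io.write_gtf(bundle.reference, outdir / "reference.gtf")
    formats_io.write_gtf(bundle.assembly, outdir / "assembly.gtf")
    formats_io.write_fasta(bundle.sequences, outdir / "transcripts.fasta")
    expr = simulate_expression(config, bundle)
    formats_io.write_expression(expr, outdir / "expr.tsv")
    coding = simulate_coding_calls(config, bundle)
    formats_io.write_table(coding, outdir / "coding_calls.tsv")
    panel = simulate_population(config, bundle)
    formats_io.write_vcf(panel, outdir / "panel.vcf")
    pd.DataFrame(
        {"sample": panel.samples, "group": [panel.sample_groups[s] for s in panel.samples]}
    ).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    geno, pos, pheno = simulate_phenotype_and_array(config, bundle)
    geno.to_csv(outdir / "array.tsv", sep="\t", index_label="sample")
    pos.to_csv(outdir / "array_pos.tsv", sep="\t")
    pheno.to_csv(outdir / "pheno.tsv", sep="\t", index_label="sample", float_format="%.6g")
    binding, energy = simulate_binding_and_energy(config, bundle)
    formats_io.write_table(binding, outdir / "binding.tsv")
    formats_io.write_table(energy, outdir / "energy.tsv")
    hits = simulate_homologs(config, bundle)
    formats_io.write_table(hits, outdir / "hits.tsv")
    qtl, intro = simulate_intervals(config, bundle)
    formats_io.write_bed(qtl, outdir / "qtl.bed")
    formats_io.write_bed(intro, outdir / "introgression.bed")
    truth = bundle.truth
    with open(outdir / "truth.json", "w") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1, sort_keys=True)
    return truth
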