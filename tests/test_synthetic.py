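import filecmp
import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from spikelnc.discovery import assign_class_code
from spikelnc.models import GROUP_SIZES, GenomicInterval
from spikelnc.popgen import nucleotide_diversity
from spikelnc.synthetic import (
    SimulationConfig,
    simulate_all,
    simulate_annotation,
    simulate_expression,
    simulate_phenotype_and_array,
    simulate_population,
)

from conftest import SMALL_SIM


def test_default_group_sizes_sum_to_panel_total():
    cfg = SimulationConfig()
    assert sum(cfg.group_sizes.values()) == 261
    assert cfg.group_sizes == GROUP_SIZES


def test_config_validation():
    with pytest.raises(ValueError, match="heritability"):
        SimulationConfig(causal_h2=1.5)
    with pytest.raises(ValueError, match="saturates"):
        SimulationConfig(pair_rho=0.9999)
    with pytest.raises(ValueError, match="planted"):
        SimulationConfig(n_lncrnas=10, n_planted_cis=20)
    with pytest.raises(ValueError, match="0.5"):
        SimulationConfig(group_diversity={**SimulationConfig().group_diversity, "A1": 0.6})


def test_byte_identical_determinism(tmp_path):
    cfg = dict(SMALL_SIM)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate_all(SimulationConfig(seed=21, **cfg), a)
    simulate_all(SimulationConfig(seed=21, **cfg), b)
    files = sorted(p.name for p in a.iterdir())
    assert files == sorted(p.name for p in b.iterdir())
    match, mismatch, errors = filecmp.cmpfiles(a, b, files, shallow=False)
    assert mismatch == [] and errors == []


def test_single_exon_count_is_deterministic():
    cfg = SimulationConfig(
        seed=2,
        n_genes=30,
        n_lncrnas=10,
        fraction_single_exon=0.9,
        n_planted_cis=2,
        n_planted_trans=0,
        n_planted_triangles=0,
    )
    bundle = simulate_annotation(cfg)
    lncs = [t for t in bundle.assembly if t.biotype == "lncRNA-candidate"]
    assert sum(t.n_exons == 1 for t in lncs) == 9


def test_planted_cis_within_window_and_class_codes(annotation_bundle):
    ivs = {t.transcript_id: t.interval for t in annotation_bundle.assembly}
    for p in annotation_bundle.truth.pairs:
        d = ivs[p["lncrna_id"]].gap_to(ivs[p["mrna_id"]])
        if p["mode"] == "cis":
            assert d <= 100_000
        else:
            assert d > 100_000
    by_chrom = {}
    for r in annotation_bundle.reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    for tid, want in annotation_bundle.truth.planted_classes.items():
        t = next(x for x in annotation_bundle.assembly if x.transcript_id == tid)
        assert assign_class_code(t, by_chrom.get(t.chrom, [])).code == want


def test_length_contrast_matches_configured_medians(annotation_bundle):
    lnc_len = [t.length for t in annotation_bundle.assembly if t.biotype == "lncRNA-candidate"]
    mrna_len = [t.length for t in annotation_bundle.reference]
    assert np.median(lnc_len) < np.median(mrna_len)
    assert 700 < np.median(lnc_len) < 3200
    assert 2300 < np.median(mrna_len) < 6500


def test_planted_rho_achieved(annotation_bundle):
    cfg = SimulationConfig(seed=5)
    expr = simulate_expression(cfg, annotation_bundle)
    for p in annotation_bundle.truth.pairs[:10]:
        rho = sstats.spearmanr(expr.loc[p["lncrna_id"]], expr.loc[p["mrna_id"]])[0]
        assert 0.90 <= rho <= 0.99
    for t in annotation_bundle.truth.triangles:
        rho = sstats.spearmanr(expr.loc[t["lncrna_id"]], expr.loc[t["mrna_id"]])[0]
        assert -0.9 <= rho <= -0.65


def test_unplanted_features_uncorrelated(annotation_bundle):
    cfg = SimulationConfig(seed=5)
    expr = simulate_expression(cfg, annotation_bundle)
    planted = {p["lncrna_id"] for p in annotation_bundle.truth.pairs}
    planted |= {t["lncrna_id"] for t in annotation_bundle.truth.triangles}
    decoys = [t for t in annotation_bundle.truth.lncrna_ids if t not in planted][:20]
    genes = [t.transcript_id for t in annotation_bundle.reference][:20]
    rhos = [
        abs(sstats.spearmanr(expr.loc[l], expr.loc[g])[0])
        for l, g in zip(decoys, genes)
    ]
    assert max(rhos) < 0.3  # n=186 independence


def test_population_diversity_tracks_targets(annotation_bundle):
    cfg = SimulationConfig(seed=5)
    panel = simulate_population(cfg, annotation_bundle)
    chroms = sorted({s.interval.chrom for s in panel.sites})
    span = [
        (GenomicInterval(c, 0, 10**9), c) for c in chroms
    ]
    realized = {}
    for g in ("A1", "A2", "AB1", "ABD2", "D1"):
        res = nucleotide_diversity(panel, g, windows=span, denominator="sites")
        vals = np.array([r.pi * r.n_sites for r in res])
        realized[g] = vals.sum() / sum(r.n_sites for r in res)
    for g, pi in realized.items():
        assert pi == pytest.approx(cfg.group_diversity[g], rel=0.2)
    # halving target -> realized ratio in [0.4, 0.6]
    assert 0.4 <= realized["A2"] / realized["A1"] <= 0.6


def test_phenotype_effect_direction():
    cfg = SimulationConfig(seed=9, n_array_snps=300)
    geno, pos, pheno = simulate_phenotype_and_array(cfg)
    causal = geno.columns[0]  # first trait's causal SNP
    y = pheno[cfg.traits[0]]
    assert y[geno[causal] == 2].mean() > y[geno[causal] == 0].mean()


def test_truth_referential_integrity(default_run):
    truth = default_run["truth"]
    d = default_run["dir"]
    expr_ids = set(
        pd.read_csv(d / "expr.tsv", sep="\t", usecols=[0]).iloc[:, 0]
    )
    from spikelnc.formats_io import read_gtf

    asm_ids = {t.transcript_id for t in read_gtf(d / "assembly.gtf")}
    for tid in truth["lncrna_ids"]:
        assert tid in asm_ids and tid in expr_ids
    for p in truth["pairs"]:
        assert p["lncrna_id"] in asm_ids and p["mrna_id"] in asm_ids
    binding = pd.read_csv(d / "binding.tsv", sep="\t", comment="#")
    bound = set(zip(binding.transcript_id, binding.mirna_id))
    for t in truth["triangles"]:
        assert (t["lncrna_id"], t["mirna_id"]) in bound
        assert (t["mrna_id"], t["mirna_id"]) in bound
    array_cols = set(
        pd.read_csv(d / "array.tsv", sep="\t", nrows=0).columns
    )
    for trait, snp in truth["causal"].items():
        assert snp in array_cols
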