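import itertools

import numpy as np
import pandas as pd
import pytest

from spikelnc.models import MISSING, GenomicInterval, Site, VariantPanel
from spikelnc.popgen import (
    diversity_shift,
    haplotypes,
    nucleotide_diversity,
    pairwise_fst,
    snp_density,
    wc_fst_components,
)


def panel_from_haplotypes(haps, positions=None, chrom="chr1", groups=None):
    """Build a fully phased panel from a (n_sites, n_chromosomes) 0/1 array.

    Chromosome copies are paired into diploid samples (n_chromosomes even).
    """
    haps = np.asarray(haps, dtype=np.int8)
    n_sites, n_chrom = haps.shape
    assert n_chrom % 2 == 0
    n_samp = n_chrom // 2
    positions = positions if positions is not None else list(range(10, 10 + n_sites))
    sites = [
        Site(GenomicInterval(chrom, p, p + 1), "A", "G") for p in positions
    ]
    hap3 = haps.reshape(n_sites, n_samp, 2)
    samples = [f"s{i}" for i in range(n_samp)]
    groups = groups or {s: "A1" for s in samples}
    return VariantPanel(
        sites=sites,
        samples=samples,
        genotypes=hap3.sum(axis=2).astype(np.int8),
        sample_groups=groups,
        haplotypes=hap3,
    )


def mean_pairwise_diff(haps, span):
    """Oracle: average per-bp pairwise difference over all haplotype pairs."""
    n = haps.shape[1]
    total = sum(
        np.sum(haps[:, i] != haps[:, j]) for i, j in itertools.combinations(range(n), 2)
    )
    return total / (n * (n - 1) / 2) / span


def test_pi_monomorphic_window_is_zero():
    panel = panel_from_haplotypes(np.zeros((5, 10)))
    (res,) = nucleotide_diversity(
        panel, "A1", windows=[(GenomicInterval("chr1", 0, 100), "w")]
    )
    assert res.pi == 0.0


def test_pi_single_site_half_frequency():
    # 10 chromosomes, one site at p=0.5, window 100 bp
    haps = np.array([[1, 1, 1, 1, 1, 0, 0, 0, 0, 0]])
    panel = panel_from_haplotypes(haps)
    (res,) = nucleotide_diversity(
        panel, "A1", windows=[(GenomicInterval("chr1", 0, 100), "w")]
    )
    expected = (10 / 9) * 2 * 0.25 / 100
    assert res.pi == pytest.approx(expected)
    assert res.pi == pytest.approx(mean_pairwise_diff(haps, 100))


def test_pi_denominator_scales_with_span():
    haps = np.array([[1, 1, 1, 0, 0, 0]])
    panel = panel_from_haplotypes(haps)
    (w1,) = nucleotide_diversity(panel, "A1", windows=[(GenomicInterval("chr1", 0, 100), "a")])
    (w2,) = nucleotide_diversity(panel, "A1", windows=[(GenomicInterval("chr1", 0, 200), "b")])
    assert w2.pi == pytest.approx(w1.pi / 2)


def test_pi_equals_mean_pairwise_difference_oracle():
    """Per-site unbiased-heterozygosity pi == exhaustive pairwise-diff pi."""
    rng = np.random.default_rng(7)
    for _ in range(60):
        n_chrom = 2 * int(rng.integers(2, 11))
        n_sites = int(rng.integers(1, 51))
        haps = (rng.random((n_sites, n_chrom)) < rng.uniform(0.1, 0.9)).astype(int)
        span = 10 * n_sites
        panel = panel_from_haplotypes(haps, positions=list(range(n_sites)))
        res = nucleotide_diversity(
            panel, "A1", windows=[(GenomicInterval("chr1", 0, span), "w")], min_alleles=2
        )
        pi = res[0].pi if res else 0.0
        assert pi == pytest.approx(mean_pairwise_diff(haps, span), abs=1e-12)


def test_fst_identical_groups_near_zero():
    rng = np.random.default_rng(3)
    p = rng.uniform(0.1, 0.9, size=2000)
    haps = (rng.random((2000, 80)) < p[:, None]).astype(int)
    groups = {f"s{i}": ("A1" if i < 20 else "A2") for i in range(40)}
    panel = panel_from_haplotypes(haps, positions=list(range(2000)), groups=groups)
    res = pairwise_fst(panel, "A1", "A2")
    assert abs(res.fst) < 0.02


def test_fst_fixed_difference_is_one():
    haps = np.hstack([np.zeros((50, 20)), np.ones((50, 20))]).astype(int)
    groups = {f"s{i}": ("A1" if i < 10 else "A2") for i in range(20)}
    panel = panel_from_haplotypes(haps, positions=list(range(50)), groups=groups)
    assert pairwise_fst(panel, "A1", "A2").fst == pytest.approx(1.0)


def test_fst_two_site_hand_computed_components():
    """Term-by-term Weir-Cockerham components on a tiny two-site panel."""
    # site 1: pop1 genotypes (0,1,2), pop2 (0,0,1); site 2: pop1 (2,2,1), pop2 (0,1,0)
    d1 = np.array([0, 1, 2]), np.array([0, 0, 1])
    d2 = np.array([2, 2, 1]), np.array([0, 1, 0])

    def hand_components(da, db):
        n1, n2 = len(da), len(db)
        p1, p2 = da.sum() / (2 * n1), db.sum() / (2 * n2)
        h1, h2 = np.mean(da == 1), np.mean(db == 1)
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
        return a, b, c

    for da, db in (d1, d2):
        got = wc_fst_components(da, db)
        want = hand_components(da, db)
        assert got == pytest.approx(want, abs=1e-12)

    # ratio-of-sums aggregation over the two sites
    comps = [hand_components(da, db) for da, db in (d1, d2)]
    want_fst = sum(a for a, _, _ in comps) / sum(a + b + c for a, b, c in comps)
    geno = np.array([[0, 1, 2, 0, 0, 1], [2, 2, 1, 0, 1, 0]], dtype=np.int8)
    sites = [Site(GenomicInterval("chr1", p, p + 1), "A", "G") for p in (5, 9)]
    samples = [f"s{i}" for i in range(6)]
    groups = {s: ("P1" if i < 3 else "P2") for i, s in enumerate(samples)}
    panel = VariantPanel(sites, samples, geno, groups)
    assert pairwise_fst(panel, "P1", "P2").fst == pytest.approx(want_fst, abs=1e-12)


def test_fst_split_halves_of_one_group_small():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.05, 0.95, size=2000)
    haps = (rng.random((2000, 60)) < p[:, None]).astype(int)
    groups = {f"s{i}": ("H1" if i < 15 else "H2") for i in range(30)}
    panel = panel_from_haplotypes(haps, positions=list(range(2000)), groups=groups)
    assert abs(pairwise_fst(panel, "H1", "H2").fst) < 0.05


def test_fst_monotone_in_simulated_divergence():
    """Larger Balding-Nichols F between groups -> larger estimated Fst."""
    rng = np.random.default_rng(5)
    estimates = []
    for f in (0.02, 0.1, 0.3, 0.6):
        p_anc = rng.uniform(0.2, 0.8, size=1500)
        haps = np.empty((1500, 80), dtype=int)
        for g, cols in ((0, slice(0, 40)), (1, slice(40, 80))):
            a, b = p_anc * (1 - f) / f, (1 - p_anc) * (1 - f) / f
            pg = rng.beta(a, b)
            haps[:, cols] = rng.random((1500, 40)) < pg[:, None]
        groups = {f"s{i}": ("G1" if i < 20 else "G2") for i in range(40)}
        panel = panel_from_haplotypes(haps, positions=list(range(1500)), groups=groups)
        estimates.append(pairwise_fst(panel, "G1", "G2").fst)
    assert estimates == sorted(estimates)


def test_snp_density_and_boundary():
    haps = np.ones((6, 4), dtype=int)
    panel = panel_from_haplotypes(haps, positions=[100, 200, 300, 400, 500, 1000])
    df = snp_density(
        panel,
        [
            (GenomicInterval("chr1", 0, 1000), "f1"),  # site at 1000 excluded
            (GenomicInterval("chr1", 2000, 3000), "f2"),
        ],
    )
    assert df.set_index("feature").loc["f1", "snps_per_kb"] == pytest.approx(5.0)
    assert df.set_index("feature").loc["f2", "snps_per_kb"] == 0.0


def _hap_panel_for_groups(n_h1, n_h2, group="AB3", n_sites=26):
    """All-homozygous two-haplotype panel: H1 = all ref, H2 = all alt."""
    n = n_h1 + n_h2
    haps = np.zeros((n_sites, 2 * n), dtype=int)
    haps[:, 2 * n_h1 :] = 1
    groups = {f"s{i}": group for i in range(n)}
    return panel_from_haplotypes(haps, positions=list(range(n_sites)), groups=groups)


def test_major_haplotype_rule_mirrors_study_pattern():
    panel = _hap_panel_for_groups(10, 3)
    table = haplotypes(panel, GenomicInterval("chr1", 0, 100), "feat", ["AB3"])
    freqs = table.group_frequencies["AB3"]
    major = table.major["AB3"]
    assert major is not None
    assert freqs[major] == pytest.approx(10 / 13)
    assert round(100 * freqs[major], 2) == 76.92
    assert len(major) == 26


def test_major_haplotype_strictly_greater_than_half():
    panel = _hap_panel_for_groups(5, 5)
    table = haplotypes(panel, GenomicInterval("chr1", 0, 100), "feat", ["AB3"])
    assert table.major["AB3"] is None
    assert sum(table.group_frequencies["AB3"].values()) == pytest.approx(1.0)


def test_haplotypes_exclude_unphased_and_count():
    panel = _hap_panel_for_groups(3, 1)
    # make sample 0 unphased-het at site 0: dosage 1 without phase
    panel.genotypes[0, 0] = 1
    panel.haplotypes[0, 0, :] = MISSING
    table = haplotypes(panel, GenomicInterval("chr1", 0, 100), "feat", ["AB3"])
    assert table.excluded_samples["AB3"] == 1
    total_chroms = sum(
        round(f * 6) for f in table.group_frequencies["AB3"].values()
    )
    assert total_chroms == 6  # (4 samples - 1 excluded) * 2


def test_diversity_shift_signs_and_ratio():
    df = diversity_shift(
        {"A1": 0.4, "A2": 0.2, "AB1": 0.3, "AB2": 0.3, "AB3": 0.4, "ABD1": 0.1, "ABD2": 0.05},
        lineage_edges=[("A1", "A2"), ("AB1", "AB2"), ("AB2", "AB3"), ("ABD1", "ABD2")],
    )
    rows = df.set_index(["parent", "child"])
    assert rows.loc[("A1", "A2"), "sign"] == "-"
    assert rows.loc[("A1", "A2"), "ratio"] == pytest.approx(0.5)
    assert rows.loc[("AB1", "AB2"), "sign"] == "0"
    assert rows.loc[("AB2", "AB3"), "sign"] == "+"
    assert not rows.loc[("AB2", "AB3"), "bottleneck"]


def test_diversity_shift_missing_group_error():
    with pytest.raises(ValueError, match="missing group"):
        diversity_shift({"A1": 0.1}, lineage_edges=[("A1", "A2")])


def test_group_too_small_error():
    panel = _hap_panel_for_groups(1, 0)
    with pytest.raises(ValueError, match="< 2 samples"):
        nucleotide_diversity(panel, "AB3", windows=[(GenomicInterval("chr1", 0, 10), "w")])
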