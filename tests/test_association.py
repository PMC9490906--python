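import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from spikelnc.association import (
    AssociationHit,
    assign_candidates,
    colocalize,
    fisher_enrichment,
    gwas_scan,
    ld_r2,
)
from spikelnc.models import GenomicInterval
from spikelnc.synthetic import SimulationConfig, simulate_phenotype_and_array


@pytest.fixture(scope="module")
def array_data():
    cfg = SimulationConfig(seed=9, n_array_snps=600)
    geno, pos, pheno = simulate_phenotype_and_array(cfg)
    return cfg, geno, pos, pheno


def test_gwas_matches_statsmodels_single_snp(array_data):
    """Vectorized residualized OLS == statsmodels OLS with PC covariates."""
    import statsmodels.api as sm

    from spikelnc.association import _pc_covariates

    cfg, geno, pos, pheno = array_data
    hits = gwas_scan(geno, pheno["HD"], trait="HD", positions=pos, n_pcs=3, maf_min=0.05)
    x = geno.values.astype(float)
    freq = x.mean(axis=0) / 2
    keep = np.minimum(freq, 1 - freq) >= 0.05
    pcs = _pc_covariates(x[:, keep], 3)
    by_id = {h.snp_id: h for h in hits}
    for sid in list(geno.columns[keep])[:5]:
        g = geno[sid].values.astype(float)
        X = sm.add_constant(np.column_stack([g, pcs]))
        fit = sm.OLS(pheno["HD"].values, X).fit()
        h = by_id[sid]
        assert h.effect == pytest.approx(fit.params[1], rel=1e-8)
        assert h.p_value == pytest.approx(fit.pvalues[1], rel=1e-6)


def test_causal_snp_is_top_hit(array_data):
    cfg, geno, pos, pheno = array_data
    for trait in ("SL", "HD"):
        hits = gwas_scan(geno, pheno[trait], trait=trait, positions=pos)
        top = min(hits, key=lambda h: h.p_value)
        causal_col = list(geno.columns)[
            list(cfg.traits).index(trait) * (cfg.n_array_snps // len(cfg.traits))
        ]
        assert top.snp_id == causal_col
        assert top.passes_threshold


def test_permuted_phenotype_null_calibration(array_data):
    cfg, geno, pos, pheno = array_data
    rng = np.random.default_rng(1)
    y = pd.Series(
        rng.permutation(pheno["GN"].values), index=pheno.index, name="GN"
    )
    hits = gwas_scan(geno, y, trait="GN", positions=pos)
    pvals = np.array([h.p_value for h in hits])
    frac = np.mean(pvals < 0.05)
    assert 0.02 <= frac <= 0.08
    # 1/Ne threshold applied as strict less-than with the stated Ne
    hits_ne = gwas_scan(geno, pheno["HD"], trait="HD", ne=21868)
    thr = 1 / 21868
    for h in hits_ne:
        assert h.passes_threshold == (h.p_value < thr)
    assert thr == pytest.approx(4.573e-5, rel=1e-3)


def test_gwas_errors():
    geno = pd.DataFrame(np.ones((40, 5)), index=[f"s{i}" for i in range(40)])
    y = pd.Series(np.ones(40), index=geno.index)
    with pytest.raises(ValueError, match="variance"):
        gwas_scan(geno, y)
    with pytest.raises(ValueError, match="30"):
        gwas_scan(geno.iloc[:10], pd.Series(np.arange(10.0), index=geno.index[:10]))


def test_ld_r2_identity_and_flip_monotonicity():
    rng = np.random.default_rng(2)
    a = rng.binomial(2, 0.4, size=93).astype(float)
    assert ld_r2(a, a) == pytest.approx(1.0)

    def flip(v, frac):
        v = v.copy()
        idx = rng.choice(len(v), int(frac * len(v)), replace=False)
        v[idx] = rng.binomial(2, 0.4, size=len(idx))
        return v

    r_small = ld_r2(a, flip(a, 0.1))
    r_big = ld_r2(a, flip(a, 0.6))
    assert 1.0 >= r_small >= r_big


def test_ld_r2_independent_sites_bias_level():
    rng = np.random.default_rng(3)
    n = 93
    vals = [
        ld_r2(rng.binomial(2, 0.3, n).astype(float), rng.binomial(2, 0.3, n).astype(float))
        for _ in range(400)
    ]
    assert np.mean(vals) == pytest.approx(1 / (n - 1), rel=0.35)


def _hit(chrom, pos, p=1e-9, passes=True):
    return AssociationHit(
        site=GenomicInterval(chrom, pos, pos + 1),
        trait="HD",
        effect=1.0,
        p_value=p,
        passes_threshold=passes,
        snp_id=f"snp_{pos}",
    )


def test_assign_candidates_window_boundaries():
    hit = _hit("chr1", 10_000_000)
    feats = [
        (GenomicInterval("chr1", 10_000_000 - 4_900_000 - 1000, 10_000_000 - 4_900_000), "near"),
        (GenomicInterval("chr1", 15_100_001, 15_200_000), "far"),
        (GenomicInterval("chr1", 9_999_000, 10_001_000), "on_top"),
    ]
    out = assign_candidates([hit], feats, window=5_000_000)
    got = {a.feature_id: a.distance for a in out}
    assert "near" in got and "far" not in got
    assert got["on_top"] == 0
    # widening the window never removes assignments; order never matters
    wider = assign_candidates([hit], feats[::-1], window=6_000_000)
    assert {a.feature_id for a in out} <= {a.feature_id for a in wider}
    # non-passing hits assign nothing
    assert assign_candidates([_hit("chr1", 1, passes=False)], feats) == []


def test_colocalize_half_open_abutting():
    feats = [(GenomicInterval("chr1", 100, 200), "f1")]
    sets = {"qtl": [(GenomicInterval("chr1", 200, 300), "q1")]}
    df = colocalize(feats, sets)
    assert df.iloc[0]["n_overlaps"] == 0


def test_fisher_worked_values():
    # diagonal table: p = 2 / C(20,10)
    assert fisher_enrichment(10, 0, 0, 10) == pytest.approx(2 / 184756, rel=1e-9)
    assert fisher_enrichment(5, 5, 5, 5) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        fisher_enrichment(0, 0, 0, 0)


def test_fisher_matches_scipy_small_margins():
    for a in range(7):
        for b in range(7):
            for c in range(7):
                for d in range(7):
                    if a + b + c + d == 0:
                        continue
                    ours = fisher_enrichment(a, b, c, d)
                    ref = sstats.fisher_exact([[a, b], [c, d]])[1]
                    assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)


def test_pair_introgression_enrichment_significant(default_run):
    """Planted introgression cover of pair lncRNAs yields a strong Fisher signal."""
    enr = pd.read_csv(default_run["dir"] / "enrichment.tsv", sep="\t", comment="#")
    assert enr.iloc[0]["fisher_p"] < 1e-4
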