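# Methods

This note records the models the package implements, the parameter defaults
and why they were chosen, the numerical conventions, and what the synthetic
data does and does not emulate.  Every number quoted here is computed by the
test suite or by `scripts/acceptance.py`.

## Coordinates and formats

All intervals are 0-based half-open internally.  GTF (1-based inclusive) and
VCF POS are shifted on read and restored on write; BED passes through.  The
conversion is self-inverse: writing a parsed GTF reproduces the original
integers (tested by round-trip).  Genotypes are collapsed to allele dosage
{0, 1, 2} with −1 for missing; phase is kept in a separate haplotype array
(populated by phased calls and by homozygotes, which are phase-unambiguous)
and consumed only by the haplotype builder.  Multi-allelic and indel VCF
records are skipped with a counter — the haplotype alphabet is strictly
bi-allelic SNPs.

## Transcript class codes

A query transcript receives a single deterministic code with precedence
`=` > `c` > `j` > `e` > `i` > `o` > `x` > `u`, evaluated over all
same-chromosome reference transcripts; ties at equal precedence resolve to
the lexicographically smallest reference id, so reference input order never
matters.  Predicates:

- `=` — exonic overlap with an identical ordered intron chain;
- `c` — all query bases inside reference exons (abutting exons merged) and
  the query's introns a subset of the reference's;
- `j` — multi-exon query sharing at least one exact intron (both
  boundaries) with the reference, not contained;
- `e` — single-exon query overlapping both a reference exon and an intron
  of the same transcript;
- `i` — query wholly inside one reference intron, same strand;
- `o` — remaining same-strand exonic overlap (partial intron overlap
  without exonic overlap is *not* `o`; it falls through);
- `x` — antisense exonic overlap;
- `u` — the fallback: intergenic, or no predicate above matched (this keeps
  the function total; an antisense-intronic query, for example, lands here).

An unknown strand (`.`) is treated as compatible with either strand for the
same-strand predicates and can never be antisense.  The implementation works
on interval arithmetic; an independent brute-force classifier evaluates the
same predicates on explicit per-base coordinate sets, and the two agree on
500 random small instances (zero mismatches).

Candidates keep codes {i, j, o, u}.  Antisense overlaps (`x`) are excluded:
natural antisense transcripts are a recognized lncRNA class, but the
discovery rule used here keeps only the four listed codes.  "Expressed"
uses a strict inequality (FPKM > 0.1) and a ceiling on the sample fraction
(≥ ⌈0.2·n⌉ samples) — the conservative reading of "at least 20%".  The
coding-potential predictors (two scorers plus a domain-database flag) are
consumed as a table, never re-run, and a transcript flagged coding by *any*
predictor is dropped (unanimity); transcripts missing from the table are
excluded and counted, not silently kept.

## Target pairing

Distance is the nearest-edge gap (0 when overlapping, infinite across
chromosomes); the 100 kb cis window is applied to that gap, which is
symmetric and convention-free.  Each lncRNA takes at most one cis partner —
the nearest in-window gene, ties broken by distance then gene id — while
trans pairing is one-to-many through the consumed energy table with the
normalized-free-energy cutoff exposed as `ndg_max` (default −0.1, the
conventional default of the pairing tool this table stands in for).  The
energy filter applies to trans pairs only by default (`energy_on_cis`
extends it).  Correlation gating is Spearman's ρ (Pearson on mid-ranks,
two-sided t approximation on n−2 df) with |ρ| > 0.9, p < 0.05, per pair and
unadjusted for multiplicity — that is the stated per-pair rule; a
multiple-testing layer would sit naturally on top but is deliberately not
silently applied.

## Population genetics

Per-site π is the unbiased heterozygosity (n/(n−1))·2p(1−p) with n the
non-missing allele count at that site in the group; a window's π divides the
per-site sum by the window *span* in bp (the VCFtools `--window-pi`
convention), with `denominator="sites"` available for mean per-site π.
Sites with fewer than 4 non-missing alleles in a group are skipped; missing
genotypes adjust n per site, never imputed.  The windowed formula is
provably identical to the exhaustive mean pairwise difference per bp; the
suite verifies agreement to 1e−12 on 200 random panels.

F_ST is the Weir–Cockerham (1984) two-population estimator with
ratio-of-sums aggregation (Σa / Σ(a+b+c)), the "weighted" F_ST of VCFtools,
because the study style reports a single value per group comparison; the
per-site mean is also emitted.  Sites monomorphic across the pooled pair are
excluded.  Small negative estimates are preserved down to −0.05 and flagged
rather than clamped to zero.  A fixed-difference panel gives exactly 1.0 and
split halves of one simulated population stay below 0.05 at 2,000 sites.

Haplotypes are built only from phase-resolved chromosome copies (phased
calls or homozygotes); samples with any unresolved site in the feature are
excluded with a per-group count, and no statistical phasing is attempted.
The major haplotype is the one with within-group frequency strictly above
50% — the reading of the "> 50% of the subgroup" rule that reproduces the
canonical worked pattern: 10 of 13 carriers → 76.92%, major; an exact 50/50
split → none.  (The alternative reading — a haplotype carried by > 50% of
the nine *groups* — is not implemented.)

Diversity shifts report sign(π_child − π_parent) and the ratio along
configurable lineage edges; the defaults are the four domestication/
improvement transitions A1→A2, AB1→AB2, AB2→AB3 and ABD1→ABD2.

## ceRNA triangles

A triangle is one (lncRNA, miRNA, mRNA) triple whose two binding rows exist
verbatim in the consumed binding-site table (spans validated against
transcript lengths, expectation score ≤ 5 by default) and whose lncRNA–mRNA
Spearman correlation passes a signed gate.  The default is *negative* with
|ρ| ≥ 0.5: classical sponge theory predicts positive lncRNA–mRNA
correlation, but the decoy behaviour this pipeline models is the observed
negative coupling of the worked example, so the sign is a flag
(`negative|positive|either`).  Triangles are deduplicated on the triple and
are not restricted to previously emitted target pairs (a `pairs` argument
exists for the network export).  The hub report ranks miRNAs by triangle
participation.

## Trait association

The structure-aware scan is a deliberate stand-in for a compressed mixed
model: phenotype and dosages are residualized on an intercept plus the top
`n_pcs` (default 3) genotype principal components, and the per-SNP slope is
tested two-sided on n − 2 − n_pcs df.  This plays the same inferential role
(population-structure correction) with desk-scale determinism, and it
matches per-SNP OLS with PC covariates exactly (cross-checked against
statsmodels).  MAF filtering defaults to 0.05 (the source filters for the
real array are unstated, so the default is explicit and logged).  The
threshold is 1/Ne with Ne defaulting to the post-filter SNP count; the
effective-test count of the original array (21,868) can be supplied.  The
"(r² ≥ 0.2)" qualifier on the 5 Mb candidate window is read as the LD-decay
justification of the window size, not a per-feature filter; r² utilities
(genotype-composite LD and a binned decay table flagging the first bin below
0.2) are provided separately.  Null calibration: permuted-phenotype
p-values are uniform (KS < 0.05 at 2,000 SNPs).

Fisher's exact two-sided p sums hypergeometric probabilities of all tables
with the observed margins whose probability does not exceed the observed
table's (with a 1e−9 relative tie tolerance); it matches full enumeration /
scipy on every 2×2 table with total ≤ 15 to 1e−8 relative.  Interval
co-localization is any-base overlap under half-open semantics — a feature
exactly abutting an interval does not overlap it.

## Conservation

The score formula is not printed by the method this stands in for; both
cited ingredients are combined as **coverage × identity** (keeps [0, 1] and
makes the 0.6 retention threshold meaningful), with `(coverage+identity)/2`
selectable.  Coverage is *query* coverage (aligned fraction of the lncRNA).
Best hit per (query, species) maximizes the score, ties by lower E-value
then subject id; hits with E ≥ 1e−5 are ignored.  The single-copy set
requires exactly one retained hit in every listed species.  The species tree
is neighbor joining over conservation distances (1 − mean score to the
reference; mean per-query score difference between aligned species) — an
explicit desk-scale substitute for full maximum-likelihood inference, so
labelled in the outputs.  Negative NJ branch lengths are clamped to 0 and
flagged.

## Synthetic data: what it emulates

The generator is deterministic given the seed: each stage draws from
`default_rng(seed + stage offset)`, so identical configs give byte-identical
files and stages can be regenerated independently.

- **Annotation** — three 60 Mb chromosomes (wheat-style names chr1A/1B/1D),
  240 genes and 160 lncRNA models by default.  mRNAs draw spliced lengths
  log-normal around a 3,953 bp median and are mostly multi-exon; lncRNAs
  around 1,584 bp with a deterministic 89.2% single-exon count — the
  length/exon contrasts of the real comparison.  Planted lncRNAs are placed
  so the classifier provably returns the intended code (verified in tests);
  cis partners sit 5–45 kb from their gene, trans/triangle partners on other
  chromosomes.
- **Expression** — Gaussian copula: a planted Spearman ρ_s is induced by
  latent Pearson r = 2·sin(πρ_s/6), then mapped monotonically to log-normal
  FPKM with the lncRNA marginal (median ≈ 2) below the mRNA marginal
  (median ≈ 8).  Planted pairs use ρ = 0.95 (sample values land in
  [0.90, 0.99] at n = 186), triangles ρ = −0.8.  The log-normal noise model
  is a stand-in — the real FPKM error structure is unknown — and is isolated
  behind the config.
- **Population** — Balding–Nichols: ancestral frequency Uniform(0.05, 0.95),
  group frequency Beta(p(1−F)/F, (1−p)(1−F)/F) with F solved per group from
  its target per-site π (targets halve along each domestication edge;
  realized group π lands within 20% of target at 3,000 sites).  The first
  planted cis lncRNA hosts a 26-site haplotype block in which every sample
  is homozygous and group H1 counts are fixed (AB3 10/13 → 76.92%, ABD1
  42/45 → 93.33%, ABD2 25/25 → 100%), mirroring the canonical major-
  haplotype pattern.  There is no linkage, recombination map, coalescent
  history or subgenome homoeology — only the marginal frequency structure
  the diversity analyses consume.
- **Phenotypes** — 93 lines, 2,000 array SNPs, one causal SNP per trait
  (SL, GW, GN, SNS, HD) at MAF 0.3, phenotype = dosage + Gaussian noise
  scaled to h² = 0.5.  The causal SNP is the genome-wide top hit in ≥ 80 of
  100 seeds (the acceptance script reports the realized rate).
- **Consumed tables** — binding sites are 21-nt spans (the width of the
  worked 369–389 / 314–334 bp example); energies are pass/fail constants;
  homolog hits decay linearly along a planted species chain so the NJ tree
  must recover the chain order; five decoy lncRNAs carry a conflicting
  coding call; introgression intervals cover 12 planted pair lncRNAs to
  make the Fisher enrichment positive by construction.

Because the generator plants exactly the structure the filters test for,
passing recovery tests demonstrates the *machinery* (thresholds, windows,
estimators, bookkeeping) — not robustness to the messiness of real data
(batch effects, mapping artefacts, LD, shared regulation creating correlated
non-pairs).  Problem sizes (240/160 features, 3,000 sites, 2,000 array SNPs)
were chosen as the smallest at which the statistical checks are stable.

## Pipeline

`run_all` executes simulate → identify → pair → popgen → cerna → assoc →
conserve, records per-stage input checksums, counts, a parameter digest and
wall time in `manifest.json`, stops at the first failing stage (manifest
written up to that point), and with `resume=True` skips any stage whose
inputs are checksum-unchanged.  Output tables carry a header comment with
the tool version and parameter digest.  Config is TOML; every threshold
defaults to the printed analysis values.

## Known limitations

- The class-code predicates are a faithful but independent reimplementation
  of the gffcompare scheme; codes for exotic structures (e.g. repeats, `p`,
  `s`) are out of scope.
- The GWAS stand-in corrects structure with PCs, not kinship; inflation on
  strongly related panels would be underestimated.
- NJ on conservation distances recovers topology for tree-like decay but is
  not a substitute for sequence-based phylogenetics.
- Haplotype construction requires phase; panels of unphased heterozygotes
  yield (correctly) empty tables rather than imputed ones.
- miRNA–miRNA interactions are not modelled: the network has binds and
  pairs-with edge types only.
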