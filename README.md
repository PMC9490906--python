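# spikelnc

Population-transcriptome analysis of long non-coding RNAs (lncRNAs) in the
wheat spike, reimplemented as a tested, fully synthetic-data-driven pipeline.

## The scientific problem

Wheat spike development is controlled in part by lncRNAs — transcripts longer
than 200 bp with no protein-coding potential.  Characterizing them at the
population scale requires chaining several analyses that are usually run as
one-off scripts:

1. **Discovery** — classify assembled transcripts against the reference
   annotation with gffcompare-style class codes and keep candidates of class
   `i` (intronic), `j` (novel junction isoform), `o` (other same-strand exonic
   overlap) and `u` (intergenic) that are expressed (FPKM > 0.1 in ≥ 20% of
   samples), longer than 200 bp, and unanimously called non-coding by the
   consumed coding-potential predictors.
2. **Target pairing** — a protein-coding gene within 100 kb of a lncRNA is its
   *cis* target (one per lncRNA, the nearest); genes farther away or on other
   chromosomes are *trans* candidates supported by a pairing free-energy
   table.  Either way the pair must be co-expressed: Spearman |ρ| > 0.9,
   p < 0.05.
3. **Population genetics** — across nine *Triticum*/*Aegilops* groups
   (A1–A3, AB1–AB3, ABD1–ABD2, D1; 261 accessions): nucleotide diversity
   π (per-site unbiased heterozygosity, VCFtools windowed-π convention),
   pairwise Weir–Cockerham F_ST (ratio-of-sums Σa / Σ(a+b+c)), SNP density,
   per-group haplotype tables with the "> 50% within a group = major
   haplotype" rule, and signed diversity shifts along the domestication
   lineage (bottleneck when π_child/π_parent < 1).
4. **ceRNA triangles** — lncRNA–miRNA–mRNA triples in which both the lncRNA
   and the mRNA carry a binding site for the same miRNA and the lncRNA–mRNA
   expression correlation passes a signed threshold (default negative,
   |ρ| ≥ 0.5).
5. **Trait association** — per-SNP linear model `phenotype ~ dosage + top-3
   genotype PCs` with the 1/Ne significance threshold (Ne = effective number
   of independent tests), 5 Mb candidate windows around passing SNPs, LD r²
   utilities, and exact two-sided Fisher enrichment against QTL and
   introgression intervals.
6. **Conservation** — consumed cross-species alignment hits scored as
   coverage × identity (retained > 0.6), single-copy homolog extraction, and
   a neighbor-joining species tree over conservation distances.

Real inputs at this scale (terabases of RNA-seq plus consortium
re-sequencing) are not reproducible at a desk, so the package ships a
first-class **synthetic-data generator** that emulates the statistical
structure every stage consumes — planted correlations via a Gaussian copula,
Balding–Nichols allele frequencies tuned to per-group π targets, planted
haplotypes, causal SNPs with controlled heritability — together with the
ground truth, so every stage is testable end to end.

## Worked example

```bash
python analysis/01_simulate_inputs.py     # synthetic inputs -> results/run/
python analysis/02_identify_lncrnas.py
python analysis/03_pair_targets.py
python analysis/04_population_genetics.py
python analysis/05_cerna_network.py
python analysis/06_trait_association.py
python analysis/07_conservation.py
```

With the default seed the drivers print (abridged):

```
discovery funnel: {'input': 400, ..., 'coding': 5, 'candidates': 155}
median length lncRNA 1638 bp vs mRNA 3836 bp; single-exon lncRNA fraction 0.92
40 pairs: 20 cis, 20 trans
planted-pair recall 100.00%, false-discovery proportion 0.00%
mean per-site pi by group: {'A1': 0.2954, 'A2': 0.1504, ..., 'ABD2': 0.0636}
parent child sign    ratio  bottleneck
    A1    A2    - 0.509183        True
AB3 major haplotype at lnc.1.1: 76.92%
10 unique triangles; planted-triangle recall 100%
SL: top AX-100000 p=3.66e-16 (planted causal)
introgression enrichment: table (12,28;1,114), Fisher two-sided p = 2.29e-07
58 single-copy lncRNAs across 8 species
```

Reading the numbers: the discovery funnel keeps exactly the planted
non-coding set (155 of 160 lncRNA models; 5 were planted with a conflicting
coding call); all 20 planted cis and 20 trans pairs are recovered at
|ρ| > 0.9 with no false pairs at n = 186 samples; per-group π tracks its
configured target (halving along each domestication edge, hence four minus
signs); the AB3 group reports a 76.92 % (10/13) major haplotype; each trait's
top association is its planted causal SNP; and the NJ tree orders the eight
species along the planted conservation gradient.

The same pipeline is scriptable as a whole (`spikelnc run --out DIR --seed N`)
or stage by stage via the `spikelnc` subcommands (`simulate`, `identify`,
`pair`, `popgen`, `cerna`, `assoc`, `conserve`, `validate`, `convert`).

## Layout

- `src/spikelnc/` — the library: `formats_io`, `synthetic`, `discovery`,
  `pairing`, `popgen`, `cerna`, `association`, `conservation`, `pipeline`,
  `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end recovery tests.
- `docs/methods.md` — models, parameter choices, numerical conventions and
  known limitations.
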