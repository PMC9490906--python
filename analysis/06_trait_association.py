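#!/usr/bin/env python
"""Trait association scan and QTL/introgression co-localization.

Per trait: PC-adjusted per-SNP regression with the 1/Ne threshold, 5 Mb
candidate windows around passing SNPs, interval co-localization, and the
Fisher enrichment of pair lncRNAs inside introgression regions.  Writes
results/run/{gwas,gwas_candidates,coloc,enrichment}.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from spikelnc import association, formats_io

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    geno = pd.read_csv(RUN / "array.tsv", sep="\t", index_col=0)
    pos = pd.read_csv(RUN / "array_pos.tsv", sep="\t", index_col=0)
    pheno = pd.read_csv(RUN / "pheno.tsv", sep="\t", index_col=0)
    cands = formats_io.read_gtf(RUN / "candidates.gtf")
    mrnas = formats_io.read_gtf(RUN / "reference.gtf")
    features = [(t.interval, t.transcript_id) for t in cands + mrnas]
    truth = json.loads((RUN / "truth.json").read_text())

    gwas_rows, cand_rows = [], []
    for trait in pheno.columns:
        hits = association.gwas_scan(geno, pheno[trait], trait=trait, positions=pos)
        sig = [h for h in hits if h.passes_threshold]
        top = min(hits, key=lambda h: h.p_value)
        mark = "(planted causal)" if top.snp_id == truth["causal"].get(trait) else ""
        print(f"{trait}: {len(sig)} significant SNPs; top {top.snp_id} "
              f"p={top.p_value:.2e} {mark}")
        gwas_rows += [
            {"trait": trait, "snp_id": h.snp_id, "chrom": h.site.chrom,
             "pos": h.site.start, "effect": h.effect, "p": h.p_value}
            for h in sig
        ]
        cand_rows += [
            {"trait": trait, "feature": a.feature_id, "snp_id": a.hit.snp_id,
             "distance": a.distance}
            for a in association.assign_candidates(hits, features)
        ]
    formats_io.write_table(pd.DataFrame(gwas_rows), RUN / "gwas.tsv")
    formats_io.write_table(pd.DataFrame(cand_rows), RUN / "gwas_candidates.tsv")
    print(f"{len(cand_rows)} feature-trait candidate assignments within 5 Mb")

    qtl = formats_io.read_bed(RUN / "qtl.bed")
    intro = formats_io.read_bed(RUN / "introgression.bed")
    coloc = association.colocalize(features, {"qtl": qtl, "introgression": intro})
    formats_io.write_table(coloc, RUN / "coloc.tsv")

    pairs = pd.read_csv(RUN / "pairs.tsv", sep="\t", comment="#")
    pair_lncs = set(pairs.lncrna_id)
    in_intro = {
        r.feature for r in coloc.itertuples(index=False)
        if r.set == "introgression" and r.n_overlaps > 0
    }
    lnc_feats = {name for _, name in features if name.startswith("lnc")}
    a = len(pair_lncs & in_intro)
    b = len(pair_lncs - in_intro)
    c = len((lnc_feats - pair_lncs) & in_intro)
    d = len(lnc_feats - pair_lncs - in_intro)
    p = association.fisher_enrichment(a, b, c, d)
    formats_io.write_table(
        pd.DataFrame([{"a": a, "b": b, "c": c, "d": d, "fisher_p": p}]),
        RUN / "enrichment.tsv",
    )
    print(f"introgression enrichment of pair lncRNAs: "
          f"table ({a},{b};{c},{d}), Fisher two-sided p = {p:.2e}")


if __name__ == "__main__":
    main()
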