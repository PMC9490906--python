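#!/usr/bin/env python
"""Population-genetic characterization across the nine groups.

Per-feature nucleotide diversity, all 36 pairwise Weir-Cockerham Fst
values, SNP density, per-group haplotype tables with the > 50% major rule,
and signed diversity shifts along the domestication lineage.  Writes
results/run/{pi,fst,density,haplotypes,shifts}.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from spikelnc import formats_io, popgen

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    panel = formats_io.read_vcf(RUN / "panel.vcf", RUN / "groups.tsv")
    cands = formats_io.read_gtf(RUN / "candidates.gtf")
    mrnas = formats_io.read_gtf(RUN / "reference.gtf")
    features = [(t.interval, t.transcript_id) for t in cands + mrnas]
    groups = sorted(set(panel.sample_groups.values()))
    print(f"panel: {panel.n_sites} SNPs, {panel.n_samples} accessions, {len(groups)} groups")

    pi_rows, pi_by_group = [], {}
    for g in groups:
        res = popgen.nucleotide_diversity(panel, g, windows=features, denominator="sites")
        pi_by_group[g] = float(np.mean([r.pi for r in res]))
        pi_rows += [{"scope": r.scope, "group": g, "pi": r.pi, "n_sites": r.n_sites} for r in res]
    formats_io.write_table(pd.DataFrame(pi_rows), RUN / "pi.tsv")
    print("mean per-site pi by group:",
          {g: round(v, 4) for g, v in pi_by_group.items()})

    fst_rows = []
    for i, ga in enumerate(groups):
        for gb in groups[i + 1:]:
            r = popgen.pairwise_fst(panel, ga, gb)
            fst_rows.append({"group_a": ga, "group_b": gb, "fst": r.fst, "n_sites": r.n_sites})
    fst = pd.DataFrame(fst_rows)
    formats_io.write_table(fst, RUN / "fst.tsv")
    hi, lo = fst.loc[fst.fst.idxmax()], fst.loc[fst.fst.idxmin()]
    print(f"largest Fst {hi.fst:.3f} ({hi.group_a}-{hi.group_b}); "
          f"smallest {lo.fst:.4f} ({lo.group_a}-{lo.group_b})")

    formats_io.write_table(popgen.snp_density(panel, features), RUN / "density.tsv")

    shifts = popgen.diversity_shift(pi_by_group)
    formats_io.write_table(shifts, RUN / "shifts.tsv")
    print("lineage shifts:")
    print(shifts.to_string(index=False))

    truth = json.loads((RUN / "truth.json").read_text())
    hap_rows = []
    for iv, name in features:
        if len(panel.sites_in(iv)) == 0:
            continue
        table = popgen.haplotypes(panel, iv, name)
        for g, freqs in table.group_frequencies.items():
            for hap, f in sorted(freqs.items()):
                hap_rows.append({"feature": name, "group": g, "haplotype": hap,
                                 "freq": f, "major": table.major[g] == hap})
    formats_io.write_table(pd.DataFrame(hap_rows), RUN / "haplotypes.tsv")
    block = [r for r in hap_rows
             if r["feature"] == truth["hap_feature"] and r["group"] == "AB3" and r["major"]]
    if block:
        print(f"AB3 major haplotype at {truth['hap_feature']}: "
              f"{100 * block[0]['freq']:.2f}% ({block[0]['haplotype'][:12]}...)")


if __name__ == "__main__":
    main()
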