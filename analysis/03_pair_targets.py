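#!/usr/bin/env python
"""Build cis/trans lncRNA-mRNA target pairs.

cis: nearest gene within 100 kb, one per lncRNA; trans: energy-table
entries beyond the window; both gated on Spearman |rho| > 0.9, p < 0.05.
Compares the emitted pairs against the planted truth and writes
results/run/pairs.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from spikelnc import formats_io, pairing

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    cands = formats_io.read_gtf(RUN / "candidates.gtf")
    mrnas = formats_io.read_gtf(RUN / "reference.gtf")
    expr = formats_io.read_expression(RUN / "expr.tsv")
    energy = formats_io.read_table(RUN / "energy.tsv")
    pairs = pairing.build_pairs(cands, mrnas, expr, energy)
    formats_io.write_table(pairing.pairs_to_frame(pairs), RUN / "pairs.tsv")
    n_cis = sum(p.mode == "cis" for p in pairs)
    print(f"{len(pairs)} pairs: {n_cis} cis, {len(pairs) - n_cis} trans")
    truth = json.loads((RUN / "truth.json").read_text())
    t = {(p["lncrna_id"], p["mrna_id"]) for p in truth["pairs"]}
    f = {(p.lncrna_id, p.mrna_id) for p in pairs}
    print(
        f"planted-pair recall {len(t & f) / len(t):.2%}, "
        f"false-discovery proportion {len(f - t) / max(1, len(f)):.2%}"
    )
    cis_d = [p.distance for p in pairs if p.mode == "cis"]
    if cis_d:
        print(f"cis distances: {min(cis_d):.0f}-{max(cis_d):.0f} bp "
              f"(mean {sum(cis_d) / len(cis_d):.0f})")


if __name__ == "__main__":
    main()
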