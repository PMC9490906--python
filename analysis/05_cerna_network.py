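#!/usr/bin/env python
"""Infer the lncRNA-miRNA-mRNA ceRNA triangle network.

Triangles require a shared miRNA binding site on both the lncRNA and the
mRNA plus a negative lncRNA-mRNA Spearman correlation (|rho| >= 0.5,
p < 0.05).  Writes results/run/{triangles,nodes,edges,hubs}.tsv.
"""

import json
from pathlib import Path

from spikelnc import cerna, formats_io

RUN = Path(__file__).resolve().parents[1] / "results" / "run"


def main():
    binding = formats_io.read_table(RUN / "binding.tsv")
    assembly = formats_io.read_gtf(RUN / "assembly.gtf")
    expr = formats_io.read_expression(RUN / "expr.tsv")
    lengths = {t.transcript_id: t.length for t in assembly}
    sites = cerna.read_binding_sites(binding, lengths)
    import pandas as pd

    cand_ids = set(
        pd.read_csv(RUN / "candidates.tsv", sep="\t", comment="#").transcript_id
    )
    shared = cerna.shared_mirnas(
        [s for s in sites if s.transcript_id in cand_ids],
        [s for s in sites if s.transcript_id not in cand_ids],
    )
    triangles = cerna.build_triangles(shared, expr)
    tables = cerna.network_export(triangles)
    for name, df in tables.items():
        formats_io.write_table(df, RUN / f"{name}.tsv")
    print(f"{len(triangles)} unique triangles; "
          f"{len(tables['nodes'])} nodes, {len(tables['edges'])} edges")
    if not tables["hubs"].empty:
        hub = tables["hubs"].iloc[0]
        print(f"hub miRNA: {hub.mirna_id} ({hub.n_triangles} triangles)")
    truth = json.loads((RUN / "truth.json").read_text())
    t = {(x["lncrna_id"], x["mirna_id"], x["mrna_id"]) for x in truth["triangles"]}
    f = {(x.lncrna_id, x.mirna_id, x.mrna_id) for x in triangles}
    print(f"planted-triangle recall {len(t & f) / len(t):.0%}, extras {len(f - t)}")


if __name__ == "__main__":
    main()
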