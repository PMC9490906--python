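#!/usr/bin/env python
"""Call candidate lncRNAs from the assembled transcriptome.

Filters: expressed (FPKM > 0.1 in >= 20% of samples), length > 200 bp,
class code in {i, j, o, u} against the reference annotation, unanimous
non-coding verdict.  Prints the filter funnel and the lncRNA/mRNA feature
contrasts; writes results/run/candidates.{tsv,gtf} and results/feature_stats.tsv.
"""

import pandas as pd
from pathlib import Path

from spikelnc import discovery, formats_io

RUN = Path(__file__).resolve().parents[1] / "results" / "run"
RESULTS = RUN.parent


def main():
    assembly = formats_io.read_gtf(RUN / "assembly.gtf")
    reference = formats_io.read_gtf(RUN / "reference.gtf")
    expr = formats_io.read_expression(RUN / "expr.tsv")
    coding = formats_io.read_table(RUN / "coding_calls.tsv")
    cands, report = discovery.identify_lncrnas(assembly, reference, expr, coding)
    print("discovery funnel:", report)
    df = pd.DataFrame(
        [
            {
                "transcript_id": c.transcript.transcript_id,
                "class_code": c.class_code.code,
                "length": c.transcript.length,
                "n_exons": c.transcript.n_exons,
                "n_expressed_samples": c.n_expressed_samples,
                "mean_fpkm": c.mean_fpkm,
            }
            for c in cands
        ]
    )
    formats_io.write_table(df, RUN / "candidates.tsv")
    formats_io.write_gtf([c.transcript for c in cands], RUN / "candidates.gtf")
    seqs = formats_io.read_fasta(RUN / "transcripts.fasta")
    stats = discovery.feature_stats(cands, reference, expr, seqs)
    formats_io.write_table(stats["summary"], RESULTS / "feature_stats.tsv")
    s = stats["summary"].set_index("class")
    print(f"candidates: {len(cands)}")
    print("class codes:", df.class_code.value_counts().to_dict())
    print(
        f"median length lncRNA {s.loc['lncRNA', 'median_length']:.0f} bp vs "
        f"mRNA {s.loc['mRNA', 'median_length']:.0f} bp; "
        f"single-exon lncRNA fraction {s.loc['lncRNA', 'single_exon_fraction']:.2f}"
    )


if __name__ == "__main__":
    main()
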