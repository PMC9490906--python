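import json
from pathlib import Path

import numpy as np
import pytest

from spikelnc.models import GenomicInterval, TranscriptModel
from spikelnc.pipeline import RunConfig, run_all
from spikelnc.synthetic import SimulationConfig, simulate_annotation

#: compact config for integration tests that don't need the full panel
SMALL_SIM = dict(
    n_genes=60,
    n_lncrnas=40,
    n_planted_cis=6,
    n_planted_trans=6,
    n_planted_triangles=4,
    n_sites=800,
    n_array_snps=400,
    n_coding_flagged=2,
    n_homolog_queries=20,
)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full default-condition pipeline run shared by the suite."""
    wd = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(workdir=str(wd), seed=3, sim=SimulationConfig(seed=3))
    manifest = run_all(cfg)
    truth = json.loads((wd / "truth.json").read_text())
    return {"dir": Path(wd), "manifest": manifest, "truth": truth}


@pytest.fixture(scope="session")
def annotation_bundle():
    return simulate_annotation(SimulationConfig(seed=5))


def make_transcript(tid, chrom, exon_coords, strand="+", gene=None):
    exons = [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    iv = GenomicInterval(chrom, exons[0].start, exons[-1].end, strand)
    return TranscriptModel(tid, gene or tid, iv, exons)


def random_instance(rng, max_coord=1000, max_refs=5):
    """One random small classifier instance: (query, references)."""

    def random_tx(tid, chrom, strand):
        n_exons = int(rng.integers(1, 4))
        # 2*n_exons sorted distinct breakpoints -> exons with >= 0 bp gaps
        pts = np.sort(rng.choice(np.arange(1, max_coord), 2 * n_exons, replace=False))
        coords = [(int(pts[2 * i]), int(pts[2 * i + 1])) for i in range(n_exons)]
        return make_transcript(tid, chrom, coords, strand)

    strands = ["+", "-", "."]
    q_chrom = "chr1"
    query = random_tx("q", q_chrom, strands[int(rng.integers(0, 3))])
    refs = []
    for r in range(int(rng.integers(0, max_refs + 1))):
        chrom = "chr1" if rng.random() < 0.9 else "chr2"
        refs.append(random_tx(f"r{r}", chrom, strands[int(rng.integers(0, 2))]))
    # occasionally make the query share structure with a reference
    if refs and rng.random() < 0.5:
        donor = refs[int(rng.integers(0, len(refs)))]
        if rng.random() < 0.5 and donor.n_exons > 1 and donor.chrom == q_chrom:
            s, e = donor.introns[0]
            if s > 20 and e + 20 < max_coord and s < e:
                query = make_transcript(
                    "q", q_chrom, [(s - 20, s), (e, e + 20)], donor.strand
                )
        elif donor.chrom == q_chrom:
            query = make_transcript(
                "q",
                q_chrom,
                [(x.start, x.end) for x in donor.exons],
                donor.strand,
            )
    return query, refs
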