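"""Cross-species lncRNA conservation.

Consumed alignment hits (BLAST-outfmt-6-like, plus query length) are scored
as coverage x identity; the best hit per (query, species) is retained when
its score exceeds 0.6.  Queries with exactly one retained hit in every
species form the single-copy set, and a neighbor-joining tree over
conservation distances (1 - mean pairwise score) stands in for a full
maximum-likelihood species tree at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class HomologHit:
    query: str
    species: str
    subject: str
    align_length: int
    identity: float  # fraction in [0, 1]
    e_value: float
    coverage: float  # aligned fraction of the query

    def __post_init__(self):
        if not (0 <= self.identity <= 1 and 0 <= self.coverage <= 1):
            raise ValueError("identity/coverage must be in [0, 1]")
        if self.e_value < 0:
            raise ValueError("negative e-value")


@dataclass
class ConservationRecord:
    query: str
    species: str
    score: float
    retained: bool
    subject: str = ""


def conservation_score(hit: HomologHit, formula: str = "product") -> float:
    """Combine coverage and identity into one [0, 1] score.

    ``product`` (default): coverage * identity; ``mean``:
    (coverage + identity) / 2.
    """
    if formula == "product":
        return hit.coverage * hit.identity
    if formula == "mean":
        return (hit.coverage + hit.identity) / 2.0
    raise ValueError("formula must be product|mean")


def score_hits(
    hits: Iterable[HomologHit],
    threshold: float = 0.6,
    max_e_value: float = 1e-5,
    formula: str = "product",
    best_only: bool = True,
) -> list[ConservationRecord]:
    """Score hits and mark retention (score > threshold).

    With ``best_only`` (default) one hit per (query, species) is kept — the
    highest score, ties by lower e-value then subject id.  ``best_only=False``
    keeps every E-value-passing hit, which the single-copy rule needs to see
    duplicated loci.  Hits failing the E-value cutoff are ignored.
    """
    if not best_only:
        return [
            ConservationRecord(
                query=h.query,
                species=h.species,
                score=conservation_score(h, formula),
                retained=conservation_score(h, formula) > threshold,
                subject=h.subject,
            )
            for h in hits
            if h.e_value < max_e_value
        ]
    best: dict[tuple[str, str], tuple] = {}
    for h in hits:
        if h.e_value >= max_e_value:
            continue
        s = conservation_score(h, formula)
        key = (h.query, h.species)
        cand = (-s, h.e_value, h.subject, h)
        if key not in best or cand < best[key]:
            best[key] = cand
    return [
        ConservationRecord(
            query=q, species=sp, score=-neg_s, retained=(-neg_s) > threshold, subject=subj
        )
        for (q, sp), (neg_s, _e, subj, _h) in sorted(best.items())
    ]


def read_hits_table(table: pd.DataFrame) -> list[HomologHit]:
    """Build hits from a BLAST-outfmt-6-like TSV with columns query, species,
    subject, align_length, pident (percent), evalue, query_length.
    Query coverage = align_length / query_length."""
    out = []
    for r in table.itertuples(index=False):
        out.append(
            HomologHit(
                query=r.query,
                species=r.species,
                subject=r.subject,
                align_length=int(r.align_length),
                identity=float(r.pident) / 100.0,
                e_value=float(r.evalue),
                coverage=min(1.0, float(r.align_length) / float(r.query_length)),
            )
        )
    return out


def single_copy_set(
    records: list[ConservationRecord], species: list[str]
) -> set[str]:
    """Queries with exactly one retained hit in every listed species.

    ``score_hits`` already collapses to one best hit per (query, species);
    multi-copy queries are those whose retained records name the same
    species twice in an uncollapsed record list.
    """
    if not species:
        raise ValueError("empty species list")
    per_query: dict[str, dict[str, int]] = {}
    for r in records:
        if r.retained:
            per_query.setdefault(r.query, {}).setdefault(r.species, 0)
            per_query[r.query][r.species] += 1
    return {
        q
        for q, by_sp in per_query.items()
        if all(by_sp.get(sp, 0) == 1 for sp in species)
    }


def conservation_distance_matrix(
    records: list[ConservationRecord], species: list[str], reference: str = "wheat"
) -> pd.DataFrame:
    """Species distance matrix from retained conservation scores.

    Hits are all relative to the reference's queries, so only distances to
    the reference are directly observable: d(ref, sp) = 1 - mean score in
    sp.  Between two aligned species the mean absolute per-query score
    difference is used (queries shared by both), which orders species along
    the conservation gradient away from the reference.
    """
    by_sp: dict[str, dict[str, float]] = {}
    for r in records:
        if r.retained:
            by_sp.setdefault(r.species, {})[r.query] = r.score
    mean_score = {sp: (float(np.mean(list(v.values()))) if v else 0.0) for sp, v in by_sp.items()}
    taxa = [reference] + [s for s in species if s != reference]
    n = len(taxa)
    d = np.zeros((n, n))
    for i, a in enumerate(taxa):
        for j in range(i + 1, n):
            b = taxa[j]
            if a == reference:
                val = 1.0 - mean_score.get(b, 0.0)
            else:
                shared = set(by_sp.get(a, {})) & set(by_sp.get(b, {}))
                if shared:
                    val = float(np.mean([abs(by_sp[a][q] - by_sp[b][q]) for q in shared]))
                else:
                    val = abs(mean_score.get(a, 0.0) - mean_score.get(b, 0.0))
            d[i, j] = d[j, i] = val
    return pd.DataFrame(d, index=taxa, columns=taxa)


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree (Newick) from a symmetric zero-diagonal species
    distance matrix; negative branch lengths are clamped to 0."""
    import re

    from skbio import DistanceMatrix
    from skbio.tree import nj

    d = distances.values.astype(float)
    if distances.shape[0] < 3:
        raise ValueError("need >= 3 taxa")
    if np.abs(d - d.T).max() > 1e-9:
        raise ValueError("distance matrix not symmetric")
    if np.abs(np.diag(d)).max() > 1e-12:
        raise ValueError("distance matrix diagonal must be zero")
    tree = nj(DistanceMatrix(d, ids=list(distances.index)))
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    newick = str(tree).strip()
    if clamped:
        import logging

        logging.getLogger(__name__).warning(
            "nj_tree: clamped %d negative branch lengths to 0", clamped
        )
    # normalise scientific/float formatting artifacts
    newick = re.sub(r"\s+", "", newick)
    return newick
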