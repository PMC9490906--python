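"""ceRNA triangle inference.

A lncRNA that shares a miRNA binding site with an mRNA can act as a decoy
(sponge) for that miRNA; each (lncRNA, miRNA, mRNA) triple with shared
binding evidence and a qualifying lncRNA-mRNA expression correlation is one
ceRNA triangle.  The default correlation gate is negative rho with
|rho| >= 0.5, mirroring the worked lncRNA.2204.2 / tae-miR319 / TaBuB
example; sign and threshold are parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import networkx as nx
import pandas as pd

from spikelnc.pairing import spearman

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BindingSite:
    transcript_id: str
    mirna_id: str
    start: int  # transcript coordinates, 0-based half-open
    end: int
    expectation: float = 0.0

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("invalid binding span")


@dataclass
class CeRNATriangle:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    lnc_span: tuple[int, int]
    mrna_span: tuple[int, int]
    rho_lnc_mrna: float
    p_value: float


def read_binding_sites(
    table: pd.DataFrame,
    transcript_lengths: Optional[dict[str, int]] = None,
    max_expectation: float = 5.0,
) -> list[BindingSite]:
    """Validate and filter a consumed binding-site table
    (columns transcript_id, mirna_id, start, end, expectation).

    Spans exceeding the transcript length are rejected and logged; rows above
    the expectation cutoff are dropped.
    """
    sites = []
    rejected = 0
    for row in table.itertuples(index=False):
        exp = float(getattr(row, "expectation", 0.0))
        if exp > max_expectation:
            continue
        if row.end <= row.start or row.start < 0:
            rejected += 1
            continue
        if transcript_lengths is not None:
            length = transcript_lengths.get(row.transcript_id)
            if length is not None and row.end > length:
                rejected += 1
                continue
        sites.append(
            BindingSite(row.transcript_id, row.mirna_id, int(row.start), int(row.end), exp)
        )
    if rejected:
        log.warning("read_binding_sites: %d invalid spans rejected", rejected)
    return sites


def shared_mirnas(
    lnc_sites: list[BindingSite], mrna_sites: list[BindingSite]
) -> dict[tuple[str, str], dict[str, tuple]]:
    """miRNAs bound by both members of each (lncRNA, mRNA) candidate pair.

    Returns {(lnc, mrna): {mirna: (lnc_span, mrna_span)}}; the first span
    per (transcript, miRNA) in sorted order is reported.
    """
    def index(sites):
        by: dict[str, dict[str, tuple[int, int]]] = {}
        for s in sorted(sites, key=lambda s: (s.transcript_id, s.mirna_id, s.start)):
            by.setdefault(s.transcript_id, {}).setdefault(s.mirna_id, (s.start, s.end))
        return by

    lnc_by = index(lnc_sites)
    mrna_by = index(mrna_sites)
    out: dict[tuple[str, str], dict[str, tuple]] = {}
    for lnc, lmap in lnc_by.items():
        for mrna, mmap in mrna_by.items():
            common = set(lmap) & set(mmap)
            if common:
                out[(lnc, mrna)] = {m: (lmap[m], mmap[m]) for m in sorted(common)}
    return out


def build_triangles(
    shared: dict[tuple[str, str], dict[str, tuple]],
    expr: pd.DataFrame,
    rho_threshold: float = 0.5,
    alpha: float = 0.05,
    sign: str = "negative",
) -> list[CeRNATriangle]:
    """Keep triangles whose lncRNA-mRNA Spearman rho has the configured sign
    and |rho| >= threshold with p < alpha; duplicates collapse to one."""
    if sign not in ("negative", "positive", "either"):
        raise ValueError("sign must be negative|positive|either")
    skipped = 0
    seen = set()
    out: list[CeRNATriangle] = []
    for (lnc, mrna), mirnas in sorted(shared.items()):
        if lnc not in expr.index or mrna not in expr.index:
            skipped += len(mirnas)
            continue
        rho, p = spearman(expr.loc[lnc].values, expr.loc[mrna].values)
        if abs(rho) < rho_threshold or p >= alpha:
            continue
        if sign == "negative" and rho >= 0:
            continue
        if sign == "positive" and rho <= 0:
            continue
        for mirna, (lspan, mspan) in mirnas.items():
            key = (lnc, mirna, mrna)
            if key in seen:
                continue
            seen.add(key)
            out.append(CeRNATriangle(lnc, mirna, mrna, lspan, mspan, rho, p))
    if skipped:
        log.warning("build_triangles: %d triangles skipped (missing expression)", skipped)
    return out


def network_export(
    triangles: list[CeRNATriangle], pairs=None
) -> dict[str, pd.DataFrame]:
    """Typed node/edge tables plus degree and miRNA-hub reports."""
    g = nx.Graph()
    for t in triangles:
        g.add_node(t.lncrna_id, kind="lncRNA")
        g.add_node(t.mirna_id, kind="miRNA")
        g.add_node(t.mrna_id, kind="mRNA")
        g.add_edge(t.lncrna_id, t.mirna_id, kind="binds")
        g.add_edge(t.mrna_id, t.mirna_id, kind="binds")
        g.add_edge(t.lncrna_id, t.mrna_id, kind="pairs-with")
    if pairs:
        for p in pairs:
            g.add_node(p.lncrna_id, kind="lncRNA")
            g.add_node(p.mrna_id, kind="mRNA")
            g.add_edge(p.lncrna_id, p.mrna_id, kind="pairs-with")
    nodes = pd.DataFrame(
        [{"id": n, "kind": d["kind"], "degree": g.degree(n)} for n, d in sorted(g.nodes(data=True))],
        columns=["id", "kind", "degree"],
    )
    edges = pd.DataFrame(
        [
            {"source": a, "target": b, "kind": d["kind"]}
            for a, b, d in sorted(g.edges(data=True))
        ],
        columns=["source", "target", "kind"],
    )
    hub_counts: dict[str, int] = {}
    for t in triangles:
        hub_counts[t.mirna_id] = hub_counts.get(t.mirna_id, 0) + 1
    hubs = pd.DataFrame(
        sorted(hub_counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["mirna_id", "n_triangles"],
    )
    triangle_df = pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "lnc_span": f"{t.lnc_span[0]}-{t.lnc_span[1]}",
                "mrna_span": f"{t.mrna_span[0]}-{t.mrna_span[1]}",
                "rho": t.rho_lnc_mrna,
                "p": t.p_value,
            }
            for t in triangles
        ],
        columns=["lncrna_id", "mirna_id", "mrna_id", "lnc_span", "mrna_span", "rho", "p"],
    )
    return {"nodes": nodes, "edges": edges, "hubs": hubs, "triangles": triangle_df}
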