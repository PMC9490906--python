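"""cis/trans lncRNA-mRNA target pairing.

A protein-coding gene within 100 kb of a lncRNA is its cis target (one per
lncRNA, the nearest); genes beyond the window, or on another chromosome,
are trans candidates supported by a pairing free-energy table.  Either way
the pair must be strongly co-expressed: Spearman |rho| > 0.9, p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from scipy import stats

from spikelnc.models import TRANS_DISTANCE, GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)


@dataclass
class TargetPair:
    lncrna_id: str
    mrna_id: str
    mode: str  # cis | trans
    distance: float  # bp; 0 when overlapping; inf across chromosomes
    rho: float
    p_value: float
    energy: Optional[float] = None


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (Pearson on mid-ranks) with the t-approximation p-value
    on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 5:
        raise ValueError("need n >= 5 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def pair_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Nearest-edge gap in bp (0 when overlapping, inf across chromosomes)."""
    return a.gap_to(b)


def build_pairs(
    candidates: Iterable[TranscriptModel],
    mrnas: Iterable[TranscriptModel],
    expr: pd.DataFrame,
    energy_table: Optional[pd.DataFrame] = None,
    rho_min: float = 0.9,
    alpha: float = 0.05,
    cis_window: int = 100_000,
    ndg_max: float = -0.1,
    energy_on_cis: bool = False,
) -> list[TargetPair]:
    """Emit the cis/trans pair list.

    cis: each lncRNA may pair with its single nearest gene inside the
    window (ties by distance then gene id).  trans: every energy-table entry
    beyond the window with energy <= ndg_max.  All emitted pairs pass the
    correlation gate.  Features absent from the expression matrix are
    skipped with a warning; trans candidates without an energy entry are
    counted and skipped.
    """
    mrnas = list(mrnas)
    pairs: list[TargetPair] = []
    skipped_no_expr = 0
    skipped_no_energy = 0

    energy: dict[tuple[str, str], float] = {}
    if energy_table is not None and len(energy_table):
        energy = {
            (r.lncrna_id, r.mrna_id): float(r.energy)
            for r in energy_table.itertuples(index=False)
        }

    def correlated(lnc_id: str, mrna_id: str):
        nonlocal skipped_no_expr
        if lnc_id not in expr.index or mrna_id not in expr.index:
            skipped_no_expr += 1
            return None
        rho, p = spearman(expr.loc[lnc_id].values, expr.loc[mrna_id].values)
        if abs(rho) > rho_min and p < alpha:
            return rho, p
        return None

    mrna_by_id = {m.transcript_id: m for m in mrnas}
    for lnc in candidates:
        # nearest gene within the cis window, one-to-one
        best: Optional[tuple[float, str]] = None
        for m in mrnas:
            d = lnc.interval.gap_to(m.interval)
            if d <= cis_window and (best is None or (d, m.transcript_id) < best):
                best = (d, m.transcript_id)
        if best is not None:
            d, mid = best
            res = correlated(lnc.transcript_id, mid)
            if res is not None:
                e = energy.get((lnc.transcript_id, mid))
                if not energy_on_cis or (e is not None and e <= ndg_max):
                    pairs.append(
                        TargetPair(lnc.transcript_id, mid, "cis", d, *res, energy=e)
                    )
        # trans candidates come from the energy table
        for (lid, mid), e in energy.items():
            if lid != lnc.transcript_id or mid not in mrna_by_id:
                continue
            d = lnc.interval.gap_to(mrna_by_id[mid].interval)
            if d <= cis_window:
                continue
            if e > ndg_max:
                skipped_no_energy += 1
                continue
            res = correlated(lid, mid)
            if res is not None:
                pairs.append(TargetPair(lid, mid, "trans", d, *res, energy=e))
    if skipped_no_expr:
        log.warning("build_pairs: %d candidate pairs lacked expression rows", skipped_no_expr)
    if skipped_no_energy:
        log.info("build_pairs: %d trans candidates failed the energy cutoff", skipped_no_energy)
    return pairs


def pairs_to_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "mrna_id": p.mrna_id,
                "mode": p.mode,
                "distance": p.distance if np.isfinite(p.distance) else "cross_chrom",
                "rho": p.rho,
                "p": p.p_value,
                "energy": p.energy,
            }
            for p in pairs
        ],
        columns=["lncrna_id", "mrna_id", "mode", "distance", "rho", "p", "energy"],
    )
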