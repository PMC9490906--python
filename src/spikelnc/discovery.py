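"""Candidate lncRNA discovery.

An assembled transcript becomes a candidate lncRNA when it (1) is expressed
(FPKM > 0.1 in at least 20% of samples), (2) is longer than 200 bp spliced,
(3) carries class code i, j, o or u against the reference annotation, and
(4) is called non-coding unanimously by the consumed coding-potential
predictors.  Class codes follow the gffcompare-style single-letter scheme
with fixed precedence = > c > j > e > i > o > x > u.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from spikelnc.models import GenomicInterval, TranscriptModel

log = logging.getLogger(__name__)

KEPT_CODES = frozenset("ijou")
CODE_PRECEDENCE = "=cjeioxu"


@dataclass(frozen=True)
class ClassCode:
    code: str
    matched_reference_id: Optional[str] = None

    def __post_init__(self):
        if self.code not in CODE_PRECEDENCE:
            raise ValueError(f"unknown class code {self.code!r}")
        if (self.code == "u") != (self.matched_reference_id is None):
            raise ValueError("code u iff no matched reference")


@dataclass
class CandidateLncRNA:
    transcript: TranscriptModel
    class_code: ClassCode
    n_expressed_samples: int = 0
    mean_fpkm: float = 0.0
    coding_calls: dict = field(default_factory=dict)


def _strands_compatible(a: str, b: str) -> bool:
    # '.' (unknown) is compatible with either strand
    return a == b or a == "." or b == "."


def _antisense(a: str, b: str) -> bool:
    return {a, b} == {"+", "-"}


def _classify_vs_one(query: TranscriptModel, ref: TranscriptModel) -> Optional[str]:
    """Best code of `query` against a single reference transcript, or None."""
    if query.chrom != ref.chrom:
        return None
    exonic_overlap = any(qe.overlaps(re_) for qe in query.exons for re_ in ref.exons)
    q_introns = query.introns
    r_introns = ref.introns
    same_strand = _strands_compatible(query.strand, ref.strand)

    if same_strand:
        if exonic_overlap and q_introns == r_introns:
            return "="
        # contained: every query base within reference exons (abutting exons
        # merged so zero-length introns don't break containment), and the
        # query's intron chain a subset of the reference chain
        merged: list[list[int]] = []
        for re_ in ref.exons:
            if merged and re_.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], re_.end)
            else:
                merged.append([re_.start, re_.end])
        contained = all(
            any(s <= qe.start and qe.end <= e for (s, e) in merged)
            for qe in query.exons
        ) and all(i in r_introns for i in q_introns)
        if contained and exonic_overlap:
            return "c"
        if query.n_exons > 1 and any(i in r_introns for i in q_introns):
            return "j"
        intronic_overlap = any(
            max(qe.start, s) < min(qe.end, e)
            for qe in query.exons
            for (s, e) in r_introns
        )
        if query.n_exons == 1 and exonic_overlap and intronic_overlap:
            return "e"
        fully_intronic = any(
            s <= query.interval.start and query.interval.end <= e for (s, e) in r_introns
        )
        if fully_intronic:
            return "i"
        if exonic_overlap:
            return "o"
        return None
    if _antisense(query.strand, ref.strand) and exonic_overlap:
        return "x"
    return None


def assign_class_code(
    query: TranscriptModel, reference: Iterable[TranscriptModel]
) -> ClassCode:
    """Single deterministic class code for a query against the whole reference.

    The best (highest-precedence) code over all reference transcripts wins;
    ties at the same code level are broken by reference transcript id so the
    result is invariant to reference input order.  Queries matching nothing
    are intergenic/unknown (``u``).
    """
    best_rank = len(CODE_PRECEDENCE) - 1  # u
    best_ref: Optional[str] = None
    for ref in reference:
        code = _classify_vs_one(query, ref)
        if code is None:
            continue
        rank = CODE_PRECEDENCE.index(code)
        if rank < best_rank or (
            rank == best_rank
            and best_ref is not None
            and ref.transcript_id < best_ref
        ):
            best_rank, best_ref = rank, ref.transcript_id
    code = CODE_PRECEDENCE[best_rank]
    return ClassCode(code, best_ref if code != "u" else None)


def assign_class_code_bruteforce(
    query: TranscriptModel, reference: Iterable[TranscriptModel]
) -> ClassCode:
    """Reference classifier that evaluates every predicate on explicit
    per-base coordinate sets.  Intended for small coordinates only; serves as
    the independent check of :func:`assign_class_code`.
    """

    def base_set(intervals) -> set[int]:
        out: set[int] = set()
        for iv in intervals:
            out.update(range(iv.start, iv.end))
        return out

    q_bases = base_set(query.exons)
    q_all = set(range(query.interval.start, query.interval.end))
    q_introns = set(query.introns)

    best_rank = len(CODE_PRECEDENCE) - 1
    best_ref = None
    for ref in reference:
        if ref.chrom != query.chrom:
            continue
        r_exon_bases = base_set(ref.exons)
        r_intron_ivs = ref.introns
        r_intron_bases = base_set(
            GenomicInterval(ref.chrom, s, e, ref.strand) for (s, e) in r_intron_ivs if s < e
        )
        exonic = bool(q_bases & r_exon_bases)
        code = None
        if _strands_compatible(query.strand, ref.strand):
            if exonic and list(query.introns) == list(r_intron_ivs):
                code = "="
            elif (
                exonic
                and q_bases <= r_exon_bases
                and q_introns <= set(r_intron_ivs)
            ):
                code = "c"
            elif query.n_exons > 1 and q_introns & set(r_intron_ivs):
                code = "j"
            elif query.n_exons == 1 and exonic and (q_bases & r_intron_bases):
                code = "e"
            elif any(
                s <= query.interval.start and query.interval.end <= e
                for (s, e) in r_intron_ivs
            ):
                code = "i"
            elif exonic:
                code = "o"
        elif _antisense(query.strand, ref.strand) and exonic:
            code = "x"
        if code is None:
            continue
        rank = CODE_PRECEDENCE.index(code)
        if rank < best_rank or (
            rank == best_rank and best_ref is not None and ref.transcript_id < best_ref
        ):
            best_rank, best_ref = rank, ref.transcript_id
    code = CODE_PRECEDENCE[best_rank]
    return ClassCode(code, best_ref if code != "u" else None)


def expression_filter(
    matrix: pd.DataFrame, min_fpkm: float = 0.1, min_fraction: float = 0.2
) -> set[str]:
    """Ids of features with FPKM strictly above ``min_fpkm`` in at least
    ``ceil(min_fraction * n_samples)`` samples."""
    if not (0 < min_fraction <= 1):
        raise ValueError("min_fraction must be in (0, 1]")
    if matrix.empty:
        log.warning("expression_filter: empty matrix")
        return set()
    need = math.ceil(min_fraction * matrix.shape[1])
    n_over = (matrix.values > min_fpkm).sum(axis=1)
    return set(matrix.index[n_over >= need])


def identify_lncrnas(
    assembly: Iterable[TranscriptModel],
    reference: list[TranscriptModel],
    expr: pd.DataFrame,
    coding_calls: pd.DataFrame,
    min_len: int = 200,
    min_fpkm: float = 0.1,
    min_fraction: float = 0.2,
) -> tuple[list[CandidateLncRNA], dict]:
    """Run the four discovery filters and return candidates plus a funnel report.

    ``coding_calls`` columns: transcript_id, predictor, verdict
    (coding/noncoding).  A length-passing transcript absent from the table is
    excluded and counted under ``no_call`` rather than silently kept.
    """
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for r in reference:
        by_chrom.setdefault(r.chrom, []).append(r)
    expressed = expression_filter(expr, min_fpkm, min_fraction)
    calls: dict[str, dict[str, str]] = {}
    for row in coding_calls.itertuples(index=False):
        calls.setdefault(row.transcript_id, {})[row.predictor] = row.verdict

    report = {
        "input": 0,
        "not_expressed": 0,
        "too_short": 0,
        "class_code_excluded": 0,
        "no_call": 0,
        "coding": 0,
        "candidates": 0,
    }
    out: list[CandidateLncRNA] = []
    for t in assembly:
        report["input"] += 1
        if t.transcript_id not in expressed:
            report["not_expressed"] += 1
            continue
        if t.length <= min_len:
            report["too_short"] += 1
            continue
        code = assign_class_code(t, by_chrom.get(t.chrom, []))
        if code.code not in KEPT_CODES:
            report["class_code_excluded"] += 1
            continue
        tcalls = calls.get(t.transcript_id)
        if not tcalls:
            report["no_call"] += 1
            continue
        if any(v != "noncoding" for v in tcalls.values()):
            report["coding"] += 1
            continue
        row = expr.loc[t.transcript_id]
        out.append(
            CandidateLncRNA(
                transcript=t,
                class_code=code,
                n_expressed_samples=int((row > min_fpkm).sum()),
                mean_fpkm=float(row.mean()),
                coding_calls=dict(tcalls),
            )
        )
        report["candidates"] += 1
    log.info("identify_lncrnas funnel: %s", report)
    return out, report


def feature_stats(
    candidates: list[CandidateLncRNA],
    mrnas: list[TranscriptModel],
    expr: pd.DataFrame,
    sequences: Optional[dict[str, str]] = None,
    density_bin: int = 1_000_000,
) -> dict[str, pd.DataFrame]:
    """Summary contrasts between candidate lncRNAs and protein-coding models:
    median spliced length, exon-count distribution, GC content when sequences
    are supplied, expressed-sample counts and per-Mb chromosome densities."""
    if not candidates or not mrnas:
        raise ValueError("feature_stats needs non-empty candidate and mRNA sets")

    def _gc(tid: str) -> float:
        seq = sequences[tid].upper()
        return (seq.count("G") + seq.count("C")) / len(seq) if seq else float("nan")

    if sequences is not None:
        missing = [
            t.transcript_id
            for t in [c.transcript for c in candidates] + mrnas
            if t.transcript_id not in sequences
        ]
        if missing:
            raise ValueError(f"ids missing from FASTA: {missing[:10]}")

    rows = []
    for cls, models in (
        ("lncRNA", [c.transcript for c in candidates]),
        ("mRNA", mrnas),
    ):
        lengths = [m.length for m in models]
        exon_counts = [m.n_exons for m in models]
        in_expr = [m.transcript_id for m in models if m.transcript_id in expr.index]
        n_expr = (
            (expr.loc[in_expr] > 0.1).sum(axis=1).mean() if in_expr else float("nan")
        )
        rows.append(
            {
                "class": cls,
                "n": len(models),
                "median_length": float(np.median(lengths)),
                "single_exon_fraction": float(np.mean([c == 1 for c in exon_counts])),
                "median_exons": float(np.median(exon_counts)),
                "mean_expressed_samples": float(n_expr),
                "mean_gc": (
                    float(np.mean([_gc(m.transcript_id) for m in models]))
                    if sequences
                    else float("nan")
                ),
            }
        )
    summary = pd.DataFrame(rows)

    dens_rows = []
    for cls, models in (
        ("lncRNA", [c.transcript for c in candidates]),
        ("mRNA", mrnas),
    ):
        per_chrom: dict[str, int] = {}
        extent: dict[str, int] = {}
        for m in models:
            per_chrom[m.chrom] = per_chrom.get(m.chrom, 0) + 1
            extent[m.chrom] = max(extent.get(m.chrom, 0), m.interval.end)
        for chrom, count in sorted(per_chrom.items()):
            mb = max(extent[chrom] / density_bin, 1e-9)
            dens_rows.append(
                {"class": cls, "chrom": chrom, "n": count, "per_mb": count / mb}
            )
    return {"summary": summary, "density": pd.DataFrame(dens_rows)}
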