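"""End-to-end orchestration with a run manifest.

``run_all`` executes simulate (optional) -> identify -> pair -> popgen ->
cerna -> assoc -> conserve, each stage reading only declared inputs and
prior-stage outputs.  Every stage records input checksums, row counts,
parameters and wall time in the manifest; with ``resume=True`` a stage
whose inputs are checksum-unchanged since the previous run is skipped.
All thresholds default to the study's printed values (0.1 FPKM, 20%,
200 bp, 100 kb, |r| > 0.9, p < 0.05, 50 kb windows, > 50% major haplotype,
0.6 conservation, 5 Mb window, 1/Ne).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from spikelnc import __version__, formats_io
from spikelnc import association, cerna, conservation, discovery, pairing, popgen
from spikelnc.synthetic import SimulationConfig, simulate_all

log = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_fpkm": 0.1,
    "min_fraction": 0.2,
    "min_len": 200,
    "cis_window": 100_000,
    "rho_min": 0.9,
    "alpha": 0.05,
    "ndg_max": -0.1,
    "pi_window": 50_000,
    "cerna_rho": 0.5,
    "cerna_sign": "negative",
    "conservation_threshold": 0.6,
    "gwas_window": 5_000_000,
    "maf_min": 0.05,
    "n_pcs": 3,
    "ne": None,
}


@dataclass
class RunConfig:
    workdir: str
    seed: int = 0
    simulate: bool = True
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))
    sim: SimulationConfig | None = None

    @classmethod
    def from_toml(cls, path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        params = dict(DEFAULT_PARAMS)
        params.update(raw.get("params", {}))
        sim = SimulationConfig(**raw.get("sim", {})) if raw.get("simulate", True) else None
        return cls(
            workdir=raw["workdir"],
            seed=raw.get("seed", 0),
            simulate=raw.get("simulate", True),
            params=params,
            sim=sim,
        )


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_digest(params: dict) -> str:
    return hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write(df: pd.DataFrame, path: Path, params: dict) -> None:
    formats_io.write_table(
        df, path, comment=f"spikelnc {__version__} params={_params_digest(params)}"
    )


def validate_config(cfg: RunConfig) -> list[str]:
    """Check that every declared input exists; returns the missing paths."""
    wd = Path(cfg.workdir)
    if cfg.simulate:
        return []
    needed = [
        "reference.gtf", "assembly.gtf", "expr.tsv", "coding_calls.tsv",
        "panel.vcf", "groups.tsv", "array.tsv", "array_pos.tsv", "pheno.tsv",
        "binding.tsv", "energy.tsv", "hits.tsv", "qtl.bed", "introgression.bed",
    ]
    return [f for f in needed if not (wd / f).exists()]


def run_all(cfg: RunConfig, resume: bool = False) -> dict:
    """Execute the pipeline; returns (and writes) the run manifest."""
    wd = Path(cfg.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    missing = validate_config(cfg)
    if missing:
        raise FileNotFoundError(f"missing pipeline inputs: {missing}")
    manifest_path = wd / "manifest.json"
    prev = {}
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text()).get("stages", {})
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    params = cfg.params

    def stage(name, inputs, outputs, fn):
        t0 = time.time()
        in_sums = {str(p): _checksum(wd / p) for p in inputs if (wd / p).exists()}
        entry = prev.get(name)
        if (
            resume
            and entry
            and entry.get("inputs") == in_sums
            and all((wd / o).exists() for o in outputs)
        ):
            manifest["stages"][name] = {**entry, "skipped": True}
            log.info("stage %s skipped (inputs unchanged)", name)
            return None
        try:
            counts = fn() or {}
        except Exception:
            manifest["stages"][name] = {
                "inputs": in_sums,
                "failed": True,
                "wall_s": round(time.time() - t0, 3),
            }
            manifest_path.write_text(json.dumps(manifest, indent=1))
            raise
        manifest["stages"][name] = {
            "inputs": in_sums,
            "outputs": outputs,
            "counts": counts,
            "params_digest": _params_digest(params),
            "wall_s": round(time.time() - t0, 3),
            "skipped": False,
        }
        return counts

    state: dict = {}

    def ensure_core_state():
        """Reload upstream artifacts from disk when a stage was resumed-over."""
        if "assembly" not in state:
            state["assembly"] = formats_io.read_gtf(wd / "assembly.gtf")
            state["reference"] = formats_io.read_gtf(wd / "reference.gtf")
            state["expr"] = formats_io.read_expression(wd / "expr.tsv")
        if "cands" not in state and (wd / "candidates.tsv").exists():
            cand_df = pd.read_csv(wd / "candidates.tsv", sep="\t", comment="#")
            by_id = {t.transcript_id: t for t in state["assembly"]}
            state["cands"] = [
                discovery.CandidateLncRNA(
                    transcript=by_id[r.transcript_id],
                    class_code=discovery.ClassCode(
                        r.class_code,
                        None if r.class_code == "u" else "resumed",
                    ),
                    n_expressed_samples=int(r.n_expressed_samples),
                    mean_fpkm=float(r.mean_fpkm),
                )
                for r in cand_df.itertuples(index=False)
            ]
        if "pairs" not in state and (wd / "pairs.tsv").exists():
            pair_df = pd.read_csv(wd / "pairs.tsv", sep="\t", comment="#")
            state["pairs"] = [
                pairing.TargetPair(
                    r.lncrna_id,
                    r.mrna_id,
                    r.mode,
                    float("inf") if r.distance == "cross_chrom" else float(r.distance),
                    float(r.rho),
                    float(r.p),
                )
                for r in pair_df.itertuples(index=False)
            ]

    if cfg.simulate:
        sim = cfg.sim or SimulationConfig(seed=cfg.seed)
        stage(
            "simulate",
            [],
            ["assembly.gtf", "expr.tsv", "panel.vcf", "truth.json"],
            lambda: {"files": 16} if simulate_all(sim, wd) else {},
        )

    def do_identify():
        assembly = formats_io.read_gtf(wd / "assembly.gtf")
        reference = formats_io.read_gtf(wd / "reference.gtf")
        expr = formats_io.read_expression(wd / "expr.tsv")
        coding = formats_io.read_table(wd / "coding_calls.tsv")
        cands, report = discovery.identify_lncrnas(
            assembly,
            reference,
            expr,
            coding,
            min_len=params["min_len"],
            min_fpkm=params["min_fpkm"],
            min_fraction=params["min_fraction"],
        )
        state.update(assembly=assembly, reference=reference, expr=expr, cands=cands)
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
            ],
            columns=["transcript_id", "class_code", "length", "n_exons", "n_expressed_samples", "mean_fpkm"],
        )
        _write(df, wd / "candidates.tsv", params)
        formats_io.write_gtf([c.transcript for c in cands], wd / "candidates.gtf")
        return report

    stage(
        "identify",
        ["assembly.gtf", "reference.gtf", "expr.tsv", "coding_calls.tsv"],
        ["candidates.tsv", "candidates.gtf"],
        do_identify,
    )

    def do_pair():
        ensure_core_state()
        energy = formats_io.read_table(wd / "energy.tsv")
        pairs = pairing.build_pairs(
            [c.transcript for c in state["cands"]],
            state["reference"],
            state["expr"],
            energy,
            rho_min=params["rho_min"],
            alpha=params["alpha"],
            cis_window=params["cis_window"],
            ndg_max=params["ndg_max"],
        )
        state["pairs"] = pairs
        _write(pairing.pairs_to_frame(pairs), wd / "pairs.tsv", params)
        return {
            "pairs": len(pairs),
            "cis": sum(p.mode == "cis" for p in pairs),
            "trans": sum(p.mode == "trans" for p in pairs),
        }

    stage("pair", ["candidates.tsv", "energy.tsv", "expr.tsv"], ["pairs.tsv"], do_pair)

    def do_popgen():
        ensure_core_state()
        panel = formats_io.read_vcf(wd / "panel.vcf", wd / "groups.tsv")
        state["panel"] = panel
        groups = sorted(set(panel.sample_groups.values()))
        features = [
            (c.transcript.interval, c.transcript.transcript_id) for c in state["cands"]
        ] + [(m.interval, m.transcript_id) for m in state["reference"]]
        pi_rows, pi_by_group = [], {}
        for g in groups:
            res = popgen.nucleotide_diversity(
                panel, g, windows=features, denominator="sites"
            )
            vals = [r.pi for r in res]
            pi_by_group[g] = float(np.mean(vals)) if vals else float("nan")
            for r in res:
                pi_rows.append(
                    {"scope": r.scope, "group": g, "pi": r.pi, "n_sites": r.n_sites}
                )
        _write(pd.DataFrame(pi_rows), wd / "pi.tsv", params)
        fst_rows = []
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                try:
                    r = popgen.pairwise_fst(panel, ga, gb)
                except ValueError:
                    continue
                fst_rows.append(
                    {"group_a": ga, "group_b": gb, "fst": r.fst, "n_sites": r.n_sites}
                )
        _write(pd.DataFrame(fst_rows), wd / "fst.tsv", params)
        _write(popgen.snp_density(panel, features), wd / "density.tsv", params)
        shifts = popgen.diversity_shift(pi_by_group)
        _write(shifts, wd / "shifts.tsv", params)
        hap_rows = []
        for iv, name in features:
            if len(panel.sites_in(iv)) == 0:
                continue
            table = popgen.haplotypes(panel, iv, name)
            for g, freqs in table.group_frequencies.items():
                for hap, f in sorted(freqs.items()):
                    hap_rows.append(
                        {
                            "feature": name,
                            "group": g,
                            "haplotype": hap,
                            "freq": f,
                            "major": table.major[g] == hap,
                        }
                    )
        _write(pd.DataFrame(hap_rows), wd / "haplotypes.tsv", params)
        state["pi_by_group"] = pi_by_group
        return {"groups": len(groups), "fst_pairs": len(fst_rows)}

    stage(
        "popgen",
        ["panel.vcf", "groups.tsv", "candidates.tsv"],
        ["pi.tsv", "fst.tsv", "density.tsv", "shifts.tsv", "haplotypes.tsv"],
        do_popgen,
    )

    def do_cerna():
        ensure_core_state()
        binding = formats_io.read_table(wd / "binding.tsv")
        lengths = {t.transcript_id: t.length for t in state["assembly"]}
        sites = cerna.read_binding_sites(binding, lengths)
        lnc_ids = {c.transcript.transcript_id for c in state["cands"]}
        lnc_sites = [s for s in sites if s.transcript_id in lnc_ids]
        mrna_sites = [s for s in sites if s.transcript_id not in lnc_ids]
        shared = cerna.shared_mirnas(lnc_sites, mrna_sites)
        triangles = cerna.build_triangles(
            shared,
            state["expr"],
            rho_threshold=params["cerna_rho"],
            alpha=params["alpha"],
            sign=params["cerna_sign"],
        )
        state["triangles"] = triangles
        tables = cerna.network_export(triangles, state.get("pairs"))
        for name, df in tables.items():
            _write(df, wd / f"{name}.tsv", params)
        return {"triangles": len(triangles)}

    stage(
        "cerna",
        ["binding.tsv", "expr.tsv", "candidates.tsv"],
        ["triangles.tsv", "nodes.tsv", "edges.tsv", "hubs.tsv"],
        do_cerna,
    )

    def do_assoc():
        ensure_core_state()
        geno = pd.read_csv(wd / "array.tsv", sep="\t", index_col=0)
        pos = pd.read_csv(wd / "array_pos.tsv", sep="\t", index_col=0)
        pheno = pd.read_csv(wd / "pheno.tsv", sep="\t", index_col=0)
        features = [
            (c.transcript.interval, c.transcript.transcript_id) for c in state["cands"]
        ] + [(m.interval, m.transcript_id) for m in state["reference"]]
        gwas_rows, cand_rows = [], []
        for trait in pheno.columns:
            hits = association.gwas_scan(
                geno,
                pheno[trait],
                trait=trait,
                positions=pos,
                n_pcs=params["n_pcs"],
                maf_min=params["maf_min"],
                ne=params["ne"],
            )
            for h in hits:
                if h.passes_threshold:
                    gwas_rows.append(
                        {
                            "trait": trait,
                            "snp_id": h.snp_id,
                            "chrom": h.site.chrom,
                            "pos": h.site.start,
                            "effect": h.effect,
                            "p": h.p_value,
                        }
                    )
            for a in association.assign_candidates(
                hits, features, window=params["gwas_window"]
            ):
                cand_rows.append(
                    {
                        "trait": trait,
                        "feature": a.feature_id,
                        "snp_id": a.hit.snp_id,
                        "distance": a.distance,
                    }
                )
        _write(pd.DataFrame(gwas_rows), wd / "gwas.tsv", params)
        _write(pd.DataFrame(cand_rows), wd / "gwas_candidates.tsv", params)
        qtl = formats_io.read_bed(wd / "qtl.bed")
        intro = formats_io.read_bed(wd / "introgression.bed")
        pair_lncs = {p.lncrna_id for p in state.get("pairs", [])}
        pair_feats = [
            (iv, name) for iv, name in features if name in pair_lncs
        ]
        coloc = association.colocalize(features, {"qtl": qtl, "introgression": intro})
        _write(coloc, wd / "coloc.tsv", params)
        # enrichment of lncRNA-mRNA pair members inside introgression regions
        in_intro = {
            r.feature
            for r in coloc.itertuples(index=False)
            if r.set == "introgression" and r.n_overlaps > 0
        }
        lnc_feats = {name for _, name in features if name.startswith("lnc")}
        a = len(pair_lncs & in_intro)
        b = len(pair_lncs - in_intro)
        c = len((lnc_feats - pair_lncs) & in_intro)
        d = len(lnc_feats - pair_lncs - in_intro)
        p = association.fisher_enrichment(a, b, c, d)
        _write(
            pd.DataFrame(
                [{"a": a, "b": b, "c": c, "d": d, "fisher_p": p}]
            ),
            wd / "enrichment.tsv",
            params,
        )
        state["fisher_p"] = p
        return {"gwas_hits": len(gwas_rows), "candidates": len(cand_rows), "fisher_p": p}

    stage(
        "assoc",
        ["array.tsv", "array_pos.tsv", "pheno.tsv", "qtl.bed", "introgression.bed"],
        ["gwas.tsv", "gwas_candidates.tsv", "coloc.tsv", "enrichment.tsv"],
        do_assoc,
    )

    def do_conserve():
        hits_df = formats_io.read_table(wd / "hits.tsv")
        hits = conservation.read_hits_table(hits_df)
        records = conservation.score_hits(
            hits, threshold=params["conservation_threshold"]
        )
        df = pd.DataFrame(
            [
                {
                    "query": r.query,
                    "species": r.species,
                    "score": r.score,
                    "retained": r.retained,
                }
                for r in records
            ]
        )
        _write(df, wd / "conservation.tsv", params)
        species = sorted({r.species for r in records})
        all_records = conservation.score_hits(
            hits, threshold=params["conservation_threshold"], best_only=False
        )
        sc = conservation.single_copy_set(all_records, species)
        (wd / "single_copy.txt").write_text("\n".join(sorted(sc)) + "\n")
        dm = conservation.conservation_distance_matrix(records, species)
        newick = conservation.nj_tree(dm)
        (wd / "species_tree.nwk").write_text(newick + "\n")
        return {"retained": int(df["retained"].sum()), "single_copy": len(sc)}

    stage(
        "conserve",
        ["hits.tsv"],
        ["conservation.tsv", "single_copy.txt", "species_tree.nwk"],
        do_conserve,
    )

    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
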