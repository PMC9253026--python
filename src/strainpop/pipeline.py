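"""End-to-end orchestration: filter → pileup → SNPs → π → LD → Fst → sweeps → iRep.

``run_all`` executes every stage from a :class:`RunConfig` and writes TSV
tables (positions 1-based in files) plus a run manifest; identical config
and inputs give identical tables.  ``write_report`` summarises the tables
of a finished run and can be regenerated from them alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, linkage, replication, variants
from .config import RunConfig
from .differentiation import gene_fst, genome_fst, site_fst_table, sweep_confirm, sweep_scan
from .filtering import Pileup, build_pileup, filter_read_pairs
from .reads import ReadSet, from_sam
from .synthetic import Gene, read_fasta, read_gff3

log = logging.getLogger("strainpop")


class StageError(RuntimeError):
    def __init__(self, stage: str, reason: str):
        super().__init__(f"stage '{stage}' failed: {reason}")
        self.stage = stage


def _config_hash(cfg: RunConfig) -> str:
    import dataclasses
    d = dataclasses.asdict(cfg)
    return hashlib.sha256(
        yaml.safe_dump(d, sort_keys=True).encode()).hexdigest()[:16]


def run_all(
    cfg: RunConfig,
    readsets: dict[str, ReadSet] | None = None,
) -> dict:
    """Run every stage; returns in-memory results and writes tables.

    ``readsets`` bypasses SAM loading (the simulator produces ReadSets
    directly); when omitted, alignments are loaded from ``cfg.alignments``.
    """
    t0 = time.time()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": _config_hash(cfg), "stages": {}}

    if readsets is None:
        cfg.validate_paths()
    reference = read_fasta(cfg.reference_fasta)
    genes = read_gff3(cfg.genes_gff)
    results: dict = {"reference": reference, "genes": genes}

    def stage(name):
        def deco(fn):
            t = time.time()
            try:
                r = fn()
            except Exception as e:  # noqa: BLE001
                raise StageError(name, str(e)) from e
            manifest["stages"].setdefault(name, {})["seconds"] = round(time.time() - t, 3)
            return r
        return deco

    # --- filter + pileup per sample ------------------------------------
    masks: dict[str, np.ndarray] = {}
    piles: dict[str, Pileup] = {}
    rs_by_sample: dict[str, ReadSet] = {}
    reports = {}

    @stage("filter_pileup")
    def _filter():
        for sample, path in cfg.alignments.items():
            rs = (readsets[sample] if readsets is not None
                  else from_sam(path, reference))
            mask, rep = filter_read_pairs(rs, cfg.filter, reference)
            rs_by_sample[sample] = rs
            masks[sample] = mask
            piles[sample] = build_pileup(rs, mask, cfg.filter)
            reports[sample] = rep.as_dict()
        manifest["filter_reports"] = reports

    # --- pooled pileups + SNPs per population --------------------------
    pop_piles: dict[str, Pileup] = {}
    pop_snps: dict[str, pd.DataFrame] = {}
    pop_effects: dict[str, pd.DataFrame] = {}

    @stage("snps")
    def _snps():
        for pop, samples in cfg.populations.items():
            pooled = piles[samples[0]]
            for s in samples[1:]:
                pooled = pooled + piles[s]
            pop_piles[pop] = pooled
            snps = variants.call_snps(
                pooled, min_freq=cfg.snp_min_freq, error_rate=cfg.error_rate,
                alpha_site=cfg.alpha_site, min_cov=cfg.min_cov)
            eff = variants.classify_effects(snps, genes, reference)
            pop_snps[pop] = snps
            pop_effects[pop] = eff
            variants.snp_table_1based(eff).to_csv(
                out / f"snps_{pop}.tsv", sep="\t", index=False)
        manifest["stages"]["snps"] = {
            **manifest["stages"].get("snps", {}),
            "n_snps": {p: len(t) for p, t in pop_snps.items()},
        }

    # --- diversity ------------------------------------------------------
    pop_gene_pi: dict[str, pd.DataFrame] = {}

    @stage("diversity")
    def _pi():
        for pop, pooled in pop_piles.items():
            gp = diversity.gene_pi_table(pooled, genes, min_cov=cfg.min_cov)
            pop_gene_pi[pop] = gp
            gp.to_csv(out / f"gene_pi_{pop}.tsv", sep="\t", index=False)
            diversity.category_means(gp).to_csv(
                out / f"pi_by_category_{pop}.tsv", sep="\t", index=False)

    # --- linkage ---------------------------------------------------------
    pop_ld: dict[str, pd.DataFrame] = {}

    @stage("linkage")
    def _ld():
        for pop, samples in cfg.populations.items():
            tables = []
            for s in samples:
                haps = linkage.collect_spanning_haplotypes(
                    rs_by_sample[s], masks[s], pop_snps[pop],
                    min_span=1, min_base_quality=cfg.filter.min_base_quality,
                    max_distance=cfg.ld_max_distance)
                tables.append(haps)
            haps = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
            if len(haps):
                haps = (haps.groupby(["bin", "pos1", "pos2", "distance"],
                                     as_index=False)[linkage.HAP_COLS].sum())
                haps["n_span"] = haps[linkage.HAP_COLS].sum(axis=1)
                haps = haps[haps["n_span"] >= cfg.min_span]
            pairs = linkage.pair_ld(haps) if len(haps) else haps
            if len(pairs):
                pairs = linkage.assign_pair_class(pairs, pop_effects[pop])
            pop_ld[pop] = pairs
            pw = pairs.copy()
            if len(pw):
                pw[["pos1", "pos2"]] += 1
            pw.to_csv(out / f"ld_pairs_{pop}.tsv", sep="\t", index=False)

    # --- differentiation -------------------------------------------------
    pair_tables: dict[tuple[str, str], dict] = {}

    @stage("differentiation")
    def _fst():
        for pa, pb in cfg.comparisons:
            frames = []
            for bin_id in reference:
                snps_union = np.union1d(
                    pop_snps[pa].query("bin == @bin_id")["pos"].to_numpy(),
                    pop_snps[pb].query("bin == @bin_id")["pos"].to_numpy(),
                ).astype(np.int64)
                if len(snps_union) == 0:
                    continue
                frames.append(site_fst_table(
                    pop_piles[pa][bin_id], pop_piles[pb][bin_id],
                    snps_union, bin_id=bin_id, min_cov=cfg.min_cov))
            sites = (pd.concat(frames, ignore_index=True) if frames
                     else pd.DataFrame(columns=["bin", "pos", "p1", "p2",
                                                "n1", "n2", "num", "den"]))
            cov = {}
            for g in genes:
                c = (pop_piles[pa].coverage(g.bin_id)[g.start:g.end].mean()
                     + pop_piles[pb].coverage(g.bin_id)[g.start:g.end].mean()) / 2
                cov[g.gene_id] = c
            gfst = gene_fst(sites, genes, pd.Series(cov))
            regions = sweep_scan(gfst, window=cfg.sweep_window, k_sd=cfg.sweep_k_sd)
            pair_pi = pop_gene_pi[pa][["gene_id"]].copy()
            pair_pi["pi_gene"] = (
                pop_gene_pi[pa]["pi_gene"].to_numpy()
                + pop_gene_pi[pb]["pi_gene"].to_numpy()) / 2
            pair_ld_pairs = pd.concat(
                [pop_ld[pa], pop_ld[pb]], ignore_index=True) if (
                len(pop_ld[pa]) or len(pop_ld[pb])) else pop_ld[pa]
            effects = pd.concat([pop_effects[pa], pop_effects[pb]],
                                ignore_index=True)
            regions = sweep_confirm(
                regions, pair_pi, pair_ld_pairs, genes,
                effects=effects, alpha=cfg.sweep_alpha)
            name = f"{pa}_vs_{pb}"
            sites_w = sites.copy()
            sites_w["pos"] += 1
            sites_w.to_csv(out / f"fst_sites_{name}.tsv", sep="\t", index=False)
            gfst.to_csv(out / f"fst_genes_{name}.tsv", sep="\t", index=False)
            regions.to_csv(out / f"sweep_regions_{name}.tsv", sep="\t", index=False)
            pair_tables[(pa, pb)] = {
                "sites": sites, "genes": gfst, "regions": regions,
                "genome_fst": genome_fst(sites),
            }

    # --- replication index ----------------------------------------------
    @stage("irep")
    def _irep():
        tab = replication.irep_table(
            rs_by_sample, masks, window_size=cfg.irep_window,
            step=cfg.irep_step, trim_frac=cfg.irep_trim,
            min_mean_cov=cfg.irep_min_mean_cov)
        tab.to_csv(out / "irep.tsv", sep="\t", index=False)
        results["irep"] = tab

    manifest["seconds_total"] = round(time.time() - t0, 3)
    manifest["n_samples"] = len(cfg.alignments)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    results.update(
        masks=masks, pileups=piles, pop_pileups=pop_piles, snps=pop_snps,
        effects=pop_effects, gene_pi=pop_gene_pi, ld=pop_ld,
        pairs=pair_tables, manifest=manifest, filter_reports=reports,
    )
    return results


def write_report(output_dir: str | Path) -> Path:
    """Summary tables regenerated from a finished run directory alone."""
    out = Path(output_dir)
    lines = ["# strainpop run summary", ""]

    pi_files = sorted(out.glob("pi_by_category_*.tsv"))
    for f in pi_files:
        pop = f.stem.replace("pi_by_category_", "")
        df = pd.read_csv(f, sep="\t")
        lines.append(f"## Nucleotide diversity — {pop}")
        lines.append(df.to_string(index=False))
        lines.append("")

    fst_files = sorted(out.glob("fst_genes_*.tsv"))
    mat_rows = []
    for f in fst_files:
        pair = f.stem.replace("fst_genes_", "")
        sites_f = out / f"fst_sites_{pair}.tsv"
        if sites_f.exists():
            s = pd.read_csv(sites_f, sep="\t")
            fst = (s["num"].sum() / s["den"].sum()) if s["den"].sum() > 0 else np.nan
            a, b = pair.split("_vs_")
            mat_rows.append({"pop_a": a, "pop_b": b, "genome_fst": fst})
    if mat_rows:
        mat = pd.DataFrame(mat_rows)
        sym = pd.concat([mat, mat.rename(
            columns={"pop_a": "pop_b", "pop_b": "pop_a"})], ignore_index=True)
        fst_matrix = sym.pivot(index="pop_a", columns="pop_b", values="genome_fst")
        fst_matrix.to_csv(out / "fst_matrix.tsv", sep="\t")
        lines.append("## Pairwise genome-wide Fst")
        lines.append(fst_matrix.to_string())
        lines.append("")

    sweep_files = sorted(out.glob("sweep_regions_*.tsv"))
    for f in sweep_files:
        df = pd.read_csv(f, sep="\t")
        lines.append(f"## Sweep regions — {f.stem.replace('sweep_regions_', '')}")
        lines.append(df.to_string(index=False) if len(df) else "(none)")
        lines.append("")

    ld_files = sorted(out.glob("ld_pairs_*.tsv"))
    for f in ld_files:
        pop = f.stem.replace("ld_pairs_", "")
        df = pd.read_csv(f, sep="\t")
        if len(df) == 0:
            continue
        summ = linkage.ld_summaries(df)
        summ["decay"].to_csv(out / f"ld_decay_{pop}.tsv", sep="\t", index=False)
        lines.append(
            f"## LD — {pop}: mean r2={summ['mean_r2']:.4f} "
            f"mean D'={summ['mean_d_prime']:.4f} "
            f"frac D'<1={summ['frac_dprime_lt1']:.3f} n={summ['n_pairs']}")
        lines.append("")

    irep_f = out / "irep.tsv"
    if irep_f.exists():
        lines.append("## Replication index")
        lines.append(pd.read_csv(irep_f, sep="\t").to_string(index=False))
        lines.append("")

    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
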