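"""Synthetic-community validation experiments.

Standardised recovery experiments that exercise the whole pipeline under
known ground truth: the LD and π worked examples, Hudson-Fst parameter
recovery under the Balding–Nichols model, SNP-caller specificity on a
variant-free genome, planted-sweep recovery and null-scan specificity,
replication-index calibration, and the monotone differentiation gradient.
Each function is deterministic given its seed and returns a dict of plain
numbers, so the same experiments back both the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CommunityConfig, FilterConfig, RunConfig, SweepInterval
from .differentiation import genome_fst, hudson_components, site_fst_table
from .diversity import site_pi, subsample_pi
from .filtering import build_pileup, filter_read_pairs
from .linkage import pair_ld
from .replication import (
    coverage_track,
    estimate_irep,
    interpret_irep,
    window_coverage,
)
from .synthetic import simulate_community, write_fasta, write_gff3
from .variants import call_snps


def ld_worked_example() -> dict:
    """r²/D' from the haplotype counts AB=40, Ab=10, aB=10, ab=40."""
    haps = pd.DataFrame([{
        "bin": "b", "pos1": 0, "pos2": 100, "distance": 100,
        "n_AB": 40, "n_Ab": 10, "n_aB": 10, "n_ab": 40, "n_span": 100,
    }])
    row = pair_ld(haps).iloc[0]
    return {"D": float(row["D"]), "r2": float(row["r2"]),
            "d_prime": float(row["d_prime"])}


def pi_worked_example() -> dict:
    """Site π for a 10A/10G column, plus subsampling bias at depth 20."""
    pi, _ = site_pi(np.array([[10, 0, 10, 0]]), min_cov=20)
    return {"pi_site": float(pi[0])}


def subsample_bias(seed: int, reps: int = 200, n_columns: int = 40) -> dict:
    """Mean |subsampled - full| π over random depth-100 columns at depth 20."""
    rng = np.random.default_rng(seed)
    devs = []
    for _ in range(n_columns):
        p = rng.uniform(0.1, 0.5)
        a = rng.binomial(100, p)
        counts = [100 - a, a, 0, 0]
        full, _ = site_pi(np.array([counts]), min_cov=2)
        sub = subsample_pi(counts, 20, reps=reps, rng=rng)
        devs.append(abs(sub - full[0]))
    return {"mean_abs_dev": float(np.mean(devs)),
            "max_abs_dev": float(np.max(devs))}


def fst_recovery(seed: int, f: float = 0.1, n_sites: int = 5000,
                 depth: int = 50) -> dict:
    """Genome-wide ratio-of-averages Hudson Fst under Balding–Nichols.

    Per-population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws
    around ancestral p ~ U(0.1, 0.9); allele counts are binomial reads.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, n_sites)
    ratio = (1 - f) / f
    q1 = rng.beta(p * ratio, (1 - p) * ratio)
    q2 = rng.beta(p * ratio, (1 - p) * ratio)
    p1 = rng.binomial(depth, q1) / depth
    p2 = rng.binomial(depth, q2) / depth
    num, den = hudson_components(p1, depth, p2, depth)
    return {"fst": float(num.sum() / den.sum()), "true_f": f,
            "n_sites": n_sites}


def snp_null_specificity(seed: int, genome_length: int = 1_000_000,
                         depth: float = 100.0) -> dict:
    """SNP calls on an error-only simulation (no true variants)."""
    cfg = CommunityConfig(
        seed=seed, n_bins=1, genome_length=genome_length, depth=depth,
        n_populations=1, samples_per_population=1, within_diversity=0.0,
        gene_density=0.3, error_rate=0.001)
    reference, _, samples = simulate_community(cfg)
    rs = samples["p0_s0"]
    mask, _ = filter_read_pairs(rs, FilterConfig(), reference.sequences)
    pile = build_pileup(rs, mask)
    snps = call_snps(pile, error_rate=0.001, alpha_site=1e-6)
    return {"false_calls": int(len(snps)), "n_sites": genome_length}


def _sweep_community(seed: int, planted: bool, small: bool):
    """Two-population community; optionally a planted 5-gene sweep."""
    if small:
        kw = dict(genome_length=38_000, gene_length_range=(270, 330),
                  samples_per_population=1)
    else:
        kw = dict(genome_length=100_000, gene_length_range=(720, 900),
                  samples_per_population=2)
    sweeps = (SweepInterval(0, 45, 50, f_high=0.6, diversity_factor=0.1),) \
        if planted else ()
    return CommunityConfig(seed=seed, n_bins=1, gene_density=0.8, depth=50,
                           target_fst=0.05, sweep_intervals=sweeps, **kw)


def _run_pair(cfg: CommunityConfig, workdir) -> dict:
    from .pipeline import run_all
    from pathlib import Path
    workdir = Path(workdir)
    reference, truth, samples = simulate_community(cfg)
    write_fasta(reference, workdir / "ref.fasta")
    write_gff3(reference, workdir / "genes.gff3")
    spp = cfg.samples_per_population
    rc = RunConfig(
        reference_fasta=str(workdir / "ref.fasta"),
        genes_gff=str(workdir / "genes.gff3"),
        alignments={s: "" for s in samples},
        populations={"inner": [f"p0_s{r}" for r in range(spp)],
                     "outer": [f"p1_s{r}" for r in range(spp)]},
        comparisons=[("inner", "outer")],
        output_dir=str(workdir / "out"), seed=0)
    res = run_all(rc, readsets=samples)
    return {"regions": res["pairs"][("inner", "outer")]["regions"],
            "truth": truth}


def sweep_recovery(seed: int, workdir) -> dict:
    """Planted 5-gene sweep (genes 45-49) on a ~100-gene genome."""
    out = _run_pair(_sweep_community(seed, planted=True, small=False), workdir)
    regions = out["regions"]
    covers = bool(
        len(regions) == 1
        and regions["start_gene_index"].iloc[0] <= 45
        and regions["stop_gene_index"].iloc[0] >= 50)
    confirmed = int((regions["status"] == "confirmed_sweep").sum())
    return {"n_regions": int(len(regions)),
            "covers_planted": covers,
            "n_confirmed": confirmed}


def sweep_null_specificity(seed: int, workdir, n_genomes: int = 200) -> dict:
    """Fraction of sweep-free genomes with any confirmed sweep region."""
    from pathlib import Path
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, n_genomes)
    n_with_confirmed = 0
    n_regions = 0
    for i, s in enumerate(seeds):
        d = Path(workdir) / f"null_{i}"
        d.mkdir(parents=True, exist_ok=True)
        out = _run_pair(_sweep_community(int(s), planted=False, small=True), d)
        regions = out["regions"]
        n_regions += len(regions)
        if (regions["status"] == "confirmed_sweep").any():
            n_with_confirmed += 1
    return {"n_genomes": n_genomes,
            "n_regions_total": int(n_regions),
            "frac_confirmed": n_with_confirmed / n_genomes}


def irep_calibration(seed: int) -> dict:
    """Uniform-coverage exactness, ratio-2 recovery and scale invariance."""
    uniform = estimate_irep(window_coverage(np.full(100_000, 30.0), "u"))
    cfg = CommunityConfig(
        seed=seed, n_bins=1, genome_length=150_000, depth=100,
        coverage_ratio=2.0, n_populations=1, samples_per_population=1,
        within_diversity=0.0, gene_density=0.3)
    reference, _, samples = simulate_community(cfg)
    rs = samples["p0_s0"]
    mask, _ = filter_read_pairs(rs, FilterConfig(), reference.sequences)
    track = coverage_track(rs, mask)["bin_0"]
    grad = estimate_irep(window_coverage(track, "bin_0",
                                         window_size=10_000, step=200))
    scaled = estimate_irep(window_coverage(track * 11.0, "bin_0",
                                           window_size=10_000, step=200))
    return {
        "irep_uniform": float(uniform.irep),
        "irep_ratio2": float(grad.irep),
        "scale_invariance_dev": float(abs(scaled.irep - grad.irep)),
        "fraction_replicating_at_2": interpret_irep(2.0),
        "fraction_replicating_at_1_25": interpret_irep(1.25),
    }


def gradient_recovery(seed: int) -> dict:
    """Three populations with F = (0.02, 0.02, 0.28): pairwise Fst ordering.

    Pairwise Balding–Nichols Fst between populations a and b is
    (F_a + F_b)/2, so the configured contrast is 0.02 (near pair) versus
    0.15 (far pairs), a monotone differentiation gradient.
    """
    cfg = CommunityConfig(
        seed=seed, n_bins=1, genome_length=30_000, depth=50,
        n_populations=3, samples_per_population=1,
        target_fst=(0.02, 0.02, 0.28))
    reference, _, samples = simulate_community(cfg)
    piles, snps = {}, {}
    for s, rs in samples.items():
        mask, _ = filter_read_pairs(rs, FilterConfig(), reference.sequences)
        piles[s] = build_pileup(rs, mask)
        snps[s] = call_snps(piles[s])

    def pair_fst(a, b):
        union = np.union1d(snps[a]["pos"], snps[b]["pos"]).astype(np.int64)
        tab = site_fst_table(piles[a]["bin_0"], piles[b]["bin_0"], union,
                             bin_id="bin_0")
        return genome_fst(tab)

    near = pair_fst("p0_s0", "p1_s0")
    far = pair_fst("p0_s0", "p2_s0")
    return {"fst_near_pair": float(near), "fst_far_pair": float(far),
            "ordering_matches": bool(far > near)}
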