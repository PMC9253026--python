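"""Synthetic community generator: determinism, packing, frequency laws,
read bookkeeping and the planted-sweep signature."""

import numpy as np
import pandas as pd
import pytest

from strainpop.config import CommunityConfig, FilterConfig, SweepInterval
from strainpop.diversity import site_pi
from strainpop.filtering import build_pileup, filter_read_pairs
from strainpop.linkage import collect_spanning_haplotypes, pair_ld
from strainpop.reads import from_sam, write_sam
from strainpop.synthetic import (
    PackingError,
    draw_site_frequencies,
    generate_reference,
    read_truth,
    simulate_community,
    write_truth,
)
from strainpop.variants import call_snps


def test_reference_lengths_and_gene_bounds():
    cfg = CommunityConfig(seed=3, n_bins=2, genome_length=50_000)
    ref = generate_reference(cfg)
    assert set(ref.sequences) == {"bin_0", "bin_1"}
    for seq in ref.sequences.values():
        assert len(seq) == 50_000
    for g in ref.genes:
        assert 0 <= g.start < g.end <= 50_000
        assert (g.end - g.start) % 3 == 0
        assert g.strand in "+-"
    # non-overlapping within each bin
    for b in ref.sequences:
        gs = sorted(ref.genes_of(b), key=lambda g: g.start)
        for a, c in zip(gs, gs[1:]):
            assert a.end <= c.start


def test_reference_deterministic_given_seed():
    cfg = CommunityConfig(seed=11, n_bins=2, genome_length=10_000)
    r1 = generate_reference(cfg)
    r2 = generate_reference(cfg)
    for b in r1.sequences:
        assert np.array_equal(r1.sequences[b], r2.sequences[b])
    assert r1.genes == r2.genes


def test_infeasible_packing_raises():
    with pytest.raises(PackingError):
        generate_reference(CommunityConfig(
            seed=1, n_bins=1, genome_length=1000,
            gene_density=0.95, gene_length_range=(300, 300)))


def test_alignment_determinism_bit_for_bit(tmp_path):
    cfg = CommunityConfig(seed=5, n_bins=1, genome_length=6000, depth=15,
                          samples_per_population=1)
    simulate_community(cfg, tmp_path / "a")
    simulate_community(cfg, tmp_path / "b")
    for f in sorted((tmp_path / "a").iterdir()):
        assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name


def test_balding_nichols_f_zero_degenerate():
    cfg = CommunityConfig(seed=2, n_bins=1, genome_length=10_000, target_fst=0.0)
    ref = generate_reference(cfg)
    truth = draw_site_frequencies(ref, cfg)
    s = truth.sites
    assert np.allclose(s["freq_model_p0"], s["ancestral_p"])
    assert np.allclose(s["freq_model_p1"], s["ancestral_p"])


def test_balding_nichols_moments():
    # var of the population frequency is F p (1-p)
    rng = np.random.default_rng(7)
    p, F, n = 0.5, 0.1, 100_000
    ratio = (1 - F) / F
    q = rng.beta(p * ratio, (1 - p) * ratio, n)
    assert abs(q.mean() - p) < 0.005
    assert abs(q.var() - F * p * (1 - p)) < 0.002


def test_sweep_sites_flagged_with_high_f():
    cfg = CommunityConfig(
        seed=4, n_bins=1, genome_length=30_000, gene_density=0.8,
        gene_length_range=(270, 330),
        sweep_intervals=(SweepInterval(0, 10, 15, f_high=0.6),))
    ref = generate_reference(cfg)
    truth = draw_site_frequencies(ref, cfg)
    sw = truth.sites[truth.sites["sweep_index"] >= 0]
    assert len(sw) > 0
    assert (sw["f_p0"] == 0.6).all()
    assert len(truth.sweep_truth) == 1
    lo = truth.sweep_truth["start"].iloc[0]
    hi = truth.sweep_truth["stop"].iloc[0]
    assert ((sw["pos"] >= lo) & (sw["pos"] < hi)).all()


def test_read_pair_conservation_and_coverage(small_community, small_pileups):
    cfg, reference, truth, samples = small_community
    expected_pairs = round(cfg.depth * cfg.genome_length / (2 * cfg.read_length))
    for rs in samples.values():
        assert len(rs) == 2 * expected_pairs
    piles, _ = small_pileups
    cov = piles["p0_s0"].coverage("bin_0")
    assert abs(cov.mean() - cfg.depth) / cfg.depth < 0.10


def test_noiseless_single_haplotype_reads_are_monomorphic():
    cfg = CommunityConfig(seed=6, n_bins=1, genome_length=15_000, depth=40,
                          n_haplotypes=1, crossover_rate=0.0, error_rate=0.0,
                          samples_per_population=1)
    ref, truth, samples = simulate_community(cfg)
    pile = build_pileup(samples["p0_s0"])
    counts = pile["bin_0"]
    cov = counts.sum(axis=1)
    # every covered column carries exactly one allele: only fixed
    # differences from the reference, no within-sample variation
    assert (counts.max(axis=1) == cov).all()
    assert len(call_snps(pile)) == 0


def test_sweep_depresses_heterozygosity():
    cfg = CommunityConfig(
        seed=8, n_bins=1, genome_length=40_000, gene_density=0.8,
        gene_length_range=(600, 720), depth=60, samples_per_population=1,
        error_rate=0.0,
        sweep_intervals=(SweepInterval(0, 20, 25, diversity_factor=0.1),))
    ref, truth, samples = simulate_community(cfg)
    pile = build_pileup(samples["p0_s0"])
    pi, ok = site_pi(pile["bin_0"])
    lo = truth.sweep_truth["start"].iloc[0]
    hi = truth.sweep_truth["stop"].iloc[0]
    inside = np.nanmean(np.where(ok, pi, 0.0)[lo:hi])
    outside = np.concatenate([
        np.where(ok, pi, 0.0)[:lo], np.where(ok, pi, 0.0)[hi:]])
    ratio = inside / np.nanmean(outside)
    assert ratio < 0.45  # strong reduction from the dominant haplotype


def test_truth_tables_round_trip(tmp_path, small_community):
    _, _, truth, _ = small_community
    write_truth(truth, tmp_path)
    back = read_truth(tmp_path)
    pd.testing.assert_frame_equal(
        truth.sites.reset_index(drop=True), back.sites, check_dtype=False)
    assert len(back.gene_truth) == len(truth.gene_truth)
    # empty sweep list still writes a header-only file
    assert (tmp_path / "truth_sweeps.tsv").read_text().startswith("bin")


def test_sam_round_trip_preserves_pileup(tmp_path, small_community, small_pileups):
    _, reference, _, samples = small_community
    piles, _ = small_pileups
    write_sam(samples["p0_s0"], str(tmp_path / "s.sam"))
    rs2 = from_sam(str(tmp_path / "s.sam"))
    mask2, _ = filter_read_pairs(rs2, FilterConfig(), reference.sequences)
    pile2 = build_pileup(rs2, mask2)
    assert np.array_equal(piles["p0_s0"]["bin_0"], pile2["bin_0"])


def _mean_r2_at(cfg_seed, crossover, dist_range=(150, 450)):
    cfg = CommunityConfig(seed=cfg_seed, n_bins=1, genome_length=25_000,
                          depth=60, samples_per_population=1,
                          within_diversity=0.02, crossover_rate=crossover)
    ref, truth, samples = simulate_community(cfg)
    rs = samples["p0_s0"]
    mask, _ = filter_read_pairs(rs, FilterConfig(), ref.sequences)
    pile = build_pileup(rs, mask)
    snps = call_snps(pile)
    pairs = pair_ld(collect_spanning_haplotypes(rs, mask, snps))
    sel = pairs[(pairs["distance"] >= dist_range[0])
                & (pairs["distance"] < dist_range[1])]
    return sel["r2"].mean()


def test_ld_decreases_with_crossover_rate():
    r2 = [_mean_r2_at(99, c) for c in (0.0, 1.0, 3.0)]
    assert r2[0] > r2[1] > r2[2]
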