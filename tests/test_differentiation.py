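"""Hudson Fst, gene ratio-of-averages, sweep scan and confirmation."""

import numpy as np
import pandas as pd
import pytest

from strainpop.differentiation import (
    gene_fst,
    genome_fst,
    hudson_components,
    site_fst_table,
    sweep_confirm,
    sweep_scan,
)
from strainpop.synthetic import Gene


def test_fixed_difference_gives_ratio_one():
    num, den = hudson_components(1.0, 30, 0.0, 30)
    assert num == pytest.approx(1.0)
    assert den == pytest.approx(1.0)


def test_shared_polymorphism_formula():
    num, den = hudson_components(0.5, 20, 0.5, 20)
    assert num == pytest.approx(-0.25 / 19 * 2)
    assert den == pytest.approx(0.5)
    assert num / den == pytest.approx(-0.0526315789, abs=1e-6)


def test_gene_ratio_of_averages():
    n1, d1 = hudson_components(1.0, 30, 0.0, 30)
    n2, d2 = hudson_components(0.5, 20, 0.5, 20)
    assert (n1 + n2) / (d1 + d2) == pytest.approx(0.6491, abs=1e-4)


def test_symmetry_in_population_order():
    rng = np.random.default_rng(0)
    p1, p2 = rng.random(100), rng.random(100)
    n1 = rng.integers(20, 60, 100)
    n2 = rng.integers(20, 60, 100)
    a_num, a_den = hudson_components(p1, n1, p2, n2)
    b_num, b_den = hudson_components(p2, n2, p1, n1)
    assert np.allclose(a_num, b_num) and np.allclose(a_den, b_den)


def _counts(L, pairs):
    c = np.zeros((L, 4), dtype=np.int64)
    for pos, row in pairs:
        c[pos] = row
    return c


def test_site_fst_table_min_cov_and_monomorphic_exclusion():
    c1 = _counts(300, [(10, [30, 10, 0, 0]), (20, [40, 0, 0, 0]),
                       (30, [15, 4, 0, 0])])
    c2 = _counts(300, [(10, [10, 30, 0, 0]), (20, [40, 0, 0, 0]),
                       (30, [30, 10, 0, 0])])
    tab = site_fst_table(c1, c2, np.array([10, 20, 30]), bin_id="b")
    # pos 20 monomorphic identical (num=den=0) excluded; pos 30 below 20x in c1
    assert tab["pos"].tolist() == [10]


def test_gene_fst_missing_and_high_coverage_exclusion():
    sites = pd.DataFrame({
        "bin": "b", "pos": [10, 50],
        "p1": [1.0, 0.5], "p2": [0.0, 0.5], "n1": [30, 20], "n2": [30, 20],
    })
    nums, dens = hudson_components(sites["p1"], sites["n1"],
                                   sites["p2"], sites["n2"])
    sites["num"], sites["den"] = nums, dens
    genes = [Gene(f"g{i}", "b", i * 100, i * 100 + 99, "+", "genic")
             for i in range(10)]
    cov = pd.Series({f"g{i}": 50.0 for i in range(10)})
    cov["g7"] = 50 + 3 * pd.Series([50.0] * 9 + [200.0]).std()  # way high
    cov["g9"] = 500.0
    out = gene_fst(sites, genes, cov)
    g0 = out[out["gene_id"] == "g0"].iloc[0]
    assert g0["fst"] == pytest.approx(0.6491, abs=1e-4)
    assert g0["n_snps"] == 2
    g1 = out[out["gene_id"] == "g1"].iloc[0]
    assert np.isnan(g1["fst"]) and g1["reason"] == "no_segregating_sites"
    g9 = out[out["gene_id"] == "g9"].iloc[0]
    assert g9["excluded"] and g9["reason"] == "high_coverage"


def _fst_series(bg, planted=(), n=100, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(bg, 0.01, n)
    for lo, hi, v in planted:
        vals[lo:hi] = v
    return pd.DataFrame({
        "gene_id": [f"g{i}" for i in range(n)], "bin": "b",
        "gene_index": np.arange(n), "n_snps": 5, "fst": vals,
        "excluded": False, "reason": "",
    })


def test_scan_recovers_planted_window():
    df = _fst_series(0.05, [(40, 45, 0.6)])
    regions = sweep_scan(df)
    assert len(regions) == 1
    r = regions.iloc[0]
    assert r["start_gene_index"] <= 40 and r["stop_gene_index"] >= 45
    assert r["window_fst"] > r["threshold"]
    assert r["status"] == "high_fst"


def test_scan_constant_series_finds_nothing():
    df = _fst_series(0.05)
    df["fst"] = 0.05
    assert len(sweep_scan(df)) == 0


def test_scan_two_disjoint_windows_not_merged():
    df = _fst_series(0.05, [(20, 25, 0.6), (60, 65, 0.6)])
    regions = sweep_scan(df)
    assert len(regions) == 2
    assert regions.iloc[0]["stop_gene_index"] <= 30
    assert regions.iloc[1]["start_gene_index"] >= 55


def test_scan_skips_missing_genes():
    df = _fst_series(0.05, [(40, 45, 0.6)])
    df.loc[42, "fst"] = np.nan
    regions = sweep_scan(df)
    assert len(regions) == 1
    members = regions.iloc[0]["member_genes"].split(",")
    assert "g42" not in members
    assert {"g40", "g41", "g43", "g44"} <= set(members)


def test_scan_needs_enough_genes():
    df = _fst_series(0.05, n=4)
    assert len(sweep_scan(df)) == 0


def _region_frame():
    return pd.DataFrame([{
        "bin": "b", "start_gene_index": 40, "stop_gene_index": 45,
        "member_genes": ",".join(f"g{i}" for i in range(40, 45)),
        "n_genes": 5, "window_fst": 0.6, "threshold": 0.2,
        "status": "high_fst",
    }])


def _confirm_inputs(pi_low=True, ld_high=True, seed=0):
    rng = np.random.default_rng(seed)
    genes = [Gene(f"g{i}", "b", i * 100, i * 100 + 90, "+", "genic")
             for i in range(100)]
    pi = rng.normal(0.02, 0.002, 100)
    if pi_low:
        pi[40:45] = 0.004
    gene_pi = pd.DataFrame({"gene_id": [g.gene_id for g in genes],
                            "pi_gene": pi})
    rows = []
    for i in range(100):
        for k in range(3):
            pos1 = i * 100 + 5 + k
            pos2 = i * 100 + 50 + k
            r2 = rng.uniform(0.0, 0.2)
            if ld_high and 40 <= i < 45:
                r2 = rng.uniform(0.7, 1.0)
            rows.append({"bin": "b", "pos1": pos1, "pos2": pos2,
                         "distance": pos2 - pos1, "r2": r2, "d_prime": 1.0})
    return gene_pi, pd.DataFrame(rows), genes


@pytest.mark.parametrize("pi_low,ld_high,expect", [
    (True, True, "confirmed_sweep"),
    (True, False, "high_fst"),      # low pi but background LD: not confirmed
    (False, True, "high_fst"),
])
def test_confirmation_requires_both_signals(pi_low, ld_high, expect):
    gene_pi, ld_pairs, genes = _confirm_inputs(pi_low, ld_high)
    out = sweep_confirm(_region_frame(), gene_pi, ld_pairs, genes)
    assert out.iloc[0]["status"] == expect


def test_confirmation_insufficient_data_stays_high_fst():
    gene_pi, ld_pairs, genes = _confirm_inputs()
    no_ld = ld_pairs[ld_pairs["pos1"] > 990_000]     # empty
    out = sweep_confirm(_region_frame(), gene_pi, no_ld, genes)
    assert out.iloc[0]["status"] == "high_fst"
    assert out.iloc[0]["reason"] == "insufficient_data"


def test_genome_fst_ratio_of_averages():
    tab = pd.DataFrame({"num": [1.0, -0.02], "den": [1.0, 0.5]})
    assert genome_fst(tab) == pytest.approx(0.98 / 1.5)
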