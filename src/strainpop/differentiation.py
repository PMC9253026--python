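"""Hudson Fst between sample sites, sweep scanning and confirmation.

Per-site Hudson components (with sample-size correction, the form
recommended for ratio-of-averages estimation):

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

Gene-level Fst is the ratio of averages Σnum / Σden over the gene's
qualifying segregating sites (union of sites segregating in either
population, both populations at >= ``min_cov`` reads).  Genes whose mean
coverage exceeds the genome mean by more than ``exclude_sd`` standard
deviations are excluded (a guard against mismapping inflation).

The sweep scan slides a window of 5 consecutive non-missing genes and
seeds a region wherever the window mean Fst exceeds
mean + ``k_sd``·SD of the gene-Fst series; overlapping qualifying windows
merge, so a region ends where the running window mean drops below the
threshold.  A region is a confirmed sweep when member-gene π is
significantly below the genomic background AND member-pair r² is
significantly above it (one-sided Welch t tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import Gene


def hudson_components(p1, n1, p2, n2):
    """Vectorised Hudson numerator/denominator; requires n1, n2 >= 2."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def site_fst_table(
    counts1: np.ndarray,
    counts2: np.ndarray,
    positions: np.ndarray,
    *,
    bin_id: str = "",
    min_cov: int = 20,
) -> pd.DataFrame:
    """Hudson components at candidate positions from two pooled pileups.

    The two alleles of each site are the top two by combined count; p is
    the frequency of the combined-minor allele in each population.  Sites
    below ``min_cov`` in either population, or monomorphic and identical
    in both (num = den = 0), are excluded.
    """
    positions = np.asarray(positions, dtype=np.int64)
    c1 = counts1[positions].astype(np.int64)
    c2 = counts2[positions].astype(np.int64)
    comb = c1 + c2
    order = np.argsort(-comb, axis=1, kind="stable")
    a_major = order[:, 0]
    a_minor = order[:, 1]
    rowix = np.arange(len(positions))
    n1 = c1[rowix, a_major] + c1[rowix, a_minor]
    n2 = c2[rowix, a_major] + c2[rowix, a_minor]
    ok = (n1 >= max(min_cov, 2)) & (n2 >= max(min_cov, 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, c1[rowix, a_minor] / np.maximum(n1, 1), np.nan)
        p2 = np.where(ok, c2[rowix, a_minor] / np.maximum(n2, 1), np.nan)
    seg = ok & ((p1 > 0) | (p2 > 0)) & ((p1 < 1) | (p2 < 1))
    num, den = hudson_components(p1[seg], n1[seg], p2[seg], n2[seg])
    return pd.DataFrame({
        "bin": bin_id, "pos": positions[seg],
        "p1": p1[seg], "p2": p2[seg],
        "n1": n1[seg], "n2": n2[seg],
        "num": num, "den": den,
    })


def genome_fst(site_table: pd.DataFrame) -> float:
    """Genome-wide ratio-of-averages Fst."""
    den = site_table["den"].sum()
    return float(site_table["num"].sum() / den) if den > 0 else np.nan


def gene_fst(
    site_table: pd.DataFrame,
    genes: list[Gene],
    gene_coverage: pd.Series | None = None,
    *,
    exclude_sd: float = 2.0,
) -> pd.DataFrame:
    """Ratio-of-averages Fst per gene, with high-coverage exclusion.

    ``gene_coverage`` maps gene_id -> mean coverage over the gene body;
    genes above (mean + exclude_sd * SD) of that distribution are excluded
    with reason ``high_coverage``.  Genes with Σden = 0 or no qualifying
    sites report NaN.
    """
    rows = []
    by_bin = {b: t.sort_values("pos") for b, t in site_table.groupby("bin")}
    for order_idx, g in enumerate(genes):
        sub = by_bin.get(g.bin_id)
        if sub is not None:
            pos = sub["pos"].to_numpy()
            i0, i1 = np.searchsorted(pos, [g.start, g.end])
            num = sub["num"].to_numpy()[i0:i1].sum()
            den = sub["den"].to_numpy()[i0:i1].sum()
            n_snps = i1 - i0
        else:
            num = den = 0.0
            n_snps = 0
        rows.append({
            "gene_id": g.gene_id, "bin": g.bin_id, "gene_index": order_idx,
            "n_snps": int(n_snps),
            "fst": float(num / den) if den > 0 else np.nan,
            "mean_coverage": (float(gene_coverage[g.gene_id])
                              if gene_coverage is not None else np.nan),
            "excluded": False, "reason": "" if den > 0 else "no_segregating_sites",
        })
    df = pd.DataFrame(rows)
    if gene_coverage is not None and len(df):
        mu = df["mean_coverage"].mean()
        sd = df["mean_coverage"].std(ddof=1)
        if np.isfinite(sd) and sd > 0:
            high = df["mean_coverage"] > mu + exclude_sd * sd
            df.loc[high, ["excluded", "reason"]] = True, "high_coverage"
            df.loc[high, "fst"] = np.nan
    return df


def sweep_scan(
    gene_fst_table: pd.DataFrame,
    *,
    window: int = 5,
    k_sd: float = 1.5,
) -> pd.DataFrame:
    """High-Fst regions from a sliding window over genes in genome order.

    Missing-Fst genes are skipped (a window is ``window`` consecutive
    non-missing genes within one bin).  The threshold is
    mean + k_sd * SD of the non-missing gene-Fst series, per bin.
    """
    regions = []
    for bin_id, sub in gene_fst_table.groupby("bin"):
        sub = sub.sort_values("gene_index")
        ok = sub.dropna(subset=["fst"])
        vals = ok["fst"].to_numpy()
        if len(vals) < window:
            continue
        thr = vals.mean() + k_sd * vals.std(ddof=1)
        wmeans = np.convolve(vals, np.ones(window) / window, mode="valid")
        hot = wmeans > thr
        if not hot.any():
            continue
        # merge overlapping qualifying windows (in compacted index space)
        h = np.nonzero(hot)[0]
        breaks = np.nonzero(np.diff(h) >= window)[0]
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [len(h) - 1]])
        for s, e in zip(seg_starts, seg_ends):
            lo, hi = h[s], h[e] + window  # compacted gene span [lo, hi)
            members = ok.iloc[lo:hi]
            regions.append({
                "bin": bin_id,
                "start_gene_index": int(members["gene_index"].iloc[0]),
                "stop_gene_index": int(members["gene_index"].iloc[-1]) + 1,
                "member_genes": ",".join(members["gene_id"]),
                "n_genes": len(members),
                "window_fst": float(members["fst"].mean()),
                "threshold": float(thr),
                "status": "high_fst",
            })
    cols = ["bin", "start_gene_index", "stop_gene_index", "member_genes",
            "n_genes", "window_fst", "threshold", "status"]
    return pd.DataFrame(regions, columns=cols)


def sweep_confirm(
    regions: pd.DataFrame,
    gene_pi: pd.DataFrame,
    ld_pairs: pd.DataFrame,
    genes: list[Gene],
    *,
    effects: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Confirm high-Fst regions by π reduction and LD elevation.

    ``gene_pi``: columns gene_id, pi_gene (the pair's per-gene diversity);
    ``ld_pairs``: per-pair r² with bin/pos1/pos2.  Regions with fewer than
    2 member genes with π, or fewer than 2 member LD pairs, stay
    ``high_fst`` with the reason recorded.
    """
    if len(regions) == 0:
        out = regions.copy()
        for c in ("p_pi", "p_ld", "pi_region", "pi_background",
                  "ld_region", "ld_background"):
            out[c] = pd.Series(dtype=float)
        out["n_count"] = pd.Series(dtype=int)
        out["s_count"] = pd.Series(dtype=int)
        out["reason"] = pd.Series(dtype=object)
        return out

    gene_by_id = {g.gene_id: g for g in genes}
    pi_map = gene_pi.set_index("gene_id")["pi_gene"]
    out_rows = []
    for _, reg in regions.iterrows():
        row = reg.to_dict()
        members = reg["member_genes"].split(",")
        member_set = set(members)
        pi_in = pi_map.reindex(members).dropna().to_numpy()
        pi_bg = pi_map[[g for g in pi_map.index
                        if g not in member_set]].dropna().to_numpy()

        spans = [(gene_by_id[m].start, gene_by_id[m].end) for m in members
                 if m in gene_by_id]

        def in_member(pos):
            return any(s <= pos < e for s, e in spans)

        lp = ld_pairs[ld_pairs["bin"] == reg["bin"]]
        if len(lp):
            is_member = lp.apply(
                lambda r: in_member(r["pos1"]) and in_member(r["pos2"]), axis=1)
            ld_in = lp.loc[is_member, "r2"].to_numpy()
            ld_bg = lp.loc[~is_member, "r2"].to_numpy()
        else:
            ld_in = ld_bg = np.empty(0)

        row.update(
            pi_region=float(pi_in.mean()) if len(pi_in) else np.nan,
            pi_background=float(pi_bg.mean()) if len(pi_bg) else np.nan,
            ld_region=float(ld_in.mean()) if len(ld_in) else np.nan,
            ld_background=float(ld_bg.mean()) if len(ld_bg) else np.nan,
            p_pi=np.nan, p_ld=np.nan, reason="",
        )
        if len(pi_in) < 2 or len(pi_bg) < 2 or len(ld_in) < 2 or len(ld_bg) < 2:
            row["reason"] = "insufficient_data"
        else:
            _, p_pi = stats.ttest_ind(pi_in, pi_bg, equal_var=False,
                                      alternative="less")
            _, p_ld = stats.ttest_ind(ld_in, ld_bg, equal_var=False,
                                      alternative="greater")
            row["p_pi"], row["p_ld"] = float(p_pi), float(p_ld)
            if p_pi < alpha and p_ld < alpha:
                row["status"] = "confirmed_sweep"

        if effects is not None and len(effects):
            mem_eff = effects[effects["gene_id"].isin(member_set)]
            row["n_count"] = int((mem_eff["effect"] == "nonsynonymous").sum())
            row["s_count"] = int((mem_eff["effect"] == "synonymous").sum())
        else:
            row["n_count"] = row["s_count"] = 0
        out_rows.append(row)
    return pd.DataFrame(out_rows)
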