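"""Per-site and per-gene nucleotide diversity (π).

π at a position is the probability that two distinct reads drawn without
replacement carry different alleles:

    π = Σ_{b != b'} n_b n_{b'} / (n (n - 1))

Only positions with coverage >= ``min_cov`` (default 20) qualify; per-gene
π is the arithmetic mean of per-site π over all qualifying positions in
the gene body (monomorphic qualifying positions contribute 0).  The
without-replacement form is unbiased under coverage subsampling, which
:func:`subsample_pi` verifies empirically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import Pileup
from .synthetic import Gene


def site_pi(counts: np.ndarray, min_cov: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Per-position π and the qualifying (coverage >= min_cov) mask.

    ``counts`` is an (L, 4) allele-count matrix; non-qualifying positions
    get NaN.
    """
    counts = np.atleast_2d(counts)
    n = counts.sum(axis=1)
    ok = n >= max(min_cov, 2)
    pi = np.full(len(n), np.nan)
    nn = n[ok].astype(np.float64)
    pi[ok] = (nn ** 2 - (counts[ok].astype(np.float64) ** 2).sum(axis=1)) / (nn * (nn - 1))
    return pi, ok


def gene_pi_table(
    pile: Pileup,
    genes: list[Gene],
    *,
    min_cov: int = 20,
    snp_sites_only: bool = False,
    snp_positions: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-gene mean π over qualifying positions.

    Genes with zero qualifying positions report NaN.  With
    ``snp_sites_only`` the mean runs over called SNP positions only
    (requires ``snp_positions``: bin -> sorted 0-based positions).
    """
    rows = []
    pis = {b: site_pi(c, min_cov) for b, c in pile.items()}
    for g in genes:
        if g.bin_id not in pis:
            rows.append({"gene_id": g.gene_id, "bin": g.bin_id, "category": g.category,
                         "n_sites": 0, "pi_gene": np.nan})
            continue
        pi, ok = pis[g.bin_id]
        sel = ok[g.start:g.end].copy()
        if snp_sites_only:
            keep = np.zeros(g.end - g.start, dtype=bool)
            sp = snp_positions.get(g.bin_id, np.empty(0, int)) if snp_positions else np.empty(0, int)
            inside = sp[(sp >= g.start) & (sp < g.end)] - g.start
            keep[inside] = True
            sel &= keep
        vals = pi[g.start:g.end][sel]
        rows.append({
            "gene_id": g.gene_id, "bin": g.bin_id, "category": g.category,
            "n_sites": int(sel.sum()),
            "pi_gene": float(vals.mean()) if len(vals) else np.nan,
        })
    return pd.DataFrame(rows)


def category_means(gene_table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean π over genes, per category plus overall."""
    ok = gene_table.dropna(subset=["pi_gene"])
    rows = [{"category": "all", "n_genes": len(ok), "mean_pi": ok["pi_gene"].mean()}]
    for cat, sub in ok.groupby("category"):
        rows.append({"category": cat, "n_genes": len(sub), "mean_pi": sub["pi_gene"].mean()})
    return pd.DataFrame(rows)


def subsample_pi(
    counts: np.ndarray,
    target_depth: int,
    reps: int = 200,
    rng: np.random.Generator | int | None = None,
) -> float | None:
    """Mean π over ``reps`` draws of ``target_depth`` bases without replacement.

    Returns None when coverage < target_depth (position skipped).  At
    target_depth == coverage this equals full-column π exactly.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if n < target_depth:
        return None
    if n == target_depth:
        pi, _ = site_pi(counts[None, :], min_cov=2)
        return float(pi[0])
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sub = rng.multivariate_hypergeometric(counts, target_depth, size=reps)
    m = float(target_depth)
    pis = (m ** 2 - (sub.astype(np.float64) ** 2).sum(axis=1)) / (m * (m - 1))
    return float(pis.mean())


def compare_groups(
    a: np.ndarray, b: np.ndarray, n_comparisons: int = 1
) -> dict:
    """Welch two-sample t test on per-gene π with Bonferroni adjustment.

    Degenerate input (all values equal across both groups) is reported as
    t = 0, p = 1 with a flag rather than an error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 genes per group")
    out = {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
           "n_a": len(a), "n_b": len(b), "degenerate": False}
    if np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]:
        out.update(t=0.0, p_raw=1.0, p_adj=1.0, degenerate=True)
        return out
    t, p = stats.ttest_ind(a, b, equal_var=False)
    out.update(t=float(t), p_raw=float(p), p_adj=float(min(1.0, p * n_comparisons)))
    return out
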