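"""SNP calling from pileups and synonymous/nonsynonymous classification.

A site is called as a biallelic SNP when the second-most-frequent allele
has frequency strictly above ``min_freq`` (default 5%, computed over the
top two alleles only) AND the binomial tail probability of seeing that
many minor bases from sequencing error alone,
P(X >= minor_count | n = coverage, error_rate), is below ``alpha_site``.
With ~1e6 tested sites and alpha_site = 1e-6 the expected number of false
discoveries is of order one or less.

Effect classification substitutes the minor allele into the reference
codon (reverse-complemented for minus-strand genes) and translates both
with the bacterial genetic code (NCBI table 11).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .filtering import Pileup
from .reads import BASES
from .synthetic import Gene, _COMP

EFFECTS = ("synonymous", "nonsynonymous", "intergenic", "unclassified")


def call_snps(
    pile: Pileup,
    *,
    min_freq: float = 0.05,
    error_rate: float = 1e-3,
    alpha_site: float = 1e-6,
    min_cov: int = 20,
) -> pd.DataFrame:
    """Biallelic segregating sites from a (possibly pooled) pileup.

    Columns: bin, pos (0-based), major, minor, major_count, minor_count,
    coverage (all four alleles), minor_freq (over the top two alleles),
    p_null.  Multi-allelic sites are reduced to the top two alleles;
    third-allele counts are excluded from the frequency denominator.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must lie in (0, 1)")
    frames = []
    for bin_id, counts in pile.items():
        order = np.argsort(-counts, axis=1, kind="stable")
        c1 = np.take_along_axis(counts, order[:, :1], axis=1)[:, 0]
        c2 = np.take_along_axis(counts, order[:, 1:2], axis=1)[:, 0]
        cov2 = c1 + c2
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cov2 > 0, c2 / np.maximum(cov2, 1), 0.0)
        cand = (cov2 >= min_cov) & (freq > min_freq)
        if not cand.any():
            continue
        pos = np.nonzero(cand)[0]
        p_null = stats.binom.sf(c2[pos] - 1, cov2[pos], error_rate)
        called = p_null < alpha_site
        pos = pos[called]
        if not len(pos):
            continue
        frames.append(pd.DataFrame({
            "bin": bin_id,
            "pos": pos,
            "major": [BASES[b] for b in order[pos, 0]],
            "minor": [BASES[b] for b in order[pos, 1]],
            "major_count": c1[pos],
            "minor_count": c2[pos],
            "coverage": counts[pos].sum(axis=1),
            "minor_freq": freq[pos],
            "p_null": p_null[called],
        }))
    cols = ["bin", "pos", "major", "minor", "major_count", "minor_count",
            "coverage", "minor_freq", "p_null"]
    return (pd.concat(frames, ignore_index=True) if frames
            else pd.DataFrame(columns=cols))


def _codon_effect(ref_codes: np.ndarray, gene: Gene, pos: int,
                  minor_code: int) -> str:
    if (gene.end - gene.start) % 3 != 0:
        return "unclassified"
    if gene.strand == "+":
        ci = (pos - gene.start) // 3
        cstart = gene.start + 3 * ci
    else:
        off = gene.end - 1 - pos
        ci = off // 3
        cstart = gene.end - 3 * (ci + 1)
    ref_codon = ref_codes[cstart:cstart + 3].copy()
    alt_codon = ref_codon.copy()
    alt_codon[pos - cstart] = minor_code
    if gene.strand == "-":
        ref_codon = _COMP[ref_codon][::-1]
        alt_codon = _COMP[alt_codon][::-1]
    aa_ref = str(Seq("".join(BASES[c] for c in ref_codon)).translate(table=11))
    aa_alt = str(Seq("".join(BASES[c] for c in alt_codon)).translate(table=11))
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_effects(
    snps: pd.DataFrame,
    genes: list[Gene],
    reference_codes: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Attach gene context and coding effect to called SNPs.

    Returns one row per (SNP, containing gene) occurrence, so a SNP inside
    two overlapping genes appears twice (``n_genes`` > 1 tags these);
    SNPs outside every gene get effect ``intergenic``.  Codons containing
    a second SNP are classified against the reference codon.
    """
    if len(snps) == 0:
        out = snps.copy()
        out["gene_id"] = pd.Series(dtype=object)
        out["category"] = pd.Series(dtype=object)
        out["effect"] = pd.Series(dtype=object)
        out["n_genes"] = pd.Series(dtype=int)
        return out

    rows = []
    for bin_id, sub in snps.groupby("bin", sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        hit_count = np.zeros(len(sub), dtype=int)
        gene_rows: list[list] = [[] for _ in range(len(sub))]
        for g in (g for g in genes if g.bin_id == bin_id):
            i0, i1 = np.searchsorted(pos, [g.start, g.end])
            for k in range(i0, i1):
                minor_code = BASES.index(sub.iloc[k]["minor"])
                eff = _codon_effect(reference_codes[bin_id], g, int(pos[k]), minor_code)
                gene_rows[k].append((g.gene_id, g.category, eff))
                hit_count[k] += 1
        for k in range(len(sub)):
            base = sub.iloc[k].to_dict()
            if hit_count[k] == 0:
                rows.append({**base, "gene_id": None, "category": None,
                             "effect": "intergenic", "n_genes": 0})
            else:
                for gid, cat, eff in gene_rows[k]:
                    rows.append({**base, "gene_id": gid, "category": cat,
                                 "effect": eff, "n_genes": hit_count[k]})
    return pd.DataFrame(rows)


def snp_table_1based(snps: pd.DataFrame) -> pd.DataFrame:
    out = snps.copy()
    out["pos"] = out["pos"] + 1
    return out
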