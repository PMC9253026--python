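"""Two-locus linkage disequilibrium from read-spanning fragments.

Haplotypes are observed directly on sequenced fragments (a read or a
read pair): for every pair of called SNPs on one scaffold, fragments
reporting a quality-passing base at both sites are tallied into the four
haplotype classes (A/a = major/minor at the left site, B/b at the right).
Pairs with fewer than ``min_span`` spanning fragments (default 30) are
excluded.  From the spanning-fragment counts:

    D  = pAB - pA pB
    r² = D² / (pA (1-pA) pB (1-pB))
    D' = |D| / D_max,  D_max = min(pA (1-pB), (1-pA) pB)      if D > 0
                       D_max = min(pA pB, (1-pA) (1-pB))      if D < 0

D' is reported unsigned; D' < 1 (all four haplotypes present) is evidence
of recombination.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import FilterConfig
from .reads import BASES, ReadSet

HAP_COLS = ["n_AB", "n_Ab", "n_aB", "n_ab"]


def collect_spanning_haplotypes(
    rs: ReadSet,
    mask: np.ndarray,
    snps: pd.DataFrame,
    *,
    min_span: int = 30,
    min_base_quality: int = 20,
    max_distance: int | None = None,
) -> pd.DataFrame:
    """Haplotype counts for every sufficiently-spanned pair of SNPs.

    A fragment observes a site when either mate reports a base of quality
    >= ``min_base_quality`` there; mates disagreeing at a site drop that
    site for the fragment.  Fragments carrying a non-major/minor allele at
    either site of a pair are discarded for that pair.
    """
    out_frames = []
    idx_all = np.nonzero(mask)[0]
    for rid, bin_id in enumerate(rs.ref_names):
        sub = snps[snps["bin"] == bin_id].sort_values("pos")
        if len(sub) < 2:
            continue
        P = sub["pos"].to_numpy(np.int64)
        major = np.array([BASES.index(b) for b in sub["major"]], dtype=np.uint8)
        minor = np.array([BASES.index(b) for b in sub["minor"]], dtype=np.uint8)

        idx = idx_all[rs.ref_id[idx_all] == rid]
        frag_l, site_l, code_l = [], [], []
        for i in idx:
            s0 = np.searchsorted(P, rs.pos[i])
            s1 = np.searchsorted(P, rs.pos[i] + rs.length[i])
            if s1 <= s0:
                continue
            off = P[s0:s1] - rs.pos[i]
            q_ok = rs.qual[i, off] >= min_base_quality
            if not q_ok.any():
                continue
            frag_l.append(np.full(int(q_ok.sum()), rs.frag[i]))
            site_l.append(np.arange(s0, s1)[q_ok])
            code_l.append(rs.seq[i, off[q_ok]])
        if not frag_l:
            continue
        frag = np.concatenate(frag_l)
        site = np.concatenate(site_l)
        code = np.concatenate(code_l)
        order = np.lexsort((site, frag))
        frag, site, code = frag[order], site[order], code[order]

        # Collapse duplicate (fragment, site) observations from overlapping
        # mates; conflicting bases invalidate the site for that fragment.
        key = frag * (len(P) + 1) + site
        uniq, start_idx, counts_per = np.unique(key, return_index=True, return_counts=True)
        keep_code = code[start_idx].astype(np.int16)
        dup = counts_per == 2
        if dup.any():
            second = code[start_idx[dup] + 1]
            conflict = second != code[start_idx[dup]]
            kc = keep_code[dup]
            kc[conflict] = -1
            keep_code[dup] = kc
        frag_u = uniq // (len(P) + 1)
        site_u = (uniq % (len(P) + 1)).astype(np.int64)

        # allele class: 0 = major, 1 = minor, -1 = other/conflict
        aclass = np.full(len(keep_code), -1, dtype=np.int8)
        aclass[keep_code == major[site_u]] = 0
        aclass[keep_code == minor[site_u]] = 1

        # All within-fragment site pairs, vectorised by grouping fragments
        # on their number of observed sites.
        boundaries = np.nonzero(np.diff(frag_u))[0] + 1
        run_starts = np.concatenate([[0], boundaries])
        run_lens = np.diff(np.concatenate([run_starts, [len(frag_u)]]))
        S = len(P)
        key_parts = []
        for k in np.unique(run_lens):
            if k < 2:
                continue
            rs_k = run_starts[run_lens == k]
            gather = rs_k[:, None] + np.arange(k)[None, :]
            mat_s = site_u[gather]
            mat_a = aclass[gather]
            iu, ju = np.triu_indices(int(k), 1)
            s1 = mat_s[:, iu].ravel()
            s2 = mat_s[:, ju].ravel()
            a1 = mat_a[:, iu].ravel().astype(np.int64)
            a2 = mat_a[:, ju].ravel().astype(np.int64)
            good = (a1 >= 0) & (a2 >= 0)
            if max_distance is not None:
                good &= (P[s2] - P[s1]) <= max_distance
            key_parts.append((s1[good] * S + s2[good]) * 4 + 2 * a1[good] + a2[good])
        if not key_parts:
            continue
        keys = np.concatenate(key_parts)
        uk, kc = np.unique(keys, return_counts=True)
        pair_key = uk // 4
        hap_idx = uk % 4
        up, inv = np.unique(pair_key, return_inverse=True)
        table = np.zeros((len(up), 4), dtype=np.int64)
        table[inv, hap_idx] = kc
        span = table.sum(axis=1)
        keep = span >= min_span
        if not keep.any():
            continue
        up, table, span = up[keep], table[keep], span[keep]
        p1 = P[up // S]
        p2 = P[up % S]
        out_frames.append(pd.DataFrame({
            "bin": bin_id, "pos1": p1, "pos2": p2, "distance": p2 - p1,
            "n_AB": table[:, 0], "n_Ab": table[:, 1],
            "n_aB": table[:, 2], "n_ab": table[:, 3], "n_span": span,
        }))
    cols = ["bin", "pos1", "pos2", "distance", *HAP_COLS, "n_span"]
    if not out_frames:
        return pd.DataFrame(columns=cols)
    return (pd.concat(out_frames, ignore_index=True)
            .sort_values(["bin", "pos1", "pos2"], ignore_index=True))


def pair_ld(haps: pd.DataFrame) -> pd.DataFrame:
    """r², D' and D for each spanning-haplotype count table.

    Pairs monomorphic among spanning fragments are dropped.  Frequencies
    pA/pB refer to the major allele at each site as labelled in the input;
    r² and D' are invariant to that labelling.
    """
    haps = haps[haps[HAP_COLS].sum(axis=1) > 0] if len(haps) else haps
    if len(haps) == 0:
        return haps.assign(pA=[], pB=[], pAB=[], D=[], r2=[], d_prime=[])
    n = haps[HAP_COLS].sum(axis=1).to_numpy(np.float64)
    AB, Ab, aB, ab = (haps[c].to_numpy(np.float64) for c in HAP_COLS)
    pA = (AB + Ab) / n
    pB = (AB + aB) / n
    pAB = AB / n
    seg = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    out = haps[seg].copy()
    pA, pB, pAB = pA[seg], pB[seg], pAB[seg]
    D = pAB - pA * pB
    r2 = D ** 2 / (pA * (1 - pA) * pB * (1 - pB))
    dmax = np.where(
        D > 0,
        np.minimum(pA * (1 - pB), (1 - pA) * pB),
        np.minimum(pA * pB, (1 - pA) * (1 - pB)),
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        d_prime = np.where(D == 0, 0.0, np.abs(D) / dmax)
    out["pA"], out["pB"], out["pAB"] = pA, pB, pAB
    out["D"], out["r2"], out["d_prime"] = D, r2, d_prime
    return out.reset_index(drop=True)


def assign_pair_class(pairs: pd.DataFrame, effects: pd.DataFrame) -> pd.DataFrame:
    """NN / NS / SS / other labels from the two SNPs' coding effects."""
    eff_map = {}
    for _, r in effects.iterrows():
        eff_map[(r["bin"], int(r["pos"]))] = r["effect"]
    short = {"nonsynonymous": "N", "synonymous": "S"}

    def cls(row):
        e1 = short.get(eff_map.get((row["bin"], row["pos1"])))
        e2 = short.get(eff_map.get((row["bin"], row["pos2"])))
        if e1 is None or e2 is None:
            return "other"
        return "".join(sorted([e1, e2]))  # NN, NS, SS

    out = pairs.copy()
    out["pair_class"] = out.apply(cls, axis=1) if len(out) else pd.Series(dtype=object)
    return out


def ld_summaries(
    pairs: pd.DataFrame,
    distance_edges: np.ndarray | None = None,
) -> dict:
    """Decay profile, r2N/r2S ratio, fraction D' < 1 and mean D'."""
    if len(pairs) == 0:
        raise ValueError("no LD pairs to summarise")
    if distance_edges is None:
        distance_edges = np.arange(0, pairs["distance"].max() + 51, 50)
    binned = pd.cut(pairs["distance"], distance_edges, right=False)
    decay = (
        pairs.assign(distance_bin=binned)
        .groupby("distance_bin", observed=True)
        .agg(mean_r2=("r2", "mean"), mean_d_prime=("d_prime", "mean"),
             n_pairs=("r2", "size"))
        .reset_index()
    )
    out = {
        "decay": decay,
        "mean_r2": float(pairs["r2"].mean()),
        "mean_d_prime": float(pairs["d_prime"].mean()),
        "frac_dprime_lt1": float((pairs["d_prime"] < 1.0).mean()),
        "n_pairs": len(pairs),
    }
    if "pair_class" in pairs:
        nn = pairs.loc[pairs["pair_class"] == "NN", "r2"]
        ss = pairs.loc[pairs["pair_class"] == "SS", "r2"]
        out["r2N_r2S"] = float(nn.mean() / ss.mean()) if len(nn) and len(ss) else None
    return out
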