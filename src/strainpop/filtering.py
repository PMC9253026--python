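"""Read-retention rules and per-sample allele-count pileups.

A read is retained iff its mate maps to the same scaffold, its per-read
identity (1 - edit distance / aligned length) is at least ``min_identity``
and its mapping quality is strictly greater than ``min_mapq_exclusive``.
Pileups count bases with quality >= ``min_base_quality``; bases where
overlapping mates of one fragment cover the same position are counted once
(the higher-quality base wins, first mate on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import FilterConfig
from .reads import ReadSet


@dataclass
class FilterReport:
    n_input: int = 0
    n_retained: int = 0
    dropped: dict = field(default_factory=dict)   # reason -> count

    def as_dict(self) -> dict:
        return {"input": self.n_input, "retained": self.n_retained, **{
            f"dropped_{k}": v for k, v in sorted(self.dropped.items())}}


def filter_read_pairs(
    rs: ReadSet,
    cfg: FilterConfig | None = None,
    reference_codes: dict[str, np.ndarray] | None = None,
    min_identity: float | None = None,
) -> tuple[np.ndarray, FilterReport]:
    """Boolean retention mask over ``rs`` plus a per-reason drop report.

    Every dropped read is attributed to exactly one reason, checked in
    order: missing mate, mate on another scaffold, low identity, low mapq.
    ``min_identity`` overrides the config value (e.g. for a 98% ANI
    sensitivity re-run, see ``FilterConfig.ani_mode``).
    """
    cfg = cfg or FilterConfig()
    ident_cut = min_identity if min_identity is not None else cfg.min_identity
    n = len(rs)
    report = FilterReport(n_input=n)
    if reference_codes is not None and np.any(rs.nm < 0):
        rs.recompute_nm(reference_codes)

    reason = np.zeros(n, dtype=np.int8)  # 0 keep, 1.. drop reasons
    if cfg.require_same_scaffold_mates:
        missing = rs.mate_ref_id < 0
        other = (~missing) & (rs.mate_ref_id != rs.ref_id)
        reason[missing] = 1
        reason[other] = 2
    with np.errstate(invalid="ignore"):
        identity = np.where(rs.nm >= 0, 1.0 - rs.nm / np.maximum(rs.length, 1), np.nan)
    low_ident = (reason == 0) & ((rs.nm < 0) | (identity < ident_cut))
    reason[low_ident] = 3
    low_mapq = (reason == 0) & (rs.mapq <= cfg.min_mapq_exclusive)
    reason[low_mapq] = 4

    names = {1: "missing_mate", 2: "mate_other_scaffold", 3: "low_identity", 4: "low_mapq"}
    for code, name in names.items():
        c = int((reason == code).sum())
        if c:
            report.dropped[name] = c
    mask = reason == 0
    report.n_retained = int(mask.sum())
    return mask, report


class Pileup(dict):
    """Mapping bin_id -> (L, 4) int64 allele-count matrix (A, C, G, T)."""

    def coverage(self, bin_id: str) -> np.ndarray:
        return self[bin_id].sum(axis=1)

    def __add__(self, other: "Pileup") -> "Pileup":
        out = Pileup()
        for k in set(self) | set(other):
            if k in self and k in other:
                out[k] = self[k] + other[k]
            else:
                out[k] = (self.get(k) if k in self else other[k]).copy()
        return out


def _overlap_skip_mask(rs: ReadSet, idx: np.ndarray) -> np.ndarray:
    """Per-base skip mask so each fragment contributes once per position."""
    skip = np.zeros(rs.seq.shape, dtype=bool)
    order = idx[np.argsort(rs.frag[idx], kind="stable")]
    frags = rs.frag[order]
    same_next = np.nonzero(frags[:-1] == frags[1:])[0]
    for k in same_next:
        i, j = order[k], order[k + 1]
        if rs.ref_id[i] != rs.ref_id[j]:
            continue
        if rs.pos[i] > rs.pos[j]:
            i, j = j, i
        ov_lo = int(rs.pos[j])
        ov_hi = min(int(rs.pos[i] + rs.length[i]), int(rs.pos[j] + rs.length[j]))
        if ov_hi <= ov_lo:
            continue
        w = ov_hi - ov_lo
        qi = rs.qual[i, ov_lo - rs.pos[i]:ov_lo - rs.pos[i] + w]
        qj = rs.qual[j, :w]
        keep_j = qj > qi  # ties go to the leftmost (first) mate
        skip[i, ov_lo - rs.pos[i]:ov_lo - rs.pos[i] + w] = keep_j
        skip[j, :w] = ~keep_j
    return skip


def build_pileup(
    rs: ReadSet,
    mask: np.ndarray | None = None,
    cfg: FilterConfig | None = None,
) -> Pileup:
    """Allele counts per position from retained reads.

    Reads extending past the declared reference length are a fatal error
    (guarded at load time); positions with no qualifying base have
    coverage 0.
    """
    cfg = cfg or FilterConfig()
    if mask is None:
        mask = np.ones(len(rs), dtype=bool)
    idx = np.nonzero(mask)[0]
    skip = (_overlap_skip_mask(rs, idx) if cfg.count_overlap_once
            else np.zeros(rs.seq.shape, dtype=bool))

    pile = Pileup()
    max_len = rs.seq.shape[1]
    cols = np.arange(max_len)
    for rid, (name, L) in enumerate(zip(rs.ref_names, rs.ref_lengths)):
        counts = np.zeros(4 * L, dtype=np.int64)
        sel = idx[rs.ref_id[idx] == rid]
        for chunk in range(0, len(sel), 200_000):
            s = sel[chunk:chunk + 200_000]
            valid = (
                (cols[None, :] < rs.length[s, None])
                & (rs.qual[s] >= cfg.min_base_quality)
                & (rs.seq[s] < 4)
                & ~skip[s]
            )
            keys = (rs.seq[s].astype(np.int64) * L
                    + (rs.pos[s, None] + cols[None, :]))[valid]
            counts += np.bincount(keys, minlength=4 * L)
        pile[name] = counts.reshape(4, L).T
    return pile


def pileup_to_frame(pile: Pileup):
    """Optional TSV-ready dump: bin, pos (1-based), A, C, G, T, coverage."""
    import pandas as pd
    frames = []
    for bin_id, counts in pile.items():
        cov = counts.sum(axis=1)
        nz = np.nonzero(cov)[0]
        frames.append(pd.DataFrame({
            "bin": bin_id, "pos": nz + 1,
            "A": counts[nz, 0], "C": counts[nz, 1],
            "G": counts[nz, 2], "T": counts[nz, 3], "coverage": cov[nz],
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["bin", "pos", "A", "C", "G", "T", "coverage"])
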