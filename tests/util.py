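"""Hand-construction helpers for alignment fixtures."""

from __future__ import annotations

import numpy as np

from strainpop.reads import ReadSet, encode_seq


def build_readset(ref_names, ref_lengths, reads, read_len=None):
    """Build a ReadSet from a list of dicts.

    Each dict: ref (name), pos, seq (str); optional qual (int or list),
    mapq (default 60), nm (default 0), frag (default index//2),
    is_read1, is_reverse, mate_ref (name or None), mate_pos.
    """
    n = len(reads)
    max_len = read_len or max(len(r["seq"]) for r in reads)
    rs = ReadSet(
        list(ref_names), list(ref_lengths),
        np.zeros(n, np.int32), np.zeros(n, np.int32), np.zeros(n, np.int32),
        np.full((n, max_len), 4, np.uint8), np.zeros((n, max_len), np.uint8),
        np.zeros(n, np.uint8), np.full(n, -1, np.int32), np.zeros(n, np.int64),
        np.zeros(n, bool), np.zeros(n, bool),
        np.full(n, -1, np.int32), np.full(n, -1, np.int32),
    )
    for i, r in enumerate(reads):
        L = len(r["seq"])
        rs.ref_id[i] = ref_names.index(r.get("ref", ref_names[0]))
        rs.pos[i] = r["pos"]
        rs.length[i] = L
        rs.seq[i, :L] = encode_seq(r["seq"])
        q = r.get("qual", 37)
        rs.qual[i, :L] = q if np.isscalar(q) else np.asarray(q, np.uint8)
        rs.mapq[i] = r.get("mapq", 60)
        rs.nm[i] = r.get("nm", 0)
        rs.frag[i] = r.get("frag", i // 2)
        rs.is_read1[i] = r.get("is_read1", i % 2 == 0)
        rs.is_reverse[i] = r.get("is_reverse", i % 2 == 1)
        mr = r.get("mate_ref", r.get("ref", ref_names[0]))
        if mr is not None:
            rs.mate_ref_id[i] = ref_names.index(mr)
            rs.mate_pos[i] = r.get("mate_pos", r["pos"])
    return rs
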