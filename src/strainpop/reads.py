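"""Column-oriented container for aligned paired-end reads.

A :class:`ReadSet` holds gapless (all-M CIGAR) alignments as numpy arrays so
that filtering, pileup construction and linkage collection are vectorised.
It can be loaded from a coordinate-sorted SAM/BAM via pysam and written back
out as sorted SAM; the simulator produces ReadSets directly, and a
round-trip through SAM is exact.

Base codes: A=0, C=1, G=2, T=3, anything else (incl. N) = 4.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode_seq(s: str) -> np.ndarray:
    return _CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)


@dataclass
class ReadSet:
    """Aligned reads over a set of reference bins/scaffolds."""

    ref_names: list[str]
    ref_lengths: list[int]
    ref_id: np.ndarray      # (n,) int32, index into ref_names
    pos: np.ndarray         # (n,) int32, 0-based leftmost reference position
    length: np.ndarray      # (n,) int32, aligned length (gapless)
    seq: np.ndarray         # (n, max_len) uint8 base codes, padded with 4
    qual: np.ndarray        # (n, max_len) uint8 Phred scores
    mapq: np.ndarray        # (n,) uint8
    nm: np.ndarray          # (n,) int32 edit distance; -1 when missing
    frag: np.ndarray        # (n,) int64 fragment (template) id
    is_read1: np.ndarray    # (n,) bool
    is_reverse: np.ndarray  # (n,) bool
    mate_ref_id: np.ndarray  # (n,) int32; -1 when mate missing/unmapped
    mate_pos: np.ndarray     # (n,) int32

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def end(self) -> np.ndarray:
        """Exclusive reference end position of each read."""
        return self.pos + self.length

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(
            self.ref_names,
            self.ref_lengths,
            *(a[mask] for a in (
                self.ref_id, self.pos, self.length)),
            self.seq[mask],
            self.qual[mask],
            *(a[mask] for a in (
                self.mapq, self.nm, self.frag, self.is_read1,
                self.is_reverse, self.mate_ref_id, self.mate_pos)),
        )

    def recompute_nm(self, reference_codes: dict[str, np.ndarray]) -> None:
        """Fill in missing NM values by comparing bases to the reference."""
        missing = np.nonzero(self.nm < 0)[0]
        for i in missing:
            ref = reference_codes[self.ref_names[self.ref_id[i]]]
            L = self.length[i]
            self.nm[i] = int(
                np.sum(self.seq[i, :L] != ref[self.pos[i]:self.pos[i] + L])
            )


def from_sam(path: str, reference_codes: dict[str, np.ndarray] | None = None) -> ReadSet:
    """Load a SAM/BAM file into a ReadSet.

    Only gapless alignments (CIGAR of a single M/=/X run) are supported;
    indel-containing records raise.  Unmapped records are skipped.
    """
    with pysam.AlignmentFile(path, check_sq=True) as fh:
        ref_names = list(fh.references)
        ref_lengths = [fh.get_reference_length(r) for r in ref_names]
        recs = []
        for rec in fh:
            if rec.is_unmapped:
                continue
            cig = rec.cigartuples
            if cig is None or len(cig) != 1 or cig[0][0] not in (0, 7, 8):
                raise ValueError(
                    f"read {rec.query_name}: only gapless alignments supported"
                )
            if rec.reference_end > ref_lengths[rec.reference_id]:
                raise ValueError(
                    f"read {rec.query_name} extends past the declared length of "
                    f"{ref_names[rec.reference_id]}"
                )
            recs.append(rec)

    n = len(recs)
    max_len = max((r.query_length for r in recs), default=0)
    out = ReadSet(
        ref_names, ref_lengths,
        np.zeros(n, np.int32), np.zeros(n, np.int32), np.zeros(n, np.int32),
        np.full((n, max_len), 4, np.uint8), np.zeros((n, max_len), np.uint8),
        np.zeros(n, np.uint8), np.full(n, -1, np.int32), np.zeros(n, np.int64),
        np.zeros(n, bool), np.zeros(n, bool),
        np.full(n, -1, np.int32), np.full(n, -1, np.int32),
    )
    frag_ids: dict[str, int] = {}
    for i, rec in enumerate(recs):
        out.ref_id[i] = rec.reference_id
        out.pos[i] = rec.reference_start
        L = rec.query_length
        out.length[i] = L
        out.seq[i, :L] = encode_seq(rec.query_sequence)
        q = rec.query_qualities
        out.qual[i, :L] = 30 if q is None else np.asarray(q, np.uint8)
        out.mapq[i] = rec.mapping_quality
        out.nm[i] = rec.get_tag("NM") if rec.has_tag("NM") else -1
        out.frag[i] = frag_ids.setdefault(rec.query_name, len(frag_ids))
        out.is_read1[i] = not rec.is_read2
        out.is_reverse[i] = rec.is_reverse
        if rec.is_paired and not rec.mate_is_unmapped and rec.next_reference_id >= 0:
            out.mate_ref_id[i] = rec.next_reference_id
            out.mate_pos[i] = rec.next_reference_start
    if reference_codes is not None:
        out.recompute_nm(reference_codes)
    return out


def write_sam(rs: ReadSet, path: str) -> None:
    """Write a ReadSet as a coordinate-sorted SAM file (deterministic)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": n, "LN": int(l)}
            for n, l in zip(rs.ref_names, rs.ref_lengths)
        ],
    }
    order = np.lexsort((rs.is_read1, rs.pos, rs.ref_id))
    with pysam.AlignmentFile(path, "wh", header=header) as fh:
        for i in order:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = f"frag{rs.frag[i]}"
            L = int(rs.length[i])
            a.query_sequence = decode_seq(rs.seq[i, :L])
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rs.qual[i, :L])
            )
            a.reference_id = int(rs.ref_id[i])
            a.reference_start = int(rs.pos[i])
            a.mapping_quality = int(rs.mapq[i])
            a.cigartuples = [(0, L)]
            flag = 0x1 | 0x2
            flag |= 0x40 if rs.is_read1[i] else 0x80
            if rs.is_reverse[i]:
                flag |= 0x10
            else:
                flag |= 0x20
            a.flag = flag
            if rs.mate_ref_id[i] >= 0:
                a.next_reference_id = int(rs.mate_ref_id[i])
                a.next_reference_start = int(rs.mate_pos[i])
                lo = min(int(rs.pos[i]), int(rs.mate_pos[i]))
                hi = max(int(rs.pos[i]) + L, int(rs.mate_pos[i]) + L)
                tlen = hi - lo
                a.template_length = tlen if rs.pos[i] <= rs.mate_pos[i] else -tlen
            if rs.nm[i] >= 0:
                a.set_tag("NM", int(rs.nm[i]))
            fh.write(a)
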