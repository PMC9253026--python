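"""Synthetic metagenomic community with known population-genetic truth.

Generates, per genome bin: a reference sequence with packed gene models, a
field of segregating sites whose per-population allele frequencies follow
the Balding–Nichols model Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
frequency p, a finite pool of haplotypes per population (with optional
planted selective sweeps), and coordinate-correct paired-end alignments
with configurable per-base error — everything the downstream modules
consume, plus truth tables for parameter-recovery tests.

Planted sweeps follow the classic signature: sites in the sweep get an
elevated F (strong differentiation), and in every population one dominant
haplotype (carrying the alternate allele in population 0 and the reference
allele elsewhere, so populations diverge) receives frequency weight
(1 - diversity_factor), collapsing within-population diversity and raising
linkage in the interval.

All randomness flows from ``config.seed`` through keyed
``numpy.random.SeedSequence`` substreams, so per-bin output is stable under
unrelated config edits and identical configs give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import CommunityConfig, SweepInterval
from .reads import BASES, ReadSet, decode_seq

CATEGORIES = ("genic", "ribosomal", "biosynthetic")
_CATEGORY_PROBS = (0.8, 0.1, 0.1)
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


class PackingError(ValueError):
    """Gene density is infeasible for the genome and gene-length range."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    bin_id: str
    start: int   # 0-based half-open
    end: int
    strand: str
    category: str


@dataclass
class Reference:
    sequences: dict[str, np.ndarray]   # bin_id -> base codes (uint8)
    genes: list[Gene]

    @property
    def bin_ids(self) -> list[str]:
        return list(self.sequences)

    def genes_of(self, bin_id: str) -> list[Gene]:
        return [g for g in self.genes if g.bin_id == bin_id]


@dataclass
class TruthTable:
    """Ground truth of the simulated community.

    sites: one row per segregating site with ancestral p, the F used, the
        Balding–Nichols model frequency and (after alignment simulation)
        the realized haplotype-pool frequency per population.
    gene_truth: per gene, expected π per population and pairwise Fst
        computed from the realized haplotype-pool frequencies.
    sweep_truth: the planted intervals with bp spans.
    """

    sites: pd.DataFrame
    gene_truth: pd.DataFrame = field(default_factory=pd.DataFrame)
    sweep_truth: pd.DataFrame = field(default_factory=pd.DataFrame)


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# stage tags for substream derivation
_REF, _FREQ, _ALN = 1, 2, 3


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes][::-1].copy()


def generate_reference(config: CommunityConfig) -> Reference:
    """Random genome bins with non-overlapping packed gene models.

    Gene lengths are uniform multiples of 3 within ``gene_length_range``;
    genes carry start/stop codons on their strand and a ``category`` label.
    Raises :class:`PackingError` when ``gene_density`` cannot be reached.
    """
    sequences: dict[str, np.ndarray] = {}
    genes: list[Gene] = []
    lo, hi = config.gene_length_range
    lo3, hi3 = max(6, lo // 3 * 3), hi // 3 * 3
    for b in range(config.n_bins):
        rng = _rng(config.seed, _REF, b)
        bin_id = f"bin_{b}"
        L = config.genome_length
        probs = [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
        seq = rng.choice(4, size=L, p=probs).astype(np.uint8)

        target = config.gene_density * L
        lengths: list[int] = []
        total = 0
        while total < target:
            room = L - total
            if room < lo3:
                raise PackingError(
                    f"gene_density {config.gene_density} infeasible for "
                    f"genome_length {L} and gene_length_range {config.gene_length_range}"
                )
            l = int(rng.integers(lo3 // 3, min(hi3, room) // 3 + 1)) * 3
            lengths.append(l)
            total += l
        gap_total = L - total
        gaps = rng.multinomial(gap_total, np.full(len(lengths) + 1, 1 / (len(lengths) + 1)))
        pos = 0
        for gi, glen in enumerate(lengths):
            pos += int(gaps[gi])
            start, end = pos, pos + glen
            strand = "+" if rng.random() < 0.5 else "-"
            category = CATEGORIES[rng.choice(3, p=_CATEGORY_PROBS)]
            if strand == "+":
                seq[start:start + 3] = [0, 3, 2]          # ATG
                seq[end - 3:end] = [3, 0, 0]              # TAA
            else:
                seq[end - 3:end] = [1, 0, 3]              # revcomp(ATG)
                seq[start:start + 3] = [3, 3, 0]          # revcomp(TAA)
            genes.append(Gene(f"{bin_id}_g{gi:04d}", bin_id, start, end, strand, category))
            pos = end
        sequences[bin_id] = seq
    return Reference(sequences, genes)


def _expected_het(law: tuple) -> float:
    """E[2p(1-p)] under the ancestral frequency law."""
    kind = law[0]
    if kind == "uniform":
        a, b = law[1], law[2]
        m1 = (a + b) / 2
        m2 = (b - a) ** 2 / 12 + m1 ** 2
    elif kind == "beta":
        al, be = law[1], law[2]
        m1 = al / (al + be)
        m2 = al * (al + 1) / ((al + be) * (al + be + 1))
    else:
        raise ValueError(f"unknown ancestral_freq_law {law!r}")
    return 2 * (m1 - m2)


def _draw_ancestral(rng: np.random.Generator, law: tuple, n: int) -> np.ndarray:
    if law[0] == "uniform":
        return rng.uniform(law[1], law[2], n)
    return rng.beta(law[1], law[2], n)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Per-population frequencies; F=0 degenerates to the ancestral p."""
    q = p.copy()
    pos = f > 0
    if np.any(pos):
        ratio = (1 - f[pos]) / f[pos]
        q[pos] = rng.beta(p[pos] * ratio, (1 - p[pos]) * ratio)
    return q


def sweep_bp_spans(reference: Reference, config: CommunityConfig) -> pd.DataFrame:
    """Planted intervals as bp spans; validates disjointness within a bin."""
    rows = []
    for iv in config.sweep_intervals:
        bin_id = f"bin_{iv.bin_index}"
        genes = reference.genes_of(bin_id)
        if iv.gene_stop > len(genes):
            raise ValueError(f"sweep interval {iv} exceeds the {len(genes)} genes of {bin_id}")
        rows.append({
            "bin": bin_id, "gene_start": iv.gene_start, "gene_stop": iv.gene_stop,
            "start": genes[iv.gene_start].start, "stop": genes[iv.gene_stop - 1].end,
            "f_high": iv.f_high, "diversity_factor": iv.diversity_factor,
        })
    df = pd.DataFrame(rows, columns=["bin", "gene_start", "gene_stop", "start",
                                     "stop", "f_high", "diversity_factor"])
    for bin_id, sub in df.groupby("bin"):
        s = sub.sort_values("start")
        if (s["start"].values[1:] < s["stop"].values[:-1]).any():
            raise ValueError(f"sweep intervals overlap within {bin_id}")
    return df


def draw_site_frequencies(reference: Reference, config: CommunityConfig) -> TruthTable:
    """Choose segregating sites and their per-population model frequencies.

    The number of sites is set so the expected genome-wide per-site π
    (over the realized haplotype pool) equals ``config.within_diversity``.
    """
    fs = np.array(config.fst_per_population())
    sweeps = sweep_bp_spans(reference, config)
    e_het = _expected_het(config.ancestral_freq_law)
    pool_factor = 1 - 1 / config.n_haplotypes
    per_site = e_het * (1 - fs.mean()) * pool_factor
    frames = []
    for b, bin_id in enumerate(reference.bin_ids):
        rng = _rng(config.seed, _FREQ, b)
        L = len(reference.sequences[bin_id])
        n_sites = int(round(config.within_diversity * L / per_site)) if per_site > 0 else 0
        n_sites = min(n_sites, L // 2)
        pos = np.sort(rng.choice(L, size=n_sites, replace=False)).astype(np.int64)
        p = _draw_ancestral(rng, config.ancestral_freq_law, n_sites)
        ref_codes = reference.sequences[bin_id][pos]
        alt_codes = ((ref_codes + rng.integers(1, 4, n_sites)) % 4).astype(np.uint8)

        sw = sweeps[sweeps["bin"] == bin_id]
        f_site = np.repeat(fs[None, :], n_sites, axis=0)  # (n_sites, n_pops)
        in_sweep = np.full(n_sites, -1, dtype=np.int64)
        for k, (_, row) in enumerate(sw.iterrows()):
            m = (pos >= row["start"]) & (pos < row["stop"])
            f_site[m, :] = row["f_high"]
            in_sweep[m] = k
        df = pd.DataFrame({
            "bin": bin_id, "pos": pos,
            "ref": [BASES[c] for c in ref_codes],
            "alt": [BASES[c] for c in alt_codes],
            "ancestral_p": p, "sweep_index": in_sweep,
        })
        for j in range(config.n_populations):
            df[f"f_p{j}"] = f_site[:, j]
            df[f"freq_model_p{j}"] = _balding_nichols(rng, p, f_site[:, j])
        frames.append(df)
    sites = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["bin", "pos", "ref", "alt", "ancestral_p", "sweep_index"]))
    return TruthTable(sites=sites, sweep_truth=sweeps)


def _realize_haplotypes(rng, q_model, sweep_site_mask, pop_index, config):
    """Haplotype alt-allele matrix (n_haplotypes, n_sites) for one bin/pop.

    Alleles are independent Bernoulli(q) across sites and haplotypes,
    except in sweep intervals where haplotype 0 is the dominant lineage:
    all-alternate in population 0, all-reference in every other population.
    """
    H = (rng.random((config.n_haplotypes, len(q_model))) < q_model[None, :])
    H = H.astype(np.uint8)
    if sweep_site_mask.any():
        H[0, sweep_site_mask] = 1 if pop_index == 0 else 0
    return H


def _pool_frequencies(H, sweep_site_mask, diversity_factor_site):
    """Frequency of the alternate allele in the weighted haplotype pool."""
    n_hap = H.shape[0]
    q = H.mean(axis=0)
    if sweep_site_mask.any():
        df_s = diversity_factor_site[sweep_site_mask]
        w0 = 1 - df_s
        rest = df_s / (n_hap - 1)
        q[sweep_site_mask] = (
            w0 * H[0, sweep_site_mask]
            + rest * H[1:, sweep_site_mask].sum(axis=0)
        )
    return q


def _gradient_positions(rng, n, limit, ratio):
    """Fragment starts in [0, limit) with log-linear coverage decline by `ratio`."""
    u = rng.random(n)
    if ratio == 1.0:
        return (u * limit).astype(np.int64)
    x = -np.log(1 - u * (1 - 1 / ratio)) / np.log(ratio)  # in [0, 1)
    return (x * limit).astype(np.int64)


def simulate_alignments(
    reference: Reference, truth: TruthTable, config: CommunityConfig
) -> dict[str, ReadSet]:
    """Emit per-sample coordinate-correct paired-end alignments.

    Each fragment copies one haplotype from its population's pool, with
    Poisson(``crossover_rate``) template switches to other haplotypes;
    per-base errors are applied at ``error_rate``.  Fills the realized pool
    frequencies and ``gene_truth`` of the truth table in place.
    """
    rl = config.read_length
    n_pops = config.n_populations
    bin_ids = reference.bin_ids
    ref_lengths = [len(reference.sequences[b]) for b in bin_ids]

    # Realize haplotype pools and pool frequencies per (bin, population).
    pools: dict[tuple[str, int], np.ndarray] = {}
    site_info: dict[str, dict] = {}
    for b, bin_id in enumerate(bin_ids):
        sub = truth.sites[truth.sites["bin"] == bin_id]
        pos = sub["pos"].to_numpy(np.int64)
        alt = np.array([BASES.index(a) for a in sub["alt"]], dtype=np.uint8)
        sweep_mask = sub["sweep_index"].to_numpy() >= 0
        df_site = np.ones(len(sub))
        sw = truth.sweep_truth[truth.sweep_truth["bin"] == bin_id].reset_index(drop=True)
        sweep_starts = sw["start"].to_numpy(np.int64) if len(sw) else np.empty(0, np.int64)
        sweep_stops = sw["stop"].to_numpy(np.int64) if len(sw) else np.empty(0, np.int64)
        sweep_df = sw["diversity_factor"].to_numpy() if len(sw) else np.empty(0)
        for k in range(len(sw)):
            m = (pos >= sweep_starts[k]) & (pos < sweep_stops[k])
            df_site[m] = sweep_df[k]
        site_info[bin_id] = dict(
            pos=pos, alt=alt, sweep_mask=sweep_mask, df_site=df_site,
            sweep_starts=sweep_starts, sweep_stops=sweep_stops, sweep_df=sweep_df,
            sub_index=sub.index,
        )
        for j in range(n_pops):
            rng = _rng(config.seed, _ALN, b, j)
            q_model = sub[f"freq_model_p{j}"].to_numpy()
            H = _realize_haplotypes(rng, q_model, sweep_mask, j, config)
            pools[(bin_id, j)] = H
            q_pool = _pool_frequencies(H, sweep_mask, df_site)
            truth.sites.loc[sub.index, f"freq_pool_p{j}"] = q_pool

    _fill_gene_truth(reference, truth, config)

    samples: dict[str, ReadSet] = {}
    for j in range(n_pops):
        for r in range(config.samples_per_population):
            sample = f"p{j}_s{r}"
            parts = []
            frag_base = 0
            for b, bin_id in enumerate(bin_ids):
                rng = _rng(config.seed, _ALN, b, j, r + 1)
                part = _simulate_bin_sample(
                    rng, reference.sequences[bin_id], b, site_info[bin_id],
                    pools[(bin_id, j)], j, config, frag_base,
                )
                if len(part["frag"]):
                    frag_base = int(part["frag"].max()) + 1
                parts.append(part)
            samples[sample] = _concat_readsets(parts, bin_ids, ref_lengths)
    return samples


def _simulate_bin_sample(rng, seq, bin_index, info, H, pop_index, config, frag_base):
    L = len(seq)
    rl = config.read_length
    n_hap = config.n_haplotypes
    n_frags = int(round(config.depth * L / (2 * rl)))
    if n_frags == 0:
        return _empty_part(bin_index, L, rl)

    insert = rng.normal(config.insert_mean, config.insert_sd, n_frags)
    insert = np.clip(np.round(insert), rl, L).astype(np.int64)
    limit = L - insert  # per-fragment start limit (inclusive of 0)
    u_pos = _gradient_positions(rng, n_frags, L, config.coverage_ratio)
    starts = np.minimum(u_pos, limit)

    # Haplotype choice, weighted toward the dominant lineage inside sweeps.
    # Crossover donors are drawn from the same position-dependent weights:
    # in a swept population most templates, including recombination donors,
    # belong to the dominant lineage.
    sw_starts, sw_stops = info["sweep_starts"], info["sweep_stops"]

    def draw_haps(at: np.ndarray, reach: np.ndarray) -> np.ndarray:
        """Template choice for segments spanning [at, at + reach)."""
        h = rng.integers(0, n_hap, len(at))
        if len(sw_starts):
            # a segment intersecting a sweep interval draws from its weights
            idx = np.searchsorted(sw_starts, at + reach, side="right") - 1
            in_sw = (idx >= 0) & (at < sw_stops[np.clip(idx, 0, None)])
            dfac = np.where(in_sw, info["sweep_df"][np.clip(idx, 0, None)], 1.0)
            dominant = in_sw & (rng.random(len(at)) < (1 - dfac))
            h = np.where(dominant, 0, h)
        return h

    hap = draw_haps(starts, insert)
    n_cross = rng.poisson(config.crossover_rate, n_frags)

    # Alleles carried by each fragment at the sites it spans.
    P = info["pos"]
    i0 = np.searchsorted(P, starts)
    i1 = np.searchsorted(P, starts + insert)
    alle_frag, alle_site, alle_val = [], [], []
    has_sites = np.nonzero(i1 > i0)[0]
    for fi in has_sites:
        s0, s1 = i0[fi], i1[fi]
        if n_cross[fi] == 0:
            hs = np.full(s1 - s0, hap[fi])
        else:
            cuts = np.sort(rng.integers(starts[fi], starts[fi] + insert[fi], n_cross[fi]))
            seg = np.searchsorted(cuts, P[s0:s1], side="right")
            seg_haps = np.empty(n_cross[fi] + 1, dtype=np.int64)
            seg_haps[0] = hap[fi]
            seg_haps[1:] = draw_haps(cuts, starts[fi] + insert[fi] - cuts)
            hs = seg_haps[seg]
        alle_frag.append(np.full(s1 - s0, fi))
        alle_site.append(np.arange(s0, s1))
        alle_val.append(H[hs, np.arange(s0, s1)])
    if alle_frag:
        alle_frag = np.concatenate(alle_frag)
        alle_site = np.concatenate(alle_site)
        alle_val = np.concatenate(alle_val)
    else:
        alle_frag = alle_site = alle_val = np.empty(0, np.int64)

    # Assemble reads: read1 forward at start, read2 reverse at start+insert-rl.
    n_reads = 2 * n_frags
    pos = np.empty(n_reads, np.int64)
    pos[0::2] = starts
    pos[1::2] = starts + insert - rl
    reads_seq = np.empty((n_reads, rl), np.uint8)
    for chunk in range(0, n_reads, 200_000):
        sl = slice(chunk, min(chunk + 200_000, n_reads))
        gather = pos[sl, None] + np.arange(rl)[None, :]
        reads_seq[sl] = seq[gather]

    # Scatter haplotype alternate alleles into the reads that cover them.
    carried = alle_val == 1
    if carried.any():
        fsel = alle_frag[carried]
        psel = P[alle_site[carried]]
        acode = info["alt"][alle_site[carried]]
        for ridx, rpos in ((2 * fsel, psel), (2 * fsel + 1, psel)):
            off = rpos - pos[ridx]
            ok = (off >= 0) & (off < rl)
            reads_seq[ridx[ok], off[ok]] = acode[ok]

    # Sequencing errors.
    if config.error_rate > 0:
        for chunk in range(0, n_reads, 200_000):
            sl = slice(chunk, min(chunk + 200_000, n_reads))
            block = reads_seq[sl]
            err = rng.random(block.shape) < config.error_rate
            if err.any():
                block[err] = (block[err] + rng.integers(1, 4, int(err.sum()))) % 4
    # NM vs reference.
    nm = np.empty(n_reads, np.int32)
    for chunk in range(0, n_reads, 200_000):
        sl = slice(chunk, min(chunk + 200_000, n_reads))
        gather = pos[sl, None] + np.arange(rl)[None, :]
        nm[sl] = (reads_seq[sl] != seq[gather]).sum(axis=1)

    frag = np.repeat(np.arange(n_frags, dtype=np.int64) + frag_base, 2)
    mate_pos = np.empty(n_reads, np.int64)
    mate_pos[0::2] = pos[1::2]
    mate_pos[1::2] = pos[0::2]
    return dict(
        bin_index=bin_index, pos=pos, seq=reads_seq, nm=nm, frag=frag,
        mate_pos=mate_pos, rl=rl,
    )


def _empty_part(bin_index, L, rl):
    return dict(
        bin_index=bin_index, pos=np.empty(0, np.int64),
        seq=np.empty((0, rl), np.uint8), nm=np.empty(0, np.int32),
        frag=np.empty(0, np.int64), mate_pos=np.empty(0, np.int64), rl=rl,
    )


def _concat_readsets(parts, bin_ids, ref_lengths) -> ReadSet:
    rl = parts[0]["rl"] if parts else 0
    n = sum(len(p["pos"]) for p in parts)
    rs = ReadSet(
        list(bin_ids), list(ref_lengths),
        np.empty(n, np.int32), np.empty(n, np.int32), np.full(n, rl, np.int32),
        np.empty((n, rl), np.uint8), np.empty((n, rl), np.uint8),
        np.empty(n, np.uint8), np.empty(n, np.int32), np.empty(n, np.int64),
        np.empty(n, bool), np.empty(n, bool),
        np.empty(n, np.int32), np.empty(n, np.int32),
    )
    at = 0
    for p in parts:
        k = len(p["pos"])
        sl = slice(at, at + k)
        rs.ref_id[sl] = p["bin_index"]
        rs.pos[sl] = p["pos"]
        rs.seq[sl] = p["seq"]
        rs.nm[sl] = p["nm"]
        rs.frag[sl] = p["frag"]
        rs.mate_ref_id[sl] = p["bin_index"]
        rs.mate_pos[sl] = p["mate_pos"]
        rs.is_read1[sl] = np.arange(k) % 2 == 0
        rs.is_reverse[sl] = np.arange(k) % 2 == 1
        at += k
    return rs


def finalize_readset(rs: ReadSet, config: CommunityConfig) -> ReadSet:
    rs.qual[:] = config.base_quality
    rs.mapq[:] = config.mapping_quality
    return rs


def _fill_gene_truth(reference, truth, config):
    """Per-gene expected π (per population) and pairwise Fst from pool frequencies."""
    rows = []
    n_pops = config.n_populations
    for gene in reference.genes:
        sub = truth.sites[
            (truth.sites["bin"] == gene.bin_id)
            & (truth.sites["pos"] >= gene.start)
            & (truth.sites["pos"] < gene.end)
        ]
        glen = gene.end - gene.start
        row = {"gene_id": gene.gene_id, "bin": gene.bin_id,
               "category": gene.category, "n_sites": len(sub)}
        qs = [sub[f"freq_pool_p{j}"].to_numpy() if len(sub) else np.empty(0)
              for j in range(n_pops)]
        for j in range(n_pops):
            het = 2 * qs[j] * (1 - qs[j])
            row[f"pi_p{j}"] = float(het.sum() / glen) if glen else np.nan
        for a in range(n_pops):
            for b in range(a + 1, n_pops):
                num = ((qs[a] - qs[b]) ** 2).sum()
                den = (qs[a] * (1 - qs[b]) + qs[b] * (1 - qs[a])).sum()
                row[f"fst_p{a}_p{b}"] = float(num / den) if den > 0 else np.nan
        rows.append(row)
    truth.gene_truth = pd.DataFrame(rows)


def simulate_community(
    config: CommunityConfig, out_dir: str | Path | None = None
) -> tuple[Reference, TruthTable, dict[str, ReadSet]]:
    """Full generation: reference, truth and per-sample alignments.

    When ``out_dir`` is given, writes reference.fasta, genes.gff3, one
    sorted SAM per sample, and the truth tables.
    """
    reference = generate_reference(config)
    truth = draw_site_frequencies(reference, config)
    samples = simulate_alignments(reference, truth, config)
    for rs in samples.values():
        finalize_readset(rs, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(reference, out / "reference.fasta")
        write_gff3(reference, out / "genes.gff3")
        from .reads import write_sam
        for name, rs in samples.items():
            write_sam(rs, str(out / f"{name}.sam"))
        write_truth(truth, out)
    return reference, truth, samples


# ---------------------------------------------------------------------------
# file writers / readers

def write_fasta(reference: Reference, path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    recs = [
        SeqRecord(Seq(decode_seq(seq)), id=bin_id, description="")
        for bin_id, seq in reference.sequences.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    from Bio import SeqIO
    from .reads import encode_seq
    return {rec.id: encode_seq(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(reference: Reference, path: str | Path) -> None:
    """1-based inclusive coordinates, strand +/-, category attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in reference.genes:
            fh.write(
                f"{g.bin_id}\tstrainpop\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t0\tID={g.gene_id};category={g.category}\n"
            )


def read_gff3(path: str | Path) -> list[Gene]:
    import pyranges
    df = pyranges.read_gff3(str(path)).df
    genes = []
    for _, r in df.iterrows():
        genes.append(Gene(
            gene_id=r.get("ID"), bin_id=r["Chromosome"],
            start=int(r["Start"]), end=int(r["End"]), strand=r["Strand"],
            category=r.get("category", "other"),
        ))
    return sorted(genes, key=lambda g: (g.bin_id, g.start))


def write_fastq(rs: ReadSet, prefix: str | Path) -> None:
    """Optional FASTQ emitter (R1/R2) for end-to-end runs with a real aligner."""
    prefix = str(prefix)
    with open(prefix + "_R1.fastq", "w") as f1, open(prefix + "_R2.fastq", "w") as f2:
        order = np.argsort(rs.frag, kind="stable")
        for i in order:
            L = int(rs.length[i])
            codes = rs.seq[i, :L]
            if rs.is_reverse[i]:
                codes = _revcomp(codes)
            s = decode_seq(codes)
            q = "".join(chr(q + 33) for q in rs.qual[i, :L])
            if rs.is_reverse[i]:
                q = q[::-1]
            fh = f1 if rs.is_read1[i] else f2
            mate = 1 if rs.is_read1[i] else 2
            fh.write(f"@frag{rs.frag[i]}/{mate}\n{s}\n+\n{q}\n")


_TRUTH_FILES = {"sites": "truth_sites.tsv", "gene_truth": "truth_genes.tsv",
                "sweep_truth": "truth_sweeps.tsv"}


def write_truth(truth: TruthTable, out_dir: str | Path) -> None:
    """Tab-separated truth tables; positions are written 1-based."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sites = truth.sites.copy()
    if len(sites):
        sites["pos"] = sites["pos"] + 1
    sites.to_csv(out / _TRUTH_FILES["sites"], sep="\t", index=False)
    truth.gene_truth.to_csv(out / _TRUTH_FILES["gene_truth"], sep="\t", index=False)
    sw = truth.sweep_truth.copy()
    if len(sw):
        sw["start"] = sw["start"] + 1
    sw.to_csv(out / _TRUTH_FILES["sweep_truth"], sep="\t", index=False)


def read_truth(out_dir: str | Path) -> TruthTable:
    out = Path(out_dir)
    sites = pd.read_csv(out / _TRUTH_FILES["sites"], sep="\t")
    if len(sites):
        sites["pos"] = sites["pos"] - 1
    genes = pd.read_csv(out / _TRUTH_FILES["gene_truth"], sep="\t")
    sweeps = pd.read_csv(out / _TRUTH_FILES["sweep_truth"], sep="\t")
    if len(sweeps):
        sweeps["start"] = sweeps["start"] - 1
    return TruthTable(sites=sites, gene_truth=genes, sweep_truth=sweeps)
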