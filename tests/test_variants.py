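"""SNP calling thresholds, the binomial null model and coding effects."""

import math

import numpy as np
import pytest

from strainpop.config import CommunityConfig
from strainpop.filtering import Pileup
from strainpop.synthetic import Gene, generate_reference
from strainpop.reads import BASES, encode_seq
from strainpop.variants import call_snps, classify_effects


def _pileup_from_counts(rows, bin_id="bin_0"):
    p = Pileup()
    p[bin_id] = np.array(rows, dtype=np.int64)
    return p


def exact_binom_tail(k, n, eps):
    """Independent oracle: P(X >= k), direct summation."""
    return sum(math.comb(n, i) * eps ** i * (1 - eps) ** (n - i)
               for i in range(k, n + 1))


@pytest.mark.parametrize("major,minor,called", [
    (95, 5, False),    # frequency exactly 5%: not strictly above
    (94, 6, True),     # 6%: above threshold and tail < 1e-6
    (19, 1, False),    # coverage 20, frequency 5%
])
def test_frequency_threshold_is_strict(major, minor, called):
    counts = [[major, minor, 0, 0]]
    snps = call_snps(_pileup_from_counts(counts))
    assert (len(snps) == 1) == called


def test_binomial_tail_matches_exact_summation():
    counts = [[94, 6, 0, 0], [80, 20, 0, 0], [55, 45, 0, 0]]
    snps = call_snps(_pileup_from_counts(counts), error_rate=0.001)
    assert len(snps) == 3
    for _, row in snps.iterrows():
        oracle = exact_binom_tail(
            int(row["minor_count"]), int(row["coverage"]), 0.001)
        assert row["p_null"] == pytest.approx(oracle, rel=1e-9)
    assert exact_binom_tail(6, 100, 0.001) < 1e-6  # the 6/100 case really passes


def test_error_tolerant_sites_not_called():
    # 4 errors at 100x has tail ~ 3.8e-6 > 1e-6 under eps=0.01
    snps = call_snps(_pileup_from_counts([[92, 8, 0, 0]]), error_rate=0.01)
    assert len(snps) == 0


def test_multiallelic_reduced_to_top_two():
    snps = call_snps(_pileup_from_counts([[60, 30, 10, 0]]))
    assert len(snps) == 1
    row = snps.iloc[0]
    assert (row["major"], row["minor"]) == ("A", "C")
    assert row["minor_freq"] == pytest.approx(30 / 90)   # third allele excluded
    assert row["coverage"] == 100


def test_invalid_error_rate_fatal():
    with pytest.raises(ValueError):
        call_snps(_pileup_from_counts([[50, 50, 0, 0]]), error_rate=0.0)


# --- effect classification -------------------------------------------------

def _snp_frame(bin_id, pos, major, minor):
    import pandas as pd
    return pd.DataFrame({
        "bin": [bin_id], "pos": [pos], "major": [major], "minor": [minor],
        "major_count": [90], "minor_count": [10], "coverage": [100],
        "minor_freq": [0.1], "p_null": [0.0],
    })


def test_plus_strand_codon_classification():
    #           gene: ATG GCT TAA  (Met Ala stop)
    ref = {"b": encode_seq("ATGGCTTAA")}
    gene = Gene("g1", "b", 0, 9, "+", "genic")
    # GCT -> GCC still Ala: synonymous
    syn = classify_effects(_snp_frame("b", 5, "T", "C"), [gene], ref)
    assert syn["effect"].tolist() == ["synonymous"]
    # GCT -> GTT is Val: nonsynonymous
    non = classify_effects(_snp_frame("b", 4, "C", "T"), [gene], ref)
    assert non["effect"].tolist() == ["nonsynonymous"]


def test_intergenic_and_partial_genes():
    ref = {"b": encode_seq("ATGGCTTAAACGT")}
    gene = Gene("g1", "b", 0, 9, "+", "genic")
    part = Gene("g2", "b", 9, 13, "+", "genic")   # length 4: partial
    inter = classify_effects(_snp_frame("b", 12, "T", "A"), [gene], ref)
    assert inter["effect"].tolist() == ["intergenic"]
    unc = classify_effects(_snp_frame("b", 10, "C", "A"), [gene, part], ref)
    assert unc["effect"].tolist() == ["unclassified"]


def _whole_gene_translation_oracle(seq_codes, gene, pos, minor):
    """Mutate the genome, translate the whole CDS, compare proteins."""
    from Bio.Seq import Seq
    genome = "".join("ACGTN"[c] for c in seq_codes)
    mutated = genome[:pos] + minor + genome[pos + 1:]

    def protein(g):
        cds = g[gene.start:gene.end]
        s = Seq(cds)
        if gene.strand == "-":
            s = s.reverse_complement()
        return str(s.translate(table=11))

    return ("synonymous" if protein(genome) == protein(mutated)
            else "nonsynonymous")


def test_minus_strand_matches_whole_gene_translation_oracle():
    rng = np.random.default_rng(17)
    cfg = CommunityConfig(seed=33, n_bins=1, genome_length=5000,
                          gene_length_range=(150, 300))
    ref = generate_reference(cfg)
    codes = ref.sequences["bin_0"]
    checked = 0
    for gene in ref.genes:
        for _ in range(8):
            pos = int(rng.integers(gene.start, gene.end))
            ref_base = BASES[codes[pos]]
            minor = BASES[(codes[pos] + rng.integers(1, 4)) % 4]
            got = classify_effects(
                _snp_frame("bin_0", pos, ref_base, minor), [gene],
                ref.sequences)["effect"].iloc[0]
            want = _whole_gene_translation_oracle(codes, gene, pos, minor)
            assert got == want, (gene.strand, pos, ref_base, minor)
            checked += 1
    assert checked >= 80


def test_effect_partition_is_exhaustive(small_community, small_pileups):
    _, reference, _, _ = small_community
    piles, _ = small_pileups
    snps = call_snps(piles["p0_s0"])
    eff = classify_effects(snps, reference.genes, reference.sequences)
    # genes are non-overlapping: exactly one row per SNP, each either in a
    # gene (classified) or intergenic
    assert len(eff) == len(snps)
    assert set(eff["effect"]) <= {"synonymous", "nonsynonymous",
                                  "intergenic", "unclassified"}
    in_gene = eff["gene_id"].notna()
    assert (eff.loc[~in_gene, "effect"] == "intergenic").all()
    assert (eff.loc[in_gene, "effect"] != "intergenic").all()


def test_strand_relabeling_invariance(small_community, small_pileups):
    """Reverse-complementing the whole genome must not change the N/S split."""
    _, reference, _, _ = small_community
    piles, _ = small_pileups
    snps = call_snps(piles["p0_s0"])
    eff = classify_effects(snps, reference.genes, reference.sequences)

    L = len(reference.sequences["bin_0"])
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc_codes = encode_seq("".join(
        comp["ACGTN"[c]] for c in reference.sequences["bin_0"][::-1]))
    rc_genes = [
        Gene(g.gene_id, g.bin_id, L - g.end, L - g.start,
             "+" if g.strand == "-" else "-", g.category)
        for g in reference.genes
    ]
    rc_snps = snps.copy()
    rc_snps["pos"] = L - 1 - rc_snps["pos"]
    rc_snps["major"] = rc_snps["major"].map(comp)
    rc_snps["minor"] = rc_snps["minor"].map(comp)
    rc_eff = classify_effects(rc_snps, rc_genes, {"bin_0": rc_codes})

    a = eff.sort_values("pos")["effect"].value_counts().to_dict()
    b = rc_eff.sort_values("pos")["effect"].value_counts().to_dict()
    assert a == b
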