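"""Configuration objects for the simulator, the read filter and pipeline runs.

All coordinates are 0-based half-open internally; files written by the
package use 1-based conventions (SAM, GFF3) as noted per writer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml


@dataclass(frozen=True)
class SweepInterval:
    """A planted selective sweep: a contiguous run of genes in one bin.

    Genes ``gene_start`` .. ``gene_stop - 1`` (indices in genome order) are
    simulated with elevated between-population differentiation (``f_high``)
    and, in every population, one dominant haplotype that removes most
    within-population variation (weight ``1 - diversity_factor``).
    """

    bin_index: int
    gene_start: int
    gene_stop: int
    f_high: float = 0.6
    diversity_factor: float = 0.1

    def __post_init__(self) -> None:
        if not (0 <= self.gene_start < self.gene_stop):
            raise ValueError("need 0 <= gene_start < gene_stop")
        if not (0.0 <= self.f_high < 1.0):
            raise ValueError("f_high must lie in [0, 1)")
        if not (0.0 < self.diversity_factor <= 1.0):
            raise ValueError("diversity_factor must lie in (0, 1]")


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of the synthetic metagenomic community.

    The defaults describe a small hypersaline-mat-like community: a few
    genome bins sequenced as 150 bp paired-end reads, moderate genome-wide
    microdiversity (``within_diversity`` is the expected per-site π over the
    whole genome), and weak background differentiation between the
    populations sampled along the gradient (``target_fst``).
    """

    seed: int
    n_bins: int = 2
    genome_length: int = 50_000
    gc: float = 0.5
    gene_density: float = 0.75
    gene_length_range: tuple[int, int] = (300, 900)
    n_populations: int = 2
    samples_per_population: int = 2
    # ("uniform", lo, hi) or ("beta", a, b): law of the ancestral allele
    # frequency p at segregating sites.
    ancestral_freq_law: tuple = ("uniform", 0.05, 0.95)
    # Balding–Nichols F per population (scalar applied to all, or one per
    # population).  Pairwise Fst between two populations with parameters
    # F_a and F_b is (F_a + F_b) / 2 in expectation.
    target_fst: float | Sequence[float] = 0.05
    # Expected genome-wide per-site nucleotide diversity; sets the number of
    # segregating sites given the ancestral law and F.
    within_diversity: float = 0.01
    sweep_intervals: tuple[SweepInterval, ...] = ()
    n_haplotypes: int = 24
    crossover_rate: float = 0.5
    read_length: int = 150
    insert_mean: float = 350.0
    insert_sd: float = 40.0
    error_rate: float = 0.001
    base_quality: int = 37
    mapping_quality: int = 60
    depth: float = 50.0
    # Optional origin/terminus coverage gradient: coverage declines
    # log-linearly from the origin (position 0) by this factor at the far
    # end of each bin; 1.0 means flat coverage (no active replication).
    coverage_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("gc", "gene_density", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid gene_length_range")
        if self.genome_length < hi:
            raise ValueError("genome_length must be >= max gene length")
        for f in self.fst_per_population():
            if not (0.0 <= f < 1.0):
                raise ValueError("target_fst values must lie in [0, 1)")
        if not (0.0 <= self.within_diversity <= 1.0):
            raise ValueError("within_diversity must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        if self.coverage_ratio <= 0:
            raise ValueError("coverage_ratio must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def fst_per_population(self) -> tuple[float, ...]:
        if isinstance(self.target_fst, (int, float)):
            return (float(self.target_fst),) * self.n_populations
        fs = tuple(float(f) for f in self.target_fst)
        if len(fs) != self.n_populations:
            raise ValueError("target_fst sequence length must equal n_populations")
        return fs

    def sample_names(self) -> list[str]:
        return [
            f"p{p}_s{r}"
            for p in range(self.n_populations)
            for r in range(self.samples_per_population)
        ]

    def population_of(self, sample: str) -> int:
        return int(sample.split("_")[0][1:])


@dataclass(frozen=True)
class FilterConfig:
    """Read-retention rules applied before any population-genetic statistic.

    Defaults follow the common metagenomic strain-analysis practice of
    keeping only read pairs where both mates map to the same scaffold, with
    per-read identity >= 96% and mapping quality strictly greater than 1,
    counting only bases with quality >= 20.
    """

    min_identity: float = 0.96
    min_mapq_exclusive: int = 1
    require_same_scaffold_mates: bool = True
    min_base_quality: int = 20
    # Alternate identity cutoff for sensitivity re-runs (e.g. 0.98).
    ani_mode: float | None = None
    # Count overlapping mate bases once per fragment (higher-quality base
    # wins); switchable because tools differ on this.
    count_overlap_once: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.min_identity <= 1.0):
            raise ValueError("min_identity must lie in (0, 1]")
        if self.min_base_quality < 0:
            raise ValueError("min_base_quality must be >= 0")


@dataclass
class RunConfig:
    """Everything a full pipeline run needs: inputs, sample layout, thresholds."""

    reference_fasta: str
    genes_gff: str
    alignments: dict[str, str]            # sample name -> SAM/BAM path
    populations: dict[str, list[str]]     # population name -> sample names
    comparisons: list[tuple[str, str]]    # population pairs
    output_dir: str
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    min_cov: int = 20
    snp_min_freq: float = 0.05
    error_rate: float = 0.001
    alpha_site: float = 1e-6
    min_span: int = 30
    ld_max_distance: int = 1000
    sweep_window: int = 5
    sweep_k_sd: float = 1.5
    sweep_alpha: float = 0.05
    irep_window: int = 5000
    irep_step: int = 100
    irep_trim: float = 0.05
    irep_min_mean_cov: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        filt = FilterConfig(**raw.pop("filter", {}))
        raw["comparisons"] = [tuple(c) for c in raw.get("comparisons", [])]
        return cls(filter=filt, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["comparisons"] = [list(c) for c in d["comparisons"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [self.reference_fasta, self.genes_gff, *self.alignments.values()]
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")
        known = set(self.alignments)
        for pop, samples in self.populations.items():
            unknown = set(samples) - known
            if unknown:
                raise ValueError(f"population {pop} names unknown samples {unknown}")
        for a, b in self.comparisons:
            if a not in self.populations or b not in self.populations:
                raise ValueError(f"comparison ({a}, {b}) names unknown population")
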