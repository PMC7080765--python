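"""Seeded synthetic fixtures emulating every input of the chip pipeline.

The generators reproduce the statistical structure of the real design
inputs so the whole toolkit is testable offline:

* a genome + gene catalog with category labels and category-specific mean
  gene lengths;
* candidate variant sites Poisson-placed at category-specific densities
  (defaults: SCP 35.2, CSCSP 6.9, AGCP 22.7, DRDRP 16.6, MCP 111.8 SNPs
  per kbp — the published reference-set densities), with pileup fields
  drawn so a configurable fraction fails each site filter;
* a structured variety panel: two subpopulations with Balding–Nichols
  allele-frequency divergence, admixed individuals as frequency mixtures,
  residual heterozygosity ~9.8% and a small no-call rate (the panel the
  chip was validated on averaged 9.79% heterozygosity and a 99.27% call
  rate);
* an F8 RIL population segregating 1:1 with residual per-locus
  heterozygosity (1/2)^7, plus an optional planted fraction of
  3:1-distorted markers.

Every generator takes a seed and is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from chipsmith.gene_catalog import (
    CatalogEntry,
    GeneCategory,
    GeneModel,
    build_reference_catalog,
)
from chipsmith.genotype_qc import MISSING, GenotypeMatrix
from chipsmith.snp_catalog import SiteSummary

__all__ = [
    "CatalogSpec",
    "SiteSpec",
    "PopulationSpec",
    "RilSpec",
    "DEFAULT_DENSITIES",
    "simulate_genome_and_catalog",
    "simulate_snp_sites",
    "simulate_population",
    "simulate_ril",
]

#: published per-category SNP densities (SNPs per kbp of reference sequence)
DEFAULT_DENSITIES: dict[str, float] = {
    "SCP": 35.2,
    "CSCSP": 6.9,
    "AGCP": 22.7,
    "DRDRP": 16.6,
    "MCP": 111.8,
}

_BASES = np.array(list("ACGT"))


@dataclass
class CatalogSpec:
    """Gene-catalog geometry per category."""

    n_genes: dict[str, int] = field(
        default_factory=lambda: {"SCP": 10, "CSCSP": 6, "AGCP": 2, "DRDRP": 3, "MCP": 2}
    )
    mean_gene_length: dict[str, int] = field(
        default_factory=lambda: {
            "SCP": 1214, "CSCSP": 3175, "AGCP": 3214, "DRDRP": 3326, "MCP": 2095,
        }
    )
    upstream_flank_bp: int = 500
    downstream_flank_bp: int = 100
    margin_bp: int = 600  # contig slack on each side so flanks always fit
    exon_count_range: tuple[int, int] = (2, 5)


@dataclass
class SiteSpec:
    """Variant-site generation: densities and per-filter failure fractions."""

    densities: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    fail_coverage: float = 0.05
    fail_reads: float = 0.05
    fail_quality: float = 0.05
    fail_frequency: float = 0.05


@dataclass
class PopulationSpec:
    """Two-subpopulation structured variety panel."""

    n_samples: int = 95
    subpop_sizes: tuple[int, int] = (56, 39)
    admixed_fraction: float = 0.36
    fst: float = 0.25
    het_rate: float = 0.098
    nocall_rate: float = 0.0073
    n_snps: int = 500
    n_chromosomes: int = 11
    chrom_length: int = 1_000_000

    def __post_init__(self) -> None:
        if sum(self.subpop_sizes) != self.n_samples:
            raise ValueError("subpop sizes must sum to n_samples")


@dataclass
class RilSpec:
    """F8 recombinant inbred lines from two homozygous parents."""

    n_lines: int = 94
    n_markers: int = 1000
    f_generation: int = 8
    distortion_fraction: float = 0.0
    distortion_ratio: float = 0.75  # P(parent-A allele) at distorted markers

    @property
    def residual_het(self) -> float:
        return 0.5 ** (self.f_generation - 1)


def simulate_genome_and_catalog(
    spec: CatalogSpec = CatalogSpec(), seed: int = 0
) -> tuple[dict[str, str], list[GeneModel], dict[str, CatalogEntry]]:
    """Random contigs with planted gene models, one contig per gene.

    Returns (genome, gene models, extracted catalog with category labels).
    Gene lengths are normal around the category mean (floored at 400 bp);
    each gene gets 2–4 internal introns.
    """
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    categories: dict[str, GeneCategory] = {}
    for cat in sorted(spec.n_genes):
        mean_len = spec.mean_gene_length[cat]
        for k in range(spec.n_genes[cat]):
            gid = f"{cat}-{k + 1}"
            glen = max(400, int(rng.normal(mean_len, mean_len * 0.2)))
            contig_len = glen + 2 * spec.margin_bp
            contig = "".join(rng.choice(_BASES, size=contig_len))
            start = spec.margin_bp + 1
            end = start + glen - 1
            n_exons = int(rng.integers(*spec.exon_count_range))
            # cut the span into alternating exon/intron blocks
            cuts = np.sort(rng.choice(np.arange(1, glen), size=2 * n_exons - 2, replace=False))
            bounds = [0, *cuts.tolist(), glen]
            exons = []
            for e in range(n_exons):
                a = bounds[2 * e] + start
                b = bounds[2 * e + 1] - 1 + start
                exons.append((a, b))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom = f"ctg_{gid}"
            genome[chrom] = contig
            models.append(
                GeneModel(
                    gene_id=gid, chrom=chrom, strand=strand, start=start, end=end,
                    exons=exons,
                    upstream_flank_bp=spec.upstream_flank_bp,
                    downstream_flank_bp=spec.downstream_flank_bp,
                )
            )
            categories[gid] = GeneCategory(cat)
    catalog = build_reference_catalog(models, genome, categories)
    return genome, models, catalog


def simulate_snp_sites(
    catalog: dict[str, CatalogEntry],
    spec: SiteSpec = SiteSpec(),
    seed: int = 0,
) -> list[SiteSummary]:
    """Poisson-placed candidate sites over a catalog at category densities.

    Pileup fields are drawn in the clearly-passing range, then each site
    independently gets each field pushed below its threshold with the
    configured failure fraction.
    """
    rng = np.random.default_rng(seed)
    sites: list[SiteSummary] = []
    others = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}
    for gid in sorted(catalog):
        entry = catalog[gid]
        density = spec.densities.get(str(entry.category), 10.0)
        n = rng.poisson(density * entry.length_bp / 1000.0)
        n = min(n, entry.length_bp)
        if n == 0:
            continue
        positions = np.sort(rng.choice(entry.length_bp, size=n, replace=False)) + 1
        for p in positions:
            ref = entry.sequence[p - 1].upper()
            if ref not in "ACGT":
                ref = "A"
            alt = others[ref][rng.integers(3)]
            depth = int(rng.integers(12, 60))
            freq = float(rng.uniform(0.10, 1.0))
            alt_reads = max(2, int(round(depth * freq)))
            alt_reads = min(alt_reads, depth)
            qual = float(rng.uniform(28, 40))
            if rng.random() < spec.fail_coverage:
                depth = int(rng.integers(1, 10))
                alt_reads = min(alt_reads, depth)
            if rng.random() < spec.fail_reads:
                alt_reads = int(rng.integers(0, 2))
            if rng.random() < spec.fail_quality:
                qual = float(rng.uniform(5, 25 - 1e-6))
            if rng.random() < spec.fail_frequency:
                freq = float(rng.uniform(0.0, 0.05 - 1e-9))
            sites.append(
                SiteSummary(
                    gene_id=gid, position=int(p), ref_allele=ref, alt_allele=alt,
                    depth=depth, alt_reads=alt_reads,
                    avg_base_quality=round(qual, 1), alt_frequency=round(freq, 4),
                )
            )
    return sites


def simulate_population(
    spec: PopulationSpec = PopulationSpec(), seed: int = 0
) -> tuple[GenotypeMatrix, list[str]]:
    """Structured variety panel: GenotypeMatrix plus true labels.

    Labels are ``pop1``/``pop2`` for pure samples and ``admixed1``/
    ``admixed2`` for admixed ones (suffix = majority ancestry).  Allele
    frequencies per subpopulation follow the Balding–Nichols model with
    differentiation ``fst`` around a uniform(0.2, 0.8) ancestral
    frequency.  Genotypes are homozygous dosages (varieties are mostly
    inbred) with explicit residual-heterozygosity and no-call noise.
    """
    rng = np.random.default_rng(seed)
    p_anc = rng.uniform(0.2, 0.8, size=spec.n_snps)
    if spec.fst > 0:
        a = p_anc * (1 - spec.fst) / spec.fst
        b = (1 - p_anc) * (1 - spec.fst) / spec.fst
        p1 = rng.beta(a, b)
        p2 = rng.beta(a, b)
    else:
        p1 = p2 = p_anc
    pops = [0] * spec.subpop_sizes[0] + [1] * spec.subpop_sizes[1]
    labels: list[str] = []
    calls = np.empty((spec.n_samples, spec.n_snps), dtype=np.int8)
    for i, pop in enumerate(pops):
        own, other = (p1, p2) if pop == 0 else (p2, p1)
        if rng.random() < spec.admixed_fraction:
            alpha = rng.uniform(0.55, 0.8)  # majority own ancestry
            p_ind = alpha * own + (1 - alpha) * other
            labels.append(f"admixed{pop + 1}")
        else:
            p_ind = own
            labels.append(f"pop{pop + 1}")
        g = 2 * (rng.random(spec.n_snps) < p_ind).astype(np.int8)
        het = rng.random(spec.n_snps) < spec.het_rate
        g[het] = 1
        nocall = rng.random(spec.n_snps) < spec.nocall_rate
        g[nocall] = MISSING
        calls[i] = g
    samples = [f"VAR{i + 1:03d}" for i in range(spec.n_samples)]
    per_chrom = int(np.ceil(spec.n_snps / spec.n_chromosomes))
    chroms, poss = [], []
    for j in range(spec.n_snps):
        c = j // per_chrom + 1
        within = j % per_chrom
        step = spec.chrom_length // max(per_chrom, 1)
        chroms.append(f"LG{c}")
        poss.append(within * step + 1)
    snps = [f"SNP{j + 1:05d}" for j in range(spec.n_snps)]
    meta = {"chrom": chroms, "pos": poss,
            "ref": ["A"] * spec.n_snps, "alt": ["B"] * spec.n_snps}
    return GenotypeMatrix(samples, snps, calls, meta), labels


def simulate_ril(
    spec: RilSpec = RilSpec(), seed: int = 0
) -> tuple[GenotypeMatrix, list[str], np.ndarray]:
    """F8 RIL genotype matrix with parent rows ``P1`` (AA) and ``P2`` (BB).

    Markers are independent (no linkage map): each line is AA or BB with
    probability given by the marker's segregation ratio (1:1, or the
    distortion ratio for the planted distorted fraction), and heterozygous
    with the residual F8 probability (1/2)^7.  Returns the matrix, the
    line names, and the boolean mask of distorted markers.
    """
    rng = np.random.default_rng(seed)
    n_distorted = int(round(spec.distortion_fraction * spec.n_markers))
    distorted = np.zeros(spec.n_markers, dtype=bool)
    if n_distorted:
        distorted[rng.choice(spec.n_markers, size=n_distorted, replace=False)] = True
    p_a = np.where(distorted, spec.distortion_ratio, 0.5)
    lines = [f"RIL{i + 1:03d}" for i in range(spec.n_lines)]
    calls = np.empty((spec.n_lines + 2, spec.n_markers), dtype=np.int8)
    calls[0] = 0  # parent A
    calls[1] = 2  # parent B
    for i in range(spec.n_lines):
        g = np.where(rng.random(spec.n_markers) < p_a, 0, 2).astype(np.int8)
        het = rng.random(spec.n_markers) < spec.residual_het
        g[het] = 1
        calls[i + 2] = g
    samples = ["P1", "P2", *lines]
    snps = [f"M{j + 1:05d}" for j in range(spec.n_markers)]
    matrix = GenotypeMatrix(samples, snps, calls,
                            {"ref": ["A"] * spec.n_markers, "alt": ["B"] * spec.n_markers})
    return matrix, lines, distorted
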