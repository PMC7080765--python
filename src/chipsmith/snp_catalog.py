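"""Variant-site filtering, gene-feature annotation and catalog summaries.

Candidate SNP sites come as per-site pileup summaries (depth, supporting
reads, mean base quality, variant allele frequency) produced by a variant
caller.  The caller itself is out of scope; the design pipeline's
contribution is the filter settings applied to its output:

    depth >= 10, alt reads >= 2, mean base quality >= 25, alt frequency >= 0.05

all as inclusive lower bounds, with multiallelic sites rejected outright.

Passing SNPs are then annotated against the gene geometry of the extracted,
flanked reference sequences.  Because the catalog never distinguishes
annotated UTRs from the added 500/100 bp regulatory flanks, everything
upstream of the first exon is classed ``five_prime`` and everything
downstream of the last exon ``three_prime``; positions inside exons are
``exon`` and positions between exons ``intron``.  The four classes
partition every SNP.

Summary statistics mirror a chip design report: per category, SNP density
per kbp, average gene size, SNPs per gene, and shares of the final chip.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from chipsmith.gene_catalog import CatalogEntry, GeneCategory

__all__ = [
    "SiteSummary",
    "SnpRecord",
    "FilterThresholds",
    "CategorySummary",
    "FEATURES",
    "filter_sites",
    "annotate_feature",
    "summarize_catalog",
    "summary_from_counts",
    "snps_per_gene_distribution",
    "round_half_up",
]

FEATURES = ("exon", "intron", "five_prime", "three_prime")

_VALID_BASES = set("ACGT")


@dataclass(frozen=True)
class SiteSummary:
    """Pileup summary for one candidate variant site within a gene."""

    gene_id: str
    position: int  # 1-based offset within the extracted gene sequence
    ref_allele: str
    alt_allele: str
    depth: int
    alt_reads: int
    avg_base_quality: float
    alt_frequency: float


@dataclass(frozen=True)
class SnpRecord:
    gene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    feature: str = ""
    category: GeneCategory = GeneCategory.UNCLASSIFIED


@dataclass(frozen=True)
class FilterThresholds:
    """Inclusive lower bounds applied to each candidate site."""

    min_coverage: int = 10
    min_reads: int = 2
    min_avg_qual: float = 25.0
    min_var_freq: float = 0.05


def site_failure_reasons(site: SiteSummary, thresholds: FilterThresholds) -> list[str]:
    """All reasons a site fails, empty when it passes."""
    reasons = []
    if len(site.ref_allele) != 1 or len(site.alt_allele) != 1 or not (
        set(site.ref_allele + site.alt_allele) <= _VALID_BASES
    ) or "," in site.alt_allele:
        return ["multiallelic"]
    if site.depth < thresholds.min_coverage:
        reasons.append("low_coverage")
    if site.alt_reads < thresholds.min_reads:
        reasons.append("few_alt_reads")
    if site.avg_base_quality < thresholds.min_avg_qual:
        reasons.append("low_quality")
    if site.alt_frequency < thresholds.min_var_freq:
        reasons.append("low_frequency")
    return reasons


def filter_sites(
    sites: Iterable[SiteSummary],
    thresholds: FilterThresholds = FilterThresholds(),
) -> tuple[list[SnpRecord], dict[tuple[str, int], list[str]]]:
    """Apply the four site-quality thresholds.

    Returns the passing sites as :class:`SnpRecord` plus a log mapping
    ``(gene_id, position)`` of every failing site to its reasons.
    """
    passing: list[SnpRecord] = []
    log: dict[tuple[str, int], list[str]] = {}
    for site in sites:
        reasons = site_failure_reasons(site, thresholds)
        if reasons:
            log[(site.gene_id, site.position)] = reasons
        else:
            passing.append(
                SnpRecord(site.gene_id, site.position, site.ref_allele, site.alt_allele)
            )
    return passing, log


def annotate_feature(position: int, entry: CatalogEntry) -> str:
    """Feature class of a position in an extracted gene sequence.

    Geometry only: before the first exon -> ``five_prime``; inside an exon
    -> ``exon``; between exons -> ``intron``; after the last exon ->
    ``three_prime``.  Coordinates are gene-oriented and 1-based.
    """
    if position < 1 or position > entry.length_bp:
        raise ValueError(
            f"{entry.gene_id}: position {position} outside extracted sequence "
            f"of {entry.length_bp} bp"
        )
    exons = entry.exons_local
    if not exons or position < exons[0][0]:
        return "five_prime"
    if position > exons[-1][1]:
        return "three_prime"
    for (a, b) in exons:
        if a <= position <= b:
            return "exon"
    return "intron"


def annotate_records(
    records: Iterable[SnpRecord], catalog: Mapping[str, CatalogEntry]
) -> list[SnpRecord]:
    """Attach feature class and gene category to each passing SNP."""
    out = []
    for r in records:
        if r.gene_id not in catalog:
            raise KeyError(f"SNP references uncatalogued gene {r.gene_id}")
        entry = catalog[r.gene_id]
        out.append(
            SnpRecord(
                r.gene_id,
                r.position,
                r.ref_allele,
                r.alt_allele,
                feature=annotate_feature(r.position, entry),
                category=entry.category,
            )
        )
    return out


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass
class CategorySummary:
    """Derived design-report statistics for one gene category.

    ``n_genes``/``total_length_bp``/``n_snps`` describe the reference set in
    which SNPs were identified; ``chip_*`` fields the subset that survived
    assay design onto the chip (optional).
    """

    category: str
    n_genes: int
    total_length_bp: int
    n_snps: int
    chip_genes: int | None = None
    chip_snps: int | None = None

    @property
    def snp_density_per_kbp(self) -> float:
        return 1000.0 * self.n_snps / self.total_length_bp if self.total_length_bp else 0.0

    @property
    def avg_gene_size_bp(self) -> float:
        return self.total_length_bp / self.n_genes if self.n_genes else 0.0

    @property
    def snps_per_gene(self) -> float:
        return self.n_snps / self.n_genes if self.n_genes else 0.0

    @property
    def bp_per_snp(self) -> float:
        """Average spacing: one SNP every this many base pairs."""
        return self.total_length_bp / self.n_snps if self.n_snps else math.inf

    @property
    def chip_snps_per_gene(self) -> float:
        if not self.chip_genes or self.chip_snps is None:
            return 0.0
        return self.chip_snps / self.chip_genes

    @property
    def gene_inclusion_pct(self) -> float:
        """Percent of the category's reference genes that made the chip."""
        if self.chip_genes is None or not self.n_genes:
            return 0.0
        return 100.0 * self.chip_genes / self.n_genes

    @property
    def snp_inclusion_pct(self) -> float:
        if self.chip_snps is None or not self.n_snps:
            return 0.0
        return 100.0 * self.chip_snps / self.n_snps

    def chip_snp_share_pct(self, total_chip_snps: int) -> float:
        """Percent of all chip SNPs belonging to this category."""
        if not total_chip_snps or self.chip_snps is None:
            return 0.0
        return 100.0 * self.chip_snps / total_chip_snps


def summary_from_counts(
    counts: Mapping[str, Mapping[str, int]]
) -> dict[str, CategorySummary]:
    """Build per-category summaries (plus a ``Total`` row) from raw counts.

    ``counts`` maps category name to a dict with keys ``n_genes``,
    ``total_length_bp``, ``n_snps`` and optionally ``chip_genes``,
    ``chip_snps``.  This is the arithmetic core of a design report: feed it
    the count columns and every derived column follows.
    """
    out: dict[str, CategorySummary] = {}
    tot = {"n_genes": 0, "total_length_bp": 0, "n_snps": 0}
    chip_tot = {"chip_genes": 0, "chip_snps": 0}
    any_chip = False
    for cat, c in counts.items():
        out[cat] = CategorySummary(
            category=cat,
            n_genes=c["n_genes"],
            total_length_bp=c["total_length_bp"],
            n_snps=c["n_snps"],
            chip_genes=c.get("chip_genes"),
            chip_snps=c.get("chip_snps"),
        )
        for k in tot:
            tot[k] += c[k]
        if "chip_genes" in c:
            any_chip = True
            chip_tot["chip_genes"] += c["chip_genes"]
            chip_tot["chip_snps"] += c["chip_snps"]
    out["Total"] = CategorySummary(
        category="Total",
        **tot,
        chip_genes=chip_tot["chip_genes"] if any_chip else None,
        chip_snps=chip_tot["chip_snps"] if any_chip else None,
    )
    return out


def summarize_catalog(
    records: Sequence[SnpRecord],
    catalog: Mapping[str, CatalogEntry],
) -> tuple[dict[str, CategorySummary], dict[str, float]]:
    """Per-category summaries and the feature distribution of a SNP set.

    Every record's gene must be catalogued.  Returns the category summaries
    (keyed by category name plus ``Total``) and the feature share of all
    SNPs in percent (keys ``exon``/``intron``/``five_prime``/``three_prime``).
    """
    counts: dict[str, dict[str, int]] = {}
    for gid, entry in catalog.items():
        c = counts.setdefault(
            str(entry.category), {"n_genes": 0, "total_length_bp": 0, "n_snps": 0}
        )
        c["n_genes"] += 1
        c["total_length_bp"] += entry.length_bp
    for r in records:
        if r.gene_id not in catalog:
            raise KeyError(f"SNP references uncatalogued gene {r.gene_id}")
        counts[str(catalog[r.gene_id].category)]["n_snps"] += 1
    feature_counts = Counter(r.feature for r in records)
    n = len(records)
    features = {f: 100.0 * feature_counts.get(f, 0) / n if n else 0.0 for f in FEATURES}
    return summary_from_counts(counts), features


def snps_per_gene_distribution(records: Iterable[SnpRecord]) -> dict[int, int]:
    """Histogram of genes by their SNP count (gene count per SNP-count bin)."""
    per_gene = Counter(r.gene_id for r in records)
    return dict(Counter(per_gene.values()))
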