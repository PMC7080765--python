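"""Gene categorization and flanked reference-sequence catalog construction.

A genic SNP chip is designed from a reference set of genes partitioned into
five categories:

* ``SCP``   — single-copy genes unique to the target species,
* ``CSCSP`` — single-copy genes conserved with soybean (*Glycine max*),
* ``AGCP``  — homologs of agronomically important cloned genes,
* ``DRDRP`` — disease-resistance / defense-response genes (curated list),
* ``MCP``   — multi-copy control genes (curated list).

Single-copy status is decided from an all-vs-all similarity search of the
gene set against itself: a gene is single copy when its only hit is the
self-match, or when the best non-self hit scores below a bit-score cutoff
(default 200).  Single-copy genes are then split into SCP and CSCSP using
cross-species hits against three legume relatives; AGCP membership comes
from hits of curated cloned-gene queries at a bit score >= 100.

For probe design every catalogued gene is extracted in full length together
with 500 bp of upstream and 100 bp of downstream flanking sequence
(gene-oriented: minus-strand genes are reverse complemented so position 1
is the farthest upstream base).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneCategory",
    "GeneModel",
    "SimilarityHit",
    "CatalogEntry",
    "SC_SECOND_HIT_BITSCORE",
    "AGCP_BITSCORE",
    "CROSS_SPECIES_BITSCORE",
    "classify_single_copy",
    "classify_cross_species",
    "match_agronomic_genes",
    "categorize_genes",
    "build_reference_catalog",
]

#: best non-self bit score below which a gene counts as single copy
SC_SECOND_HIT_BITSCORE = 200.0
#: curated agronomic-gene queries match at a bit score >= this cutoff
AGCP_BITSCORE = 100.0
#: cross-species homology counts as significant at this bit score (configurable)
CROSS_SPECIES_BITSCORE = 100.0


class GeneCategory(str, Enum):
    SCP = "SCP"
    CSCSP = "CSCSP"
    AGCP = "AGCP"
    DRDRP = "DRDRP"
    MCP = "MCP"
    UNCLASSIFIED = "UNCLASSIFIED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular similarity search result."""

    query_id: str
    subject_id: str
    bitscore: float
    species: str = "self-db"

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore for {self.query_id}/{self.subject_id}")


def sort_hits(hits: Iterable[SimilarityHit]) -> list[SimilarityHit]:
    """Deterministic hit order: bitscore descending, subject_id ascending."""
    return sorted(hits, key=lambda h: (-h.bitscore, h.subject_id))


@dataclass
class GeneModel:
    """A gene with 1-based inclusive coordinates (GFF3 convention)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    upstream_flank_bp: int = 500
    downstream_flank_bp: int = 100

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"{self.gene_id}: bad span {self.start}-{self.end}")
        self.exons = sorted(self.exons)
        prev_end = None
        for (a, b) in self.exons:
            if a < self.start or b > self.end or b < a:
                raise ValueError(f"{self.gene_id}: exon {a}-{b} outside span")
            if prev_end is not None and a <= prev_end:
                raise ValueError(f"{self.gene_id}: overlapping exons")
            prev_end = b

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


_COMPLEMENT = str.maketrans("ACGTRYKMBVDHacgtrykmbvdh", "TGCAYRMKVBHDtgcayrmkvbhd")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class CatalogEntry:
    """Extracted, gene-oriented reference sequence for one catalogued gene."""

    gene_id: str
    category: GeneCategory
    sequence: str
    upstream_flank_bp: int      # realized (possibly truncated) flank lengths
    downstream_flank_bp: int
    exons_local: list[tuple[int, int]]  # exon intervals in extracted coordinates
    upstream_truncated: bool = False
    downstream_truncated: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


def classify_single_copy(hits: Sequence[SimilarityHit], cutoff: float = SC_SECOND_HIT_BITSCORE) -> bool:
    """Decide single-copy status for one gene from its self-database hits.

    The hit table must contain the self-match (``query_id == subject_id``);
    its absence signals a malformed search result.  A gene is single copy
    when no other gene in its own genome reaches ``cutoff``: the only hit is
    the self-match, or the best non-self bit score is strictly below 200.
    All non-self hits are inspected, not just the rank-2 one.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("empty hit table: self-match missing")
    query = hits[0].query_id
    if not any(h.subject_id == h.query_id for h in hits):
        raise ValueError(f"{query}: self-match missing from hit table")
    non_self = [h.bitscore for h in hits if h.subject_id != h.query_id]
    return not non_self or max(non_self) < cutoff


def classify_cross_species(
    gene_id: str,
    cross_hits: Iterable[SimilarityHit],
    significance_bitscore: float = CROSS_SPECIES_BITSCORE,
) -> GeneCategory:
    """Split a single-copy gene into SCP / CSCSP from cross-legume hits.

    SCP genes show no significant homology to any of the three relatives
    (*Cicer*, *Glycine*, *Medicago*); CSCSP genes are conserved with
    soybean (a significant *Glycine* hit).  Genes hitting only *Cicer* or
    *Medicago* fit neither published definition and stay UNCLASSIFIED.
    """
    significant = {h.species for h in cross_hits if h.bitscore >= significance_bitscore}
    if not significant:
        return GeneCategory.SCP
    if "glycine" in significant:
        return GeneCategory.CSCSP
    return GeneCategory.UNCLASSIFIED


def match_agronomic_genes(
    curated_hits: Iterable[SimilarityHit], cutoff: float = AGCP_BITSCORE
) -> set[str]:
    """Subject genes hit by any curated cloned-gene query at bitscore >= cutoff."""
    return {h.subject_id for h in curated_hits if h.bitscore >= cutoff}


def categorize_genes(
    gene_ids: Sequence[str],
    self_hits: Mapping[str, Sequence[SimilarityHit]],
    cross_hits: Mapping[str, Sequence[SimilarityHit]],
    agronomic_hits: Iterable[SimilarityHit] = (),
    drdrp_ids: Iterable[str] = (),
    mcp_ids: Iterable[str] = (),
    *,
    sc_cutoff: float = SC_SECOND_HIT_BITSCORE,
    agcp_cutoff: float = AGCP_BITSCORE,
    cross_cutoff: float = CROSS_SPECIES_BITSCORE,
) -> dict[str, GeneCategory]:
    """Assign exactly one category per gene.

    Precedence when memberships overlap: AGCP > DRDRP > MCP > single-copy
    classes.  Genes qualifying for nothing are UNCLASSIFIED, so the result
    is a partition of ``gene_ids``.
    """
    agcp = match_agronomic_genes(agronomic_hits, agcp_cutoff)
    drdrp = set(drdrp_ids)
    mcp = set(mcp_ids)
    out: dict[str, GeneCategory] = {}
    for gid in gene_ids:
        if gid in agcp:
            out[gid] = GeneCategory.AGCP
        elif gid in drdrp:
            out[gid] = GeneCategory.DRDRP
        elif gid in mcp:
            out[gid] = GeneCategory.MCP
        elif gid in self_hits and classify_single_copy(sort_hits(self_hits[gid]), sc_cutoff):
            out[gid] = classify_cross_species(gid, cross_hits.get(gid, ()), cross_cutoff)
        else:
            out[gid] = GeneCategory.UNCLASSIFIED
    return out


def extract_flanked_sequence(model: GeneModel, contig: str) -> CatalogEntry:
    """Extract a gene with flanks from its contig, gene-oriented.

    Plus strand: genomic ``[start-upstream, end+downstream]``.  Minus
    strand: the upstream flank lies genomically 3' of ``end``; the window
    ``[start-downstream, end+upstream]`` is extracted and reverse
    complemented.  Flanks that run off a contig end are truncated and
    flagged.  Exon intervals are re-expressed in extracted (1-based,
    gene-oriented) coordinates.
    """
    n = len(contig)
    if model.start > n or model.end > n:
        raise ValueError(
            f"{model.gene_id}: span {model.start}-{model.end} outside contig of {n} bp"
        )
    up, down = model.upstream_flank_bp, model.downstream_flank_bp
    if model.strand == "+":
        left_want, right_want = up, down
    else:
        left_want, right_want = down, up
    left = min(left_want, model.start - 1)
    right = min(right_want, n - model.end)
    g0, g1 = model.start - left, model.end + right  # genomic window, 1-based incl.
    seq = contig[g0 - 1 : g1]
    if model.strand == "+":
        realized_up, realized_down = left, right
        up_trunc, down_trunc = left < left_want, right < right_want
        exons_local = [(a - g0 + 1, b - g0 + 1) for (a, b) in model.exons]
    else:
        seq = reverse_complement(seq)
        realized_up, realized_down = right, left
        up_trunc, down_trunc = right < right_want, left < left_want
        exons_local = sorted((g1 - b + 1, g1 - a + 1) for (a, b) in model.exons)
    return CatalogEntry(
        gene_id=model.gene_id,
        category=GeneCategory.UNCLASSIFIED,
        sequence=seq,
        upstream_flank_bp=realized_up,
        downstream_flank_bp=realized_down,
        exons_local=exons_local,
        upstream_truncated=up_trunc,
        downstream_truncated=down_trunc,
    )


def build_reference_catalog(
    models: Iterable[GeneModel],
    genome: Mapping[str, str],
    categories: Mapping[str, GeneCategory] | None = None,
) -> dict[str, CatalogEntry]:
    """Extract every gene model with flanks from ``genome`` (contig -> sequence)."""
    catalog: dict[str, CatalogEntry] = {}
    for model in models:
        if model.chrom not in genome:
            raise ValueError(f"{model.gene_id}: contig {model.chrom} not in genome")
        entry = extract_flanked_sequence(model, genome[model.chrom])
        if categories is not None:
            entry.category = categories.get(model.gene_id, GeneCategory.UNCLASSIFIED)
        catalog[model.gene_id] = entry
    return catalog
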