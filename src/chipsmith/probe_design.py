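"""Axiom-style probe candidate construction from filtered genic SNPs.

The assay design stage turns each surviving SNP into a 72-bp "plex": the
SNP sits at base 36 with 35 bp of left and 36 bp of right flank, and the
two alleles are rendered in bracket notation (``...NNN[A/G]NNN...``).  Two
filters shape the funnel:

* **interference** — a target SNP is unusable when any other SNP of the
  same gene lies within 10 bp on either side (positional distance <= 10;
  both partners fail their own window test);
* **geometry** — SNPs closer than 35/36 bp to a sequence end cannot fill
  the plex and are marked ``not_possible``.

Vendors score each plex with a proprietary conversion-probability model
and keep probes scoring > 0.50.  That model is closed, so this module
ships a transparent surrogate designability score: it starts at 1.0 and
multiplies in a penalty of 0.5 for each documented defect (GC content
outside [0.30, 0.70], a homopolymer run of 6+, a flank 16-mer shared with
another gene in the catalog, ambiguity characters in the flanks).  The
>0.50 gate is kept, so a single defect already demotes a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from chipsmith.gene_catalog import CatalogEntry, reverse_complement
from chipsmith.snp_catalog import SnpRecord

__all__ = [
    "ProbeConfig",
    "ProbeCandidate",
    "AttritionReport",
    "interfering_filter",
    "extract_plex",
    "score_candidate",
    "design_pipeline",
    "build_kmer_index",
]


@dataclass(frozen=True)
class ProbeConfig:
    plex_length: int = 72
    snp_offset: int = 36  # 1-based position of the SNP within the plex
    interference_window: int = 10
    score_threshold: float = 0.50
    penalty: float = 0.5
    gc_bounds: tuple[float, float] = (0.30, 0.70)
    homopolymer_run: int = 6
    uniqueness_k: int = 16

    def __post_init__(self) -> None:
        if not (1 <= self.snp_offset <= self.plex_length):
            raise ValueError("snp_offset must lie within the plex")
        if self.interference_window < 0:
            raise ValueError("interference window must be >= 0")

    @property
    def left_flank(self) -> int:
        return self.snp_offset - 1

    @property
    def right_flank(self) -> int:
        return self.plex_length - self.snp_offset


@dataclass
class ProbeCandidate:
    snp_id: str
    gene_id: str
    category: str
    plex: str
    forward_probe: str
    reverse_probe: str
    surrogate_score: float
    status: str  # neutral | recommended | not_recommended | not_possible
    reason: str = ""


@dataclass
class AttritionReport:
    """Stage-by-stage survivor counts of the design funnel."""

    identified: int = 0
    interference_filtered: int = 0
    plex_extracted: int = 0
    recommended: int = 0
    per_stage_drops: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, int]:
        return {
            "identified": self.identified,
            "interference_filtered": self.interference_filtered,
            "plex_extracted": self.plex_extracted,
            "recommended": self.recommended,
        }


def interfering_filter(positions: Sequence[int], window: int = 10) -> list[int]:
    """Positions (one gene, 1-based) surviving the interfering-SNP rule.

    A target survives iff no other SNP lies at distance <= ``window``.  The
    relation is symmetric, so interfering pairs eliminate each other.
    Duplicate positions indicate a malformed catalog.
    """
    pos = sorted(positions)
    if len(set(pos)) != len(pos):
        raise ValueError("duplicate SNP positions within one gene")
    keep = []
    for i, p in enumerate(pos):
        left_ok = i == 0 or p - pos[i - 1] > window
        right_ok = i == len(pos) - 1 or pos[i + 1] - p > window
        if left_ok and right_ok:
            keep.append(p)
    return keep


def extract_plex(sequence: str, snp: SnpRecord, config: ProbeConfig = ProbeConfig()) -> str | None:
    """72-bp plex with bracketed alleles, or None when flanks don't fit."""
    p = snp.position
    if p - config.left_flank < 1 or p + config.right_flank > len(sequence):
        return None
    left = sequence[p - 1 - config.left_flank : p - 1]
    right = sequence[p : p + config.right_flank]
    return f"{left}[{snp.ref_allele}/{snp.alt_allele}]{right}"


def debracket(plex: str, allele: str = "ref") -> str:
    """Collapse bracket notation back to a plain sequence."""
    i, j = plex.index("["), plex.index("]")
    ref, alt = plex[i + 1 : j].split("/")
    return plex[:i] + (ref if allele == "ref" else alt) + plex[j + 1 :]


def build_kmer_index(
    catalog: Mapping[str, CatalogEntry], k: int = 16
) -> dict[str, set[str]]:
    """k-mer -> set of gene_ids containing it, over all catalog sequences."""
    index: dict[str, set[str]] = {}
    for gid, entry in catalog.items():
        seq = entry.sequence.upper()
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], set()).add(gid)
    return index


def _max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def score_candidate(
    plex: str,
    config: ProbeConfig = ProbeConfig(),
    kmer_index: Mapping[str, set[str]] | None = None,
    gene_id: str | None = None,
) -> tuple[float, str]:
    """Surrogate designability score in [0, 1] and the resulting status.

    Each firing penalty multiplies the score by ``config.penalty`` (0.5):
    GC fraction outside bounds, homopolymer run >= 6, a flank 16-mer found
    in another catalog gene (needs ``kmer_index`` + ``gene_id``), and
    non-ACGT characters in the flanks.  Status is ``recommended`` above the
    strict > 0.50 gate, else ``not_recommended``; malformed plexes are
    ``not_possible``.
    """
    try:
        seq = debracket(plex).upper()
    except ValueError:
        return 0.0, "not_possible"
    if len(seq) != config.plex_length:
        raise ValueError(f"plex collapses to {len(seq)} bp, expected {config.plex_length}")
    flanks = plex[: plex.index("[")].upper() + plex[plex.index("]") + 1 :].upper()
    score = 1.0
    gc = sum(seq.count(b) for b in "GC") / len(seq)
    if not (config.gc_bounds[0] <= gc <= config.gc_bounds[1]):
        score *= config.penalty
    if _max_homopolymer(seq) >= config.homopolymer_run:
        score *= config.penalty
    if any(c not in "ACGT" for c in flanks):
        score *= config.penalty
    if kmer_index is not None and gene_id is not None:
        k = config.uniqueness_k
        shared = any(
            kmer_index.get(flanks[i : i + k], set()) - {gene_id}
            for i in range(len(flanks) - k + 1)
        )
        if shared:
            score *= config.penalty
    status = "recommended" if score > config.score_threshold else "not_recommended"
    return score, status


def design_pipeline(
    catalog: Mapping[str, CatalogEntry],
    snps: Iterable[SnpRecord],
    config: ProbeConfig = ProbeConfig(),
    check_uniqueness: bool = True,
) -> tuple[list[ProbeCandidate], AttritionReport]:
    """End-to-end assay design: interference filter, plex extraction, scoring.

    Returns every candidate that reached plex extraction (including
    ``not_possible`` and ``not_recommended`` ones, for auditability) and an
    attrition report with survivor counts at each stage.
    """
    snps = list(snps)
    report = AttritionReport(identified=len(snps))
    by_gene: dict[str, list[SnpRecord]] = {}
    for s in snps:
        if s.gene_id not in catalog:
            raise KeyError(f"SNP references uncatalogued gene {s.gene_id}")
        by_gene.setdefault(s.gene_id, []).append(s)

    survivors: list[SnpRecord] = []
    for gid, gene_snps in by_gene.items():
        keep = set(interfering_filter([s.position for s in gene_snps], config.interference_window))
        survivors.extend(s for s in gene_snps if s.position in keep)
    report.interference_filtered = len(survivors)
    report.per_stage_drops["interference"] = report.identified - len(survivors)

    kmer_index = build_kmer_index(catalog, config.uniqueness_k) if check_uniqueness else None
    candidates: list[ProbeCandidate] = []
    n_extracted = n_recommended = 0
    for s in survivors:
        entry = catalog[s.gene_id]
        snp_id = f"{s.gene_id}_{s.position}"
        plex = extract_plex(entry.sequence, s, config)
        if plex is None:
            candidates.append(
                ProbeCandidate(snp_id, s.gene_id, str(entry.category), "", "", "",
                               0.0, "not_possible", reason="insufficient_flank")
            )
            continue
        n_extracted += 1
        score, status = score_candidate(plex, config, kmer_index, s.gene_id)
        left = plex[: plex.index("[")]
        right = plex[plex.index("]") + 1 :]
        forward = left + s.ref_allele + right
        candidates.append(
            ProbeCandidate(snp_id, s.gene_id, str(entry.category), plex,
                           forward, reverse_complement(forward), score, status)
        )
        n_recommended += status == "recommended"
    report.plex_extracted = n_extracted
    report.per_stage_drops["plex_geometry"] = len(survivors) - n_extracted
    report.recommended = n_recommended
    report.per_stage_drops["score_gate"] = n_extracted - n_recommended
    return candidates, report
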