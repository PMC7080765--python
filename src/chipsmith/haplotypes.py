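"""Gene haplotype extraction, Nei diversity and median-joining networks.

A multi-SNP chip scores several SNPs per gene, so each sample carries a
per-gene haplotype: the concatenation of its alleles across the gene's
SNPs.  Only unambiguous samples are assigned — the default policy drops
any sample with a missing or heterozygous call at the gene (phase within
a heterozygote is unknown without family data).

Haplotype diversity uses Nei's unbiased estimator

    Hd = n / (n - 1) * (1 - sum_i p_i^2)

over haplotype frequencies p_i among the n assigned samples.

Genealogical relationships are drawn as a median-joining network: the
minimum spanning network (union of all minimum spanning trees under
Hamming distance, tolerance epsilon = 0) is augmented with inferred
"median" haplotypes — consensus sequences of close triplets that shorten
the network — and rebuilt until stable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from chipsmith.genotype_qc import MISSING, GenotypeMatrix

__all__ = [
    "HaplotypeTable",
    "extract_gene_haplotypes",
    "haplotype_diversity",
    "minimum_spanning_network",
    "median_joining_network",
    "subset_saturation",
    "hamming",
]


@dataclass
class HaplotypeTable:
    """Per-gene haplotype assignments and frequencies."""

    gene_id: str
    assignments: dict[str, str]  # sample -> haplotype string
    counts: dict[str, int] = field(init=False)
    frequencies: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        c = Counter(self.assignments.values())
        # order: frequency descending, then lexicographic, for stable output
        self.counts = dict(sorted(c.items(), key=lambda kv: (-kv[1], kv[0])))
        n = self.n
        self.frequencies = {h: k / n for h, k in self.counts.items()}

    @property
    def n(self) -> int:
        return len(self.assignments)

    @property
    def haplotypes(self) -> list[str]:
        return list(self.counts)

    @property
    def n_haplotypes(self) -> int:
        return len(self.counts)


def extract_gene_haplotypes(
    matrix: GenotypeMatrix,
    gene_snps: Sequence[str],
    policy: str = "exclude",
    gene_id: str = "",
) -> HaplotypeTable:
    """Concatenate each sample's alleles across a gene's SNPs.

    ``policy="exclude"`` (default) assigns only samples whose calls at the
    gene are all homozygous and non-missing.  ``policy="het-as-missing"``
    keeps every sample, rendering heterozygous and missing calls as ``N``
    (such strings form their own haplotype classes).
    """
    if policy not in ("exclude", "het-as-missing"):
        raise ValueError(f"unknown policy {policy!r}")
    sub = matrix.subset_snps(list(gene_snps))
    ref = sub.snp_meta.get("ref", ["A"] * sub.n_snps)
    alt = sub.snp_meta.get("alt", ["B"] * sub.n_snps)
    assignments: dict[str, str] = {}
    for i, sample in enumerate(sub.samples):
        row = sub.calls[i]
        if policy == "exclude" and np.any((row == 1) | (row == MISSING)):
            continue
        chars = []
        for g, r, a in zip(row, ref, alt):
            if g == 0:
                chars.append(r)
            elif g == 2:
                chars.append(a)
            else:
                chars.append("N")
        assignments[sample] = "".join(chars)
    if not assignments:
        raise ValueError(f"gene {gene_id or gene_snps}: no assignable samples")
    return HaplotypeTable(gene_id=gene_id, assignments=assignments)


def haplotype_diversity(table: HaplotypeTable | Mapping[str, float], n: int | None = None) -> float:
    """Nei's haplotype diversity Hd = n/(n-1) * (1 - sum p_i^2)."""
    if isinstance(table, HaplotypeTable):
        freqs = list(table.frequencies.values())
        n = table.n
    else:
        freqs = list(table.values())
        if n is None:
            raise ValueError("n required when passing raw frequencies")
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    total = sum(freqs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError("frequencies must sum to 1")
    return n / (n - 1) * (1.0 - sum(p * p for p in freqs))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("haplotypes of unequal length")
    return sum(x != y for x, y in zip(a, b))


def minimum_spanning_network(haps: Sequence[str]) -> nx.Graph:
    """Union of all minimum spanning trees under Hamming distance.

    Kruskal by distance class: an edge (u, v) enters iff u and v are not
    already connected using only strictly shorter edges — exactly the
    condition for (u, v) to belong to some MST.
    """
    haps = sorted(set(haps))
    g = nx.Graph()
    g.add_nodes_from(haps)
    if len(haps) < 2:
        return g
    edges = sorted(
        (hamming(u, v), u, v) for i, u in enumerate(haps) for v in haps[i + 1 :]
    )
    comp = nx.Graph()
    comp.add_nodes_from(haps)
    i = 0
    while i < len(edges):
        j = i
        cls = []
        while j < len(edges) and edges[j][0] == edges[i][0]:
            d, u, v = edges[j]
            if not nx.has_path(comp, u, v):
                cls.append((u, v, d))
            j += 1
        for u, v, d in cls:
            g.add_edge(u, v, weight=d)
            comp.add_edge(u, v)
        i = j
    return g


def _median(u: str, v: str, w: str) -> str:
    """Positionwise majority consensus; three-way ties resolved from the
    lexicographically smallest of the three strings (deterministic)."""
    first = min(u, v, w)
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            out.append(first[len(out)])
    return "".join(out)


def median_joining_network(
    table: HaplotypeTable | Sequence[str],
    epsilon: int = 0,
    max_rounds: int = 20,
) -> nx.Graph:
    """Median-joining haplotype network (epsilon = 0).

    Starting from the minimum spanning network, every triplet (u, v, w)
    with u and w both adjacent to v is offered a consensus median m; m is
    added when it is new and strictly cheaper as a Steiner point, i.e.
    d(u,m) + d(v,m) + d(w,m) < cost of the triplet's own spanning tree.
    The network is rebuilt over the enlarged node set until no median is
    accepted.  Nodes carry ``frequency`` (0 for medians) and ``median``
    flags; edge ``weight`` is the Hamming distance.
    """
    if epsilon != 0:
        raise NotImplementedError("only epsilon = 0 is supported")
    if isinstance(table, HaplotypeTable):
        observed = table.haplotypes
        freqs = table.counts
    else:
        observed = sorted(set(table))
        freqs = Counter(table)
    if not observed:
        raise ValueError("no haplotypes")
    length = len(observed[0])
    for h in observed:
        if len(h) != length:
            raise ValueError("haplotypes of unequal length")
    nodes = sorted(set(observed))
    for _ in range(max_rounds):
        msn = minimum_spanning_network(nodes)
        new: set[str] = set()
        for v in msn.nodes:
            nbrs = sorted(msn.neighbors(v))
            for a in range(len(nbrs)):
                for b in range(a + 1, len(nbrs)):
                    u, w = nbrs[a], nbrs[b]
                    m = _median(u, v, w)
                    if m in nodes or m in new:
                        continue
                    star = hamming(u, m) + hamming(v, m) + hamming(w, m)
                    pair = sorted([hamming(u, v), hamming(v, w), hamming(u, w)])
                    if star < pair[0] + pair[1]:
                        new.add(m)
        if not new:
            break
        nodes = sorted(set(nodes) | new)
    g = minimum_spanning_network(nodes)
    observed_set = set(observed)
    for h in g.nodes:
        g.nodes[h]["median"] = h not in observed_set
        g.nodes[h]["frequency"] = freqs.get(h, 0)
    return g


def subset_saturation(
    matrix: GenotypeMatrix,
    gene_snps: Sequence[str],
    sizes: Sequence[int],
    replicates: int = 1,
    seed: int = 0,
    policy: str = "exclude",
    gene_id: str = "",
) -> dict[tuple[int, int], int]:
    """Haplotype counts from random SNP subsets of one gene.

    For each requested subset size and replicate, draw that many of the
    gene's SNPs without replacement (seeded) and count the haplotypes they
    resolve.  A subset equal to the full SNP set reproduces the gene's
    total haplotype count; any subset resolves at most as many haplotypes
    as the full set (coarsening property).
    """
    gene_snps = list(gene_snps)
    rng = np.random.default_rng(seed)
    out: dict[tuple[int, int], int] = {}
    for size in sizes:
        if size < 1 or size > len(gene_snps):
            raise ValueError(f"subset size {size} outside [1, {len(gene_snps)}]")
        for rep in range(replicates):
            if size == len(gene_snps):
                chosen = gene_snps
            else:
                idx = rng.choice(len(gene_snps), size=size, replace=False)
                chosen = [gene_snps[int(k)] for k in sorted(idx)]
            t = extract_gene_haplotypes(matrix, chosen, policy=policy, gene_id=gene_id)
            out[(size, rep)] = t.n_haplotypes
    return out
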