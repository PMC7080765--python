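"""Diversity analysis: IBS distances, neighbor-joining, SNP subsetting, exports.

The diversity workflow mirrors chip-validation practice: restrict to SNPs
with 100% call rate, compute pairwise identity-by-state (IBS) distances
(one minus the shared-allele proportion, a heterozygote sharing half an
allele with either homozygote), build an unrooted neighbor-joining tree,
and select a small genome-wide set of unlinked, informative SNPs (three
per chromosome, MAF >= 0.3) for model-based structure analysis, exported
in STRUCTURE and PLINK text formats.

Neighbor joining is the classic Saitou–Nei agglomeration: at each step the
pair minimising Q(i, j) = (n-2) d(i,j) - r_i - r_j is joined (ties broken
by the lowest index pair), branch lengths follow the standard formulas,
and the reduced distances are d(u,k) = (d(i,k) + d(j,k) - d(i,j)) / 2.  On
an additive (tree-like) distance matrix this recovers the generating tree
exactly, topology and branch lengths.
"""

from __future__ import annotations

import warnings as _warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode

from chipsmith.genotype_qc import MISSING, GenotypeMatrix, minor_allele_frequency

__all__ = [
    "select_full_callrate_snps",
    "ibs_distance",
    "neighbor_joining",
    "select_unlinked_subset",
    "export_structure",
    "export_plink",
    "import_plink",
]


def select_full_callrate_snps(matrix: GenotypeMatrix) -> list[str]:
    """SNP IDs with no missing call in any sample."""
    full = (matrix.calls != MISSING).all(axis=0)
    return [s for s, ok in zip(matrix.snps, full) if ok]


def ibs_distance(matrix: GenotypeMatrix, subset: Sequence[str] | None = None) -> DistanceMatrix:
    """Pairwise IBS distance: 1 - mean shared-allele proportion.

    Per SNP the shared proportion between dosages g, h is ``1 - |g - h|/2``
    (identical genotypes share 1, AA vs AB shares 0.5, AA vs BB shares 0),
    averaged over jointly non-missing SNPs.  A pair with no jointly called
    SNP is an error.
    """
    m = matrix if subset is None else matrix.subset_snps(list(subset))
    if m.n_snps == 0:
        raise ValueError("empty SNP subset")
    calls = m.calls.astype(float)
    called = calls != MISSING
    n = m.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = called[i] & called[j]
            if not both.any():
                raise ValueError(f"samples {m.samples[i]!r} and {m.samples[j]!r} share no called SNPs")
            shared = 1.0 - np.abs(calls[i, both] - calls[j, both]) / 2.0
            d[i, j] = d[j, i] = 1.0 - shared.mean()
    return DistanceMatrix(d, ids=m.samples)


def neighbor_joining(dm: DistanceMatrix | np.ndarray, ids: Sequence[str] | None = None) -> TreeNode:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Accepts a scikit-bio DistanceMatrix or a square symmetric array plus
    ``ids``.  Returns an unrooted tree as a scikit-bio TreeNode (the last
    join leaves a trifurcating root).  Negative branch lengths are kept as
    computed.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data.astype(float).copy()
        names = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float).copy()
        if ids is None:
            raise ValueError("ids required with a plain array")
        names = list(ids)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: list[TreeNode] = [TreeNode(name=name) for name in names]

    while len(nodes) > 2:
        n = len(nodes)
        r = d.sum(axis=1)
        # r_i + r_j first: addition commutes exactly, keeping Q bit-symmetric
        q = (n - 2) * d - (r[:, None] + r[None, :])
        np.fill_diagonal(q, np.inf)
        # lowest-index (i, j) pair among the minima of Q
        qmin = q.min()
        i, j = min(
            (int(a), int(b))
            for a, b in zip(*np.nonzero(q == qmin))
            if a < b
        )
        dij = d[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = dij - li
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent.append(ci)
        parent.append(cj)
        dnew = 0.5 * (d[i, :] + d[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.empty((len(keep) + 1, len(keep) + 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d2[-1, -1] = 0.0
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    a, b = nodes
    dist = float(d[0, 1])
    if len(a.children) == 0 and len(b.children) > 0:
        a, b = b, a
    if len(a.children) > 0:
        b.length = dist
        a.append(b)
        root = a
    else:  # two-taxon tree
        root = TreeNode()
        a.length, b.length = 0.0, dist
        root.append(a)
        root.append(b)
    return root


def select_unlinked_subset(
    matrix: GenotypeMatrix,
    per_chrom: int = 3,
    maf_min: float = 0.30,
) -> list[str]:
    """Genome-wide unlinked SNP subset: ``per_chrom`` anchors per chromosome.

    Chromosome/position metadata must be in ``matrix.snp_meta`` under
    ``chrom``/``pos``.  Anchor points are evenly spread over each
    chromosome's covered interval (for the default 3: start, midpoint and
    end — a proxy for telomere/centromere placement); for each anchor the
    qualifying candidate (MAF >= ``maf_min``) nearest to it is taken, ties
    to the smaller position.  A SNP is selected at most once, so sparse
    chromosomes contribute fewer SNPs (with a warning).
    """
    if "chrom" not in matrix.snp_meta or "pos" not in matrix.snp_meta:
        raise ValueError("snp_meta must provide 'chrom' and 'pos'")
    maf = minor_allele_frequency(matrix)
    chroms = matrix.snp_meta["chrom"]
    pos = matrix.snp_meta["pos"]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for idx, (c, p) in enumerate(zip(chroms, pos)):
        by_chrom.setdefault(str(c), []).append((int(p), idx))
    selected: list[str] = []
    for c in sorted(by_chrom):
        sites = sorted(by_chrom[c])
        qualifying = [(p, idx) for p, idx in sites if maf[idx] >= maf_min]
        if not qualifying:
            _warnings.warn(f"chromosome {c}: no SNP with MAF >= {maf_min}", stacklevel=2)
            continue
        lo, hi = sites[0][0], sites[-1][0]
        if per_chrom == 1:
            anchors = [(lo + hi) / 2.0]
        else:
            anchors = [lo + k * (hi - lo) / (per_chrom - 1) for k in range(per_chrom)]
        chosen: list[int] = []
        for anchor in anchors:
            best = min(qualifying, key=lambda t: (abs(t[0] - anchor), t[0]))
            if best[1] not in chosen:
                chosen.append(best[1])
        if len(chosen) < per_chrom:
            _warnings.warn(
                f"chromosome {c}: only {len(chosen)} distinct qualifying SNP(s)",
                stacklevel=2,
            )
        selected.extend(matrix.snps[i] for i in chosen)
    return selected


def bipartition_accuracy(
    tree: TreeNode,
    labels: dict[str, str],
    groups: tuple[str, str] = ("pop1", "pop2"),
) -> float:
    """How well the tree's best edge separates two known groups.

    Only samples labelled with one of ``groups`` are scored (admixed or
    unlabelled tips are ignored).  Every internal edge induces a
    bipartition of those samples; the returned value is the best fraction
    of samples placed on the majority side of their group, over all edges
    and both group orientations.  1.0 means some edge splits the groups
    perfectly.
    """
    pure = {s for s, l in labels.items() if l in groups}
    if not pure:
        raise ValueError("no samples carry the requested group labels")
    best = 0.0
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()} & pure
        other = pure - side
        for a, b in (groups, groups[::-1]):
            correct = sum(labels[s] == a for s in side) + sum(labels[s] == b for s in other)
            best = max(best, correct / len(pure))
    return best


def _alleles(matrix: GenotypeMatrix) -> list[tuple[str, str]]:
    ref = matrix.snp_meta.get("ref", ["A"] * matrix.n_snps)
    alt = matrix.snp_meta.get("alt", ["B"] * matrix.n_snps)
    return list(zip(ref, alt))


def export_structure(
    matrix: GenotypeMatrix, path: str | Path, subset: Sequence[str] | None = None
) -> None:
    """Write a STRUCTURE main input file (two rows per individual, -9 missing).

    Alleles are coded 1 (ref) / 2 (alt).  The first line lists marker names.
    """
    m = matrix if subset is None else matrix.subset_snps(list(subset))
    rows = []
    rows.append(" ".join(m.snps))
    for i, sample in enumerate(m.samples):
        first, second = [], []
        for g in m.calls[i]:
            if g == MISSING:
                first.append("-9"); second.append("-9")
            else:
                first.append("1" if g <= 1 else "2")
                second.append("1" if g == 0 else "2")
        rows.append(sample.replace(" ", "_") + " " + " ".join(first))
        rows.append(sample.replace(" ", "_") + " " + " ".join(second))
    Path(path).write_text("\n".join(rows) + "\n")


def export_plink(matrix: GenotypeMatrix, ped_path: str | Path, map_path: str | Path) -> None:
    """Write PLINK .ped/.map text files (missing genotype = ``0 0``)."""
    alleles = _alleles(matrix)
    chrom = matrix.snp_meta.get("chrom", ["0"] * matrix.n_snps)
    pos = matrix.snp_meta.get("pos", list(range(1, matrix.n_snps + 1)))
    with open(map_path, "w") as fh:
        for s, c, p in zip(matrix.snps, chrom, pos):
            fh.write(f"{c}\t{s}\t0\t{p}\n")
    with open(ped_path, "w") as fh:
        for i, sample in enumerate(matrix.samples):
            fields = [sample.replace(" ", "_"), sample.replace(" ", "_"), "0", "0", "0", "-9"]
            for (ref, alt), g in zip(alleles, matrix.calls[i]):
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [ref, ref]
                elif g == 1:
                    fields += [ref, alt]
                else:
                    fields += [alt, alt]
            fh.write("\t".join(fields) + "\n")


def import_plink(
    ped_path: str | Path,
    map_path: str | Path,
    ref_alleles: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Read PLINK .ped/.map back into a GenotypeMatrix.

    The ped format does not say which allele is the reference; by default
    the alphabetically smaller observed allele is taken as ref (so the
    exporter's default A/B labels round-trip losslessly).  Pass
    ``ref_alleles`` to override per SNP.
    """
    snps, chroms, poss = [], [], []
    for line in Path(map_path).read_text().splitlines():
        if not line.strip():
            continue
        c, s, _, p = line.split()[:4]
        snps.append(s); chroms.append(c); poss.append(int(p))
    samples: list[str] = []
    raw: list[list[tuple[str, str]]] = []
    for line in Path(ped_path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        samples.append(parts[1])
        gts = parts[6:]
        if len(gts) != 2 * len(snps):
            raise ValueError(f"sample {parts[1]}: expected {2*len(snps)} allele fields")
        raw.append([(gts[2 * k], gts[2 * k + 1]) for k in range(len(snps))])
    refs: list[str] = []
    alts: list[str] = []
    for k in range(len(snps)):
        seen = sorted({a for row in raw for a in row[k] if a != "0"})
        if ref_alleles is not None:
            ref = ref_alleles[k]
            others = [a for a in seen if a != ref]
            alt = others[0] if others else "B"
        else:
            ref = seen[0] if seen else "A"
            alt = seen[1] if len(seen) > 1 else ("B" if ref != "B" else "A")
        refs.append(ref); alts.append(alt)
    calls = np.full((len(samples), len(snps)), MISSING, dtype=np.int8)
    for i, row in enumerate(raw):
        for k, (a1, a2) in enumerate(row):
            if a1 == "0" or a2 == "0":
                continue
            calls[i, k] = int(a1 != refs[k]) + int(a2 != refs[k])
    return GenotypeMatrix(
        samples=samples,
        snps=snps,
        calls=calls,
        snp_meta={"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
    )
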