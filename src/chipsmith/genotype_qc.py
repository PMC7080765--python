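"""Chip genotype-call quality control.

Calls are held in a :class:`GenotypeMatrix` — samples x SNPs, biallelic
coding ``0`` (AA), ``1`` (AB), ``2`` (BB), ``-1`` (NoCall).  QC metrics are
the standard array-validation set: call rate per sample or marker (with a
count above a 95.5% gate), per-sample heterozygosity, duplicate-sample
concordance, and minor allele frequency.

For recombinant-inbred-line (RIL) populations the module implements the
marker filter used before linkage mapping: keep markers homozygous and
polymorphic between the parents, treat residual heterozygous calls in the
lines as missing (at F8 a locus is heterozygous with probability (1/2)^7,
so true hets are rare), and test the homozygous counts against the
expected 1:1 segregation with a df=1 chi-square, discarding markers with
P < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "SegregationTest",
    "call_rate",
    "heterozygosity",
    "concordance",
    "minor_allele_frequency",
    "segregation_test",
    "ril_marker_filter",
]

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for samples x SNPs.

    ``snp_meta`` optionally carries per-SNP metadata columns such as
    ``chrom``/``pos``/``gene_id`` and per-SNP allele labels
    (``ref``/``alt``) used by the PLINK/STRUCTURE exporters.
    """

    samples: list[str]
    snps: list[str]
    calls: np.ndarray  # shape (n_samples, n_snps), int, values {0,1,2,-1}
    snp_meta: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.snps)})"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls must be coded {0, 1, 2, -1}")
        for k, v in self.snp_meta.items():
            if len(v) != len(self.snps):
                raise ValueError(f"snp_meta[{k!r}] length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def subset_snps(self, snp_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.snps.index(s) for s in snp_ids]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            calls=self.calls[:, idx].copy(),
            snp_meta={k: [v[i] for i in idx] for k, v in self.snp_meta.items()},
        )


def call_rate(
    matrix: GenotypeMatrix, axis: str = "sample", threshold: float = 0.955
) -> tuple[np.ndarray, int]:
    """Fraction of non-missing calls per sample or per SNP.

    Returns the rates and the count of samples/SNPs whose rate exceeds
    ``threshold`` (strict >, the published "call rates of >95.5%" gate).
    """
    if matrix.calls.size == 0:
        raise ValueError("empty genotype matrix")
    ax = {"sample": 1, "snp": 0}[axis]
    rates = (matrix.calls != MISSING).mean(axis=ax)
    return rates, int((rates > threshold).sum())


def heterozygosity(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-sample fraction of heterozygous calls among non-missing calls.

    Samples with no called genotypes get NaN.
    """
    called = matrix.calls != MISSING
    n_called = called.sum(axis=1)
    n_het = (matrix.calls == 1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        return np.where(n_called > 0, n_het / np.maximum(n_called, 1), np.nan)


def concordance(matrix: GenotypeMatrix, sample_a: str, sample_b: str) -> float:
    """Agreement fraction between two samples over jointly called SNPs."""
    a = matrix.calls[matrix.sample_index(sample_a)]
    b = matrix.calls[matrix.sample_index(sample_b)]
    both = (a != MISSING) & (b != MISSING)
    if not both.any():
        raise ValueError(f"samples {sample_a!r} and {sample_b!r} share no called SNPs")
    return float((a[both] == b[both]).mean())


def minor_allele_frequency(matrix: GenotypeMatrix, snp: str | int | None = None) -> np.ndarray | float:
    """MAF in [0, 0.5] per SNP (or for one SNP), from allele counts.

    Monomorphic or fully missing markers get MAF 0.
    """
    calls = matrix.calls
    called = calls != MISSING
    n_alleles = 2 * called.sum(axis=0)
    alt = np.where(called, calls, 0).sum(axis=0)  # alt dosage sum
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), 0.0)
    maf = np.minimum(f, 1.0 - f)
    maf = np.where(n_alleles > 0, maf, 0.0)
    if snp is None:
        return maf
    i = snp if isinstance(snp, int) else matrix.snps.index(snp)
    return float(maf[i])


@dataclass(frozen=True)
class SegregationTest:
    """1:1 segregation chi-square for one marker (homozygous calls only)."""

    marker_id: str
    n_AA: int
    n_BB: int
    chi_square: float
    p_value: float
    keep: bool
    reason: str = ""


def segregation_test(marker_id: str, n_AA: int, n_BB: int, alpha: float = 0.05) -> SegregationTest:
    """Goodness of fit of homozygous counts against 1:1, df=1, no continuity
    correction.  ``keep`` iff P >= alpha."""
    n = n_AA + n_BB
    if n == 0:
        return SegregationTest(marker_id, 0, 0, float("nan"), float("nan"), False, "no_calls")
    chi2 = (n_AA - n_BB) ** 2 / n
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTest(marker_id, n_AA, n_BB, chi2, p, p >= alpha)


def ril_marker_filter(
    matrix: GenotypeMatrix,
    parent_a: str,
    parent_b: str,
    alpha: float = 0.05,
) -> tuple[list[str], list[SegregationTest]]:
    """RIL marker filter: parental polymorphism + 1:1 segregation.

    A marker passes to testing only when both parents are called,
    homozygous and different; heterozygous line calls are treated as
    missing.  Returns the kept marker IDs and a test record per marker
    (excluded markers carry a reason and ``keep=False``).
    """
    ia, ib = matrix.sample_index(parent_a), matrix.sample_index(parent_b)
    lines = [i for i in range(matrix.n_samples) if i not in (ia, ib)]
    kept: list[str] = []
    tests: list[SegregationTest] = []
    for j, marker in enumerate(matrix.snps):
        pa, pb = int(matrix.calls[ia, j]), int(matrix.calls[ib, j])
        if pa == MISSING or pb == MISSING:
            tests.append(SegregationTest(marker, 0, 0, float("nan"), float("nan"), False, "parent_missing"))
            continue
        if pa == 1 or pb == 1:
            tests.append(SegregationTest(marker, 0, 0, float("nan"), float("nan"), False, "parent_heterozygous"))
            continue
        if pa == pb:
            tests.append(SegregationTest(marker, 0, 0, float("nan"), float("nan"), False, "monomorphic_parents"))
            continue
        col = matrix.calls[lines, j]
        n_a = int((col == pa).sum())
        n_b = int((col == pb).sum())
        t = segregation_test(marker, n_a, n_b, alpha)
        tests.append(t)
        if t.keep:
            kept.append(marker)
    return kept, tests
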