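"""Published count columns of the pigeonpea 62 K 'CcSNPnks' genic-SNP array.

These are the raw counts of the published design report for the pigeonpea
62 K Axiom chip: per gene category, the number of reference genes, their
total extracted length, SNPs identified by re-sequencing 45 varieties, and
the genes/SNPs that survived assay design onto the chip; plus the feature
distribution of the 62,053 chip SNPs.  Only counts are stored — every
derived statistic (densities, per-gene means, shares, inclusion rates) is
recomputed by :func:`chipsmith.snp_catalog.summary_from_counts`.
"""

from __future__ import annotations

__all__ = ["CCSNPNKS_CATEGORY_COUNTS", "CCSNPNKS_FEATURE_COUNTS"]

#: category -> raw design-report counts
CCSNPNKS_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "SCP": {
        "n_genes": 10_064,
        "total_length_bp": 12_218_733,
        "n_snps": 430_380,
        "chip_genes": 4_314,
        "chip_snps": 24_537,
    },
    "CSCSP": {
        "n_genes": 5_899,
        "total_length_bp": 18_726_973,
        "n_snps": 130_439,
        "chip_genes": 4_328,
        "chip_snps": 27_291,
    },
    "AGCP": {
        "n_genes": 192,
        "total_length_bp": 617_039,
        "n_snps": 13_979,
        "chip_genes": 156,
        "chip_snps": 1_536,
    },
    "DRDRP": {
        "n_genes": 874,
        "total_length_bp": 2_907_123,
        "n_snps": 48_387,
        "chip_genes": 746,
        "chip_snps": 8_090,
    },
    "MCP": {
        "n_genes": 96,
        "total_length_bp": 201_088,
        "n_snps": 22_477,
        "chip_genes": 85,
        "chip_snps": 599,
    },
}

#: distribution of the 62,053 chip SNPs over gene features
CCSNPNKS_FEATURE_COUNTS: dict[str, int] = {
    "exon": 17_957,
    "intron": 20_506,
    "five_prime": 17_102,
    "three_prime": 6_488,
}
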