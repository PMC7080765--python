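"""Readers and writers for the toolkit's standard file dialects.

FASTA via Biopython, GFF3 gene models via gffutils, candidate sites as
VCF 4.2 (read through cyvcf2) or a TSV fallback, similarity hits as
12-column tabular text, genotype matrices and manifests as TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from chipsmith.gene_catalog import CatalogEntry, GeneModel, SimilarityHit
from chipsmith.genotype_qc import GenotypeMatrix
from chipsmith.probe_design import AttritionReport, ProbeCandidate
from chipsmith.snp_catalog import SiteSummary

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gene_models_gff3",
    "write_gff3",
    "read_similarity_hits",
    "read_sites_vcf",
    "write_sites_vcf",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_genotype_tsv",
    "write_genotype_tsv",
    "write_catalog_manifest",
    "write_probe_manifest",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_gene_models_gff3(
    path: str | Path, upstream_flank_bp: int = 500, downstream_flank_bp: int = 100
) -> list[GeneModel]:
    """Gene models (gene features + exon children) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        exons = [(e.start, e.end) for e in db.children(gene, featuretype="exon")]
        gid = gene.attributes.get("ID", [gene.id])[0]
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons,
                upstream_flank_bp=upstream_flank_bp,
                downstream_flank_bp=downstream_flank_bp,
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\tchipsmith\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for k, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\tchipsmith\texon\t{a}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{k};Parent={m.gene_id}\n"
                )


def read_similarity_hits(path: str | Path, species: str = "self-db") -> list[SimilarityHit]:
    """12-column tabular similarity results (qseqid sseqid ... bitscore)."""
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 12:
            raise ValueError(f"expected 12 columns, got {len(f)}: {line[:60]!r}")
        hits.append(SimilarityHit(query_id=f[0], subject_id=f[1], bitscore=float(f[11]),
                                  species=species))
    return hits


_VCF_HEADER = """##fileformat=VCFv4.2
##source=chipsmith
##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=AR,Number=1,Type=Integer,Description="Reads supporting the alternate allele">
##INFO=<ID=ABQ,Number=1,Type=Float,Description="Average base quality">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_sites_vcf(sites: Iterable[SiteSummary], path: str | Path) -> None:
    """Candidate sites as VCF 4.2; CHROM is the gene id, POS the offset in
    the extracted gene sequence."""
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for s in sites:
            info = f"DP={s.depth};AR={s.alt_reads};ABQ={s.avg_base_quality};AF={s.alt_frequency}"
            fh.write(f"{s.gene_id}\t{s.position}\t.\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t{info}\n")


def read_sites_vcf(path: str | Path) -> list[SiteSummary]:
    from cyvcf2 import VCF

    sites = []
    for v in VCF(str(path)):
        alt = v.ALT[0] if v.ALT else ""
        if len(v.ALT) > 1:
            alt = ",".join(v.ALT)  # multiallelic, rejected downstream
        sites.append(
            SiteSummary(
                gene_id=v.CHROM,
                position=v.POS,
                ref_allele=v.REF,
                alt_allele=alt,
                depth=int(v.INFO.get("DP", 0)),
                alt_reads=int(v.INFO.get("AR", 0)),
                avg_base_quality=float(v.INFO.get("ABQ", 0.0)),
                alt_frequency=float(v.INFO.get("AF", 0.0)),
            )
        )
    return sites


_SITE_COLS = ["gene_id", "position", "ref_allele", "alt_allele",
              "depth", "alt_reads", "avg_base_quality", "alt_frequency"]


def write_sites_tsv(sites: Iterable[SiteSummary], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in sites], columns=_SITE_COLS).to_csv(
        path, sep="\t", index=False
    )


def read_sites_tsv(path: str | Path) -> list[SiteSummary]:
    df = pd.read_csv(path, sep="\t")
    return [
        SiteSummary(
            gene_id=str(r.gene_id), position=int(r.position),
            ref_allele=str(r.ref_allele), alt_allele=str(r.alt_allele),
            depth=int(r.depth), alt_reads=int(r.alt_reads),
            avg_base_quality=float(r.avg_base_quality),
            alt_frequency=float(r.alt_frequency),
        )
        for r in df.itertuples()
    ]


def write_genotype_tsv(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Samples x SNPs call matrix ({0,1,2,-1}) as TSV, samples as index."""
    pd.DataFrame(matrix.calls, index=matrix.samples, columns=matrix.snps).to_csv(
        path, sep="\t", index_label="sample"
    )


def read_genotype_tsv(path: str | Path, meta_path: str | Path | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta: dict[str, list] = {}
    if meta_path is not None:
        md = pd.read_csv(meta_path, sep="\t").set_index("snp").loc[list(df.columns)]
        meta = {c: md[c].tolist() for c in md.columns}
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        snps=[str(c) for c in df.columns],
        calls=df.to_numpy(dtype=np.int8),
        snp_meta=meta,
    )


def write_catalog_manifest(catalog: Mapping[str, CatalogEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["gene_id", "category", "length_bp",
                    "upstream_truncated", "downstream_truncated"])
        for gid in sorted(catalog):
            e = catalog[gid]
            w.writerow([gid, str(e.category), e.length_bp,
                        int(e.upstream_truncated), int(e.downstream_truncated)])


def write_probe_manifest(
    candidates: Sequence[ProbeCandidate], report: AttritionReport, path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["snp_id", "gene_id", "category", "plex", "forward_probe",
                    "reverse_probe", "surrogate_score", "status", "reason"])
        for c in candidates:
            w.writerow([c.snp_id, c.gene_id, c.category, c.plex, c.forward_probe,
                        c.reverse_probe, f"{c.surrogate_score:.4f}", c.status, c.reason])
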