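"""Readers and writers for the study file formats.

* VCF 4.2 with per-sample GT fields; functional annotations either inline as
  INFO keys (GENE, FCLASS, SIFT_D, PPH2, AF_ESPEA, AF_ESPALL, AF_1KGEA,
  AF_1KGALL) or in a sidecar TSV keyed by ``chrom:pos:ref:alt``.
* Phenotype TSV: sample_id, family_id, sex, age_years, soct_cs.
* Pairs TSV: family_id, sib_a, sib_b.
* PPI edge list: two-column TSV of gene symbols (undirected, self-loops dropped).
* Risk-gene list: one symbol per line.
"""

from __future__ import annotations

import hashlib
from typing import List, Sequence, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import pysam

from .cohorts import PHENOTYPE_COLUMNS
from .filters import GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "read_pairs",
    "write_pairs",
    "read_ppi",
    "write_ppi",
    "read_gene_list",
    "write_gene_list",
    "sha256_of",
    "ANNOTATION_COLUMNS",
]

#: variant-table annotation columns <-> VCF INFO keys
_INFO_OF = {
    "gene": "GENE",
    "functional_class": "FCLASS",
    "sift_damage": "SIFT_D",
    "polyphen": "PPH2",
    "af_espEA": "AF_ESPEA",
    "af_espALL": "AF_ESPALL",
    "af_1kgEA": "AF_1KGEA",
    "af_1kgALL": "AF_1KGALL",
}
ANNOTATION_COLUMNS = tuple(_INFO_OF)
_FLOAT_COLUMNS = tuple(c for c in ANNOTATION_COLUMNS if c not in ("gene", "functional_class"))

VARIANT_COLUMNS = ("key", "chrom", "pos", "ref", "alt") + ANNOTATION_COLUMNS


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _vcf_header(chroms: Sequence[str], samples: Sequence[str], with_annotations: bool) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in chroms:
        header.contigs.add(chrom)
    if with_annotations:
        header.info.add("GENE", 1, "String", "Gene symbol")
        header.info.add("FCLASS", 1, "String", "Functional class")
        header.info.add("SIFT_D", 1, "Float", "SIFT damaging-confidence score")
        header.info.add("PPH2", 1, "Float", "PolyPhen-2 probability damaging")
        header.info.add("AF_ESPEA", 1, "Float", "ESP European-American allele frequency")
        header.info.add("AF_ESPALL", 1, "Float", "ESP all-samples allele frequency")
        header.info.add("AF_1KGEA", 1, "Float", "1000 Genomes European allele frequency")
        header.info.add("AF_1KGALL", 1, "Float", "1000 Genomes all-samples allele frequency")
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in samples:
        header.add_sample(sample)
    return header


_GT_OF = {0: (0, 0), 1: (0, 1), 2: (1, 1), GenotypeMatrix.MISSING: (None, None)}


def _chrom_sort_key(c: str):
    c = str(c)
    return (0, int(c)) if c.isdigit() else (1, c)


def write_vcf(
    variants: pd.DataFrame,
    genotypes: GenotypeMatrix,
    path,
    annotation: str = "info",
    sidecar_path=None,
) -> None:
    """Write the variant table + genotype matrix as an uncompressed VCF 4.2.

    ``annotation="info"`` stores annotations in INFO keys;
    ``annotation="sidecar"`` writes a plain VCF and a sidecar annotation TSV
    at ``sidecar_path``.
    """
    if annotation not in ("info", "sidecar"):
        raise ValueError(f"unknown annotation dialect {annotation!r}")
    if annotation == "sidecar" and sidecar_path is None:
        raise ValueError("sidecar dialect requires sidecar_path")
    if list(variants["key"]) != genotypes.variant_keys:
        raise ValueError("variant table and genotype matrix keys differ")
    chroms = sorted({str(c) for c in variants["chrom"]}, key=_chrom_sort_key) or ["1"]
    header = _vcf_header(chroms, genotypes.samples, with_annotations=annotation == "info")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i, row in enumerate(variants.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(row.chrom), start=int(row.pos) - 1, alleles=(row.ref, row.alt)
            )
            if annotation == "info":
                rec.info["GENE"] = str(row.gene)
                rec.info["FCLASS"] = str(row.functional_class)
                for col, key in _INFO_OF.items():
                    if col in ("gene", "functional_class"):
                        continue
                    val = getattr(row, col)
                    if val is not None and not pd.isna(val):
                        rec.info[key] = float(val)
            gts = genotypes.data[i]
            for sample, g in zip(genotypes.samples, gts):
                rec.samples[sample]["GT"] = _GT_OF[int(g)]
            vcf.write(rec)
    if annotation == "sidecar":
        side = variants[["key", *ANNOTATION_COLUMNS]]
        side.to_csv(sidecar_path, sep="\t", index=False)


def read_vcf(path, sidecar_path=None) -> Tuple[pd.DataFrame, GenotypeMatrix]:
    """Read a study VCF back into a variant table and genotype matrix.

    Annotations come from the INFO fields when present, otherwise from the
    sidecar TSV; a VCF with neither yields NaN annotation columns.
    """
    rows: List[dict] = []
    gt_rows: List[np.ndarray] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        has_info = "GENE" in vcf.header.info
        for rec in vcf:
            alt = rec.alts[0] if rec.alts else "."
            row = {
                "key": f"{rec.contig}:{rec.pos}:{rec.ref}:{alt}",
                "chrom": str(rec.contig),
                "pos": int(rec.pos),
                "ref": rec.ref,
                "alt": alt,
            }
            if has_info:
                row["gene"] = rec.info.get("GENE")
                row["functional_class"] = rec.info.get("FCLASS")
                for col, key in _INFO_OF.items():
                    if col in ("gene", "functional_class"):
                        continue
                    val = rec.info.get(key)
                    row[col] = float(val) if val is not None else np.nan
            rows.append(row)
            gts = np.empty(len(samples), dtype=np.int8)
            for j, sample in enumerate(samples):
                alleles = rec.samples[sample].get("GT", (None, None))
                if alleles is None or any(a is None for a in alleles):
                    gts[j] = GenotypeMatrix.MISSING
                else:
                    gts[j] = sum(alleles)
            gt_rows.append(gts)
    variants = pd.DataFrame(rows)
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t", dtype={"key": str})
        variants = variants.merge(side, on="key", how="left", suffixes=("", "_side"))
    for col in ANNOTATION_COLUMNS:
        if col not in variants.columns:
            variants[col] = np.nan
    variants = variants.reindex(columns=list(VARIANT_COLUMNS))
    data = (
        np.vstack(gt_rows) if gt_rows else np.empty((0, len(samples)), dtype=np.int8)
    )
    return variants, GenotypeMatrix(list(variants["key"]), samples, data)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "family_id": str})
    missing = set(PHENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"family_id", "sib_a", "sib_b"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pairs table missing columns {sorted(missing)}")
    return df


def write_pairs(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_ppi(path) -> nx.Graph:
    """Two-column TSV edge list -> simple undirected graph (self-loops dropped)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: PPI edge list needs two columns")
    graph = nx.Graph()
    a, b = df.columns[:2]
    for u, v in zip(df[a], df[b]):
        if u != v:
            graph.add_edge(u, v)
    return graph


def write_ppi(graph: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v)) for u, v in graph.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> List[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
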