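"""Reading and writing the on-disk formats: VCFv4.2 genotype files plus TSV
tables for ground-truth ancestry fractions and the annotation catalog.

VCFs are written as plain text with a GT FORMAT field ("./." for missing,
unphased) and read back through cyvcf2. Only biallelic SNV-style records are
accepted on read; others are counted and skipped.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .simulate import Annotation, AnnotationCatalog, TrueQ, ANCESTRY_COMPONENTS
from .variants import MISSING, GenotypeMatrix, VariantKey

logger = logging.getLogger(__name__)

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
# cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
_GT_TYPE_TO_DOSAGE = np.array([0, 1, MISSING, 2], dtype=np.int8)


def write_vcf(g: GenotypeMatrix, path: str | Path, source: str = "admixscreen") -> Path:
    """Write a genotype matrix as uncompressed VCFv4.2, sorted by genomic
    coordinate (required by downstream indexed readers)."""
    path = Path(path)
    order = sorted(range(g.n_sites), key=lambda j: g.sites[j].sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for chrom in _chrom_order(g.sites):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.samples) + "\n")
        for j in order:
            site = g.sites[j]
            gts = "\t".join(_GT_STRINGS[int(v)] for v in g.values[:, j])
            row = f"{site.chrom}\t{site.pos}\t{site}\t{site.ref}\t{site.alt}\t.\t.\t.\tGT"
            fh.write(row + ("\t" + gts if g.n_samples else "") + "\n")
    return path


def _chrom_order(sites: list[VariantKey]) -> list[str]:
    seen: dict[str, tuple] = {}
    for s in sites:
        seen.setdefault(s.chrom, s.sort_key[:3])
    return sorted(seen, key=seen.get)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix of alt-allele dosages.

    Non-biallelic or non-SNV-compatible records are skipped with a logged
    count; duplicate keys within one file keep the first record seen.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    sites: list[VariantKey] = []
    rows: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.ALT[0] or rec.ALT[0] == rec.REF:
            n_skipped += 1
            continue
        key = VariantKey.from_record(rec.CHROM, rec.POS, rec.REF, rec.ALT[0])
        if key in seen:
            n_skipped += 1
            continue
        seen.add(key)
        sites.append(key)
        rows.append(_GT_TYPE_TO_DOSAGE[rec.gt_types])
    vcf.close()
    if n_skipped:
        logger.info("read_vcf(%s): skipped %d non-biallelic/duplicate records", path, n_skipped)
    values = (
        np.column_stack(rows).astype(np.int8)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, values=values)


def write_q_tsv(q: np.ndarray, samples: list[str], path: str | Path,
                cluster: np.ndarray | None = None,
                cluster_name: list[str] | None = None) -> Path:
    """Write ancestry fractions (and optional cluster assignment) as TSV."""
    path = Path(path)
    df = pd.DataFrame(q, columns=list(ANCESTRY_COMPONENTS))
    df.insert(0, "sample", samples)
    if cluster is not None:
        df["cluster"] = cluster
    if cluster_name is not None:
        df["cluster_name"] = cluster_name
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_q_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df[list(ANCESTRY_COMPONENTS)].to_numpy(), df["sample"].astype(str).tolist()


def write_true_q_tsv(true_q: TrueQ, samples: list[str], path: str | Path) -> Path:
    return write_q_tsv(true_q.q, samples, path, cluster=true_q.true_cluster)


def write_annotations_tsv(catalog: AnnotationCatalog, path: str | Path) -> Path:
    path = Path(path)
    rows = [
        {
            "variant": str(key),
            "clinvar_class": ann.clinvar_class,
            "pharm_level": ann.pharm_level,
            "label": ann.label,
        }
        for key, ann in sorted(catalog.entries.items(), key=lambda kv: kv[0].sort_key)
    ]
    pd.DataFrame(rows, columns=["variant", "clinvar_class", "pharm_level", "label"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_annotations_tsv(path: str | Path) -> AnnotationCatalog:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    catalog = AnnotationCatalog()
    for row in df.itertuples(index=False):
        catalog.set(
            VariantKey.from_string(row.variant),
            Annotation(
                clinvar_class=row.clinvar_class,
                pharm_level=str(row.pharm_level),
                label=str(row.label),
            ),
        )
    return catalog
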