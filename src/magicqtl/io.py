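"""Readers and writers for every format the pipeline touches.

Conventions
-----------
* Genetic map: TSV with columns marker, chrom, cM, bp.
* Genotypes: VCF (founders as the first eight samples, then lines; GT-only,
  homozygous calls; heterozygous or missing calls read back as missing
  because lines are treated as inbred) or a plain TSV matrix.
* Phenotypes: long CSV (line, experiment, treatment, replicate, trait,
  value); UTF-8, comma-separated, '.' decimal, missing as empty field.
* Variants: VCF with an ``ANN=gene|effect`` INFO key (founder alleles as
  the eight sample genotypes), or TSV.
* Genes: BED (0-based half-open; name in column 4) or GFF3 (1-based closed
  on disk, converted to half-open on read; annotation in ``Note``).

Every writer/reader pair round-trips its in-memory object exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .gmap import GeneticMap
from .pheno import PhenotypeTable
from .qtl import QtlRecord
from .simulate import (
    FOUNDER_NAMES,
    FounderGenotypes,
    GeneSet,
    VariantTable,
    MISSING,
)

__all__ = [
    "FormatError",
    "write_genotype_vcf",
    "read_genotype_vcf",
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_variants_vcf",
    "read_variants_vcf",
    "write_variants_tsv",
    "read_variants_tsv",
    "write_genes_bed",
    "read_genes_bed",
    "write_genes_gff3",
    "read_genes_gff3",
    "write_qtl_table",
    "read_qtl_table",
]

REF, ALT = "A", "C"  # fixed letter coding for the biallelic 0/1 alleles


class FormatError(ValueError):
    """Malformed input file; message carries file and position."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _gt(code: int) -> str:
    if code == 0:
        return "0/0"
    if code == 1:
        return "1/1"
    return "./."


def write_genotype_vcf(
    path,
    gmap: GeneticMap,
    founders: FounderGenotypes,
    line_genotypes: pd.DataFrame,
) -> None:
    """Founder + line genotypes as a GT-only VCF (founders first)."""
    lines = list(line_genotypes.index)
    samples = list(founders.founders) + lines
    geno = np.vstack(
        [founders.alleles, line_genotypes[list(gmap.markers)].to_numpy(np.int8)]
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=magicqtl\n")
        for chrom in gmap.chromosomes:
            length = int(gmap.chrom_table(chrom)["bp"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        t = gmap.table
        for j in range(len(t)):
            row = t.iloc[j]
            gts = "\t".join(_gt(int(g)) for g in geno[:, j])
            fh.write(
                f"{row['chrom']}\t{int(row['bp'])}\t{row['marker']}\t{REF}\t{ALT}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotype_vcf(path, gmap: GeneticMap) -> tuple[FounderGenotypes, pd.DataFrame]:
    """Read the VCF written by :func:`write_genotype_vcf`.

    The first eight samples are founders.  Heterozygous calls are recoded
    missing (lines assumed inbred); records with more than one ALT allele
    are rejected with their position.
    """
    vcf = VCF(str(path))
    samples = vcf.samples
    if len(samples) < 8:
        raise FormatError(f"{path}: fewer than 8 samples (founders)")
    markers, columns = [], []
    for rec in vcf:
        if rec.ALT and len(rec.ALT) > 1:
            raise FormatError(f"{path}: non-biallelic record at {rec.CHROM}:{rec.POS}")
        code = np.full(len(samples), MISSING, dtype=np.int8)
        gt = rec.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        code[gt == 0] = 0
        code[gt == 3] = 1
        markers.append(rec.ID)
        columns.append(code)
    g = np.column_stack(columns)
    order = [markers.index(m) for m in gmap.markers]
    g = g[:, order]
    founders = FounderGenotypes(founders=tuple(samples[:8]), alleles=g[:8])
    line_df = pd.DataFrame(
        g[8:], index=pd.Index(samples[8:], name="line"), columns=gmap.markers
    )
    return founders, line_df


def write_genotype_tsv(path, genotypes: pd.DataFrame) -> None:
    genotypes.to_csv(path, sep="\t", index_label="line")


def read_genotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="line")
    return df.astype(np.int8)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def write_phenotypes_csv(path, table: PhenotypeTable) -> None:
    table.data.to_csv(path, index=False)


def read_phenotypes_csv(path, log_traits=()) -> PhenotypeTable:
    df = pd.read_csv(
        path,
        dtype={"line": str, "experiment": str, "treatment": str, "trait": str},
    )
    required = ["line", "experiment", "treatment", "replicate", "trait", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return PhenotypeTable(data=df, log_traits=frozenset(log_traits))


# ---------------------------------------------------------------------------
# variants and genes
# ---------------------------------------------------------------------------


def write_variants_vcf(path, variants: VariantTable) -> None:
    """Variant table as VCF; founder alleles as sample GTs, ANN=gene|effect."""
    t = variants.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=magicqtl\n")
        for chrom in t["chrom"].unique():
            length = int(t.loc[t["chrom"] == chrom, "pos"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=1,Type=String,Description="gene|effect_class">\n'
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(variants.founders) + "\n")
        for i, row in enumerate(t.itertuples(index=False)):
            gts = "\t".join(_gt(int(getattr(row, f))) for f in variants.founders)
            fh.write(
                f"{row.chrom}\t{int(row.pos)}\tv{i + 1:06d}\t{REF}\t{ALT}\t.\t.\t"
                f"ANN={row.gene}|{row.effect}\tGT\t{gts}\n"
            )


def read_variants_vcf(path) -> VariantTable:
    vcf = VCF(str(path))
    founders = tuple(vcf.samples)
    if len(founders) != 8:
        raise FormatError(f"{path}: variant VCF must carry exactly 8 founder samples")
    rows = []
    for rec in vcf:
        if rec.ALT and len(rec.ALT) > 1:
            raise FormatError(f"{path}: non-biallelic record at {rec.CHROM}:{rec.POS}")
        ann = rec.INFO.get("ANN")
        if ann is None or "|" not in ann:
            raise FormatError(f"{path}: missing ANN INFO at {rec.CHROM}:{rec.POS}")
        gene, effect = ann.split("|", 1)
        code = np.full(8, MISSING, dtype=np.int8)
        gt = rec.gt_types
        code[gt == 0] = 0
        code[gt == 3] = 1
        rows.append((rec.CHROM, rec.POS, *code.tolist(), gene, effect))
    df = pd.DataFrame(rows, columns=["chrom", "pos", *founders, "gene", "effect"])
    return VariantTable(table=df, founders=founders)


def write_variants_tsv(path, variants: VariantTable) -> None:
    variants.table.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path, founders: tuple[str, ...] = FOUNDER_NAMES) -> VariantTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "effect": str})
    return VariantTable(table=df, founders=founders)


def write_genes_bed(path, genes: GeneSet) -> None:
    """Genes as BED4 (0-based half-open); the annotation text is not kept."""
    t = genes.table[["chrom", "start", "end", "gene"]]
    t.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path) -> GeneSet:
    import pyranges as pr

    gr = pr.read_bed(str(path)).df
    df = pd.DataFrame(
        {
            "gene": gr["Name"].astype(str),
            "chrom": gr["Chromosome"].astype(str),
            "start": gr["Start"].astype(int),
            "end": gr["End"].astype(int),
            "annotation": "",
        }
    )
    return GeneSet(table=df)


def write_genes_gff3(path, genes: GeneSet) -> None:
    """Genes as GFF3 gene features; annotation in the Note attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.table.itertuples(index=False):
            attrs = f"ID={row.gene}"
            if row.annotation:
                attrs += f";Note={row.annotation}"
            fh.write(
                f"{row.chrom}\tmagicqtl\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t{attrs}\n"
            )


def read_genes_gff3(path) -> GeneSet:
    import pyranges as pr

    gr = pr.read_gff3(str(path)).df
    gr = gr[gr["Feature"] == "gene"]
    note = gr["Note"] if "Note" in gr.columns else ""
    df = pd.DataFrame(
        {
            "gene": gr["ID"].astype(str),
            "chrom": gr["Chromosome"].astype(str),
            "start": gr["Start"].astype(int),  # pyranges converts to 0-based
            "end": gr["End"].astype(int),
            "annotation": note if isinstance(note, str) else note.fillna("").astype(str),
        }
    )
    return GeneSet(table=df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# QTL tables
# ---------------------------------------------------------------------------


def write_qtl_table(path, records: list[QtlRecord], founders: tuple[str, ...]) -> None:
    rows = [r.to_row(founders) for r in records]
    cols = (
        ["trait", "context", "chrom", "peak_cM", "peak_lod", "ci_low_cM", "ci_high_cM",
         "ci_low_bp", "ci_high_bp", "pve", "n"]
        + [f"eff_{f}" for f in founders]
        + [f"eff_centered_{f}" for f in founders]
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_qtl_table(path, founders: tuple[str, ...] = FOUNDER_NAMES) -> list[QtlRecord]:
    df = pd.read_csv(path, dtype={"trait": str, "context": str, "chrom": str})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            QtlRecord(
                trait=row.trait,
                context=row.context,
                chrom=row.chrom,
                peak_cM=float(row.peak_cM),
                peak_lod=float(row.peak_lod),
                ci_low_cM=float(row.ci_low_cM),
                ci_high_cM=float(row.ci_high_cM),
                ci_low_bp=int(row.ci_low_bp),
                ci_high_bp=int(row.ci_high_bp),
                effects=tuple(float(getattr(row, f"eff_{f}")) for f in founders),
                pve=float(row.pve),
                n=int(row.n),
            )
        )
    return records
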