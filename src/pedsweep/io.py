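"""Readers and writers for the on-disk formats used by the pipeline.

VCF is written directly (v4.2, GT-only) because the panel is homozygous
biallelic SNPs with invented alleles; reading goes through :mod:`cyvcf2`
so arbitrary conforming VCFs are accepted as well.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from pedsweep.core import MAP_COLUMNS, GeneticMap, GenotypeMatrix

# Invented nucleotides: REF is always parent-1's allele by simulator convention.
_REF_ALLELE = "A"
_ALT_ALLELE = "T"

_GT_STRINGS = {-1: "./.", 0: "0/0", 1: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike, chrom_lens: dict[str, int] | None = None) -> None:
    """Write a GT-only VCF v4.2. Contig lengths default to the last marker position."""
    path = Path(path)
    if chrom_lens is None:
        chrom_lens = {
            c: int(gm.pos_bp[gm.chrom_mask(c)].max()) for c in gm.chromosomes
        }
    lines = ["##fileformat=VCFv4.2", "##source=pedsweep"]
    for chrom in gm.chromosomes:
        lines.append(f"##contig=<ID={chrom},length={chrom_lens[chrom]}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples)
    )
    for i in range(gm.n_markers):
        gts = "\t".join(_GT_STRINGS[int(g)] for g in gm.calls[i])
        lines.append(
            f"{gm.chrom[i]}\t{gm.pos_bp[i]}\t{gm.marker_id[i]}\t"
            f"{_REF_ALLELE}\t{_ALT_ALLELE}\t.\tPASS\t.\tGT\t{gts}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: str | os.PathLike, map_tsv: str | os.PathLike | None = None) -> GenotypeMatrix:
    """Read homozygous biallelic calls from a VCF.

    Heterozygous calls are rejected (the pipeline models inbred material).
    If ``map_tsv`` is given, genetic positions are joined from it; otherwise
    pos_cM is set to NaN.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chroms, pos, ids, rows = [], [], [], []
    for var in vcf:
        gt = np.asarray(var.gt_types)  # 0=hom-ref, 1=het, 2=hom-alt, 3=missing
        if np.any(gt == 1):
            raise ValueError(f"heterozygous call at {var.CHROM}:{var.POS}; inbred lines expected")
        calls = np.where(gt == 3, -1, np.where(gt == 2, 1, 0)).astype(np.int8)
        chroms.append(var.CHROM)
        pos.append(var.POS)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        rows.append(calls)
    vcf.close()
    if not rows:
        raise ValueError(f"no variants in {path}")
    pos = np.asarray(pos, dtype=np.int64)
    pos_cm = np.full(len(pos), np.nan)
    if map_tsv is not None:
        mp = read_map(map_tsv).frame.set_index(["chrom", "pos_bp"])["pos_cM"]
        pos_cm = np.array(
            [mp.get((c, int(p)), np.nan) for c, p in zip(chroms, pos)], dtype=float
        )
    return GenotypeMatrix(
        samples=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=pos,
        pos_cM=pos_cm,
        marker_id=ids,
        calls=np.vstack(rows),
    )


def write_map(map_frame: pd.DataFrame, path: str | os.PathLike) -> None:
    map_frame[MAP_COLUMNS].to_csv(path, sep="\t", index=False)


def read_map(path: str | os.PathLike) -> GeneticMap:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GeneticMap(frame)


def write_phenotypes(pheno: pd.DataFrame, path: str | os.PathLike) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"line": str})
    for col in ("line", "env", "rep"):
        if col not in df.columns:
            raise ValueError(f"phenotype table missing column {col!r}")
    return df


def write_truth(truth, path: str | os.PathLike) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_truth_dict(path: str | os.PathLike) -> dict:
    return json.loads(Path(path).read_text())


def write_bed(intervals: list[tuple], path: str | os.PathLike) -> None:
    """Write (chrom, start, end[, name[, score]]) tuples as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = names[: df.shape[1]]
    return df


def read_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene intervals from BED or GFF3 into (chrom, start, end, gene_id).

    GFF3 rows other than gene features are ignored; malformed records are
    skipped and counted in the DataFrame attrs.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3", ".gtf"}:
        rows, skipped = [], 0
        for raw in path.read_text().splitlines():
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 9:
                skipped += 1
                continue
            if parts[2].lower() != "gene":
                continue
            try:
                start, end = int(parts[3]) - 1, int(parts[4])  # GFF3 is 1-based closed
            except ValueError:
                skipped += 1
                continue
            gene_id = None
            for attr in parts[8].split(";"):
                key, _, val = attr.strip().partition("=")
                if key in ("ID", "gene_id", "Name"):
                    gene_id = val
                    break
            if gene_id is None:
                skipped += 1
                continue
            rows.append((parts[0], start, end, gene_id))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])
        df.attrs["n_skipped"] = skipped
        return df
    bed = read_bed(path)
    if "name" not in bed.columns:
        bed["name"] = [f"gene{i}" for i in range(len(bed))]
    df = bed.rename(columns={"name": "gene_id"})[["chrom", "start", "end", "gene_id"]]
    df.attrs["n_skipped"] = 0
    return df
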