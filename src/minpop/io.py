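"""Readers and writers for the standard formats the pipeline touches.

FASTA is read with Biopython, VCF with cyvcf2; tables go through pandas.
Internal coordinates are 0-based half-open everywhere; GFF3 (1-based
inclusive) and VCF (1-based) are converted at the boundary.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataError
from .genotypes import GenotypeMatrix

GFF_COLUMNS = [
    "contig", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


# ----------------------------------------------------------------- FASTA
def write_fasta(contigs: dict, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ----------------------------------------------------------------- GFF3
def write_gff3(genes: pd.DataFrame, path) -> None:
    """Write gene/mRNA/CDS rows for single-CDS gene models.

    ``genes`` columns: gene_id, contig, start, end (0-based half-open),
    strand, product.
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            s1, e1 = int(row.start) + 1, int(row.end)  # 1-based inclusive
            base = f"{row.contig}\tminpop\t"
            tail = f"\t{s1}\t{e1}\t.\t{row.strand}\t"
            fh.write(base + "gene" + tail + f".\tID={row.gene_id};product={row.product}\n")
            fh.write(base + "mRNA" + tail + f".\tID={row.gene_id}.t1;Parent={row.gene_id}\n")
            fh.write(base + "CDS" + tail + f"0\tID={row.gene_id}.cds;Parent={row.gene_id}.t1\n")


def _attr(attributes: pd.Series, key: str) -> pd.Series:
    return attributes.str.extract(rf"(?:^|;){key}=([^;]+)")[0]


def read_gff3(path) -> pd.DataFrame:
    """Return the raw feature table with 0-based half-open coordinates."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=GFF_COLUMNS, header=None, dtype={"contig": str}
    )
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    return df


def gene_table(gff: pd.DataFrame) -> pd.DataFrame:
    """Collapse a GFF3 feature frame back to the internal gene table."""
    genes = gff[gff["type"] == "gene"].copy()
    genes["gene_id"] = _attr(genes["attributes"], "ID")
    genes["product"] = _attr(genes["attributes"], "product").fillna("")
    return genes[["gene_id", "contig", "start", "end", "strand", "product"]].reset_index(
        drop=True
    )


def cds_table(gff: pd.DataFrame) -> pd.DataFrame:
    """CDS features with integer phase, for degeneracy annotation."""
    cds = gff[gff["type"] == "CDS"].copy()
    cds["phase"] = cds["phase"].replace(".", "0").astype(int)
    cds["cds_id"] = _attr(cds["attributes"], "ID")
    return cds[["cds_id", "contig", "start", "end", "strand", "phase"]].reset_index(drop=True)


# ----------------------------------------------------------------- VCF
def write_vcf(gm: GenotypeMatrix, path, contig_lengths: dict | None = None) -> None:
    """Write a minimal GT-only VCF 4.2."""
    lut = np.empty(36, dtype=object)
    syms = ["."] + [str(a) for a in range(5)]
    for i, a in enumerate(syms):
        for j, b in enumerate(syms):
            if i * 6 + j < 36:
                lut[i * 6 + j] = f"{a}/{b}"
    codes = (gm.gt[:, :, 0].astype(np.int16) + 1) * 6 + (gm.gt[:, :, 1].astype(np.int16) + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=minpop\n")
        names = gm.contig_names()
        for c in names:
            ln = (contig_lengths or {}).get(c)
            fh.write(f"##contig=<ID={c}" + (f",length={ln}" if ln else "") + ">\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for i in range(gm.n_sites):
            ref = gm.alleles[i][0]
            alts = ",".join(gm.alleles[i][1:]) or "."
            fh.write(
                f"{gm.contig[i]}\t{gm.pos[i] + 1}\t.\t{ref}\t{alts}\t.\tPASS\t.\tGT\t"
                + "\t".join(lut[codes[i]])
                + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    contig, pos, alleles, gts = [], [], [], []
    for v in vcf:
        contig.append(v.CHROM)
        pos.append(v.POS - 1)
        alleles.append(tuple([v.REF] + list(v.ALT)))
        g = np.asarray(v.genotypes, dtype=np.int8)
        gts.append(g[:, :2])
    vcf.close()
    if not pos:
        raise DataError(f"no variant records in {path}")
    return GenotypeMatrix(
        contig=np.array(contig, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        alleles=alleles,
        gt=np.stack(gts),
        samples=samples,
    )


# ----------------------------------------------------------------- tables
def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(df: pd.DataFrame, path, cols=("contig", "start", "end", "name")) -> None:
    use = [c for c in cols if c in df.columns]
    df[use].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    df.columns = ["contig", "start", "end", "name"][: df.shape[1]] + [
        f"extra{i}" for i in range(max(0, df.shape[1] - 4))
    ]
    return df


def mask_to_bed(mask: dict) -> pd.DataFrame:
    """Convert a per-contig boolean mask to BED intervals (0-based half-open)."""
    rows = []
    for c, arr in mask.items():
        arr = np.asarray(arr, dtype=bool)
        if not arr.any():
            continue
        flat = np.flatnonzero(np.diff(np.concatenate(([0], arr.view(np.int8), [0]))))
        for s, e in zip(flat[::2], flat[1::2]):
            rows.append((c, int(s), int(e)))
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


def bed_to_mask(bed: pd.DataFrame, contig_lengths: dict) -> dict:
    mask = {c: np.zeros(int(n), dtype=bool) for c, n in contig_lengths.items()}
    for row in bed.itertuples(index=False):
        if row.contig in mask:
            mask[row.contig][int(row.start) : int(row.end)] = True
    return mask


def sha256_of(path) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


_IR_NAME_RE = re.compile(r"^[A-Za-z0-9_.\-]+$")


def read_ir_regions(path) -> pd.DataFrame:
    """Gene regions as BED (contig, start, end, name) or YAML list of mappings."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        with open(path) as fh:
            entries = yaml.safe_load(fh)
        df = pd.DataFrame(entries)
        df = df.rename(columns={"gene": "name"})
        return df[["contig", "start", "end", "name"]]
    bed = read_bed(path)
    if "name" not in bed.columns:
        raise DataError("IR region BED needs a 4th (gene name) column")
    return bed[["contig", "start", "end", "name"]]
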