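"""Readers and writers for the formats the pipeline touches.

Conventions: TSV, UTF-8, '.' for missing values, no quoting; genomic
coordinates are 1-based inclusive (VCF/MAF convention).  Every table
written by the pipeline carries '#'-prefixed header lines recording the
tool version, seed and a parameter hash, so a results directory is
self-describing and reruns are byte-comparable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from skbio.tree import TreeNode

from clonmet.expression import GeneSet
from clonmet.somatic_filter import VARIANT_COLUMNS

__all__ = [
    "params_hash",
    "read_gmt",
    "read_matrix_tsv",
    "read_table_tsv",
    "read_variant_table",
    "write_matrix_tsv",
    "write_newick",
    "write_table_tsv",
    "write_variant_table",
    "write_vcf",
]

MISSING = "."


class FormatError(ValueError):
    """A file does not parse under the expected dialect."""


def params_hash(params: Mapping) -> str:
    """Short stable hash of a parameter mapping (for output headers)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(version: str | None, seed: int | None, phash: str | None) -> list[str]:
    lines = []
    if version is not None:
        lines.append(f"# clonmet {version}")
    if seed is not None:
        lines.append(f"# seed={seed}")
    if phash is not None:
        lines.append(f"# params={phash}")
    return lines


def write_table_tsv(
    df: pd.DataFrame,
    path: str | Path,
    index: bool = False,
    version: str | None = None,
    seed: int | None = None,
    phash: str | None = None,
) -> None:
    """Write a tidy table as commented-header TSV ('.' for missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in _header_lines(version, seed, phash):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, na_rep=MISSING, float_format="%.10g", lineterminator="\n")


def read_table_tsv(path: str | Path, index_col: int | None = None) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", comment="#", na_values=[MISSING], keep_default_na=True, index_col=index_col
    )


def write_matrix_tsv(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    """Write a genes x samples (or variants x samples) matrix, index kept."""
    write_table_tsv(df, path, index=True, **kwargs)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    return read_table_tsv(path, index_col=0)


def write_variant_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    """Write a MAF-lite variant table (validates the canonical columns)."""
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    write_table_tsv(df, path, **kwargs)


def read_variant_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a variant table from MAF-lite TSV or minimal single-sample VCF.

    ``format`` is 'maf-lite-tsv' or 'vcf'; by default it is inferred
    from the file suffix.  VCF records must carry the AD genotype field
    (ref and alt allele depths); positions are 1-based.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz") else "maf-lite-tsv"
    if format == "vcf":
        return _read_vcf(path)
    if format != "maf-lite-tsv":
        raise ValueError(f"unknown variant-table format {format!r}")
    try:
        df = read_table_tsv(path)
    except Exception as exc:  # surface the parser's line information
        raise FormatError(f"{path}: failed to parse as MAF-lite TSV: {exc}") from exc
    missing = [c for c in VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    bad = df.index[(df["ref_count"] < 0) | (df["alt_count"] < 0)]
    if len(bad):
        # +2 for the header line, 1-based; comment lines shift this further
        raise FormatError(f"{path}: negative read counts at data row(s) {list(bad[:5])}")
    return df


def _read_vcf(path: Path) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_names = list(vcf.header.samples)
        if len(sample_names) != 1:
            raise FormatError(f"{path}: expected exactly one sample, found {len(sample_names)}")
        sample = sample_names[0]
        for rec in vcf:
            call = rec.samples[sample]
            ad = call.get("AD")
            if ad is None or ad[0] is None:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} lacks the AD genotype field"
                )
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record {rec.chrom}:{rec.pos} must have exactly one ALT allele"
                )
            ref_count, alt_count = int(ad[0]), int(ad[1])
            if ref_count < 0 or alt_count < 0:
                raise FormatError(f"{path}: negative AD at {rec.chrom}:{rec.pos}")
            info_keys = set(rec.header.info.keys())
            gene = rec.info.get("GENE") if "GENE" in info_keys else None
            rows.append(
                {
                    "patient_id": rec.info.get("PATIENT") if "PATIENT" in info_keys else MISSING,
                    "sample_id": sample,
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "ref_count": ref_count,
                    "alt_count": alt_count,
                    "gene": gene if gene is not None else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def write_vcf(df: pd.DataFrame, path: str | Path) -> None:
    """Write one sample's variants as a minimal VCF with AD allele depths."""
    samples = df["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("minimal VCF output is one sample per file")
    sample = str(samples[0])
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=PATIENT,Number=1,Type=String,Description="Patient identifier">')
    for chrom in pd.unique(df["chrom"]):
        header.contigs.add(str(chrom))
    header.add_sample(sample)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for _, row in df.iterrows():
            rec = out.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,  # pysam start is 0-based
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            if pd.notna(row.get("gene")):
                rec.info["GENE"] = str(row["gene"])
            rec.info["PATIENT"] = str(row["patient_id"])
            rec.samples[sample]["AD"] = (int(row["ref_count"]), int(row["alt_count"]))
            out.write(rec)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT needs name, description, genes")
            name, _desc, *genes = parts
            genes = [g for g in genes if g]
            if not genes:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = GeneSet(name, genes)
    if not sets:
        raise FormatError(f"{path}: no gene sets found")
    return sets


def write_newick(linkage: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Write a sample dendrogram (scipy linkage matrix) as Newick."""
    tree = TreeNode.from_linkage_matrix(linkage, list(labels))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tree.write(str(path))


def load_yaml_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: YAML config must be a mapping")
    return cfg
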