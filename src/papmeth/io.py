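"""Readers and writers for the plain-text formats the pipeline exchanges.

BED coordinates are 0-based half-open throughout; a 1-based annotation can
be converted at the boundary with ``one_based=True`` (logged via warning so
the conversion is visible in run logs).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "read_bed_reads",
    "write_bed_reads",
    "read_tss_annotation",
    "write_tss_annotation",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "read_manifest",
    "write_manifest",
    "read_qmsp",
    "write_qmsp",
    "read_gene_set",
    "write_gene_set",
    "write_truth",
    "read_truth",
]


def write_bed_reads(df: pd.DataFrame, path) -> None:
    """Read starts as 4-column BED (chrom, start, end, name)."""
    out = df[["chrom", "start", "end"]].copy()
    out["name"] = [f"r{i}" for i in range(len(out))]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bed_reads(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"], dtype={0: str, 1: "int64", 2: "int64"},
    )
    return df


def write_tss_annotation(annotation: pd.DataFrame, path) -> None:
    """TSS annotation as BED6: chrom, tss, tss+1, gene|accession, 0, strand."""
    name = annotation["gene_id"].astype(str)
    if "accession" in annotation.columns:
        name = name + "|" + annotation["accession"].astype(str)
    bed = pd.DataFrame(
        {
            "chrom": annotation["chrom"],
            "start": annotation["tss"],
            "end": annotation["tss"] + 1,
            "name": name,
            "score": 0,
            "strand": annotation["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_tss_annotation(path, one_based: bool = False) -> pd.DataFrame:
    bed = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    tss = bed["start"].astype("int64")
    if one_based:
        warnings.warn("converting 1-based annotation to 0-based", stacklevel=2)
        tss = tss - 1
    parts = bed["name"].str.split("|", n=1, expand=True)
    out = pd.DataFrame(
        {"gene_id": parts[0], "chrom": bed["chrom"], "tss": tss, "strand": bed["strand"]}
    )
    if parts.shape[1] > 1 and parts[1].notna().any():
        out["accession"] = parts[1]
    return out


def write_matrix_tsv(matrix: pd.DataFrame, path, index_name: str = "feature") -> None:
    m = matrix.copy()
    m.index.name = m.index.name or index_name
    m.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_qmsp(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_qmsp(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "cp_gene", "cp_ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: qMSP table missing columns {sorted(missing)}")
    return df


def write_gene_set(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def read_gene_set(path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_truth(truth, path) -> None:
    payload = {
        "marker_genes": list(truth.marker_genes),
        "effects": truth.effects,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_truth(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
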