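"""Tab-separated readers/writers, gene-set formats and configuration.

All tables are TSV with header rows. Gene sets are accepted either as GMT
(name <tab> annotation <tab> gene...) or one gene per line. Mutation
tables are accepted either with native column names (sample, gene,
variant_class, ...) or with standard MAF column names, which are mapped on
read.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

MAF_COLUMN_MAP = {
    "Tumor_Sample_Barcode": "sample",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_class",
}

MAF_CLASS_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift_insertion",
    "Frame_Shift_Del": "frameshift_deletion",
    "In_Frame_Ins": "inframe_insertion",
    "In_Frame_Del": "inframe_deletion",
    "Splice_Site": "splice_site",
    "Silent": "silent",
}


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Samples x genes matrix with the sample id in the first column."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=True, index_label="sample")


def read_mutations(path: str | Path) -> pd.DataFrame:
    """Read a mutation table, accepting native or MAF column names."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns=MAF_COLUMN_MAP)
    for col in ("sample", "gene", "variant_class"):
        if col not in df.columns:
            raise ValueError(
                f"mutation table {path} is missing required column {col!r} "
                f"(or its MAF equivalent)"
            )
    df["variant_class"] = df["variant_class"].map(
        lambda v: MAF_CLASS_MAP.get(v, v)
    )
    if "ndamage" not in df.columns:
        df["ndamage"] = float("nan")
    if "in_mononucleotide_repeat" not in df.columns:
        df["in_mononucleotide_repeat"] = False
    return df


def read_gene_list(path: str | Path) -> list[str]:
    """One gene per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> annotation <tab> gene1 <tab> gene2 ..."""
    modules: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
        modules[parts[0]] = [g for g in parts[2:] if g]
    return modules


def write_gmt(modules: Mapping[str, list[str]], path: str | Path,
              annotations: Mapping[str, str] | None = None) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for name, genes in modules.items():
        ann = (annotations or {}).get(name, "na")
        lines.append("\t".join([name, ann, *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
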