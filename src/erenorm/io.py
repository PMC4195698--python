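"""Plain-text interchange: TSV tables and FASTA sequence sets."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "read_cq_tsv",
    "write_cq_tsv",
    "read_quantities_tsv",
    "write_quantities_tsv",
    "read_efficiency_tsv",
    "write_efficiency_tsv",
    "read_ranking_tsv",
    "read_fasta",
    "write_fasta",
]

CQ_COLUMNS = ["sample", "group", "target", "replicate", "cq"]


def read_cq_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long-form Cq table (sample, group, target, replicate, cq)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CQ_COLUMNS if c not in df.columns and c != "replicate"]
    if missing:
        raise ValueError(f"Cq table missing columns: {missing}")
    return df


def write_cq_tsv(cq: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    cq.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_quantities_tsv(q: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x targets relative-quantity matrix with group labels."""
    out = q.copy()
    groups = q.attrs.get("groups")
    if groups is not None:
        out.insert(0, "group", pd.Series(groups).reindex(q.index))
    out.index.name = "sample"
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", float_format="%.12g")


def read_quantities_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    groups = None
    if "group" in df.columns:
        groups = df.pop("group")
    df.attrs["groups"] = groups
    return df


def write_efficiency_tsv(table: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_efficiency_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "target" not in df.columns:
        raise ValueError("efficiency table requires a 'target' column")
    return df


def read_ranking_tsv(path: str | Path) -> tuple[list[str], dict[str, float]]:
    """Read a stability-ranking table into (ordered targets, M-values)."""
    df = pd.read_csv(path, sep="\t")
    if "target" not in df.columns:
        raise ValueError("ranking table requires a 'target' column")
    order = df["target"].astype(str).tolist()
    weights = (
        dict(zip(order, df["M_final"].astype(float))) if "M_final" in df.columns else {}
    )
    return order, weights


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in items]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")
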